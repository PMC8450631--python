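"""Optimal virulence for a parasite shared across several host species.

The parasite expresses a single virulence level ``v`` in every host (no
plastic, host-specific adjustment).  In host class *i* its transmission
payoff follows a saturating trade-off

    w_i(v) = b_i * v**s_i / (mu_i + v),       0 < s_i < 1,

where higher exploitation (``v``) raises transmission (numerator) but
shortens infections (denominator): ``mu_i`` is the background rate at which
infections end for reasons other than virulence, ``b_i`` scales
transmission, and ``s_i`` controls how quickly returns on exploitation
saturate.  The form is unimodal with the closed-form single-host optimum

    v*_i = s_i * mu_i / (1 - s_i),

which makes it analytically checkable while reproducing the qualitative
behaviour of multi-host virulence theory: a shared strategy settles at an
intermediate virulence, weighted by each host's relative contribution
``rho_i`` to the total force of infection, optimal in none of the hosts
individually, and skewed towards the single-host optimum of the host class
contributing most new infections.  Removing a host re-normalizes the
remaining contributions and shifts the joint optimum towards the survivors'
optima.

The trade-off is an interchangeable callable: :func:`joint_optimum` only
assumes per-host fitness functions that vanish at ``v = 0`` and decay for
large ``v``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Set

import numpy as np
from scipy.optimize import minimize_scalar


class VirulenceError(ValueError):
    pass


@dataclass(frozen=True)
class HostClass:
    """One host species/clade in a multi-host system.

    rho : relative contribution to total force of infection (>= 0;
          normalized across the system)
    mu  : background loss rate of infections (per unit time, > 0)
    b   : transmission scale (> 0)
    s   : trade-off exponent (0 < s < 1)
    """

    id: str
    rho: float
    mu: float
    b: float = 1.0
    s: float = 0.5

    def __post_init__(self):
        if self.rho < 0:
            raise VirulenceError(f"host {self.id!r}: rho must be >= 0")
        if self.mu <= 0:
            raise VirulenceError(f"host {self.id!r}: mu must be > 0")
        if self.b <= 0:
            raise VirulenceError(f"host {self.id!r}: b must be > 0")
        if not 0 < self.s < 1:
            raise VirulenceError(f"host {self.id!r}: s must be in (0, 1)")


def host_fitness(host: HostClass, v: float) -> float:
    """Transmission payoff w(v) = b * v^s / (mu + v); 0 at v = 0, unimodal
    with an interior maximum, -> 0 as v -> infinity."""
    if np.any(np.asarray(v) < 0):
        raise VirulenceError("virulence must be >= 0")
    v = np.asarray(v, dtype=float)
    w = host.b * np.power(v, host.s) / (host.mu + v)
    return float(w) if np.isscalar(v) or v.ndim == 0 else w


def single_host_optimum(host: HostClass) -> float:
    """Closed-form argmax of :func:`host_fitness`: v* = s*mu/(1-s)."""
    return host.s * host.mu / (1.0 - host.s)


@dataclass
class MultiHostSystem:
    """A set of host classes sharing one parasite with a single virulence
    strategy.  rho values are normalized to sum to 1 at construction."""

    hosts: List[HostClass]

    def __post_init__(self):
        if not self.hosts:
            raise VirulenceError("system needs at least one host class")
        ids = [h.id for h in self.hosts]
        if len(set(ids)) != len(ids):
            raise VirulenceError("duplicate host ids")
        total = sum(h.rho for h in self.hosts)
        if total <= 0:
            raise VirulenceError("rho values must have a positive sum")
        if abs(total - 1.0) > 1e-9:
            self.hosts = [replace(h, rho=h.rho / total) for h in self.hosts]

    def host(self, hid: str) -> HostClass:
        for h in self.hosts:
            if h.id == hid:
                return h
        raise VirulenceError(f"unknown host id {hid!r}")

    def mean_fitness(self, v) -> float:
        """Force-of-infection-weighted fitness sum_i rho_i w_i(v)."""
        return sum(h.rho * host_fitness(h, v) for h in self.hosts)

    def to_json(self, path) -> None:
        payload = {
            "hosts": [
                {"id": h.id, "rho": h.rho, "mu": h.mu, "b": h.b, "s": h.s}
                for h in self.hosts
            ]
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "MultiHostSystem":
        with open(path) as fh:
            payload = json.load(fh)
        return cls([HostClass(**h) for h in payload["hosts"]])


def joint_optimum(system: MultiHostSystem, xatol: float = 1e-10) -> float:
    """Virulence maximizing the rho-weighted fitness across all hosts.

    The optimum provably lies in [min_i v*_i, max_i v*_i]: every host's
    fitness is increasing below its own optimum and decreasing above it, so
    the weighted sum has positive slope below the smallest single-host
    optimum and negative slope above the largest.  A coarse grid scan over
    [0, 2*max v*] locates the basin (the weighted sum need not be
    unimodal), then bounded scalar minimization refines it.
    """
    vstars = [single_host_optimum(h) for h in system.hosts]
    lo, hi = min(vstars), max(vstars)
    if hi - lo < xatol:
        return 0.5 * (lo + hi)
    grid = np.linspace(0.0, 2.0 * hi, 4097)
    vals = system.mean_fitness(grid)
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda v: -system.mean_fitness(v),
        bounds=(a, b),
        method="bounded",
        options={"xatol": xatol},
    )
    if not res.success:
        raise VirulenceError(
            f"optimizer failed to converge on bracket [{a}, {b}]: {res.message}"
        )
    return float(np.clip(res.x, lo, hi))


def extinction_response(
    system: MultiHostSystem, removed: Iterable[str]
) -> Dict[str, object]:
    """Re-optimize virulence after removing host classes.

    The surviving hosts' force-of-infection contributions are re-normalized
    and the joint optimum recomputed.  Returns ``v_before``, ``v_after``
    and the ``direction`` of evolution (increase/decrease/unchanged, at
    tolerance 1e-9): virulence generally evolves towards the optima of the
    remaining hosts.
    """
    removed = set(removed)
    ids = {h.id for h in system.hosts}
    unknown = removed - ids
    if unknown:
        raise VirulenceError(f"unknown host ids: {sorted(unknown)}")
    survivors = [h for h in system.hosts if h.id not in removed]
    if not survivors:
        raise VirulenceError("cannot remove every host class")
    v_before = joint_optimum(system)
    v_after = joint_optimum(MultiHostSystem(survivors))
    if v_after > v_before + 1e-9:
        direction = "increase"
    elif v_after < v_before - 1e-9:
        direction = "decrease"
    else:
        direction = "unchanged"
    return {"v_before": v_before, "v_after": v_after, "direction": direction}
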
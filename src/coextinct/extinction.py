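"""Extinction scenarios over host-parasite networks.

A scenario is an ordered list of removal events (sets of host labels).
Running a scenario against a network and a host phylogeny yields a
trajectory: per-step host richness and MPD for every parasite, plus which
parasites have become coextinct under the chosen coextinction rule.

Two rules are supported.  ``all_hosts_lost`` declares a parasite coextinct
when, and only when, every one of its documented hosts has been removed --
the conventional, conservative coextinction assumption.  ``min_hosts_k``
declares it coextinct as soon as fewer than ``k`` hosts survive, modelling
obligate multi-host parasites for which even a single host loss may be
fatal.

The engine deliberately ignores host switching: a parasite's documented
host set never grows during a scenario, so these trajectories are the
no-host-jump projection of extinction impact.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .network import (
    CoextinctError,
    HostParasiteNetwork,
    NetworkError,
    SpecificityRecord,
)
from .tree import Tree, TreeError

#: removal order used by IUCN-ordered scenarios, most to least threatened
IUCN_REMOVAL_ORDER = ("CR", "EN", "VU", "NT")


class ScenarioError(ValueError):
    pass


@dataclass
class ExtinctionScenario:
    """Ordered host-removal events.

    ``events`` are pairwise disjoint, non-overlapping sets of host labels;
    ``provenance`` is ``iucn_ordered``, ``random_order`` or ``custom``;
    ``seed`` records the RNG seed for randomized orders.
    """

    events: List[FrozenSet[str]]
    provenance: str = "custom"
    seed: Optional[int] = None

    def __post_init__(self):
        self.events = [frozenset(e) for e in self.events]
        seen: Set[str] = set()
        for e in self.events:
            if e & seen:
                raise ScenarioError(
                    f"hosts appear in more than one event: {sorted(e & seen)}"
                )
            seen |= e

    @property
    def all_removed(self) -> Set[str]:
        return set().union(*self.events) if self.events else set()

    def to_json(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "seed": self.seed,
            "events": [sorted(e) for e in self.events],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ExtinctionScenario":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            events=[frozenset(e) for e in payload["events"]],
            provenance=payload.get("provenance", "custom"),
            seed=payload.get("seed"),
        )


@dataclass(frozen=True)
class CoextinctionRule:
    """When does a parasite go coextinct?

    ``all_hosts_lost``: only when no documented host survives.
    ``min_hosts_k``: when fewer than ``k`` documented hosts survive
    (``k >= 1``; ``k = 1`` is equivalent to ``all_hosts_lost``).
    """

    mode: str = "all_hosts_lost"
    k: int = 1

    def __post_init__(self):
        if self.mode not in ("all_hosts_lost", "min_hosts_k"):
            raise ScenarioError(f"unknown coextinction rule mode {self.mode!r}")
        if self.k < 1:
            raise ScenarioError("k must be >= 1")

    def is_coextinct(self, surviving_richness: int) -> bool:
        if self.mode == "all_hosts_lost":
            return surviving_richness == 0
        return surviving_richness < self.k


@dataclass
class TrajectoryStep:
    step: int
    surviving_hosts: FrozenSet[str]
    records: Dict[str, SpecificityRecord]
    newly_coextinct: FrozenSet[str]
    coextinct: FrozenSet[str]
    delta_mpd: Dict[str, float]  # vs step-0 baseline; NaN once undefined


@dataclass
class Trajectory:
    steps: List[TrajectoryStep]
    scenario: ExtinctionScenario
    rule: CoextinctionRule

    def mpd_series(self, parasite: str) -> List[float]:
        return [s.records[parasite].mpd for s in self.steps]

    def to_csv(self, path, header_lines: Sequence[str] = ()) -> None:
        """Long format: ``step,parasite,host_richness,mpd,state,delta_mpd``."""
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("step,parasite,host_richness,mpd,state,delta_mpd\n")
            for st in self.steps:
                for p in sorted(st.records):
                    r = st.records[p]
                    mpd = "" if math.isnan(r.mpd) else f"{r.mpd:.6f}"
                    dm = st.delta_mpd[p]
                    dms = "" if math.isnan(dm) else f"{dm:.6f}"
                    fh.write(
                        f"{st.step},{p},{r.host_richness},{mpd},{r.state},{dms}\n"
                    )


# --------------------------------------------------------------- scenarios


def iucn_scenario(net: HostParasiteNetwork) -> ExtinctionScenario:
    """Remove hosts in order of IUCN threat: CR, then EN, VU, NT.

    Hosts flagged domesticated, and data-deficient (DD) hosts, are treated
    as least concern and never removed.  Empty categories yield empty
    events so step indices always align with the four threat classes.
    """
    events = []
    for status in IUCN_REMOVAL_ORDER:
        ev = {
            h
            for h, a in net.host_attributes.items()
            if a["iucn_status"] == status and not a["domesticated"]
        }
        events.append(frozenset(ev & net.hosts))
    return ExtinctionScenario(events=events, provenance="iucn_ordered")


def random_order_scenario(
    net: HostParasiteNetwork,
    parasite: str,
    exclusions: Iterable[str] = (),
    seed: int = 0,
) -> ExtinctionScenario:
    """A uniformly random one-host-at-a-time extinction order over the
    documented hosts of ``parasite``, minus ``exclusions`` (e.g. humans and
    domesticated species).  The same seed reproduces the same order."""
    eligible = sorted(net.hosts_of(parasite) - set(exclusions))
    if not eligible:
        raise ScenarioError(
            f"no eligible hosts for {parasite!r} after exclusions"
        )
    rng = random.Random(seed)
    rng.shuffle(eligible)
    return ExtinctionScenario(
        events=[frozenset({h}) for h in eligible],
        provenance="random_order",
        seed=seed,
    )


# --------------------------------------------------------------------- run


def run(
    scenario: ExtinctionScenario,
    net: HostParasiteNetwork,
    tree: Tree,
    rule: CoextinctionRule = CoextinctionRule(),
) -> Trajectory:
    """Execute a scenario: step 0 is the pre-extinction state; each
    subsequent step removes one event's hosts, re-evaluates the
    coextinction rule, and recomputes every parasite's specificity on the
    surviving host set.

    Coextinct parasites keep their identity in every later step (state
    ``coextinct``, richness of surviving documented hosts, MPD undefined);
    they are never silently dropped.
    """
    extra = scenario.all_removed - net.hosts
    if extra:
        raise ScenarioError(
            f"scenario removes hosts not in the network: {sorted(extra)}"
        )
    tips = set(tree.tip_labels)
    missing = net.hosts - tips
    if missing:
        raise TreeError(
            f"network hosts missing from the tree: {sorted(missing)}"
        )

    surviving = set(net.hosts)
    coextinct: Set[str] = set()
    baseline_mpd: Dict[str, float] = {}
    steps: List[TrajectoryStep] = []

    for step_idx in range(len(scenario.events) + 1):
        if step_idx > 0:
            surviving -= scenario.events[step_idx - 1]
        records: Dict[str, SpecificityRecord] = {}
        newly: Set[str] = set()
        for p in net.parasites:
            rich = net.host_richness(p, surviving)
            dead = p in coextinct or rule.is_coextinct(rich)
            if dead and p not in coextinct:
                newly.add(p)
            if rich == 0:
                mpd = float("nan")
            else:
                mpd = net.mpd(p, tree, surviving)
            state = "coextinct" if dead else "extant"
            records[p] = SpecificityRecord(p, rich, mpd, state)
        coextinct |= newly
        if step_idx == 0:
            baseline_mpd = {p: records[p].mpd for p in records}
        delta = {
            p: records[p].mpd - baseline_mpd[p]
            if not math.isnan(records[p].mpd)
            else float("nan")
            for p in records
        }
        steps.append(
            TrajectoryStep(
                step=step_idx,
                surviving_hosts=frozenset(surviving),
                records=records,
                newly_coextinct=frozenset(newly),
                coextinct=frozenset(coextinct),
                delta_mpd=delta,
            )
        )
    return Trajectory(steps=steps, scenario=scenario, rule=rule)


# ---------------------------------------------------------- classification

OUTCOMES = (
    "coextinction",
    "reduced_to_single_host",
    "mpd_decrease",
    "mpd_increase",
    "unchanged",
    "unaffected",
)


def classify_outcome(
    net: HostParasiteNetwork,
    tree: Tree,
    lost_host: str,
    tol: float = 1e-9,
) -> Dict[str, str]:
    """Classify the impact of losing one host on every parasite.

    Parasites not documented on the lost host are ``unaffected``.  For the
    rest: a single-host parasite suffers ``coextinction``; a two-host
    parasite is ``reduced_to_single_host`` (an apparent specialist with MPD
    0); parasites with three or more hosts see their MPD ``mpd_decrease``,
    ``mpd_increase`` or stay ``unchanged`` (|change| <= ``tol``).
    """
    if lost_host not in net.hosts:
        raise NetworkError(f"unknown host {lost_host!r}")
    out = {}
    survivors = net.hosts - {lost_host}
    for p in net.parasites:
        hosts = net.hosts_of(p)
        if lost_host not in hosts:
            out[p] = "unaffected"
            continue
        n = len(hosts)
        if n == 1:
            out[p] = "coextinction"
        elif n == 2:
            out[p] = "reduced_to_single_host"
        else:
            before = net.mpd(p, tree)
            after = net.mpd(p, tree, survivors)
            if after < before - tol:
                out[p] = "mpd_decrease"
            elif after > before + tol:
                out[p] = "mpd_increase"
            else:
                out[p] = "unchanged"
    return out


# ------------------------------------------------------------------ ED shift


def ed_shift(
    full_tree: Tree, extinct_tips: Iterable[str]
) -> Dict[str, Dict[str, float]]:
    """Gain in evolutionary distinctiveness for each surviving tip after
    pruning the extinct ones.

    ``gain = ed_extant - ed_full`` (equal splits); pruning can only merge
    path segments and shrink divisors, so every gain is >= 0.  Tips that
    lost close relatives gain the most.
    """
    extinct = set(extinct_tips)
    tips = set(full_tree.tip_labels)
    unknown = extinct - tips
    if unknown:
        raise TreeError(f"unknown extinct tips: {sorted(unknown)}")
    survivors = tips - extinct
    if not survivors:
        raise TreeError("no surviving tips")
    ed_full = full_tree.ed_equal_splits()
    if extinct:
        ed_extant = full_tree.prune_to(survivors).ed_equal_splits()
    else:
        ed_extant = dict(ed_full)
    return {
        t: {
            "ed_full": ed_full[t],
            "ed_extant": ed_extant[t],
            "gain": ed_extant[t] - ed_full[t],
        }
        for t in sorted(survivors)
    }


# ------------------------------------------------------ projected extinction


def delta_mpd_projection(
    net: HostParasiteNetwork,
    tree: Tree,
    keep_statuses: Iterable[str] = ("LC", "DD"),
) -> Dict[str, Tuple[float, float, bool]]:
    """MPD now vs MPD after a projected extinction of every host whose IUCN
    status is not in ``keep_statuses`` (default: keep LC and DD).

    Domesticated hosts are treated as LC and always kept.  Returns
    ``parasite -> (mpd_now, mpd_after, coextinct)``; ``mpd_after`` is NaN
    for coextinct parasites.
    """
    keep = set(keep_statuses)
    surviving = {
        h
        for h, a in net.host_attributes.items()
        if (a["iucn_status"] in keep or a["domesticated"]) and h in net.hosts
    }
    out = {}
    for p in net.parasites:
        now = net.mpd(p, tree)
        rich = net.host_richness(p, surviving)
        if rich == 0:
            out[p] = (now, float("nan"), True)
        else:
            out[p] = (now, net.mpd(p, tree, surviving), False)
    return out
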
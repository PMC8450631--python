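"""Bipartite host-parasite association networks and phylogenetic
host-specificity metrics.

The central specificity metric is MPD, the unweighted mean pairwise
patristic distance (Myr) among the host species a parasite is documented
on.  A single-host parasite has MPD 0 by convention; a parasite with no
surviving hosts has no MPD and is tagged ``coextinct``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set

import numpy as np
import pandas as pd

from .tree import Tree, TreeError

log = logging.getLogger(__name__)

IUCN_CODES = ("CR", "EN", "VU", "NT", "LC", "DD")


class NetworkError(ValueError):
    """Invalid association data."""


class CoextinctError(NetworkError):
    """MPD requested for a parasite with no surviving hosts."""


@dataclass(frozen=True)
class SpecificityRecord:
    """Host richness and MPD of one parasite at a given community state."""

    parasite: str
    host_richness: int
    mpd: float  # NaN when richness is 0
    state: str  # "extant" | "coextinct"


@dataclass
class HostParasiteNetwork:
    """Parasite -> documented host set, plus per-host attributes.

    ``host_attributes`` maps host label to a dict with keys
    ``iucn_status`` (one of CR/EN/VU/NT/LC/DD), ``domesticated`` (bool),
    ``extinct`` (bool) and optionally ``body_mass_g`` (positive float).
    """

    associations: Dict[str, FrozenSet[str]]
    host_attributes: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        for p, hosts in self.associations.items():
            if not p or not isinstance(p, str):
                raise NetworkError(f"invalid parasite label {p!r}")
            if not hosts:
                raise NetworkError(f"parasite {p!r} has no hosts")
            self.associations[p] = frozenset(hosts)
        missing = self.hosts - set(self.host_attributes)
        if missing:
            raise NetworkError(
                f"hosts present in associations but missing from the "
                f"attribute table: {sorted(missing)}"
            )
        for h, attrs in self.host_attributes.items():
            status = attrs.get("iucn_status")
            if status not in IUCN_CODES:
                raise NetworkError(
                    f"host {h!r}: unknown IUCN status {status!r} "
                    f"(expected one of {IUCN_CODES})"
                )

    @property
    def parasites(self) -> List[str]:
        return list(self.associations)

    @property
    def hosts(self) -> Set[str]:
        return set().union(*self.associations.values()) if self.associations else set()

    def hosts_of(self, parasite: str) -> FrozenSet[str]:
        try:
            return self.associations[parasite]
        except KeyError:
            raise NetworkError(f"unknown parasite {parasite!r}") from None

    # ------------------------------------------------------------- metrics

    def host_richness(self, parasite: str, surviving: Iterable[str]) -> int:
        """Number of the parasite's documented hosts in ``surviving``."""
        return len(self.hosts_of(parasite) & set(surviving))

    def mpd(
        self,
        parasite: str,
        tree: Tree,
        surviving: Optional[Iterable[str]] = None,
    ) -> float:
        """Mean pairwise patristic distance (Myr) among the parasite's
        surviving documented hosts.

        Returns 0 when exactly one host survives.  Raises
        :class:`CoextinctError` when none do, and :class:`TreeError` when a
        surviving documented host is not a tip of ``tree``.
        """
        hosts = self.hosts_of(parasite)
        if surviving is not None:
            hosts = hosts & set(surviving)
        if not hosts:
            raise CoextinctError(f"parasite {parasite!r} is coextinct")
        labels, D = tree.distance_matrix()
        idx = {l: i for i, l in enumerate(labels)}
        missing = [h for h in hosts if h not in idx]
        if missing:
            raise TreeError(
                f"hosts of {parasite!r} missing from the tree: {sorted(missing)}"
            )
        if len(hosts) == 1:
            return 0.0
        ii = [idx[h] for h in hosts]
        sub = D[np.ix_(ii, ii)]
        n = len(ii)
        return float(sub[np.triu_indices(n, k=1)].mean())

    def specificity_table(
        self,
        tree: Tree,
        surviving: Optional[Iterable[str]] = None,
    ) -> List[SpecificityRecord]:
        """One :class:`SpecificityRecord` per parasite; parasites with no
        surviving hosts are tagged ``coextinct``, not dropped."""
        surv = set(surviving) if surviving is not None else self.hosts
        records = []
        for p in self.associations:
            rich = self.host_richness(p, surv)
            if rich == 0:
                records.append(SpecificityRecord(p, 0, float("nan"), "coextinct"))
            else:
                records.append(
                    SpecificityRecord(p, rich, self.mpd(p, tree, surv), "extant")
                )
        return records


def read_associations(edge_list_path, attributes_path) -> HostParasiteNetwork:
    """Build a network from an edge-list CSV (``parasite,host``) and a host
    attribute CSV (``host,iucn_status,domesticated,extinct[,body_mass_g]``).

    Duplicate edges are deduplicated (count logged).  Hosts appearing in the
    edge list but absent from the attribute table are an error listing them:
    silent taxon-name mismatches are the dominant failure mode with real
    association data.  Lines starting with ``#`` are ignored.
    """
    edges = pd.read_csv(edge_list_path, comment="#", dtype=str)
    if edges.empty:
        raise NetworkError("empty edge list")
    need = {"parasite", "host"}
    if not need.issubset(edges.columns):
        raise NetworkError(
            f"edge list must have columns {sorted(need)}, got {list(edges.columns)}"
        )
    n_raw = len(edges)
    edges = edges.drop_duplicates(subset=["parasite", "host"])
    if len(edges) < n_raw:
        log.info("deduplicated %d duplicate association rows", n_raw - len(edges))

    attrs = pd.read_csv(attributes_path, comment="#")
    need = {"host", "iucn_status", "domesticated", "extinct"}
    if not need.issubset(attrs.columns):
        raise NetworkError(
            f"attribute table must have columns {sorted(need)}, "
            f"got {list(attrs.columns)}"
        )
    host_attributes = {}
    for _, row in attrs.iterrows():
        rec = {
            "iucn_status": str(row["iucn_status"]).strip(),
            "domesticated": _as_bool(row["domesticated"]),
            "extinct": _as_bool(row["extinct"]),
        }
        if "body_mass_g" in attrs.columns and pd.notna(row.get("body_mass_g")):
            mass = float(row["body_mass_g"])
            if mass <= 0:
                raise NetworkError(f"host {row['host']!r}: non-positive body mass")
            rec["body_mass_g"] = mass
        host_attributes[str(row["host"])] = rec

    associations: Dict[str, set] = {}
    for _, row in edges.iterrows():
        associations.setdefault(str(row["parasite"]), set()).add(str(row["host"]))
    return HostParasiteNetwork(
        {p: frozenset(h) for p, h in associations.items()}, host_attributes
    )


def _as_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise NetworkError(f"cannot interpret {x!r} as a boolean flag")


def specificity_to_csv(records: List[SpecificityRecord], path) -> None:
    """Write ``parasite,host_richness,mpd,state`` (mpd blank when undefined)."""
    with open(path, "w") as fh:
        fh.write("parasite,host_richness,mpd,state\n")
        for r in records:
            mpd = "" if np.isnan(r.mpd) else f"{r.mpd:.6f}"
            fh.write(f"{r.parasite},{r.host_richness},{mpd},{r.state}\n")
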
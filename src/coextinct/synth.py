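"""Synthetic hosts, parasites and threat statuses with the statistical
structure the downstream analyses assume.

The generator emulates three features of real mammal host-parasite data:

* a birth-death host phylogeny (Yule by default) with branch lengths in
  Myr;
* phylogenetic signal in host sharing -- each parasite picks a focal host
  and infects other hosts with probability decaying exponentially in
  patristic distance from the focal host (decay length ``phi``, Myr), so
  close relatives of an infected host are more likely to share the
  parasite;
* trait-biased extinction risk -- body mass evolves as geometric Brownian
  motion on the tree, and the probability of being threatened rises
  logistically with (standardized) log body mass, mirroring the
  disproportionate extinction risk of large-bodied hosts.

Threatened hosts are split into CR/EN/VU/NT by quartile of their
continuous risk score (top quartile CR, and so on down to NT); this
quantile mapping is a modelling convenience, not an IUCN procedure.  All
generators are deterministic per seed.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath
from scipy.special import expit

from .network import HostParasiteNetwork
from .tree import Tree

log = logging.getLogger(__name__)


@dataclass
class SynthConfig:
    """Knobs for the synthetic world.

    n_tips            host species count (>= 2)
    tree_model        "yule" or "birth_death"
    birth_rate        speciation rate (per lineage per Myr)
    death_rate        extinction rate (birth_death only; < birth_rate)
    n_parasites       number of parasites to simulate
    phi               decay length (Myr) of infection probability with
                      patristic distance from the focal host; small phi ->
                      specialists, large phi -> generalists
    alpha, beta       intercept and slope of the logistic threat model on
                      standardized log10 body mass; beta > 0 biases threat
                      towards large-bodied hosts
    sigma_mass        Brownian SD of log10 body mass per sqrt(Myr)
    root_log10_mass   log10 body mass (g) at the root
    extinct_fraction  fraction of tips flagged extinct (for ED-shift runs)
    extinct_bias      "mass", "ed" or "none": sampling weights for the
                      extinct flag (exp of the standardized trait)
    seed              master seed; sub-generators derive streams from it
    """

    n_tips: int = 100
    tree_model: str = "yule"
    birth_rate: float = 1.0
    death_rate: float = 0.0
    n_parasites: int = 50
    phi: float = 2.0
    alpha: float = -1.0
    beta: float = 1.0
    sigma_mass: float = 0.5
    root_log10_mass: float = 3.0
    extinct_fraction: float = 0.0
    extinct_bias: str = "mass"
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.tree_model not in ("yule", "birth_death"):
            raise ValueError(f"unknown tree model {self.tree_model!r}")
        if self.tree_model == "yule":
            self.death_rate = 0.0
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        if not 0 <= self.extinct_fraction < 1:
            raise ValueError("extinct_fraction must be in [0, 1)")
        if self.extinct_bias not in ("mass", "ed", "none"):
            raise ValueError(f"unknown extinct_bias {self.extinct_bias!r}")


def simulate_tree(config: SynthConfig) -> Tree:
    """Simulate a birth-death tree conditioned on ``n_tips`` extant tips.

    Tip labels are S1..Sn.  If all lineages die before reaching ``n_tips``
    the draw is repeated (retries logged)."""
    rng = random.Random(int(_stream(config.seed, 0).generate_state(1)[0]))
    attempts = 0
    while True:
        attempts += 1
        try:
            dtree = birthdeath.birth_death_tree(
                birth_rate=config.birth_rate,
                death_rate=config.death_rate,
                num_extant_tips=config.n_tips,
                rng=rng,
                repeat_until_success=False,
            )
            break
        except Exception:
            if attempts >= 100:
                raise
            continue
    if attempts > 1:
        log.info("birth-death simulation needed %d attempts", attempts)
    for i, lf in enumerate(dtree.leaf_node_iter(), start=1):
        if lf.taxon is None:
            lf.taxon = dtree.taxon_namespace.new_taxon(label=f"S{i}")
        lf.taxon.label = f"S{i}"
    return Tree(dtree)


def simulate_network(
    tree: Tree, config: SynthConfig, return_focal: bool = False
):
    """Draw parasites with phylogenetically clustered host ranges.

    Each parasite chooses a uniform focal host f and then infects every
    other host j independently with probability exp(-d(f, j)/phi); the
    focal host is always infected, so richness >= 1.  Host attributes come
    from :func:`assign_status` under the same config.

    With ``return_focal=True`` also returns the parasite -> focal host map
    (useful for checking the distance decay of sharing).
    """
    rng = np.random.default_rng(_stream(config.seed, 1))
    labels, D = tree.distance_matrix()
    n = len(labels)
    associations = {}
    focal = {}
    for k in range(config.n_parasites):
        f = int(rng.integers(n))
        p_inf = np.exp(-D[f] / config.phi)
        infected = rng.random(n) < p_inf
        infected[f] = True
        associations[f"P{k + 1}"] = frozenset(
            labels[j] for j in range(n) if infected[j]
        )
        focal[f"P{k + 1}"] = labels[f]
    attrs = assign_status(tree, config)
    host_attributes = {
        row["host"]: {
            "iucn_status": row["iucn_status"],
            "domesticated": bool(row["domesticated"]),
            "extinct": bool(row["extinct"]),
            "body_mass_g": float(row["body_mass_g"]),
        }
        for _, row in attrs.iterrows()
    }
    net = HostParasiteNetwork(associations, host_attributes)
    return (net, focal) if return_focal else net


def simulate_body_mass(tree: Tree, config: SynthConfig) -> Dict[str, float]:
    """Geometric Brownian motion of body mass: log10 mass performs Brownian
    motion along branches with SD ``sigma_mass`` per sqrt(Myr)."""
    rng = np.random.default_rng(_stream(config.seed, 2))
    dtree = tree._t
    logm = {id(dtree.seed_node): config.root_log10_mass}
    out = {}
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        t = nd.edge.length or 0.0
        val = logm[id(nd.parent_node)] + rng.normal(0.0, config.sigma_mass) * math.sqrt(t)
        logm[id(nd)] = val
        if nd.is_leaf():
            out[nd.taxon.label] = 10.0 ** val
    return out


def assign_status(tree: Tree, config: SynthConfig) -> pd.DataFrame:
    """Simulate IUCN-like statuses biased by body mass.

    Threat probability is ``expit(alpha + beta * z)`` with z the
    standardized log10 body mass.  Threatened hosts are assigned CR, EN,
    VU, NT by descending quartile of threat probability; all others are
    LC.  Optionally flags ``extinct_fraction`` of tips extinct, sampled
    with weights increasing in mass or equal-splits ED.

    Returns a DataFrame with columns
    ``host,iucn_status,domesticated,extinct,body_mass_g``.
    """
    rng = np.random.default_rng(_stream(config.seed, 3))
    mass = simulate_body_mass(tree, config)
    hosts = tree.tip_labels
    logm = np.log10([mass[h] for h in hosts])
    z = (logm - logm.mean()) / (logm.std() if logm.std() > 0 else 1.0)
    risk = expit(config.alpha + config.beta * z)
    threatened = rng.random(len(hosts)) < risk
    status = np.array(["LC"] * len(hosts), dtype=object)
    if threatened.any():
        idx = np.flatnonzero(threatened)
        order = idx[np.argsort(-risk[idx], kind="stable")]
        cats = ("CR", "EN", "VU", "NT")
        splits = np.array_split(order, 4)
        for cat, chunk in zip(cats, splits):
            status[chunk] = cat

    extinct = np.zeros(len(hosts), dtype=bool)
    n_ext = int(round(config.extinct_fraction * len(hosts)))
    if n_ext > 0:
        if config.extinct_bias == "mass":
            w = np.exp(z)
        elif config.extinct_bias == "ed":
            ed = tree.ed_equal_splits()
            e = np.array([ed[h] for h in hosts])
            zed = (e - e.mean()) / (e.std() if e.std() > 0 else 1.0)
            w = np.exp(zed)
        else:
            w = np.ones(len(hosts))
        chosen = rng.choice(
            len(hosts), size=n_ext, replace=False, p=w / w.sum()
        )
        extinct[chosen] = True

    return pd.DataFrame(
        {
            "host": hosts,
            "iucn_status": status,
            "domesticated": False,
            "extinct": extinct,
            "body_mass_g": [mass[h] for h in hosts],
        }
    )


def refit_threat_slope(attrs: pd.DataFrame) -> Tuple[float, float]:
    """Refit the logistic threat model (threatened ~ standardized log10
    mass) on a simulated attribute table; returns (beta_hat, se)."""
    import statsmodels.api as sm

    logm = np.log10(attrs["body_mass_g"].to_numpy(dtype=float))
    z = (logm - logm.mean()) / logm.std()
    y = (~attrs["iucn_status"].isin(["LC", "DD"])).astype(int).to_numpy()
    X = sm.add_constant(z)
    fit = sm.Logit(y, X).fit(disp=0)
    return float(fit.params[1]), float(fit.bse[1])


def fixture_fig1():
    """The four canonical single-host-loss outcomes on a 3-tip toy tree.

    Tree ((A:1,B:1):2,C:3); parasites configured so that losing the stated
    host yields, in turn: coextinction of a single-host parasite, a
    generalist reduced to a single host, an MPD decrease (apparent
    specialist) and an MPD increase (apparent generalist).

    Returns ``(tree, network, expected)`` where ``expected`` maps panel
    name to ``(parasite, lost_host, outcome)``.
    """
    tree = Tree.from_newick("((A:1,B:1):2,C:3);")
    attrs = {
        h: {"iucn_status": "LC", "domesticated": False, "extinct": False}
        for h in "ABC"
    }
    net = HostParasiteNetwork(
        {
            "P_single": frozenset({"C"}),
            "P_pair": frozenset({"B", "C"}),
            "P_spec": frozenset({"A", "B", "C"}),
            "P_gen": frozenset({"A", "B", "C"}),
        },
        attrs,
    )
    expected = {
        "a_coextinction": ("P_single", "C", "coextinction"),
        "b_single_host": ("P_pair", "C", "reduced_to_single_host"),
        "c_mpd_decrease": ("P_spec", "C", "mpd_decrease"),
        "d_mpd_increase": ("P_gen", "B", "mpd_increase"),
    }
    return tree, net, expected


def write_fixtures(config: SynthConfig, outdir) -> Dict[str, str]:
    """Emit the exact file formats the pipeline consumes: Newick tree, CSV
    edge list, CSV attribute table.  Returns the paths written."""
    import os

    os.makedirs(outdir, exist_ok=True)
    tree = simulate_tree(config)
    net = simulate_network(tree, config)
    tree_path = os.path.join(outdir, "hosts.nwk")
    tree.write_newick_file(tree_path)
    edges_path = os.path.join(outdir, "associations.csv")
    with open(edges_path, "w") as fh:
        fh.write("parasite,host\n")
        for p in net.parasites:
            for h in sorted(net.hosts_of(p)):
                fh.write(f"{p},{h}\n")
    attrs_path = os.path.join(outdir, "host_attributes.csv")
    with open(attrs_path, "w") as fh:
        fh.write("host,iucn_status,domesticated,extinct,body_mass_g\n")
        for h in tree.tip_labels:
            a = net.host_attributes[h]
            fh.write(
                f"{h},{a['iucn_status']},{a['domesticated']},"
                f"{a['extinct']},{a['body_mass_g']:.6f}\n"
            )
    return {"tree": tree_path, "edges": edges_path, "attributes": attrs_path}


def _stream(seed: int, tag: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(tag,))
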
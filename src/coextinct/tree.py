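"""Rooted phylogenies: Newick I/O, pruning, patristic distances, and
evolutionary distinctiveness (ED).

A :class:`Tree` is a thin validating wrapper around a :class:`dendropy.Tree`.
Branch lengths are in millions of years (Myr) throughout; no unit conversion
happens anywhere in the package.

Evolutionary distinctiveness apportions the total branch length of the tree
among its tips.  Two apportionment schemes are provided:

* **equal splits** -- walking from a tip towards the root, each successive
  edge's length is divided by the product of the child counts of the internal
  nodes passed on the way, so a tip's pendant edge counts in full, an edge
  above a bifurcation counts half, above two nested bifurcations a quarter,
  and above a k-furcation ``1/k``;
* **fair proportion** -- each edge's length is divided equally among the tips
  that descend from it.

Both schemes conserve total branch length: the tip values sum to the tree's
total branch length exactly (up to floating point).
"""

from __future__ import annotations

import io
from typing import Dict, Iterable, Set

import dendropy


class TreeError(ValueError):
    """Invalid tree structure or tip set."""


class NewickError(TreeError):
    """Malformed Newick input."""


class Tree:
    """A rooted phylogeny with branch lengths in Myr.

    Invariants enforced at construction:

    * tip labels are unique, non-empty strings;
    * every edge length is >= 0 (the root edge may be absent, meaning 0);
    * internal branch lengths are all present;
    * no internal node has exactly one child (unifurcations are suppressed,
      summing the two edge lengths, so patristic distances are unchanged).

    Polytomies are permitted.  Internal node labels and Newick comments are
    ignored on input.
    """

    def __init__(self, dtree: dendropy.Tree):
        dtree.suppress_unifurcations()
        self._t = dtree
        self._dist_cache = None
        self._validate()

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a single Newick tree from a string.

        Branch lengths must be present on all edges except optionally the
        root; a missing root edge length is treated as 0.  Scientific
        notation and quoted labels are accepted.
        """
        if not text or not text.strip():
            raise NewickError("empty Newick input")
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickError(f"malformed Newick: {exc}") from exc
        return cls(dtree)

    @classmethod
    def from_newick_file(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        """Serialize to a Newick string (with branch lengths, no internal
        labels).  ``Tree.from_newick(t.to_newick())`` reproduces ``t`` up to
        child order."""
        s = self._t.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_internal_node_labels=True,
            unquoted_underscores=True,
        )
        return s.strip()

    def write_newick_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------ validation

    def _validate(self) -> None:
        leaves = list(self._t.leaf_node_iter())
        if not leaves:
            raise TreeError("tree has no tips")
        labels = []
        for lf in leaves:
            if lf.taxon is None or not (lf.taxon.label or "").strip():
                raise TreeError("tip with empty or missing label")
            labels.append(lf.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        root = self._t.seed_node
        for nd in self._t.preorder_node_iter():
            ln = nd.edge.length
            if nd is root:
                if ln is not None and ln < 0:
                    raise TreeError(f"negative root edge length {ln}")
                continue
            if ln is None:
                name = nd.taxon.label if nd.taxon else "<internal>"
                raise TreeError(f"missing branch length on edge above {name!r}")
            if ln < 0:
                name = nd.taxon.label if nd.taxon else "<internal>"
                raise TreeError(f"negative branch length {ln} above {name!r}")

    # ------------------------------------------------------------ properties

    @property
    def tip_labels(self) -> list:
        return [lf.taxon.label for lf in self._t.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._t.leaf_node_iter())

    def total_branch_length(self) -> float:
        """Sum of all edge lengths, including a non-zero root edge."""
        return sum(
            nd.edge.length or 0.0 for nd in self._t.preorder_node_iter()
        )

    # -------------------------------------------------------------- pruning

    def prune_to(self, keep: Iterable[str]) -> "Tree":
        """Return a new tree containing exactly the tips in ``keep``.

        Internal nodes left with a single child are suppressed and their
        edge lengths summed, so patristic distances among kept tips are
        identical before and after pruning.
        """
        keep = set(keep)
        if not keep:
            raise TreeError("cannot prune to an empty tip set")
        have = set(self.tip_labels)
        unknown = keep - have
        if unknown:
            raise TreeError(f"unknown tip labels in keep set: {sorted(unknown)}")
        sub = self._t.extract_tree_with_taxa_labels(keep)
        return Tree(sub)

    # ------------------------------------------------------------ distances

    def patristic_distance(self, a: str, b: str) -> float:
        """Branch-length distance along the path a -> MRCA -> b (Myr)."""
        depths = self._tip_root_paths()
        for lab in (a, b):
            if lab not in depths:
                raise TreeError(f"unknown tip label {lab!r}")
        if a == b:
            return 0.0
        pa, pb = depths[a], depths[b]
        # distance = depth(a) + depth(b) - 2 * depth(MRCA)
        common = set(pa) & set(pb)
        d_mrca = max(pa[c] for c in common) if common else 0.0
        return (self._tip_depth[a] - d_mrca) + (self._tip_depth[b] - d_mrca)

    def _tip_root_paths(self):
        """Map tip label -> {ancestor node id -> cumulative depth of that
        ancestor from the root}; also caches tip depths."""
        if self._dist_cache is not None:
            return self._dist_cache
        depth = {}  # node id -> depth from root (root edge excluded)
        root = self._t.seed_node
        depth[id(root)] = 0.0
        for nd in self._t.preorder_node_iter():
            if nd is root:
                continue
            depth[id(nd)] = depth[id(nd.parent_node)] + nd.edge.length
        paths = {}
        tip_depth = {}
        for lf in self._t.leaf_node_iter():
            anc = {}
            nd = lf.parent_node
            while nd is not None:
                anc[id(nd)] = depth[id(nd)]
                nd = nd.parent_node
            paths[lf.taxon.label] = anc
            tip_depth[lf.taxon.label] = depth[id(lf)]
        self._tip_depth = tip_depth
        self._dist_cache = paths
        return paths

    def distance_matrix(self):
        """All-pairs patristic distances.

        Returns ``(labels, D)`` where ``labels`` is the ordered tip list and
        ``D`` a dense symmetric :class:`numpy.ndarray`.  Computed once and
        cached (the tree is immutable after construction).
        """
        import numpy as np

        if getattr(self, "_dm", None) is not None:
            return self._labels, self._dm
        self._tip_root_paths()
        labels = self.tip_labels
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        D = np.zeros((n, n))
        # post-order: for each internal node, accumulate tip depths per child
        tipsets = {}
        for nd in self._t.postorder_node_iter():
            if nd.is_leaf():
                tipsets[id(nd)] = [(idx[nd.taxon.label], nd.edge.length or 0.0)]
                continue
            children = nd.child_nodes()
            lists = [tipsets.pop(id(c)) for c in children]
            for i in range(len(lists)):
                for j in range(i + 1, len(lists)):
                    for ta, da in lists[i]:
                        for tb, db in lists[j]:
                            D[ta, tb] = D[tb, ta] = da + db
            merged = [
                (t, d + (nd.edge.length or 0.0))
                for sub in lists
                for (t, d) in sub
            ]
            tipsets[id(nd)] = merged
        self._labels = labels
        self._dm = D
        return labels, D

    # ----------------------------------------------- evolutionary distinctiveness

    def ed_equal_splits(self) -> Dict[str, float]:
        """Equal-splits ED per tip (Myr).

        Walking from the tip to the root, each edge's length is divided by
        the product of the child counts of the internal nodes strictly
        between that edge and the tip; a non-zero root edge is apportioned
        the same way (shared by all tips).  The values sum to the total
        branch length.
        """
        out = {}
        root = self._t.seed_node
        root_len = root.edge.length or 0.0
        for lf in self._t.leaf_node_iter():
            ed = 0.0
            divisor = 1.0
            nd = lf
            while nd.parent_node is not None:
                ed += nd.edge.length / divisor
                nd = nd.parent_node
                divisor *= len(nd.child_nodes())
            if root_len:
                ed += root_len / divisor
            out[lf.taxon.label] = ed
        return out

    def ed_fair_proportion(self) -> Dict[str, float]:
        """Fair-proportion ED per tip: each edge's length divided equally
        among the tips descending from it."""
        ntips = {}
        for nd in self._t.postorder_node_iter():
            if nd.is_leaf():
                ntips[id(nd)] = 1
            else:
                ntips[id(nd)] = sum(ntips[id(c)] for c in nd.child_nodes())
        out = {}
        root = self._t.seed_node
        for lf in self._t.leaf_node_iter():
            ed = 0.0
            nd = lf
            while nd.parent_node is not None:
                ed += nd.edge.length / ntips[id(nd)]
                nd = nd.parent_node
            ed += (root.edge.length or 0.0) / ntips[id(root)]
            out[lf.taxon.label] = ed
        return out


def read_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree` (module-level convenience)."""
    return Tree.from_newick(text)


def write_newick(tree: Tree) -> str:
    """Serialize a :class:`Tree` to Newick."""
    return tree.to_newick()


def ed_table_to_csv(ed: Dict[str, float], path) -> None:
    """Write an ED table as CSV with columns ``tip,ed`` (6 decimals)."""
    with open(path, "w") as fh:
        fh.write("tip,ed\n")
        for tip in sorted(ed):
            fh.write(f"{tip},{ed[tip]:.6f}\n")
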
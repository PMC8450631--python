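# coextinct

Host extinction reshapes the tree of life that parasites live on.  When a
host species disappears, its parasites may go extinct with it, survive on
fewer hosts, or simply *look* different: a parasite's apparent host
specificity — measured from its documented hosts — can shift without any
change in what the parasite can actually infect.  `coextinct` is a Python
library for studying these effects, aimed at disease ecologists and
phylogenetic comparative biologists working with host–parasite association
data and dated host phylogenies.

It implements four connected analyses:

1. **Evolutionary distinctiveness (ED) shifts.**  ED apportions a
   phylogeny's total branch length among its tips.  The equal-splits
   scheme gives tip $i$

   $$ED_i = \sum_{e \in \text{path}(i,\text{root})} \frac{\ell_e}{\prod_{v} c_v},$$

   where the product runs over the child counts $c_v$ of internal nodes
   between edge $e$ and the tip (fair proportion, dividing each edge by
   its descendant-tip count, is also provided).  Pruning extinct tips can
   only increase a survivor's ED — `ed_shift` quantifies each survivor's
   gain in millions of years (Myr) of newly private evolutionary history.

2. **Phylogenetic host specificity.**  A parasite's specificity is the
   mean pairwise patristic distance (MPD, Myr) among its documented hosts;
   single-host parasites have MPD 0, and parasites whose hosts are all
   gone are tagged *coextinct*, never dropped.

3. **Extinction scenarios.**  Ordered host-removal scenarios — IUCN-ordered
   (CR, then EN, VU, NT; domesticated and DD hosts treated as LC and kept),
   seeded random orders, or custom — are run against a network and a tree,
   recording per-step richness, MPD, ΔMPD and coextinctions under either
   coextinction rule (all hosts lost, or a minimum-host threshold for
   obligate multi-host parasites).  Losing a single host classifies each
   parasite as coextinct, reduced to a single host, MPD-decreased (apparent
   specialist), MPD-increased (apparent generalist), unchanged, or
   unaffected.

4. **Virulence response.**  A parasite constrained to one virulence level
   $v$ across host classes with fitness $w_i(v) = b_i v^{s_i}/(\mu_i + v)$
   and single-host optima $v_i^* = s_i\mu_i/(1-s_i)$ evolves to the
   force-of-infection-weighted joint optimum
   $\arg\max_v \sum_i \rho_i w_i(v)$, which always lies between the
   smallest and largest $v_i^*$.  `extinction_response` reports which way
   virulence evolves when hosts are removed.

A synthetic-data module generates seeded birth–death host trees, networks
with phylogenetic signal in host sharing, and mass-biased IUCN-like threat
statuses, so the full pipeline is testable without external datasets.

## Worked example

```python
import coextinct as cx

tree = cx.read_newick("((A:1,B:1):2,C:3);")
print(tree.ed_equal_splits())
# {'A': 2.0, 'B': 2.0, 'C': 3.0}

attrs = {h: {"iucn_status": "LC", "domesticated": False, "extinct": False}
         for h in "ABC"}
net = cx.HostParasiteNetwork({"P": frozenset("ABC")}, attrs)
print(net.mpd("P", tree))                  # 4.666666666666667
print(net.mpd("P", tree, {"A", "B"}))      # 2.0  (losing C: apparent specialist)
print(net.mpd("P", tree, {"A", "C"}))      # 6.0  (losing B: apparent generalist)

print(cx.ed_shift(tree, {"B"})["A"])
# {'ed_full': 2.0, 'ed_extant': 3.0, 'gain': 1.0}
```

The parasite's MPD over hosts {A, B, C} averages the pairwise distances
2, 6 and 6 Myr to 14/3 ≈ 4.67 Myr.  Removing the distant host C drops MPD
to 2 (the parasite now looks specialized); removing the close host B
raises it to 6 (it looks more generalist) — same parasite, opposite
conclusions, driven only by which host was lost.  After B's extinction,
A inherits their shared 2 Myr stem in full and gains exactly 1 Myr of ED.

The `examples/` directory has one short script per capability, and the
`coextinct` console command (`ed-shift`, `specificity`, `simulate`,
`virulence`, `synth`) exposes the same operations on Newick/CSV/JSON
files with byte-reproducible, seed-stamped outputs.

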
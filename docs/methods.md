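# Methods

## Trees and units

All phylogenies are rooted, with branch lengths in millions of years
(Myr); no unit conversion happens anywhere.  Polytomies are allowed;
degree-2 internal nodes are suppressed at construction (their edge
lengths summed), so patristic distances are invariant to pruning.
Zero-length branches are legal — two tips at patristic distance 0 are
treated as interchangeable by every metric.  Newick parsing and pruning
are delegated to dendropy; internal node labels and comments are ignored,
branch lengths accept scientific notation, and a missing root edge length
means 0.

## Evolutionary distinctiveness

Equal-splits ED walks from a tip towards the root, dividing each edge's
length by the product of child counts of the internal nodes passed so
far; the divisor generalizes the bifurcating "halve at every split" rule
to a k-furcation multiplying by k.  A non-zero root edge is apportioned
by the same rule, shared by all tips.  Fair-proportion ED divides each
edge equally among its descendant tips.  Both schemes conserve total
branch length exactly (each edge's shares sum to its length by induction
over subtrees), which the tests assert at relative tolerance 1e-9 on
random birth–death trees.

Two consequences used downstream: pruning can only *increase* a
surviving tip's equal-splits ED (divisors shrink when sibling subtrees
vanish, and merged edges keep their summed length), so every `ed_shift`
gain is non-negative; and the gain is exactly the evolutionary history
the survivor no longer shares with anything alive.

ED gain is defined as `ed_extant − ed_full` (prune, then subtract the
full-tree value).  The alternative sign convention — subtracting extant
ED from pre-extinction ED — appears in some descriptions of this
quantity but yields negative "gains"; we keep gains non-negative so that
a gain of 37.69 Myr reads as 37.69 Myr of newly private history.

## Host specificity

MPD is the unweighted mean of patristic distances over all unordered
pairs of a parasite's surviving documented hosts, 0 for a single host,
undefined (NaN, state `coextinct`) for none.  No abundance weighting is
applied anywhere.  Hosts documented for a parasite but absent from the
tree raise an error naming them rather than being silently dropped:
taxon-name mismatches are the dominant failure mode with real association
tables.  Coextinct parasites keep their identity in every output so
trajectories can count them; plotting-oriented filters (e.g. dropping
zero-change parasites) are output options, never data-model behaviour.

## Extinction scenarios

IUCN-ordered scenarios remove all hosts of a threat class per step, in
the order CR, EN, VU, NT; DD and domesticated hosts are treated as LC
and never removed; empty classes produce empty events so step indices
stay aligned.  Randomized scenarios are uniform permutations of one
parasite's documented hosts minus an arbitrary exclusion set (no taxon
names are hard-coded), one host per event, reproducible per seed with no
secondary sort key.  ΔMPD is always reported against the step-0
baseline.  Host switching and pre-extinction population decline are
deliberately outside the model: trajectories are the no-host-jump
projection of extinction impact, which is exactly what makes apparent
specificity shifts interpretable.

The coextinction rules: `all_hosts_lost` (coextinct iff zero documented
hosts survive) and `min_hosts_k` (coextinct below k hosts, for obligate
multi-host parasites whose net reproduction on any single host is below
replacement).  Under the default rule the coextinct set is verified
step-by-step against a plain set-intersection oracle.

## Virulence model

The trade-off $w(v) = b\,v^{s}/(\mu + v)$ with $0<s<1$ was chosen as the
concrete functional form because it is unimodal with $w(0)=0$,
$w\to 0$ as $v\to\infty$, and has the closed-form single-host optimum
$v^* = s\mu/(1-s)$, giving every numeric result an analytic oracle.  The
trade-off is an ordinary callable on the host class, so other forms can
be substituted.  Host contributions to the force of infection, $\rho_i$,
are fixed parameters (normalized to sum to 1), not derived from a
dynamic transmission model: the framework reasons at the level of
relative epidemiological contribution.  Virulence is one shared scalar
across hosts.

The joint optimum maximizes $\sum_i \rho_i w_i(v)$.  The weighted sum of
unimodal functions need not be unimodal, so a 4097-point grid over
$[0, 2\max_i v_i^*]$ locates the global basin before bounded scalar
minimization (xatol 1e-10) refines it; the result is clamped to the
provable bracket $[\min_i v_i^*, \max_i v_i^*]$ (the sum's derivative is
positive below the smallest optimum and negative above the largest).
Agreement with an independent 1e-4-step grid search is asserted to 1e-3.

One caveat discovered during verification: "the joint optimum is closer
to the dominant host's $v^*$" is *not* guaranteed for every weight just
above 1/2.  With $b,s$ equal and $\mu$ of 1 vs 3 ($v^*$ of 1 vs 3), the
host with the lower $\mu$ has a sharper fitness peak and pulls harder
per unit weight: at $\rho = 0.70$ for the high-$\mu$ host the joint
optimum is 1.899, still nearer 1.  Equalizing peak heights does not
remove the effect.  The skew holds under clear dominance (here
$\rho \ge 0.75$), and the monotone pull of weight towards a host's
optimum holds everywhere; the tests assert exactly that.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
with defaults fixed once:

| parameter | default | meaning |
|---|---|---|
| `n_tips` | 100 | host species; analyses scale to thousands |
| `tree_model` | Yule, λ = 1/Myr | birth–death with extinction optional |
| `n_parasites` | 50 | parasites per community |
| `phi` | 2 Myr | decay length of infection probability with distance |
| `alpha`, `beta` | −1, 1 | logistic threat model on standardized log₁₀ mass |
| `sigma_mass` | 0.5 log₁₀ units/√Myr | Brownian body-mass evolution |
| `root_log10_mass` | 3 (1 kg) | root state |

Each parasite draws a uniform focal host and infects every other host
independently with probability $e^{-d/\varphi}$; φ = 2 Myr on a
λ = 1 Yule tree yields a realistic mix of specialists and mid-size
generalists (median richness ~5–10 at 100–300 tips).  Body mass evolves
as geometric Brownian motion; the threat probability is logistic in the
*standardized* log mass so that β is comparable across tree depths.
Threatened hosts are split CR/EN/VU/NT by descending quartile of their
continuous risk score — a modelling convenience, since no continuous
risk-to-category mapping is standardized.  An ED-biased (rather than
mass-biased) extinct-flag mode is provided for studying loss of
evolutionarily distinct hosts.

What the generator does **not** emulate: geographic ranges and spatial
host overlap, co-phylogenetic structure of the parasites themselves,
sampling effort bias in association records, and correlated extinction
of close relatives beyond what mass heritability induces.  Passing tests
therefore demonstrate the correctness and statistical behaviour of the
pipeline, not the realism of any particular empirical dataset.

## Numerical choices and problem sizes

MPD uses a per-tree cached all-pairs distance matrix (computed once per
tree by post-order accumulation).  CSV outputs use fixed 6-decimal
formatting and seed-stamped `#` headers so reruns are byte-identical.
Classification and direction calls use tolerance 1e-9 on MPD and
virulence comparisons.  Property ensembles run at 200 trees (≤ 200
tips) for ED conservation, 100 tree/subset pairs for prune monotonicity,
100 networks (≤ 15 hosts) for the MPD oracle, 100 random scenarios for
trajectory invariants, 500 random systems for virulence bracketing, and
5000 tips for the logistic-slope recovery — sizes at which every
statistical check is comfortably powered while the whole suite runs in
well under a minute of compute plus the 5000-tip simulation.

## Known limitations

Reproduction of published large-scale ED-gain tables from real mammal
data depends on which posterior tree of the source atlas is used and on
taxon-name harmonization between tree and association data; such runs
are supported through the same file interfaces but are approximate by
nature.  The virulence model is a static optimality argument, not
adaptive dynamics: it identifies the direction of selection after
extinction, not transient dynamics or branching.
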
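# Methods

This note documents the models implemented in `otudelim`, the conventions
and defaults that matter for interpreting its output, and the limitations
a user should know before trusting a delimitation.

## Data model and missing data

The unit of analysis is an aligned set of barcode sequences over the IUPAC
alphabet plus `-`. Everywhere in the package, ambiguity codes and gaps are
treated as *missing* and excluded per column (site statistics) or per pair
(distances), never expanded fractionally. This matches common barcoding
practice; the alternative (fractional expansion of ambiguity codes) changes
results only in the third decimal on typical COI data but would complicate
every downstream contract.

Sequences are stored uppercase with `U` mapped to `T` on read. Morphospecies
labels live in a separate metadata TSV rather than being parsed from FASTA
headers, because headers in public-database dumps are too inconsistent to
parse reliably; a best-effort `accession|species` header splitter is
provided for convenience.

## Alignment statistics

A column enters the site classification only if it has at least two
unambiguous bases. It is *conserved* if exactly one state occurs,
*parsimony-informative* if at least two states each occur in at least two
sequences, and otherwise a *singleton*. These definitions make the
identities `conserved + variable = n_sites` and
`informative + singleton = variable` exact, which the test suite asserts on
random alignments.

The transition/transversion ratio R is the pooled **count** ratio over all
sample pairs (with pairwise deletion), computed column-wise from base
counts: with per-column counts `nA, nC, nG, nT`, pooled transitions are
`nA*nG + nC*nT` and pooled transversions `(nA+nG)*(nC+nT)`. R is *not* a
maximum-likelihood estimate; ML-based estimators give systematically higher
values at high divergence because they correct for multiple hits. When no
transversions are observed R is reported as undefined, not infinity.

## K2P distances

For each sequence pair, transitions and transversions are counted over the
columns where both sequences have unambiguous bases (*pairwise deletion* —
chosen over complete deletion because it wastes far less data on barcode
alignments with ragged ends). With proportions P and Q over the n compared
sites:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

A pair is flagged **undefined** when a log argument is non-positive
(saturation) or fewer than `min_sites` columns were compared. The library
default is `min_sites = 0` so that small benchmark alignments behave
transparently; the pipeline and CLI default to a floor of 100 sites, below
which a barcode-length distance estimate is too noisy to use. Undefined
pairs are never silently capped; consumers choose a `saturation_policy`:
`error`, `drop_pair` (greedily remove the fewest samples leaving no
undefined pair — the default), or `cap_at_max`.

Distances are stored as proportions end to end; only report layers render
percentages.

## Barcode gaps, the 2% screen and the 10× rule

Per species, the gap report compares the maximum intraspecific distance
against the minimum distance to any sample of any other species (the
nearest-neighbour distance). `gap_present` is the strict condition
`max_intra < min_inter`; the margin is also reported so users can apply a
softer visual standard. The 2% screen is reported as two independent flags
(`intra_gt_2pct`, `inter_lt_2pct`) rather than a verdict, since it is a
descriptive heuristic. The 10× rule compares dataset-level means
(`mean_inter / mean_intra >= 10`). The fraction of intraspecific distances
in the 0–2% band uses an inclusive upper bound (`d <= 0.02`).

## Neighbor joining and bootstrap

NJ is the standard Saitou–Nei Q-criterion agglomeration with two
deterministic conventions: sample ids are sorted lexicographically and ties
in the Q minimum are broken by the smallest (i, j) index pair, so results
are identical across runs and platforms; negative branch-length estimates
are clamped to zero with the deficit moved to the sister branch. On
additive matrices NJ provably recovers the generating topology, which the
suite verifies on random trees, and an independent NJ implementation
(scikit-bio's) is used as a topology cross-check.

Bootstrap support resamples alignment columns with replacement, recomputes
K2P + NJ per replicate, and reports for each bipartition of the full-data
tree the percentage of replicates containing it (support annotated on the
full-data tree, not a consensus tree). Replicates whose resampled matrix
contains an undefined distance are dropped and counted; more than 10%
dropped is an error, because support values from a heavily censored
replicate set would not mean what users expect.

## Barcode-gap partitioning (ABGD-style)

The partitioner scans the sorted unique pairwise distances (with 0
prepended) for the first spacing `(d_i, d_{i+1})` such that

1. the spacing ends beyond the prior maximum intraspecific divergence
   (`d_{i+1} > prior_p`), and
2. the spacing is wider than `relative_gap_X` times the largest spacing
   among the distances at or below `d_i`.

Samples are partitioned into the connected components of the graph linking
pairs with `d` below the gap midpoint (single linkage, mirroring the
graph-connection step of gap-based partitioning), and the same rule is
applied recursively inside each component until no gap is found or
`recursion_limit` (default 10) is reached. This explicit consecutive-spacing
detector is a deliberate simplification of the original slope-based gap
statistic: it is deterministic, easy to reason about, and equivalent on
clean gaps; `relative_gap_X` (default 1.5, the common web-interface
default) plays the role of the original X. A prior at or above the largest
distance yields a single group with a warning. The prior-grid scan reports
group counts across log-spaced priors and flags (rather than hides)
violations of the expected monotonicity.

## ML Poisson tree processes

The PTP model assumes per-branch substitution-event counts on a rooted,
non-ultrametric gene tree follow two exponential branch-length classes:
*speciation* branches between species and *within-species* branches. A
delimitation is a set of "transition nodes" — roots of within-species
subtrees tiling the leaves; edges strictly below a transition node are
within-class. Each class's rate takes its ML value n/L, giving per class
`logL = n ln(n/L) - n`.

Search: hill climbing over transition-node sets (split a node into its
children / merge sibling nodes), starting from the one-species state (which
*is* the one-class null model), the all-singletons state, nineteen
threshold-cut states (cut the tree wherever subtree branch lengths fall
below a quantile of the edge-length distribution — these seed two-class
structure at every scale and were necessary for reliable optima on
~150-leaf trees), plus seeded random restarts (default 10). Subtree edge
counts and lengths are precomputed so each candidate move evaluates in
O(1).

Two guards matter:

- **Branch-length floor** (`min_branch`, default 1e-4 substitutions/site,
  about one substitution per barcode length). Zero-length branches are
  common (identical haplotypes, collapsed polytomies); with an arbitrarily
  small floor, a within-class consisting of a few collapsed edges gets an
  unbounded rate and the degenerate everything-is-a-species state dominates
  the likelihood.
- **Likelihood-ratio gate**. The two-class model nests the null and its
  class assignment adapts to noise, so it always gains some likelihood even
  on homogeneous one-rate trees. A multi-species result is accepted only if
  `2 ΔlogL` exceeds the chi-square critical value at `lrt_alpha = 0.05`
  with `lrt_df = 4` (one extra rate parameter plus ~3 effective degrees of
  freedom for the data-adaptive placement of the rate shift). In simulation
  the spurious statistic on one-class trees stays below ~12 while genuine
  two-rate structure scores 20+, so the gate sits in a wide margin.

Polytomies are resolved arbitrarily with zero-length (floored) edges and a
warning, since consumed trees often contain them. The Bayesian-support
variant of PTP is out of scope; the ML division is the delimitation.

## K/θ (the 4× rule)

For two disjoint clades, θ is each clade's mean within pairwise K2P
distance and K the minimum between-clade distance; `K/θ >= 4` declares the
clades distinct (reciprocal monophyly with ≥95% probability under the
underlying population-genetic argument). The θ in the denominator is
configurable — `max` (default, conservative), `min`, or `pooled` — and all
three ratios are reported. Distances come from the K2P matrix, not tree
path lengths, matching how the statistic is defined on pairwise distances.

Delimitation traverses a rooted tree **post-order (agglomeratively)**:
leaves start as candidate OTUs; at each node whose children each resolved
to a single candidate clade, the child clades are tested pairwise and
merged when no pair is distinct; once any child stays split, no merging
happens above it. A top-down variant that stops at the first non-distinct
node was rejected: θ of a clade containing several species is inflated by
between-species pairs, so for more than two species the root comparison
always fails and everything collapses into one OTU.

Degenerate cases follow barcoding conventions: two multi-sample clades of
identical haplotypes (θ=0 on both sides) are separated by any positive K;
a singleton tested against a clade with positive θ uses that θ as its
scale; pairs with no usable scale at all (two singletons, or a singleton
against a θ=0 clade) merge and are retested higher up with more data. This
is what makes a single-sample clade end up as its own OTU exactly when its
nearest clade is distinct, without oversplitting inside ordinary species.

## Consensus and concordance

Strict consensus co-groups two samples iff every method does (the common
refinement, computed from per-method OTU-id signatures); majority consensus
co-groups on more than half the votes followed by transitive closure, which
is logged whenever it actually changes anything (majority co-membership
need not be transitive). Method agreement is the adjusted Rand index
(delegated to scikit-learn) plus an exact-identity flag. Against
morphology, each species is classified: `match` (exactly one OTU, shared
with no other species), `split` (several exclusive OTUs), `merge` (one
shared OTU), `mixed` (several OTUs, at least one shared), with partner
species listed.

## The synthetic-data generator

The generator exists so that every stage can be validated against known
truth without external downloads. Its model:

- **Species tree**: pure-birth (Yule), made ultrametric, then scaled so the
  pair-weighted mean between-species divergence equals `d_between` exactly
  — a bisection solves for the scale jointly with a height floor of
  `min_split_frac * d_between` (default 0.4), so no species pair is closer
  than `0.8 * d_between`. The floor is what makes `d_between` mean what a
  user expects ("species are about this far apart"); without it pure-birth
  draws produce occasional sister species at negligible divergence and no
  parameter recovery statement is possible. Configured merged pairs bypass
  the floor deliberately.
- **Within species**: star genealogies with exponential tip depths of mean
  `theta_within / 2`, so the expected within-species pairwise divergence is
  `theta_within`. A full coalescent is not simulated; the star model
  produces the within/between distance structure the delimitation methods
  consume, at a fraction of the complexity. Consequences: within-species
  distances are heavier-tailed than a coalescent would give (occasional
  deep outlier samples are *expected*), and within-species tree shape is
  uninformative.
- **Mutation**: exact K2P process (transition/transversion rate ratio
  `kappa`, uniform stationary distribution) via per-branch matrix
  exponentials, so simulated distances match the analysis model exactly.
  `base_freqs` (default slight AT bias, A/C/G/T = .267/.233/.233/.267) only
  affect the root draw; composition therefore drifts toward uniform with
  divergence, and the realised ts/tv **count** ratio is ≈ `kappa/2` at low
  divergence and lower once transitions saturate.
- **Planted structure**: cryptic complexes (one label spanning n lineages
  whose roots sit `divergence/2` below the species node) and merged pairs
  (two labels on a cherry at the stated divergence, intended to be *below*
  typical species divergence). Optional mislabeling swaps labels across
  species. Every dataset ships its true lineage partition, label partition
  and generating tree; emission is byte-deterministic given the seed.

The `mackerel_like` preset (150 samples, 14 morphospecies with realistic
uneven sample counts, θ=1.2%, d=13%, one 4-lineage cryptic complex at 6%,
one merged pair at 0.3%, κ=8 so the realised count-ratio R lands near 3 at
these divergences) shapes a dataset after a typical single-genus COI
barcoding study in which 14 named species resolve into ~17 molecular
lineages.

**What passing tests do and do not show.** The simulator matches the
analysis assumptions by construction (K2P mutation, no indels, no rate
variation across sites, no recombination, star coalescence). Recovery
results on it demonstrate the *implementations* are correct and internally
consistent — not that the methods are robust to alignment error,
heterotachy, introgression, or sampling artefacts in real data.

## Problem sizes used in validation

The shipped validation runs at desk scale, chosen to exercise every code
path with comfortable statistical margins: toy oracles are exact; oracle
comparisons use 100–1000 random instances; the end-to-end recovery study
uses 100 seeded datasets of 5 species × 6 samples × 650 bp (within 0.5%,
between 10%), on which barcode-gap partitioning recovers the true species
count in ≥95% of runs and the tree-based methods in ≥95% when given the
generating tree. With NJ trees rebuilt from 650-bp matrices instead,
tree-based recovery drops to ~60–70% — NJ arbitrarily resolves the true
star genealogies within species and its branch-length noise creates
spurious structure — which is why tree-based delimitation should be fed the
best available tree, and why the pipeline accepts an external tree as
input.

## Known limitations

- Single-locus logic throughout: no multi-locus or coalescent-model
  delimitation, and mitochondrial-specific caveats (introgression,
  male-biased dispersal) are invisible to every method here.
- The gap detector is a clean-gap variant; datasets whose intra/inter
  distributions genuinely interleave will be split at whatever spacing
  first satisfies the rule, and the prior-grid scan (not a single run) is
  the honest way to read such data.
- The PTP likelihood-ratio df is an approximation; its calibration is
  demonstrated by simulation, not derived.
- K/θ verdicts on clades of 1–2 samples rest on very little information;
  the merge-and-retest policy avoids systematic oversplitting but two
  sister singleton species cannot be separated by this statistic at all.
- `cap_at_max` exists for completeness but biases downstream means; prefer
  `drop_pair` (default) or fix the alignment.
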
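# Methods

This note documents the models, rules and numerical choices behind
`phylotier`, in the spirit of a methods supplement: what is computed, under
which assumptions, and where the design was genuinely open.

## Substitution models and likelihoods

All likelihood work uses reversible GTR-family nucleotide models (JC and
HKY85 as constrained cases) with stationary frequencies π and the rate
matrix scaled so the mean substitution rate at stationarity is 1; branch
lengths are therefore expected substitutions per site.  Among-site rate
variation follows a Gamma(α, α) distribution, discretised into
equal-probability categories whose rates are the conditional means of the
within-category density (default 4 categories).  With one category, or
α = ∞, the model is exactly rate-homogeneous.

Two places deliberately use the *continuous* Gamma mixture instead of the
discretisation:

* **Pairwise ML distances.**  For two sequences the mixture integrates
  analytically eigenvalue-wise — e^{λt} is replaced by (1 − λt/α)^{−α} —
  so the fitted distance reproduces the classical closed forms exactly
  (e.g. JC+Γ: t = (3/4)·α·((1 − 4p/3)^{−1/α} − 1); at α = 0.5 and
  p = 0.25 this is 0.46875).  Tree likelihoods cannot use this shortcut
  because the site's rate is shared across branches.
* Nothing else; pruning always uses discrete categories.

Site patterns are compressed per partition (models are unlinked across
partitions; partitions never share patterns).  Tip ambiguity codes enter
pruning as their IUPAC state sets; `N`, `?` and `-` contribute partial
likelihood 1 for every state.  In *distance* computations all non-ACGT
characters are treated as missing, and a site is comparable only when both
sequences are determinate.  Per-node rescaling (tracked in log space)
prevents underflow on large or long trees.

Branch-length optimization is round-robin Brent per branch
(bounds [1e−8, 10], tolerance 1e−6 log-units by default), with conditional
likelihoods recomputed before each branch so the total log-likelihood is
non-decreasing across sweeps; a decrease beyond tolerance raises (a bug
trap, not a user error).  Model fitting on a fixed topology sets base
frequencies empirically (pseudocount 1e−6 guards the eigendecomposition
against zero frequencies), then alternates Nelder–Mead over
log-exchangeabilities and log-α with branch-length re-optimization.

## Placement on a fixed backbone

The backbone topology and its branch lengths are held fixed.  For each
backbone edge, two conditional likelihood vectors are available from a
two-pass pruning sweep: the subtree below the edge and the rest of the
tree.  Grafting the query onto that edge then costs O(patterns) per
likelihood evaluation regardless of tree size, and only the three local
lengths (the two sub-edges created by the attachment node, initialised at
half the original edge length, and the pendant, initialised at 0.1) are
optimized, coordinate-wise by Brent, pendant first.  Edges are identified
by the leaf-set bipartition they induce, so placement records are stable
across replicates and rogue deletions are set operations.

**Bootstrap.**  Site resampling (stratified within partitions, preserving
partition sizes) is equivalent to redrawing pattern weights from a
multinomial, so the conditional likelihoods are shared across replicates.
Each replicate scores every edge at its full-data local optimum, then
re-optimizes the best five candidates (one coordinate sweep, search
bracketed within ×16 of the seed values, length tolerance 0.02) and
records the winner.  The preselection mirrors standard placement-tool
practice; with ~20 candidate edges and the margins typical of multi-kb
data the tally is insensitive to it, and support values are insensitive to
branch lengths at the 0.02 level because the edge ranking is driven by
log-likelihood differences orders of magnitude larger.

**Rogue-aware summaries.**  Designated rogue taxa are pruned from the
backbone and re-placed jointly with the query in every replicate
(most-complete taxon first), and each replicate stores the full augmented
tree.  *Effective support* for a clade C with rogues R is the percentage
of replicates in which, after pruning R from the replicate tree,
C∖R ∪ {query} is monophyletic — i.e. the query attaches inside or as
sister to the rogue-free clade.  With R = ∅ this is the plain bootstrap
support for the clade including the query.  For hand-constructed tallies
(descriptor records without trees) the same rule is evaluated on the
attachment splits, with recorded rogue positions deciding monophyly; a
query nested strictly inside a rogue group is conservatively counted as
non-qualifying.  *Region support* counts replicates whose attachment edge
has at least one region taxon on both sides, or one side fully inside the
region — exactly the edges of the region's subtrees and their connecting
spine.

**Subset selection** greedily accumulates backbone clades by
support-gain-per-taxon until the region support of the union reaches the
threshold (deterministic tie-breaks: larger gain, smaller clade,
lexicographic), then adds the k least-missing representatives of each
named outgroup clade (ties lexicographic).

## Saturation screen

For each gene × codon-position unit, taxa with ≥ 50 determinate sites
(`min_sites`) enter two distance matrices — uncorrected p-distances and
HKY85+Γ ML distances — each turned into a neighbor-joining tree; the
paired tip-to-tip (patristic) distances from the two trees form the
saturation plot (model-corrected on x, observed on y).  The plateau is
operationalised as a two-piece OLS slope ratio: slope of y on x above the
median x over the slope at or below it.  A unit is excluded when the ratio
falls below 0.5 or the global OLS slope below 0.3 (both config-exposed;
they are explicit substitutes for a visual judgement and are reported in
every output).  Perfectly linear data give ratio ≈ 1; both statistics are
invariant to rescaling all branch lengths.

The per-unit HKY model for distances uses empirical frequencies, a pooled
transition/transversion moment estimate of κ (Kimura-formula family;
saturated pairs make a likelihood fit of κ unstable), and a fixed Gamma
shape of 0.5 — distance-tree *shapes* are insensitive to α, and only the
ranking/plateau geometry matters here.

**Outliers.**  A taxon's score is its median model-corrected tip-to-tip
distance to all others; it is flagged when the score exceeds the overall
median by 5 MADs, with the MAD floored at 0.25 × median.  The floor
matters: in panels of a dozen taxa the raw MAD collapses toward zero and
would flag ordinary among-lineage rate variation (scores within ~2× of
the median), while genuine contaminants sit orders of magnitude higher
once corrected (a random sequence has p ≈ 0.75, which Γ-corrected
distances map beyond any plausible tree depth).  Because one extreme
sequence distorts the whole NJ tree and inflates its neighbours' path
lengths, flagged taxa are peeled iteratively — remove the worst, rebuild
the unit's trees, re-test — and the plateau assessment runs on the peeled
pairs, so a single contaminant cannot sink an otherwise clean unit.
Exclusion is local: the taxon's cells in that unit are masked to `?`; its
other markers are untouched.

## RELL and the AU test

Site-wise log-likelihood matrices are computed per tree with branch
lengths optimized independently; rows share one site order and sum to the
tree's total log-likelihood.  RELL replicates resample site columns with
replacement within partitions (multinomial weights; no re-optimization).
The AU procedure resamples at scales r ∈ {0.5, 0.6, …, 1.4} (replicate
size ⌈r·n⌉, 10 000 replicates per scale by default), records each tree's
winning proportion BP(r) with ties split as equal fractions, fits
z(r) = Φ⁻¹(1 − BP(r)) against (√r, 1/√r) by weighted least squares with
weights B·φ(z)²/(BP(1−BP)), and reports p = 1 − Φ(d − c).  Proportions of
exactly 0 or 1 are continuity-corrected to 1/(2B) and 1 − 1/(2B); a tree
with fewer than three informative scales gets a degenerate p of 1/(2B) or
1 − 1/(2B) with a flag.  The two-tree comparison is the same multi-tree
procedure run on the pair, and a KH-style one-sided normal approximation
on RELL differences is available as an ordering cross-check.  Calibration
is assessed marginally: under an exchangeable two-tree null the frequency
with which a *fixed* tree's p falls below 0.05 should be ≈ 0.05 (the
minimum of the two p-values would double-count by symmetry).

## The synthetic-study generator

`default_study_config` defines the reference study: a 12-leaf random
binary backbone with uniform branch lengths in [0.008, 0.045] — giving
tip-to-tip depths up to ≈ 0.3 substitutions/site for nuclear markers, the
regime of real multi-marker amphibian supermatrices — and six markers
(~5 kb): two mitochondrial protein-coding genes (HKY κ=6, AT-rich, α=0.4,
rate ×1.5, codon-position rates 1 : 0.5 : 15), one mitochondrial rRNA
(×1.2), and three nuclear protein-coding genes (HKY κ=3, α=0.8, position
rates 1 : 0.5 : 1.5).  Third positions of the mitochondrial genes are
thus ×22.5 overall — deeply saturated (corrected depths of several
substitutions per site) — while every other unit stays in the linear
regime; the screen's expected answer is planted by construction.  The
query attaches at a random backbone edge with pendant 0.05.

Missing data are masked as whole taxon × marker blocks (the structure of
real supermatrices, and the structure the completeness ranking in subset
selection must see), never scattered cells, until the global fraction is
within ±2% of target; a taxon always keeps one marker.  Contaminants are
i.i.d. uniform bases over one taxon × marker block.  All randomness flows
through `numpy.random.Generator` seeded from the config, so identical
configurations are byte-identical.

What the generator does *not* emulate: indels and alignment error,
base-composition heterogeneity across lineages, codon structure beyond
per-position rates (no selection), and gene-tree discordance — passing
tests demonstrate the machinery is correct under the model it assumes, not
that real supermatrices satisfy that model.

## Pipeline

`run_two_tier` is a pure function of (inputs, config, seed): stage seeds
are derived from the master seed, every artifact is written with sorted,
timestamp-free serialization, and a rerun is bytewise identical.  Every
exclusion (unit, taxon-marker, outlier) lands in the run log with its
triggering statistic.  Per-unit models in the pipeline are the quick
moment-estimated HKY+Γ models with a relative rate multiplier (the unit's
mean pairwise ML distance over the site-weighted global mean), so unlinked
models share one backbone branch-length set; a config flag enables full
backbone branch-length re-optimization under those models.  Hypothesis
trees for the AU stage are built by regrafting the query onto the
best-fitting tier-2 tree at each named clade — rivals are therefore not
penalised for unrelated topological differences.

Problem sizes in the test suite and acceptance script — 10–12 leaf
backbones, ~5 kb, B = 100 bootstrap replicates, 500 null matrices at 1 000
RELL replicates per scale — were chosen so the full property suite
exercises every stage end to end in minutes on one CPU.

## Known limitations

* Placement optimizes three local branch lengths per candidate edge; a
  full re-optimization of all branch lengths per candidate (available via
  the slower `optimize_branch_lengths` on grafted trees) may shift
  likelihoods slightly when backbone lengths are poor.
* The moment estimate of κ and the fixed α = 0.5 in the saturation screen
  are deliberately crude; they feed distance *trees*, not inference.
* `select_subset` is greedy; the "smallest union" is exact in the common
  concentrated-tally case but not guaranteed minimal in pathological
  tallies.
* Multiple queries are placed sequentially with one refinement pass, not
  jointly.
* The AU implementation follows the standard multiscale-bootstrap
  formulation; very flat likelihood surfaces (fewer than three informative
  scales) are reported as degenerate rather than extrapolated.
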
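# Methods

## Detection calls

A probeset's presence in one array is decided from its PM/MM probe pairs.
The discrimination score R = (PM − MM)/(PM + MM) lies in (−1, 1); near 0
for background-only pairs, approaching 1 for strong specific signal. The
test is a one-sided Wilcoxon signed-rank of H₀: median(R) = τ against
median(R) > τ with τ = 0.015. Differences exactly equal to zero are dropped
before ranking; tied absolute differences receive midranks. P/M/A call
thresholds are 0.04/0.06 (the conventional defaults), while the
compendium-wide filter applies its own α = 0.05 to the p-value itself; the
two are deliberately separate parameters because a screen may want the
filter stricter or looser than the call convention.

The null distribution is computed exactly for up to 25 informative pairs by
convolving the doubled ranks (doubling turns midranks into integers), so
the standard 11-pair probeset always takes the exact path; the p-value is
P(W⁺ ≥ observed) over the 2ⁿ equiprobable sign assignments. Above 25 pairs
a normal approximation with tie and continuity corrections is used. Fewer
than three informative pairs make the test indeterminate, which the filter
treats as Absent. The exact-null survival function is cached per rank
multiset, so calling a full compendium (thousands of probesets sharing the
untied 1..11 rank pattern) costs one convolution, not one per probeset.

The filter itself is intentionally severe: a gene must achieve p < α in
*every* array of *every* replicate group. One failing replicate excludes
the gene — the behaviour that removes classical references like Actin1
when a single tissue fails to express them.

## CV screening and panel selection

CV = SD/mean is computed on linear-scale normalized intensities (means in
the hundreds to tens of thousands), never on log values: on a log scale the
ratio SD/mean is not scale-free and cannot be compared across genes of
different abundance. The SD uses the n−1 denominator; with tens to hundreds
of arrays per scope the choice is numerically immaterial, and the
fixed-point check against the published panel is denominator-independent
since it recomputes CV from printed mean/SD pairs. A gene with zero mean
has undefined CV and is excluded from ranking and selection.

The three scopes are development, stress = abiotic ∪ biotic, and entire =
all samples including hormone treatments (hormone arrays enter *only* the
entire scope). Stability is the OR-combination: CV at or below the cut-off
in at least one scope. The only published cut-off value, 0.35, is the
default for all three scopes; each is an independent `SelectionConfig`
parameter. Per-scope picks are purely rank-based among stable genes (no
additional per-scope threshold is imposed on them), ties broken by gene id.
The random extras are drawn without replacement from a lexicographically
sorted candidate pool with `numpy.random.default_rng(rng_seed)`, making
the "randomly selected" picks reproducible. Provenance tags are assigned in
the order stress → development → entire → random and are mutually
exclusive: a gene taken by an earlier criterion is skipped by later ones.

Display rendering of CV uses half-up rounding at two decimals (the
reporting convention of the field's tables); all computation is at full
float precision.

## geNORM engine

Implemented from the published definition rather than wrapping the
original closed-source tool. Fixed conventions: log base 2, SD with the
n−1 denominator, amplification efficiency default E = 2.0 (perfect
doubling). V_jk = SD over samples of log₂(a_j/a_k); M_j is the arithmetic
mean of V_jk over partners. Since V_jk depends only on genes j and k, the
pairwise matrix is computed once and the stepwise exclusion just averages
shrinking submatrices, making the ranking O(G²) after an O(G²·S) setup;
each row of V is computed as the SD of explicit log-ratio differences
(not via the covariance identity, which loses the exact zero of
proportional genes to cancellation). Ties on M at an exclusion step are
broken by gene id, the greater id leaving first; the final two genes share
one M equal to their pairwise V, and within the final pair the smaller id
ranks first. These tie rules are declared conventions chosen for
determinism, not inferred behaviour of any existing tool.

Ct tables may contain missing values ("not measured"); the Ct → quantity
transform keeps them missing and pairwise statistics use pairwise-complete
samples with a minimum overlap of two. Normalization factors are per-sample
geometric means of the chosen genes' quantities; V_{n/n+1} compares NF
built from the n and n+1 most stable genes, and the recommended panel size
is the smallest n ≥ 2 with V below the 0.15 convention — when the series
never meets it, G−1 is reported with an explicit flag rather than silently.

## Clustering and reporting

Replicate averaging takes the mean of log₂(max(value, floor)) per replicate
group with floor = 1.0 (GC-RMA-style outputs are ≥ ~1 in practice; the
floor only guards degenerate sub-1 values and is configurable).
Average-linkage clustering on Euclidean distance is implemented with
Lance-Williams updates; among minimal-distance pairs the smallest (i, j)
cluster-index pair merges first, with leaves numbered in input order and
internal nodes in creation order — a declared deterministic rule. Average
linkage is reducible, so merge heights are nondecreasing; the test suite
asserts this on random instances and checks the merge tree against a
brute-force recomputation of mean inter-cluster distances from raw leaves.
The dendrogram is exported as leaf order plus a simple nested-parentheses
text form; no figure rendering is attempted.

The two-group comparison (e.g. mock vs infected replicate means) is an
equal-variance Student's t-test by default, with the Welch variant behind a
flag; the degenerate zero-variance-equal-means case returns p = 1. The
combined report joins geNORM M values with entire-scope CVs and sorts by
(M, CV); genes missing from either input are flagged with an asterisk and
listed last — stability on only one axis is visible, not hidden.

## Synthetic compendium generator

The generator emulates the structure that makes multi-laboratory screens
hard, not any particular organism's biology: 16 replicate groups across
the four partitions (6 development, 5 abiotic, 3 biotic, 2 hormone), each
assigned to one of 8 studies and carrying 2–4 replicates, ~49 arrays in
total at defaults; 500 genes split 10% stable / 40% responsive / 20%
tissue-absent / 30% housekeeping-like; base abundances uniform on 2⁶..2¹⁴.

Intensities are log-normal: value = 2^(base + batch + effect + ε). The
batch term is a **gene-by-study** interaction (SD 0.3 log₂). A study-level
shift common to all genes would be a per-sample rescaling that CV is
exactly invariant to, so it could not model the CV inflation that
multi-laboratory compendia exhibit; the interaction term does. Responsive
genes receive a ±2 log₂ (4-fold) shift independently per replicate group
with probability 0.5 — in every partition, modelling genes regulated
across tissues and treatments alike. This matters for what the tests can
claim: a gene responsive only to stress would be CV-stable in the
development scope and the OR-combined screen would rightly keep it, making
"responsive genes leak ≤ 5%" unmeasurable. Tissue-absent genes drop to
near-background (2⁵, SD 0.3 log₂) in 1–3 randomly chosen groups. Noise SDs
are 0.15 (stable), 0.25 (responsive/tissue-absent when expressed) and 0.4
(housekeeping-like) log₂ — the last chosen to straddle the 0.35 CV cut-off
so that selection is nontrivial at the boundary.

Probe-level data: per-probeset affinities 2^N(0, 0.5) drawn once and
reused across samples (detection calls correlate within a probeset as on
real arrays); PM = (signal·affinity + 30)·u, MM = 30·u′ with u = 2^N(0, 0.1).
Expressed genes at the lowest base abundance still yield median R ≈ 0.3 ≫ τ,
absent genes R ≈ 0, so the detection stage is informative but not
degenerate. Simulated Ct values are offset − log₂(expected expression) +
N(0, 0.2) cycles per replicate group, with per-gene noise overrides for
planting deliberately unstable genes.

All randomness flows from one `numpy.random.default_rng` (PCG64) seed in a
fixed order; identical configuration gives bitwise-identical tables, which
is what the end-to-end byte-identity check relies on.

### What the generator does not emulate

Probe GC-content effects, spatial artifacts, saturation, cross-
hybridisation, unbalanced replicate loss, and correlated responsiveness
between genes (each responsive gene draws its group shifts independently).
Passing recovery tests on this generator therefore shows the pipeline's
statistics behave as specified under a realistic noise/batch structure; it
does not certify performance on any real compendium, where detection-call
error and normalization artifacts are platform-specific.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at the
generator's default scale (500 genes × ~49 arrays, ~270k probe rows;
~10 s), oracle comparisons at small sizes where exhaustive enumeration is
exact (2ⁿ sign patterns for n ≤ 12; G ≤ 6, S ≤ 8 for geNORM re-enumeration;
6×4 matrices for the O(n³) clustering oracle), and 200-replicate seeded
studies for the planted-unstable elimination rate. Float comparisons
against oracles use absolute tolerances of 1e-10..1e-12; exact-null
p-values are compared exactly up to 1e-12. Numbers reported by the package
(CV display, report tables) render at full precision with a separate
2-decimal display column.

## Known limitations

* The detection stage implements only the call algorithm; signal
  estimation (Tukey biweight, scaling, background correction) is out of
  scope, and the pipeline consumes already-normalized matrices.
* The expressed-everywhere filter supports p-value matrices without a
  paired expression matrix (real collections sometimes ship calls for
  arrays whose raw files are unavailable), but the CV stage then simply
  has fewer columns — no imputation is attempted.
* geNORM's original software may break ties differently; rankings agree
  wherever M values are distinct.
* The V_{n/n+1} recommendation is a convention, not a test; the package
  reports the series so a user can see how close the margin is.
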
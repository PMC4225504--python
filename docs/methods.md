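# Methods

This note documents the models, numerical choices, and design decisions
behind phylokit, and what the synthetic-data tests do and do not establish
about behavior on real data.

## DNA distance estimation

Pair counting produces the sufficient statistics (valid sites, matches,
A↔G transitions P₁, C↔T transitions P₂, transversions Q, and fractional
base tallies) in one pass per pair. Sites where either sequence has a gap
are excluded (pairwise deletion). Two counting modes exist:

* **ambiguity mode (default for in-memory matrices)** — a site pairing
  IUPAC symbols with candidate sets S_a, S_b adds weight 1/(|S_a||S_b|) to
  the category of every (x, y) ∈ S_a×S_b. This is the uniform expectation
  over candidate resolutions: deterministic, symmetric in the two
  sequences, and exactly equal to plain counting when no ambiguity codes
  are present. Base tallies likewise spread 1/|S| over the candidates.
  Other weightings (e.g. composition-weighted resolution) are defensible;
  uniform was chosen for having no free parameters.
* **strict mode** — any site with a non-ACGT symbol is excluded. The
  row-streaming path uses this mode only, keeping its inner loop on a
  packed 2-bit-representable alphabet; streamed and in-memory results are
  required (and tested) to be bit-identical.

The four estimators are the standard closed forms (p, Jukes–Cantor, Kimura
2-parameter, Tamura–Nei 1993). TN93 estimates base frequencies per pair by
default; a `global_freqs` option substitutes the alignment-wide
composition, which stabilizes the estimate when individual pairs have few
sites. Saturation — any correction logarithm at a non-positive argument —
and pairs with zero comparable sites yield NaN entries. NaN is deliberately
not given a numeric stand-in by default; downstream consumers either
substitute an explicit `--saturation-distance` or fail loudly, because any
silent default (twice the maximum? a fixed 10?) biases tree shape in a way
the user should opt into.

`partition_rows` splits the upper-triangular workload (row i costs n−1−i
pairs) into contiguous blocks balanced to within one row's work, so
external schedulers can distribute block computation and concatenate the
streamed results.

## Protein distance estimation

The five bundled empirical models (WAG, JTT, Dayhoff, MVR/VT, LG) are
stored as PAML-layout rate files: 19 rows of lower-triangle
exchangeabilities S followed by stationary frequencies π (sources cited in
each file header). Loading validates symmetry and normalization, builds
Q[i,j] = S[i,j]·π[j] with the diagonal set to make rows sum to zero, and
rescales Q so −Σ π_i Q_ii = 1; distances are therefore in expected
substitutions per site (multiply by 100 for PAM units via `--pam`).

Because the models are reversible, diag(√π)·Q·diag(1/√π) is symmetric; its
eigendecomposition gives P(d) = e^{Qd} and the first two derivatives in
closed form. The two-sequence log-likelihood is
ℓ(d) = Σ_ab N[a,b]·ln(π_a P_ab(d)), invariant under transposing the count
table N.

**ML estimator.** Newton–Raphson on ℓ′(d) with analytic ℓ″, bracketed on
[d_min, d_max] = [1e-6, 10], derivative tolerance 1e-8, at most 50
iterations, initialized from Kimura's correction of the observed
p-distance. Any step that leaves the bracket, encounters non-negative
curvature, or exhausts the iteration budget falls back to golden-section
search on ℓ over the bracket (tolerance 1e-10). Identical sequences return
d_min; a likelihood still rising at d_max returns d_max flagged as
saturated. d_max = 10 is well past the point where P(d) is numerically
stationary for all bundled models.

**Expected estimator.** E[d|a,b] is the posterior mean over a discrete
prior; the default is flat weights on a 400-point geometric grid over
[1e-4, 10]. The geometric spacing matches the likelihood's roughly
log-scale curvature so short distances are not under-resolved.
Likelihoods are combined with a log-sum-exp shift; a posterior that
underflows everywhere raises rather than returning an arbitrary value.
This flat grid prior is this package's own documented choice; with
informative priors the estimator is the usual Bayesian posterior mean and
inherits the prior's shrinkage.

## Tree reconstruction

All three builders share one agglomeration state: working matrix D over
active nodes, row sums R maintained incrementally, the selection criterion
S(i,j) = (m−2)D(i,j) − R(i) − R(j), and the NJ branch-length rule
l_i = D(i,j)/2 + (R(i)−R(j))/(2(m−2)). The last three (or two) nodes are
resolved by the closed-form three-point/two-point lengths; the serialized
root is the final trifurcation.

* **NJ** evaluates S for every active pair each iteration.
* **FNJ** stores one candidate partner per node (found by a linear row
  scan at node creation). Each iteration evaluates S only on the visible
  pairs {(i, vis(i))} under the current m and R, joins the minimum, and —
  when a node's stored partner was consumed by a join — refreshes that
  node's entry with a fresh row scan; the new node scans once. The joined
  pair is by construction always a member of the visibility set. Total
  S-evaluations are empirically ≤ c·n² (asserted over n = 50…400); the
  rescan-on-stale policy trades a small constant factor for robustness of
  the additive-case guarantee below.
* **BioNJ** selects pairs like NJ but propagates a variance store V
  (initialized to D) and reduces with
  D(u,k) = λ(D(i,k)−l_i) + (1−λ)(D(j,k)−l_j), where
  λ = ½ + Σ_k (V(j,k)−V(i,k)) / (2(m−2)V(i,j)), clamped to [0,1] and set
  to ½ when V(i,j)=0. On additive inputs D(i,k)−l_i = D(j,k)−l_j, so the
  reduction coincides with NJ's for every λ.

Ties in S break toward the lexicographically smallest pair of original
node indices — deterministic and permutation-checkable. Negative branch
lengths are kept by default, faithful to the canonical estimators; an
optional floor clamps a branch and transfers the deficit to its sibling so
the joined pair's path length is preserved.

On additive matrices all three methods provably (NJ) or testably (FNJ,
BioNJ) return the generating tree; the suite asserts topological identity
(Robinson–Foulds 0) and branch lengths to 1e-10 at n ∈ {8, 20, 50}. On
noisy matrices the methods legitimately differ; a simulation test asserts
only BioNJ's non-inferiority to NJ in topology accuracy.

## Bootstrap

Columns are resampled i.i.d. with replacement, jointly across taxa.
Replicate r uses NumPy's PCG64 seeded with the SeedSequence [seed, r], so
any replicate is recomputable in isolation — the property that makes
per-replicate parallel jobs exact, not just statistically equivalent. With
no seed given, a clock-derived seed is drawn and logged to stderr.
Resampling operates on raw columns, before any ambiguity handling.

## Synthetic data

Topologies are drawn uniformly over labeled unrooted topologies by
sequential random attachment to a uniformly chosen edge; branch lengths
are i.i.d. exponential (default mean 0.1 substitutions/site). Sequences
evolve site-independently: root from π, each edge applying e^{Qℓ}. Default
lengths are 2,000 sites for DNA and 350 for protein — typical single-gene
scales. DNA ambiguity injection replaces a stated fraction of leaf bases
with a uniformly chosen compatible IUPAC code.

What the generator does *not* emulate: indels and alignment error (gaps
only arise via explicit injection), site-rate heterogeneity, compositional
drift across the tree, and non-uniform topology priors (Yule/coalescent
shapes). Passing the parameter-recovery suites therefore shows estimator
correctness *under the model each estimator assumes*, not robustness to
model violation on real data.

## Problem sizes used in the test and acceptance suites

Chosen to make the checked properties sharp while keeping the default run
fast: sequence length 10⁵ with ~8 replicates for DNA consistency (binomial
standard error ≈ 2·10⁻³ at d = 0.3); 200 replicates of length 350 for
protein ML bias at d ∈ {0.1, 0.5, 1.0}; additive recovery at n ∈ {8, 20,
50} × 20 trees; NJ brute-force equivalence up to n = 12; FNJ work counts
at n ∈ {50, 100, 200, 400}; binary size-law validation at n ∈ {100, 1000}
with the n = 100,000 footprint evaluated analytically.

## Known limitations

* No gamma rate heterogeneity, LogDet, or model selection for DNA; no
  site-rate or profile variation for proteins.
* The ambiguity weighting is the uniform-expectation convention described
  above; published bit-parallel counting schemes may weight differently.
* Saturated entries cannot be represented in the binary format by design;
  producers must substitute a finite distance first.
* FNJ's quadratic work bound is asserted empirically on the tested sizes,
  not proven for adversarial inputs under the rescan-on-stale policy.
* The XML dialect is this package's own minimal schema (self-describing
  via `--print-schema`); it is not byte-compatible with any other tool's
  XML.
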
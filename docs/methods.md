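# Methods

## Scope and model

`tadsi` scores chromosomal rearrangements (CRs) for their potential to
disrupt 3D genome organization. The underlying model: a CR is a candidate
3D-acting pathogenic event when (i) it contains at least one TAD boundary,
so the rearrangement can restructure the neighbouring domains, and (ii)
strong enhancers lie near its breakpoints or near that boundary, so the
restructured domains can rewire enhancer–gene contacts. Both features are
measured per cell line from a binned Hi-C contact matrix and a
chromatin-state segmentation, combined as a product of within-cohort
percentiles (the SI score), and assessed against a pairing-permutation
null.

## Coordinates and intervals

All coordinates are 0-based half-open `[start, end)` (the BED convention);
a CR's length is `end − start`. This reproduces published CR lengths
exactly from their printed genome loci (e.g. a deletion at
chr2:220019492–220643226 has length 623,734 bp). Enhancer base-pair
tallies are coverage measures: overlapping records are merged before
counting, so no base is counted twice. CR tables are ingested
permissively — rows with unknown types or degenerate intervals are
rejected with a recorded reason rather than aborting the read.

## Contact matrices

Matrices are dense, per-chromosome, symmetric and nonnegative. COO triplet
text (either triangle) and dense text are read; symmetrization is by
max-fill, and conflicting duplicate COO entries resolve to the larger
value with a warning. Normalization is optional and off by default
(`balance(method="ice")` provides iterative correction when wanted); raw
and balanced runs are distinguished by the config header every CLI output
carries. Zero-coverage bins are retained so the bin↔coordinate mapping
stays trivial; the insulation step masks bins whose marginal is below 10 %
of the median row sum.

## Boundary calling

* **Insulation.** For window `w` (bins), `raw(i)` is the mean contact in
  the square `[i−w, i−1] × [i+1, i+w]`; the normalized track is
  `log2(raw / mean raw)` over valid bins. Bins within `w` of the matrix
  edge, low-coverage bins, and bins with `raw = 0` are invalid.
* **Directionality index (DI).** Dixon's statistic
  `sign(B−A)·((A−E)²/E + (B−E)²/E)` with `A`/`B` the upstream/downstream
  contact sums within the window and `E = (A+B)/2`; zero when `A = B` or
  `A + B = 0`. Windows truncate at chromosome ends.
* **Segmentation.** A 3-state HMM with Gaussian emissions is fit to the DI
  track by EM with deterministic initialization (means at the 10/50/90 %
  DI quantiles, shared variance, sticky transitions) and a fixed seed;
  decoding is Viterbi. States are labelled by fitted mean: most negative →
  upstream-biased, most positive → downstream-biased, middle → unbiased. A
  constant (e.g. all-zero) DI track short-circuits to all-unbiased.
  `emissions="mixture"` swaps in 3-component Gaussian-mixture emissions
  per state; its EM uses a looser convergence threshold because on a
  single long sequence the mixture degenerates if driven far past
  convergence.
* **Calls.** A boundary is placed between an upstream-biased run and the
  next downstream-biased run (domain end → domain start), refined to the
  nearest local minimum of normalized insulation within ±5 bins. Its
  strength is the insulation valley depth there: the smaller of the two
  flanking maxima minus the valley value, clamped at zero. Valley depth is
  one of several boundary statistics in use in the field; it is the single
  definition used everywhere downstream and is recorded in output
  metadata.

Window defaults are 50 bins (500 kb at 10 kb resolution) for insulation
and 2 Mb for DI — the conventional genome-scale settings for ~1 Mb TADs.
The synthetic benchmarks in the test suite and acceptance script use 10
bins and 400 kb respectively, scaled to the generator's 100-bin TADs by
the same window-to-domain ratio reasoning.

## CR scoring

Filtering keeps deletions/duplications/inversions, on configured
chromosomes, with length in [100 kb, 10 Mb] by default (bounds are
mandatory config, echoed in the filter report), containing ≥ 1 boundary.
The per-CR **Insulation Score** is the maximum boundary strength inside
the CR. The default **Enhancer Score** sums strong-enhancer base pairs
over the three 400 kb windows centred on the two breakpoints and the
strongest contained boundary; the three tallies are summed per-window
(windows of short CRs may overlap; a `union` flag deduplicates them). The
whole-region variant divides enhancer coverage of the CR by its length.
Percentiles use the ≤-count convention with maximal rank under ties, so
the transform is deterministic, the largest value maps to 1.0, and SI
depends only on ranks — any strictly monotone rescaling of the raw scores
leaves it unchanged. Mean SI across cell lines averages per-cell-line SI
values (percentiles are always computed within a cell line first).

A consequence of max-rank ties worth knowing: when a large fraction of a
cohort ties at a raw score of zero, all tied members receive the same
*high* percentile (the fraction of the cohort at or below zero). Scoring
should therefore be run on the filtered cohort, where insulation scores
are continuous; the `missing_boundary="zero"` escape hatch used in
benchmarking deliberately scores unfiltered CRs and inherits this
behaviour.

## Permutation FDR

The null shuffles the pairing between the two percentile vectors
(uniformly random permutations, seeded). With `c` the smallest score of
the observed top 5 % (the k-th largest SI, `k = round(0.05·N)`), the FDR
is `min(1, mean #\{null products > c\} / n_top)` where `n_top` counts
observed SI strictly above `c`; if ties make that count zero, `k` is used
so the ratio stays defined (both counts are reported). Per-CR tail FDRs
evaluate the same ratio at each CR's own SI. The FDR of the mean SI is the
minimum per-cell-line FDR. With iid Uniform(0,1) percentile vectors the
null exceedance fraction has the closed form `1 − c + c·ln c` (≈ 0.0577
at c = 0.68), which the acceptance script verifies by Monte Carlo.

## 3D reconstruction

Contacts convert to dissimilarities `d = 1/c^α` (α = 1 by default; zero
contacts are unreachable), completed to a metric by all-pairs shortest
paths (error on a disconnected contact graph, with components listed),
and embedded by classical (Torgerson) MDS: double-centre `−½ J D² J`,
eigendecompose, scale the top-3 eigenvectors by the square roots of the
nonnegative-clipped eigenvalues. Negative eigenvalues among the retained
spectrum trigger a non-Euclidean warning and are summarized by a strain
statistic `Σ|λ⁻| / Σ|λ|`. Rank-deficient configurations (collinear
points, n = 2) embed with surplus coordinates identically zero rather
than erroring. Region models snap outward to the TAD boundaries flanking
the CR when boundary calls are available, else extend ±1 Mb; bins
overlapping the CR are flagged for highlighting, and coordinates export
as annotated TSV or a minimal PDB-like file.

## Synthetic data

The generator emulates the features the pipeline consumes, not raw Hi-C
reads. Expected counts are
`λ(i,j) = A · (|i−j|+1)^(−γ) · (f if i,j share a TAD else 1)` with
defaults A = 100, γ = 1, f = 3, 500 bins of 10 kb and boundary elements at
bins 100/200/300/400 (1 Mb TADs, matching mammalian medians); noise is
Poisson by default. Enhancer tracks are non-overlapping intervals
(exponential lengths, mean 2 kb) at 5 % coverage — the order of ChromHMM
strong-enhancer coverage in gene-dense regions — optionally concentrated
near hotspot positions. Labelled CR sets place positives across a boundary
with enhancer-rich scoring windows and negatives strictly inside a TAD.

Two rearrangement routes are deliberate alternatives:

* `apply_rearrangement` remaps bin indices
  (`c'(i,j) = c(m(i), m(j))`) — the contact pattern travels with the
  sequence. This preserves cross-junction depletion after a deletion and
  is the *structural null* (what the map would look like if 3D structure
  did not respond to the rearrangement).
* `simulate_rearranged` rebuilds expected contacts from the rearranged
  genome's surviving boundary elements with distance decay in the new
  coordinates. Deleting a region containing a boundary element therefore
  merges the flanking TADs — the enhancer-hijacking scenario — and this is
  the route used for the merge benchmarks.

What passing synthetic tests does **not** show: robustness to real-data
artifacts (coverage heterogeneity, unmappable regions, normalization
choices), to nested/hierarchical domain structure, or to the strong
score-tie structure of real CR cohorts. In particular, in the synthetic
cohort the insulation and enhancer scores of filtered CRs are uncoupled
across CRs by construction (every boundary carries the same enrichment
and the same hotspot weight), so the top-5 % permutation FDR on a
synthetic cohort is close to 1 — correctly reporting that its top
pairings are chance. Real cohorts derive low FDRs from genuine
heterogeneity (some loci pair strong boundaries with dense enhancer
clusters); the estimator itself is validated against the closed-form
uniform null instead.

## Problem sizes and determinism

The shipped benchmarks use 500-bin chromosomes, 20 simulation replicates
for boundary recall/precision and TAD-merge rates, 40–400 CR cohorts, and
1000 permutations for FDR — sizes chosen so the whole suite and the
acceptance script each run in seconds while keeping Monte Carlo error well
inside the asserted margins. Every stochastic component (generator, HMM
initialization, permutations) takes an explicit seed; reruns are
bit-reproducible, and the 3D pipeline is fully deterministic.

## Known limitations

* Per-chromosome, intra-chromosomal analysis only; translocations and
  ring chromosomes are parsed but not scored.
* No `.hic`/cooler binary ingestion; matrices arrive as COO or dense text.
* The boundary-strength definition (insulation valley depth) is one of
  several reasonable choices; scores are comparable only within runs that
  share it.
* Gene-level consequence annotation (which gene is hijacked) is out of
  scope; the score flags loci, not targets.
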
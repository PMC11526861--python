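# Methods

## The synthetic contact model

All analyses in this package are exercised on synthetic binned contact data
whose structure is planted and recorded. The cis expectation for a pixel at
bins *i < j* on one chromosome is

    E[i,j] = s^-alpha · c(i,j) · g(i,j) · l(i,j),   s = j - i (bins)

with the four factors mapping one-to-one onto the benchmarked features:
power-law decay (`alpha`, default 1.0, the classic fractal-globule-like
exponent), two-compartment plaid (`c = 1 + delta` for same-label pairs,
`delta` default 1.0, giving saddle strengths in the range seen in
differentiated cells), boundary insulation (`g = gamma^k`, `gamma` default
0.5, `k` = planted insulator bins strictly between *i* and *j*, capped at 3
so long-range plaid remains visible across many boundaries), and focal loops
(`l = beta` at loop pixels, default 3.0, with a one-bin shoulder at
`(1+beta)/2` so aggregate windows show a peaked rather than single-pixel
signal). Trans pixels get `trans_rate · mean(cis) · c(i,j)`. The model is
normalized over all off-diagonal unordered pixels and sampled multinomially
at a configured depth (equivalent to independent Poisson counts conditioned
on the total); overdispersion beyond Poisson is deliberately not modeled and
is the main respect in which the noise is idealized.

Compartment labels are alternating A/B blocks with geometric lengths (mean
1 Mb). A planted boundary is an insulator *bin* b attenuating pairs with
i < b < j; label changes contribute the first bin of each new block, and
evenly spaced within-label insulators can be added (`extra_boundary_count`)
for boundary-recovery experiments with a controlled count. Loops couple to
the regulatory annotation: a configurable fraction are promoter–enhancer
loops in which one promoter anchor carries a geometric number (1–4) of
enhancers at in-range separations — so planted per-gene enhancer counts
vary — and the rest are insulator–insulator pairs; anchor roles are kept
disjoint so the planted wiring is unambiguous. Loop pixels keep a Chebyshev
separation of ≥ 3 bins (shared anchors excepted) so shoulders never overlap.

1D tracks emulate nuclear-position assays as
`coeff · z(label) + N(0, sd)`: a SON TSA-seq-like speckle signal (positive
in A), a Lamin-B1 DamID-like signal (positive in B), and a Repli-seq-like
early/late log-ratio (positive in A). Multiway proximity clusters use a
star model: log-uniform size, an anchor bin drawn by coverage, members drawn
with replacement from the anchor's contact profile, deduplicated per bin.
This is a tractable stand-in for jointly coherent multiway sampling; the
cluster-module tests use the matching star-model oracle, and member–member
pairs in large clusters are flatter in distance and richer in trans than the
underlying pairwise map — the qualitative behavior expected of large
proximity clusters.

What the generator does **not** emulate: sequence-level biases and hence
realistic balancing corrections (biases are planted only in the rank-1 test),
overdispersed/duplicated reads, smooth compartment transitions (planted
plaid edges are infinitely sharp), centromeres/arms, and per-assay
noise signatures. Passing tests therefore demonstrate correctness of the
computations and recoverability under Poisson noise, not robustness to every
artifact of real libraries.

## Analysis conventions

* Coordinates are 0-based half-open; bin index = floor(start / bin_size);
  matrices store the upper triangle once; balanced value = count·w_i·w_j.
* **Balancing** is iterative correction with MAD-max coverage filtering
  (defaults mad_max 5, tol 1e-5 on the coefficient of variation of balanced
  marginals, max_iter 200), weights scaled to preserve total mass. On
  synthetic near-uniform-coverage matrices the MAD is tiny and the filter can
  mask genuinely depleted boundary-adjacent bins; boundary calling therefore
  bridges isolated missing bins (gaps ≤ 2) by linear interpolation before
  peak finding.
* **Expected-by-distance** is the zero-inclusive per-diagonal mean over
  unmasked pixels, required for unbiased O/E at long range.
* **P(s)** uses geometric distance bins (8 per decade) from two bin widths
  to the chromosome length, chromosome-aggregated with valid-pixel weights,
  normalized to unit sum; the derivative is a centered local least-squares
  slope (window 5, truncated at the ends, missing where P ≤ 0). The reported
  dynamic range is log10(max P / min P) over populated bins — an explicit
  operationalization, since no standard numeric definition exists.
* **Eigenvectors** come from dense symmetric eigendecomposition of
  (O/E − 1) per chromosome (undefined entries treated as expectation, masked
  bins removed and re-embedded as missing), selecting among the three
  largest-|eigenvalue| vectors the one best correlated with the reference
  track, signed positive-with-track. Per-chromosome rather than per-arm:
  synthetic genomes have no centromeres. Zero correlation with the reference
  is an error, never a silent choice.
* **Saddle**: Q = 50 equal-occupancy quantiles by default (tests and
  benchmarks use Q = 10 on 400-bin genomes so each quantile keeps ≥ 40
  bins), cis pairs at ≥ 2 bins separation. Corner strengths are
  **pair-weighted** means over the corner block of cells (corner_fraction
  default 0.2): this makes strengths invariant to the arbitrary ordering of
  tied ranks, which matters when ranking by a two-valued label track; the
  displayed grid remains per-cell means. The strength CI, when requested, is
  a block bootstrap over chromosomes.
* **Insulation** is the log2 diamond mean (window default 250 kb = 10 bins)
  centered by the chromosome mean of log2 values (geometric-mean
  normalization), so defined scores average exactly zero — the arithmetic
  normalization would not have that property. Boundaries are local minima
  with topographic prominence ≥ 0.2 log2 units, leftmost bin on plateaus.
  A consensus helper intersects calls from ≥ 2 datasets within ±1 bin.
* **Loop calling** is a deterministic donut-style test: candidate pixels in
  a distance band, null expectation = max over four local-neighborhood
  backgrounds (donut, lower-left, horizontal, vertical; outer radius 5,
  inner exclusion 2) of the local mean O/E × distance expectation / (w_i
  w_j), Poisson upper-tail p-values, Benjamini–Hochberg jointly across all
  candidates (no lambda-chunking), significant pixels clustered by
  8-connectivity and reported at the maximal pixel. An optional
  fold-enrichment filter against the donut/lower-left backgrounds (the
  strips can be contaminated by peaks sharing an anchor) is off by default:
  on infinitely sharp synthetic plaid it rejects genuine loops in locally
  depleted contexts more readily than plaid-corner artifacts. Calibration
  holds exactly on structure-free nulls; on sharp plaid the local-mean
  background model is violated at block corners, an artifact of the
  idealized simulator rather than of the test.
* **APA** uses the standard 21×21-pixel window at the matrix resolution,
  skipping loops within half-window+1 bins of edges or the diagonal;
  apa_score = center / mean of the lower-left 6×6 corner. The shift null
  moves both anchors along the diagonal.
* **Anchor union** merges pooled anchor intervals by single linkage within
  1 bin and reports per-source membership combinations (upset counts).
  State fold enrichment is (category bp fraction in state) / (genome bp
  fraction in state) on half-open intervals, NaN for absent states. Loop
  clustering runs k-means (default k = 6, seeded) on orientation-normalized
  concatenated anchor state-fraction vectors (anchor vectors sorted
  lexicographically, since loops are unordered pairs); the seeded UMAP
  projection is for display only.
* **SPRITE conversion** weights each pair of an n-distinct-bin cluster by
  2/n (total mass exactly n − 1), with a "unit" rule available for
  sensitivity analysis; cluster size is counted on distinct bins after
  deduplication by default (raw fragment counts are retained and selectable)
  because pairwise weights would otherwise double-count within-bin
  fragments.
* **Concordance** uses pairwise-complete correlation (Spearman for
  compartment profiles, Pearson for insulation, both available), constant
  profiles flagged undefined, and average-linkage agglomeration on 1 − r
  with labels pre-sorted for deterministic tie-breaking; dendrograms are
  serialized as Newick.

## Benchmark battery and problem sizes

`nucbench.benchmarks.run_all(seed)` (used by both `tests/test_acceptance.py`
and `scripts/acceptance.py`) simulates every study condition from scratch on
one 10 Mb chromosome at 25 kb bins (400 bins; two chromosomes for trans and
SPRITE checks), depths 10^6–10^7, with 20-seed replication where a rate is
estimated — sizes chosen to leave clear statistical margins while keeping
the whole battery within a few minutes on one CPU. Null FDR calibration is
reported as the mean per-replicate false-discovery proportion over 20
loop-free simulations (the standard empirical estimate of FDR = E[FDP];
pooling is degenerate on an all-null family where any call makes FDP 1).
The exact-equality check between track-ranked and eigenvector-ranked saddle
strengths uses exactly balanced planted labels with corner_fraction 0.5 so
both rankings select the identical corner bin set; with unbalanced labels
the corner sets differ through rank tie-breaking and machine-precision
equality is not a meaningful expectation.

## Known limitations

* Poisson sampling only; negative-binomial overdispersion is an extension
  point.
* The loop caller is unsupervised and deterministic; it does not emulate
  trained platform-specific callers, and its local-mean backgrounds are
  misspecified exactly at infinitely sharp planted discontinuities.
* Under the full structured model (strong insulation plus plaid), the
  leading eigenvector can legitimately disagree with planted labels on
  short, strongly insulated blocks — a property of eigenvector compartment
  calling itself, visible here because the truth is known.
* Cluster generation is anchor-star-shaped, not jointly coherent multiway
  sampling.
* No read-level processing, no multi-resolution pyramids, no per-assay
  normalization beyond matrix balancing.
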
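# Methods

This note documents the models implemented in `cnasig`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Feature encoding

Copy-number segments are classified by total copy number and length into 28
categories: homozygous deletion (0 copies) with length classes
[0, 100 Kb), [100 Kb, 1 Mb), [1 Mb, ∞); and LOH (1 copy), diploid (2),
gain 3–4, gain 5–8, gain 9+ with length classes [0, 100 Kb), [100 Kb, 1 Mb),
[1 Mb, 10 Mb), [10 Mb, 40 Mb), [40 Mb, ∞). All intervals are half-open on
length in bp, which makes the scheme mutually exclusive and exhaustive and
resolves boundary ties deterministically. Design choices:

* **LOH proxy.** Public panel releases carry no allele-specific data, so
  total copy number 1 is labeled LOH; copy-neutral LOH is invisible to the
  encoding.
* **Denominator.** Feature values are fractions of the *per-sample total
  segmented length*, not of the genome: panel segment calls cover only the
  assay footprint, and this convention makes non-empty rows sum to 1 — a
  testable invariant. Feature rows are therefore comparable across panels
  only up to footprint differences.
* **log2 → copies.** Integer copies are derived as
  `round(2 · 2^seg_mean)` with half-away-from-zero rounding, floored at 0.
  No purity or ploidy correction is applied; segment means are taken at
  face value from the caller.
* **Coordinates.** 1-based inclusive (SEG convention), length =
  end − start + 1. Chromosome Y is dropped by default; X is treated as
  autosome-like.

## Extraction backends

All four backends return non-negative signatures with rows summing to 1 and
are bit-reproducible for a fixed seed (every random draw descends from
`numpy` `SeedSequence`s spawned from the seed).

**NMF.** Multiplicative updates for the Frobenius objective (Lee–Seung),
300 iterations or relative improvement < 1e-8. Rank selection: for each k
in the configured range (default 2–8), 20 random restarts; stability is the
mean Hungarian-matched cosine over all restart pairs (sensitive to ranks
whose surplus components split arbitrarily); the chosen k maximizes
`stability − error/‖X‖_F`, with score differences below 0.01 treated as
restart noise and resolved toward the smaller rank — degenerate low-rank
data therefore selects the lower bound of the range.
Reported signatures are per-component medians over matched
restarts (robust to stray restarts), L1-normalized, with exposures refit by
NNLS.

**Non-negative ICA.** NMF warm start (100 iterations), then per iteration:
multiplicative data updates for both factors, a *relaxed* symmetric
decorrelation of the mixing matrix,
`A ← (1 − w) A + w A(AᵀA)^{-1/2}` with `w = 0.1`, then projection of the
components onto the non-negative orthant and L1 renormalization.
Full decorrelation (`w = 1`) forces orthogonal activities and distorts
genuinely correlated signatures; the relaxed step trades a controlled amount
of independence (reported as the mean absolute pairwise Pearson correlation
of the activity columns) against fidelity. Tolerance 1e-6 on the component
change, max 500 iterations; non-convergence returns the best iterate with a
flag rather than raising.

**Graph-regularized NMF.** The 28 categories form a graph whose edge
weights are absolute Pearson correlations between category columns of X
(self-loops removed, weights < 0.1 pruned — the threshold keeps the graph
sparse without isolating nodes on realistic cohorts). With the
combinatorial Laplacian L = D − W, the objective is

```
‖X − AS‖²_F + α·tr(S L Sᵀ) + β·Σ_{i≠j} cos(S_i, S_j) + γ·‖S‖₁ ,  A, S ≥ 0
```

minimized by multiplicative updates whose numerator/denominator split
follows the sign structure of each penalty gradient. With α = β = γ = 0 the
update is exactly plain NMF, a limit the tests pin down. Defaults
α = 0.1, β = 0.05, γ = 0.01 — small relative to the data term so penalties
shape rather than dominate the solution.

**HDP.** A desk-scale approximation of hierarchical-Dirichlet-process
signature extraction. Feature rows are discretized to pseudo-counts
`round(1000 · x)`; a *truncated* (10 components) HDP topic model is sampled
by blocked Gibbs: exact multinomial token splits per (sample, category)
cell via sequential binomials, Dirichlet draws for component category
distributions (base 0.1) and per-sample mixing weights (concentration 1.0
over shared base weights, whose table counts are approximated by the number
of samples using each component). 400 sweeps, 200 burn-in. Because the
truncated blocked sampler lacks the table dynamics that let the untruncated
process collapse redundant components, posterior-mean components with
pairwise cosine > 0.8 are merged (token-share weighted) before reporting;
a component is reported when it holds ≥ 2% of tokens on average and is
present in > 5% of post-burn-in sweeps, so k is inferred. The merge
threshold is intentionally far above the ≤ 0.6 pairwise cosine at which
distinct signatures are planted/expected, and the chain is summarized by
per-index posterior means (label switching is not corrected; it was not
observed at this scale, and the consensus stage is robust to it).

## Consensus stage

Pooled signatures are compared by cosine similarity (scale-invariant and
natural for L1-normalized non-negative vectors) and clustered by Ward
linkage on 1 − cosine, treated as a dissimilarity without metricity
correction. For each candidate cluster number in 4–15 the fraction of
clusters passing a validity test is computed; the test passes when a
cluster (a) spans ≥ 2 methods, (b) contains ≥ 26% of one method's pooled
signatures, or (c) holds ≥ 3 signatures from one method. The chosen number
maximizes that fraction with ties toward fewer clusters. Note that all
three criteria are monotone under cluster union, so along a dendrogram an
all-valid partition stays all-valid when coarsened; a strict interior
optimum therefore only occurs when some clusters are invalid, and the
tie rule resolves the all-valid plateau to the smallest candidate.
Valid clusters are collapsed to their unweighted elementwise median
(robust, assumption-free, every method contributes equally), renormalized,
and labeled CON1..CONm ordered by descending total pooled-exposure share
(cluster size when exposures are unavailable).

Diagnostics: mean silhouette width on 1 − cosine (undefined for
singleton-only partitions and reported as missing), cophenetic correlation
of the Ward dendrogram, relative NNLS reconstruction error of X against the
consensus signatures, and mean distinct methods per cluster. Stability:
bootstrap subsampling *without replacement* (default 100 iterations at 80%)
reruns extraction + consensus per iteration; resampled consensus signatures
are matched to the original by Hungarian assignment on cosine — optimal and
deterministic — and the per-pair Pearson correlations are averaged. Failed
iterations are recorded as missing; more than 50% failures aborts.

## Refitting

Activities solve `argmin_{a≥0} ‖x − aᵀS‖² + λ‖a‖²`, computed exactly by
NNLS on the design stacked with `√λ·I`. Default λ = 1e-6: large enough to
break degeneracies between nearly collinear signatures, orders of magnitude
below the data term for unit-scale feature vectors. A non-negative elastic
net (scikit-learn coordinate descent, `positive=True`) is the documented
alternative; at `alpha = 0` it is routed to the NNLS solver, whose solution
it must match. Per-sample QC: Pearson r, R² (against the observed vector's
mean — the standard baseline), RMSE; high quality ⇔ r > 0.8. Cohort
summaries report the same metrics on the stacked observed/reconstructed
values, and the hold-out validation in the acceptance script reports both
per-sample and stacked correlations since either convention is found in
practice. Activities are in feature-fraction units; a `log2(a + 1)`
transform is provided for display.

## Association statistics

* **FGA** is the length-weighted fraction of segmented genome with
  `|log2 ratio| ≥ 0.2` (the cBioPortal convention), or `copies ≠ 2` when
  only integers are available; samples without segments are missing, not 0.
* **Median split**: value > median → high, ties to low (deterministic).
* **Mann–Whitney** association of activities between altered and wild-type
  samples, with Cohen's d on the *pooled* SD as effect size
  (|d| > 0.2 flags a meaningful effect).
* **Fisher enrichment** of alterations in a signature's high-activity
  samples against high-activity samples of other signatures; fold
  enrichment > 1.2 with FDR < 0.05 flags a meaningful enrichment.
  Zero-margin tables report a missing odds ratio with a Haldane-corrected
  estimate alongside.
* **120-day progression** odds ratios between median-split groups, BH-FDR
  within the declared test family.
* **BH adjustment** delegates to statsmodels (step-up with monotonicity),
  behind the package's own validated interface. Genes altered in < 1% of
  samples are excluded before testing.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes: sparse
L1-normalized signatures (symmetric Dirichlet, concentration 0.15,
rejection-sampled to pairwise cosine ≤ 0.6), optionally one diploid-like
signature with ≥ 90% of its mass on 2-copy categories; exposures active per
sample with signature-specific prevalences — default ladder
(0.999, 0.64, 0.6, 0.385), from near-ubiquitous to rare — with
gamma-distributed active weights (shape 2) normalized per sample;
multiplicative lognormal noise with σ = `noise_level` (default 0.05; no
explicit noise model exists for the real data, so this is the package's
choice of a realistic perturbation), or Dirichlet resampling as an
alternative; and a segment-level realization drawing log-uniform lengths
within each category's class, uniform copies within each copy class, packed
non-overlapping largest-first onto hg19 autosome + X lengths (rounded to
Mb, shipped as a constant table). The reference study conditions are 300
samples, 4 signatures, 5% noise.

What the generator does **not** emulate: breakpoint hotspots and recurrent
focal lesions, purity/subclonality, panel-footprint bias, caller noise
correlated along chromosomes, and inter-signature exposure correlations.
Passing tests demonstrate correctness of the machinery and recoverability
under idealized mixing; they do not certify that real panels contain
recoverable signatures, nor that the categories have the biological
interpretation found in any particular cohort.

## Problem sizes and numerical conventions

The test suite and acceptance script run the reference conditions (300
samples; bootstrap reduced to 20 iterations on the zero-noise variant; the
hold-out harness uses 500 samples split 300/200) — sizes at which every
stage's behavior is already asymptotic for a 28-dimensional feature space.
Ties in the NMF rank score and the cluster-number score break toward the
smaller candidate; Hungarian matching breaks ties by index order; all
epsilon guards are 1e-12; feature TSVs are written at 12 significant
digits, which round-trips the matrices used here bit-for-bit.

## Known limitations

The HDP backend is an approximation, not a reimplementation of
mSigHdp-style samplers; its component count depends on the merge threshold
for heavily overlapping signatures. The 26% proportional-representation
rule is interpreted per-method (share of one method's pooled signatures),
and each cluster's passing criterion is logged so users can audit the
choice. Ward on 1 − cosine is a pragmatic, widely used combination but
1 − cosine is not a metric. Purity, ploidy, and allele-specific copy
number are out of scope.
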
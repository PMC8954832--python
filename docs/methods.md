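# Methods

`isolocal` implements and compares three ways of choosing the training set
for a binary origin classifier operating on four stable isotope ratios
(δ¹³C, δ¹⁵N, δ²H, δ¹⁸O, all in ‰): train on everything (*global*), train on
one representative subset chosen by Adaptive Kennard–Stone (*AKS*), or build
a fresh *local* model for every test sample from its DD-SIMCA full-distance
neighborhood. This note records the models, the defaults and why, the
numerical choices, and what the synthetic benchmark does and does not show.

## Data model

A library is an ordered table of samples. Each sample carries a unique id,
a banner (county of origin: Sunite Right, Sunite Left, Siziwang, Abaga) and
the four δ values. The class label is determined by geography — the two
Sunite banners are the PGI (Protected Geographical Indication) region — so
it is derived from the banner and checked for consistency, never trusted
from the file alone. Train/test partitioning is stratified by banner at a
4:1 ratio: each banner contributes ⌊n·f⌋ test samples plus largest-remainder
top-ups until the global test count equals round(N·f). This reconciles
"4:1 within each region" with an exact global 4:1 when banner counts are not
divisible by five; with banner counts 85/6/19/6 (N=116) it yields exactly
93 training (68/5/15/5) and 23 test samples.

δ notation is provided as a utility in both its universal form,
(R_sample − R_standard)/R_standard × 1000, and the variant that normalizes
by R_sample instead. Both appear in the literature; they agree to first
order for |δ| ≪ 1000 ‰. The universal form is the default.

## PCA core

Both selection approaches work in principal-component score space. Columns
are mean-centred and, by default, autoscaled to unit variance — δ²H spans
tens of ‰ while δ¹⁵N spans ~3 ‰, so unscaled Euclidean geometry would be a
hydrogen ruler. The decomposition is an SVD; each loading's sign is fixed by
making its largest-magnitude entry positive, so orderings and plots
reproduce bit-for-bit across back-ends. Default `pc = 2` (configurable
1–4): two components capture the dominant PGI/non-PGI contrast and leave a
non-trivial residual for the orthogonal distance.

## Adaptive Kennard–Stone

Kennard–Stone ordering: start from the farthest pair (exact O(n²) search,
not a centroid heuristic), then repeatedly add the sample maximizing the
minimum distance to the selected set. All ties break toward the lowest
index after a canonical sort by sample id, making the ordering a pure
function of the data multiset.

The stopping rule scores every prefix of length `n_min`..N by the D-optimal
information per sample, log Det(SᵀS/N), where **S is the score matrix of a
PCA refit on that prefix alone**, and keeps the argmax. Refitting per
prefix is a deliberate design choice: if prefixes are instead scored inside
the single full-set model, the per-sample information is monotone
decreasing in prefix length for elliptical data — the first KS picks are
the farthest-out points and always carry the most variance — so the
"adaptive" rule would degenerate to always choosing the minimum. With
refitting, the curve rises while new samples add genuinely new directions
of spread and falls once they are redundant, giving an interior maximum
(typically 10–40 of 93 on the synthetic benchmark). `n_min = pc + 2` by
default because the Gram determinant is singular or unstable below
`pc + 1` samples; a prefix too degenerate to refit scores −∞.

Selection runs on both classes jointly (class-stratified selection is
available but off by default): representativeness of the whole library is
the point, and the chosen subset may be class-imbalanced.

## DD-SIMCA distances and the full distance

For a fitted PCA model, each sample has a score distance
SD = Σₐ t²ₐ/λₐ (squared Mahalanobis distance in score space) and an
orthogonal distance OD (squared residual norm). With training means SD₀,
OD₀ and degrees of freedom N_h, N_q the full distance is

    FD = N_h·SD/SD₀ + N_q·OD/OD₀ ,

approximately χ²(N_h + N_q). The DOF are estimated by the classical method
of moments — if a distance is (c/k)·χ²(k) then 2·mean²/var = k — rounded
and clamped to [1, 250]. Mean training FD equals N_h + N_q exactly by
construction (the scaling uses the training means).

Zone limits: *regular* when FD ≤ χ²₁₋α(N_h+N_q) with α = 0.05 (the green
boundary), *outlier* when FD exceeds the χ² quantile at (1−γ)^(1/n) with
γ = 0.01 (the red boundary, with the per-sample correction appropriate for
an extreme-of-n bound), *extreme* in between. Acceptance-plot coordinates
are exported in the standard log form u = ln(1 + N_h·SD/SD₀),
v = ln(1 + N_q·OD/OD₀); iso-FD curves ("yellow lines") are exportable for
any FD level, and samples with equal FD lie on the same curve.

The model is fit on the full training set (both classes) by default — here
DD-SIMCA serves as a similarity engine, not a one-class classifier —
and test samples are only ever projected, never included in the fit.

## Local FD neighborhoods

For each test sample Pᵢ, training samples are ranked by |FDᵢ − FD(Pᵢ)| and
the nearest window is its one-time local training set; the window's
(min, max) FD is recorded as the band. The window size follows a two-regime
rule driven by where FD(Pᵢ) falls among the training FDs: if its percentile
deviates from the median by more than 0.25 (i.e. outside the interquartile
range), the small regime (27 samples, midpoint of 20–34) is used; otherwise
the medium regime (42, midpoint of 35–49). The quartile threshold and the
symmetric nearest-|ΔFD| window are this package's concrete reading of
"selected centering on the FD of the test sample"; the regime boundaries
follow the observed subset-size ranges. Boundary percentiles count as
central. Subsets may be class-imbalanced and are not rebalanced; a window
that captures a single class degrades the classifiers to a constant
predictor for that one prediction, flagged and logged rather than fatal.

## Classifier harness

Five families, identical standardized features (scaler fit on whatever set
trains the model, so local models are self-contained), PGI always the
positive class, no internal tuning — single fits evaluated on the held-out
test set. Defaults, all logged per fit:

| method | back-end defaults |
|---|---|
| LDA | no shrinkage |
| RF | 500 trees, √p features per split, seeded |
| SVM | RBF kernel, C = 1, kernel width 1/(p·var) |
| BPNN | one hidden layer of 8 logistic units, L-BFGS, ≤ 2000 iterations, seeded |
| KNN | k = 5, Euclidean on standardized features |

L-BFGS was chosen for the BPNN because first-order stochastic optimizers
are noisy and slow to converge on 20–90-sample training sets. In the AKS
harness, a D-optimal optimum smaller than KNN's k shrinks k to the subset
size (logged); direct calls to `train` still reject k > n.

## Evaluation

Confusion matrices with PGI positive; sensitivity TP/(TP+FN), specificity
TN/(TN+FP), accuracy P₀, chance agreement
Pe = [(TP+FN)(TP+FP) + (TN+FN)(TN+FP)]/total², and Cohen's kappa
(P₀−Pe)/(1−Pe), graded excellent (> 0.75), good (0.40–0.75], poor
(≤ 0.40). Kappa matters here because the test set is imbalanced (18 PGI vs
5 non-PGI): ignoring the minority class still buys 78% accuracy. The
degenerate Pe = 1 case is defined as kappa 1 when P₀ = 1, else 0. Display
rounding is 4 decimals, half-up; full precision is kept internally.
Library characterization uses Welch's unequal-variance t-test between
groups — the non-PGI spreads are roughly twice the PGI spreads, so a pooled
variance would be wrong.

## Synthetic benchmark

The generator draws each banner's samples from its class's multivariate
normal: PGI mean (−19.31, 7.28, −99.48, 13.65) ‰ with SD
(1.52, 0.94, 5.44, 1.90); non-PGI mean (−21.92, 6.45, −120.02, 8.53) ‰ with
SD (2.65, 0.70, 11.84, 3.28); banner counts 68/5/15/5 for the 93-sample
training-style library and 85/6/19/6 for the 116-sample full library (the
latter chosen so the 4:1 stratified split reproduces the former exactly).
Isotopes are independent by default — only group-level moments are
available — with an optional correlation matrix and optional per-banner
mean offsets (e.g. to emulate altitude depletion of δ²H at Sunite Left).

What this emulates: the class separation (≈1–2 pooled SD per isotope, most
of it in δ²H/δ¹⁸O), the class and banner imbalance, and the 93/23 design.
What it does not: within-class multi-modality by banner, isotope
covariance, measurement drift, or any non-Gaussian tail behavior of real
defatted-muscle measurements. Benchmark results therefore show that the
pipeline recovers a separation of this magnitude and shape — not that any
particular field library will behave identically, and not the original
study's exact subset sizes or predictions, which depend on its raw data.

The standard benchmark (`isolocal.workflow.replicate`, also used by
`scripts/acceptance.py`) runs 20 seeded replicates of
generate → split 93/23 → global/AKS/local-FD × five classifiers, and
reports median test accuracies. Twenty replicates keep the medians stable
at the granularity of a 23-sample test set (1/23 ≈ 0.043 accuracy steps)
while the whole benchmark stays in the minutes range.

## Numerical choices and edge cases

- Rank-0 data (all rows identical) and constant columns under autoscaling
  are fit errors; data lying exactly in the score subspace (OD ≡ 0 up to
  rounding, detected relative to the scaled data energy) is a DD-SIMCA fit
  error since OD₀ would be meaningless.
- Singular Gram matrices in the D-optimal score yield a −∞ sentinel, never
  an exception mid-curve.
- All orderings and selections are deterministic: ties break toward lower
  canonical index, stochastic classifiers take explicit seeds, and one
  master seed fans out to stages via `numpy.random.SeedSequence`.

## Known limitations

- The FD-window width rule (quartile threshold, 27/42 midpoints) is one
  defensible operationalization of a procedure whose exact form is not
  fully specified by its source material; other windows inside the 20–47
  range would be equally admissible.
- DD-SIMCA here is a similarity/screening engine; no multi-class SIMCA
  classification, robust DOF estimators, or alternative similarity metrics
  (Euclidean, Mahalanobis, LLE) are provided.
- The AKS information curve on strongly clustered real data may be rugged;
  the argmax rule takes the global maximum and ignores secondary plateaus.
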
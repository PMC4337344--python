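# Methods

`cycleconn` implements a longitudinal, single-subject resting-state fMRI
analysis that relates menstrual-cycle hormone levels to whole-brain
functional connectivity. This note documents the models, the numerical
choices, and what the synthetic data generator does and does not emulate.

## Eigenvector centrality on the voxel similarity graph

Let `x_i ∈ R^T` be the BOLD time course of in-mask voxel `i` (N voxels,
T frames). The similarity matrix is

    C = R + 1,    R_ij = Pearson correlation of x_i and x_j,

so every entry of `C` lies in [0, 2] and the diagonal is exactly 2. By the
Perron–Frobenius theorem a nonnegative matrix of this form has a unique
real largest eigenvalue `λ` whose eigenvector `v` can be chosen with
strictly positive components (strict positivity holds whenever no pair is
perfectly anti-correlated). The eigenvector centrality (EC) of voxel `i`
is `v_i`, with `‖v‖₂ = 1` fixed as the normalization; the eigenvector is
only defined up to scale and downstream statistics compare maps across
scans, so one fixed rule is required. Intuitively, a voxel is central
when it is strongly connected to voxels that are themselves central —
the same fixed-point idea as PageRank, on a dense weighted graph.

Two implementations are provided and tested against each other:

* `ec_dense` materializes `C` (O(N²) memory) and calls a symmetric
  eigensolver — the small-N reference.
* `ec_fast` is matrix-free. Rows are centered and scaled to unit norm
  (matrix `Z`), which makes `R = Z Zᵀ` exact with unit diagonal, so

      C v = Z (Zᵀ v) + (Σ_i v_i) · 1

  costs O(N·T) per power-iteration step and never forms `C`. The
  iteration starts from the uniform positive vector (nonzero overlap with
  the Perron vector is guaranteed), normalizes each iterate, and stops
  when the max-abs componentwise change drops below `tol = 1e-10`
  (default; `max_iter = 1000`, non-convergence is a hard error carrying
  the final residual). Convergence is fast in practice because the
  rank-one "+1" term gives `C` a large spectral gap.

Zero-variance voxels have no defined correlation and are a hard error
listing the offending rows; silently imputing r = 0 would perturb the
Perron vector unpredictably.

## Preprocessing

The pipeline starts from spatially normalized volumes. Functional frames
are smoothed with an isotropic Gaussian kernel of 8 mm FWHM applied
frame-by-frame; per-axis sigma in voxels is
`fwhm / (voxel_size · 2√(2 ln 2))`, the kernel is truncated at 4 sigma,
and the boundary is zero-padded (background treated as zero, the common
convention for neuroimaging smoothers). The analysis mask is built from a
gray-matter probability image smoothed at 4 mm FWHM and thresholded at a
minimum probability of 0.12. The mask stores a fixed linear ordering of
included voxels (first spatial axis fastest), so every row of every
downstream matrix is traceable to a voxel and to world-mm coordinates via
the affine.

## Hormone panel

One row per scan: session, cycle day (days since menses onset), serum
estradiol, progesterone, LH and cortisol. Covariates enter the GLM
z-standardized (sample SD, pooled over all scans by default; per-session
standardization is available because sessions are ~10 months apart). The
t statistic of a single covariate is invariant to affine rescaling of
that covariate, so raw-unit covariates give identical inference — a
tested invariance.

Cycle phases are labeled from the LH surge: the surge day is the cycle
day of maximal LH, accepted only if the maximum exceeds the panel median
by ≥ 2 panel SDs (no standard numeric criterion exists; this one is
deliberately conservative and degrades to "unlabeled with warning").
Ovulation is estimated as surge day + 1; scans earlier than surge − 1 are
follicular, within surge ± 1 periovulatory, after ovulation luteal.

## Second-level GLM

The per-scan EC (or seed-connectivity) maps form a scan-by-voxel matrix.
The design has one 0/1 indicator per scanning session (replacing the
global intercept, so long-interval session offsets are absorbed), plus
mean-centered covariates: one hormone of interest per model and cortisol
as nuisance. Estradiol and progesterone are tested in separate models by
default because both are cycle-phase-locked and would be collinear in a
joint model (a joint and an interaction option exist but are off by
default). OLS per voxel gives `β` and `σ̂² = RSS/(n − rank X)`; a
contrast `c` yields

    t = cᵀβ / √(σ̂² · cᵀ(XᵀX)⁻¹c),   df = n − rank(X)

with a one-sided p (signed correlations are the hypotheses; two-sided by
flag) and the equivalent normal quantile Z. Exact fits (zero residual up
to rounding, detected at relative tolerance 1e-24 on RSS/SST) report
t = ±∞ with the smallest representable p.

### Multiple comparisons

Peak-level family-wise error is controlled by Bonferroni (`min(1, n·p)`)
or Šidák (`1 − (1−p)ⁿ`) over a configurable comparison count `n`. When a
study-specific resel (resolution element) count is known — e.g. supplied
by acquisition software — it can be configured directly. When none is
configured the pipeline defaults to counting every comparison it actually
makes per hormone model: two one-sided contrasts × in-mask voxels. This
is deliberately conservative; Bonferroni over all comparisons controls
FWER under arbitrary dependence as long as per-voxel p values are
calibrated (which the null simulations verify). A naive geometric resel
estimate (mask volume / FWHM³) is provided for reference but is *not* the
default and is not a random-field-theory smoothness estimate; RFT
cluster-level p values are out of scope, and the cluster table leaves
that column empty.

### Clusters

Supra-threshold voxels (uncorrected p below the voxel threshold, default
0.001) are grouped into connected components under 6-, 18- or
26-connectivity (default 18, the convention of the major SPM-style
packages), components below the extent threshold are dropped, and each
cluster is reported with extent k_E, peak t/Z/p, FWE-adjusted peak p and
the peak's world-mm coordinates, sorted by descending peak t. An empty
result is an empty table, not an error.

## Seed-based connectivity

Seeds are spheres (default radius 6 mm) of in-mask voxels around a
world-mm center — by default the peak coordinate of the whole-brain EC
analysis, mirroring the two-stage workflow (whole-brain EC first, then
seeds in the identified regions; the original region geometry is not
specified anywhere, so spheres at peaks are this package's choice). The
seed time course is the unweighted mean of seed-voxel series; per scan,
every in-mask voxel's Pearson r with that course is Fisher-transformed
(z = atanh r, variance-stabilizing; raw-r mode exists for sensitivity
checks) with |r| clamped to 1 − 1e-7 so seed voxels stay finite. The
second level reuses the same GLM with one hormone covariate (progesterone
by default, positive one-sided contrast) at uncorrected voxel thresholds
0.005 and 0.001 with extent k > 20.

## Synthetic studies

No scan data is distributable for the motivating design, so the generator
emulates it with known ground truth.

**Design.** 32 scans in 2 sessions of 16, one scan every 2–3 days
(alternating gaps), each session starting on a different cycle day so the
two sessions jointly cover the 28-day cycle densely. Default geometry is
a desk-scale 24×24×12 grid at 3 mm with 120 frames at TR 2 s; a
`paper_scale()` preset (48×56×40, 300 frames, ~7·10⁴ brain voxels) exists
for performance checks only.

**Hormones.** Noiseless curves over cycle day: estradiol = baseline 0.5 +
a periovulatory Gaussian bump (amplitude 3.0, sd 1.5 d, peak at
ovulation − 2 = day 12) + a smaller late-luteal bump (amplitude 1.5, sd
3 d, peak at ovulation + 7); progesterone = baseline 0.3 + a smoothed
rectangle (amplitude 3.0, sigmoid rise centered at ovulation + 2, fall at
ovulation + 12, widths 1.5 d); LH = baseline 0.3 + a narrow surge
(amplitude 5.0, sd 1.2 d) centered one day after the estradiol peak and
one day before ovulation. Units are arbitrary (no absolute serum values
are being modeled); the pipeline consumes z-scores, so units are
immaterial. Measurement noise is multiplicative log-normal with CV 0.08
— small enough that the scan sampled nearest the surge carries the LH
argmax, which is what real panels confirmed by LH kits look like.
Cortisol is independent truncated-Gaussian noise (mean 1.0, sd 0.2).

**Scans.** Every voxel carries stationary AR(1) noise (coefficient 0.3,
unit sd, 50-frame burn-in) to emulate BOLD temporal autocorrelation, plus
a constant baseline of 100. Each coupled ROI pair (default: left
DLPFC-analogue with left hippocampus-analogue, 3×3×3 boxes spaced ≥ 2
voxels apart inside a brain block) shares a per-scan latent standard
normal signal with weight

    w_scan = α + β · z_progesterone(scan),   defaults α = 0.8, β = 0.4,

clipped at 0. The shared signal raises within- and between-ROI
correlations, hence both EC and seed connectivity, monotonically with
progesterone — the qualitative finding the pipeline must recover. β = 0
defines the null study (constant, progesterone-independent coupling —
a stricter null than pure noise). α and β were chosen to put the
second-level effect in a realistic range (peak t of order 10 at 32
scans) while leaving the estradiol contrast, which shares only the
cycle-phase correlation between the two hormone curves, below the
voxel-wise threshold. The gray-matter probability volume is 1 on the
brain block and 0 outside. Everything is reproducible from
(params, design, truth, seed); scans are generated lazily per index so a
32-scan study never holds all volumes in memory.

**What the generator does not emulate:** hemodynamic response shape,
physiological noise and motion, scanner drift, anatomical structure
beyond box ROIs, spatial noise correlation before smoothing, and
calibrated hormone concentrations. Passing recovery tests therefore shows
the *pipeline* recovers a hormone-coupled connectivity signal of
plausible size under realistic temporal autocorrelation — not that any
particular real brain effect exists.

## Validation experiments and problem sizes

`cycleconn.validation` packages the standing experiments (also run by
`scripts/acceptance.py`):

* fast-vs-dense EC agreement: 50 random instances, N ∈ {10, 50, 200},
  T ∈ {10, 100}, agreement to 1e-8 max-abs;
* GLM null calibration: 10 runs × 5000 pure-noise voxels, one-sided FPR
  at p < 0.001 within 3 Monte-Carlo SEs of nominal;
* FWE arithmetic on a (p, n) grid including n = 575 (the motivating
  study's resel count for its 61 940-voxel whole-brain mask, kept as the
  reference magnitude);
* cluster labeling vs a pure-Python BFS flood-fill oracle, 25 random
  volumes × {6, 18, 26}-connectivity, plus the corner-touching case that
  separates 18 from 26;
* recovery: 20 seeded coupled studies at the default desk-scale geometry
  (progesterone must be found in ≥ 18, estradiol in ≤ 2; seed second
  level must recover the partner ROI in ≥ 18);
* null control: 20 seeded null studies, FWE-clean in ≥ 18;
* hormone contract: 50-seed sweep of the panel dynamics.

The desk-scale sizes keep the complete validation suite at a few minutes
on one CPU while preserving every qualitative property being tested.

## Known limitations

* FWE inference is peak-level Bonferroni/Šidák only; no random-field or
  permutation inference, no cluster-level corrected p values.
* The recovery/null criteria are stochastic by construction; the null
  control in particular sits near its Bonferroni bound and a rare
  unlucky seed batch can exceed 2 findings in 20 studies.
* Phase labeling assumes a single detectable LH surge per panel.
* The EC second level treats per-scan maps as exchangeable Gaussian
  observations; EC sampling noise is only approximately Gaussian.
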
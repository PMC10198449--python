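# Methods

This note documents the models, numerical choices, and simulation
conditions behind `selfrsa`, in the spirit of the model documentation that
accompanies packages like statsmodels or msprime. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic data model

No raw data accompanies the analysis this package implements, so the
generator (`selfrsa.synthgen`) is first-class, tested code that defines the
study conditions under which everything downstream is validated.

### Ratings

Each participant rates `n_items` items on a set of 7-point dimensions
(five in the two-task self/word design, seven in the self/other design;
word length and item provenance are item metadata, not ratings).
Ratings are drawn from a latent-Gaussian copula: a multivariate standard
normal is cut at the fixed equal-probability cutpoints Φ⁻¹(k/7), k = 1..6,
giving exactly uniform 7-point marginals. Coarse discretization attenuates
correlation (a latent r of 0.90 yields a discrete r of about 0.87), so the
latent correlation for each pair is calibrated by exact inversion: the
discrete-scale correlation of a latent ρ is computed from the 36 bivariate
normal orthant probabilities, tabulated on a ρ-grid, and interpolated. The
`dimension_corr_targets` matrix therefore specifies the Pearson correlation
of the *ratings as observed*. If calibration nudges a borderline matrix off
positive semi-definiteness, eigenvalues are clipped and the matrix is
rescaled to unit diagonal.

Default targets (used by `generate_cohort` and the pipeline): 0.5 between
descriptiveness and importance of the same target person (these are
reported to correlate strongly for some participants, which is also why the
stimulus optimizer supports a cap on exactly this pair), 0.3 between
self-descriptiveness/importance and valence and between familiarity and
autobiographical memory, 0.1 elsewhere. Item metadata: character counts
uniform on 2–12, provenance Bernoulli(0.5) — values chosen once as
realistic for short self-descriptive phrases; they exercise both
metadata-based similarity kinds.

### Activation patterns

`generate_item_patterns` embeds representational geometry for one chosen
*encoding dimension* (default `self_importance`) into a designated ROI (a
3-voxel-radius sphere inside an ellipsoidal mask), for one *signal task*
only. Each rating level ℓ = 1..7 gets a prototype pattern over the ROI
voxels; the prototypes are constructed (Cholesky factor applied to a
zero-mean orthonormal basis) so that their sample correlation matrix is
*exactly* the Gaussian kernel exp(−(ℓ−m)²/4). This is the dense-population
limit of Gaussian tuning curves of width 1 rating level tiling the scale:
pattern similarity decays strictly monotonically with |Δrating|, so the
noiseless ROI neural RSM is a rank-perfect match to the 7−|Δ| model RSM —
which is what makes exact recovery tests possible. An item's ROI pattern is
`effect × prototype(level)`; prototypes have unit per-voxel variance, so
`effect` is the signal-to-noise amplitude ratio against the i.i.d. Gaussian
run noise (`noise_sd`, default 1.0). Outside the ROI, and everywhere in the
control task, patterns are pure noise, independent across the 6 runs.

Study conditions fixed once: 40 items, 6 runs × 2 tasks, effect 1.0, noise
SD 1.0. A pilot check (5 cohorts of 8 participants) confirmed the full
pipeline recovers the embedded effect at these settings before the
acceptance thresholds were frozen; the settings were not revisited
afterwards.

What the generator does *not* emulate: spatial autocorrelation of noise,
physiological or motion artifacts, inter-participant anatomical
variability, non-spherical ROIs, and rating-level floor/ceiling effects.
Passing tests therefore demonstrate correctness and calibration of the
*machinery*, not effect sizes attainable on real data.

### Time series

`generate_timeseries` renders patterns into BOLD-like 4D runs: one 1.5-s
trial per item, inter-trial intervals uniform on [3, 7] s (mean 5 s),
TR 2.5 s, a 32-s tail; voxel time courses are the HRF-convolved item
design weighted by that run's pattern amplitudes plus stationary AR(1)
noise (marginal SD `noise_sd`, lag-1 autocorrelation `ar_phi`, innovation
variance scaled so the marginal variance is exact from the first sample).

## Stimulus selection

`select_stimulus_set` is best-of-n random subset search (default
n_iter = 100,000 with early stop when the objective drops below 0.05 —
desk-scale replacements for an impractically large nominal iteration
count), with an exhaustive mode used both for small problems and as the
test oracle. `r_highest` defaults to max |r| because collinearity is
sign-agnostic; a signed mode exists. The cap variant applies the signed
threshold (`r < 0.6`) to the designated pair and removes that pair from the
objective; infeasibility is a reported status, not an exception.

The 3-SD consistency exclusion uses Fisher-z scores and the *population*
SD with an inclusive boundary: with a sample SD, a single outlier among n
participants can never exceed (n−1)/√n < 3 SDs, so a strict sample-SD rule
could never fire on exactly the configuration it exists for.

## Model RSMs and predictors

Regression operates on strictly-lower-triangle vectors (diagonal excluded),
standard RSA practice. "Standardization" is z-scoring each model RSM's
pair vector; the alternative reading (z-scoring raw ratings before
computing similarity) is available via
`model_rsms_for_participant(..., standardize_ratings_first=True)` but is
not the default, because the regression inputs are the pair vectors and
z-scoring them puts all predictors on one scale regardless of units.
`maxlen` for the word-length RSM is computed within the participant's
final item set. Zero-variance predictors (e.g. every item self-provided)
are dropped with a log entry rather than propagated as NaN.

## First-level GLM

Canonical HRF: SPM-style double gamma (peak 6 s, undershoot 16 s, unit
dispersions, undershoot ratio 1/6, 32-s support), peak-normalized; built at
dt = 0.1 s and sampled at scan times. Parametric modulators are
mean-centered before multiplication into the boxcar (the convention that
keeps the condition regressor interpretable), convolved, then serially
orthogonalized by Gram–Schmidt in declared order; swapping modulator order
changes the columns but not the column span (tested via projection-matrix
equality). The default fit is OLS — no prewhitening — with an optional
single-pass AR(1) Cochrane–Orcutt flag; t = β/SE with df = scans − rank,
and rank-deficient designs fall back to the pseudo-inverse with a warning.
Session effects are per-run intercepts. The run-pooled RSA path fits one
concatenated GLM with a regressor per (task, item); the MVPA path fits each
run separately.

## Searchlight RSA

Searchlight membership and centers are restricted to in-mask voxels;
centers with fewer than `min_voxels` (default 10) members are NaN.
Neural RSMs use Pearson correlation (Spearman by flag); |r| is clipped at
1 − 10⁻⁷ before Fisher-z so degenerate searchlights remain finite.
Zero-variance item patterns make their pairs missing; missing pairs are
dropped listwise in the regression (fast path: when no pair is missing,
β = pinv(X)·y with the pseudo-inverse computed once per participant, since
the design is shared across searchlights). An intercept is always
included; with z-scored predictors it absorbs the mean neural similarity.
Because a searchlight reaches `radius` voxels away, signal "spills" that
far outside a true source — visible in the worked example and expected.

## Group inference

Smoothing is NaN-aware Gaussian (σ = FWHM/(2√(2 ln 2)) per axis in mm,
renormalized by the smoothed validity mask, so constants are preserved and
missing voxels do not bleed in). The sign-flip test forms the observed
one-sample t, thresholds at the Student-t quantile of the cluster-forming
p (one-sided positive by default), labels clusters by 18-connectivity
(6/26 available), and compares each cluster's extent with the permutation
null of the maximum extent; corrected p uses the add-one (Phipson–Smyth)
form, so p is never zero. The per-voxel sum of squares is flip-invariant,
so all permuted t-maps are computed with one matrix product. For fewer
than 10 participants (e.g. leave-one-participant-out re-analyses) all 2ⁿ
sign assignments are enumerated and the null is exact. Zero-variance or
non-finite voxels are excluded with a log entry. Cluster tables report
both peak t and the matching normal quantile Z. Plain t is used, not
pseudo-t variance smoothing. Dual thresholds (in-mask .005 / whole-brain
.001) are two configured calls rather than one special mode.

`bootstrap_power` resamples participants with replacement and reports the
fraction of replicates with any FWE-significant in-mask cluster; reduced
permutation counts per replicate are allowed and logged.

## Classifier MVPA

Tertile thresholds (t1 < t2 on the 1..6 boundary grid) minimize the spread
of the three bin sizes on the self-importance distribution, ties broken
toward lower thresholds; the identical thresholds are applied to the
friend-importance ratings. Note that thresholding a 7-level rating cannot
always reach the ideal ±1 partition — forty items with level counts
[6,6,6,6,6,5,5] split at best 12/12/16 — and the implementation returns
that true minimax split. With fewer than three distinct ratings the split
degenerates to fewer bins with a warning.

The LOPO ROI re-runs the group test without the left-out participant,
searches the peak-t voxel within 30 mm (mm space, via the affine) of the
full-group peak — restricted to supra-threshold voxels when any exist,
otherwise the plain search-sphere peak, logged — and extracts a
3-voxel-radius sphere (≤ 123 voxels, in-mask only).

SVM features are raw ROI t-values without per-feature scaling (matching a
default-cost LIBSVM-style workflow; a z-scaling flag exists). Run k of one
task pairs with run k of the other; each leave-one-pair-out fold trains on
the 10 remaining samples. Decision ties go to the positive
(lexicographically larger) class, deterministically. The permutation null
shuffles training-fold labels with the CV structure fixed; one-tailed
p = (1 + #{null ≥ observed})/(1 + n_perm), significant at 0.05/3.

Run-pair consistency computes all 15 pair correlations per condition,
Fisher-z, averages within participant, and fits the 2 × 3
repeated-measures ANOVA via statsmodels' AnovaRM (validated against an
explicit sums-of-squares oracle in the tests).

## Simulation sizes

The validation suites use deliberately desk-scale problems, chosen as the
smallest sizes at which the statistical claims are testable: an
ellipsoidal mask of ≈ 800 voxels in a 14 × 16 × 14 grid (3-mm voxels) for
pipeline runs, a 216-voxel box for null calibration (200 null datasets ×
500 sign flips, n = 12), 400 seeds for the CV chance-level check (each
dataset's accuracy has an SD of ≈ 17 points, so the ±3-point band sits at
≈ 3.4 standard errors), 200 datasets × 49 permutations for p-value
validity, and 50 cohorts of 8 participants for ground-truth recovery. The
acceptance script uses the same configurations at slightly reduced
replicate counts and finishes in a few minutes on one CPU.

## Known limitations

- OLS first-level fits ignore serial correlation unless the AR(1) flag is
  set; t-map dfs are correct for white noise only.
- The sign-flip test assumes symmetric per-participant errors; it is exact
  under that null but not robust to asymmetric confounds.
- Cluster-extent FWE inference is calibrated for the smoothness actually
  present in the maps; the synthetic noise is spatially white before the
  4-mm smoothing step, which is smoother than typical real residuals at
  3-mm voxels.
- The copula calibration assumes bivariate-normal dependence between
  latent dimensions; target matrices with extreme off-diagonals may be
  adjusted by the PSD repair step.
- `tertile_bins` documents one tie-breaking rule among several defensible
  ones; analyses sensitive to the exact rule should pass their own bins.
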
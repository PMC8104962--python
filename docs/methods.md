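# Methods

This note documents the models, estimators and numerical choices behind
`fmralert`, in the spirit of a package reference manual: what is computed,
under which assumptions, and where the design was genuinely open.

## EEG alertness index

The raw index is the per-TR alpha/theta rms ratio: for each volume's EEG
interval, the selected channels (default posterior montage P3, P4, Pz,
O1, O2, Oz) are averaged, the window is Hann-tapered, and the rms
amplitudes in 8–12 Hz and 3–7 Hz are computed from the window's discrete
magnitude spectrum with inclusive band edges. Band rms follows Parseval:
the root summed squared magnitude over the band's bins, so a tone's
energy is counted wherever leakage puts it inside the band. This
spectral estimator was chosen over a time-domain band-pass because a
~2 s window leaves too few cycles at 3 Hz for sharp IIR band edges; the
window-length constant cancels in the ratio, which also makes the index
exactly invariant to channel gain. The plain ratio is used by default; a
`log` option exists. The first volumes of a scan (pre-steady-state) are
dropped with `align_to_fmri` (default 7).

For comparison with BOLD the index is mean-centered, convolved with the
canonical HRF, and band-pass filtered. The HRF is the conventional
double-gamma: gamma-density response with peak delay 6 s minus a
16 s-delay undershoot scaled by 1/6, unit dispersions, 32 s support —
the standard parameter set, since only "the canonical HRF" is ever
specified by convention. Convolution is full mode truncated to the input
length (causal kernel, leading edge preserved). The band-pass is a
zero-phase 4th-order Butterworth (0.01–0.2 Hz nominal cutoffs, applied
forward and backward via `sosfiltfilt`), after which the series is
re-centered so the hemodynamic index is zero-mean to numerical tolerance.

## Vigilance template and projection

Template construction: per training scan, Pearson correlation of every
masked voxel series with that scan's hemodynamic EEG index
(zero-variance voxels get r = 0, counted and logged), Fisher-Z transform
with |r| clamped to 1 − 1e−7 (degenerate synthetic voxels would
otherwise produce infinities), and averaging across scans on the
intersection of the masks.

Thresholding retains, per sign, the top fraction of voxels by magnitude
(the fraction applies to each sign's own voxel count, matching the
"highest X% of positive and of negative voxels" convention). Ties at
the boundary are broken by (|value| descending, linear voxel index
ascending) with a stable sort, deterministic across platforms; the
retained count is rounded half away from zero with a minimum of one
voxel per requested sign. Values are not re-normalized after
thresholding — the projection is scale-invariant.

Projection: the scan is temporally z-scored per voxel, and the fMRI
alertness index at volume *t* is the spatial Pearson correlation between
template weights and volume-*t* intensities over the retained-support ∩
mask voxels. For thresholded templates only retained voxels enter the
correlation; treating the structural zeros as values would distort it.
Fewer than 3 overlapping voxels is an error (a 2-point correlation is
always ±1).

Cross-correlation convention: positive lag means the first series leads
(r(L) = corr(a[:−L], b[L:])). The permutation null re-pairs fMRI and EEG
indices across scans using random derangements — no self-pairs, since a
"shuffled assignment between scans" that allowed identity pairings would
contaminate the null with true signal. Scans of unequal length are
truncated to the common minimum. Train/test partitions are structural:
`SplitPlan` refuses overlapping sets at construction, so leakage cannot
be expressed.

The `TemplateVigilanceDecoder` estimator packages
fit-on-(scans, EEG indices) / predict-on-scans in scikit-learn form,
with optional sparsification at fit time.

## Behavioral analysis

Alertness indices are linearly interpolated by 2.5× (TR 2.1 s → 0.84 s
grid) for event alignment. Segments cover the closed window [−5, 10] s
around each onset with grid offsets k·dt for k from floor(−5/dt) to
ceil(10/dt) — the outermost points chosen to *cover* the window edges,
giving 19 samples at dt = 0.84 s; each segment value is the fine-grid
sample nearest to onset + offset, so segments are exact index values.
Trials whose window leaves the recording are dropped (not NaN-padded)
and logged.

A miss is no button press or a response slower than 5 s. Hits split at
the pooled-median reaction time (ties assigned slow and logged, since
strict-inequality thresholds leave equality unspecified); a
`subject_decile` mode labels each scan's fastest and slowest 10%
instead. Interval means average grid points in the closed interval per
trial, then trials per class per scan; scans missing a class simply
drop out of paired contrasts involving it.

Paired t-tests report Cohen's d as mean(diff)/sd(diff) (switchable to
pooled-sd); a zero-variance nonzero difference is reported as infinite t
with a degenerate flag rather than an exception. One-way ANOVA uses
scipy's F with statsmodels' Tukey–Kramer (Tukey HSD with unequal-n
correction) for the pairwise table.

## Task GLM

Event regressors are unit impulses at the TR nearest each onset (error
≤ TR/2 ≈ 1 s, acceptable at this sampling), convolved with the
canonical HRF; hit and miss events are separate columns, and an empty
miss condition is dropped with a warning. Alertness covariates are
mean-centered; an intercept is always appended; rank deficiency is an
error naming the columns. Per-voxel OLS gives betas, residual variance
with dof = volumes − rank, and t = beta/se. Drift columns are not added
by default — the pipeline contract is that input data are already
detrended — but `synthesize_fmri` can generate drift for testing.
Group-level inference is a voxelwise one-sample t across scans
(df = n − 1); numerically zero between-scan variance with a nonzero mean
is flagged ±inf. No cluster correction is applied.

## Physiological regression

RV is the standard deviation of the respiration belt waveform in a 6 s
window centered on each TR midpoint (±3 s, clipped at the recording
edges). HR is 60 over the mean inter-beat interval of beats whose
midpoints fall in the same window; pulse peaks are local maxima above
the 60th amplitude percentile with a 0.25 s refractory period, and
windows with too few beats inherit the nearest valid value (logged).
Zero-meaned RV and HR are convolved with the published respiration and
cardiac response functions (closed forms pinned in `fmralert.hrf` with
their literature coefficients), each augmented with a temporal
derivative (finite difference) and a dispersion derivative computed as
the normalized sensitivity to a 1% perturbation of the kernel time
constants (no analytic dispersion form is published); the six columns
are band-passed 0.01–0.2 Hz and re-centered. `regress_out` projects the
basis plus intercept out of every voxel; being a projection it is
idempotent and leaves residuals orthogonal to the basis.

## Lasso decoder

Features (voxel or ROI time series; ROI = mean over in-mask voxels per
atlas label) are standardized on training rows; the scaling record is
stored and applied, never refit, at prediction. The lambda grid is 50
log-spaced values spanning 4 decades down from the null-model lambda
max|Xᵀ(y − ȳ)|/n; the lambda minimizing mean k-fold CV error (default
k = 10) is selected — the one-standard-error rule is *not* applied —
and the model is refit on all rows. Folds are shuffled rows by default
(the conventional choice); a `blocked` option keeps temporally
contiguous folds because autocorrelated rows make random CV optimistic.

## Synthetic generator

The generator defines the study conditions under which the pipeline is
validated. Defaults per scan: 700 volumes at TR 2.1 s (24.5 min), a
16×16×12 voxel grid, EEG at 250 Hz over six posterior channels, ~33
auditory trials at inter-stimulus intervals uniform in 30–60 s, about a
quarter of them misses.

- **Latent arousal**: low-pass-filtered (zero-phase Butterworth,
  0.02 Hz) Gaussian noise, standardized, scaled by an amplitude
  parameter (0 gives an exactly zero series). Chosen over an
  Ornstein–Uhlenbeck process as the simplest process with directly
  controllable bandwidth.
- **Anatomy**: an ellipsoidal mask with a negative cortex-like shell,
  a positive ventricle-like core and a neutral noise-only band between.
  Negative voxels outnumber positive ones roughly 3:1; the core is
  sized so that even 1% retention leaves a projectable (≥3 voxel)
  positive set at this grid size. Magnitudes vary smoothly via a fixed
  geometry constant; the template is anatomy, shared across a cohort,
  not a random draw.
- **EEG**: 10 Hz and 5 Hz carriers with envelopes exp(±gain·z(t))
  (strictly positive; log-ratio linear in the latent) plus white noise;
  the latent is held constant within each TR window.
- **BOLD**: voxel series = weight × (HRF-convolved latent, rescaled to
  unit variance so weights are in SNR units) + optional Legendre drift +
  AR(1) noise of unit stationary variance (spatially independent
  innovations; spatial correlation is out of scope at this grid size).
  Default SNR 1.
- **Behavior**: miss probability logistic(−1.2 − 1.5·z̄pre), reaction
  time 565 − 100·z̄pre ms + N(0, 150²), floored at 150 ms (a
  physiological lower bound); responses over 5 s are recorded as misses.
  Intercept and base RT give roughly the observed miss rate and median
  RT of sustained-attention auditory tasks.
- **Physiology**: belt = latent-modulated-amplitude sinusoid at 0.25 Hz;
  PPG = sharp pulse train whose instantaneous rate is 65 + 5·z(t)
  beats/min via phase integration, at 50 Hz.
- An optional stimulus-evoked arousal rebound adds a gamma-shaped bump
  whose amplitude grows the drowsier the pre-stimulus state
  (amplitude = gain · max(0, ceiling − z̄pre)), used for the
  post-stimulus convergence and GLM-confound experiments.

All draws flow from one master seed through `SeedSequence` spawning;
identical seed and parameters regenerate a world bit-for-bit.

What the generator does **not** model: head motion, scanner drift-of-
gain, EEG gradient/ballistocardiogram artifacts, multi-echo structure,
spatially correlated noise, inter-subject anatomical variability, or any
generative account of why prediction quality differs across subjects
(per-scan SNR and coupling strengths are exposed instead). Passing tests
therefore demonstrate correctness of the estimators under the stated
statistical structure, not robustness to real-data artifacts.

## Reference experiments and problem sizes

`fmralert.experiments` wires the pipeline end to end. Sizes were chosen
as the package's reference desk scale: the primary recovery experiment
uses one default cohort (12 subjects × 700 volumes, SNR 1, 250 Hz EEG)
with a 1000-draw derangement null; the behavioral, GLM-covariate and
physiological-removal replications each use 50 independent cohorts at
the same per-scan defaults except that EEG is synthesized at 125 Hz
(the 3–12 Hz bands are fully resolved at either rate and the coupling
structure is identical; synthesizing hundreds of 250 Hz recordings
would dominate the replications' compute for no statistical gain);
the lasso comparison runs at reduced size
(4 subjects, 200 volumes, 10×10×8 grid) because the voxel-feature lasso
path dominates compute; calibration uses 2000 ANOVA replicates and a
20000-voxel group t map. On one CPU the full acceptance script takes
roughly 7 minutes and the test suite about 6.

## Known limitations

- The alpha/theta estimator assumes stationarity within each TR window;
  very short TRs (< 2 cycles of 3 Hz) trigger a warning and coarse
  theta estimates.
- The pooled-median RT split treats threshold-equal responses as slow;
  with continuous RTs this is measure-zero, with rounded RTs it can
  bias bin counts slightly (ties are logged).
- `fit_glm` uses one shared design per scan; voxelwise AR-whitening is
  not implemented (the synthetic AR(1) noise mildly inflates GLM t
  statistics, which is immaterial for the covariate-contrast
  experiments that compare models on identical data).
- The lasso's random CV folds are optimistic under strong temporal
  autocorrelation; use `blocked=True` for honest error curves.
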
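# Methods

`lamsurf` implements the analysis chain of a depth-resolved (laminar) 7 T
fMRI experiment on illusory surface-motion perception, together with a
ground-truthed synthetic data generator that stands in for the real dataset.
This note documents the models, the parameter choices, the numerical
decisions, and what the synthetic validation does and does not show.

## Experimental model

Three stimulus conditions share an identical left visual hemifield: a
'Pac-Man' disk (7.5° diameter) whose 70° mouth rocks sinusoidally (±35° at
0.85 Hz) about the right horizontal meridian (motion induction), the same
figure frozen (static control), and a 220° stationary left wedge paired with
a rotating 65° right wedge (dynamic control).  Runs are block designs: a
fixed 20.8 s initial rest, then 16 stimulus blocks of 10.4 s alternating
with variable rests of 18.7 / 20.8 / 22.9 s.  The block and rest durations
are printed as rounded seconds; internally every duration is snapped to an
integer number of TRs (TR = 2.079 s: blocks 5 TRs, rests 9/10/11 TRs) with a
5 % tolerance, which reproduces the printed 520 s / 250-volume run length as
250 TRs = 519.75 s.  Rest durations are counterbalanced — counts as equal as
possible with the remainder assigned to the middle duration — because that
is the only assignment consistent with the printed totals; their order is
shuffled by the run seed.

Fixation-target events (0.8 s, mean ITI 30 ± 10 s, none within 15 s of the
run edges) are decorrelated from the stimulus predictor by rejection
sampling: draw a candidate event train, convolve both event trains with the
haemodynamic kernel on a 0.1 s grid, and accept when the Pearson correlation
of the two predicted responses falls below 0.001.  The achieved correlation,
iteration count and seed are recorded; the search has a hard iteration cap
(default 10⁵) and reports the best correlation achieved on failure.

The background texture draws i.i.d. Gaussian pixel intensities (mean 40,
SD 60, 8-bit units), clips to [0, 255], and applies a 6 × 6 uniform box
filter.  The order of clipping and filtering is configurable (clip-first is
the default); both keep intensities in the 8-bit range.  Display luminance
is the fixed measured cubic y = −78.8x³ + 78.7x² + 317.2x + 163.3 cd/m² of
the projection system, evaluated exactly; out-of-range pixel values are
flagged but still evaluated.

Aperture movies are binary: a pixel is occupied when its centre lies inside
the shape (no anti-aliasing), which keeps the pRF forward model a plain
masked sum.  The frame rate defaults to 30 frames/s (the projector refresh
is not part of the design specification).  Coordinates are degrees of visual
angle, x rightward, y upward, origin at fixation, angles counter-clockwise
from +x.

## GLM

Each condition is modelled by two predictors: a sustained boxcar over the
block and a transient regressor with unit-area impulses at block onset and
offset sharing one beta; target events add one nuisance column.  All
predictors are convolved with a canonical double-gamma HRF (peak delay 6 s,
undershoot delay 16 s, unit dispersions, undershoot ratio 1/6, 32 s kernel)
on a fine grid (TR/21) and sampled at acquisition times.  The kernel is
normalised so its continuous-time peak is 1, making kernels at different
sampling rates subsamples of one function.  Each regressor is scaled to unit
peak so betas are in raw-signal units of peak response.

High-pass filtering projects out a discrete-cosine drift basis (all periods
≥ 35 s, constant included) from both data and design.  A DCT projection is
used rather than a running-line filter because it is an exact idempotent
projector, which makes the algebra of the tests exact; the 35 s cutoff is
kept.  Fitting is ordinary least squares; no prewhitening is applied —
temporal autocorrelation is handled at the group level, where inference
lives.  Betas are converted to percent signal change (PSC) against the mean
raw signal of the first 20.8 s of the run (the initial rest).  Differential
contrasts are differences of PSC values.

Event-related averages cut segments starting one volume before each block
onset, express them as PSC against that pre-block baseline volume, and
average across the block repetitions (mean ± SEM).

## Cortical depth model

Depth is a fraction from the pial surface (0 % = pial/CSF border, 100 % =
white/grey-matter boundary).  The grey matter is divided into 10 equi-volume
compartments, giving 11 depth boundaries.  Geometry is parameterised per
column: flat (equidistant boundaries), annular or spherical-shell, where the
equal-volume rule places boundary radii at
r_j = √(r_wm² + (j/n)(r_pial² − r_wm²)) (cube-root analogue for spheres).
The package works on a lattice 'flattened cortex' (column × depth) with a
voxel↔column index map instead of a surface mesh; mesh construction on real
anatomy is out of scope, but the equi-volume algebra is exercised on the
curved geometries.  Depth sampling interpolates linearly along the depth
axis (the lattice analogue of the trilinear sampling used on real volumes).

ROI selection is all-or-none per cortical segment: a column enters iff its
median-over-depth pRF R² exceeds 0.15, its minimum mean-EPI intensity over
depth is at least 7000 (a scanner-specific default exposed in the
configuration, not a constant), and its median eccentricity falls in the
band — 1–3° for the stimulus-centre ROI, 3.5–4.0° for the edge ROI.

## Draining-vein model and deconvolution

Ascending veins carry deoxygenated blood toward the cortical surface, so
gradient-echo BOLD at a depth mixes in signal from all deeper depths.  The
forward model is observed = W · local with W lower-triangular
(deep → superficial ordering) and unit diagonal.  Deconvolution proceeds by
sequential substitution from the deepest level upward — subtracting the
estimated contribution of all deeper levels — which is algebraically a
lower-triangular solve and is tested against `scipy.linalg.solve_triangular`.
The published weight values live in cited vascular-model literature and are
not printed in the study itself, so the shipped default is an explicit
approximation: a cumulative-drain matrix in which a fraction λ = 0.3 of each
depth's signal is carried to every more superficial depth.  Any full matrix
can be loaded from TSV.  The procedure is robust to weight misspecification:
on the phantom's single-peak contrast profiles, perturbing the weights by
±20 % moves the recovered peak by at most one depth level (asserted in the
tests).

## Visual-field projection

Per-unit statistics are projected into visual space as a pRF-weighted mean:
V_ij = Σ_k M_ijk p_k / Σ_k M_ijk, where M_ijk is unit k's 2D Gaussian pRF
evaluated at pixel (i, j).  No smoothing is applied.  Pixels whose pRF
density Σ_k M_ijk falls below 1 % of its peak are masked as unsupported (the
floor is reported with the output).  Group projections concatenate all
subjects' pRF models and statistics before normalising — deliberately not an
average of per-subject maps.  Default grid resolution is 0.05°/pixel for
stimulus rendering and 0.25°/pixel for projections (the figure-production
resolution is not part of the design; both are configurable).

## pRF estimation

The pRF model is an isotropic 2D Gaussian (x₀, y₀, σ).  Mapping stimuli are
checkerboard bars (width 1.25°) at 4 orientations × 8 positions = 32
configurations, each shown for one TR, 12 repetitions in random order; a
padding parameter (default 16 rest volumes, split between run start and
end) reproduces the 400-volume run length, since the printed run arithmetic
implies unstated rest volumes.  Fitting is an exhaustive grid search —
x/y spanning the mapped field, σ log-spaced — with the amplitude solved by
least squares per candidate and the maximal-R² candidate returned; exact
ties break towards the smallest σ, then the smallest eccentricity.
Nonlinear refinement is off by default so results are deterministic.
Zero-variance time courses are flagged (R² undefined) and excluded
downstream by the R² criterion.

## Group statistics

*Contrasts.* Per-subject, per-depth PSC differences, summarised as group
mean ± SEM.

*Onset detection.* Per time point, a two-sided one-sample t-test across
subjects against zero at the Bonferroni level α/n (n = in-window time
points, α = 0.05); the onset is the earliest significant index.  Detection
is sign-agnostic because the study design produces positive (edge) and
negative (centre) responses.  Zero-variance time points are skipped with a
warning.

*Peaks.* The peak of a contrast depth profile is its global maximum;
'superficial' means within the upper third of the grey matter (depth ≤ 1/3
from the pial surface).  Exact ties resolve towards the more superficial
depth (a documented, isolated rule; the deep-wins variant is available
behind a flag).  Superficial-peak ratios are compared between areas with a
Pearson chi-squared test, no continuity correction; pooled comparisons (V1
vs V2+V3) are expressed as summed count pairs.

*Mixed models.* Nested linear mixed models with fixed effects for ROI,
condition and depth (selected two-way interactions), a random intercept and
depth slope per subject, fitted by maximum likelihood (not REML, so models
differing in fixed effects are comparable) via statsmodels' MixedLM; the
likelihood-ratio statistic 2·Δloglik is referred to a chi-squared with df
equal to the fixed-parameter difference.  Residuals are treated as
conditionally independent given the random effects: a continuous-AR(1)
correlation over depth is a natural extension, but the implemented model is
the one the calibration simulation targets (the generator draws independent
residuals), and the type-I error of the test is verified by simulation to
sit in [0.03, 0.08] at α = 0.05.  Negative LR statistics (an optimizer
artefact) trigger a refit with alternative optimizers and are clipped at
zero.

## Synthetic data generator

The phantom emulates the statistical structure of the study data, not its
anatomy:

- **Lattice.** 3 areas (V1, V2, V3) × 8 eccentricity levels × 6 polar
  angles = 144 columns, 11 depth levels.  Eccentricities (1.25–4.3°) are
  chosen to populate the centre (1–3°) and edge (3.5–4°) ROI bands plus one
  level outside the stimulus; polar angles span the left hemifield (the
  physically constant stimulus half, represented in the right hemisphere).
- **Retinotopy.** Each column's true pRF centre sits at its (ecc, angle);
  σ grows with eccentricity and area (0.3/0.5/0.7° base + 0.1°/deg),
  mimicking the coarser tuning of extrastriate cortex.
- **Responses.** Interior columns (ecc ≤ 3.3°) carry a sustained −2.5 %
  response in every condition — the negative surface response, generated as
  a deficit against the elevated texture-background baseline; edge columns
  (3.4–4.1°) carry a +2 % transient at block onset/offset.  The motion
  condition adds a sustained increment of 0.3 % with a Gaussian depth
  profile (width 0.1) peaking at 25 % depth in V1, 50 % in V2 and 40 % in
  V3 — the feedback signature the analysis chain must recover.
- **Acquisition.** The laminar amplitude vector passes through the draining
  forward model, is converted to signal via the same regressor construction
  the GLM uses (so a noiseless run is an exact linear model and recovery is
  machine-precision), and rides on a mean-EPI baseline of 10 000 units with
  10 % fixed spatial 'anatomy' jitter (shared across runs, so the spatial-
  correlation QC has structure to correlate).  Noise is stationary AR(1)
  (coefficient 0.3) plus white noise at 0.5 % of baseline, plus a slow
  cosine drift (0.5 %, 100 s period, random phase).  Subjects differ by a
  multiplicative amplitude factor ~ N(1, 0.15).  The noise model is the
  minimal one that exercises high-pass filtering and group inference; the
  paper gives no noise specification.
- **Determinism.** A seed is mandatory everywhere; identical spec + seed
  reproduce bit-identical truth tables and volumes, and the written dataset
  (NIfTI + TSV + manifest JSON) round-trips exactly.

What passing on the phantom does **not** show: robustness to motion,
distortion, segmentation error, physiological noise, pRF model mismatch, or
vascular physiology beyond the linear triangular leakage model.  Per-depth
SNR gradients of gradient-echo BOLD are parameterisable but default to
depth-constant noise, as no defensible default is derivable from the study.

## Pipeline, QC, problem sizes

The orchestrated chain (simulate → pRF fit → GLM → ROI → depth profiles →
deconvolve → project → group stats) enforces two QC gates per run: mean
volume-to-reference spatial correlation ≥ 0.95 and fixation-target hit rate
≥ 70 % (responses matched greedily within 2 s; each response credits one
target).  Excluded runs are logged with reasons and downstream sample sizes
shrink accordingly.  A manifest records the seed, configuration, truth hash
and output hashes, so a rerun from the same config is bit-identical for the
deterministic stages.

Default validation sizes, chosen to keep the whole suite a desk-scale
computation: 10 simulated subjects × 3 conditions × 1 run for the
end-to-end recovery; 216 units for pRF recovery at SNR 10 (grid step 0.25°);
1000 random matrices for the deconvolution oracle; 500 replicates (9
subjects, 3 × 3 × 5 cells) for the mixed-model type-I calibration.

## Known limitations

- The real study's statistics (its LRT and chi-squared values, peak depths,
  −3 %→+1 % background effect) derive from nine human subjects at 7 T and
  are not reproducible from synthetic data; the pipeline reproduces its own
  programmed ground truth instead.
- The leakage weights are a parameterised approximation, not the published
  vascular-model values.
- The mixed model omits the CAR(1) residual depth correlation (see above).
- The lattice phantom has no cortical curvature or mesh topology; curved
  geometry appears only in the equi-volume boundary algebra.
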
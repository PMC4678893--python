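# Methods

This note documents the models behind `hemiflow`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a user auditing results should know
about.

## The synthetic-data generator

The generator exists so that every analysis stage can be validated
against known ground truth. A dataset is built in four layers:

1. **Paradigm.** An alternating two-condition block design:
   `build_paradigm(4, 30, 3, n_dummy=5)` reproduces the standard run of
   4 task + 4 control blocks of 30 s at TR = 3 s — 80 retained volumes
   after dummy-scan discard. Trials within blocks are not modelled; the
   analysis is block-level throughout, so the boxcar at block resolution
   is the input.
2. **Latent neural dynamics.** Region signals follow
   `x_t = Σ_k A_k x_{t−k} + g·u_t + e_t`, a VAR of configurable order
   (default 1 — the generative order of real neural data is unknown and
   lag-1 at TR = 3 s is the simplest structure CGC can recover), driven
   by the condition boxcars `u_t` with per-region, per-condition gains
   `g` and independent Gaussian innovations. Every emitted network must
   have a companion-matrix spectral radius < 1; non-stationary requests
   are rejected, and subject-level coupling jitter is shrunk back inside
   the stationary region if needed. A 200-sample burn-in is discarded so
   initial transients never reach outputs.
3. **Hemodynamics.** Each region's latent signal is convolved with its
   own double-gamma HRF (peak delay 6 s, undershoot delay 16 s,
   undershoot ratio 1/6, 32 s support); regional latency differences are
   expressed as a shift of both gamma delays
   (`HRFSpec.with_latency_offset`). Gaussian measurement noise (default
   SD 0.5, against unit-SD innovations) is added after convolution.
4. **Voxels.** Regions are block-shaped parcels on a lattice (default
   20×20×10 at 3 mm isotropic) mirrored across the x = 0 midline plane;
   hemisphere membership is decided in world coordinates (x < 0 = left).
   A voxel drawn *truly active* carries the (centred) region signal on
   top of a baseline of 100 plus voxel noise. Active-draw probabilities
   are calibrated so the expected left:right active-voxel count ratio
   equals the group's `asymmetry_ratio` exactly, whatever the parcel
   geometry. Within a cohort the active mask is drawn once from the
   group master seed: a cohort has one functional anatomy, and subjects
   differ in noise realizations and coupling jitter. For activation-level
   validation without autoregressive dynamics,
   `simulate_activation_volume` programs a literal percent-signal-change
   amplitude (the task-vs-control difference as % of baseline).

The two default cohorts emulate the study design the pipeline targets: a
left-asymmetric "RH-like" group (asymmetry ratio 3, matching an LI near
0.5) and a symmetric "LH-like" group (ratio 1, LI near 0) of 28 subjects
each, the latter additionally carrying two extra cross-hemisphere
couplings from right MOG into bilateral insula (+0.35) — the kind of
edge difference the group comparison is meant to detect. Task drive
defaults to gain 2 on the occipital entry regions and 1 elsewhere, so
most of the task signal reaches downstream regions through the network.

**What the generator does not emulate:** scanner artifacts, head motion,
physiological noise, spatial autocorrelation or smoothing, slice timing,
non-Gaussian innovations, temporal autocorrelation beyond the VAR and
HRF, trial-by-trial behaviour. Passing tests therefore demonstrate the
*statistical machinery* — calibration, recovery, error control — under
the model's assumptions, not robustness to real-scanner confounds.

## Activation mapping

Per-voxel OLS on a design of HRF-convolved condition boxcars, Legendre
drift terms up to `drift_order` (default 1), and an intercept; the
contrast of interest is task − control with one-sided p-values (the
hypothesis is activation, not deactivation). Group maps are one-sample t
tests across subjects' contrast estimates (the summary-statistics
approach). Thresholding is Benjamini–Hochberg FDR at q = 0.01 followed
by a cluster-extent filter that keeps components **strictly larger
than** 10 voxels under 26-connectivity (both configurable; the strict
inequality and SPM-style corner connectivity are the operative map
filter here). Conjunction across groups uses the conjunction-null
(minimum-statistic) reading: a voxel survives only if it survives the
full threshold rule in every group — equivalently the intersection of
per-group masks, which is what the implementation computes. Percent
signal change scales the contrast estimate by the peak height of the
contrast-combined condition regressor and divides by the intercept
estimate (the MarsBaR-style convention for block designs).

## Lateralization index

Counts of suprathreshold voxels per hemisphere are taken over a grid of
t cutoffs (default: 0 to the territory's 99.9th percentile in 40 equal
steps) within a configurable territory (a label set over the
parcellation, e.g. cerebral vs cerebellar parcels). Each hemisphere's
curve is fitted with a single exponential `N(t) = c·exp(−λt)` by
ordinary least squares on log counts; thresholds with fewer than 5
voxels are excluded — zero counts have no logarithm, and the log of a
handful of voxels is noisy enough that keeping such points makes the
estimate drift with the grid density, violating grid stability. If
fewer than 4 usable points remain, the fit falls back to nonlinear least
squares on the raw counts. The index is the normalized difference of the
fitted constants; categories use the inclusive ±0.2 boundaries. The
exact regression family of the original threshold-free method is not
published in detail; the exponential form is recorded in every output's
`model_form` field and alternatives can be plugged in at the
`fit_curve` seam.

## Deconvolved conditional Granger causality

**HRF estimation.** The ROI series is regressed on the task boxcar
convolved with a canonical kernel and its latency derivative (plus
intercept and linear drift). The kernel used for inversion is the
canonical shape shifted by the estimated latency (the
derivative-to-peak weight ratio, clipped to ±4 s) rather than the raw
weighted basis sum: for weakly task-driven ROIs the unconstrained sum
can be arbitrarily wild, and inverting a wild kernel destroys the
series. An FIR basis is available (`basis="fir"`) and keeps the raw
reconstruction; it is less stable on block designs, whose lagged
boxcars are nearly collinear.

**Deconvolution.** Frequency-domain Wiener inversion
`X(ω) = H*(ω)Y(ω) / (|H(ω)|² + reg)` on a zero-padded grid, output
mean-centred. The default regularization scales a noise-floor estimate
(median spectral power of the top-quartile frequencies, relative to
total power) by the kernel's peak spectral power, times 0.1; it is
configurable and recorded in the output.

**Task-evoked removal.** Before the VAR stage each series is
residualized against the task boxcar at lags 0..5 plus an intercept,
then linearly detrended. This stage is essential for calibrated
inference: every task-responsive ROI carries a copy of the same
deterministic input, the bootstrap null below contains no counterpart
for it, and without removal the measured false-edge rate reached 0.4–0.5
at nominal 0.05. It can be disabled (`remove_evoked=False`) for
methodological experiments on the evoked confound itself — the
deconvolution-benefit analysis compares raw vs deconvolved series
without it, since the latency confound it studies lives in the
task-locked component.

**VAR and CGC.** Per-equation least squares with intercept; the order is
selected on a common sample window by information criterion over 1..5.
The pipeline default is **AIC**: on hemodynamically smoothed series BIC
systematically picks order 1, and the unmodelled autocorrelation
anti-conservatively inflates false edges (~0.11 measured at nominal
0.05); AIC typically selects order 2 at TR = 3 s and restores
calibration. For every ordered pair, `F(i→j | rest) =
ln(RSS_reduced/RSS_full)` with the reduced model omitting the source's
lags; both models share one sample, so the statistic is non-negative up
to a −1e-10 numerical floor, and the conditioning set is always all
remaining ROIs. CGC values are invariant to rescaling any single series.

## Bootstrap significance and networks

The null model preserves each region's own dynamics and destroys
coupling: the fitted VAR's cross-region coefficients are zeroed
(self-lags shrunk if a univariate polynomial ends up unstable),
replicates are simulated with jointly resampled fitted residuals
(instantaneous covariance preserved), and each replicate passes through
the same preprocessing as the data before CGC is recomputed. The
threshold is the empirical (1 − α) quantile of the pooled off-diagonal
null values (default α = 0.05, n_reps ≥ 100; a matched null for
unconditional pairwise GC is available via `include_pairwise`). A
phase-randomization surrogate would be a reasonable alternative scheme;
the residual-bootstrap scheme's name is written into every output's
metadata.

Group networks aggregate subject-level exceedances: an edge enters when
the number of subjects whose CGC exceeds their own threshold beats a
one-sided binomial test against the per-subject α, at `alpha_group` =
0.01 by default (majority vote is available). Degree tables sort by
ascending In-Out degree with the published tie-break (descending
out-degree among sources, ascending in-degree otherwise). Hemispheric
counts treat a midline–lateral edge as inter-hemispheric and exclude
midline nodes from intra counts; a bidirectional connection is an
unordered cross-hemisphere pair significant in both directions, so
`inter_directional ≥ 2 × inter_bidirectional` always. Edge-wise group
comparisons use Welch's unequal-variance t (group variances are never
asserted equal) with one-tailed alternatives and Bonferroni control over
the n(n−1) ordered pairs at FWE p = 0.01; the four count comparisons are
two-sample t tests at p < 0.01, one-sided for the two "more
inter-hemispheric connections" hypotheses and two-sided for the two
intra-hemisphere ones.

## Pipeline and reproducibility

`run_pipeline` chains simulate → activation → conjunction → ROIs →
laterality → signal change → CGC → bootstrap networks → degrees/counts →
group comparisons, writing TSV/NIfTI/JSON artifacts plus a manifest with
the config hash, seeds and SHA-256 checksums of every output. The
manifest deliberately contains no wall-clock timestamps, and the config
echo excludes output paths, so identical configuration + seed reproduce
the manifest bytewise. All randomness flows from explicit integer seeds;
per-subject seeds derive deterministically from the group master seed.

## Study conditions used by the validation suite

The acceptance tests and `scripts/acceptance.py` run these problem
sizes, chosen as the package's own validation conditions: closed-form GC
at T = 20,000; chain pseudo-causality with coupling 0.7 at T = 240, VAR
order 2 (the bivariate margin of a VAR(1) chain needs two lags), 100
replicates with 100 bootstrap draws each; bootstrap calibration on 200
uncoupled, undriven subjects (4 regions, T = 80, n_reps = 200) — a
*shared* task input is genuine common-input dependence that no
significance threshold should be expected to absorb, which is why the
calibration null carries none; deconvolution benefit on 200 subjects
(2 s latency handicap on the source, coupling 0.4, T = 240, task gain
2); network recovery with 28 subjects on the 8-node demo network at
T = 240 with occipital-only drive; edge-difference detection with a
+0.35 offset on one edge, 28 subjects per group, 200 replicates; LI
recovery at asymmetry ratios {1, 1.5, 3} with 3% programmed amplitude
over 30 subjects; empirical FDR on 200 fully-null 2,048-voxel volumes,
where the false-discovery proportion per volume is 0 or 1 and its mean
is compared to q within the 200-replicate Monte-Carlo band.

## Known limitations

- The common-input confound of task designs is handled by projecting out
  lagged boxcars, which also removes genuinely task-locked coupling;
  connectivity inference here is effectively about the stochastic
  (trial-to-trial) dynamics.
- Wiener deconvolution colors the noise spectrum; the information
  criterion usually absorbs this with one extra lag, but heavily
  regularized inversions on short runs can still be slightly
  anti-conservative.
- The LI decay model is a single exponential; real count curves are
  survival-function mixtures, and the fitted constant is a
  model-dependent summary rather than a literal voxel count.
- Group aggregation by exceedance counts treats subjects as exchangeable
  and ignores the magnitude of supra-threshold CGC values.
- The voxel model has no spatial autocorrelation, so cluster-extent
  thresholds are stricter here than they would be on smoothed real data.
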
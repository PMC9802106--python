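# Methods

This note documents the models, the tunable parameters, the numerical
choices, and what the synthetic validation does and does not establish.

## The analysis chain

**Conditioning.** Filters are 4th-order Butterworth IIR in second-order
sections, applied forward–backward (`sosfiltfilt`), so they are zero-phase:
a slow evoked deflection is not shifted in time, which matters when
activity is averaged in 250-ms tone windows. The notch defaults to
48–52 Hz, the band-pass to 0.1–1 Hz (the slow band in which sequence
recognition is expressed). The 0.1-Hz corner is stabilized with
odd-reflection padding over the record; steady-state stop-band attenuation
is ≥ 20 dB and DC is suppressed below 10⁻⁶ of its input level.
Downsampling uses a polyphase FIR (Kaiser β = 10, linear edge extension),
output length `ceil(n·fs_out/fs_in)`. Epochs span −100..3400 ms around
sequence onset with `floor(duration·fs/1000)` samples (onset sample
included; 525 samples at 150 Hz); each trial's pre-onset mean is subtracted
from the whole trial. Analyses use correctly answered trials only;
a participant is excluded from group statistics (with a logged warning)
when any condition retains fewer than two correct trials, the minimum for a
nondegenerate residual covariance.

**Beamformer.** Scalar (fixed-orientation) unit-gain LCMV. The sensor
covariance is the second-moment matrix of all pooled post-stimulus samples
of both conditions — common weights, so the spatial filters cannot be
condition-biased — computed after subtracting each condition's
trial-averaged evoked response. Using residual (background) covariance is
deliberate: adapting the filter to data containing a strong, patch-wide
coherent evoked signal makes LCMV partially cancel that very signal, and
the cancellation grows with the participant's effect amplitude, which
nonlinearly distorts amplitude–behaviour coupling. With residual
covariance the reconstruction is linear in the planted amplitude.
Diagonal loading is `0.05 × mean(diag)` by default; a singular covariance
raises a rank error instructing regularization rather than silently
pseudo-inverting. Weights are applied per time point to each condition's
evoked response.

**Window statistics.** Trial-averaged source time courses are averaged in
five half-open tone windows (`250·(w−1) ≤ t < 250·w` ms), yielding one
number per participant × voxel × window × condition. Two polarity rules
exist. `signed` (default) keeps raw reconstructed values: in this package
source polarity is meaningful because every participant's exact forward
model is known. `rectified` (|value| per sample before window averaging)
is the conventional workaround for the arbitrary per-voxel sign of
beamformer output on real anatomy, and is fully supported — but note it
makes the window measure an even function of amplitude, which (a)
compresses condition effects whose amplitudes straddle zero, and (b)
couples any behaviour-dependent amplitude to the *whole volume*: a
participant with a larger planted amplitude has more leaked signal power
everywhere, and rectified activity increases with power. In simulation
this floods the WM-correlation map (hundreds of spuriously suprathreshold
voxels), so cluster inference on rectified correlation maps should be
interpreted with care on any data.

The group statistics are a paired t across participants on
memorized − novel (df = n − 1), a Pearson correlation of WM score with
memorized − novel (df = n − 2, via the exact t transform for p-values), and
the behavioural Pearson correlation. Voxels with zero variance of the
paired differences are flagged and set to t = 0 rather than NaN. Pearson
maps are invariant to affine rescaling of WM scores; the contrast map
flips sign when conditions are swapped. These invariants are tested.

**Cluster correction.** Statistic maps are binarized at a two-sided
voxel-level α (contrast .001, correlation .05, per-group .025) and split by
sign; positive and negative families are corrected independently.
Connected components use the grid's connectivity (26 by default,
configurable 6/18/26; `scipy.ndimage.label`, cross-checked in the tests
against a pure-Python flood fill). The permutation null relocates the
observed number of suprathreshold voxels uniformly at random, without
replacement, over the in-brain grid — count-preserving spatial shuffling —
and records the maximum cluster size; 1000 permutations by default. The
decision threshold is the nearest-rank 95th percentile
(`ceil(0.95·n)`-th order statistic) and the decision is strict: a cluster
whose size *equals* the threshold is not significant. For masks of ≤ 3
voxels the null maxima are computed in closed form from pairwise adjacency
(validated against brute force); larger masks are labelled explicitly.
Permutation streams are spawned per window, sign and analysis from one
top-level seed, so per-window analyses are independent yet the whole run is
bit-reproducible.

## The synthetic-study generator

The generator emulates the *statistical structure* of a 70-participant,
two-condition recognition study: 120 trials per condition at 150 Hz with
3500-ms epochs (100 ms baseline) by default, an 8-mm source grid, WM scores
Normal(100, 15) truncated to [40, 160] (the WM-index norm convention),
a musician/nonmusician label (musician fraction 48/71), and recognition
accuracy drawn through a Gaussian copula with an exact Binomial(total
trials, 0.85) margin whose latent correlates with the WM latent at
`behavior_wm_r` (default 0 — the study regime in which accuracy and WM are
uncoupled).

Source activity is white Gaussian noise (SD `noise_sd`). Planted
memorized-condition amplitudes are constant within designated tone windows
and expressed in noise-SD units:

* effect clusters: `amp = d + effect_between_sd · η`, η ~ N(0,1) per
  participant and voxel. With `effect_between_sd = 1` (default), `d` is a
  between-participant Cohen's d, so the group paired t at an effect voxel
  concentrates near `d·√n` — the calibration that makes power analytically
  checkable. Without a between-participant amplitude term the
  across-participant variance would be only trial noise and t values would
  be two orders of magnitude larger than any plausible group study.
* correlation clusters: `amp = mean_amplitude + β·z(WM) + residual_sd·ε`,
  population correlation `β/√(β² + residual_sd²)`. Defaults
  `mean_amplitude 0.8, residual_sd 0.8`.

Lead fields are seeded Gaussian random sensor patterns, spatially smoothed
so column correlation decays as `exp(−d²/2s²)` with inter-source distance
(`smoothness_mm`, default 4 mm — half the voxel spacing — so neighbouring
sources correlate ~0.14 and the inverse stays well-posed with localization
error ≤ 1 voxel). Each participant receives an independently seeded lead
field by default, emulating different head geometries. This is essential
for group inference: with a single shared lead field, beamformer cross-talk
from a planted effect is identical in every participant, so leakage becomes
a consistent offset that the group t-test amplifies brain-wide. With
per-participant fields, long-range leakage is zero-mean across participants
while short-range (spatially smooth) leakage remains, which is the regime a
multi-subject beamformer study actually operates in.
`shared_leadfield=True` restores the single-field variant.

Because the unplanted source background reaches the sensors only through
the lead field, the generator draws it at the sensors directly from its
exact implied covariance `noise_sd²·GGᵀ + sensor_noise_sd²·I` per time
point — the same multivariate-normal law as materializing noise at all
sources and projecting, at a fraction of the cost. Planted effects enter
explicitly through their sources' lead-field columns (so, e.g., noiseless
studies reproduce the planted amplitudes exactly under least squares).
Ground truth (masks, parameters, per-participant amplitudes) is stored on
the Study and serialized with it.

What the generator does **not** emulate: head geometry and sensor physics
(gradiometer/magnetometer distinction), head movement, physiological
artifacts (EOG/ECG), 1/f and oscillatory background spectra,
between-region correlation structure, or anatomical labels. Passing the
validation suite therefore demonstrates the *statistical machinery* —
error control, recovery, calibration — under a faithful spatial-leakage
model, not robustness to real-world artifact structure.

## Validation study sizes

The statistical validation batches (test suite and
`scripts/acceptance.py`) use scaled studies chosen so a full batch runs in
minutes on one CPU while the group-level statistics stay in the same
regime as the full design: 12×12×12 full-box grid (1728 sources, 8 mm,
26-connectivity), 96 sensors, 100 Hz sampling, epochs −100..1250 ms (the
five tone windows plus baseline), 4 trials/condition for global-null
studies (under the null the trial count only sets the small
within-participant noise) and 16 trials/condition for recovery studies;
n = 30 participants for null batches and n = 70 for recovery, per the
validated claims. Planted conditions: 30 contiguous voxels at d = 0.8 in
windows 3–4 (contrast recovery); 20 contiguous voxels with population
r = 0.6 (β = 0.6, residual 0.8) for correlation recovery, with matched
null runs at β = 0. Measured at these conditions: family-wise error of the
full contrast pipeline ≈ 0.03–0.05 (nominal .05); contrast clusters
recovered at Jaccard ≈ 0.9; correlation regions flagged in ≥ 80% of runs.

## Known limitations

* **The correction is per family, not per study.** Each window × sign
  family gets its own permutation null, so the 95th-percentile rule
  controls the false-cluster probability *within that family* (realized
  level ~3–4% at α = .05 mask densities; ~0.4% at α = .001, where 0–3-voxel
  masks make the discrete test very conservative). A study runs 10 such
  families (5 windows × 2 signs), so the probability of some false cluster
  *somewhere* in a null study is ~25% at α = .05 even for ideal white
  maps — we measured 26/100 on iid-normal window differences with no
  beamformer at all. Validation therefore bounds the per-family rate for
  the α = .05 correlation analysis, and the per-study rate for the α = .001
  contrast analysis (where the families are conservative enough that the
  study-level rate stays below nominal). Readers of any analysis using
  this procedure should keep the same distinction in mind.
* The spatial-shuffle null treats suprathreshold voxels as exchangeable in
  space. Smooth statistic maps clump suprathreshold voxels, so the
  procedure's realized family-wise error rises with the map's spatial
  autocorrelation; with the 4-mm lead-field smoothness used here the
  per-family rate stays near nominal (~4% vs 3.2% for ideal white maps at
  α = .05), but heavier smoothing would make it anticonservative.
* Scalar (fixed-orientation) dipoles; no vector beamformer, no depth
  normalization. Orientation handling on real anatomy is out of scope.
* The correlation analysis assumes the WM coupling lives in the
  memorized-minus-novel amplitude; couplings expressed in variance or
  latency are invisible to it.
* `rectified` polarity is supported but interacts pathologically with
  amplitude-coupled covariates (see above); the default is `signed`.
* Cluster size is the only cluster statistic (no cluster mass, no TFCE),
  matching the procedure under study.
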
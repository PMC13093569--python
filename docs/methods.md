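# Methods

## Cantilever force transduction

Each PDMS pillar is modelled as a cantilever beam with a concentrated
load at its free end: tip deflection δ = P L³/(3EI) with I = πd⁴/64 for
a circular cross-section. The package works with the inverse relation
P = kδ, k = 3EI/L³. Defaults (L = 12 mm, E = 1.7 MPa, d = 1.2 mm) give
I ≈ 1.0179·10⁻¹³ m⁴ and k ≈ 0.30041 N/m, so 1 μm of deflection
corresponds to ≈0.30 μN. The linear formula is used without
large-deflection correction; a warning is emitted if δ exceeds 10% of L.
Force is reported for the tracked pillar only — the formula describes a
single cantilever, and no doubling for the two-pillar construct is
applied.

Baseline policy: the diastolic (resting) level of a displacement trace
is estimated as the median of its lowest decile and subtracted before
conversion, so the headline force is the active force above rest. The
unsubtracted conversion is kept in `ForceTrace.force_absolute_n`, since
whether a published force is baseline-referenced is often unstated.

## Phase-only correlation tracking

`poc_shift` normalises the cross-power spectrum of two frames to unit
magnitude (spectral floor 10⁻¹² relative to the spectrum maximum),
inverse-transforms, and refines the correlation peak:

* mean subtraction and a separable Hann window suppress wrap-around
  edge correlation (disable `apodize` only for genuinely periodic
  frames, where the unwindowed phase relation is exact);
* a radial raised-cosine taper (cutoff 0.5 of the Nyquist radius)
  down-weights the noise-dominated high frequencies;
* the subpixel offset comes from the closed-form two-point fit of the
  sinc-shaped peak model, t = (r₊₁+r₋₁)/(r₊₁−r₋₁), with a parabolic
  vertex as fallback when that fit is degenerate;
* by default a second pass re-registers after Fourier-shifting the
  moving frame by the running estimate. This matters: windowing
  decorrelates the frames in proportion to the shift, which biases a
  single-pass estimate by up to ~0.04 px at 5 px shifts; the
  re-registration pass operates near zero shift where the bias vanishes,
  leaving a few millipixels of error on noiseless band-limited inputs.

Sign convention, fixed in one place: the returned (dy, dx) is the
translation of the moving frame's content relative to the reference
(row, column). In `track_stack`, positive 1-D displacement is the
contraction direction — the direction of the largest excursion from the
resting baseline. The projection axis is the principal axis (SVD) of
the 2-D shift cloud unless supplied in the config; recordings report
1-D deflection, but no axis is stored in the files.

Two tracking modes are provided: `frame_to_frame_cumulative` (default;
consecutive-pair shifts summed, appropriate because inter-frame
deformation during a contraction is minimal) and `fixed_reference`
(every frame against frame 0, immune to random-walk accumulation).
On noiseless rigid motion they agree to <0.01 px; under noise the
cumulative mode accumulates a slow random walk, which the per-beat
baseline subtraction in the force stage largely removes.

Pairs whose normalised peak falls below 0.1 are flagged low-confidence;
a run aborts when more than 20% of pairs are flagged.

`brute_force_shift` is the independent oracle used in tests: exhaustive
normalised cross-correlation over integer circular shifts, refined by a
closed-form 2-D quadratic fit on the 3×3 neighbourhood. It shares no
spectral code with the POC path.

## Calcium-transient features

Traces are normalised to ΔF/F₀: a linear drift line fitted through
inter-beat baseline points (lowest quartile of each pacing-period
chunk) is removed, F₀ is the 10th percentile of the detrended trace,
and the output is (F−F₀)/F₀. Pure intensity rescaling (gain) leaves
ΔF/F₀ and all features unchanged; an additive offset changes F₀ and
therefore the amplitude scale (the timing features remain invariant) —
this is inherent to ΔF/F₀ rather than an estimator property.

Beats are detected on a Savitzky–Golay-smoothed copy (window ≈50–70 ms,
order 2) with a minimum spacing of 0.7 pacing periods and a prominence
of half the global transient amplitude; windows are anchored to the
transient with a pre-onset margin of ~0.2 periods, and partial
first/last windows are discarded. A trace whose global amplitude is
below 5 noise SDs yields an explicit empty result.

Per-beat features:

* **baseline** — mean of the smoothed pre-onset segment. An order
  statistic (e.g. the within-window minimum) would be biased low by
  ~1.3 noise SDs; an unselected mean is not.
* **onset** — a line is fitted to the contiguous rising run between 5%
  and 25% of the amplitude and solved for the baseline crossing. The
  generator's quarter-sine rise is near-linear at low amplitude, so the
  back-extrapolation error is ≪1 sample.
* **amplitude** — maximum of the smoothed signal within ±2 samples of
  the detected peak, minus baseline.
* **peak time** — anchored on the decay branch: a log-linear fit to the
  samples between the 90% and 25% decay levels (with a delta-method
  correction, +σ²/2y², for the bias of log of a noisy value) is
  extrapolated back to the amplitude level. In the noiseless limit this
  is exactly the peak time; under noise it is fit-averaged and, unlike
  an argmax at the rise/decay kink, not systematically early (an argmax
  picks rise-side noise excursions, ≈1 sample early at 5% noise).
* **decay80** — first crossing of (baseline + 0.2·amplitude) after the
  peak, located by a short local line fit around the crossing sample
  (plain first-crossing of a noisy signal is one-sidedly early). For a
  pure exponential with rate λ this reproduces ln(5)/λ to within one
  sample across λ ∈ {2, …, 16} s⁻¹. The fitted exponential time
  constant 1/λ̂ is reported separately as `tau_exp_s`; "decay80" keeps
  the measured 80%-reduction definition and is the headline kinetic.

Beats that never reach the 80%-decay level inside their window, or that
have no identifiable rise, are flagged invalid and excluded from ROI
averages; ROI summaries average up to 10 consecutive valid beats and
record the count actually used.

At 5% noise with 10-beat averaging, the bias of each feature is <2% and
the RMSE <3% over 100 simulated ROIs (the acceptance script recomputes
these numbers).

## Synthetic data generator

The generator's purpose is verifiability: every recording ships with
exact ground truth.

Videos: a band-limited Gaussian random field (Gaussian filter, σ =
1.5 px, seeded) masked to a high-contrast disk on a darker background
is translated rigidly by δ(t)/pixel_scale along the displacement axis,
where δ(t) comes from the prescribed force waveform through the same
`PillarGeometry` compliance the analysis inverts. Translation uses
Fourier resampling so fractional shifts are rendered faithfully.
Per-beat force pulses are raised cosines (default width 0.4 s) at 1 Hz;
defaults are 50 frames/s, 3.79 μm/px, 192×192 px and 30 μN peaks
(≈100 μm plateau deflection, ≈26 px). Additive Gaussian noise and a
multiplicative per-frame brightness factor are applied after
translation; the brightness drift exists specifically to exercise POC's
gain invariance. Displacements beyond a quarter of the frame are
rejected rather than wrapped.

Traces: per-beat quarter-sine rise (zero slope at the peak, finite
slope at onset — chosen over a raised cosine so that the upstroke onset
is identifiable from the trace alone) to baseline+amplitude, then
exponential decay; beats superpose, with linear drift and Gaussian
noise on top. Defaults: 12 s at 100 Hz, baseline 100, amplitude 50
(ΔF/F₀ = 0.5), rise 0.15 s, λ = 8 s⁻¹ (decay80 ≈ 0.201 s), noise SD
2.5 (5% of amplitude), drift 0.5 intensity/s. A transient retaining
more than 5% of its amplitude at the next stimulus records an overlap
warning in the ground truth.

Cohorts: two-group collections draw an independent multiplicative scale
Normal(1, CV) per recording (default CV 10%, the assumed between-tissue
variability) on the group's headline magnitude, with sub-seeds derived
deterministically from the cohort seed. In the demo cohort the disease
group has half the peak force, 0.6× the Ca²⁺ amplitude, 0.75× the time
to peak and 1.5× the decay80 of control — the direction of effects seen
in failing-heart cardiomyocyte models (weaker contraction, smaller and
faster-rising-to-smaller-peak transients, slower reuptake).

What the generator does **not** emulate: optics (PSF, vignetting,
shot-noise statistics), tissue deformation other than rigid pillar-head
translation, multi-pillar scenes, beat-to-beat waveform variability
within a recording, or the noise character of any particular camera.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not instrument-specific performance on real
recordings.

## Statistics

`compare_groups` is the pooled-variance Student's t test (two-tailed),
matching the conventional wording of two-group comparisons in this
assay; Welch's correction is available via `welch=True` and is the
safer default when group variances differ — it is recommended for real
data. Zero-variance identical groups return p = 1 by convention,
flagged as degenerate. Summaries report mean ± SEM and box statistics
(25th/75th percentile box, min–max whiskers, median line). No
multiple-testing correction is applied by default; `holm_adjust` is
available. At α = 0.05 the empirical type-I error over 2,000 null
simulations (n = 5/group) is within 0.05 ± 0.02, and the power to
detect a 50% force reduction at n = 5 tissues per group with 10%
between-tissue CV is ≈1.0 (both recomputed by the acceptance script).

## Numerical and design choices

* Spectral floor 10⁻¹² (relative) in phase normalisation; correlation
  peak normalised so identical frames score 1 under the radial taper.
* POC refinement passes default to 2; pass counts >2 improve noiseless
  accuracy below 10⁻³ px but change nothing material under noise.
* Problem sizes in tests and the acceptance script (96–192 px frames,
  150–200 frames/video, 100 ROIs, 2,000 null simulations) were chosen
  as the smallest sizes at which the measured quantities are stable to
  well within their tolerance bands.
* Threshold crossings everywhere use linear interpolation between
  samples (or a local line fit under noise) for subsample timing.
* `beat_metrics` anchors the stimulus phase to the global force maximum
  (no stimulus log is assumed) and requires a per-window prominence of
  3× the diastolic noise SD, floored at 5% of the force span so that
  numerical ripple in a noiseless flat window can never count as a
  beat. Windows clipped by the recording edge still count when the beat
  peak itself is interior.
* Config files are strictly validated; unknown keys are an error.

## Known limitations

* The POC tracker estimates pure translation; rotation, scale change or
  non-rigid tissue deformation within the ROI is not modelled and will
  degrade (and flag) the correlation peak.
* Cumulative tracking accumulates a random walk on noisy recordings;
  prefer `fixed_reference` when a stable rest frame exists.
* decay80 requires the transient to complete 80% of its decay within
  the pacing window; strongly overlapping transients (slow reuptake at
  fast pacing) are flagged invalid per beat, and the generator warns at
  construction. The closed-form decay sweep is therefore validated on
  standalone single-beat windows.
* ΔF/F₀ amplitude is reported; raw-intensity amplitude depends on
  acquisition gain and background handling, which the trace files do
  not carry.
* E of PDMS is taken from the config, never estimated from calibration
  videos; errors in E scale force estimates linearly.
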
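# ehtkit

Video-based contractile-force analysis for engineered heart tissues
(EHTs) and calcium-transient kinetics for paced cardiomyocytes — the two
quantitative readouts of in vitro disease models of systolic
dysfunction (e.g. dilated cardiomyopathy iPSC-CM models).

An EHT is a strip of cardiomyocytes in a hydrogel suspended between two
elastic PDMS pillars. Every beat bends the pillars; recording the pillar
head with a microscope and tracking its motion therefore measures the
tissue's contractile force without touching it. Fluorescence recordings
of a calcium indicator under 1 Hz field stimulation provide the
complementary Ca²⁺-handling readout.

## What it computes

**Force pipeline (video → force).** Frame-to-frame pillar-head motion is
estimated by phase-only correlation (POC): the cross-power spectrum of
two frames is normalised to unit magnitude,
`R = F·conj(G)/|F·conj(G)|`, and the inverse transform peaks at the
inter-frame translation. Using phase alone makes the estimate robust to
brightness changes and sharp enough to localise shifts well below one
pixel (≲0.01 px here). The 2-D shifts are projected onto the deflection
axis, scaled by the pixel size (3.79 μm/px by default), and converted
to force with the cantilever-beam model

    δ = P L³ / (3 E I),   I = π d⁴ / 64   ⇒   P = k δ,  k = 3 E I / L³

with defaults L = 12 mm, E = 1.7 MPa (PDMS), d = 1.2 mm, giving
k ≈ 0.3004 N/m (about 0.30 μN per μm of deflection). Per-beat peaks,
their mean and the force at maximum pillar deflection are reported.

**Calcium pipeline (trace → features).** Each ROI trace is normalised to
ΔF/F₀, segmented into pacing windows, and each transient is reduced to
amplitude, time to peak (from the detected upstroke onset) and decay80 —
the time from the peak until the signal has fallen by 80% of its
amplitude (ln 5/λ for an exponential decay with rate λ). Features are
averaged over up to 10 beats per ROI.

**Statistics.** Two-group comparisons use unpaired two-tailed Student's
t tests (pooled variance; Welch optional); results are reported as
mean ± SEM with box summaries (25th/75th percentiles, min–max whiskers,
median).

**Synthetic data.** `ehtkit.synthetic` generates pillar-deflection
videos and paced fluorescence traces with exact ground truth, so every
stage of both pipelines is verifiable end to end without any external
recording.

## Worked example

```python
import ehtkit as ek
from ehtkit.pipeline import run_force_pipeline

# a 4 s, 1 Hz-paced synthetic recording with 30 uN beats
spec = ek.SyntheticVideoSpec(n_frames=200, peak_force_n=30e-6,
                             noise_sd=0.02, texture_seed=42)
stack, truth = ek.generate_pillar_video(spec)
ek.write_video(stack, "example_video.tiff")

cfg = ek.RunConfig(input_path="example_video.tiff", output_dir="example_run")
res = run_force_pipeline(cfg)
m = res["metrics"]
print("n_beats:", m.n_beats)
print(f"mean peak force: {m.mean_peak_force_n*1e6:.2f} uN")
print(f"max force:       {m.max_force_n*1e6:.2f} uN")
```

prints

```
n_beats: 4
mean peak force: 30.04 uN
max force:       30.08 uN
```

i.e. the four prescribed 30 μN beats are recovered to ~0.1%. The same
round trip for a noisy calcium trace (ΔF/F₀ amplitude 0.5, rise 0.15 s,
λ = 8 s⁻¹ so decay80 = 0.201 s):

```python
tr, _ = ek.generate_calcium_trace(
    ek.SyntheticTraceSpec(noise_sd=2.5, drift_slope=0.5, seed=42))
table, s = ek.analyze_trace(tr)
print(f"amplitude={s.amplitude:.3f} ttp={s.time_to_peak_s:.3f}s "
      f"decay80={s.decay80_s:.3f}s n={s.n_beats}")
# amplitude=0.492 ttp=0.152s decay80=0.196s n=10
```

A command-line interface mirrors the library
(`ehtkit simulate|track|force|calcium|compare|demo`); `ehtkit demo`
runs a full synthetic mutant-vs-rescue cohort through both pipelines
and the statistical report.

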
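# cachalot

Acoustic line-transect analysis of foraging sperm whales from a towed
hydrophone array: 3D localization of echolocating whales from the
surface-echo multipath of their clicks, dive-behaviour classification,
and depth-corrected distance-sampling density and abundance estimation —
with a synthetic survey simulator that provides ground truth for every
stage.

## Who this is for

Passive-acoustic-monitoring analysts who localize odontocetes from towed
linear arrays, and distance-sampling practitioners who need to correct
perpendicular distances for animal depth. The package re-implements a
complete survey analysis chain as tested, scriptable components, and
ships a simulator so every step can be validated against known truth.

## The analysis

A vessel tows a shallow hydrophone pair (5–10 m deep, ~300 m astern, at
16–20 km/h). Sperm whales echolocate almost continuously while foraging
(usual clicks, inter-click interval 0.2–2.0 s), so each whale yields a
long click train:

1. **Detection & 2D localization.** Audio is band-passed 2–20 kHz
   (4th-order Butterworth, zero-phase) and decimated to 96 kHz; clicks
   trigger at 12 dB above the running noise floor. Per-click conical
   bearings θ = arccos(cΔt/d) from the pair delay are intersected along
   the track by Nelder–Mead target motion analysis, giving each event a
   perpendicular **slant** range D, truncated at w = 6500 m.
2. **Click depth from the surface echo.** Each click also arrives via a
   surface reflection; the lag τ between the two (the *slant delay*) is
   measured on the envelope of the clip's autocorrelation, accepting the
   best peak with correlation ≥ 0.02 in the 0.0005–0.015 s window.
   Image-source geometry gives the closed form

   ```
   z = c·τ·(2D + c·τ) / (4h)
   ```

   with h the array depth. Depths > 4000 m are discarded as false
   echoes; events need ≥ 8 coherent delays, and event averages deeper
   than the seafloor are rejected.
3. **Dive behaviour.** Click-depth series with a descent, bottom phase
   and ascent lasting > 5 min are U-shaped dives, split at 800/1600 m by
   maximum depth; time-at-depth is tallied in 400-m bins and compared to
   the seafloor bin.
4. **Depth-corrected distance sampling.** The TMA slant range
   overestimates the horizontal distance of deep whales near the
   trackline, so distances are corrected to `sqrt(D² − z²)` (coerced to
   0 when z ≥ D) using the event's estimated depth, or the first
   quartile of the click-weighted average depths when no depth could be
   measured. Detection functions g(x) — uniform, half-normal
   `exp(−x²/2σ²)` or hazard-rate `1 − exp(−(x/σ)^−b)` keys with cosine,
   simple-polynomial or Hermite adjustments — are fit by maximum
   likelihood, selected by AIC with Kolmogorov–Smirnov and
   Cramér–von Mises GOF, and give the effective strip half-width
   ESW = ∫₀ʷ g. Density is `D̂ = n/(2·ESW·L)` and abundance `N̂ = D̂·A`,
   with a two-component CV (encounter rate across legs + ESW).

## Worked example

Run a 120-km synthetic survey at a true density of 0.03 whales/km²
(≈ 47 whales in the 2 × 6.5 km strip):

```python
from cachalot import pipeline

bundle = pipeline.run_pipeline({
    "seed": 7,
    "simulate": {"effort_length_km": 120.0, "whale_density_per_km2": 0.03,
                 "max_clips_per_event": 48},
    "distance": {"n_boot": 99},
})
print(bundle["funnel"])
print(bundle["abundance"][["n", "esw_m", "density_per_km2", "cv"]])
```

prints the event funnel and the estimate:

```
 detected  localized  converged  truncated  localized_3d
       49         49         48         48            47

 n  esw_m  density_per_km2       cv
48 6500.0         0.030769 0.160776
```

49 click-train events were detected, 48 survived bearing-convergence
review and the 6500-m truncation, and 47 yielded 3D localizations. The
fitted detection function is flat (the simulator detects every whale in
the strip, so the uniform key wins the AIC comparison with ESW = w =
6500 m), and the density estimate 0.0308 /km² (CV 16%) brackets the true
0.03 /km². Per-event depth summaries land within a few percent of truth
for most events, e.g.:

```
 event_id  n  avg_depth_m      sd_m  accepted
        0 24   953.778248 22.303247      True
        1 22   539.008486  5.974477      True
```

The same pipeline is scriptable from the shell:

```sh
cachalot all --config survey.yaml --seed 7 --outdir out/
```

writing `events.csv`, `depth_summaries.csv`, `classifications.csv`,
`distances.csv`, `model_comparison.csv`, `abundance.csv`, the funnel
table and a run log.

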
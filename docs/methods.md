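# Methods

This note documents the models, conventions and numerical choices behind
`cachalot`, and what the synthetic-data tests do and do not demonstrate
about real towed-array recordings.

## Coordinate and geometry conventions

Planar survey coordinates: `x` along the trackline (m), `y`
perpendicular and signed (m), `z` depth positive down with the sea
surface at `z = 0`. Real surveys work in geographic coordinates; at the
scale of a single transect the planar approximation is exact enough that
nothing in the analysis depends on it. The towed array is modeled as its
final hydrophone pair only (the elements actually used for the
measurements), at depth `h ∈ [5, 10] m` (default 7.5), `300 m` behind
the vessel, with configurable element spacing (default 0.25 m — the real
spacing is hardware-specific, and nothing downstream is sensitive to it
as long as bearings use the same value the simulator used).

## Multipath depth model

The sea surface is treated as a perfect mirror with reflection
coefficient −1. A click from `(x, y, z)` reaches the hydrophone directly
over length `D` and via the surface as if from an image hydrophone at
`−h`, so the echo lag is `τ = (‖image path‖ − D)/c` and

    (D + cτ)² − D² = 4zh   ⇒   z = c·τ·(2D + c·τ)/(4h).

This closed form is the exact inversion of the image-source forward
model (verified to 1e−6 relative over a 10⁴-point grid in the tests).
`D` is the *radial* distance from the hydrophone at each click time to
the event's fixed 2D solution — recomputed per click as the array moves.
Per-click variance propagates by the delta method
(`∂z/∂τ = c(D + cτ)/2h`, `∂z/∂D = cτ/2h`, `∂z/∂h = −z/h`), and the
event SD combines the between-click sample variance with the mean
propagated variance, both divided by the click count. The event average
is an unweighted mean of the accepted click depths. Click depths above
4000 m are treated as false echo detections and dropped; left/right
ambiguity of a linear array is unresolved, so perpendicular distances
are unsigned.

## Slant-delay measurement

The slant delay is read off the envelope of the clip's waveform
autocorrelation (magnitude of the analytic signal of the
autocorrelation), normalized so the zero-lag value is 1 — the surface
echo is phase-inverted, so it appears as a *negative* raw-correlation
peak that the envelope rectifies. The accepted measurement is the
highest envelope peak with correlation ≥ 0.02 in the lag window
0.0005–0.015 s; the lower bound keeps the search out of the direct
click's own correlation lobe. The integer-lag peak is refined to
sub-sample precision by a parabolic fit on the raw autocorrelation's
local trough (the known reflection phase selects the trough; without
that prior the refinement would be ambiguous by half a carrier period).
A clip shorter than the window after the click onset, or whose only
above-threshold structure lies below 0.0005 s (echo merged with the
click — shallow or very close whales), is rejected `outside_window`;
clips with no qualifying correlation are `below_threshold`.

Quality control stands in for the manual review of delay-vs-time plots:
accepted delays are smoothed with a centered rolling median (window 11
clicks), and points with residual above `3 × MAD` are re-flagged
(two passes, so clusters of false peaks fall out). Residual floors — a
few samples at 96 kHz, and 6% of the event's delay excursion — stop the
filter from eating exact-constant or steep-but-genuine trends. An event
enters depth analysis only if ≥ 8 accepted delays remain *and* the
surviving series is pattern-coherent (median absolute residual
≤ 0.2 ms). A whale's delay drifts slowly, so genuine series have
residuals of microseconds; series dominated by false peaks (no
detectable echo) have residuals of milliseconds, and the coherence gate
excludes them — the analogue of an event failing review for lack of
surface-reflected echoes.

The click detector uses a 1-ms RMS window (comparable to a click pulse)
against a noise floor tracked by an exponential moving average with a
1-s time constant, frozen while triggered; the 12 dB trigger and the
20 ms refractory period are configuration constants.

## Target motion analysis

Bearings are conical angles from the array axis,
`θ = arccos(cΔt/spacing)` (delays beyond endfire are clipped with a
warning). TMA minimizes the sum of squared bearing residuals over a
stationary surface source with Nelder–Mead (position tolerance 1e−3 m,
5 restarts: one from a first/last-bearing triangulation, the rest
perturbed). A solution counts as converged only if the optimizer
succeeded, the bearing residual RMS is ≤ 5°, and the bearing series
spans ≥ 10° — a near-constant series carries no crossing information.
The reported range error comes from the curvature of the residual
surface at the solution; it is a stand-in for whatever the original
tracking software reports and is not calibrated. Because conical
bearings encode the full 3D direction, the TMA distance of a deep whale
is a perpendicular *slant* range: a whale at 1000 m directly under the
track localizes ~1000 m off-track. The pipeline must exhibit this bias —
it is exactly what the Pythagorean depth correction removes.

## Dive classification

The published pattern assignment was manual; the automated stand-in
smooths the click depths with a rolling median (window 11) and requires,
for a U-shape, a net descent ≥ 200 m before the plateau, a plateau
(within 200 m of the maximum) lasting ≥ 2 min, a net ascent ≥ 200 m
after it, and > 5 min total duration. The 200-m excursion and 2-min
plateau thresholds are configurable; defaults were chosen to reproduce
textbook U-profiles and are symmetric under time reversal (descending ↔
ascending, U invariant). Depth classes split on the *raw* maximum click
depth at 800 and 1600 m (800 and 1600 themselves fall in the middle
class). Time-at-depth uses half-open 400-m bins `[lower, upper)`; each
inter-click interval ≤ 120 s is credited to the bin of its starting
click, longer gaps are discarded — a conservative attribution across
detection dropouts. The bottom-phase bin is the bin of the plateau's
median depth, reported in the conventional 400–800 / 800–1200 / >1200 m
groups. A whale is foraging in the water column when the upper edge of
its 90th-percentile depth bin sits more than 400 m above the lower edge
of the seafloor's bin; a percentile bin *below* the seafloor bin flags
an inconsistency (bad bathymetry or bad deep clicks).

## Distance sampling

Corrected distance: `sqrt(D² − z²)`, coerced to 0 when `z ≥ D`. Events
without an accepted depth use an assumed depth: a weighted quantile
(default Q1) or weighted mean of the event average depths, weights =
clicks with measured delay. Weighted quantiles interpolate the weighted
empirical CDF at plotting positions `p_i = (C_i − w_i)/(W − w_n)`, the
weighted analogue of type-7 interpolation (and identical to it for equal
weights).

The detection function is `g(x) = key(x)·[1 + Σ a_j p_j]` with keys
uniform / half-normal / hazard-rate and series adjustments cosine
`cos(jπx/w)`, simple polynomial `(x/w)^{2j}`, Hermite `H_{2j}(x/σ)`
(`x/w` for the uniform key). The likelihood of `f = g/∫₀ʷ g` is
maximized by Nelder–Mead over log-transformed scale/shape parameters
plus free adjustment coefficients; the normalizing integral uses
256-node Gauss–Legendre quadrature, negative `g` is clipped with a
quadratic penalty, and `ESW = ∫₀ʷ g / g(0)` (closed form
`σ√(π/2)·erf(w/σ√2)` for a bare half-normal). The candidate model space
is each key alone plus cosine {2}, {2,3}, simple polynomial {2}, {2,4}
and Hermite {4}; selection is lowest AIC among converged fits, ties to
fewer parameters. Monotonicity of `g` is checked and warned, not
enforced; a fit whose `g(0)` falls below its own maximum enough to push
ESW above `w` is not a usable detection function and is flagged
non-converged. GOF p-values come from a parametric bootstrap (simulate
from the fitted model by inverse-CDF on a 4096-point grid, refit the
same specification; 999 resamples by default, fewer in the pipeline
config where runtime matters). ESW standard errors use the delta method
on the observed information (numeric Hessian).

Density is `D̂ = n/(2·ESW·L)` with no group-size term (each event is one
foraging whale); `N̂ = D̂·A`. `CV²(D̂) = CV²(n/L) + CV²(ESW)` with the
standard R2-type encounter-rate variance across transect legs; a single
leg leaves that component undefined (flagged). Abundance intervals are
log-normal. Exact CV replication against any particular software run is
not claimed — variance-estimator choices differ between
implementations.

## The synthetic survey

The simulator emulates the study conditions: vessel at 18 km/h
(16–20 valid), array at 7.5 m depth and 300 m setback, sound speed
1500 m/s (validated against the plausible 1499–1543 m/s range), whales
Poisson-placed with uniform perpendicular distance out to 6500 m,
U-shaped dives with 1.2 m/s descent/ascent, bottom depths uniform in
400–1200 m (clipped 100 m above the seafloor), bottom durations 15–25
min, usual-click ICIs uniform in 0.2–2.0 s. Foraging whales cycle dive →
~9-min silent surface interval, and the dive nearest the vessel's
closest approach starts at a uniform random phase of that cycle, so most
whales are mid-click-train when the vessel passes — consistent with
animals that spend >70% of their time foraging. Clicks are Gabor
transients at 10 kHz (within the 5–15 kHz centroid band, envelope
τ = 0.1 ms) with a polarity-inverted, attenuated (0.3×) surface echo and
optional inter-pulse-interval second pulse; Gaussian noise is set so the
click peak is `snr_db` above the noise RMS, and in the pipeline the
per-click SNR falls off from its value at a 2-km reference range by
spherical spreading. One master seed drives everything; per-whale
substreams derive from (seed, whale id), so identical configurations are
byte-identical.

What the simulator does **not** model: refraction and multi-bounce
propagation, vessel noise, array movement from currents or waves, whale
horizontal movement within an event, coda/slow clicks, and group
structure. Passing the synthetic recovery tests therefore demonstrates
the correctness of the estimators under the stated geometry and noise
model, not robustness to every confound of real recordings — in
particular, real slant-delay measurement degrades with sea state and
off-axis multi-pulse clicks in ways the QC stand-in only approximates.

## Problem sizes and runtime choices

The test suite and the worked examples run surveys of tens of whales
with up to ~50 audio clips per event (events are down-sampled from the
full click trains, which can run to thousands of clicks, before audio
synthesis; truth bookkeeping uses the full trains). Simulation studies
use 50–200 replicates/events and GOF bootstraps of 9–99 resamples;
these sizes give stable pass/fail behaviour for the stated tolerances
while keeping a full run in tens of seconds. All of them are
configuration parameters, not limits of the implementation.

## Known limitations

- The TMA error estimate is a residual-curvature stand-in, not a
  calibrated confidence measure.
- Shallow whales (echo merged with the click) are systematically
  excluded from depth analysis, so event-depth distributions are
  truncated from below — the same selection the real analysis reports.
- The correlation threshold's normalization basis in the original
  tracking software is unknown; zero-lag normalization is assumed, and
  residual false peaks near the 0.02 threshold can survive QC in events
  that mix strong and merged echoes, biasing a minority of event depths
  high.
- No availability-bias or g(0) correction: estimates are of *foraging*
  (acoustically active) whales.
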
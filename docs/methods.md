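# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `echospace`. Everything quantitative stated here is
computed by the test suite or the examples; nothing is quoted from data the
package does not itself generate.

## Pose geometry

The egocentric frame comes from the marker triad alone: head aim
`ex = (P − midpoint(Q,R)) / |·|`, dorsal axis `ez ∝ (Q−P)×(R−P)`, and
`ey = ez×ex`. We define the aim as rear-midpoint → front-marker (the front
marker leads the head), so `ex` points where the bat faces, and label Q as
left-rear so `ez` points dorsally for an upright bat. Marker triads whose
rear baseline |QR| deviates from the nominal 21 mm by more than 1 mm are
rejected, mirroring the tracking-quality gate the error analysis assumes.
Missing-marker frames are dropped; position gaps of ≤3 frames (10 ms at
300 Hz) are linearly interpolated, longer gaps are left as gaps.

Two angle conventions are computed side by side: the arcsin-of-dot pair
(θ = arcsin(â·ex), φ = arcsin(â·ey)), under which a target dead ahead has
θ = 90°, and conventional azimuth/elevation (atan2, arcsin), under which it
has azimuth 0°. Downstream tuning uses the conventional pair; the identity
`offaxis = 90° − θ` is verified by test.

**Error analysis.** With both rear markers perturbed independently inside
radius-*r* spheres, the midpoint displacement never exceeds *r* (midpoint of
two radius-r balls lies in a radius-r ball); a 10⁵-draw Monte-Carlo verifies
the bound and approaches it within 1%. The angular head-aim bound is
arcsin(r/L) = 5.47° at r = 1 mm, L = 10.5 mm; the Monte-Carlo maximum over
10⁴ draws stays below it.

## Echo model

Ranges are measured to object *centers* (point-object approximation);
`point_object_time_error` quantifies the resulting timing error for the
finite cylinders (6.5 cm radius, 30 cm length) by analytic nearest-point
geometry (side / rim / cap), cross-checked against dense surface sampling.
Broadside at 2 m the error is 2·radius/c ≈ 0.38 ms; end-on it is larger.
The emission cone is a hard gate at half-angle 25° — half the 50° −6 dB
beam width at 30 kHz; no frequency-dependent beam model is attempted because
only that single width is available. The cone test is inclusive at the
boundary and implemented on cosines to avoid arccos round-off. Delay ties
between equidistant objects are broken by object id. The speed of sound
defaults to 343 m/s (room temperature) and is configurable. Echoes from
walls, cameras and microphones are not modelled; in the experimental
geometry they arrive last and the analysis uses first echoes only.
Propagation compensation (microphone time → source time) solves
`t = t_mic − |bat(t) − mic|/c` by fixed-point iteration (≤5 iterations,
1 µs tolerance) — a contraction for any flight speed far below c.

## Sonar sound groups

The detector scans left to right for maximal runs of internal PIs each
within 5% of the run mean, with both flanking PIs ≥ 1.2× the group mean PI
(for 2-call groups, the single internal PI). Flank comparison against the
adjacent internal PI instead of the group mean is available via
`flank_reference="adjacent"`; the group-mean reading is the default. A call
belongs to at most one group, and edge calls lacking a flank cannot be
members. Plan-projection stereotypy uses 10 cm × 10 cm occupancy histograms
("10 cm² bins" read as 10 cm squares) normalised to unit mass; similarity is
the peak 2D cross-correlation divided by the geometric mean of the two
autocorrelation peaks, which by Cauchy-Schwarz lies in [0, 1] with a unit
diagonal.

## Unit classification

Spikes are referenced to the nearest preceding first-echo arrival, nearest
preceding call, and nearest following call, keeping latencies within a
40 ms window; dispersion is the median absolute deviation (s.d. optional).
References sampled by fewer than ~10 spikes are marked unreliable (infinite
dispersion) rather than failing the unit. Labels: sensory if the echo
dispersion is less than 0.85× the best call dispersion; premotor for the
converse; sensorimotor if neither dominates but both are under 5 ms;
otherwise unclassified. The 0.85 ratio is a deliberate choice: for a
range-tuned unit the delays of its *responding* echoes vary little, so its
call-referenced latency spread exceeds its echo-referenced spread only
modestly, and a stricter ratio misroutes genuine sensory units with broad
latency jitter into the sensorimotor class. On planted populations (50
units per class, 1500 stimuli each) the confusion-matrix diagonal exceeds
0.9. Sensory units then pass a first-echo filter: the probability of a
response attributable *exclusively* to order-≥2 echoes must be below 0.1
and at least 3× smaller than the first-echo response probability — spikes
inside overlapping response windows are credited to the nearest preceding
echo and excluded from the later-echo count, since closely spaced echoes
are intrinsically unresolvable.

## Spatial tuning

Stimuli are discrete first echoes, so "time spent" occupancy is
operationalised as first-echo counts per bin (continuous dwell-time
normalisation would mis-weight a stimulus stream that only exists at call
times). Default bins: 10 cm over 0–4 m range, 10° over ±90° azimuth and
elevation. Bins whose event count falls more than one s.d. below the mean
per-bin count (over occupied bins) are excluded, as are empty bins; under
exactly uniform coverage nothing is masked. The Gaussian fit
(amplitude, mean, sigma, baseline; all bounded, least squares) requires ≥4
included bins; half-widths are reported only at R² ≥ 0.5. FWHM =
2√(2 ln 2)·σ. Session stability splits samples at the median emission time,
requires 3D selectivity in both halves (else indeterminate), and flags a
change when fitted means differ beyond the joint 95% CI from the fit
covariances.

For the SSG comparison, the per-condition samples are the ranges of
spike-eliciting first echoes. Brown-Forsythe is Levene's test with group
medians; "sharpening" requires both p < 0.05 and a smaller SSG dispersion,
"proximal shift" both rank-sum p < 0.05 and a nearer SSG median. Both the
Brown-Forsythe and rank-sum versions of the comparison are always reported.
The permutation power screen pools the two sets, reshuffles into the
original sizes 1000 times, and computes p = (1+k)/(R+1) for the observed
|statistic|; units enter the comparison only at p < 0.05. The rank-sum
variant exploits that pooled ranks are invariant under shuffling, reducing
each rep to a subset sum. Units are tested independently without
multiple-testing correction, matching per-unit reporting practice.

## Gamma LFP

Filters are second-order elliptic designs applied forward-backward, so the
effective response is the squared magnitude: zero phase (no latency bias,
verified by planted-burst recovery within ±2 ms) at the cost of doubled
ripple — hence the default 0.5 dB passband ripple (1.0 dB effective) and
40 dB stopband. Gamma RMS is the mean over per-window RMS values rather
than the RMS of the mean waveform, because bursts are amplitude-locked but
phase-random across trials and raw averaging cancels them; burst timing
instead uses the trial-averaged Hilbert envelope (5 ms moving-average
smoothed), jointly normalised across conditions, with the Gaussian-fit mean
as the peak latency. The artifact screen keeps channels with
10·log10(P(10–20 Hz)/P(gamma)) strictly below 6 dB.

## Synthetic sessions

The generator's defaults encode the experimental regime: 6×6×2.5 m room,
300 Hz marker frames, 21 mm rear baseline with the front marker 18.2 mm
ahead of the rear midpoint, flight speed 4 m/s with heading along velocity,
four upright cylinders (13 cm diameter, 30 cm long). Sessions consist of
ten 9 s flight trials; trials steer through straight approach runs at the
obstacles so that echoes actually populate the beam cone, mimicking the
task. Marker jitter is uniform in a 0.5 mm ball per marker, so the combined
rear-pair error respects the 1 mm error budget of the closed-form analysis
and reconstructed head aim stays within the 5.5° bound frame-wise (verified
per frame by test). Pulse intervals follow PI = 40 ms + 25 ms/m ×
nearest-object distance (clipped to 15–150 ms, 2% jitter), durations shrink
on approach, and SSGs are inserted at rate 0.18 per call with internal PIs
at 0.5× the local base PI — flanks therefore sit at ~2×, comfortably above
the 1.2× detection threshold, and roughly a third of calls end up in
groups, matching the roughly half-and-half SSG/non-SSG event split of
attentive flight.

Planted receptive fields default to σ = 0.15 m / 12° / 12° with peak
response probability 0.8 over a 0.02 baseline; SSG echoes see σ_range
scaled by 0.6 and the range center shifted 0.2 m closer. Spike latency is
truncated-normal (mean 5.9 ms, s.d. 3.4 ms, minimum 3 ms); session units
draw per-unit means from 4–9 ms and per-unit jitter s.d. from 1.2–3.8 ms,
spanning the sharp-to-broad population range. LFP is 1/f noise plus Gabor
bursts (95 Hz carrier, 10 ms envelope s.d., random phase) centered at a
configurable latency from each sensory spike, scaled 2× for SSG spikes,
with an optional 12 Hz wingbeat component for screening tests.

What the generator does *not* emulate: echo amplitudes and signal-to-noise
(responses depend only on geometry), atmospheric absorption and multipath,
call spectro-temporal structure, non-Gaussian or multi-lobed receptive
fields, spike-sorting contamination, and behavioral correlations between
flight kinematics and SSG production beyond the distance-PI law. Passing
tests therefore demonstrate that the *analysis chain* is correct and
calibrated — not that real collicular data would show these effects.

## Study sizes and calibration

Parameter-recovery checks use 500-echo samples over 100 seeds with stimuli
drawn from Gaussian spreads around the field (azimuth 0±18°, elevation
0±16°, range 1.3±0.35 m — the concentration repeated object approaches
produce); recovery accuracy is median |μ̂−μ| within half a bin and median
|σ̂/σ−1| within 20%. Statistical calibration uses 1000 null seeds per test
(ANOVA, Brown-Forsythe, rank-sum, permutation screen, across-unit
sign-rank), asserting type-I error within a ±3-standard-error band around
5%, and ≥80% Brown-Forsythe power at a planted 0.6 dispersion ratio with
200 samples per condition. Full sessions process end-to-end in seconds.

## Known limitations

* The point-object approximation is kept for ranges exactly as in the
  modelled experiment; the error calculator reports its size but nothing
  corrects for it.
* ANOVA on binary response flags is a large-sample approximation; bins with
  fewer than two events are excluded from the test.
* With few units, the across-unit sign-rank saturates (minimum two-sided
  p = 0.0625 at n = 5), so session-level gamma significance requires ≥6
  units with usable event counts.
* The classification thresholds (0.85 ratio, 5 ms floor, 30-spike minimum)
  are package choices exposed in configuration; no numeric criterion for
  "sharpest" exists to import.
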
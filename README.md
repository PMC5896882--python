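# echospace

Reconstruction of a free-flying echolocating bat's instantaneous 3D sensory
space, and analysis of how midbrain spatial tuning and gamma-band LFP change
with the bat's own sonar behavior.

Big brown bats (*Eptesicus fuscus*) perceive the world through the echoes of
their own calls. Given motion-capture tracking of a three-marker headstage,
the positions of obstacles in the flight room, and the time of each sonar
vocalization, the physics of sound fully determines *what the bat heard*:
which objects returned echoes, from which egocentric direction, and when.
`echospace` implements that reconstruction (the *echo model*) and the
neurophysiology built on top of it — 3D spatial receptive fields of superior
colliculus neurons and their modulation by *sonar sound groups* (SSGs), the
call clusters bats produce when closely inspecting objects. It is written
for auditory/active-sensing neurophysiologists and for anyone who needs a
tested, seeded reference implementation of this analysis chain.

## The model

**Egocentric frame.** From front marker P and rear markers Q, R (21 mm
apart), the head-aim unit vector runs from the rear midpoint to P; the
dorsal axis is the marker-plane normal `(Q−P)×(R−P)` normalised; the third
axis completes a right-handed frame. Marker error of radius *r* displaces
the rear midpoint by at most *r*, bounding the head-aim error by
`β = arcsin(r/L)` — 5.47° for r = 1 mm, L = 10.5 mm.

**Echo model.** An object at egocentric range *R* inside the emission cone
(half-angle 25°, half the 50° −6 dB beam width at 30 kHz) returns an echo at

    T_arr = 2R / c_air            (c_air = 343 m/s)

so the obstacles encountered at ~0.7–2 m map to 4–12 ms echo delays. Echoes
are ordered by delay; neural analyses use only the first-arriving echo of
each call, which makes responses attributable to a unique source.

**Sonar sound groups.** Two or more calls whose pulse intervals (PIs) are
each within 5% of the group mean, flanked on both sides by PIs at least
1.2× larger.

**Receptive fields.** Each first echo is one stimulus; a unit's response is
binary (≥1 spike 2–20 ms after echo arrival). Along range / azimuth /
elevation, spike counts per bin are divided by stimulus counts per bin
(occupancy normalisation), low-coverage bins are excluded, and a Gaussian
fit supplies the tuning mean, s.d. and half-width. Selectivity is a
per-dimension ANOVA at p < 0.05. SSG versus non-SSG range tuning is compared
by Brown-Forsythe (sharpening), Wilcoxon rank-sum (proximal shift), and a
1000-rep permutation screen that excludes under-powered units.

**Gamma LFP.** Second-order elliptic filters (zero-phase) isolate the
50–140 Hz gamma band; channels with 10–20 Hz / gamma power ratios ≥ 6 dB
(wingbeat artifact) are dropped; 100 ms spike-triggered gamma windows give
per-condition RMS power (sign-rank across units) and burst-peak latency via
a Gaussian fit to the averaged envelope.

A fully seeded synthetic-session generator (`echospace.simulate`) emulates
the experiment — spline flights in a 6×6×2.5 m room at 300 Hz, jittered
marker triads, distance-adaptive PIs with embedded SSGs, spikes from planted
3D Gaussian fields, LFP with spike-locked gamma bursts — so every stage is
testable against known ground truth.

## Worked example

`examples/03_receptive_field.py` plants a 3D Gaussian field (peak response
probability 0.8 at 1.3 m range, dead ahead, σ = 0.20 m / 15° / 15°), probes
it with 800 first echoes, and refits it:

```
800 first-echo stimuli, 146 evoked responses
3D selective (ANOVA p<0.05 on all axes): True
    range: mu   1.29 m  sigma  0.21  half-width  0.25  R2 0.93
  azimuth: mu   0.99 deg  sigma 13.43  half-width 15.81  R2 0.99
elevation: mu  -0.43 deg  sigma 12.33  half-width 14.52  R2 0.92
planted:   mu 1.30 m / 0 deg / 0 deg; sigma 0.20 m / 15 deg / 15 deg
```

The fitted centers land within a bin of the planted values and the widths
within ~20% — the pipeline's documented recovery accuracy at this sample
size. The other examples cover pose/echo geometry, SSG detection,
SSG-conditioned sharpening and shift statistics, gamma power and timing,
and the full session pipeline (`echospace run-all` from the shell does the
same). Each prints the numbers it computes and a line on what they mean.

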
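"""Spike-triggered gamma power and timing, by sound-group condition.

Synthesises an LFP channel with 1/f background plus gamma bursts locked to
spikes (twice the amplitude when the driving call was in an SSG), filters
the gamma band (50-140 Hz, zero-phase elliptic), and measures RMS power
and burst-peak latency per condition.  A second channel carries a strong
12 Hz wingbeat artifact and is rejected by the 6 dB screen.
"""

import numpy as np

from echospace.lfp import (filter_bands, gamma_peak_latency, noise_ratio_db,
                           spike_triggered_gamma)
from echospace.simulate import simulate_lfp

rng = np.random.default_rng(12)
spikes = np.sort(rng.uniform(1.0, 299.0, 200))
ssg = rng.uniform(size=200) < 0.5

ch = simulate_lfp(spikes, ssg, seed=13, fs=1000.0, t_stop=300.0,
                  ssg_gain=2.0, burst_latency=0.0, noise_amp=0.3)
gamma = filter_bands(ch)["gamma"]
gs = spike_triggered_gamma("unit0", spikes, ssg, gamma, fs=1000.0)
lat = gamma_peak_latency(gs)
print(f"spike-triggered gamma RMS: SSG {gs.rms['ssg']:.3f} "
      f"vs non-SSG {gs.rms['nonssg']:.3f} "
      f"(ratio {gs.rms['ssg'] / gs.rms['nonssg']:.2f})")
print(f"gamma peak latency: SSG {lat['ssg']:+.1f} ms, "
      f"non-SSG {lat['nonssg']:+.1f} ms (bursts planted at 0 ms)")

wing = simulate_lfp(spikes, ssg, seed=14, fs=1000.0, t_stop=300.0,
                    wingbeat_amp=8.0)
print(f"clean channel 10-20 Hz/gamma ratio: {noise_ratio_db(ch):+.1f} dB "
      f"(kept); wingbeat channel: {noise_ratio_db(wing):+.1f} dB (rejected)")
# Elevated gamma power around SSG spikes is the LFP signature of sonar
# inspection; the screen removes channels where movement artifact would
# masquerade as low-frequency power.
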
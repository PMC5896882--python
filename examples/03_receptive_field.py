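"""Recover a planted 3D receptive field from binary echo responses.

Draws 800 first-echo stimuli, generates spikes from a planted Gaussian
field (peak probability 0.8 at 1.3 m range, dead ahead), and fits the
occupancy-normalised tuning profiles along range, azimuth and elevation.
"""

from echospace.simulate import (PlantedRF, simulate_spikes,
                                synthetic_first_echoes)
from echospace.tuning import associate_spikes, fit_all_dimensions, is_selective_3d

rf = PlantedRF(mu_range=1.3, sigma_range=0.2, sigma_az=15, sigma_el=15)
echoes = synthetic_first_echoes(
    800, seed=5, gaussian=dict(azimuth=(0, 18), elevation=(0, 16),
                               range=(1.3, 0.35)))
spikes = simulate_spikes(echoes, rf, seed=6)
samples = associate_spikes(spikes, echoes)

print(f"{len(samples)} first-echo stimuli, "
      f"{samples['response'].sum()} evoked responses")
print("3D selective (ANOVA p<0.05 on all axes):", is_selective_3d(samples))

fits = fit_all_dimensions(samples)
units = dict(range="m", azimuth="deg", elevation="deg")
for dim, f in fits.items():
    print(f"{dim:>9}: mu {f.mu:6.2f} {units[dim]}  sigma {f.sigma:5.2f}"
          f"  half-width {f.half_width:5.2f}  R2 {f.r2:.2f}")
print(f"planted:   mu 1.30 m / 0 deg / 0 deg; "
      f"sigma 0.20 m / 15 deg / 15 deg")
# The fitted means land within a bin of the planted center and the widths
# within ~20%, which is the pipeline's documented recovery accuracy.
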
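import numpy as np
import pytest

from echospace.geometry import MarkerFrame, Pose, reconstruct_pose


def random_pose(rng) -> Pose:
    """A random valid pose built through the marker-triad reconstruction."""
    frame = random_marker_frame(rng)
    return reconstruct_pose(frame)


def random_marker_frame(rng, scale=0.02) -> MarkerFrame:
    while True:
        P, Q, R = rng.normal(size=(3, 3)) * scale + rng.uniform(-2, 2, 3)
        n = np.cross(Q - P, R - P)
        if np.linalg.norm(n) > 1e-6 * scale ** 2:
            return MarkerFrame(t=0.0, P=P, Q=Q, R=R)


def planted_samples(n, seed, rf=None, ssg_fraction=0.0, **box):
    """Stimulus samples for one planted unit via the full response chain.

    Draws first-echo stimuli, generates spikes from the planted receptive
    field, and binds them back into binary response samples with
    associate_spikes — the same route session data takes.
    """
    from echospace.simulate import PlantedRF, simulate_spikes, synthetic_first_echoes
    from echospace.tuning import associate_spikes
    rf = rf or PlantedRF()
    ech = synthetic_first_echoes(n, seed=seed, ssg_fraction=ssg_fraction, **box)
    ssg_by_voc = dict(zip(ech["voc_id"], ech["ssg"]))
    spikes = simulate_spikes(ech, rf, seed=seed + 1, ssg_by_voc=ssg_by_voc)
    return associate_spikes(spikes, ech, ssg_member=ssg_by_voc), rf


# study conditions for planted-field parameter recovery: the stimulus draw
# concentrates around the field the way repeated approaches do
RECOVERY_RF = dict(sigma_range=0.2, sigma_az=15.0, sigma_el=15.0)
RECOVERY_BOX = dict(gaussian=dict(azimuth=(0.0, 18.0), elevation=(0.0, 16.0),
                                  range=(1.3, 0.35)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_session():
    """One small synthetic session shared across integration tests."""
    from echospace.simulate import simulate_session
    return simulate_session(seed=7, n_trials=4, trial_duration=9.0,
                            n_sensory=3, n_premotor=1, n_sensorimotor=1,
                            n_unclassified=1, wingbeat_channels=1)
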
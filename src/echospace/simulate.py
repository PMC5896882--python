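"""Seeded synthetic sessions with known ground truth for every stage.

Emulates the experimental setting: a big brown bat flying smooth trial
trajectories inside a 6 x 6 x 2.5 m room past cylindrical obstacles,
carrying a three-marker headstage tracked at 300 Hz; distance-adaptive
pulse intervals with embedded sonar sound groups; collicular units whose
spiking follows planted 3D Gaussian receptive fields probed by the first-
arriving echo of each call; and LFP channels built from 1/f background plus
gamma bursts locked to sensory spikes (stronger during SSGs), optionally
contaminated by a 12 Hz wingbeat artifact.

Every generator is a pure function of (config, seed); the ground truth
needed to score each downstream stage is returned (and serialisable)
alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from . import echo_model, geometry
from .echo_model import SceneObject, Vocalization, compute_echoes
from .errors import ConfigError
from .lfp import LFPChannel

ROOM = (6.0, 6.0, 2.5)
FRAME_RATE = 300.0

# headstage geometry (meters), matching a 21 mm rear baseline with the front
# marker 18.2 mm ahead of the rear midpoint; centroid at the local origin
_MARKER_LOCAL = {
    "P": np.array([2 * 0.0182 / 3, 0.0, 0.0]),
    "Q": np.array([-0.0182 / 3, 0.0105, 0.0]),
    "R": np.array([-0.0182 / 3, -0.0105, 0.0]),
}


def default_scene(n_objects: int = 4, room=ROOM, rng=None) -> List[SceneObject]:
    """Cylindrical flight obstacles (13 cm diameter, 30 cm long, upright)."""
    rng = np.random.default_rng(rng)
    objs = []
    for k in range(n_objects):
        center = np.array([
            rng.uniform(1.5, room[0] - 1.5),
            rng.uniform(1.5, room[1] - 1.5),
            rng.uniform(0.8, room[2] - 0.8),
        ])
        objs.append(SceneObject(id=f"obj{k}", center=center, shape="cylinder",
                                radius=0.065, length=0.30, axis=(0, 0, 1)))
    return objs


# ---------------------------------------------------------------------------
# Flight and markers


def simulate_flight(room=ROOM, duration: float = 6.0, speed: float = 4.0,
                    seed=None, *, fs: float = FRAME_RATE,
                    jitter_mm: float = 0.5, t0: float = 0.0,
                    n_waypoints: Optional[int] = None, margin: float = 0.8,
                    waypoints=None):
    """One smooth flight: marker table at ``fs`` Hz plus true poses.

    The path is a cubic spline through random waypoints inside the room
    (kept ``margin`` m off the walls), traversed at approximately constant
    ``speed``.  The marker triad rides rigidly on the head with the aim axis
    along the velocity and the dorsal axis up; each marker is jittered
    isotropically within a ``jitter_mm`` radius ball.

    Returns ``(markers, truth)`` where ``markers`` is a DataFrame with
    columns t, Px..Rz and ``truth`` a dict of true origin/axis arrays.
    """
    if duration <= 0:
        raise ConfigError("duration must be positive")
    if speed <= 0 or speed > 12:
        raise ConfigError(f"infeasible flight speed {speed} m/s")
    rng = np.random.default_rng(seed)
    lo = np.array([margin, margin, margin])
    hi = np.array(room) - margin
    if waypoints is not None:
        way = np.asarray(waypoints, float)
    else:
        if n_waypoints is None:
            # enough waypoints (~2.2 m apart on average) to cover the flight
            n_waypoints = int(np.ceil(speed * duration / 2.2)) + 2
        n_way = max(int(n_waypoints), 3)
        way = rng.uniform(lo, hi, size=(n_way, 3))
    # arc-length parameterisation so the ground speed stays near `speed`
    seg = np.linalg.norm(np.diff(way, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    spline = CubicSpline(s, way, axis=0)
    total_len = speed * duration
    # rescale/extend the waypoint path to cover the requested distance
    s_grid = np.linspace(0, s[-1], 4096)
    d = np.linalg.norm(spline(s_grid, 1), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(0.5 * (d[1:] + d[:-1]) * np.diff(s_grid))])
    if arclen[-1] < total_len:
        total_len = arclen[-1]          # shorter flight rather than looping
    t = np.arange(0.0, duration, 1.0 / fs)
    target = np.linspace(0, total_len, len(t))
    s_of_t = np.interp(target, arclen, s_grid)
    pos = spline(s_of_t)
    vel = spline(s_of_t, 1) * np.gradient(s_of_t, t, edge_order=1)[:, None]

    ex = vel / np.maximum(np.linalg.norm(vel, axis=1, keepdims=True), 1e-12)
    up = np.array([0.0, 0.0, 1.0])
    ez = up - (ex @ up)[:, None] * ex
    ez /= np.linalg.norm(ez, axis=1, keepdims=True)
    ey = np.cross(ez, ex)

    jr = jitter_mm * 1e-3
    cols = {"t": t + t0}
    truth = dict(t=t + t0, origin=pos, ex=ex, ey=ey, ez=ez)
    for name, local in _MARKER_LOCAL.items():
        world = (pos + local[0] * ex + local[1] * ey + local[2] * ez)
        world = world + _ball_jitter(rng, len(t), jr)
        cols[f"{name}x"], cols[f"{name}y"], cols[f"{name}z"] = world.T
    return pd.DataFrame(cols), truth


def _ball_jitter(rng, n, radius):
    if radius <= 0:
        return np.zeros((n, 3))
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * radius * rng.uniform(size=(n, 1)) ** (1 / 3)


def _obstacle_course(scene: Sequence[SceneObject], rng, *, room=ROOM,
                     margin: float = 0.8, passes: int = 2,
                     offset: float = 0.35) -> np.ndarray:
    """Waypoints that repeatedly steer the flight toward scene objects.

    Flying from a random point toward a waypoint just beside an object puts
    the object inside the emission cone during the whole approach, mirroring
    how the bats interacted with the flight obstacles.
    """
    lo = np.array([margin] * 3)
    hi = np.array(room) - margin
    way = [rng.uniform(lo, hi)]
    order = list(rng.permutation(len(scene))) * passes
    for k in order:
        # straight approach run: collinear waypoints keep the heading on the
        # object from ~2.2 m down to the fly-by, then veer off sideways
        u = rng.normal(size=3)
        u[2] *= 0.7                     # approaches tilted toward horizontal
        u /= np.linalg.norm(u)
        side = np.cross(u, [0.0, 0.0, 1.0])
        side /= max(np.linalg.norm(side), 1e-9)
        c = scene[k].center
        for d in (2.2, 1.2, 0.5):
            way.append(np.clip(c + d * u, lo, hi))
        way.append(np.clip(c - 0.7 * u + offset * side, lo, hi))
    return np.asarray(way)


def synthetic_first_echoes(n: int, seed=None, *, az_range=(-60.0, 60.0),
                           el_range=(-50.0, 50.0), r_range=(0.3, 3.5),
                           spacing: float = 0.1, ssg_fraction: float = 0.0,
                           gaussian=None) -> pd.DataFrame:
    """Directly sampled first-echo stimulus table for unit-level studies.

    Bypasses flight and acoustics: draws ``n`` independent egocentric echo
    locations over the given azimuth/elevation/range box, with arrival times
    ``spacing`` s apart, and (optionally) a random SSG label per event.  By
    default the draw is uniform; passing ``gaussian`` as a dict of
    (center, sd) per dimension, e.g. ``dict(azimuth=(0, 18), elevation=(0,
    16), range=(1.3, 0.35))``, concentrates the stimuli the way repeated
    object approaches concentrate echoes around the encountered directions
    and distances (values are clipped to the box).  The columns match
    :func:`echospace.echo_model.compute_echoes` restricted to order-1 rows.
    """
    rng = np.random.default_rng(seed)
    t = spacing * np.arange(n)
    boxes = dict(azimuth=az_range, elevation=el_range, range=r_range)
    cols = {}
    for dim, box in boxes.items():
        if gaussian and dim in gaussian:
            mu, sd = gaussian[dim]
            cols[dim] = np.clip(rng.normal(mu, sd, n), *box)
        else:
            cols[dim] = rng.uniform(*box, n)
    df = pd.DataFrame(dict(
        voc_id=np.arange(n), t_emit=t,
        azimuth=cols["azimuth"], elevation=cols["elevation"],
        range=cols["range"], offaxis=np.zeros(n), order=np.ones(n, int)))
    df["t_arrival"] = df["t_emit"] + 2 * df["range"] / 343.0
    df["delay"] = df["t_arrival"] - df["t_emit"]
    df["ssg"] = rng.uniform(size=n) < ssg_fraction
    return df


# ---------------------------------------------------------------------------
# Calls with embedded sonar sound groups


@dataclass
class CallLaw:
    """Distance-adaptive vocal production law.

    Pulse interval grows linearly with nearest-object distance
    (``pi_base + pi_slope * d`` seconds, clipped), with multiplicative
    jitter; call duration shrinks on approach similarly.  SSGs are inserted
    with probability ``ssg_rate`` per call: 2-4 calls at a constant internal
    PI equal to ``ssg_ratio`` x the local base PI, so flanking intervals
    exceed the internal PI by ~1/ssg_ratio (comfortably above the 1.2x
    detection threshold).
    """

    pi_base: float = 0.040
    pi_slope: float = 0.025
    pi_min: float = 0.015
    pi_max: float = 0.150
    pi_jitter: float = 0.02
    dur_base: float = 0.0005
    dur_slope: float = 0.00075
    ssg_rate: float = 0.18
    ssg_ratio: float = 0.5
    ssg_sizes: tuple = (2, 3, 4)

    def pi(self, d: float) -> float:
        return float(np.clip(self.pi_base + self.pi_slope * d,
                             self.pi_min, self.pi_max))

    def duration(self, d: float) -> float:
        return self.dur_base + self.dur_slope * d


def simulate_calls(trajectory: geometry.Trajectory, scene: Sequence[SceneObject],
                   law: Optional[CallLaw] = None, seed=None, *,
                   t_start: Optional[float] = None,
                   t_stop: Optional[float] = None,
                   id_offset: int = 0) -> pd.DataFrame:
    """Vocalization table with distance-adaptive PIs and planted SSGs.

    Columns: voc_id, t_emit, duration, nearest_d, ssg_true (ground-truth
    sound-group membership), group_id (-1 outside groups).
    """
    law = law or CallLaw()
    rng = np.random.default_rng(seed)
    span = trajectory.span
    t0 = span[0] if t_start is None else t_start
    t1 = span[1] if t_stop is None else t_stop
    centers = np.array([o.center for o in scene])

    times, durs, flags = [], [], []
    t = t0 + law.pi(2.0) * rng.uniform(0.5, 1.0)
    pending_ssg = 0
    current_pi = None
    while t < t1:
        d = float(np.min(np.linalg.norm(centers - trajectory(t), axis=1)))
        times.append(t)
        durs.append(law.duration(d))
        base_pi = law.pi(d) * (1.0 + law.pi_jitter * rng.standard_normal())
        base_pi = max(base_pi, law.pi_min * 0.5)
        if pending_ssg > 0:
            flags.append(True)
            pending_ssg -= 1
            # constant internal PI inside the group, base-law PI as the
            # right flank (~2x the internal PI) after the last member
            t += current_pi if pending_ssg > 0 else law.pi(d)
            continue
        flags.append(False)
        if rng.uniform() < law.ssg_rate and len(times) >= 2:
            size = int(rng.choice(law.ssg_sizes))
            current_pi = law.ssg_ratio * law.pi(d)
            pending_ssg = size
            t += base_pi        # left flank before the group
        else:
            t += base_pi
    n = len(times)
    # a group's calls are the `size` calls following the flank call
    df = pd.DataFrame(dict(
        voc_id=np.arange(id_offset, id_offset + n),
        t_emit=np.asarray(times), duration=np.asarray(durs),
        nearest_d=[float(np.min(np.linalg.norm(centers - trajectory(tt), axis=1)))
                   for tt in times],
        ssg_true=np.asarray(flags, bool)))
    # drop trailing truncated groups (flank after group never emitted)
    if df["ssg_true"].iloc[-1:].any():
        last_false = np.flatnonzero(~df["ssg_true"].to_numpy())
        cut = last_false[-1] + 1 if len(last_false) else 0
        df = df.iloc[:cut].reset_index(drop=True)
    return df


def planted_ssg_sequence(n_calls: int = 120, seed=None, *,
                         pi_lo: float = 0.050, pi_hi: float = 0.100,
                         step: float = 0.02, internal_ratio: float = 0.5,
                         internal_jitter: float = 0.01,
                         ssg_rate: float = 0.12,
                         sizes=(2, 3, 4)):
    """A pure call-time sequence with planted sound groups and known truth.

    Base PIs follow a slowly drifting multiplicative random walk (+-``step``
    per call) inside [pi_lo, pi_hi]; inserted groups have internal PIs at
    ``internal_ratio`` x the local base PI (so flanks are ~1/internal_ratio
    times larger, a comfortable margin over the 1.2x rule) with
    ``internal_jitter`` relative scatter (well inside the 5% coherence rule).

    Returns ``(times, truth)``: call onset times and boolean ground-truth
    membership flags.
    """
    rng = np.random.default_rng(seed)
    times, flags = [0.0], [False]
    pi = rng.uniform(pi_lo, pi_hi)
    while len(times) < n_calls:
        pi = float(np.clip(pi * (1 + step * rng.uniform(-1, 1)), pi_lo, pi_hi))
        if rng.uniform() < ssg_rate and len(times) >= 2 and len(times) < n_calls - 5:
            size = int(rng.choice(sizes))
            internal = internal_ratio * pi
            times.append(times[-1] + pi)          # left flank interval
            flags.append(True)
            for _ in range(size - 1):
                times.append(times[-1] + internal
                             * (1 + internal_jitter * rng.uniform(-1, 1)))
                flags.append(True)
            times.append(times[-1] + pi)          # right flank interval
            flags.append(False)
        else:
            times.append(times[-1] + pi)
            flags.append(False)
    return np.asarray(times), np.asarray(flags, bool)


# ---------------------------------------------------------------------------
# Planted receptive fields and spikes


@dataclass
class PlantedRF:
    """Ground-truth 3D Gaussian receptive field of a synthetic unit.

    SSG-condition echoes see a sharpened (``ssg_sigma_ratio``) and
    proximally shifted (``ssg_mu_shift`` m) range tuning, mimicking the
    attention-linked modulation the pipeline is built to detect.
    """

    mu_az: float = 0.0
    mu_el: float = 0.0
    mu_range: float = 1.3
    sigma_az: float = 12.0
    sigma_el: float = 12.0
    sigma_range: float = 0.15
    peak_p: float = 0.8
    baseline_p: float = 0.02
    ssg_sigma_ratio: float = 0.6
    ssg_mu_shift: float = -0.2
    latency_mean: float = 0.0059
    latency_sd: float = 0.0034
    latency_min: float = 0.003

    def response_probability(self, az, el, rng_m, ssg=False) -> np.ndarray:
        mu_r = self.mu_range + (self.ssg_mu_shift if ssg else 0.0)
        s_r = self.sigma_range * (self.ssg_sigma_ratio if ssg else 1.0)
        z = (((np.asarray(az) - self.mu_az) / self.sigma_az) ** 2
             + ((np.asarray(el) - self.mu_el) / self.sigma_el) ** 2
             + ((np.asarray(rng_m) - mu_r) / s_r) ** 2)
        return self.baseline_p + self.peak_p * np.exp(-0.5 * z)


def _truncated_latency(rf: PlantedRF, size, rng) -> np.ndarray:
    a = (rf.latency_min - rf.latency_mean) / rf.latency_sd
    return stats.truncnorm.rvs(a, np.inf, loc=rf.latency_mean,
                               scale=rf.latency_sd, size=size, random_state=rng)


def simulate_spikes(echoes: pd.DataFrame, rf: PlantedRF, seed=None, *,
                    ssg_by_voc: Optional[Dict] = None) -> np.ndarray:
    """Sensory spike train from first-echo events and a planted RF.

    For each order-1 echo, a Bernoulli response with probability given by
    the planted Gaussian at the echo's egocentric location (SSG-conditioned
    parameters where the emitting call is in a sound group); spike time =
    echo arrival + truncated-normal latency (min 3 ms).
    """
    rng = np.random.default_rng(seed)
    first = echoes[echoes["order"] == 1]
    ssg = (first["voc_id"].map(ssg_by_voc).fillna(False).to_numpy(bool)
           if ssg_by_voc is not None else np.zeros(len(first), bool))
    p = np.where(ssg,
                 rf.response_probability(first["azimuth"], first["elevation"],
                                         first["range"], ssg=True),
                 rf.response_probability(first["azimuth"], first["elevation"],
                                         first["range"], ssg=False))
    fire = rng.uniform(size=len(first)) < p
    lat = _truncated_latency(rf, int(fire.sum()), rng)
    return np.sort(first["t_arrival"].to_numpy()[fire] + lat)


def simulate_premotor_spikes(call_times, seed=None, *, lead: float = 0.006,
                             jitter: float = 0.0008, p: float = 0.8) -> np.ndarray:
    """Vocal-premotor spikes: tightly locked just before each call onset."""
    rng = np.random.default_rng(seed)
    ct = np.asarray(call_times, float)
    fire = rng.uniform(size=len(ct)) < p
    t = ct[fire] - lead + jitter * rng.standard_normal(int(fire.sum()))
    return np.sort(t)


def simulate_sensorimotor_spikes(call_times, echo_arrivals, seed=None, *,
                                 call_lead: float = 0.0015,
                                 echo_lat: float = 0.0059,
                                 jitter: float = 0.0008,
                                 p_call: float = 0.6, p_echo: float = 0.6) -> np.ndarray:
    """Spikes locked to both call production and echo arrival."""
    rng = np.random.default_rng(seed)
    ct = np.asarray(call_times, float)
    ea = np.asarray(echo_arrivals, float)
    f1 = rng.uniform(size=len(ct)) < p_call
    f2 = rng.uniform(size=len(ea)) < p_echo
    t = np.concatenate([
        ct[f1] - call_lead + jitter * rng.standard_normal(int(f1.sum())),
        ea[f2] + echo_lat + jitter * rng.standard_normal(int(f2.sum())),
    ])
    return np.sort(t)


def simulate_poisson_spikes(t_start, t_stop, rate, seed=None) -> np.ndarray:
    """Homogeneous Poisson spikes (unclassified units)."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * (t_stop - t_start))
    return np.sort(rng.uniform(t_start, t_stop, n))


# ---------------------------------------------------------------------------
# LFP synthesis


def one_over_f_noise(n: int, fs: float, rng, *, amplitude: float = 1.0,
                     exponent: float = 1.0) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spec = (rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs)))
    with np.errstate(divide="ignore"):
        shape = np.where(freqs > 0, freqs ** (-exponent / 2.0), 0.0)
    x = np.fft.irfft(spec * shape, n)
    return amplitude * x / x.std()


def simulate_lfp(spike_times, ssg_flags, seed=None, *, fs: float = 1000.0,
                 t_start: float = 0.0, t_stop: Optional[float] = None,
                 burst_freq: float = 95.0, burst_sd: float = 0.010,
                 burst_amp: float = 1.0, ssg_gain: float = 2.0,
                 burst_latency: float = 0.0, noise_amp: float = 1.0,
                 wingbeat_amp: float = 0.0, wingbeat_freq: float = 12.0,
                 channel_id: str = "ch0") -> LFPChannel:
    """LFP channel: 1/f background + spike-locked gamma bursts (+ wingbeat).

    Each spike contributes a Gabor atom (``burst_freq`` Hz carrier, Gaussian
    envelope of sd ``burst_sd`` s, random phase) centered ``burst_latency``
    s after the spike; bursts for spikes whose call was inside a sound group
    are scaled by ``ssg_gain``.
    """
    st = np.asarray(spike_times, float)
    flags = np.asarray(ssg_flags, bool)
    if t_stop is None:
        t_stop = (st.max() if len(st) else t_start) + 0.5
    n = int(round((t_stop - t_start) * fs))
    rng = np.random.default_rng(seed)
    x = one_over_f_noise(n, fs, rng, amplitude=noise_amp)
    t = t_start + np.arange(n) / fs
    half = int(round(4 * burst_sd * fs))
    tau = np.arange(-half, half + 1) / fs
    for s_t, is_ssg in zip(st, flags):
        c = int(round((s_t + burst_latency - t_start) * fs))
        if c - half < 0 or c + half + 1 > n:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        amp = burst_amp * (ssg_gain if is_ssg else 1.0)
        x[c - half:c + half + 1] += amp * np.exp(-0.5 * (tau / burst_sd) ** 2) \
            * np.cos(2 * np.pi * burst_freq * tau + phase)
    if wingbeat_amp > 0:
        x += wingbeat_amp * np.sin(2 * np.pi * wingbeat_freq * t
                                   + rng.uniform(0, 2 * np.pi))
    return LFPChannel(channel_id=channel_id, fs=fs, samples=x, t0=t_start)


# ---------------------------------------------------------------------------
# Full sessions


@dataclass
class GroundTruth:
    """Everything needed to score a session's pipeline outputs."""

    seed: int
    rf_params: Dict[str, dict]
    unit_classes: Dict[str, str]
    ssg_by_voc: Dict[int, bool]
    gamma_ssg_gain: float
    gamma_burst_latency: float
    scene: List[dict]
    room: tuple = ROOM

    def to_json(self, path):
        d = asdict(self)
        d["ssg_by_voc"] = {str(k): bool(v) for k, v in self.ssg_by_voc.items()}
        Path(path).write_text(json.dumps(d, indent=1, default=_jsonify))


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))


@dataclass
class SyntheticSession:
    markers: pd.DataFrame
    poses: pd.DataFrame
    trials: List[pd.DataFrame]          # per-trial marker tables
    scene: List[SceneObject]
    calls: pd.DataFrame
    echoes: pd.DataFrame
    spikes: Dict[str, np.ndarray]
    lfp: Dict[str, LFPChannel]
    truth: GroundTruth


def simulate_session(seed: int = 0, *, n_trials: int = 10,
                     trial_duration: float = 9.0, trial_gap: float = 21.0,
                     n_objects: int = 4, n_sensory: int = 6,
                     n_premotor: int = 2, n_sensorimotor: int = 1,
                     n_unclassified: int = 1, law: Optional[CallLaw] = None,
                     lfp_fs: float = 1000.0, ssg_gain: float = 2.0,
                     burst_latency: float = 0.0,
                     wingbeat_channels: int = 1,
                     jitter_mm: float = 0.5) -> SyntheticSession:
    """Generate a complete session and its ground truth.

    The session is a set of ``n_trials`` independent smooth flights through
    a shared scene.  Calls follow the distance-adaptive law with planted
    SSGs; echoes are computed by the actual echo model from the actual
    reconstructed poses; unit spike trains follow their planted classes; one
    LFP channel per unit carries spike-locked gamma bursts (``ssg_gain``
    amplitude for SSG spikes), plus ``wingbeat_channels`` extra channels
    with a strong 12 Hz artifact for the screening stage.
    """
    root = np.random.default_rng(seed)
    scene = default_scene(n_objects, rng=root)
    trials = []
    t0 = 0.0
    for k in range(n_trials):
        mk, _ = simulate_flight(duration=trial_duration, t0=t0,
                                seed=root.integers(2 ** 31),
                                jitter_mm=jitter_mm,
                                waypoints=_obstacle_course(scene, root))
        trials.append(mk)
        t0 += trial_duration + trial_gap
    markers = pd.concat(trials, ignore_index=True)

    poses = geometry.poses_from_table(markers)
    traj_by_trial = []
    vocs: List[Vocalization] = []
    call_tables = []
    offset = 0
    pose_lookup_t = poses["t"].to_numpy()
    for mk in trials:
        tr_poses = poses[(poses["t"] >= mk["t"].iloc[0] - 1e-9)
                         & (poses["t"] <= mk["t"].iloc[-1] + 1e-9)]
        traj = geometry.Trajectory(tr_poses["t"].to_numpy(),
                                   tr_poses[["x", "y", "z"]].to_numpy())
        traj_by_trial.append(traj)
        calls = simulate_calls(traj, scene, law=law,
                               seed=root.integers(2 ** 31), id_offset=offset)
        offset += len(calls) + 1            # keep voc ids unique across trials
        call_tables.append(calls)
    calls = pd.concat(call_tables, ignore_index=True)

    # pose at each call time = nearest reconstructed frame
    idx = np.clip(np.searchsorted(pose_lookup_t, calls["t_emit"].to_numpy()),
                  1, len(pose_lookup_t) - 1)
    nearer = np.abs(pose_lookup_t[idx - 1] - calls["t_emit"].to_numpy()) \
        < np.abs(pose_lookup_t[idx] - calls["t_emit"].to_numpy())
    idx = np.where(nearer, idx - 1, idx)
    for row, pi_ in zip(calls.itertuples(index=False), idx):
        prec = poses.iloc[pi_]
        pose = geometry.pose_from_quaternion((prec.x, prec.y, prec.z),
                                             (prec.qx, prec.qy, prec.qz, prec.qw))
        vocs.append(Vocalization(id=int(row.voc_id), t_emit=float(row.t_emit),
                                 position=pose.origin, pose=pose,
                                 duration=float(row.duration)))
    echoes = compute_echoes(vocs, scene)

    ssg_by_voc = dict(zip(calls["voc_id"].astype(int), calls["ssg_true"]))
    first = echoes[echoes["order"] == 1]
    first_arrivals = first["t_arrival"].to_numpy()
    first_ssg = first["voc_id"].map(ssg_by_voc).fillna(False).to_numpy(bool)
    call_times = calls["t_emit"].to_numpy()

    spikes: Dict[str, np.ndarray] = {}
    rf_params: Dict[str, dict] = {}
    unit_classes: Dict[str, str] = {}
    for k in range(n_sensory):
        uid = f"sens{k}"
        # per-unit latency statistics span the observed population: means a
        # few ms past the 3 ms floor, jitter s.d. from ~1 ms up to ~4 ms
        rf = PlantedRF(mu_az=float(root.uniform(-12, 12)),
                       mu_el=float(root.uniform(-12, 12)),
                       mu_range=float(root.uniform(1.0, 1.8)),
                       latency_mean=float(root.uniform(0.004, 0.009)),
                       latency_sd=float(root.uniform(0.0012, 0.0038)))
        spikes[uid] = simulate_spikes(echoes, rf, seed=root.integers(2 ** 31),
                                      ssg_by_voc=ssg_by_voc)
        rf_params[uid] = asdict(rf)
        unit_classes[uid] = "sensory"
    for k in range(n_premotor):
        uid = f"pre{k}"
        spikes[uid] = simulate_premotor_spikes(call_times,
                                               seed=root.integers(2 ** 31))
        unit_classes[uid] = "premotor"
    for k in range(n_sensorimotor):
        uid = f"sm{k}"
        spikes[uid] = simulate_sensorimotor_spikes(
            call_times, first_arrivals, seed=root.integers(2 ** 31))
        unit_classes[uid] = "sensorimotor"
    for k in range(n_unclassified):
        uid = f"unc{k}"
        spikes[uid] = simulate_poisson_spikes(0.0, t0, rate=3.0,
                                              seed=root.integers(2 ** 31))
        unit_classes[uid] = "unclassified"

    lfp: Dict[str, LFPChannel] = {}
    t_stop = t0
    for uid, cls in unit_classes.items():
        if cls != "sensory":
            continue
        st = spikes[uid]
        sf = _spike_ssg_flags(st, first_arrivals, first_ssg)
        lfp[uid] = simulate_lfp(st, sf, seed=root.integers(2 ** 31), fs=lfp_fs,
                                t_start=0.0, t_stop=t_stop, ssg_gain=ssg_gain,
                                burst_latency=burst_latency,
                                channel_id=f"ch_{uid}")
    for k in range(wingbeat_channels):
        lfp[f"wing{k}"] = simulate_lfp(
            np.empty(0), np.empty(0, bool), seed=root.integers(2 ** 31),
            fs=lfp_fs, t_start=0.0, t_stop=t_stop, wingbeat_amp=8.0,
            channel_id=f"ch_wing{k}")

    truth = GroundTruth(seed=seed, rf_params=rf_params,
                        unit_classes=unit_classes, ssg_by_voc=ssg_by_voc,
                        gamma_ssg_gain=ssg_gain,
                        gamma_burst_latency=burst_latency,
                        scene=[dict(id=o.id, center=o.center.tolist(),
                                    shape=o.shape, radius=o.radius,
                                    length=o.length) for o in scene])
    return SyntheticSession(markers=markers, poses=poses, trials=trials,
                            scene=scene, calls=calls, echoes=echoes,
                            spikes=spikes, lfp=lfp, truth=truth)


def _spike_ssg_flags(spike_times, first_arrivals, first_ssg) -> np.ndarray:
    """SSG flag per spike: membership of the nearest preceding first echo."""
    idx = np.searchsorted(first_arrivals, spike_times, side="right") - 1
    idx = np.clip(idx, 0, len(first_arrivals) - 1)
    return np.asarray(first_ssg)[idx]
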
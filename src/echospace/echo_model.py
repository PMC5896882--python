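"""Acoustic echo model: which objects return echoes, when, and from where.

Each sonar vocalization ensonifies the objects inside the emission cone
(default half-angle 25 deg, i.e. half of the 50 deg -6 dB beam width of a big
brown bat call at 30 kHz).  For every ensonified object the model computes
the egocentric echo-source direction and the two-way travel time

    T_arr = 2 R / c_air,

with R the range to the object's center (point-object approximation) and
c_air the speed of sound (default 343 m/s).  Closed-form error analyses
quantify the two approximations involved: the angular head-aim error induced
by marker-tracking noise, and the timing error of treating finite cylinders
as point reflectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import geometry
from .errors import InsideObject, InvalidErrorModel, PropagationError, ZeroRange
from .geometry import Pose, Trajectory

#: Default speed of sound in air at room temperature (m/s).
SPEED_OF_SOUND = 343.0
#: Default emission-cone half angle (degrees): half the 50 deg -6 dB width.
BEAM_HALF_ANGLE = 25.0


@dataclass(frozen=True)
class SceneObject:
    """A reflecting object: a point, or an upright finite cylinder.

    ``center`` is in world coordinates (m).  Cylinders carry ``radius`` and
    ``length`` (m) and a unit ``axis`` vector.
    """

    id: str
    center: np.ndarray
    shape: str = "point"            # "point" | "cylinder"
    radius: float = 0.0
    length: float = 0.0
    axis: Optional[np.ndarray] = None

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        if self.shape == "cylinder":
            if self.radius <= 0 or self.length <= 0:
                raise ValueError("cylinder radius and length must be positive")
            ax = np.asarray(self.axis if self.axis is not None else (0, 0, 1.0), float)
            object.__setattr__(self, "axis", ax / np.linalg.norm(ax))


@dataclass(frozen=True)
class Vocalization:
    """A sonar call, timed at the source (propagation-compensated)."""

    id: int
    t_emit: float
    position: np.ndarray
    pose: Pose
    duration: float = float("nan")
    pi_prev: float = float("nan")
    pi_next: float = float("nan")

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, float))


@dataclass(frozen=True)
class EchoEvent:
    """One echo of one call from one object, in egocentric coordinates."""

    voc_id: int
    object_id: str
    t_emit: float
    t_arrival: float
    delay: float
    direction: geometry.EgoDirection
    offaxis: float
    order: int = 0


def compensate_propagation(t_mic: float, mic_position, trajectory: Trajectory,
                           c: float = SPEED_OF_SOUND, *, max_iter: int = 5,
                           tol: float = 1e-6) -> float:
    """Convert a microphone-referenced call time to the source time.

    Solves t = t_mic - |bat(t) - mic| / c by fixed-point iteration (the map
    is a contraction for any flight speed far below c).

    Raises :class:`PropagationError` if the iteration leaves the trajectory's
    time span or fails to reach ``tol`` seconds within ``max_iter`` steps.
    """
    mic = np.asarray(mic_position, float)
    t0, t1 = trajectory.span
    t = t_mic
    for _ in range(max_iter):
        if not (t0 <= t <= t1):
            raise PropagationError(
                f"t={t:.6f} s outside trajectory span [{t0:.6f}, {t1:.6f}]")
        pos = trajectory(t)
        if not np.isfinite(pos).all():
            raise PropagationError(f"trajectory gap at t={t:.6f} s")
        t_new = t_mic - float(np.linalg.norm(pos - mic)) / c
        if abs(t_new - t) < tol:
            return t_new
        t = t_new
    raise PropagationError(
        f"propagation compensation did not converge within {max_iter} iterations")


def ensonified_objects(voc: Vocalization, scene: Sequence[SceneObject],
                       half_angle: float = BEAM_HALF_ANGLE) -> list:
    """Ids of scene objects inside the emission cone, sorted by range.

    The cone test is inclusive: an object exactly at ``half_angle`` off axis
    is ensonified.
    """
    cos_gate = np.cos(np.radians(half_angle))
    hits = []
    for obj in scene:
        rel = obj.center - voc.pose.origin
        rng = np.linalg.norm(rel)
        if rng == 0.0:
            raise ZeroRange(f"object {obj.id} at call origin")
        # inclusive cone test on cosines (objects exactly on the boundary
        # count as ensonified, robust to arccos round-off)
        if rel @ voc.pose.ex / rng >= cos_gate - 1e-12:
            hits.append((rng, obj.id))
    hits.sort()
    return [oid for _, oid in hits]


def echo_arrival(voc: Vocalization, obj: SceneObject,
                 c: float = SPEED_OF_SOUND) -> EchoEvent:
    """Echo event for one (call, object) pair; range to the object center."""
    direction = geometry.direction_angles(obj.center, voc.pose)
    rel = obj.center - voc.pose.origin
    offax = float(np.degrees(np.arccos(
        np.clip(rel @ voc.pose.ex / direction.range, -1.0, 1.0))))
    delay = 2.0 * direction.range / c
    return EchoEvent(voc_id=voc.id, object_id=obj.id, t_emit=voc.t_emit,
                     t_arrival=voc.t_emit + delay, delay=delay,
                     direction=direction, offaxis=offax)


def assign_echo_order(events: Iterable[EchoEvent]) -> list:
    """Sort one call's echoes by delay (ties by object id) and set ``order``.

    Order 1 is the first-arriving echo.
    """
    ordered = sorted(events, key=lambda e: (e.delay, str(e.object_id)))
    return [EchoEvent(**{**e.__dict__, "order": k + 1}) for k, e in enumerate(ordered)]


def compute_echoes(vocs: Sequence[Vocalization], scene: Sequence[SceneObject],
                   c: float = SPEED_OF_SOUND,
                   half_angle: float = BEAM_HALF_ANGLE) -> pd.DataFrame:
    """Full echo table for a session: one row per (call, ensonified object).

    Columns: voc_id, object_id, t_emit, t_arrival, delay, azimuth, elevation,
    range, offaxis, order (1 = first echo of the call).
    """
    by_obj = {o.id: o for o in scene}
    rows = []
    for voc in vocs:
        ids = ensonified_objects(voc, scene, half_angle)
        events = assign_echo_order(echo_arrival(voc, by_obj[i], c) for i in ids)
        for e in events:
            rows.append(dict(voc_id=e.voc_id, object_id=e.object_id,
                             t_emit=e.t_emit, t_arrival=e.t_arrival, delay=e.delay,
                             azimuth=e.direction.azimuth,
                             elevation=e.direction.elevation,
                             range=e.direction.range, offaxis=e.offaxis,
                             order=e.order))
    return pd.DataFrame(rows, columns=["voc_id", "object_id", "t_emit", "t_arrival",
                                       "delay", "azimuth", "elevation", "range",
                                       "offaxis", "order"])


# ---------------------------------------------------------------------------
# Error analyses


@dataclass(frozen=True)
class ErrorModel:
    """Marker-tracking error geometry.

    ``r`` is the allowed marker position error radius and ``L`` the half
    distance between the two rear markers (both meters).  The maximal angular
    head-aim error induced by rear-midpoint displacement is arcsin(r/L).
    """

    r: float = 0.001
    L: float = 0.0105

    def __post_init__(self):
        if not (0 <= self.r < self.L):
            raise InvalidErrorModel(f"need 0 <= r < L, got r={self.r}, L={self.L}")


def headaim_error_bound(model: ErrorModel) -> float:
    """Closed-form maximum head-aim angular error, degrees: arcsin(r/L)."""
    return float(np.degrees(np.arcsin(model.r / model.L)))


def midpoint_error_check(r: float, L: float, n_samples: int = 100_000,
                         rng=None) -> float:
    """Monte-Carlo maximum displacement of the rear-pair midpoint.

    Perturbs both rear markers independently within radius-``r`` spheres and
    returns the largest midpoint displacement, which can never exceed ``r``
    (the midpoint of two radius-r balls lies in a radius-r ball).
    """
    rng = np.random.default_rng(rng)
    dq = _uniform_ball(rng, n_samples, r)
    dr = _uniform_ball(rng, n_samples, r)
    return float(np.linalg.norm((dq + dr) / 2.0, axis=1).max())


def headaim_error_monte_carlo(model: ErrorModel, n_samples: int = 10_000,
                              rng=None) -> float:
    """Monte-Carlo maximum head-aim angular error, degrees.

    Samples rear-midpoint displacements from the marker-error geometry and
    converts the component perpendicular to the baseline into an angular
    error arcsin(d_perp / L); the maximum approaches the closed-form bound
    arcsin(r/L) from below.
    """
    rng = np.random.default_rng(rng)
    dq = _uniform_ball(rng, n_samples, model.r)
    dr = _uniform_ball(rng, n_samples, model.r)
    dm = (dq + dr) / 2.0
    d_perp = np.linalg.norm(dm[:, 1:], axis=1)  # baseline along x
    ang = np.degrees(np.arcsin(np.clip(d_perp / model.L, 0.0, 1.0)))
    return float(ang.max())


def _uniform_ball(rng, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return radius * u * v


def nearest_cylinder_point(position, obj: SceneObject) -> np.ndarray:
    """Closest point on a finite cylinder's surface (side, cap, or rim).

    Raises :class:`InsideObject` for positions inside the cylinder.
    """
    if obj.shape != "cylinder":
        return obj.center.copy()
    p = np.asarray(position, float) - obj.center
    h = float(p @ obj.axis)                    # axial coordinate
    radial = p - h * obj.axis
    rho = float(np.linalg.norm(radial))
    half = obj.length / 2.0
    if abs(h) <= half and rho <= obj.radius:
        raise InsideObject("position inside cylinder")
    u = radial / rho if rho > 0 else _any_perpendicular(obj.axis)
    if abs(h) <= half:                          # side
        surf = np.clip(h, -half, half) * obj.axis + obj.radius * u
    elif rho <= obj.radius:                     # cap
        surf = np.sign(h) * half * obj.axis + rho * u
    else:                                       # rim
        surf = np.sign(h) * half * obj.axis + obj.radius * u
    return obj.center + surf


def _any_perpendicular(axis: np.ndarray) -> np.ndarray:
    v = np.array([1.0, 0, 0]) if abs(axis[0]) < 0.9 else np.array([0, 1.0, 0])
    v = v - (v @ axis) * axis
    return v / np.linalg.norm(v)


def point_object_time_error(bat_position, obj: SceneObject,
                            c: float = SPEED_OF_SOUND) -> float:
    """Echo-timing error (s) of the point-object approximation.

    Difference between the two-way travel time to the object's center and to
    the true nearest surface point.
    """
    pos = np.asarray(bat_position, float)
    d_center = float(np.linalg.norm(pos - obj.center))
    surf = nearest_cylinder_point(pos, obj)
    d_surf = float(np.linalg.norm(pos - surf))
    return abs(2.0 * d_center - 2.0 * d_surf) / c
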
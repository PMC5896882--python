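"""Head pose from a rigid marker triad and world <-> egocentric transforms.

A free-flying bat carries a lightweight headstage with three retro-reflective
markers tracked at 300 Hz: ``P`` at the front of the headstage and ``Q``/``R``
at the left/right trailing edge (nominal rear baseline |QR| = 21 mm).  The
instantaneous egocentric frame is built from the triad:

* ``ex`` — head-aim unit vector, from the midpoint of QR toward P;
* ``ez`` — dorsal axis, normal to the marker plane, (Q-P) x (R-P) normalised;
* ``ey`` — leftward axis, ez x ex (right-handed frame).

All directions of scene objects are then expressed in this frame, either as
conventional azimuth/elevation (atan2 / arcsin, 0 deg dead ahead) or as the
arcsin-of-dot-product angle pair used in some of the sonar literature, where
a target dead ahead sits at theta = 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import DegenerateMarkers, MissingMarker, ZeroRange

#: Nominal distance between the two rear markers (meters).
NOMINAL_BASELINE = 0.021
#: Allowed deviation of the measured rear baseline from nominal (meters).
BASELINE_TOLERANCE = 0.001


@dataclass(frozen=True)
class MarkerFrame:
    """One motion-capture frame of the three headstage markers.

    Parameters
    ----------
    t : float
        Frame time in seconds.
    P, Q, R : array-like of shape (3,)
        Marker positions in world coordinates, meters.  ``P`` is the front
        marker, ``Q`` the left-rear, ``R`` the right-rear.
    valid : tuple of bool
        Per-marker validity flags (False where the tracker lost the marker).
    """

    t: float
    P: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    valid: tuple = (True, True, True)

    def __post_init__(self):
        for name in ("P", "Q", "R"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def baseline_ok(self, nominal: float = NOMINAL_BASELINE,
                    tol: float = BASELINE_TOLERANCE) -> bool:
        """True when the rear baseline |QR| is within tolerance of nominal."""
        return abs(float(np.linalg.norm(self.Q - self.R)) - nominal) <= tol


@dataclass(frozen=True)
class Pose:
    """Instantaneous egocentric frame: origin plus orthonormal axes.

    ``origin`` is the marker centroid.  ``ex`` points along the head aim,
    ``ey`` to the animal's left, ``ez`` dorsally; the axes form a
    right-handed orthonormal basis (det = +1).
    """

    origin: np.ndarray
    ex: np.ndarray
    ey: np.ndarray
    ez: np.ndarray

    def __post_init__(self):
        for name in ("origin", "ex", "ey", "ez"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with the egocentric axes as rows (world -> ego)."""
        return np.vstack([self.ex, self.ey, self.ez])

    def as_quaternion(self) -> np.ndarray:
        """Unit quaternion (x, y, z, w) of the ego -> world rotation."""
        return Rotation.from_matrix(self.rotation.T).as_quat()

    @classmethod
    def identity(cls, origin=(0.0, 0.0, 0.0)) -> "Pose":
        return cls(np.asarray(origin, float),
                   np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))


@dataclass(frozen=True)
class EgoDirection:
    """Direction and range of a point in the egocentric frame.

    ``azimuth``/``elevation`` are the conventional spherical angles
    (atan2(y, x), arcsin(z/r); degrees).  ``theta`` and ``phi`` are the
    arcsin-of-dot-product pair (arcsin(a.ex), arcsin(a.ey)), under which a
    target dead ahead has theta = 90 deg.  ``range`` is the Euclidean
    distance in meters.
    """

    theta: float
    phi: float
    azimuth: float
    elevation: float
    range: float


def reconstruct_pose(frame: MarkerFrame, *, collinear_tol: float = 1e-9) -> Pose:
    """Reconstruct the egocentric frame from one marker triad.

    Raises
    ------
    MissingMarker
        If any of the three markers is flagged invalid or non-finite.
    DegenerateMarkers
        If the triad is (numerically) collinear, leaving the marker-plane
        normal undefined.
    """
    if not all(frame.valid):
        raise MissingMarker(f"frame t={frame.t}: marker flags {frame.valid}")
    P, Q, R = frame.P, frame.Q, frame.R
    if not np.isfinite([P, Q, R]).all():
        raise MissingMarker(f"frame t={frame.t}: non-finite marker coordinates")

    normal = np.cross(Q - P, R - P)
    scale = max(np.linalg.norm(Q - P) * np.linalg.norm(R - P), np.finfo(float).tiny)
    if np.linalg.norm(normal) <= collinear_tol * scale:
        raise DegenerateMarkers(f"frame t={frame.t}: collinear marker triad")

    mid = 0.5 * (Q + R)
    aim = P - mid
    ex = aim / np.linalg.norm(aim)
    ez = normal / np.linalg.norm(normal)
    # Markers are coplanar, so ez is already orthogonal to ex; re-orthogonalise
    # anyway to push round-off below the 1e-9 frame tolerance.
    ez = ez - (ez @ ex) * ex
    ez /= np.linalg.norm(ez)
    ey = np.cross(ez, ex)
    return Pose(origin=(P + Q + R) / 3.0, ex=ex, ey=ey, ez=ez)


def world_to_egocentric(point, pose: Pose) -> np.ndarray:
    """Express world-frame point(s) in the pose's egocentric frame.

    Accepts a single 3-vector or an (n, 3) array.
    """
    p = np.asarray(point, dtype=float)
    return (p - pose.origin) @ pose.rotation.T


def egocentric_to_world(point, pose: Pose) -> np.ndarray:
    """Inverse of :func:`world_to_egocentric`."""
    p = np.asarray(point, dtype=float)
    return p @ pose.rotation + pose.origin


def direction_angles(point_world, pose: Pose) -> EgoDirection:
    """Egocentric direction angles and range of a world-frame point.

    Raises :class:`ZeroRange` when the point coincides with the origin.
    """
    local = world_to_egocentric(point_world, pose)
    rng = float(np.linalg.norm(local))
    if rng == 0.0:
        raise ZeroRange("target at egocentric origin")
    a = local / rng
    return EgoDirection(
        theta=float(np.degrees(np.arcsin(np.clip(a[0], -1, 1)))),
        phi=float(np.degrees(np.arcsin(np.clip(a[1], -1, 1)))),
        azimuth=float(np.degrees(np.arctan2(local[1], local[0]))),
        elevation=float(np.degrees(np.arcsin(np.clip(a[2], -1, 1)))),
        range=rng,
    )


def offaxis_angle(point_world, pose: Pose) -> float:
    """Angle (degrees, in [0, 180]) between the head aim and the target.

    Equals 90 deg minus the arcsin-of-dot theta angle.
    """
    rel = np.asarray(point_world, float) - pose.origin
    rng = np.linalg.norm(rel)
    if rng == 0.0:
        raise ZeroRange("target at egocentric origin")
    return float(np.degrees(np.arccos(np.clip(rel @ pose.ex / rng, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Trajectory handling


@dataclass
class Trajectory:
    """Sampled 3D position track with linear interpolation between samples.

    Missing frames (NaN positions) are filled by linear interpolation when
    the gap is at most ``max_gap_frames`` samples; longer gaps remain NaN and
    querying inside them raises :class:`PropagationError` downstream.
    """

    t: np.ndarray
    xyz: np.ndarray
    max_gap_frames: int = 3
    _filled: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.xyz = np.asarray(self.xyz, float)
        self._filled = _fill_short_gaps(self.xyz, self.max_gap_frames)

    def __call__(self, t) -> np.ndarray:
        """Position(s) at time(s) ``t`` (linear interpolation)."""
        t = np.asarray(t, float)
        out = np.stack([np.interp(t, self.t, self._filled[:, k]) for k in range(3)],
                       axis=-1)
        return out

    @property
    def span(self) -> tuple:
        return float(self.t[0]), float(self.t[-1])


def _fill_short_gaps(xyz: np.ndarray, max_gap: int) -> np.ndarray:
    out = xyz.copy()
    bad = ~np.isfinite(xyz).all(axis=1)
    if not bad.any():
        return out
    idx = np.arange(len(xyz))
    # identify runs of consecutive bad frames
    starts = np.flatnonzero(bad & ~np.roll(bad, 1))
    if bad[0]:
        starts = np.unique(np.concatenate([[0], starts]))
    for s in starts:
        e = s
        while e < len(bad) and bad[e]:
            e += 1
        interior = s > 0 and e < len(bad)
        if interior and (e - s) <= max_gap:
            for k in range(3):
                out[s:e, k] = np.interp(idx[s:e], [s - 1, e], [xyz[s - 1, k], xyz[e, k]])
    return out


def poses_from_table(frames: pd.DataFrame, *, nominal: float = NOMINAL_BASELINE,
                     tol: float = BASELINE_TOLERANCE) -> pd.DataFrame:
    """Reconstruct poses for a motion-capture table.

    ``frames`` must have columns ``t, Px,Py,Pz, Qx,Qy,Qz, Rx,Ry,Rz`` (seconds
    and meters).  Frames whose rear baseline violates the 21 +/- 1 mm check,
    with missing markers, or with a degenerate triad are dropped.  Returns a
    table with the origin and the ego->world quaternion per retained frame.
    """
    rows = []
    for rec in frames.itertuples(index=False):
        f = MarkerFrame(
            t=rec.t,
            P=(rec.Px, rec.Py, rec.Pz),
            Q=(rec.Qx, rec.Qy, rec.Qz),
            R=(rec.Rx, rec.Ry, rec.Rz),
        )
        if not np.isfinite([f.P, f.Q, f.R]).all():
            continue
        if not f.baseline_ok(nominal, tol):
            continue
        try:
            pose = reconstruct_pose(f)
        except (MissingMarker, DegenerateMarkers):
            continue
        qx, qy, qz, qw = pose.as_quaternion()
        rows.append(dict(t=f.t, x=pose.origin[0], y=pose.origin[1], z=pose.origin[2],
                         qx=qx, qy=qy, qz=qz, qw=qw))
    return pd.DataFrame(rows, columns=["t", "x", "y", "z", "qx", "qy", "qz", "qw"])


def pose_from_quaternion(origin, quat) -> Pose:
    """Rebuild a :class:`Pose` from origin + (x, y, z, w) quaternion."""
    m = Rotation.from_quat(np.asarray(quat, float)).as_matrix()
    return Pose(origin=np.asarray(origin, float), ex=m[:, 0], ey=m[:, 1], ez=m[:, 2])
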
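"""Echo model: ensonification, arrival times, and the error analyses."""

import numpy as np
import pytest

from echospace import echo_model as em
from echospace.echo_model import (ErrorModel, SceneObject, Vocalization,
                                  assign_echo_order, compensate_propagation,
                                  echo_arrival, ensonified_objects,
                                  headaim_error_bound, midpoint_error_check,
                                  nearest_cylinder_point,
                                  point_object_time_error)
from echospace.errors import (InsideObject, InvalidErrorModel,
                              PropagationError)
from echospace.geometry import Pose, Trajectory

from conftest import random_pose

C = 343.0


def make_voc(origin=(0, 0, 0), ex=(1, 0, 0)):
    ex = np.asarray(ex, float) / np.linalg.norm(ex)
    up = np.array([0.0, 0, 1.0])
    ez = up - (up @ ex) * ex
    if np.linalg.norm(ez) < 1e-9:
        ez = np.array([1.0, 0, 0]) - ex[0] * ex
    ez /= np.linalg.norm(ez)
    ey = np.cross(ez, ex)
    pose = Pose(np.asarray(origin, float), ex, ey, ez)
    return Vocalization(id=0, t_emit=0.0, position=pose.origin, pose=pose)


class TestPropagationCompensation:
    def test_static_bat(self):
        traj = Trajectory(np.array([0.0, 2.0]), np.array([[1.0, 0, 0]] * 2))
        t = compensate_propagation(1.0, (0, 0, 0), traj, c=C)
        assert t == pytest.approx(1.0 - 1.0 / C, abs=1e-9)

    def test_bat_at_microphone(self):
        traj = Trajectory(np.array([0.0, 2.0]), np.zeros((2, 3)))
        assert compensate_propagation(1.0, (0, 0, 0), traj) == pytest.approx(1.0)

    def test_moving_bat_matches_dense_root_search(self):
        # linear flight at 4 m/s away from the mic
        t_grid = np.linspace(0, 2, 1201)
        xyz = np.stack([1.0 + 4.0 * t_grid, 0 * t_grid, 0 * t_grid], axis=1)
        traj = Trajectory(t_grid, xyz)
        mic = np.zeros(3)
        t_mic = 1.0
        t_est = compensate_propagation(t_mic, mic, traj, c=C)
        # brute-force root of t + |bat(t)|/c - t_mic on a fine grid
        tt = np.linspace(0.8, 1.0, 2_000_001)
        resid = tt + np.linalg.norm(traj(tt) - mic, axis=1) / C - t_mic
        t_oracle = tt[np.argmin(np.abs(resid))]
        assert abs(t_est - t_oracle) < 1e-6

    def test_outside_span_raises(self):
        traj = Trajectory(np.array([0.0, 0.5]), np.ones((2, 3)))
        with pytest.raises(PropagationError):
            compensate_propagation(3.0, (0, 0, 0), traj)


class TestEnsonification:
    def scene_at_angles(self, angles_deg, rng_m=2.0):
        objs = []
        for k, a in enumerate(angles_deg):
            a = np.radians(a)
            objs.append(SceneObject(id=f"o{k}",
                                    center=(rng_m * np.cos(a), rng_m * np.sin(a), 0)))
        return objs

    def test_threshold_cases(self):
        voc = make_voc()
        scene = self.scene_at_angles([20.0, 30.0])
        assert ensonified_objects(voc, scene) == ["o0"]

    def test_boundary_inclusive(self):
        voc = make_voc()
        scene = self.scene_at_angles([25.0])
        assert ensonified_objects(voc, scene, half_angle=25.0) == ["o0"]

    def test_sorted_by_range(self):
        voc = make_voc()
        scene = [SceneObject(id="far", center=(3, 0, 0)),
                 SceneObject(id="near", center=(1, 0, 0))]
        assert ensonified_objects(voc, scene) == ["near", "far"]

    def test_matches_brute_force_filter(self, rng):
        for _ in range(300):
            pose = random_pose(rng)
            voc = Vocalization(id=0, t_emit=0.0, position=pose.origin, pose=pose)
            scene = [SceneObject(id=f"o{k}", center=rng.uniform(-4, 4, 3))
                     for k in range(6)]
            got = set(ensonified_objects(voc, scene))
            expect = set()
            for o in scene:
                rel = o.center - pose.origin
                ang = np.degrees(np.arccos(np.clip(
                    rel @ pose.ex / np.linalg.norm(rel), -1, 1)))
                if ang <= 25.0:
                    expect.add(o.id)
            assert got == expect


class TestEchoArrival:
    def test_forced_arithmetic(self):
        voc = make_voc()
        e = echo_arrival(voc, SceneObject(id="o", center=(1.715, 0, 0)), c=C)
        assert e.delay == pytest.approx(0.010)
        assert e.t_arrival == pytest.approx(0.010)

    @pytest.mark.parametrize("range_m,delay_ms", [(2.00, 12), (0.70, 4)])
    def test_room_scale_delays_round_as_reported(self, range_m, delay_ms):
        voc = make_voc()
        e = echo_arrival(voc, SceneObject(id="o", center=(range_m, 0, 0)), c=C)
        assert round(e.delay * 1000) == delay_ms

    def test_delay_consistent_with_range_invariant(self, rng):
        voc = make_voc()
        for _ in range(100):
            c = rng.uniform(330, 350)
            obj = SceneObject(id="o", center=rng.uniform(0.2, 4, 3))
            e = echo_arrival(voc, obj, c=c)
            assert e.delay == pytest.approx(2 * e.direction.range / c, abs=1e-12)

    def test_scaling_speed_of_sound_scales_delays(self):
        voc = make_voc()
        obj = SceneObject(id="o", center=(1.3, 0.2, -0.1))
        d1 = echo_arrival(voc, obj, c=C).delay
        d2 = echo_arrival(voc, obj, c=2 * C).delay
        assert d2 == pytest.approx(d1 / 2)


class TestEchoOrder:
    def test_nearest_first(self):
        voc = make_voc()
        evs = [echo_arrival(voc, SceneObject(id="b", center=(2, 0, 0))),
               echo_arrival(voc, SceneObject(id="a", center=(1, 0, 0)))]
        ordered = assign_echo_order(evs)
        assert [e.object_id for e in ordered] == ["a", "b"]
        assert [e.order for e in ordered] == [1, 2]

    def test_equal_ranges_tie_broken_by_id(self):
        voc = make_voc()
        evs = [echo_arrival(voc, SceneObject(id="z", center=(1, 0, 0))),
               echo_arrival(voc, SceneObject(id="a", center=(0, 1, 0)))]
        ordered = assign_echo_order(evs)
        assert ordered[0].object_id == "a"

    def test_matches_sort_oracle(self, rng):
        voc = make_voc()
        for _ in range(200):
            scene = [SceneObject(id=f"o{k}", center=rng.uniform(-3, 3, 3))
                     for k in range(5)]
            evs = [echo_arrival(voc, o) for o in scene]
            ordered = assign_echo_order(evs)
            expect = sorted(evs, key=lambda e: (e.delay, e.object_id))
            assert [e.object_id for e in ordered] == [e.object_id for e in expect]


class TestHeadAimErrorBound:
    def test_headstage_geometry_bound(self):
        b = headaim_error_bound(ErrorModel(r=0.001, L=0.0105))
        assert b == pytest.approx(np.degrees(np.arcsin(1 / 10.5)))
        assert b == pytest.approx(5.47, abs=0.01)

    def test_zero_error(self):
        assert headaim_error_bound(ErrorModel(r=0.0, L=0.0105)) == 0.0

    def test_half_baseline_gives_30_degrees(self):
        assert headaim_error_bound(ErrorModel(r=0.5, L=1.0)) == pytest.approx(30.0)

    def test_r_at_least_L_rejected(self):
        with pytest.raises(InvalidErrorModel):
            ErrorModel(r=0.02, L=0.0105)


class TestMidpointError:
    def test_opposite_extremes_cancel(self):
        # midpoint of (+r, -r) displacements along one axis is unmoved
        dq = np.array([0.001, 0, 0])
        assert np.linalg.norm((dq + (-dq)) / 2) == 0.0

    def test_same_direction_extremes_reach_r(self):
        dq = np.array([0.001, 0, 0])
        assert np.linalg.norm((dq + dq) / 2) == pytest.approx(0.001)

    def test_monte_carlo_bounded_by_r(self):
        r = 0.001
        m = midpoint_error_check(r, 0.0105, n_samples=100_000, rng=3)
        assert m <= r
        assert m >= 0.97 * r   # supremum approached


class TestPointObjectApproximation:
    cyl = SceneObject(id="c", center=(0, 0, 0), shape="cylinder",
                      radius=0.065, length=0.30, axis=(0, 0, 1))

    def test_broadside_closed_form(self):
        # nearest point is on the side wall: error = 2*radius/c
        err = point_object_time_error((2.0, 0, 0), self.cyl, c=C)
        assert err == pytest.approx(2 * 0.065 / C, abs=1e-12)
        assert err == pytest.approx(0.379e-3, abs=1e-5)

    def test_point_limit_is_zero(self):
        pt = SceneObject(id="p", center=(0, 0, 0))
        assert point_object_time_error((2, 0, 0), pt) == 0.0

    def test_inside_raises(self):
        with pytest.raises(InsideObject):
            point_object_time_error((0.01, 0, 0.05), self.cyl)

    def test_nearest_point_matches_dense_surface_sampling(self, rng):
        # dense surface sampling oracle
        n_phi, n_z = 720, 241
        phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
        z = np.linspace(-0.15, 0.15, n_z)
        side = np.stack([0.065 * np.cos(phi)[:, None] + 0 * z,
                         0.065 * np.sin(phi)[:, None] + 0 * z,
                         0 * phi[:, None] + z], axis=-1).reshape(-1, 3)
        rr = np.linspace(0, 0.065, 80)
        caps = []
        for zc in (-0.15, 0.15):
            caps.append(np.stack([rr[:, None] * np.cos(phi),
                                  rr[:, None] * np.sin(phi),
                                  np.full((len(rr), n_phi), zc)],
                                 axis=-1).reshape(-1, 3))
        surface = np.vstack([side] + caps)
        for _ in range(200):
            pos = rng.uniform(-2, 2, 3)
            rho = np.hypot(pos[0], pos[1])
            if abs(pos[2]) <= 0.16 and rho <= 0.075:
                continue  # too close to (or inside) the cylinder
            near = nearest_cylinder_point(pos, self.cyl)
            d_analytic = np.linalg.norm(pos - near)
            d_oracle = np.linalg.norm(surface - pos, axis=1).min()
            assert abs(d_analytic - d_oracle) < 1e-4


def test_compute_echoes_reproducible(small_session):
    """Echo tables are bit-identical when recomputed from the same inputs."""
    from echospace.echo_model import compute_echoes
    from echospace.geometry import pose_from_quaternion
    poses = small_session.poses
    calls = small_session.calls
    t = poses["t"].to_numpy()
    idx = np.clip(np.searchsorted(t, calls["t_emit"].to_numpy()), 1, len(t) - 1)
    vocs = []
    for row, k in zip(calls.itertuples(index=False), idx):
        p = poses.iloc[k]
        pose = pose_from_quaternion((p.x, p.y, p.z), (p.qx, p.qy, p.qz, p.qw))
        vocs.append(Vocalization(id=int(row.voc_id), t_emit=float(row.t_emit),
                                 position=pose.origin, pose=pose))
    e1 = compute_echoes(vocs, small_session.scene)
    e2 = compute_echoes(vocs, small_session.scene)
    assert e1.equals(e2)
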
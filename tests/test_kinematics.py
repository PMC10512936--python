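"""Frame construction, Cardan decomposition, derivatives and norms."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitnorm import kinematics as kin
from gaitnorm.errors import DegenerateGeometryError, InputError
from gaitnorm.kinematics import MarkerTrajectory


def _static(label, p, T=4, rate=200.0):
    return MarkerTrajectory(label=label, positions=np.tile(p, (T, 1)), rate=rate)


def _foot_markers(T=4):
    return dict(
        heel=_static("heel", [0.0, 0.0, 0.0], T),
        mt1=_static("mt1", [0.05, 0.2, 0.0], T),
        mt5=_static("mt5", [-0.05, 0.2, 0.0], T),
        mml=_static("mml", [0.03, 0.05, 0.07], T),
        lml=_static("lml", [-0.03, 0.05, 0.07], T),
    )


class TestFootFrame:
    def test_printed_construction_by_hand(self):
        frame = kin.build_foot_frame(side="left", **_foot_markers())
        np.testing.assert_allclose(frame.origin[0], [0.0, 0.1, 0.0], atol=1e-12)
        np.testing.assert_allclose(frame.axes[0][:, 1], [0.0, 1.0, 0.0], atol=1e-12)
        # z up, x right for the left foot with MT1 medial (+x)
        np.testing.assert_allclose(frame.axes[0][:, 2], [0.0, 0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(frame.axes[0][:, 0], [1.0, 0.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("side", ["left", "right"])
    def test_orthonormal_right_handed(self, side, rng):
        m = _foot_markers()
        if side == "right":
            for tr in m.values():
                tr.positions[:, 0] *= -1
        frame = kin.build_foot_frame(side=side, **m)
        eye = np.swapaxes(frame.axes, 1, 2) @ frame.axes
        np.testing.assert_allclose(eye, np.tile(np.eye(3), (4, 1, 1)), atol=1e-9)
        np.testing.assert_allclose(np.linalg.det(frame.axes), 1.0, atol=1e-9)

    def test_rigid_rotation_equivariance(self, rng):
        m = _foot_markers()
        Q = Rotation.random(random_state=3).as_matrix()
        m_rot = {
            k: MarkerTrajectory(k, v.positions @ Q.T, v.rate) for k, v in m.items()
        }
        f0 = kin.build_foot_frame(side="left", **m)
        f1 = kin.build_foot_frame(side="left", **m_rot)
        np.testing.assert_allclose(f1.axes, Q @ f0.axes, atol=1e-9)

    def test_collinear_markers_rejected_with_sample(self):
        m = _foot_markers()
        m["mt5"] = _static("mt5", [0.025, 0.1, 0.0])  # on the heel-mt1 line
        with pytest.raises(DegenerateGeometryError, match="sample 0"):
            kin.build_foot_frame(side="left", **m)


class TestCardan:
    def test_identity_and_single_axis(self):
        a, b, c = kin.cardan_xyz(np.eye(3))
        assert (a, b, c) == (0.0, 0.0, 0.0)
        R = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        a, b, c = kin.cardan_xyz(R)
        np.testing.assert_allclose([a, b, c], [30.0, 0.0, 0.0], atol=1e-12)

    def test_compose_decompose_round_trip(self, rng):
        angles = np.column_stack(
            [
                rng.uniform(-170, 170, 50),
                rng.uniform(-84, 84, 50),
                rng.uniform(-170, 170, 50),
            ]
        )
        R = Rotation.from_euler("XYZ", angles, degrees=True).as_matrix()
        a, b, c = kin.cardan_xyz(R)
        np.testing.assert_allclose(
            np.column_stack([a, b, c]), angles, atol=1e-9
        )

    def test_matches_scipy_euler(self, rng):
        R = Rotation.random(20, random_state=9)
        ours = np.column_stack(kin.cardan_xyz(R.as_matrix()))
        theirs = R.as_euler("XYZ", degrees=True)
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_gimbal_proximity_flagged(self):
        R = Rotation.from_euler("XYZ", [25, 90, 0], degrees=True).as_matrix()
        a, b, c = kin.cardan_xyz(R)
        assert c == 0.0
        np.testing.assert_allclose(b, 90.0, atol=1e-6)

    def test_non_orthogonal_rejected(self):
        with pytest.raises(InputError):
            kin.cardan_xyz(np.eye(3) * 1.1)


class TestJointAngles:
    def _frames(self, axes, T=3):
        return kin.SegmentFrame(origin=np.zeros((T, 3)), axes=np.tile(axes, (T, 1, 1)))

    def test_identical_frames_zero(self):
        f = self._frames(np.eye(3))
        ja = kin.joint_angles(f, f, f, f)
        assert np.all(ja.as_array() == 0.0)

    @pytest.mark.parametrize(
        "joint,expected", [("hip", 10.0), ("knee", -10.0), ("ankle", 10.0)]
    )
    def test_single_axis_sign_convention(self, joint, expected):
        Rx10 = Rotation.from_euler("x", 10, degrees=True).as_matrix()
        eye = self._frames(np.eye(3))
        rot = self._frames(Rx10)
        frames = {"pelvis": eye, "thigh": eye, "shank": eye, "foot": eye}
        # rotate the distal frame of the joint under test
        distal = {"hip": "thigh", "knee": "shank", "ankle": "foot"}[joint]
        frames[distal] = rot
        ja = kin.joint_angles(frames["pelvis"], frames["thigh"], frames["shank"], frames["foot"])
        got = getattr(ja, joint)[0]
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestVirtualMarkerAndDerivatives:
    def test_virtual_marker_hand_case(self):
        m = dict(
            mt1=_static("mt1", [0.1, 0, 0]),
            mt5=_static("mt5", [-0.1, 0, 0]),
            mml=_static("mml", [0, 0.1, 0]),
            lml=_static("lml", [0, -0.1, 0]),
        )
        v = kin.virtual_foot_marker(**m)
        np.testing.assert_allclose(v.positions, 0.0, atol=1e-15)

    def test_virtual_marker_affine(self, rng):
        pts = {k: rng.normal(size=3) for k in ("mt1", "mt5", "mml", "lml")}
        shift = np.array([0.3, -0.2, 0.5])
        v0 = kin.virtual_foot_marker(**{k: _static(k, p) for k, p in pts.items()})
        v1 = kin.virtual_foot_marker(
            **{k: _static(k, p + shift) for k, p in pts.items()}
        )
        np.testing.assert_allclose(v1.positions - v0.positions, np.tile(shift, (4, 1)), atol=1e-12)

    def test_acceleration_exact_on_quadratic(self):
        rate = 200.0
        t = np.arange(50) / rate
        g = np.array([0.0, 0.0, -9.81])
        traj = MarkerTrajectory("p", 0.5 * np.outer(t**2, g), rate=rate)
        acc = kin.linear_acceleration(traj)
        np.testing.assert_allclose(acc.values[1:-1], np.tile(g, (48, 1)), atol=1e-8)
        assert not acc.valid[0] and not acc.valid[-1]

    def test_acceleration_sine_second_order(self):
        w = 2 * np.pi * 3.0
        errs = []
        for rate in (100.0, 200.0):
            t = np.arange(int(rate)) / rate
            p = np.column_stack([np.sin(w * t), np.zeros_like(t), np.zeros_like(t)])
            acc = kin.linear_acceleration(MarkerTrajectory("p", p, rate))
            expect = -(w**2) * p
            errs.append(np.abs(acc.values[1:-1] - expect[1:-1]).max())
        assert errs[1] < errs[0] / 3.0  # roughly O(rate^-2)

    def test_constant_position_zero_acceleration(self):
        acc = kin.linear_acceleration(_static("p", [1.0, 2.0, 3.0], T=10))
        np.testing.assert_allclose(acc.values, 0.0, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            kin.linear_acceleration(_static("p", [0, 0, 0], T=2))


class TestQuaternions:
    def test_identity_and_rz90(self):
        f = kin.SegmentFrame(origin=np.zeros((2, 3)), axes=np.tile(np.eye(3), (2, 1, 1)))
        q = kin.frame_quaternions(f)
        np.testing.assert_allclose(q.wxyz[0], [1, 0, 0, 0], atol=1e-12)
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        f = kin.SegmentFrame(origin=np.zeros((2, 3)), axes=np.tile(Rz, (2, 1, 1)))
        q = kin.frame_quaternions(f)
        s = np.sqrt(0.5)
        np.testing.assert_allclose(np.abs(q.wxyz[0]), [s, 0, 0, s], atol=1e-12)

    def test_round_trip_and_continuity(self, rng):
        # slow rotation about a fixed axis crossing the 180-degree boundary
        angles = np.linspace(0, 350, 100)[:, None]
        R = Rotation.from_euler("z", angles, degrees=True)
        f = kin.SegmentFrame(origin=np.zeros((100, 3)), axes=R.as_matrix())
        q = kin.frame_quaternions(f)
        dots = np.einsum("ij,ij->i", q.wxyz[1:], q.wxyz[:-1])
        assert np.all(dots >= 0)
        back = Rotation.from_quat(q.wxyz[:, [1, 2, 3, 0]]).as_matrix()
        np.testing.assert_allclose(back, f.axes, atol=1e-9)

    def test_angular_velocity_constant_rate(self):
        rate = 200.0
        omega_true = 4.0  # rad/s about z
        t = np.arange(200) / rate
        R = Rotation.from_rotvec(np.outer(omega_true * t, [0, 0, 1.0])).as_matrix()
        f = kin.SegmentFrame(origin=np.zeros((200, 3)), axes=R)
        om = kin.angular_velocity(kin.frame_quaternions(f), rate)
        norms = kin.norm_series(om)[1:-1]
        np.testing.assert_allclose(norms, omega_true, rtol=1e-3)

    def test_angular_velocity_static_zero(self):
        f = kin.SegmentFrame(origin=np.zeros((5, 3)), axes=np.tile(np.eye(3), (5, 1, 1)))
        om = kin.angular_velocity(kin.frame_quaternions(f), 200.0)
        np.testing.assert_allclose(om.values, 0.0, atol=1e-12)

    def test_norm_invariant_under_fixed_premultiplication(self, rng):
        rate = 200.0
        t = np.arange(100) / rate
        R = Rotation.from_rotvec(np.outer(3.0 * t, [0.3, 0.5, 0.81])).as_matrix()
        Q = Rotation.random(random_state=12).as_matrix()
        f0 = kin.SegmentFrame(origin=np.zeros((100, 3)), axes=R)
        f1 = kin.SegmentFrame(origin=np.zeros((100, 3)), axes=Q @ R)
        n0 = kin.norm_series(kin.angular_velocity(kin.frame_quaternions(f0), rate))
        n1 = kin.norm_series(kin.angular_velocity(kin.frame_quaternions(f1), rate))
        np.testing.assert_allclose(n0[1:-1], n1[1:-1], atol=1e-9)


def test_norm_series_isometry(rng):
    v = kin.VectorSeries(values=rng.normal(size=(30, 3)), units="m/s^2")
    Q = Rotation.random(random_state=7).as_matrix()
    vq = kin.VectorSeries(values=v.values @ Q.T, units="m/s^2")
    np.testing.assert_allclose(kin.norm_series(v), kin.norm_series(vq), atol=1e-12)
    np.testing.assert_allclose(
        kin.norm_series(kin.VectorSeries(values=np.array([[3.0, 4.0, 0.0]]), units="")),
        [5.0],
    )
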
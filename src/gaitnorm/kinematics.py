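"""Segment frames, Cardan joint angles, and foot acceleration / angular velocity.

All positions are lab-frame metres.  Segment frames carry per-sample origins
and right-handed orthonormal axes stored column-wise as (x, y, z) =
(right/left, anterior/posterior, superior/inferior).  The sagittal joint
angle is the first rotation of an x-y-z Cardan decomposition of the
proximal-to-distal relative rotation, with hip/knee flexion and ankle
dorsiflexion mapped positive.

The foot frame follows the explicit heel / metatarsal construction:
origin at the midpoint of the heel marker and the MT1-MT5 midpoint, the
anterior axis from the heel to that midpoint, and the vertical axis from the
cross product of the heel-to-MT1 vector with the anterior axis (order
mirrored on the right side so the frame stays right-handed with x pointing
to the subject's right).

Derivatives use central differences; the first and last samples of any
differentiated series are flagged invalid and must not enter a gait cycle.
Angular velocity comes from quaternion central differences,
``omega = 2 * vec(dq * conj(q))``; only its Euclidean norm is consumed
downstream, which makes the whole feature set invariant to any fixed rigid
rotation of the marker cloud (the property that motivates using norms
instead of axis-resolved signals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from gaitnorm.errors import DegenerateGeometryError, InputError

_DEGENERACY_TOL = 1e-10
_GIMBAL_TOL = 1e-8

JOINTS = ("hip", "knee", "ankle")

#: sagittal sign map: +1 keeps the raw Cardan alpha, -1 flips it so that
#: flexion (hip, knee) and dorsiflexion (ankle) are positive.
SAGITTAL_SIGNS = {"hip": +1.0, "knee": -1.0, "ankle": +1.0}


@dataclass
class MarkerTrajectory:
    """A labelled 3-D landmark time series in lab-frame metres."""

    label: str
    positions: np.ndarray  # (T, 3)
    rate: float  # Hz

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise InputError(f"{self.label}: positions must be (T, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise InputError(f"{self.label}: non-finite positions")
        if self.rate <= 0:
            raise InputError(f"{self.label}: rate must be positive")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class SegmentFrame:
    """Per-sample origin and right-handed orthonormal axes of a body segment.

    ``axes[i]`` is a 3x3 matrix whose *columns* are the segment's x, y, z
    axes expressed in the lab frame; it equals the rotation matrix taking
    segment coordinates to lab coordinates.
    """

    origin: np.ndarray  # (T, 3)
    axes: np.ndarray  # (T, 3, 3)

    def __len__(self) -> int:
        return self.origin.shape[0]


@dataclass
class QuaternionSeries:
    """Unit quaternions (w, x, y, z), sign-continuous along the series."""

    wxyz: np.ndarray  # (T, 4)

    def __len__(self) -> int:
        return self.wxyz.shape[0]


@dataclass
class JointAngleSeries:
    """Hip/knee/ankle sagittal angles in degrees, flexion/dorsiflexion positive."""

    hip: np.ndarray
    knee: np.ndarray
    ankle: np.ndarray
    rate: float = 0.0

    def as_array(self) -> np.ndarray:
        """Stack as (T, 3) in hip, knee, ankle order."""
        return np.column_stack([self.hip, self.knee, self.ankle])


@dataclass
class VectorSeries:
    """A T x 3 vector time series with a per-sample validity mask."""

    values: np.ndarray  # (T, 3)
    units: str
    valid: np.ndarray = field(default=None)  # (T,) bool

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.values.shape[0], dtype=bool)


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    bad = np.nonzero(n[..., 0] < _DEGENERACY_TOL)[0]
    if bad.size:
        raise DegenerateGeometryError(f"{what}: zero-length vector at sample {bad[0]}")
    return v / n


def _check_shared(trajs: list[MarkerTrajectory]) -> None:
    t0, r0 = len(trajs[0]), trajs[0].rate
    for tr in trajs[1:]:
        if len(tr) != t0 or tr.rate != r0:
            raise InputError("marker trajectories must share length and rate")


def build_foot_frame(
    heel: MarkerTrajectory,
    mt1: MarkerTrajectory,
    mt5: MarkerTrajectory,
    mml: MarkerTrajectory,
    lml: MarkerTrajectory,
    side: str,
) -> SegmentFrame:
    """Foot segment frame from the five foot landmarks.

    Origin: midpoint of the heel and the MT1-MT5 midpoint.
    y (anterior): heel -> MT1-MT5 midpoint.
    z (superior): (heel->MT1) x y on the left; the cross order is mirrored on
    the right so z points up and the frame stays right-handed.
    x: y x z.

    Raises :class:`DegenerateGeometryError` naming the first sample where
    heel, MT1 and MT5 are collinear.
    """
    if side not in ("left", "right"):
        raise InputError(f"side must be 'left' or 'right', got {side!r}")
    _check_shared([heel, mt1, mt5, mml, lml])
    mt_mid = 0.5 * (mt1.positions + mt5.positions)
    origin = 0.5 * (heel.positions + mt_mid)
    y = _unit(mt_mid - heel.positions, "foot frame y-axis")
    v = mt1.positions - heel.positions
    z_raw = np.cross(v, y) if side == "left" else np.cross(y, v)
    nz = np.linalg.norm(z_raw, axis=1)
    bad = np.nonzero(nz < _DEGENERACY_TOL)[0]
    if bad.size:
        raise DegenerateGeometryError(
            f"collinear heel/MT1/MT5 at sample {bad[0]} ({side} foot)"
        )
    z = z_raw / nz[:, None]
    x = np.cross(y, z)
    axes = np.stack([x, y, z], axis=-1)
    return SegmentFrame(origin=origin, axes=axes)


def build_segment_frame(
    origin_lm: MarkerTrajectory,
    distal_lm: MarkerTrajectory,
    lateral_lm: MarkerTrajectory,
    side: str = "right",
) -> SegmentFrame:
    """Minimal three-landmark frame for pelvis, thigh or shank.

    z (long axis) points from the distal landmark to the origin landmark;
    y completes z x (origin->lateral); x = y x z.  The lateral landmark only
    fixes the sagittal plane, so any marker off the long axis works.  On a
    left-side segment the lateral landmark sits on the subject's left (-x),
    so the plane vector is negated to keep x pointing right in every frame.
    """
    _check_shared([origin_lm, distal_lm, lateral_lm])
    z = _unit(origin_lm.positions - distal_lm.positions, "segment long axis")
    v = lateral_lm.positions - origin_lm.positions
    if side == "left":
        v = -v
    y_raw = np.cross(z, v)
    ny = np.linalg.norm(y_raw, axis=1)
    bad = np.nonzero(ny < _DEGENERACY_TOL)[0]
    if bad.size:
        raise DegenerateGeometryError(
            f"collinear segment landmarks at sample {bad[0]}"
        )
    y = y_raw / ny[:, None]
    x = np.cross(y, z)
    axes = np.stack([x, y, z], axis=-1)
    return SegmentFrame(origin=origin_lm.positions.copy(), axes=axes)


def build_proximal_frames(
    markers: dict[str, MarkerTrajectory], side: str
) -> dict[str, SegmentFrame]:
    """Pelvis/thigh/shank frames from the generator's landmark triads.

    Expects labels ``PELVIS_O/D/L`` and ``{L|R}_{THIGH,SHANK}_O/D/L``.
    Precomputed :class:`SegmentFrame` objects stored under the segment name
    pass through unchanged.
    """
    p = "L" if side == "left" else "R"
    out: dict[str, SegmentFrame] = {}
    for seg, stem, seg_side in (
        ("pelvis", "PELVIS", "right"),  # the pelvis lateral landmark is on the right
        ("thigh", f"{p}_THIGH", side),
        ("shank", f"{p}_SHANK", side),
    ):
        if seg in markers and isinstance(markers[seg], SegmentFrame):
            out[seg] = markers[seg]
            continue
        out[seg] = build_segment_frame(
            markers[f"{stem}_O"], markers[f"{stem}_D"], markers[f"{stem}_L"], side=seg_side
        )
    return out


def cardan_xyz(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose rotation matrices as R = Rx(alpha) @ Ry(beta) @ Rz(gamma).

    Parameters
    ----------
    R : (..., 3, 3) proper orthogonal matrices.

    Returns
    -------
    (alpha, beta, gamma) in degrees; ``alpha`` is the sagittal rotation,
    ``beta`` lies in [-90, 90].  Near gimbal lock (|R[0,2]| within 1e-8 of 1)
    gamma is set to 0 and alpha absorbs the free rotation.
    """
    R = np.asarray(R, dtype=float)
    scalar = R.ndim == 2
    if scalar:
        R = R[None]
    err = np.abs(R @ np.swapaxes(R, -1, -2) - np.eye(3)).max()
    if err > 1e-6:
        raise InputError(f"matrix not orthogonal (deviation {err:.2e})")
    s = np.clip(R[..., 0, 2], -1.0, 1.0)
    beta = np.arcsin(s)
    alpha = np.arctan2(-R[..., 1, 2], R[..., 2, 2])
    gamma = np.arctan2(-R[..., 0, 1], R[..., 0, 0])
    locked = np.abs(s) >= 1.0 - _GIMBAL_TOL
    if np.any(locked):
        # beta = +-90 deg: only alpha -+ gamma is determined; put it all in alpha
        a_lock = np.arctan2(R[..., 1, 0] * np.sign(s), R[..., 1, 1])
        alpha = np.where(locked, a_lock, alpha)
        gamma = np.where(locked, 0.0, gamma)
    out = tuple(np.degrees(v[0] if scalar else v) for v in (alpha, beta, gamma))
    return out


def relative_rotation(proximal: SegmentFrame, distal: SegmentFrame) -> np.ndarray:
    """Proximal-to-distal rotation R = R_prox^T @ R_dist per sample."""
    return np.swapaxes(proximal.axes, -1, -2) @ distal.axes


def joint_angles(
    pelvis: SegmentFrame,
    thigh: SegmentFrame,
    shank: SegmentFrame,
    foot: SegmentFrame,
    rate: float = 0.0,
) -> JointAngleSeries:
    """Hip, knee and ankle sagittal angles (degrees) from segment frames.

    The sagittal component is the alpha of the x-y-z Cardan decomposition of
    the proximal-to-distal rotation; knee alpha is negated so that flexion is
    positive like the hip (the shank rotates posteriorly when the knee
    flexes).
    """
    if not (len(pelvis) == len(thigh) == len(shank) == len(foot)):
        raise InputError("segment frames must share sample count")
    out = {}
    for joint, prox, dist in (
        ("hip", pelvis, thigh),
        ("knee", thigh, shank),
        ("ankle", shank, foot),
    ):
        alpha, _, _ = cardan_xyz(relative_rotation(prox, dist))
        out[joint] = SAGITTAL_SIGNS[joint] * alpha
    return JointAngleSeries(rate=rate, **out)


def virtual_foot_marker(
    mt1: MarkerTrajectory,
    mt5: MarkerTrajectory,
    mml: MarkerTrajectory,
    lml: MarkerTrajectory,
) -> MarkerTrajectory:
    """Mid-foot virtual marker: midpoint of the metatarsal and malleolar midpoints."""
    _check_shared([mt1, mt5, mml, lml])
    pos = 0.25 * (mt1.positions + mt5.positions + mml.positions + lml.positions)
    return MarkerTrajectory(label="VIRTUAL_FOOT", positions=pos, rate=mt1.rate)


def linear_acceleration(traj: MarkerTrajectory) -> VectorSeries:
    """Central-difference linear acceleration (m/s^2); endpoints invalid."""
    p = traj.positions
    if len(traj) < 3:
        raise InputError("need at least 3 samples for central differences")
    a = np.empty_like(p)
    a[1:-1] = (p[2:] - 2.0 * p[1:-1] + p[:-2]) * traj.rate**2
    a[0] = a[1]
    a[-1] = a[-2]
    valid = np.ones(len(traj), dtype=bool)
    valid[[0, -1]] = False
    return VectorSeries(values=a, units="m/s^2", valid=valid)


def frame_quaternions(frame: SegmentFrame) -> QuaternionSeries:
    """Unit quaternions for the frame axes, sign-continuous along the series."""
    q = Rotation.from_matrix(frame.axes).as_quat()  # (T, 4) as (x, y, z, w)
    wxyz = np.column_stack([q[:, 3], q[:, 0], q[:, 1], q[:, 2]])
    # enforce dot(q_i, q_{i-1}) >= 0 by propagating a cumulative sign flip
    dots = np.einsum("ij,ij->i", wxyz[1:], wxyz[:-1])
    flips = np.cumprod(np.where(dots < 0, -1.0, 1.0))
    wxyz[1:] *= flips[:, None]
    return QuaternionSeries(wxyz=wxyz)


def _qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product of (..., 4) quaternion arrays in (w, x, y, z) order."""
    aw, ax, ay, az = (a[..., i] for i in range(4))
    bw, bx, by, bz = (b[..., i] for i in range(4))
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def angular_velocity(q: QuaternionSeries, rate: float) -> VectorSeries:
    """Angular velocity (rad/s) from quaternion central differences.

    omega_i = 2 * vec(dq_i * conj(q_i)) with dq_i = (q_{i+1} - q_{i-1}) * rate / 2.
    Endpoints are invalid.  The result is the lab-frame angular velocity;
    only its norm is used downstream, so the frame of expression is
    immaterial.
    """
    w = q.wxyz
    if w.shape[0] < 3:
        raise InputError("need at least 3 samples for central differences")
    dq = np.empty_like(w)
    dq[1:-1] = (w[2:] - w[:-2]) * (rate / 2.0)
    dq[0] = dq[1]
    dq[-1] = dq[-2]
    conj = w * np.array([1.0, -1.0, -1.0, -1.0])
    omega = 2.0 * _qmul(dq, conj)[:, 1:]
    valid = np.ones(w.shape[0], dtype=bool)
    valid[[0, -1]] = False
    return VectorSeries(values=omega, units="rad/s", valid=valid)


def norm_series(v: VectorSeries) -> np.ndarray:
    """Per-sample Euclidean norm of a vector series."""
    return np.linalg.norm(v.values, axis=1)
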
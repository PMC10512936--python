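"""Synthetic overground-walking trials with known ground-truth joint angles.

The generator emulates the structure of a barefoot straight-walking
motion-capture study: 200 Hz marker trajectories for both limbs (five foot
landmarks plus three-landmark triads for pelvis, thighs and shanks), 1,000 Hz
per-limb vertical ground-reaction force, and the hip/knee/ankle sagittal
angles that produced the markers.  Kinematics are a planar sagittal chain —
all joint rotations about the lab x (right) axis, lab frame x-right,
y-anterior, z-up — so the marker-derived Cardan angles recover the generating
angles exactly, which makes the generator the oracle for every downstream
stage.

Per-cycle joint-angle shapes are hard-coded truncated Fourier series (six
harmonics) resembling normative sagittal gait curves, scaled and offset per
subject; trial-level variability is smooth low-pass-filtered additive angle
noise.  The contralateral limb runs the same chain phase-shifted by exactly
half a cycle.  Vertical GRF is a two-peaked stance template occupying a
fixed fraction of the cycle and exactly zero in swing.

Determinism: every random draw derives from ``numpy.random.SeedSequence``
keyed by (master_seed, subject index[, trial index]), so any subject or
trial is reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gaitnorm.errors import ConfigurationError, InputError
from gaitnorm.events import zero_lag_butterworth
from gaitnorm.kinematics import JOINTS, MarkerTrajectory

GRAVITY = 9.81

#: Truncated-Fourier normative sagittal templates, degrees, phase 0 = heel
#: contact.  angle(p) = a0 + sum_k cos_k*cos(2 pi k p) + sin_k*sin(2 pi k p).
TEMPLATE_COEFFS: dict[str, dict[str, np.ndarray | float]] = {
    "hip": {
        "a0": 12.486255,
        "cos": np.array([21.122946, -2.79777, -1.110315, 0.135374, -0.080925, 0.133959]),
        "sin": np.array([-3.877667, -3.12617, 1.310614, 0.237141, 0.212115, 0.115764]),
    },
    "knee": {
        "a0": 22.191662,
        "cos": np.array([-2.28301, -15.4694, 0.1735696, -0.1648301, 0.5433462, 0.01306792]),
        "sin": np.array([-19.585547, 7.512673, 4.079427, 0.443601, -0.039697, -0.067249]),
    },
    "ankle": {
        "a0": 0.893987,
        "cos": np.array([-1.950823, 1.549998, -3.997546, 2.794523, -0.544225, 0.238915]),
        "sin": np.array([6.092076, -7.0192, 0.491711, 0.456395, -1.82193, 0.776817]),
    },
}

SIDES = ("left", "right")

# foot landmark coordinates in the foot frame (origin = ankle joint centre,
# x medial for the left foot, y anterior, z up); heights chosen so heel and
# metatarsal markers share the sole plane, which makes the constructed foot
# frame reproduce the generating rotation exactly.
_FOOT_LOCAL = {
    "HEEL": np.array([0.0, -0.05, -0.07]),
    "MT1": np.array([0.04, 0.13, -0.07]),
    "MT5": np.array([-0.04, 0.13, -0.07]),
    "MML": np.array([0.035, 0.0, 0.0]),
    "LML": np.array([-0.035, 0.0, 0.0]),
}

_BODY_WEIGHT_N = 60.0 * GRAVITY  # synthetic subjects share a nominal mass
_N_CYCLES = 4.5  # trial length in ipsilateral cycles (>= 3 full interior cycles)
_NOISE_CUTOFF_HZ = 8.0  # low-pass corner of the smooth trial noise


@dataclass
class GeneratorConfig:
    """Study-level layout and variability of the synthetic dataset."""

    n_subjects: int = 200
    n_trials_per_subject: int = 10
    marker_rate: float = 200.0
    grf_rate: float = 1000.0
    cycle_fraction_stance: float = 0.6
    noise_sd_angle: float = 0.3  # degrees, smooth per-trial angle noise
    subject_effect_sd: float = 0.15  # relative amplitude / offset spread
    master_seed: int = 0

    def __post_init__(self):
        if self.marker_rate <= 0 or self.grf_rate <= 0:
            raise ConfigurationError("sampling rates must be positive")
        ratio = self.grf_rate / self.marker_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError("grf_rate must be an integer multiple of marker_rate")
        if not 0.0 < self.cycle_fraction_stance < 1.0:
            raise ConfigurationError("cycle_fraction_stance must lie in (0, 1)")
        if self.n_subjects < 5:
            raise ConfigurationError("need at least 5 subjects for 5-group splits")
        if self.n_trials_per_subject < 1:
            raise ConfigurationError("need at least one trial per subject")
        if self.noise_sd_angle < 0 or self.subject_effect_sd < 0:
            raise ConfigurationError("noise SDs must be nonnegative")


@dataclass
class SubjectProfile:
    """Anthropometry and gait-shape parameters of one synthetic subject."""

    subject_id: str
    cadence: float  # strides / s
    stride_length: float  # m
    segment_lengths: dict[str, float]  # thigh, shank, foot, pelvis (m)
    amplitude_scales: dict[str, float]  # per joint, unitless
    offset_shifts: dict[str, float]  # per joint, degrees
    seed: int

    def __post_init__(self):
        if any(v <= 0 for v in self.segment_lengths.values()):
            raise ConfigurationError("segment lengths must be positive")
        if any(v < 0 for v in self.amplitude_scales.values()):
            raise ConfigurationError("amplitude scales must be nonnegative")


@dataclass
class SyntheticTrial:
    """One synthetic walking trial with markers, GRF and ground truth."""

    subject_id: str
    trial_id: int
    side: str  # analyzed (ipsilateral) limb
    markers: dict[str, MarkerTrajectory]
    grf_vertical: dict[str, np.ndarray]  # per limb, N, at grf_rate
    grf_rate: float
    marker_rate: float
    truth_angles: dict[str, np.ndarray]  # per limb, (T, 3) degrees [hip, knee, ankle]
    scheduled_contacts: dict[str, np.ndarray] = field(default_factory=dict)  # s


def _subject_seed(master_seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence((master_seed, index)).generate_state(1)[0] % (2**31)
    )


def make_profiles(config: GeneratorConfig) -> list[SubjectProfile]:
    """Draw ``n_subjects`` profiles, each a pure function of (master_seed, index)."""
    profiles = []
    for i in range(config.n_subjects):
        seed = _subject_seed(config.master_seed, i)
        rng = np.random.default_rng(seed)
        cadence = float(np.clip(rng.normal(0.9, 0.08), 0.65, 1.2))
        # anthropometry scales with a single stature factor, and comfortable
        # stride length follows stature and cadence (roughly constant walk
        # ratio), as in normative gait data
        stature = float(np.clip(rng.normal(1.0, 0.05), 0.8, 1.2))
        stride = 1.30 * stature * (cadence / 0.9) ** 0.42
        seg = {
            "thigh": 0.42 * stature,
            "shank": 0.41 * stature,
            "foot": 0.24 * stature,
            "pelvis": 0.12,
        }
        sd = config.subject_effect_sd
        # normative data show a larger relative spread of ankle excursion
        # (peak plantarflexion CV ~0.25-0.3) than of hip/knee excursion
        cv = {"hip": 1.0, "knee": 1.0, "ankle": 1.5}
        amp = {
            j: float(np.clip(1.0 + cv[j] * sd * rng.standard_normal(), 0.05, None))
            for j in JOINTS
        }
        # posture offsets are kept small relative to amplitude effects: a
        # constant offset rigidly rotates (part of) the limb, and rotation-
        # invariant norm features carry little or no information about it,
        # so large offsets would break the feature->angle determinism the
        # dataset is built to exhibit
        off = {j: float(2.5 * sd * rng.standard_normal()) for j in JOINTS}
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:03d}",
                cadence=cadence,
                stride_length=stride,
                segment_lengths=seg,
                amplitude_scales=amp,
                offset_shifts=off,
                seed=seed,
            )
        )
    return profiles


def joint_angle_templates(profile: SubjectProfile, cycle_phase) -> np.ndarray:
    """Hip/knee/ankle template angles (degrees) at the given cycle phase(s).

    Periodic by construction (Fourier series), scaled and offset by the
    subject profile: ``offset + scale * template(phase)``.
    """
    phase = np.asarray(cycle_phase, dtype=float)
    if np.any(phase < 0) or np.any(phase > 1):
        raise InputError("cycle phase must lie in [0, 1]")
    k = np.arange(1, 7)
    arg = 2.0 * np.pi * np.multiply.outer(phase, k)  # (..., 6)
    cols = []
    for j in JOINTS:
        c = TEMPLATE_COEFFS[j]
        base = (
            c["a0"]
            + (np.cos(arg) * c["cos"]).sum(-1)
            + (np.sin(arg) * c["sin"]).sum(-1)
        )
        cols.append(profile.offset_shifts[j] + profile.amplitude_scales[j] * base)
    return np.stack(cols, axis=-1)


def _rx(theta_rad: np.ndarray) -> np.ndarray:
    """Rotation matrices about the lab x axis, (T, 3, 3)."""
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    T = np.shape(c)[0] if np.ndim(c) else 1
    R = np.zeros((T, 3, 3))
    R[:, 0, 0] = 1.0
    R[:, 1, 1] = c
    R[:, 1, 2] = -s
    R[:, 2, 1] = s
    R[:, 2, 2] = c
    return R


def forward_kinematics(
    profile: SubjectProfile,
    truth_angles: dict[str, np.ndarray],
    time_grid: np.ndarray,
) -> dict[str, MarkerTrajectory]:
    """Marker set consistent with the given joint-angle series.

    Planar sagittal chain pelvis -> thigh -> shank -> foot per limb: the
    pelvis advances anteriorly at stride_length * cadence with identity
    orientation, thigh orientation = hip angle, shank = thigh - knee angle,
    foot = shank + ankle angle (all rotations about lab x, flexion /
    dorsiflexion positive).  Foot landmarks ride rigidly on the foot frame,
    so inter-marker distances are constant to machine precision.
    """
    for side, ang in truth_angles.items():
        if not np.all(np.isfinite(ang)):
            raise InputError(f"non-finite truth angles for {side} limb")
    t = np.asarray(time_grid, dtype=float)
    T = t.shape[0]
    rate = 1.0 / (t[1] - t[0])
    sl = profile.segment_lengths
    hip_height = sl["thigh"] + sl["shank"] + 0.07
    root = np.column_stack(
        [np.zeros(T), profile.stride_length * profile.cadence * t, np.full(T, hip_height)]
    )
    markers: dict[str, MarkerTrajectory] = {}

    def add(label: str, pos: np.ndarray) -> None:
        markers[label] = MarkerTrajectory(label=label, positions=pos, rate=rate)

    # pelvis landmark triad (identity orientation)
    add("PELVIS_O", root)
    add("PELVIS_D", root + np.array([0.0, 0.0, -sl["pelvis"]]))
    add("PELVIS_L", root + np.array([0.08, 0.0, 0.0]))

    for side in SIDES:
        p = "L" if side == "left" else "R"
        sgn = -1.0 if side == "left" else 1.0  # lab x offset of the limb
        ang = np.radians(truth_angles[side])
        th_thigh = ang[:, 0]  # pelvis orientation is identity
        th_shank = th_thigh - ang[:, 1]
        th_foot = th_shank + ang[:, 2]
        hip = root + np.array([sgn * 0.09, 0.0, 0.0])
        knee = hip + _rx(th_thigh) @ np.array([0.0, 0.0, -sl["thigh"]])
        ankle = knee + _rx(th_shank) @ np.array([0.0, 0.0, -sl["shank"]])
        add(f"{p}_THIGH_O", hip)
        add(f"{p}_THIGH_D", knee)
        add(f"{p}_THIGH_L", hip + np.array([sgn * 0.06, 0.0, 0.0]))
        add(f"{p}_SHANK_O", knee)
        add(f"{p}_SHANK_D", ankle)
        add(f"{p}_SHANK_L", knee + np.array([sgn * 0.05, 0.0, 0.0]))
        Rf = _rx(th_foot)
        fscale = sl["foot"] / 0.24
        mirror = np.array([1.0, 1.0, 1.0]) if side == "left" else np.array([-1.0, 1.0, 1.0])
        for name, local in _FOOT_LOCAL.items():
            scaled = local * np.array([1.0, fscale, 1.0]) * mirror
            add(f"{p}_{name}", ankle + Rf @ scaled)
    return markers


def _stance_force(s: np.ndarray) -> np.ndarray:
    """Two-peaked vertical GRF shape on stance phase s in [0, 1], body weights."""
    f = 1.15 * (np.sin(np.pi * s) + 0.3 * np.sin(3.0 * np.pi * s))
    return np.clip(f, 0.0, None)


def _grf_series(
    contact_times: np.ndarray, stance_dur: float, n: int, rate: float
) -> np.ndarray:
    t = np.arange(n) / rate
    force = np.zeros(n)
    for tc in contact_times:
        s = (t - tc) / stance_dur
        m = (s >= 0.0) & (s < 1.0)
        force[m] += _BODY_WEIGHT_N * _stance_force(s[m])
    return force


def _smooth_noise(rng: np.random.Generator, n: int, rate: float, sd: float) -> np.ndarray:
    """Low-pass-filtered Gaussian noise rescaled to the requested SD."""
    if sd == 0.0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    f = zero_lag_butterworth(w, cutoff=_NOISE_CUTOFF_HZ, rate=rate)
    s = f.std()
    return f * (sd / s) if s > 0 else f


def synthesize_trial(
    profile: SubjectProfile, config: GeneratorConfig, trial_id: int, subject_index: int
) -> SyntheticTrial:
    """Generate a single trial; the analyzed side alternates across trial ids."""
    ss = np.random.SeedSequence((config.master_seed, subject_index, trial_id))
    rng = np.random.default_rng(ss)
    side = "left" if trial_id % 2 == 0 else "right"
    duration = _N_CYCLES / profile.cadence
    T = int(round(duration * config.marker_rate))
    t = np.arange(T) / config.marker_rate
    phase0 = float(rng.uniform(0.0, 1.0))

    truth: dict[str, np.ndarray] = {}
    contacts: dict[str, np.ndarray] = {}
    for limb in SIDES:
        shift = 0.0 if limb == side else 0.5
        phase = (profile.cadence * t + phase0 + shift) % 1.0
        ang = joint_angle_templates(profile, phase)
        noise = np.column_stack(
            [
                _smooth_noise(rng, T, config.marker_rate, config.noise_sd_angle)
                for _ in JOINTS
            ]
        )
        truth[limb] = ang + noise
        # heel contacts: phases where (cadence * t + phase0 + shift) crosses an integer
        off = phase0 + shift
        k0 = int(np.ceil(off))
        ks = np.arange(k0, int(np.floor(profile.cadence * t[-1] + off)) + 1)
        contacts[limb] = (ks - off) / profile.cadence

    markers = forward_kinematics(profile, truth, t)
    n_grf = int(round(T * config.grf_rate / config.marker_rate))
    stance_dur = config.cycle_fraction_stance / profile.cadence
    grf = {
        limb: _grf_series(contacts[limb], stance_dur, n_grf, config.grf_rate)
        for limb in SIDES
    }
    return SyntheticTrial(
        subject_id=profile.subject_id,
        trial_id=trial_id,
        side=side,
        markers=markers,
        grf_vertical=grf,
        grf_rate=config.grf_rate,
        marker_rate=config.marker_rate,
        truth_angles=truth,
        scheduled_contacts=contacts,
    )


def synthesize_dataset(config: GeneratorConfig) -> list[SyntheticTrial]:
    """All n_subjects x n_trials_per_subject trials, deterministic in the config."""
    profiles = make_profiles(config)
    trials = []
    for i, prof in enumerate(profiles):
        for tr in range(config.n_trials_per_subject):
            trials.append(synthesize_trial(prof, config, tr, i))
    return trials
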
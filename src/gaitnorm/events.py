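"""Signal filtering, heel-contact detection, cycle extraction and matrix assembly.

A gait cycle runs from one heel contact to the next ipsilateral heel
contact, detected from the vertical ground-reaction force.  Per-cycle
channels are linearly time-normalized to 200 points; feature rows
concatenate the ipsilateral and contralateral foot acceleration- and
angular-velocity-norm waveforms (4 x 200 = 800 columns) and target rows the
ipsilateral hip/knee/ankle angle waveforms (3 x 200 = 600 columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from gaitnorm.errors import AssemblyError, ConfigurationError, InputError, NoCycleError

N_POINTS = 200
FEATURE_CHANNELS = ("ipsi_acc_norm", "ipsi_gyro_norm", "contra_acc_norm", "contra_gyro_norm")
TARGET_CHANNELS = ("hip", "knee", "ankle")


@dataclass
class ForceSeries:
    """Vertical ground-reaction force (N) at a fixed rate."""

    force: np.ndarray
    rate: float

    def __post_init__(self):
        self.force = np.asarray(self.force, dtype=float)
        if self.rate <= 0:
            raise InputError("force rate must be positive")
        if not np.all(np.isfinite(self.force)):
            raise InputError("non-finite force values")


@dataclass
class GaitCycle:
    """Heel-contact-to-heel-contact interval, indices at the marker rate."""

    subject_id: str
    trial_id: int
    side: str
    start: int
    end: int  # index of the next ipsilateral heel contact (inclusive endpoint)

    def __post_init__(self):
        if self.end <= self.start:
            raise InputError("cycle end must exceed start")


def zero_lag_butterworth(series: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Fourth-order zero-lag Butterworth low-pass.

    Implemented as a forward-backward second-order pass, so the combined
    response is fourth order with zero phase shift and unit DC gain.
    """
    if cutoff >= rate / 2.0:
        raise ConfigurationError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {rate / 2.0} Hz"
        )
    sos = butter(2, cutoff, btype="low", fs=rate, output="sos")
    return sosfiltfilt(sos, np.asarray(series, dtype=float), axis=0)


def detect_heel_contacts(
    grf: ForceSeries,
    threshold: float = 20.0,
    refractory: float = 0.2,
    onset_floor: float = 0.05,
) -> np.ndarray:
    """Heel-contact times (s) from upward threshold crossings of vertical GRF.

    Each crossing of ``threshold`` is refined to the loading onset: the first
    sample after the most recent sample at or below ``onset_floor`` (N).
    Events closer than ``refractory`` seconds to the previous accepted event
    are discarded.  Returns an ascending array, possibly empty.
    """
    f = grf.force
    above = f > threshold
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    events: list[int] = []
    for c in crossings:
        low = np.nonzero(f[:c] <= onset_floor)[0]
        onset = int(low[-1]) + 1 if low.size else 0
        if events and (onset - events[-1]) / grf.rate < refractory:
            continue
        events.append(onset)
    return np.asarray(events, dtype=float) / grf.rate


def extract_cycles(
    events_s: np.ndarray,
    marker_rate: float,
    n_samples: int,
    subject_id: str = "",
    trial_id: int = 0,
    side: str = "",
) -> list[GaitCycle]:
    """Pair consecutive ipsilateral heel contacts into gait cycles.

    Event times (seconds, typically at the GRF rate) are mapped to the
    nearest marker-rate index.  Cycles touching the first or last marker
    sample are discarded because central-difference derivatives are invalid
    there.  Raises :class:`NoCycleError` if fewer than two events are given.
    """
    if len(events_s) < 2:
        raise NoCycleError(f"trial {subject_id}/{trial_id}: fewer than 2 heel contacts")
    idx = np.rint(np.asarray(events_s) * marker_rate).astype(int)
    cycles = []
    for a, b in zip(idx[:-1], idx[1:]):
        if a >= 1 and b <= n_samples - 2 and b > a + 1:
            cycles.append(
                GaitCycle(subject_id=subject_id, trial_id=trial_id, side=side, start=int(a), end=int(b))
            )
    return cycles


def time_normalize(values: np.ndarray, n_points: int = N_POINTS) -> np.ndarray:
    """Linear interpolation of a per-cycle channel onto ``n_points`` phases.

    Phase i/(n_points - 1) for i = 0..n_points-1, both endpoints included.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[0] < 2:
        raise InputError("cycle must contain at least 2 samples")
    src = np.linspace(0.0, 1.0, v.shape[0])
    dst = np.linspace(0.0, 1.0, n_points)
    if v.ndim == 1:
        return np.interp(dst, src, v)
    return np.column_stack([np.interp(dst, src, v[:, j]) for j in range(v.shape[1])])


@dataclass
class ProcessedCycle:
    """One analyzed gait cycle: an 800-wide feature row and 600-wide target row."""

    subject_id: str
    trial_id: int
    side: str
    features: np.ndarray  # (800,)
    targets: np.ndarray  # (600,)


def assemble_matrices(
    cycles: list[ProcessedCycle], n_points: int = N_POINTS
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Stack processed cycles into the input and output waveform matrices.

    Rows are ordered deterministically by (subject_id, trial_id) so the
    result does not depend on processing order.  Returns (features t x 800,
    targets t x 600, row index with subject/trial/side per row).
    """
    if not cycles:
        raise AssemblyError("no processed cycles to assemble")
    n_feat = len(FEATURE_CHANNELS) * n_points
    n_targ = len(TARGET_CHANNELS) * n_points
    ordered = sorted(cycles, key=lambda c: (c.subject_id, c.trial_id))
    for c in ordered:
        if c.features.shape != (n_feat,):
            raise AssemblyError(
                f"{c.subject_id}/{c.trial_id}: feature width {c.features.shape} != {n_feat}"
            )
        if c.targets.shape != (n_targ,):
            raise AssemblyError(
                f"{c.subject_id}/{c.trial_id}: target width {c.targets.shape} != {n_targ}"
            )
    X = np.stack([c.features for c in ordered])
    Y = np.stack([c.targets for c in ordered])
    index = pd.DataFrame(
        {
            "subject_id": [c.subject_id for c in ordered],
            "trial_id": [c.trial_id for c in ordered],
            "side": [c.side for c in ordered],
        }
    )
    return X, Y, index
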
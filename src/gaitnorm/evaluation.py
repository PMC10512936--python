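"""Waveform accuracy metrics and angle-at-timing errors.

Per trial and joint the 200-point actual and predicted waveforms are
compared by RMSE (degrees), NRMSE (RMSE as a percentage of the actual
waveform's range) and the Pearson correlation; each is averaged over
trials.  Clinically referenced scalar timings — angles at heel contact and
cycle extrema — are compared by mean absolute error with SD across trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gaitnorm.errors import InputError
from gaitnorm.events import N_POINTS, TARGET_CHANNELS

#: (name, joint, kind) of the six reported timing quantities.  "at point 1"
#: of the normalized cycle is heel contact; extrema are over the full cycle.
TIMING_QUANTITIES = (
    ("hip_flexion_at_heel_contact", "hip", "at_heel_contact"),
    ("peak_hip_extension", "hip", "minimum"),
    ("peak_knee_flexion", "knee", "maximum"),
    ("ankle_dorsiflexion_at_heel_contact", "ankle", "at_heel_contact"),
    ("peak_ankle_dorsiflexion", "ankle", "maximum"),
    ("peak_ankle_plantar_flexion", "ankle", "minimum"),
)


@dataclass
class MetricsReport:
    """Per-joint mean RMSE / NRMSE / Pearson rho plus the per-trial table."""

    summary: pd.DataFrame  # index: joint; columns rmse_deg, nrmse_pct, rho
    per_trial: pd.DataFrame


@dataclass
class TimingErrors:
    """MAE and SD (degrees) of the six angle-at-timing quantities."""

    table: pd.DataFrame  # index: quantity; columns mae_deg, sd_deg


def _reshape(rows: np.ndarray) -> np.ndarray:
    """(n, 600) target rows -> (n, 3, 200) [hip, knee, ankle]."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != len(TARGET_CHANNELS) * N_POINTS:
        raise InputError(f"expected width {len(TARGET_CHANNELS) * N_POINTS}, got {rows.shape[1]}")
    return rows.reshape(rows.shape[0], len(TARGET_CHANNELS), N_POINTS)


def waveform_metrics(actual: np.ndarray, predicted: np.ndarray) -> MetricsReport:
    """RMSE / NRMSE / Pearson rho per joint, averaged over trials.

    Trials whose actual waveform is constant are excluded from rho (and
    NRMSE) with a warning, since neither is defined there.
    """
    A, P = _reshape(actual), _reshape(predicted)
    if A.shape != P.shape:
        raise InputError("actual and predicted shapes differ")
    if A.shape[0] < 1:
        raise InputError("need at least one trial")
    records = []
    for i in range(A.shape[0]):
        for j, joint in enumerate(TARGET_CHANNELS):
            a, p = A[i, j], P[i, j]
            rmse = float(np.sqrt(np.mean((a - p) ** 2)))
            rng = float(a.max() - a.min())
            if rng <= 0.0 or a.std() == 0.0:
                warnings.warn(
                    f"trial {i} {joint}: constant actual waveform; NRMSE/rho excluded",
                    stacklevel=2,
                )
                nrmse = np.nan
                rho = np.nan
            else:
                nrmse = 100.0 * rmse / rng
                rho = np.nan if p.std() == 0.0 else float(np.corrcoef(a, p)[0, 1])
            records.append({"trial": i, "joint": joint, "rmse_deg": rmse, "nrmse_pct": nrmse, "rho": rho})
    per_trial = pd.DataFrame(records)
    summary = (
        per_trial.groupby("joint")[["rmse_deg", "nrmse_pct", "rho"]]
        .mean()
        .reindex(list(TARGET_CHANNELS))
    )
    return MetricsReport(summary=summary, per_trial=per_trial)


def timing_angles(waveform: np.ndarray, joint: str) -> dict[str, float]:
    """Scalar timing angles of one 200-point joint waveform."""
    w = np.asarray(waveform, dtype=float)
    if w.shape != (N_POINTS,):
        raise InputError(f"waveform must have {N_POINTS} points")
    if joint not in TARGET_CHANNELS:
        raise InputError(f"unknown joint {joint!r}")
    out = {}
    for name, jnt, kind in TIMING_QUANTITIES:
        if jnt != joint:
            continue
        if kind == "at_heel_contact":
            out[name] = float(w[0])
        elif kind == "maximum":
            out[name] = float(w.max())
        else:
            out[name] = float(w.min())
    return out


def timing_mae(actual: np.ndarray, predicted: np.ndarray) -> TimingErrors:
    """MAE (with SD) of the six timing quantities across paired trials."""
    A, P = _reshape(actual), _reshape(predicted)
    if A.shape != P.shape:
        raise InputError("actual and predicted shapes differ")
    if A.shape[0] < 1:
        raise InputError("need at least one paired trial")
    jidx = {j: i for i, j in enumerate(TARGET_CHANNELS)}
    rows = []
    for name, joint, kind in TIMING_QUANTITIES:
        a, p = A[:, jidx[joint], :], P[:, jidx[joint], :]
        if kind == "at_heel_contact":
            va, vp = a[:, 0], p[:, 0]
        elif kind == "maximum":
            va, vp = a.max(axis=1), p.max(axis=1)
        else:
            va, vp = a.min(axis=1), p.min(axis=1)
        err = np.abs(va - vp)
        rows.append({"quantity": name, "mae_deg": float(err.mean()), "sd_deg": float(err.std())})
    return TimingErrors(table=pd.DataFrame(rows).set_index("quantity"))


def plot_mean_waveforms(actual: np.ndarray, predicted: np.ndarray, path) -> None:
    """Mean actual (solid) vs predicted (dashed) waveform per joint."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    A, P = _reshape(actual), _reshape(predicted)
    phase = np.linspace(0, 100, N_POINTS)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for j, (ax, joint) in enumerate(zip(axes, TARGET_CHANNELS)):
        ax.plot(phase, A[:, j].mean(axis=0), "r-", label="actual")
        ax.plot(phase, P[:, j].mean(axis=0), "k--", label="predicted")
        ax.set_title(joint)
        ax.set_xlabel("gait cycle (%)")
    axes[0].set_ylabel("angle (deg)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
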
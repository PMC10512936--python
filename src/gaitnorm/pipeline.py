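"""End-to-end per-trial processing and whole-experiment orchestration.

``process_trial`` reproduces the measurement chain on one walking trial:
zero-lag low-pass filtering of markers (10 Hz) and GRF (56 Hz), segment
frames and Cardan joint angles, virtual-foot-marker acceleration norms and
quaternion angular-velocity norms for both feet, heel-contact detection on
the ipsilateral vertical GRF, extraction of the first interior gait cycle,
and 200-point time normalization of the four feature channels and three
target channels.

``run_experiment`` wires the full study protocol together: process every
trial, assemble the waveform matrices, split subjects into five groups,
tune hyperparameters by 4-fold cross-validation, fit the main model on the
four non-test groups and evaluate predictions on the held-out test group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from gaitnorm import estimator, evaluation, kinematics
from gaitnorm.errors import NoCycleError
from gaitnorm.events import (
    N_POINTS,
    ForceSeries,
    ProcessedCycle,
    assemble_matrices,
    detect_heel_contacts,
    extract_cycles,
    time_normalize,
    zero_lag_butterworth,
)
from gaitnorm.kinematics import MarkerTrajectory
from gaitnorm.nn import HyperParams, TrainingConfig
from gaitnorm.synthetic import SyntheticTrial


@dataclass
class PipelineConfig:
    """Signal-processing constants of the measurement chain."""

    marker_cutoff: float = 10.0  # Hz, 4th-order zero-lag low-pass on markers
    grf_cutoff: float = 56.0  # Hz, same filter on vertical GRF
    hc_threshold: float = 20.0  # N, heel-contact threshold
    hc_refractory: float = 0.2  # s, minimum event spacing
    n_points: int = N_POINTS


def _filtered_markers(
    markers: dict[str, MarkerTrajectory], cutoff: float
) -> dict[str, MarkerTrajectory]:
    out = {}
    for label, tr in markers.items():
        pos = zero_lag_butterworth(tr.positions, cutoff=cutoff, rate=tr.rate)
        out[label] = MarkerTrajectory(label=label, positions=pos, rate=tr.rate)
    return out


def foot_signal_norms(
    markers: dict[str, MarkerTrajectory], side: str
) -> tuple[np.ndarray, np.ndarray]:
    """(acceleration-norm, angular-velocity-norm) series for one foot."""
    p = "L" if side == "left" else "R"
    foot = kinematics.build_foot_frame(
        markers[f"{p}_HEEL"],
        markers[f"{p}_MT1"],
        markers[f"{p}_MT5"],
        markers[f"{p}_MML"],
        markers[f"{p}_LML"],
        side,
    )
    vfm = kinematics.virtual_foot_marker(
        markers[f"{p}_MT1"], markers[f"{p}_MT5"], markers[f"{p}_MML"], markers[f"{p}_LML"]
    )
    acc = kinematics.linear_acceleration(vfm)
    omega = kinematics.angular_velocity(
        kinematics.frame_quaternions(foot), rate=vfm.rate
    )
    return kinematics.norm_series(acc), kinematics.norm_series(omega)


def ipsilateral_joint_angles(
    markers: dict[str, MarkerTrajectory], side: str
) -> kinematics.JointAngleSeries:
    """Hip/knee/ankle sagittal angles of the given limb from markers."""
    p = "L" if side == "left" else "R"
    prox = kinematics.build_proximal_frames(markers, side)
    foot = kinematics.build_foot_frame(
        markers[f"{p}_HEEL"],
        markers[f"{p}_MT1"],
        markers[f"{p}_MT5"],
        markers[f"{p}_MML"],
        markers[f"{p}_LML"],
        side,
    )
    rate = markers[f"{p}_HEEL"].rate
    return kinematics.joint_angles(
        prox["pelvis"], prox["thigh"], prox["shank"], foot, rate=rate
    )


def process_trial(trial: SyntheticTrial, cfg: PipelineConfig | None = None) -> ProcessedCycle:
    """Feature and target rows for the first interior gait cycle of a trial."""
    cfg = cfg or PipelineConfig()
    markers = _filtered_markers(trial.markers, cfg.marker_cutoff)
    n = len(next(iter(markers.values())))

    grf = zero_lag_butterworth(
        trial.grf_vertical[trial.side], cutoff=cfg.grf_cutoff, rate=trial.grf_rate
    )
    events = detect_heel_contacts(
        ForceSeries(force=grf, rate=trial.grf_rate),
        threshold=cfg.hc_threshold,
        refractory=cfg.hc_refractory,
    )
    cycles = extract_cycles(
        events,
        trial.marker_rate,
        n,
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        side=trial.side,
    )
    if not cycles:
        raise NoCycleError(f"trial {trial.subject_id}/{trial.trial_id}: no interior cycle")
    cyc = cycles[0]
    sl = slice(cyc.start, cyc.end + 1)

    contra = "right" if trial.side == "left" else "left"
    feat_parts = []
    for limb in (trial.side, contra):
        acc, gyro = foot_signal_norms(markers, limb)
        feat_parts.append(time_normalize(acc[sl], cfg.n_points))
        feat_parts.append(time_normalize(gyro[sl], cfg.n_points))
    features = np.concatenate(feat_parts)

    ang = ipsilateral_joint_angles(markers, trial.side).as_array()
    targets = np.concatenate(
        [time_normalize(ang[sl, j], cfg.n_points) for j in range(3)]
    )
    return ProcessedCycle(
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        side=trial.side,
        features=features,
        targets=targets,
    )


def build_matrices(
    trials: list[SyntheticTrial], cfg: PipelineConfig | None = None
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Process every trial and assemble the t x 800 / t x 600 matrices."""
    rows = [process_trial(tr, cfg) for tr in trials]
    return assemble_matrices(rows, (cfg or PipelineConfig()).n_points)


@dataclass
class ExperimentResult:
    """Everything the end-to-end protocol produces on one dataset."""

    split: estimator.SplitAssignment
    test_group: int
    best_hp: HyperParams
    condition_table: pd.DataFrame
    model: estimator.TrainedEstimator
    actual: np.ndarray  # test rows, (m, 600)
    predicted: np.ndarray  # (m, 600)
    baseline: np.ndarray  # mean-waveform baseline, (m, 600)
    metrics: evaluation.MetricsReport
    baseline_metrics: evaluation.MetricsReport
    timing: evaluation.TimingErrors
    index: pd.DataFrame
    test_mask: np.ndarray


@dataclass
class ExperimentConfig:
    """Protocol-level knobs for run_experiment."""

    n_groups: int = 5
    test_group: int = 5
    split_seed: int = 0
    training: TrainingConfig = field(default_factory=TrainingConfig)
    grid: list[HyperParams] | None = None  # None -> full 324-condition grid
    tune: bool = True
    fixed_hp: HyperParams | None = None  # used when tune=False


def run_experiment(
    X: np.ndarray,
    Y: np.ndarray,
    index: pd.DataFrame,
    cfg: ExperimentConfig | None = None,
) -> ExperimentResult:
    """Tune (optionally), train the main model and evaluate on the test group."""
    cfg = cfg or ExperimentConfig()
    split = estimator.split_groups(
        index["subject_id"].tolist(), n_groups=cfg.n_groups, seed=cfg.split_seed
    )
    conditions = cfg.grid if cfg.grid is not None else estimator.hyperparameter_grid()
    if cfg.tune:
        best_hp, table = estimator.cross_validate(
            X, Y, index, split, cfg.test_group, conditions, cfg.training
        )
    else:
        if cfg.fixed_hp is None:
            raise ValueError("tune=False requires fixed_hp")
        best_hp, table = cfg.fixed_hp, pd.DataFrame()
    main_cfg = replace(cfg.training, seed=cfg.training.seed + 1)
    model = estimator.fit_main(X, Y, index, split, cfg.test_group, best_hp, main_cfg)
    test_mask = split.rows_in(index, {cfg.test_group})
    train_mask = ~test_mask
    actual = Y[test_mask]
    predicted = estimator.predict(model, X[test_mask])
    baseline = estimator.mean_waveform_baseline(Y[train_mask], int(test_mask.sum()))
    return ExperimentResult(
        split=split,
        test_group=cfg.test_group,
        best_hp=best_hp,
        condition_table=table,
        model=model,
        actual=actual,
        predicted=predicted,
        baseline=baseline,
        metrics=evaluation.waveform_metrics(actual, predicted),
        baseline_metrics=evaluation.waveform_metrics(actual, baseline),
        timing=evaluation.timing_mae(actual, predicted),
        index=index,
        test_mask=test_mask,
    )
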
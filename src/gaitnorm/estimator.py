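"""Subject-level splitting, hyperparameter tuning and the main estimation model.

Subjects are randomly partitioned into five near-equal groups; every trial
of a subject stays in its subject's group, so no subject's gait appears on
both sides of any train/validation/test boundary.  Hyperparameter tuning
holds the test group out entirely and runs k-fold cross-validation (k = 4)
over the remaining groups: each of the four datasets uses one group for
validation and the other three for training, fits fresh PCA codecs on the
training rows, trains one network per grid condition, and scores the mean
absolute error between actual and predicted validation output scores.  The
condition with the lowest MAE averaged over the four datasets wins (ties
broken by grid order).

The main model then refits codecs on all four non-test groups, trains the
network with the winning condition, and predicts test joint-angle waveforms
by encode -> forward pass -> decode.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gaitnorm import pca
from gaitnorm.errors import ConfigurationError, InputError
from gaitnorm.nn import FnnWeights, HyperParams, TrainingConfig, forward, train_fnn


@dataclass
class SplitAssignment:
    """Subject -> group (1..n_groups) mapping."""

    groups: dict[str, int]
    n_groups: int = 5

    def rows_in(self, index: pd.DataFrame, wanted: set[int]) -> np.ndarray:
        """Boolean mask of matrix rows whose subject belongs to ``wanted``."""
        return index["subject_id"].map(self.groups).isin(wanted).to_numpy()


@dataclass
class GridConfig:
    """Axes of the hyperparameter grid; defaults span 12 x 3 x 3 x 3 = 324."""

    layer_node_combos: list[tuple[int, int]] = field(
        default_factory=lambda: [
            (layers, nodes) for layers in (1, 2, 3, 4) for nodes in (40, 80, 120)
        ]
    )
    batch_sizes: list[int] = field(default_factory=lambda: [128, 256, 512])
    dropout_rates: list[float] = field(default_factory=lambda: [0.3, 0.4, 0.5])
    learning_rates: list[float] = field(default_factory=lambda: [0.01, 0.001, 0.0001])


@dataclass
class TrainedEstimator:
    """Fitted input/output codecs plus network weights and their provenance."""

    input_codec: pca.PcaCodec
    output_codec: pca.PcaCodec
    weights: FnnWeights
    hyperparams: HyperParams
    config: TrainingConfig
    train_subjects: list[str] = field(default_factory=list)


def reduced_grid_config() -> GridConfig:
    """Compact 8-condition grid for scaled-down experiments.

    Sized for datasets of a few hundred subjects' worth of cycles and
    ~100-epoch budgets: small batches (more gradient updates per epoch),
    one or two hidden layers, and light-or-no dropout.
    """
    return GridConfig(
        layer_node_combos=[(1, 80), (2, 80)],
        batch_sizes=[8],
        dropout_rates=[0.0, 0.2],
        learning_rates=[0.001, 0.0003],
    )


def split_groups(
    subject_ids: list[str], n_groups: int = 5, seed: int = 0
) -> SplitAssignment:
    """Uniform random subject-level partition into near-equal groups.

    Group sizes differ by at most one; reproducible from the seed.
    """
    subjects = sorted(set(subject_ids))
    if len(subjects) < n_groups:
        raise InputError(f"need >= {n_groups} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    groups = {subjects[j]: (i % n_groups) + 1 for i, j in enumerate(order)}
    return SplitAssignment(groups=groups, n_groups=n_groups)


def hyperparameter_grid(grid: GridConfig | None = None) -> list[HyperParams]:
    """Cartesian product of the grid axes in deterministic order.

    Layer/node combinations vary outermost and learning rate innermost.
    The default axes yield 324 conditions and contain the optimum reported
    for this protocol (1 hidden layer, 80 nodes, batch 512, dropout 0.5,
    learning rate 0.001).
    """
    grid = grid or GridConfig()
    for name in ("layer_node_combos", "batch_sizes", "dropout_rates", "learning_rates"):
        if not getattr(grid, name):
            raise ConfigurationError(f"empty grid axis: {name}")
    return [
        HyperParams(
            n_hidden_layers=ln[0],
            nodes_per_layer=ln[1],
            batch_size=bs,
            dropout_rate=dr,
            learning_rate=lr,
        )
        for ln, bs, dr, lr in itertools.product(
            grid.layer_node_combos, grid.batch_sizes, grid.dropout_rates, grid.learning_rates
        )
    ]


def enumerate_cv_runs(
    split: SplitAssignment, test_group: int, conditions: list[HyperParams]
) -> list[tuple[int, HyperParams]]:
    """The (validation-group, condition) pairs cross-validation will train.

    With a 5-group split and the default 324-condition grid this enumerates
    4 x 324 = 1,296 training runs.
    """
    val_groups = [g for g in range(1, split.n_groups + 1) if g != test_group]
    return [(g, hp) for g in val_groups for hp in conditions]


def _fold_seed(base_seed: int, val_group: int, cond_idx: int) -> int:
    return int(
        np.random.SeedSequence((base_seed, val_group, cond_idx)).generate_state(1)[0]
        % (2**31)
    )


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    index: pd.DataFrame,
    split: SplitAssignment,
    test_group: int,
    conditions: list[HyperParams],
    cfg: TrainingConfig,
) -> tuple[HyperParams, pd.DataFrame]:
    """k-fold (k = n_groups - 1) hyperparameter tuning on PC scores.

    Returns the winning condition and a table with one row per condition
    holding the per-dataset validation MAEs and their mean.  The MAE is
    pooled over all entries of the validation output-score matrix.
    """
    val_groups = [g for g in range(1, split.n_groups + 1) if g != test_group]
    n_cond = len(conditions)
    maes = np.zeros((n_cond, len(val_groups)))
    for di, vg in enumerate(val_groups):
        train_groups = {g for g in val_groups if g != vg}
        tr = split.rows_in(index, train_groups)
        va = split.rows_in(index, {vg})
        if index.loc[tr, "subject_id"].nunique() < 2:
            raise InputError(f"fold with validation group {vg}: fewer than 2 training subjects")
        in_codec = pca.fit(X[tr], retention="kaiser")
        out_codec = pca.fit(Y[tr], retention="kaiser")
        Sx_tr = pca.encode(X[tr], in_codec)
        Sy_tr = pca.encode(Y[tr], out_codec)
        Sx_va = pca.encode(X[va], in_codec)
        Sy_va = pca.encode(Y[va], out_codec)
        for ci, hp in enumerate(conditions):
            fold_cfg = TrainingConfig(
                epochs=cfg.epochs, seed=_fold_seed(cfg.seed, vg, ci)
            )
            w = train_fnn(Sx_tr, Sy_tr, hp, fold_cfg)
            pred = forward(w, Sx_va)
            maes[ci, di] = float(np.mean(np.abs(pred - Sy_va)))
    mean_mae = maes.mean(axis=1)
    best = int(np.argmin(mean_mae))  # argmin takes the first minimum: grid order breaks ties
    table = pd.DataFrame(
        {
            "condition": np.arange(n_cond),
            **{f"mae_dataset_{di + 1}": maes[:, di] for di in range(len(val_groups))},
            "mean_mae": mean_mae,
        }
    )
    for f in ("n_hidden_layers", "nodes_per_layer", "batch_size", "dropout_rate", "learning_rate"):
        table[f] = [getattr(hp, f) for hp in conditions]
    return conditions[best], table


def fit_main(
    X: np.ndarray,
    Y: np.ndarray,
    index: pd.DataFrame,
    split: SplitAssignment,
    test_group: int,
    hp: HyperParams,
    cfg: TrainingConfig,
) -> TrainedEstimator:
    """Fit codecs and network on the four non-test groups."""
    train_groups = {g for g in range(1, split.n_groups + 1) if g != test_group}
    tr = split.rows_in(index, train_groups)
    if not tr.any():
        raise InputError("no training rows for the main model")
    in_codec = pca.fit(X[tr], retention="kaiser")
    out_codec = pca.fit(Y[tr], retention="kaiser")
    Sx = pca.encode(X[tr], in_codec)
    Sy = pca.encode(Y[tr], out_codec)
    weights = train_fnn(Sx, Sy, hp, cfg)
    return TrainedEstimator(
        input_codec=in_codec,
        output_codec=out_codec,
        weights=weights,
        hyperparams=hp,
        config=cfg,
        train_subjects=sorted(index.loc[tr, "subject_id"].unique()),
    )


def predict(est: TrainedEstimator, features: np.ndarray) -> np.ndarray:
    """Predicted joint-angle waveform rows for feature rows.

    encode (input codec) -> network forward pass (dropout off) -> decode
    (output codec); a (m, 800) feature matrix yields a (m, 600) angle matrix.
    """
    S_in = pca.encode(features, est.input_codec)
    S_out = forward(est.weights, S_in)
    return pca.decode(S_out, est.output_codec)


def mean_waveform_baseline(Y_train: np.ndarray, n_rows: int) -> np.ndarray:
    """Baseline prediction: the training-mean waveform repeated for each row."""
    return np.tile(Y_train.mean(axis=0), (n_rows, 1))
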
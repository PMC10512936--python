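"""Standardize-then-PCA waveform codec.

Waveform matrices are t x d (trials by per-cycle data points).  The codec
standardizes each column by its training mean and SD and projects onto the
eigenvectors of the training correlation matrix; a waveform row is
recovered from its component scores by

    W^T = M_mean + M_sd . M_loadings . S^T

where M_mean repeats the column means, M_sd is the diagonal column-SD
matrix, M_loadings is d x n and S is t x n.  Component retention follows
the Kaiser criterion (eigenvalue >= 1) by default; because correlation-PCA
eigenvalues sum to d, a retained component explains at least an average
column's worth of variance.

The same codec serves the 800-column input (foot acceleration /
angular-velocity norms) and the 600-column output (joint angles), fit on
training rows only and applied unchanged to validation and test rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from gaitnorm.errors import DegenerateColumnError, InputError

_SD_FLOOR = 1e-12


@dataclass
class PcaCodec:
    """Fitted standardization parameters plus loadings and eigenvalues."""

    means: np.ndarray  # (d,)
    sds: np.ndarray  # (d,)
    loadings: np.ndarray  # (d, n) eigenvalue-descending columns
    eigenvalues: np.ndarray  # all min(t-1, d) eigenvalues, descending
    retention: str  # 'kaiser' | 'all' | 'fixed'

    @property
    def d(self) -> int:
        return self.means.shape[0]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            means=self.means,
            sds=self.sds,
            loadings=self.loadings,
            eigenvalues=self.eigenvalues,
            retention=np.array(self.retention),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PcaCodec":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                means=z["means"],
                sds=z["sds"],
                loadings=z["loadings"],
                eigenvalues=z["eigenvalues"],
                retention=str(z["retention"]),
            )


def fit(
    train: np.ndarray,
    retention: str = "kaiser",
    n_components: int | None = None,
    kaiser_threshold: float = 1.0,
) -> PcaCodec:
    """Fit the codec on a training waveform matrix.

    Parameters
    ----------
    train : (t, d) matrix, t >= 2, no zero-variance column.
    retention : 'kaiser' keeps eigenvalues >= ``kaiser_threshold``; 'all'
        keeps every component of nonzero variance (full rank); 'fixed' keeps
        exactly ``n_components``.

    The loading-sign convention makes the largest-magnitude entry of each
    component positive, so fits are reproducible across linear-algebra
    backends.
    """
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("training matrix must be (t, d) with t >= 2")
    t, d = X.shape
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    flat = np.nonzero(sds < _SD_FLOOR)[0]
    if flat.size:
        raise DegenerateColumnError(
            f"zero-variance column(s) {flat[:5].tolist()} — flat channel upstream"
        )
    Z = (X - means) / sds
    _, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = S**2 / (t - 1)
    if retention == "kaiser":
        n = int(np.sum(eig >= kaiser_threshold))
        n = max(n, 1)
    elif retention == "all":
        n = int(np.sum(eig > 1e-10))
    elif retention == "fixed":
        if n_components is None or not 1 <= n_components <= eig.size:
            raise InputError("fixed retention requires 1 <= n_components <= rank")
        n = n_components
    else:
        raise InputError(f"unknown retention rule {retention!r}")
    V = Vt[:n].T  # (d, n)
    signs = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(n)])
    signs[signs == 0] = 1.0
    V = V * signs
    return PcaCodec(
        means=means, sds=sds, loadings=V, eigenvalues=eig, retention=retention
    )


def encode(data: np.ndarray, codec: PcaCodec) -> np.ndarray:
    """Project waveform rows onto the retained components -> (t, n) scores."""
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[1] != codec.d:
        raise InputError(f"data width {X.shape[1]} != codec width {codec.d}")
    Z = (X - codec.means) / codec.sds
    return Z @ codec.loadings


def decode(scores: np.ndarray, codec: PcaCodec) -> np.ndarray:
    """Reconstruct waveform rows from component scores -> (t, d)."""
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    if S.shape[1] != codec.n_components:
        raise InputError(
            f"score width {S.shape[1]} != retained components {codec.n_components}"
        )
    return S @ codec.loadings.T * codec.sds + codec.means


def save_bundle(path: str | Path, input_codec: PcaCodec, output_codec: PcaCodec) -> None:
    """Serialize both codecs of an estimator side by side."""
    path = Path(path)
    input_codec.save(path.with_suffix(".input.npz"))
    output_codec.save(path.with_suffix(".output.npz"))
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "input": {"d": input_codec.d, "n": input_codec.n_components},
                "output": {"d": output_codec.d, "n": output_codec.n_components},
            },
            indent=2,
        )
    )
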
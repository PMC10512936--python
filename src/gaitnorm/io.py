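"""Plain-text persistence: trial tables, dataset manifests, matrix archives.

Trial dialect
-------------
One UTF-8 file per trial with two tab-separated tables, each preceded by a
comment header line:

    # markers rate=200.0
    sample  <LABEL>_x[m]  <LABEL>_y[m]  <LABEL>_z[m]  ...  truth_<side>_hip[deg] ...
    0       ...
    # grf rate=1000.0
    sample  grf_left[N]  grf_right[N]
    0       ...

Marker columns are metres in the lab frame; ground-truth joint angles (when
present) ride along at the marker rate.  A dataset manifest CSV maps
(subject_id, trial_id, side) to file paths.

Assembled waveform matrices are stored as CSV with a JSON sidecar holding
the row index (subject/trial/side) and the channel map.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gaitnorm.errors import InputError
from gaitnorm.events import FEATURE_CHANNELS, TARGET_CHANNELS
from gaitnorm.kinematics import JOINTS, MarkerTrajectory
from gaitnorm.synthetic import SIDES, SyntheticTrial


def write_trial(trial: SyntheticTrial, path: str | Path) -> None:
    """Write one trial in the package's plain-text dialect."""
    path = Path(path)
    labels = sorted(trial.markers)
    T = len(trial.markers[labels[0]])
    cols: dict[str, np.ndarray] = {"sample": np.arange(T)}
    for lab in labels:
        for k, ax in enumerate("xyz"):
            cols[f"{lab}_{ax}[m]"] = trial.markers[lab].positions[:, k]
    for side in SIDES:
        if side in trial.truth_angles:
            for j, joint in enumerate(JOINTS):
                cols[f"truth_{side}_{joint}[deg]"] = trial.truth_angles[side][:, j]
    mtab = pd.DataFrame(cols)
    gtab = pd.DataFrame(
        {
            "sample": np.arange(len(trial.grf_vertical["left"])),
            "grf_left[N]": trial.grf_vertical["left"],
            "grf_right[N]": trial.grf_vertical["right"],
        }
    )
    with path.open("w") as fh:
        fh.write(f"# markers rate={trial.marker_rate}\n")
        mtab.to_csv(fh, sep="\t", index=False, float_format="%.9g")
        fh.write(f"# grf rate={trial.grf_rate}\n")
        gtab.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def read_trial(
    path: str | Path, subject_id: str = "", trial_id: int = 0, side: str = "left"
) -> SyntheticTrial:
    """Read a trial file written by :func:`write_trial`."""
    text = Path(path).read_text().splitlines()
    blocks: list[tuple[float, list[str]]] = []
    for line in text:
        if line.startswith("#"):
            rate = float(line.split("rate=")[1])
            blocks.append((rate, []))
        elif line.strip():
            blocks[-1][1].append(line)
    if len(blocks) != 2:
        raise InputError(f"{path}: expected a markers and a grf block")
    (m_rate, m_lines), (g_rate, g_lines) = blocks
    from io import StringIO

    mtab = pd.read_csv(StringIO("\n".join(m_lines)), sep="\t")
    gtab = pd.read_csv(StringIO("\n".join(g_lines)), sep="\t")
    markers: dict[str, MarkerTrajectory] = {}
    labels = sorted(
        {c[:-5] for c in mtab.columns if c.endswith("_x[m]")}
    )
    for lab in labels:
        pos = mtab[[f"{lab}_{ax}[m]" for ax in "xyz"]].to_numpy()
        markers[lab] = MarkerTrajectory(label=lab, positions=pos, rate=m_rate)
    truth = {}
    for s in SIDES:
        cols = [f"truth_{s}_{j}[deg]" for j in JOINTS]
        if all(c in mtab.columns for c in cols):
            truth[s] = mtab[cols].to_numpy()
    grf = {s: gtab[f"grf_{s}[N]"].to_numpy() for s in SIDES}
    return SyntheticTrial(
        subject_id=subject_id,
        trial_id=trial_id,
        side=side,
        markers=markers,
        grf_vertical=grf,
        grf_rate=g_rate,
        marker_rate=m_rate,
        truth_angles=truth,
    )


def write_dataset(trials: list[SyntheticTrial], out_dir: str | Path) -> Path:
    """Write every trial plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in trials:
        name = f"{tr.subject_id}_t{tr.trial_id:02d}.tsv"
        write_trial(tr, out_dir / name)
        rows.append(
            {"subject_id": tr.subject_id, "trial_id": tr.trial_id, "side": tr.side, "path": name}
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest: str | Path) -> list[SyntheticTrial]:
    """Read every trial referenced by a manifest CSV."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    return [
        read_trial(
            manifest.parent / r.path,
            subject_id=r.subject_id,
            trial_id=int(r.trial_id),
            side=r.side,
        )
        for r in table.itertuples()
    ]


def write_matrices(
    X: np.ndarray, Y: np.ndarray, index: pd.DataFrame, stem: str | Path
) -> None:
    """Store assembled matrices as CSV with a JSON row-index sidecar."""
    stem = Path(stem)
    pd.DataFrame(X).to_csv(stem.with_suffix(".features.csv"), index=False)
    pd.DataFrame(Y).to_csv(stem.with_suffix(".targets.csv"), index=False)
    sidecar = {
        "rows": index.to_dict(orient="records"),
        "feature_channels": list(FEATURE_CHANNELS),
        "target_channels": list(TARGET_CHANNELS),
    }
    stem.with_suffix(".index.json").write_text(json.dumps(sidecar, indent=2))


def read_matrices(stem: str | Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    stem = Path(stem)
    X = pd.read_csv(stem.with_suffix(".features.csv")).to_numpy()
    Y = pd.read_csv(stem.with_suffix(".targets.csv")).to_numpy()
    sidecar = json.loads(stem.with_suffix(".index.json").read_text())
    return X, Y, pd.DataFrame(sidecar["rows"])


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline/grid configuration file."""
    with Path(path).open() as fh:
        return yaml.safe_load(fh) or {}
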
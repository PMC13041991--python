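"""Readers and writers for the formats the pipeline touches.

The canonical internal container for responses is a plain ``.npy``
grayordinate-by-time matrix (with a TSV fallback), so the full pipeline runs
without neuroimaging-format dependencies; CIFTI-2 dense time series are
supported through an optional nibabel-backed layer. Features and tabular
results travel as TSV with JSON sidecars; every written output carries
provenance (package version, master seed, config hash) sufficient to
regenerate it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix

DEFAULT_DISCARD_INITIAL = 10


@dataclass
class BoldMatrix:
    """Grayordinate-by-time responses for one subject/run at fixed TR."""

    values: np.ndarray
    tr_seconds: float = 0.8
    subject_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (grayordinates x time)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_grayordinates(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class RunMeta:
    subject_id: str = ""
    run_id: str = ""
    movie: str = ""
    tr_seconds: float = 0.8
    n_timepoints: int = 0
    fd_threshold: int | None = None
    discarded_initial: int = 0


def read_bold(
    path: str | Path,
    discard_initial: int = DEFAULT_DISCARD_INITIAL,
    tr_seconds: float | None = None,
) -> tuple[BoldMatrix, RunMeta]:
    """Read a grayordinate-by-time matrix, discarding initial volumes.

    Supported formats: ``.npy`` (grayordinates x time), ``.tsv``
    (grayordinates x time, no index), and CIFTI-2 ``.dtseries.nii`` via
    nibabel (stored time x grayordinate; transposed on load, TR taken from
    the series axis). For npy/tsv the TR must come from ``tr_seconds`` or a
    JSON sidecar.
    """
    path = Path(path)
    name = path.name
    if name.endswith(".dtseries.nii"):
        import nibabel as nib  # optional CIFTI layer

        img = nib.load(str(path))
        data = np.asarray(img.get_fdata()).T  # to grayordinates x time
        axis = img.header.get_axis(0)
        tr = float(getattr(axis, "step", 0.8))
    elif name.endswith(".npy"):
        data = np.load(path)
        tr = tr_seconds
    elif name.endswith(".tsv"):
        data = pd.read_csv(path, sep="\t", header=None).to_numpy(float)
        tr = tr_seconds
    else:
        raise ValueError(
            f"unsupported BOLD format {name!r}; supported: .npy, .tsv, .dtseries.nii"
        )
    if tr is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            tr = json.loads(sidecar.read_text()).get("tr_seconds")
    if tr is None:
        raise ValueError("TR not found: pass tr_seconds or provide a JSON sidecar")
    data = data[:, discard_initial:]
    bold = BoldMatrix(values=data, tr_seconds=float(tr))
    meta = RunMeta(tr_seconds=float(tr), n_timepoints=data.shape[1],
                   discarded_initial=discard_initial)
    return bold, meta


def write_bold(path: str | Path, bold: BoldMatrix, **sidecar_extra) -> None:
    path = Path(path)
    if path.name.endswith(".npy"):
        np.save(path, bold.values)
    elif path.name.endswith(".tsv"):
        pd.DataFrame(bold.values).to_csv(path, sep="\t", header=False, index=False)
    else:
        raise ValueError("write_bold supports .npy and .tsv")
    sidecar = {"tr_seconds": bold.tr_seconds, "subject_id": bold.subject_id,
               "run_id": bold.run_id, **sidecar_extra}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def concat_runs(runs: list[BoldMatrix]) -> BoldMatrix:
    """Concatenate runs end-to-end along the time axis (same grayordinates)."""
    if not runs:
        raise ValueError("no runs to concatenate")
    gs = {r.n_grayordinates for r in runs}
    trs = {r.tr_seconds for r in runs}
    if len(gs) != 1 or len(trs) != 1:
        raise ValueError("runs must share grayordinate count and TR")
    return BoldMatrix(
        values=np.concatenate([r.values for r in runs], axis=1),
        tr_seconds=runs[0].tr_seconds,
        subject_id=runs[0].subject_id,
    )


def write_features(path: str | Path, fm: FeatureMatrix, **sidecar_extra) -> None:
    """Write a feature matrix as TSV (one column per feature) + JSON sidecar."""
    path = Path(path)
    pd.DataFrame(fm.values, columns=fm.column_names).to_csv(
        path, sep="\t", index=False
    )
    meta = {
        "space_tag": fm.space_tag, "tr_seconds": fm.tr_seconds,
        "convolved": fm.convolved, "standardized": fm.standardized,
        **sidecar_extra,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )


def read_features(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FeatureMatrix(
        values=df.to_numpy(float),
        space_tag=meta["space_tag"],
        tr_seconds=meta["tr_seconds"],
        column_names=list(df.columns),
        convolved=meta.get("convolved", False),
        standardized=meta.get("standardized", False),
    )


def read_confounds_fd(path: str | Path) -> np.ndarray:
    """FD series from an fMRIPrep-style confounds TSV.

    Uses the ``framewise_displacement`` column; a leading ``n/a`` (the first
    volume has no predecessor) is treated as 0.
    """
    df = pd.read_csv(path, sep="\t")
    if "framewise_displacement" not in df.columns:
        raise ValueError("confounds file lacks a framewise_displacement column")
    fd = pd.to_numeric(df["framewise_displacement"], errors="coerce").to_numpy(float)
    if np.isnan(fd[0]):
        fd[0] = 0.0
    if np.isnan(fd).any():
        raise ValueError("framewise_displacement contains missing values beyond row 0")
    return fd


def provenance(config: dict | None = None, seed: int | None = None) -> dict:
    """Provenance block written next to every output."""
    from . import __version__

    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return {
        "software": "stackenc",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(blob).hexdigest(),
    }


def write_provenance(directory: str | Path, config: dict | None = None,
                     seed: int | None = None) -> Path:
    path = Path(directory) / "provenance.json"
    path.write_text(json.dumps(provenance(config, seed), indent=2, sort_keys=True))
    return path
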
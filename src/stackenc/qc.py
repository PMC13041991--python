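"""Motion quality control: framewise displacement and run exclusion.

Runs are excluded when the fraction of volumes with framewise displacement
(FD) above 0.2 mm exceeds a threshold; results are swept over 40%, 60%, and
80% thresholds so motion-driven sampling bias is visible rather than hidden
behind a single cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_FD_CUT_MM = 0.2
DEFAULT_FRACTION_THRESHOLDS = (0.40, 0.60, 0.80)


@dataclass
class MotionTrace:
    """Per-volume motion: six rigid-body parameters or a precomputed FD series.

    ``params`` has shape (n_volumes, 6): three translations in mm then three
    rotations in radians. Alternatively ``fd`` holds an FD series in mm.
    """

    params: np.ndarray | None = None
    fd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.params is None) == (self.fd is None):
            raise ValueError("provide exactly one of params or fd")
        if self.params is not None:
            self.params = np.asarray(self.params, dtype=float)
            if self.params.ndim != 2 or self.params.shape[1] != 6:
                raise ValueError("params must have shape (n_volumes, 6)")
        if self.fd is not None:
            self.fd = np.asarray(self.fd, dtype=float)
            if (self.fd < 0).any():
                raise ValueError("FD series must be nonnegative")


@dataclass
class QCRecord:
    """Fraction of high-motion volumes and pass flags at the sweep thresholds."""

    subject_id: str
    run_id: str
    fraction_over: float
    passes: dict[float, bool] = field(default_factory=dict)

    @property
    def pass_40(self) -> bool:
        return self.passes[0.40]

    @property
    def pass_60(self) -> bool:
        return self.passes[0.60]

    @property
    def pass_80(self) -> bool:
        return self.passes[0.80]


def framewise_displacement(
    trace: MotionTrace | np.ndarray, rotation_radius_mm: float = 50.0
) -> np.ndarray:
    """Power-style framewise displacement from six rigid-body parameters.

    FD_t = sum |Δ translation| + radius × sum |Δ rotation|, with rotations
    converted to arc length on a sphere of ``rotation_radius_mm`` (default
    50 mm, the fMRIPrep convention). The first volume's FD is 0.
    """
    if rotation_radius_mm <= 0:
        raise ValueError("rotation_radius_mm must be positive")
    if isinstance(trace, MotionTrace):
        if trace.fd is not None:
            return trace.fd.copy()
        params = trace.params
    else:
        params = np.asarray(trace, dtype=float)
    if params.shape[0] < 2:
        raise ValueError("at least 2 volumes are required to compute FD")
    deltas = np.abs(np.diff(params, axis=0))
    fd = deltas[:, :3].sum(axis=1) + rotation_radius_mm * deltas[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def fd_exclusion(
    fd: np.ndarray,
    fd_cut_mm: float = DEFAULT_FD_CUT_MM,
    fraction_thresholds: tuple[float, ...] = DEFAULT_FRACTION_THRESHOLDS,
    *,
    subject_id: str = "",
    run_id: str = "",
) -> QCRecord:
    """Apply the fraction-based run-exclusion rule at each sweep threshold.

    A run fails a threshold iff the fraction of volumes with FD strictly above
    ``fd_cut_mm`` strictly exceeds that threshold ("greater than" semantics on
    both comparisons; a fraction of exactly 0.40 passes the 40% threshold).
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("FD series is empty")
    if any(not (0 < t <= 1) for t in fraction_thresholds):
        raise ValueError("fraction thresholds must lie in (0, 1]")
    fraction_over = float(np.mean(fd > fd_cut_mm))
    passes = {float(t): fraction_over <= t for t in fraction_thresholds}
    return QCRecord(
        subject_id=subject_id,
        run_id=run_id,
        fraction_over=fraction_over,
        passes=passes,
    )
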
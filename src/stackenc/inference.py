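"""Grayordinate significance, FDR, parcel pooling, and noise ceilings.

Significance of each grayordinate's stacked model is assessed against a
temporal-permutation null: the response time series is reordered, the full
fit procedure is rerun, and the observed statistic is ranked among the null
statistics with the add-one estimator p = (1 + #{null >= obs}) / (1 + B).
Benjamini-Hochberg FDR correction is applied across grayordinates within a
subject and model; parcel summaries average metrics over the surviving
grayordinates. Split-half Spearman-Brown noise ceilings bound attainable
performance per parcel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    observed: np.ndarray      # (G,)
    null: np.ndarray          # (n_perm, G)
    p: np.ndarray             # (G,)
    n_perm: int
    scheme: str


def _permute_indices(
    t: int, scheme: str, block_len: int | None, rng: np.random.Generator
) -> np.ndarray:
    if scheme == "full":
        return rng.permutation(t)
    if scheme == "block":
        if not block_len or block_len < 1:
            raise ValueError("block scheme requires a positive block_len")
        starts = np.arange(0, t, block_len)
        order = rng.permutation(len(starts))
        idx = np.concatenate(
            [np.arange(starts[i], min(starts[i] + block_len, t)) for i in order]
        )
        return idx
    raise ValueError(f"unknown permutation scheme {scheme!r}")


def permutation_null(
    fit_statistic: Callable[[np.ndarray], np.ndarray],
    responses: np.ndarray,
    observed_stat: np.ndarray | float,
    n_perm: int = 1000,
    *,
    scheme: str = "full",
    block_len: int | None = None,
    seed: int = 0,
) -> PermutationResult:
    """Temporal-permutation null for per-grayordinate statistics.

    ``fit_statistic`` runs the full fit procedure on a (T, G) response matrix
    and returns the statistic (stacked held-out R^2) per grayordinate. Each
    iteration permutes the temporal order of the responses — a full shuffle
    by default, matching the way the null is usually stated; an optional
    ``block`` scheme permutes contiguous blocks for autocorrelation-aware
    nulls — then refits and rescores. Note full shuffles are anticonservative
    under autocorrelated noise.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(responses, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    observed = np.atleast_1d(np.asarray(observed_stat, dtype=float))
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, observed.size))
    for b in range(n_perm):
        idx = _permute_indices(y.shape[0], scheme, block_len, rng)
        null[b] = np.atleast_1d(fit_statistic(y[idx]))
    exceed = np.sum(null >= observed[None, :], axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermutationResult(observed=observed, null=null, p=p,
                             n_perm=n_perm, scheme=scheme)


def fdr_bh(
    p_values: Sequence[float], q_level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment with significance flags.

    Returns (q, flags) where q are the monotonicity-enforced adjusted values
    and flags = (q <= q_level). Empty input returns empty arrays.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, q <= q_level


def pool_parcels(
    metrics: pd.DataFrame,
    flags: np.ndarray,
    parcel_labels: Sequence[str],
    *,
    subject_id: str = "",
) -> pd.DataFrame:
    """Average metrics over FDR-significant grayordinates within parcels.

    ``metrics`` is grayordinate-by-metric; ``flags`` marks significant
    grayordinates; ``parcel_labels`` assigns each grayordinate to a parcel
    (empty/NaN labels are excluded and counted in a logged remainder).
    Parcels with no significant grayordinate report NaN metrics and
    n_significant = 0. The pooled mean is unweighted and invariant to
    grayordinate order.
    """
    flags = np.asarray(flags, dtype=bool)
    labels = pd.Series(parcel_labels, dtype="object").reset_index(drop=True)
    if not (len(labels) == len(flags) == len(metrics)):
        raise ValueError("metrics, flags, and parcel_labels must align")
    unlabeled = labels.isna() | (labels.astype(str).str.strip() == "")
    if unlabeled.any():
        logger.info("%d grayordinate(s) without a parcel label excluded from pooling",
                    int(unlabeled.sum()))
    rows = []
    metrics = metrics.reset_index(drop=True)
    for parcel in sorted(labels[~unlabeled].unique()):
        in_parcel = (labels == parcel).to_numpy()
        sig = in_parcel & flags
        row = {"subject_id": subject_id, "parcel": parcel,
               "n_significant": int(sig.sum()), "n_total": int(in_parcel.sum())}
        for col in metrics.columns:
            row[col] = float(metrics.loc[sig, col].mean()) if sig.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def spearman_brown(r: np.ndarray | float) -> np.ndarray | float:
    """Spearman-Brown prophecy correction 2r / (1 + r) for a split-half r."""
    r = np.asarray(r, dtype=float)
    out = 2.0 * r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


@dataclass
class NoiseCeiling:
    parcel: str
    split_half_r: float
    corrected_r: float
    r2_ceiling: float


def split_half_noise_ceiling(
    responses: np.ndarray,
    parcel_names: Sequence[str] | None = None,
    n_splits: int = 50,
    seed: int = 0,
) -> list[NoiseCeiling]:
    """Split-half, Spearman-Brown-corrected noise ceilings per parcel.

    ``responses`` is (n_subjects, n_parcels, T): per-subject parcel-mean time
    series. Subjects are randomly split into halves; per parcel, the Pearson
    correlation between the two half-average series is averaged over
    ``n_splits`` splits, corrected with the Spearman-Brown formula, and
    squared to give an upper bound on achievable R^2.
    """
    y = np.asarray(responses, dtype=float)
    if y.ndim != 3:
        raise ValueError("responses must be (n_subjects, n_parcels, T)")
    n_sub, n_parc, _ = y.shape
    if n_sub < 4:
        raise ValueError("at least 4 subjects are required for split-half ceilings")
    if parcel_names is None:
        parcel_names = [f"parcel{i}" for i in range(n_parc)]
    rng = np.random.default_rng(seed)
    r_acc = np.zeros(n_parc)
    for _ in range(n_splits):
        order = rng.permutation(n_sub)
        half_a = y[order[: n_sub // 2]].mean(axis=0)
        half_b = y[order[n_sub // 2 :]].mean(axis=0)
        a = half_a - half_a.mean(axis=1, keepdims=True)
        b = half_b - half_b.mean(axis=1, keepdims=True)
        denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r_acc += np.where(denom > 0, (a * b).sum(axis=1) / denom, np.nan)
    r = r_acc / n_splits
    r_sb = spearman_brown(r)
    return [
        NoiseCeiling(parcel=str(parcel_names[i]), split_half_r=float(r[i]),
                     corrected_r=float(r_sb[i]), r2_ceiling=float(r_sb[i] ** 2))
        for i in range(n_parc)
    ]
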
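"""End-to-end orchestration: per-subject fits to parcel-wise group models.

One subject's analysis is: fit the stacked encoding model over the feature
spaces, test each grayordinate's stacked R^2 against a temporal-permutation
null, FDR-correct across grayordinates, and average metrics over the
surviving grayordinates within parcels. Parcel summaries across subjects
then feed the mixed-effects group models.

Permutation iterations refit ridge coefficients and stacking weights on the
permuted responses but reuse the ridge penalties selected on the observed
data (penalty re-selection inside the null would multiply the cost ~80x
without changing the statistic's meaning).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .encoding import (
    StackedFit,
    build_stacked_cache,
    fit_stacked,
    partition_unique_r2,
    preference_index,
)
from .inference import fdr_bh, permutation_null, pool_parcels

DEFAULT_METRICS = (
    "stacked_r2", "pref_high_vs_low_audio", "pref_high_vs_low_visual",
)


def subject_metrics(fit: StackedFit) -> pd.DataFrame:
    """Grayordinate-by-metric table from one stacked fit.

    Emits the stacked held-out R^2, per-space R^2 and stacking weights,
    high-vs-low preference indices per modality, and unique low/high-level
    R^2 within each modality by clipped subtraction against the stacked R^2.
    """
    out = {"stacked_r2": fit.stacked_r2}
    for ki, name in enumerate(fit.space_names):
        out[f"r2_{name}"] = fit.space_r2[:, ki]
        out[f"alpha_{name}"] = fit.alphas[:, ki]
    for modality in ("audio", "visual"):
        hi, lo = f"{modality}-high", f"{modality}-low"
        if hi in fit.space_names and lo in fit.space_names:
            out[f"pref_high_vs_low_{modality}"] = preference_index(
                fit, f"high_vs_low_{modality}"
            ).value
            out[f"unique_{modality}_low"] = partition_unique_r2(
                fit.stacked_r2, fit.space_r2[:, fit.space_names.index(hi)]
            )
            out[f"unique_{modality}_high"] = partition_unique_r2(
                fit.stacked_r2, fit.space_r2[:, fit.space_names.index(lo)]
            )
    if "visual" in fit.space_names and "audio" in fit.space_names:
        out["pref_visual_vs_audio"] = preference_index(
            fit, "visual_vs_audio"
        ).value
    return pd.DataFrame(out)


def fit_subject(
    designs: dict[str, np.ndarray],
    responses: np.ndarray,
    *,
    n_folds: int = 5,
    inner_k: int = 4,
    penalty_grid=None,
) -> tuple[StackedFit, pd.DataFrame]:
    """Fit one subject's stacked model and derive the metric table.

    ``responses`` is (T, G) (a :class:`~stackenc.io.BoldMatrix` is accepted
    and transposed).
    """
    y = responses.values.T if hasattr(responses, "values") else np.asarray(responses)
    kwargs = {} if penalty_grid is None else {"penalty_grid": penalty_grid}
    fit = fit_stacked(designs, y, n_folds=n_folds, inner_k=inner_k, **kwargs)
    return fit, subject_metrics(fit)


def grayordinate_significance(
    designs: dict[str, np.ndarray],
    responses: np.ndarray,
    fit: StackedFit,
    *,
    n_perm: int = 1000,
    scheme: str = "full",
    block_len: int | None = None,
    seed: int = 0,
    q_level: float = 0.05,
    reuse_penalties: bool = True,
) -> pd.DataFrame:
    """Permutation p, BH q, and significance flag per grayordinate.

    With ``reuse_penalties=True`` (default) null refits keep the ridge
    penalties selected on the observed data; ``False`` re-selects penalties
    inside every iteration, making null and observed fits fully exchangeable
    at a higher cost.
    """
    y = responses.values.T if hasattr(responses, "values") else np.asarray(responses)
    cache = build_stacked_cache(designs, y.shape[0], n_folds=len(fit.folds))
    fixed = fit.penalties if reuse_penalties else None

    def refit_statistic(y_perm: np.ndarray) -> np.ndarray:
        perm_fit = fit_stacked(
            designs, y_perm, n_folds=len(fit.folds),
            fixed_penalties=fixed, cache=cache,
        )
        return perm_fit.stacked_r2

    result = permutation_null(
        refit_statistic, y, fit.stacked_r2, n_perm,
        scheme=scheme, block_len=block_len, seed=seed,
    )
    q, flags = fdr_bh(result.p, q_level)
    return pd.DataFrame({"p": result.p, "q": q, "significant": flags})


def run_study(
    designs: dict[str, np.ndarray],
    bold: dict[str, np.ndarray],
    parcel_labels: np.ndarray | dict[str, np.ndarray],
    *,
    n_folds: int = 5,
    n_perm: int = 100,
    seed: int = 0,
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Per-subject fit, permutation significance, and parcel pooling.

    Returns the long-format parcel-summary table (one row per subject and
    parcel) that the group models consume. ``parcel_labels`` may be shared
    across subjects or a per-subject mapping. Per-subject permutation seeds
    derive from the master ``seed``.
    """
    rows = []
    for i, (sid, y) in enumerate(bold.items()):
        fit, metrics = fit_subject(designs, y, n_folds=n_folds)
        sig = grayordinate_significance(
            designs, y, fit, n_perm=n_perm, seed=seed + 7919 * (i + 1),
            q_level=q_level,
        )
        labels = (parcel_labels[sid] if isinstance(parcel_labels, dict)
                  else parcel_labels)
        summary = pool_parcels(
            metrics, sig["significant"].to_numpy(), labels, subject_id=sid
        )
        rows.append(summary)
    return pd.concat(rows, ignore_index=True)
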
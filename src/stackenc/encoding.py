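"""Stacked ridge encoding models.

Each feature space gets its own ridge regression per grayordinate, evaluated
with 5-fold cross-validation over contiguous time blocks (train on 80% of the
movie, test on the held-out 20%). The per-space held-out predictions are then
combined by a stacking stage that solves, per grayordinate, the convex
quadratic program

    minimise  || y - sum_k alpha_k yhat_k ||^2
    subject to alpha_k >= 0,  sum_k alpha_k = 1,

so the stacking weights alpha form a probability vector over feature spaces
and directly index each space's relative contribution. Derived metrics are
the stacked and per-space held-out R^2, unique R^2 by clipped subtraction,
and weight-difference preference indices (W_H - W_L, W_V - W_A).

Ridge solutions are computed on a shared SVD of the design so that all
grayordinates and all penalties are handled with dense matrix products; the
stacking QP is solved exactly by enumerating support sets of the KKT system
(the number of feature spaces is small).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

#: Log-spaced ridge penalty grid (inner-CV candidates).
DEFAULT_PENALTY_GRID = np.logspace(-2, 5, 20)

CONTRASTS = {
    "high_vs_low_audio": ("audio-high", "audio-low"),
    "high_vs_low_visual": ("visual-high", "visual-low"),
    "visual_vs_audio": ("visual", "audio"),
}


# ---------------------------------------------------------------------------
# Folds and scoring
# ---------------------------------------------------------------------------

def make_folds(n_timepoints: int, k: int = 5) -> list[np.ndarray]:
    """Split the time axis into k contiguous, non-overlapping blocks.

    Block sizes differ by at most one; the remainder goes to the earliest
    blocks (deterministic). Blocks partition ``range(n_timepoints)``.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n_timepoints:
        raise ValueError(f"k={k} exceeds n_timepoints={n_timepoints}")
    base, rem = divmod(n_timepoints, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(k)]


def score_r2(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    SS_tot is taken about the mean of the evaluated segment of ``observed``;
    the value can be negative. A constant observed series leaves R^2
    undefined and returns NaN with a warning.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or observed.shape[0] < 2:
        raise ValueError("predicted and observed must share a length >= 2")
    ss_tot = np.sum((observed - observed.mean()) ** 2)
    if ss_tot == 0:
        warnings.warn("constant observed series: R^2 undefined", stacklevel=2)
        return float("nan")
    ss_res = np.sum((observed - predicted) ** 2)
    return float(1.0 - ss_res / ss_tot)


def _r2_columns(predicted: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Columnwise R^2 for (T, G) arrays; constant columns give NaN."""
    resid = np.sum((observed - predicted) ** 2, axis=0)
    ss_tot = np.sum((observed - observed.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 - resid / ss_tot
    out[ss_tot == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# Ridge on a shared SVD
# ---------------------------------------------------------------------------

def _ridge_predict_grid(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_eval: np.ndarray,
    penalties: np.ndarray,
) -> np.ndarray:
    """Ridge predictions on ``x_eval`` for every penalty at once.

    Fits include an intercept (train means are removed and added back).
    Returns an array of shape (n_penalties, n_eval, n_targets).
    """
    xm = x_train.mean(axis=0)
    ym = y_train.mean(axis=0)
    u, s, vt = np.linalg.svd(x_train - xm, full_matrices=False)
    uty = u.T @ (y_train - ym)            # (r, G)
    ev = (x_eval - xm) @ vt.T             # (n_eval, r)
    out = np.empty((len(penalties), x_eval.shape[0], y_train.shape[1]))
    for i, lam in enumerate(penalties):
        d = s / (s**2 + lam)
        out[i] = ev @ (d[:, None] * uty) + ym
    return out


def _ridge_coef(
    x_train: np.ndarray, y_train: np.ndarray, penalty_per_target: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-target ridge coefficients and intercepts (targets may differ in penalty)."""
    xm = x_train.mean(axis=0)
    ym = y_train.mean(axis=0)
    u, s, vt = np.linalg.svd(x_train - xm, full_matrices=False)
    uty = u.T @ (y_train - ym)
    coef = np.empty((y_train.shape[1], x_train.shape[1]))
    for lam in np.unique(penalty_per_target):
        cols = penalty_per_target == lam
        d = s / (s**2 + lam)
        coef[cols] = (vt.T @ (d[:, None] * uty[:, cols])).T
    intercept = ym - coef @ xm
    return coef, intercept


def _select_penalties(
    x: np.ndarray,
    y: np.ndarray,
    penalty_grid: np.ndarray,
    inner_k: int,
) -> np.ndarray:
    """Choose one penalty per target by contiguous inner cross-validation."""
    inner = make_folds(x.shape[0], inner_k)
    sse = np.zeros((len(penalty_grid), y.shape[1]))
    for val in inner:
        tr = np.setdiff1d(np.arange(x.shape[0]), val)
        preds = _ridge_predict_grid(x[tr], y[tr], x[val], penalty_grid)
        sse += np.sum((preds - y[val][None]) ** 2, axis=1)
    return penalty_grid[np.argmin(sse, axis=0)]


@dataclass
class RidgeFit:
    """Cross-validated ridge fit for one feature space.

    ``heldout_pred`` concatenates out-of-fold predictions so every timepoint
    is predicted exactly once by a model that never saw it.
    """

    heldout_pred: np.ndarray          # (T, G)
    penalties: np.ndarray             # (n_folds, G) selected per outer fold
    folds: list[np.ndarray]
    coef: np.ndarray                  # (G, p) mean over outer folds
    r2: np.ndarray                    # (G,) held-out R^2

    def __post_init__(self) -> None:
        idx = np.sort(np.concatenate(self.folds))
        if not np.array_equal(idx, np.arange(self.heldout_pred.shape[0])):
            raise ValueError("folds must partition the time axis")


def fit_ridge_cv(
    design,
    response: np.ndarray,
    folds: list[np.ndarray] | None = None,
    penalty_grid: np.ndarray = DEFAULT_PENALTY_GRID,
    *,
    inner_k: int = 4,
) -> RidgeFit:
    """Fit per-grayordinate ridge models with nested cross-validation.

    For each outer fold, the penalty is chosen per grayordinate by
    ``inner_k``-fold contiguous cross-validation on the training block only;
    coefficients are then fit on the full training block and predictions
    emitted for the held-out block. ``response`` may be a single series (T,)
    or a matrix (T, G). Zero-variance responses are fit but their R^2 is NaN
    (flagged for downstream exclusion).
    """
    x = design.values if hasattr(design, "values") else np.asarray(design, float)
    y = np.asarray(response, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError("design and response must share the time axis")
    penalty_grid = np.asarray(penalty_grid, dtype=float)
    if penalty_grid.size == 0 or (penalty_grid <= 0).any():
        raise ValueError("penalty_grid must be nonempty and positive")
    if folds is None:
        folds = make_folds(x.shape[0], 5)

    t_all = np.arange(x.shape[0])
    heldout = np.empty_like(y)
    chosen = np.empty((len(folds), y.shape[1]))
    coefs = np.zeros((y.shape[1], x.shape[1]))
    for i, test in enumerate(folds):
        train = np.setdiff1d(t_all, test)
        lam = _select_penalties(x[train], y[train], penalty_grid, inner_k)
        coef, intercept = _ridge_coef(x[train], y[train], lam)
        heldout[test] = x[test] @ coef.T + intercept
        chosen[i] = lam
        coefs += coef
    coefs /= len(folds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r2 = _r2_columns(heldout, y)
    if squeeze:
        heldout = heldout[:, 0]
    return RidgeFit(heldout_pred=heldout, penalties=chosen, folds=folds,
                    coef=coefs, r2=r2)


# ---------------------------------------------------------------------------
# Simplex-constrained stacking
# ---------------------------------------------------------------------------

def simplex_lstsq(predictions: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Exact nonnegative, sum-to-one least squares over a few predictors.

    Solves min ||y - P a||^2 on the probability simplex by enumerating
    support sets of the KKT system. Singular faces (e.g. identical
    predictors) are solved in the minimum-norm sense, which makes the
    documented tie-break — uniform weights on a flat objective — automatic.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(observed, dtype=float)
    if p.ndim != 2 or p.shape[0] != y.shape[0]:
        raise ValueError("predictions must be (T, K) sharing the time axis with observed")
    k = p.shape[1]
    if k < 2:
        raise ValueError("stacking needs at least 2 feature spaces")
    gram = p.T @ p
    lin = p.T @ y

    best_obj, best_norm, best_alpha = np.inf, np.inf, None
    for m in range(1, k + 1):
        for support in itertools.combinations(range(k), m):
            idx = np.array(support)
            kkt = np.zeros((m + 1, m + 1))
            kkt[:m, :m] = gram[np.ix_(idx, idx)]
            kkt[:m, m] = 1.0
            kkt[m, :m] = 1.0
            rhs = np.concatenate([lin[idx], [1.0]])
            sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
            a = sol[:m]
            if a.min() < -1e-9 or abs(a.sum() - 1.0) > 1e-6:
                continue
            obj = 0.5 * a @ gram[np.ix_(idx, idx)] @ a - lin[idx] @ a
            norm = float(a @ a)
            if obj < best_obj - 1e-10 or (
                obj < best_obj + 1e-10 and norm < best_norm - 1e-12
            ):
                best_obj, best_norm = min(obj, best_obj), norm
                best_alpha = np.zeros(k)
                best_alpha[idx] = a
    if best_alpha is None:  # numerically degenerate input; flat objective
        best_alpha = np.full(k, 1.0 / k)
    best_alpha = np.clip(best_alpha, 0.0, None)
    return best_alpha / best_alpha.sum()


def _simplex_lstsq_batch(predictions: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Vectorised :func:`simplex_lstsq` over grayordinates.

    ``predictions`` is (T, G, K), ``observed`` is (T, G); returns (G, K).
    Identical semantics to the scalar solver: exact support enumeration with
    minimum-norm solves on singular faces (uniform tie-break on flat
    objectives).
    """
    t, g, k = predictions.shape
    gram = np.einsum("tgk,tgl->gkl", predictions, predictions)
    lin = np.einsum("tgk,tg->gk", predictions, observed)

    best_obj = np.full(g, np.inf)
    best_norm = np.full(g, np.inf)
    best_alpha = np.full((g, k), 1.0 / k)
    for m in range(1, k + 1):
        for support in itertools.combinations(range(k), m):
            idx = np.array(support)
            kkt = np.zeros((g, m + 1, m + 1))
            kkt[:, :m, :m] = gram[:, idx[:, None], idx[None, :]]
            kkt[:, :m, m] = 1.0
            kkt[:, m, :m] = 1.0
            rhs = np.concatenate([lin[:, idx], np.ones((g, 1))], axis=1)
            try:
                sol = np.linalg.solve(kkt, rhs[..., None])[..., 0]
                if not np.isfinite(sol).all():
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                # singular faces (e.g. identical predictors): minimum-norm
                # solve keeps the uniform tie-break
                sol = np.einsum("gij,gj->gi", np.linalg.pinv(kkt), rhs)
            a = sol[:, :m]
            feasible = (a.min(axis=1) >= -1e-9) & (
                np.abs(a.sum(axis=1) - 1.0) <= 1e-6
            )
            obj = 0.5 * np.einsum(
                "gi,gij,gj->g", a, gram[:, idx[:, None], idx[None, :]], a
            ) - np.einsum("gi,gi->g", lin[:, idx], a)
            norm = np.einsum("gi,gi->g", a, a)
            better = feasible & (
                (obj < best_obj - 1e-10)
                | ((obj < best_obj + 1e-10) & (norm < best_norm - 1e-12))
            )
            if better.any():
                best_obj[better] = np.minimum(obj[better], best_obj[better])
                best_norm[better] = norm[better]
                best_alpha[better] = 0.0
                best_alpha[np.ix_(better, idx)] = a[better]
    best_alpha = np.clip(best_alpha, 0.0, None)
    return best_alpha / best_alpha.sum(axis=1, keepdims=True)


def simplex_grid_search(
    predictions: np.ndarray, observed: np.ndarray, step: float = 0.005
) -> np.ndarray:
    """Brute-force simplex search over a regular grid (oracle / fallback).

    Enumerates all weight vectors with coordinates that are multiples of
    ``step`` summing to one and returns the residual minimiser. Exponential
    in the number of spaces; intended for small K.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(observed, dtype=float)
    k = p.shape[1]
    n = round(1.0 / step)

    best, best_obj = None, np.inf
    for combo in itertools.combinations(range(n + k - 1), k - 1):
        parts = np.diff(np.concatenate([[-1], combo, [n + k - 1]])) - 1
        a = parts / n
        resid = y - p @ a
        obj = resid @ resid
        if obj < best_obj:
            best_obj, best = obj, a
    return best


def _zscore_cols(a: np.ndarray) -> np.ndarray:
    """Z-score columns; (near-)constant columns become zeros."""
    mean = a.mean(axis=0)
    sd = a.std(axis=0)
    out = np.zeros_like(a)
    live = sd > 1e-12
    out[:, live] = (a[:, live] - mean[live]) / sd[live]
    return out


def _zscore_block(a: np.ndarray) -> np.ndarray:
    """Z-score a (T, G, K) block over time; near-constant series become zeros."""
    mean = a.mean(axis=0)
    sd = a.std(axis=0)
    live = sd > 1e-12
    out = np.zeros_like(a)
    np.divide(a - mean, sd, out=out, where=live)
    return out


@dataclass
class StackedSlice:
    """Stacking solution for one grayordinate on one training block."""

    alpha: np.ndarray
    prediction: np.ndarray
    r2: float


def stack_models(
    heldout_predictions: np.ndarray, observed: np.ndarray
) -> StackedSlice:
    """Combine per-space predictions with convex stacking weights.

    ``heldout_predictions`` is (T, K) with one column per feature space.
    Returns the simplex-constrained least-squares weights, the stacked
    prediction, and its R^2 against ``observed``.
    """
    alpha = simplex_lstsq(heldout_predictions, observed)
    pred = heldout_predictions @ alpha
    return StackedSlice(alpha=alpha, prediction=pred, r2=score_r2(pred, observed))


# ---------------------------------------------------------------------------
# Full stacked fit
# ---------------------------------------------------------------------------

@dataclass
class StackedFit:
    """Per-grayordinate stacked encoding fit across feature spaces."""

    space_names: list[str]
    alphas: np.ndarray                # (G, K), mean over outer folds
    fold_alphas: np.ndarray           # (n_folds, G, K)
    space_r2: np.ndarray              # (G, K) held-out R^2 per space
    stacked_r2: np.ndarray            # (G,)
    heldout_space_pred: np.ndarray    # (T, G, K)
    heldout_stacked_pred: np.ndarray  # (T, G)
    folds: list[np.ndarray] = field(default_factory=list)
    penalties: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alphas.size:
            if self.alphas.min() < -1e-10:
                raise ValueError("stacking weights must be nonnegative")
            if np.abs(self.alphas.sum(axis=1) - 1.0).max() > 1e-8:
                raise ValueError("stacking weights must sum to one")

    def weight(self, space: str) -> np.ndarray:
        return self.alphas[:, self.space_names.index(space)]


class _FoldDesignCache:
    """Precomputed SVD factors of each space's design on every fold block.

    Under temporal permutation of the responses the designs never change, so
    permutation refits reuse these factors and reduce to matrix products.
    """

    def __init__(self, xs: dict[str, np.ndarray], folds: list[np.ndarray],
                 inner_k: int):
        t = next(iter(xs.values())).shape[0]
        t_all = np.arange(t)
        self.folds = folds
        self.inner_k = inner_k
        self.train_idx = []
        self.inner_folds = []
        self.factors = {}       # (fold, space) -> svd of train block
        self.sub_factors = {}   # (fold, space, inner) -> svd of sub block
        for i, test in enumerate(folds):
            train = np.setdiff1d(t_all, test)
            self.train_idx.append(train)
            inner = make_folds(train.size, inner_k)
            self.inner_folds.append(inner)
            for name, x in xs.items():
                self.factors[(i, name)] = self._factor(x[train], x[test])
                for j, val in enumerate(inner):
                    sub = np.setdiff1d(np.arange(train.size), val)
                    self.sub_factors[(i, name, j)] = self._factor(
                        x[train][sub], x[train][val]
                    )

    @staticmethod
    def _factor(x_train, x_eval):
        xm = x_train.mean(axis=0)
        u, s, vt = np.linalg.svd(x_train - xm, full_matrices=False)
        return {"u": u, "s": s, "ev": (x_eval - xm) @ vt.T}

    @staticmethod
    def predict(factor, y_train, penalty_per_target):
        """Ridge predictions on the cached eval block, one penalty per target."""
        ym = y_train.mean(axis=0)
        uty = factor["u"].T @ (y_train - ym)
        s = factor["s"]
        out = np.empty((factor["ev"].shape[0], y_train.shape[1]))
        for lam in np.unique(penalty_per_target):
            cols = penalty_per_target == lam
            d = s / (s**2 + lam)
            out[:, cols] = factor["ev"] @ (d[:, None] * uty[:, cols])
        return out + ym

    def select_penalties(self, fold: int, space: str, y_train: np.ndarray,
                         penalty_grid: np.ndarray) -> np.ndarray:
        sse = np.zeros((len(penalty_grid), y_train.shape[1]))
        for j, val in enumerate(self.inner_folds[fold]):
            factor = self.sub_factors[(fold, space, j)]
            sub = np.setdiff1d(np.arange(y_train.shape[0]), val)
            ym = y_train[sub].mean(axis=0)
            uty = factor["u"].T @ (y_train[sub] - ym)
            s = factor["s"]
            for li, lam in enumerate(penalty_grid):
                d = s / (s**2 + lam)
                pred = factor["ev"] @ (d[:, None] * uty) + ym
                sse[li] += np.sum((pred - y_train[val]) ** 2, axis=0)
        return penalty_grid[np.argmin(sse, axis=0)]


def build_stacked_cache(
    designs: dict[str, np.ndarray], n_timepoints: int, *,
    n_folds: int = 5, inner_k: int = 4,
) -> _FoldDesignCache:
    """Precompute fold-wise design factors for repeated stacked fits."""
    xs = {
        k: (v.values if hasattr(v, "values") else np.asarray(v, float))
        for k, v in designs.items()
    }
    return _FoldDesignCache(xs, make_folds(n_timepoints, n_folds), inner_k)


def fit_stacked(
    designs: dict[str, np.ndarray],
    responses: np.ndarray,
    *,
    n_folds: int = 5,
    inner_k: int = 4,
    penalty_grid: np.ndarray = DEFAULT_PENALTY_GRID,
    fixed_penalties: dict[str, np.ndarray] | None = None,
    cache: _FoldDesignCache | None = None,
) -> StackedFit:
    """Fit the full stacked encoding model for all grayordinates.

    ``designs`` maps feature-space names to (T, p_k) design matrices;
    ``responses`` is (T, G). Within each outer training block, each space's
    ridge penalty is selected per grayordinate by inner cross-validation and
    out-of-fold predictions are generated on that block; the stacking weights
    are solved on those out-of-fold predictions and then evaluated on the
    outer held-out block, so the stacking stage never sees its own
    evaluation data.

    Base-model predictions are z-scored (within block, per grayordinate and
    space) before the stacking solve and the stacked prediction, so the
    weights index each space's relative contribution rather than the raw
    amplitude of its prediction: a space whose standardized prediction
    carries a fraction w of the response signal receives weight w.

    ``fixed_penalties`` (as returned in ``StackedFit.penalties``) bypasses the
    inner penalty selection — used by permutation nulls to keep iterations
    affordable while still refitting coefficients and weights.
    """
    names = list(designs)
    xs = {
        k: (v.values if hasattr(v, "values") else np.asarray(v, float))
        for k, v in designs.items()
    }
    y = np.asarray(responses, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    t = y.shape[0]
    for k, x in xs.items():
        if x.shape[0] != t:
            raise ValueError(f"design {k!r} does not share the response time axis")
    g = y.shape[1]
    nk = len(names)
    if cache is None:
        cache = _FoldDesignCache(xs, make_folds(t, n_folds), inner_k)
    folds = cache.folds

    heldout_space = np.empty((t, g, nk))
    heldout_stacked = np.empty((t, g))
    fold_alphas = np.empty((len(folds), g, nk))
    penalties_out = {k: np.empty((len(folds), g)) for k in names}

    for i, test in enumerate(folds):
        train = cache.train_idx[i]
        oof = np.empty((train.size, g, nk))
        test_pred = np.empty((test.size, g, nk))
        for ki, name in enumerate(names):
            if fixed_penalties is not None:
                lam = np.asarray(fixed_penalties[name][i], dtype=float)
            else:
                lam = cache.select_penalties(i, name, y[train], penalty_grid)
            penalties_out[name][i] = lam
            # out-of-fold predictions inside the training block
            for j, val in enumerate(cache.inner_folds[i]):
                sub = np.setdiff1d(np.arange(train.size), val)
                oof[val, :, ki] = cache.predict(
                    cache.sub_factors[(i, name, j)], y[train][sub], lam
                )
            test_pred[:, :, ki] = cache.predict(
                cache.factors[(i, name)], y[train], lam
            )
        ym = y[train].mean(axis=0)
        oof_z = _zscore_block(oof)
        test_z = _zscore_block(test_pred)
        alpha = _simplex_lstsq_batch(oof_z, y[train] - ym)
        fold_alphas[i] = alpha
        heldout_stacked[test] = ym + np.einsum("tgk,gk->tg", test_z, alpha)
        heldout_space[test] = test_pred

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        space_r2 = np.stack(
            [_r2_columns(heldout_space[:, :, ki], y) for ki in range(nk)], axis=1
        )
        stacked_r2 = _r2_columns(heldout_stacked, y)
    return StackedFit(
        space_names=names,
        alphas=fold_alphas.mean(axis=0),
        fold_alphas=fold_alphas,
        space_r2=space_r2,
        stacked_r2=stacked_r2,
        heldout_space_pred=heldout_space,
        heldout_stacked_pred=heldout_stacked,
        folds=folds,
        penalties=penalties_out,
    )


# ---------------------------------------------------------------------------
# Variance partitioning and preference indices
# ---------------------------------------------------------------------------

def clip_component_r2(stacked_r2, component_r2):
    """Clip a component R^2 for the unique-variance subtraction.

    Negative component R^2 is clipped to zero; a component exceeding the
    stacked R^2 is set to the stacked R^2.
    """
    stacked = np.asarray(stacked_r2, dtype=float)
    comp = np.clip(np.asarray(component_r2, dtype=float), 0.0, None)
    return np.where(comp > stacked, stacked, comp)


def partition_unique_r2(stacked_r2, component_r2):
    """Unique R^2 of the complementary space by clipped subtraction.

    unique = stacked - component, after clipping: a negative component is
    treated as zero (unique = stacked); a component exceeding the stacked
    R^2 yields unique = 0. By construction
    ``unique + clip_component_r2(stacked, component) == stacked`` in every
    branch.
    """
    stacked = np.asarray(stacked_r2, dtype=float)
    clipped = clip_component_r2(stacked, component_r2)
    out = stacked - clipped
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class PreferenceIndex:
    """A stacking-weight difference in [-1, 1]; positive = first-named space."""

    value: np.ndarray | float
    contrast: str


def preference_index(fit, contrast: str) -> PreferenceIndex:
    """Weight-difference preference index from a stacked fit.

    ``high_vs_low_audio`` and ``high_vs_low_visual`` give W_H - W_L (positive
    = high-level preference); ``visual_vs_audio`` gives W_V - W_A (positive =
    visual preference). ``fit`` may be a :class:`StackedFit` or a mapping
    from space names to weights.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; valid: {sorted(CONTRASTS)}")
    pos, neg = CONTRASTS[contrast]
    if isinstance(fit, StackedFit):
        names = fit.space_names
        if pos not in names or neg not in names:
            raise KeyError(
                f"contrast {contrast!r} needs weights {pos!r} and {neg!r}; "
                f"fit has {names}"
            )
        value = fit.weight(pos) - fit.weight(neg)
    else:
        try:
            value = np.asarray(fit[pos]) - np.asarray(fit[neg])
        except KeyError as err:
            raise KeyError(
                f"contrast {contrast!r} needs weights {pos!r} and {neg!r}"
            ) from err
    if np.max(np.abs(value)) > 1.0 + 1e-8:
        raise ValueError("preference index outside [-1, 1]; weights not convex")
    if np.ndim(value) == 0:
        value = float(value)
    return PreferenceIndex(value=value, contrast=contrast)
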
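"""Parcel-wise mixed-effects group statistics and demographic tests.

Each parcel-level encoding metric (R^2, unique R^2, or a preference index)
is modelled across subjects with a linear mixed model: the focal predictor
(diagnostic group, a severity score, age, or an age interaction) plus age,
sex, and socioeconomic status as fixed effects and acquisition site as a
random intercept. P-values for the focal coefficient are Benjamini-Hochberg
corrected across parcels within one (metric, focal, FD-threshold) family.

Group is coded ASD = 1, nonASD = 0; sex is coded M = 1, F = 0. Under this
coding a negative focal-group coefficient means the metric is lower in the
autistic group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .inference import fdr_bh

logger = logging.getLogger(__name__)

FOCAL_TERMS = {
    "group": "group_code",
    "srs": "srs_total",
    "sss": "sss",
    "age": "age",
    "age_x_group": "age:group_code",
    "age_x_srs": "age:srs_total",
}

ADHD_CONTRASTS = {
    "ASD-ADHD_vs_nonASD": ("ASD-ADHD", "nonASD"),
    "ASD+ADHD_vs_nonASD": ("ASD+ADHD", "nonASD"),
    "ASD-ADHD_vs_ASD+ADHD": ("ASD-ADHD", "ASD+ADHD"),
}

_EPS = 1e-3


@dataclass
class GroupModelSpec:
    """Declaration of one parcel-wise mixed-model family."""

    metric: str
    focal: str = "group"
    covariates: tuple[str, ...] = ("age", "sex", "ses")
    link: str = "identity"
    fd_threshold: int = 40
    q_level: float = 0.05
    min_subjects: int = 10

    def __post_init__(self) -> None:
        if self.focal not in FOCAL_TERMS:
            raise ValueError(f"focal must be one of {sorted(FOCAL_TERMS)}")
        if self.link not in ("identity", "logit"):
            raise ValueError("link must be 'identity' or 'logit'")
        if self.fd_threshold not in (40, 60, 80):
            raise ValueError("fd_threshold must be 40, 60, or 80")


def _code_covariates(phenotypes: pd.DataFrame) -> pd.DataFrame:
    df = phenotypes.copy()
    if "group_code" not in df:
        df["group_code"] = (df["group"] == "ASD").astype(float)
    if "sex_code" not in df:
        df["sex_code"] = df["sex"].map({"M": 1.0, "F": 0.0, 1: 1.0, 0: 0.0})
    return df


def _formula(spec: GroupModelSpec) -> str:
    focal = FOCAL_TERMS[spec.focal]
    terms = []
    if ":" in focal:  # interactions include their main effects
        a, b = focal.split(":")
        terms += [a, b, focal]
    else:
        terms.append(focal)
    for cov in spec.covariates:
        name = "sex_code" if cov == "sex" else cov
        if name not in terms:
            terms.append(name)
    return "outcome ~ " + " + ".join(terms)


def _transform_outcome(y: np.ndarray, link: str) -> np.ndarray:
    """Map the metric onto the model scale.

    For the logit link the metric is affinely squeezed into (eps, 1 - eps)
    first: R^2-type metrics (nonnegative scale) are clipped to [0, 1];
    signed preference indices in [-1, 1] are mapped through (x + 1) / 2.
    """
    if link == "identity":
        return y
    if y.min() < 0 and y.min() >= -1 and y.max() <= 1:
        unit = (y + 1.0) / 2.0
    else:
        unit = np.clip(y, 0.0, 1.0)
    unit = _EPS + (1.0 - 2.0 * _EPS) * unit
    return np.log(unit / (1.0 - unit))


def fit_group_model(
    summaries: pd.DataFrame,
    phenotypes: pd.DataFrame,
    spec: GroupModelSpec,
) -> pd.DataFrame:
    """Fit the parcel-wise mixed model declared by ``spec``.

    ``summaries`` is long-format with columns ``subject_id``, ``parcel`` and
    the metric named by ``spec.metric``; ``phenotypes`` carries group, age,
    sex, ses, site, and severity columns. Subjects missing the outcome in a
    parcel are dropped listwise for that parcel. Single-site data refit
    without the random term (warning logged); non-converging parcels are
    flagged and excluded from the FDR family.
    """
    if spec.metric not in summaries.columns:
        raise KeyError(f"metric {spec.metric!r} not in summaries")
    pheno = _code_covariates(phenotypes)
    focal_term = FOCAL_TERMS[spec.focal]
    formula = _formula(spec)

    rows = []
    for parcel, block in summaries.groupby("parcel"):
        data = block[["subject_id", spec.metric]].merge(pheno, on="subject_id")
        terms = {t.strip() for t in
                 formula.split("~")[1].replace(":", "+").split("+")}
        data = data.rename(columns={spec.metric: "outcome"}).dropna(
            subset=["outcome", *sorted(terms - {""})]
        )
        n = len(data)
        if n < spec.min_subjects:
            logger.info("parcel %s skipped: only %d subjects with outcome", parcel, n)
            continue
        data = data.copy()
        data["outcome"] = _transform_outcome(data["outcome"].to_numpy(float), spec.link)
        n_sites = data["site"].nunique()
        est = se = p = rvar = np.nan
        converged = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if n_sites < 2:
                    logger.warning(
                        "parcel %s: single site; fitting without random intercept",
                        parcel,
                    )
                    res = smf.ols(formula, data=data).fit()
                    converged = True
                    rvar = 0.0
                else:
                    model = smf.mixedlm(formula, data=data, groups=data["site"])
                    res = model.fit(reml=True)
                    converged = bool(res.converged)
                    if not converged or not np.isfinite(
                        res.pvalues[focal_term]
                    ):
                        # small samples often stall the default optimizer;
                        # Powell is slower but far more robust here
                        res = model.fit(reml=True, method="powell")
                        converged = bool(res.converged)
                    rvar = float(np.asarray(res.cov_re)[0, 0])
                    if rvar < 1e-8:
                        # At the boundary the mixed model degenerates to an
                        # ordinary regression; refit for exact coefficients.
                        res = smf.ols(formula, data=data).fit()
                        converged = True
                est = float(res.params[focal_term])
                se = float(res.bse[focal_term])
                p = float(res.pvalues[focal_term])
        except Exception as err:  # noqa: BLE001 - solver failures flag the parcel
            logger.warning("parcel %s: model failed (%s)", parcel, err)
        if not np.isfinite(p):
            converged = False
        rows.append({
            "parcel": parcel, "metric": spec.metric, "focal": spec.focal,
            "link": spec.link, "fd_threshold": spec.fd_threshold,
            "estimate": est, "se": se, "p": p,
            "random_intercept_var": rvar, "n": n, "converged": converged,
        })
    columns = ["parcel", "metric", "focal", "link", "fd_threshold", "estimate",
               "se", "p", "random_intercept_var", "n", "converged", "q",
               "significant"]
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=columns)
    out["q"] = np.nan
    out["significant"] = False
    ok = out["converged"].to_numpy()
    n_failed = int((~ok).sum())
    if n_failed:
        logger.warning("%d parcel(s) excluded from the FDR family", n_failed)
    if ok.any():
        # Wald p-values can underflow to exactly 0 on degenerate fits.
        p_vals = np.clip(out.loc[ok, "p"].to_numpy(), 1e-300, 1.0)
        q, flags = fdr_bh(p_vals, spec.q_level)
        out.loc[ok, "q"] = q
        out.loc[ok, "significant"] = flags
    return out


def fit_severity_model(
    summaries: pd.DataFrame,
    phenotypes: pd.DataFrame,
    spec: GroupModelSpec,
) -> pd.DataFrame:
    """Severity variant: a continuous focal predictor (SRS or SSS)."""
    if spec.focal not in ("srs", "sss"):
        raise ValueError("severity models take focal 'srs' or 'sss'")
    return fit_group_model(summaries, phenotypes, spec)


def relabel_for_contrast(phenotypes: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """Subset and recode the cohort for one ADHD-stratified pairwise contrast.

    The returned table keeps only the two strata named by ``contrast`` and
    codes the first-named stratum as group_code 1, so the same model
    machinery runs unchanged.
    """
    if contrast not in ADHD_CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; valid: {sorted(ADHD_CONTRASTS)}")
    hi, lo = ADHD_CONTRASTS[contrast]
    df = phenotypes[phenotypes["adhd_stratum"].isin([hi, lo])].copy()
    df["group_code"] = (df["adhd_stratum"] == hi).astype(float)
    return df


def demographic_tests(
    phenotypes: pd.DataFrame,
    measures: list[str],
    *,
    group_col: str = "group",
    sex_col: str = "sex",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Between-group demographic comparisons with a test-selection cascade.

    Continuous measures: within-group normality (Shapiro-Wilk for n < 50,
    else D'Agostino's K^2) and Levene's variance test route each measure to
    Student's t (normal, equal variance), Welch's t (normal, unequal
    variance), or a two-sided Mann-Whitney U (non-normal). The sex
    comparison uses a continuity-corrected 2x2 Pearson chi-square, with
    Fisher's exact test substituted when any cell count falls below five.
    P-values are Benjamini-Hochberg adjusted over the comparison family.
    """
    levels = [g for g in phenotypes[group_col].unique() if g != "excluded"]
    if len(levels) != 2:
        raise ValueError(f"expected two groups, found {levels}")
    g1 = phenotypes[phenotypes[group_col] == levels[0]]
    g2 = phenotypes[phenotypes[group_col] == levels[1]]

    rows = []
    for measure in measures:
        if measure == sex_col:
            table = pd.crosstab(
                phenotypes.loc[phenotypes[group_col].isin(levels), group_col],
                phenotypes[sex_col],
            ).to_numpy()
            if (table < 5).any():
                stat, p = stats.fisher_exact(table)
                test = "fisher_exact"
            else:
                stat, p, _, _ = stats.chi2_contingency(table, correction=True)
                test = "chi2_contingency"
            rows.append({"measure": measure, "test": test,
                         "statistic": float(stat), "p": float(p)})
            continue
        x1 = g1[measure].dropna().to_numpy(float)
        x2 = g2[measure].dropna().to_numpy(float)
        if min(len(x1), len(x2)) < 3:
            logger.info("measure %s skipped: a group has < 3 observations", measure)
            continue
        normal = True
        for x in (x1, x2):
            p_norm = (stats.shapiro(x).pvalue if len(x) < 50
                      else stats.normaltest(x).pvalue)
            normal &= p_norm > alpha
        equal_var = stats.levene(x1, x2).pvalue > alpha
        if not normal:
            res = stats.mannwhitneyu(x1, x2, alternative="two-sided")
            test = "mannwhitneyu"
        elif equal_var:
            res = stats.ttest_ind(x1, x2, equal_var=True)
            test = "student_t"
        else:
            res = stats.ttest_ind(x1, x2, equal_var=False)
            test = "welch_t"
        rows.append({"measure": measure, "test": test,
                     "statistic": float(res.statistic), "p": float(res.pvalue)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"], _ = fdr_bh(out["p"].to_numpy())
    return out
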
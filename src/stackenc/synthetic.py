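"""Synthetic study generator with known ground truth.

Emulates the statistical structure the stacked-encoding analysis assumes,
so the whole pipeline is testable without any restricted data: a shared
movie "stimulus" (smooth autocorrelated low-level features, sparse blockwise
binary high-level features), grayordinate responses built as known convex
mixtures of per-space predictions plus AR(1) noise and site offsets, a
two-group cohort with ADHD comorbidity, severity scores, and designated
"pSTS-like" parcels where the simulated-ASD group's high-vs-low visual
mixing weight is shifted toward the low-level space, the shift magnitude
tracking severity. Head-motion traces decrease with age.

All randomness derives from ``SimulationConfig.seed`` through independent
named streams, so any output is reproducible in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix, SPACE_TAGS
from .io import BoldMatrix

DEFAULT_FEATURE_DIMS = {
    "audio-low": 6,    # loudness + 5 cochleagram components
    "audio-high": 8,   # collapsed audio ontology categories
    "visual-low": 2,   # brightness, mean motion energy
    "visual-high": 2,  # faces, bodies
}

#: Baseline mixing weights (audio-low, audio-high, visual-low, visual-high)
#: in designated "pSTS-like" parcels: high-level visual dominant, so a
#: group shift toward low-level is expressible without leaving the simplex.
DESIGNATED_PROTOTYPE = np.array([0.10, 0.10, 0.30, 0.50])

_MEAN_BLOCK_TRS = 8  # mean on/off block length for high-level indicators


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the study design where one is stated (TR 0.8 s, three
    sites, the four feature-space dimensionalities) and otherwise use
    calibration choices documented in the methods note.
    """

    n_subjects_per_group: int = 30
    n_grayordinates: int = 80
    n_parcels: int = 16
    n_timepoints: int = 600
    tr_seconds: float = 0.8
    snr: float = 1.0
    ar1_coef: float = 0.3
    group_pref_shift: float = 0.3
    site_count: int = 3
    site_sd: float = 0.1
    motion_age_slope: float = -0.04
    seed: int = 0
    n_designated_parcels: int = 2
    high_level_sparsity: float = 0.2
    feature_dims: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_DIMS)
    )

    def __post_init__(self) -> None:
        for name in ("n_subjects_per_group", "n_grayordinates", "n_parcels",
                     "n_timepoints", "site_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not -1 <= self.group_pref_shift <= 1:
            raise ValueError("group_pref_shift must lie in [-1, 1]")
        if self.n_designated_parcels > self.n_parcels:
            raise ValueError("n_designated_parcels cannot exceed n_parcels")

    def rng(self, *stream: int) -> np.random.Generator:
        """A named, reproducible random stream derived from the master seed."""
        return np.random.default_rng([self.seed, *stream])


@dataclass
class GroundTruth:
    """Generative truth for one subject."""

    weights: np.ndarray                 # (G, 4) simplex rows, space order = SPACE_TAGS
    coefs: dict[str, np.ndarray]        # space -> (G, p_k)
    parcel_assignment: np.ndarray       # (G,) int
    parcel_labels: np.ndarray           # (G,) str
    designated_parcels: list[str]
    site: str
    group: str
    age: float
    sex: str
    ses: float
    severity: float
    site_offset: float

    def __post_init__(self) -> None:
        if self.weights.min() < 0 or np.abs(self.weights.sum(axis=1) - 1).max() > 1e-8:
            raise ValueError("mixing weights must be nonnegative and sum to 1")
        if len(self.parcel_assignment) != len(self.weights):
            raise ValueError("parcel assignment must cover all grayordinates")


def simulate_features(
    config: SimulationConfig,
    space: str,
    *,
    sparsity: float | None = None,
) -> FeatureMatrix:
    """Generate one feature space's TR-locked series.

    Low-level spaces are stationary AR(1) Gaussian processes with lag-1
    autocorrelation ``config.ar1_coef`` and unit marginal variance;
    high-level spaces are blockwise binary indicators, each block active
    with probability ``sparsity`` (default ``config.high_level_sparsity``).
    Deterministic given the config seed and arguments.
    """
    if space not in SPACE_TAGS:
        raise ValueError(f"unknown space tag {space!r}; valid tags: {SPACE_TAGS}")
    rng = config.rng(1, SPACE_TAGS.index(space))
    t = config.n_timepoints
    p = config.feature_dims[space]
    if space.endswith("-low"):
        phi = config.ar1_coef
        eps = rng.standard_normal((t, p))
        x = np.empty((t, p))
        x[0] = eps[0]
        scale = np.sqrt(1.0 - phi**2)
        for i in range(1, t):
            x[i] = phi * x[i - 1] + scale * eps[i]
    else:
        s = config.high_level_sparsity if sparsity is None else sparsity
        if not 0 <= s <= 1:
            raise ValueError("sparsity must lie in [0, 1]")
        x = np.zeros((t, p))
        for j in range(p):
            pos = 0
            while pos < t:
                length = rng.geometric(1.0 / _MEAN_BLOCK_TRS)
                active = rng.random() < s
                x[pos: pos + length, j] = float(active)
                pos += length
    names = [f"{space}-{i}" for i in range(p)]
    return FeatureMatrix(values=x, space_tag=space, tr_seconds=config.tr_seconds,
                         column_names=names, convolved=False, standardized=False)


def _standardized_predictions(
    designs: dict[str, FeatureMatrix | np.ndarray],
    coefs: dict[str, np.ndarray],
) -> np.ndarray:
    """Per-space predictions X_k beta_k, z-scored over time. Shape (T, G, K)."""
    names = list(designs)
    first = designs[names[0]]
    t = (first.values if hasattr(first, "values") else first).shape[0]
    g = coefs[names[0]].shape[0]
    out = np.zeros((t, g, len(names)))
    for ki, name in enumerate(names):
        x = designs[name]
        x = x.values if hasattr(x, "values") else np.asarray(x, float)
        pred = x @ coefs[name].T  # (T, G)
        sd = pred.std(axis=0)
        mean = pred.mean(axis=0)
        live = sd > 0
        out[:, live, ki] = (pred[:, live] - mean[live]) / sd[live]
    return out


def simulate_bold(
    config: SimulationConfig,
    designs: dict[str, FeatureMatrix | np.ndarray],
    truth: GroundTruth,
    *,
    noise_rng: np.random.Generator | None = None,
) -> BoldMatrix:
    """Generate one subject's grayordinate-by-time responses.

    Each grayordinate's response is the truth-weighted convex mixture of the
    standardized per-space predictions, plus the subject's site offset and
    AR(1) Gaussian noise scaled so that sd(signal) / sd(noise) equals
    ``config.snr`` (``snr = inf`` gives noiseless responses).
    """
    lengths = {
        k: (v.values if hasattr(v, "values") else np.asarray(v)).shape[0]
        for k, v in designs.items()
    }
    if len(set(lengths.values())) != 1:
        raise ValueError(f"designs disagree on the time axis: {lengths}")
    if truth.weights.shape[0] != config.n_grayordinates:
        raise ValueError("truth dimensions do not match config")
    preds = _standardized_predictions(designs, truth.coefs)  # (T, G, K)
    signal = np.einsum("tgk,gk->tg", preds, truth.weights)
    t, g = signal.shape
    if np.isinf(config.snr):
        noise = np.zeros((t, g))
    else:
        rng = noise_rng if noise_rng is not None else config.rng(2)
        phi = config.ar1_coef
        eps = rng.standard_normal((t, g))
        noise = np.empty((t, g))
        noise[0] = eps[0]
        scale = np.sqrt(1.0 - phi**2)
        for i in range(1, t):
            noise[i] = phi * noise[i - 1] + scale * eps[i]
        noise *= signal.std(axis=0) / config.snr
    values = (signal + noise + truth.site_offset).T  # (G, T)
    return BoldMatrix(values=values, tr_seconds=config.tr_seconds)


def _project_simplex(w: np.ndarray) -> np.ndarray:
    """Clip negatives to zero and renormalize rows to sum one."""
    w = np.clip(w, 0.0, None)
    return w / w.sum(axis=1, keepdims=True)


def _parcel_structure(config: SimulationConfig):
    sizes = np.full(config.n_parcels, config.n_grayordinates // config.n_parcels)
    sizes[: config.n_grayordinates % config.n_parcels] += 1
    assignment = np.repeat(np.arange(config.n_parcels), sizes)
    labels = np.array([f"P{i:02d}" for i in range(config.n_parcels)])
    designated = labels[config.n_parcels - config.n_designated_parcels:]
    return assignment, labels, list(designated)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, GroundTruth]]:
    """Generate the phenotype table and per-subject generative truth.

    The two groups share parcel-level baseline mixing weights and feature
    coefficients (the "brain" is common; groups differ only where an effect
    is injected). In designated parcels, simulated-ASD subjects have their
    visual high-level weight shifted toward the low-level space so that the
    group difference in the W_H - W_L index equals ``group_pref_shift`` on
    average, with per-subject shifts proportional to severity. Sites are
    assigned round-robin.
    """
    rng = config.rng(3)
    assignment, labels, designated = _parcel_structure(config)
    designated_idx = {labels.tolist().index(d) for d in designated}

    prototypes = np.empty((config.n_parcels, 4))
    for pi in range(config.n_parcels):
        if pi in designated_idx:
            prototypes[pi] = DESIGNATED_PROTOTYPE
        else:
            prototypes[pi] = rng.dirichlet(np.full(4, 2.0))
    base_weights = prototypes[assignment]  # (G, 4)
    coefs = {
        space: rng.standard_normal((config.n_grayordinates, config.feature_dims[space]))
        for space in SPACE_TAGS
    }
    site_offsets = config.site_sd * rng.standard_normal(config.site_count)

    n = config.n_subjects_per_group
    # Group-dependent demographics loosely matched to the study cohort:
    # the autistic group is older, more male, lower-SES, higher-severity.
    ages = np.concatenate([
        np.clip(rng.normal(12.8, 3.8, n), 5.0, 21.5),   # ASD
        np.clip(rng.normal(11.0, 3.6, n), 5.0, 21.5),   # nonASD
    ])
    sexes = np.concatenate([
        np.where(rng.random(n) < 0.83, "M", "F"),
        np.where(rng.random(n) < 0.56, "M", "F"),
    ])
    ses = np.concatenate([
        np.clip(rng.normal(49.3, 14.0, n), 9.0, 66.0),
        np.clip(rng.normal(54.4, 11.0, n), 9.0, 66.0),
    ])
    srs = np.concatenate([
        np.clip(rng.normal(68.1, 11.0, n), 38.0, 90.0),
        np.clip(rng.normal(49.3, 7.5, n), 38.0, 90.0),
    ])
    adhd = np.concatenate([rng.random(n) < 0.7, np.zeros(n, dtype=bool)])
    groups = np.array(["ASD"] * n + ["nonASD"] * n)

    item_p = np.clip((srs - 40.0) / 50.0, 0.02, 0.95)
    items = {
        f"srs_item{i}": rng.binomial(3, item_p) for i in (20, 42, 58)
    }
    scq = 3 * rng.binomial(1, item_p)
    sss = items["srs_item20"] + items["srs_item42"] + items["srs_item58"] + scq

    asd_mask = groups == "ASD"
    shift = np.zeros(2 * n)
    if config.group_pref_shift != 0:
        shift[asd_mask] = config.group_pref_shift * srs[asd_mask] / srs[asd_mask].mean()

    rows, truths = [], {}
    warned = False
    for i in range(2 * n):
        sid = f"sub-{i:03d}"
        site_i = i % config.site_count
        w = base_weights.copy()
        if shift[i] != 0:
            in_designated = np.isin(assignment, list(designated_idx))
            w[in_designated, 3] -= shift[i] / 2.0  # visual-high
            w[in_designated, 2] += shift[i] / 2.0  # visual-low
            if w.min() < -1e-12:
                if not warned:
                    warnings.warn(
                        "group_pref_shift pushed weights outside the simplex; "
                        "re-projecting (clip negatives, renormalize)",
                        stacklevel=2,
                    )
                    warned = True
                w = _project_simplex(w)
        truths[sid] = GroundTruth(
            weights=w, coefs=coefs, parcel_assignment=assignment,
            parcel_labels=labels[assignment], designated_parcels=designated,
            site=f"site{site_i}", group=groups[i], age=float(ages[i]),
            sex=str(sexes[i]), ses=float(ses[i]), severity=float(srs[i]),
            site_offset=float(site_offsets[site_i]),
        )
        rows.append({
            "subject_id": sid,
            "consensus_label": ("Autism Spectrum Disorder" if groups[i] == "ASD"
                                else "No Diagnosis Given"),
            "group": groups[i], "adhd": bool(adhd[i]),
            "age": float(ages[i]), "sex": str(sexes[i]), "ses": float(ses[i]),
            "site": f"site{site_i}", "srs_total": float(srs[i]),
            "srs_item20": int(items["srs_item20"][i]),
            "srs_item42": int(items["srs_item42"][i]),
            "srs_item58": int(items["srs_item58"][i]),
            "scq_item14": int(scq[i]), "sss": int(sss[i]),
        })
    return pd.DataFrame(rows), truths


def simulate_motion(
    config: SimulationConfig,
    ages: np.ndarray,
    n_volumes: int | None = None,
) -> list[np.ndarray]:
    """Per-subject framewise-displacement series with an age trend.

    Each subject's FD values are gamma-distributed (nonnegative) around a
    subject-level mean that decays exponentially with age at rate
    ``motion_age_slope`` (log-mm per year), plus log-normal subject noise,
    so the expected fraction of volumes above 0.2 mm decreases
    monotonically with age when the slope is negative.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("ages must be nonempty")
    if (ages < 0).any():
        raise ValueError("ages must be nonnegative")
    rng = config.rng(4)
    t = n_volumes if n_volumes is not None else config.n_timepoints
    out = []
    for age in ages:
        mu = 0.15 * np.exp(config.motion_age_slope * (age - 12.0)
                           + 0.3 * rng.standard_normal())
        out.append(rng.gamma(shape=2.0, scale=mu / 2.0, size=t))
    return out


@dataclass
class SimulatedStudy:
    """Everything one full pipeline run needs, with known truth."""

    config: SimulationConfig
    designs: dict[str, FeatureMatrix]
    phenotype: pd.DataFrame
    truths: dict[str, GroundTruth]
    bold: dict[str, BoldMatrix]
    motion: dict[str, np.ndarray]


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the shared stimulus, cohort, responses, and motion traces."""
    designs = {space: simulate_features(config, space) for space in SPACE_TAGS}
    phenotype, truths = simulate_cohort(config)
    bold = {}
    for i, (sid, truth) in enumerate(truths.items()):
        bold[sid] = simulate_bold(
            config, designs, truth, noise_rng=config.rng(2, i)
        )
        bold[sid].subject_id = sid
    fd = simulate_motion(config, phenotype["age"].to_numpy())
    motion = {sid: fd[i] for i, sid in enumerate(phenotype["subject_id"])}
    return SimulatedStudy(config=config, designs=designs, phenotype=phenotype,
                          truths=truths, bold=bold, motion=motion)
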
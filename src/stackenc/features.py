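"""Design-matrix construction for movie feature spaces.

Four feature spaces drive the encoding models: low- and high-level audio and
visual features. Low-level features are continuous series (loudness proxy,
cochleagram components, brightness, motion energy); high-level features are
detection-style scores (collapsed audio ontology categories, face/body
presence). All spaces pass through the same path to a design matrix: convolve
with a canonical haemodynamic response function at the native sampling rate,
bin-average down to the repetition time (TR), drop the initial volumes that
are also discarded from the BOLD series, and z-score each column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

SPACE_TAGS = ("audio-low", "audio-high", "visual-low", "visual-high")

#: The eight top-level audio ontology categories, in output column order.
AUDIOSET_CATEGORIES = (
    "Human Sounds, Speech",
    "Human Sounds, NonSpeech",
    "Animal Sounds",
    "Music",
    "Natural Sounds",
    "Sounds of Things",
    "Source Ambiguous Sounds",
    "Channel, Environment, Background",
)


@dataclass
class FeatureMatrix:
    """A time-by-feature design matrix for one feature space."""

    values: np.ndarray
    space_tag: str
    tr_seconds: float
    column_names: list[str]
    convolved: bool = False
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D time-by-feature matrix")
        if self.space_tag not in SPACE_TAGS:
            raise ValueError(
                f"unknown space tag {self.space_tag!r}; valid tags: {SPACE_TAGS}"
            )
        if len(self.column_names) != self.values.shape[1]:
            raise ValueError("column_names length must match feature count")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        if self.standardized:
            live = self.values.std(axis=0) > 0
            means = np.abs(self.values[:, live].mean(axis=0))
            sds = np.abs(self.values[:, live].std(axis=0) - 1.0)
            if means.size and (means.max() > 1e-7 or sds.max() > 1e-7):
                raise ValueError("standardized matrix violates mean-0 / sd-1 contract")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class OntologyMap:
    """Mapping from fine-grained audio class names to the eight categories."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values() if c not in AUDIOSET_CATEGORIES}
        if bad:
            raise ValueError(
                f"categories {sorted(bad)} are not among the eight top-level "
                f"categories {AUDIOSET_CATEGORIES}"
            )


def canonical_hrf(
    tr_seconds: float,
    length_seconds: float = 32.0,
    *,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    peak_undershoot_ratio: float = 6.0,
    onset_seconds: float = 0.0,
) -> np.ndarray:
    """Sample the canonical double-gamma HRF at TR resolution.

    The kernel is the difference of two gamma densities — a response peaking
    at ``peak_delay`` seconds and an undershoot peaking at
    ``undershoot_delay`` seconds, the undershoot scaled down by
    ``peak_undershoot_ratio`` — rescaled to unit peak.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if length_seconds < 20:
        raise ValueError("length_seconds must be at least 20 s to span the HRF")
    t = np.arange(0.0, length_seconds, tr_seconds) - onset_seconds
    peak = gamma_dist.pdf(t, peak_delay / peak_dispersion, scale=peak_dispersion)
    under = gamma_dist.pdf(
        t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
    )
    kernel = peak - under / peak_undershoot_ratio
    kernel[t < 0] = 0.0
    return kernel / kernel.max()


def build_design(
    raw: np.ndarray,
    native_rate: float,
    tr_seconds: float,
    n_trs: int,
    discard_initial: int = 10,
    *,
    space_tag: str = "visual-low",
    column_names: list[str] | None = None,
    hrf_length_seconds: float = 32.0,
    standardize: bool = True,
    drop_constant: bool = True,
) -> FeatureMatrix:
    """Convolve, resample to TR, discard initial volumes, and z-score.

    ``raw`` is a time-by-feature series sampled at ``native_rate`` Hz and must
    cover at least ``n_trs * tr_seconds`` of stimulus time. Each column is
    convolved with the canonical HRF at the native rate, averaged within TR
    bins, then the first ``discard_initial`` rows are dropped (mirroring the
    BOLD discard) and each column is z-scored. Constant input columns carry no
    information and are dropped with a warning.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[0] == 1 and raw.shape[1] > 1 and column_names is None:
        raw = raw.T
    n_native = raw.shape[0]
    needed = int(np.ceil(n_trs * tr_seconds * native_rate))
    if n_native < needed:
        raise ValueError(
            f"raw series too short: {n_native} samples cover "
            f"{n_native / native_rate:.2f} s but {n_trs} TRs of {tr_seconds} s "
            f"need {needed} samples (shortfall {needed - n_native})"
        )
    if column_names is None:
        column_names = [f"f{i}" for i in range(raw.shape[1])]
    column_names = list(column_names)

    if drop_constant:
        keep = raw.std(axis=0) > 0
        if not keep.all():
            dropped = [n for n, k in zip(column_names, keep) if not k]
            warnings.warn(
                f"dropping constant feature column(s): {dropped}", stacklevel=2
            )
            raw = raw[:, keep]
            column_names = [n for n, k in zip(column_names, keep) if k]

    kernel = canonical_hrf(1.0 / native_rate, hrf_length_seconds)
    conv = np.empty_like(raw)
    for j in range(raw.shape[1]):
        conv[:, j] = np.convolve(raw[:, j], kernel)[:n_native]

    # Bin-average within TRs (antialiasing-safe for smooth features).
    samples_per_tr = native_rate * tr_seconds
    bins = np.minimum(
        (np.arange(n_native) / samples_per_tr).astype(int), n_trs - 1
    )
    binned = np.empty((n_trs, conv.shape[1]))
    for t in range(n_trs):
        binned[t] = conv[bins == t].mean(axis=0)

    out = binned[discard_initial:]
    if standardize:
        out = (out - out.mean(axis=0)) / out.std(axis=0)
    return FeatureMatrix(
        values=out,
        space_tag=space_tag,
        tr_seconds=tr_seconds,
        column_names=column_names,
        convolved=True,
        standardized=standardize,
    )


def compute_brightness(frames: np.ndarray) -> np.ndarray:
    """Mean perceptual brightness per RGB frame, normalized to [0, 1].

    Luminance is the Rec. 601 combination 0.299 R + 0.587 G + 0.114 B averaged
    over pixels; channel scale ([0, 1] vs [0, 255]) is auto-detected.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.size == 0:
        raise ValueError("empty frame input")
    if frames.ndim == 3:  # single frame
        frames = frames[None]
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError("frames must have shape (n_frames, h, w, 3)")
    if frames.max() > 1.0:
        frames = frames / 255.0
    lum = frames @ np.array([0.299, 0.587, 0.114])
    return lum.reshape(lum.shape[0], -1).mean(axis=1)


def collapse_audioset(
    frame_scores: dict[str, np.ndarray] | "pd.DataFrame",  # noqa: F821
    ontology: OntologyMap,
    *,
    aggregation: str = "max",
) -> np.ndarray:
    """Collapse fine-grained audio-tag scores to the eight-category space.

    Each output column is the per-window ``max`` (default; preserves the
    detection semantics of tagger scores) or ``sum`` over the member fine
    classes of one top-level category. Columns follow
    :data:`AUDIOSET_CATEGORIES` order; the output dimension is exactly 8.
    """
    if aggregation not in ("max", "sum"):
        raise ValueError("aggregation must be 'max' or 'sum'")
    if hasattr(frame_scores, "columns"):  # DataFrame
        frame_scores = {c: frame_scores[c].to_numpy() for c in frame_scores.columns}
    unmapped = [name for name in frame_scores if name not in ontology.mapping]
    if unmapped:
        raise ValueError(f"fine class(es) not in ontology map: {unmapped}")
    n = len(next(iter(frame_scores.values())))
    out = np.zeros((n, len(AUDIOSET_CATEGORIES)))
    for j, category in enumerate(AUDIOSET_CATEGORIES):
        members = [
            np.asarray(s, dtype=float)
            for name, s in frame_scores.items()
            if ontology.mapping[name] == category
        ]
        if members:
            stacked = np.column_stack(members)
            out[:, j] = stacked.max(axis=1) if aggregation == "max" else stacked.sum(axis=1)
    return out


@dataclass
class PCAReduction:
    """Principal-component scores with loadings and explained variance."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray


def reduce_components(series: np.ndarray, n_components: int) -> PCAReduction:
    """First ``n_components`` principal components of a time-by-channel series.

    Components are ordered by descending explained variance; each component's
    sign is fixed so its largest-magnitude loading is positive.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be 2-D time-by-channel")
    if n_components > series.shape[1]:
        raise ValueError(
            f"n_components={n_components} exceeds channel count {series.shape[1]}"
        )
    centered = series - series.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, : u.shape[1]]
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else var
    scores = (u * s)[:, :n_components]
    return PCAReduction(
        scores=scores,
        loadings=vt[:n_components].T,
        explained_variance_ratio=evr[:n_components],
    )
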
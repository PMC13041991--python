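"""Parcel atlas handling: grayordinate labels, hemispheres, ROI groups.

Parcels follow the multimodal-parcellation nomenclature (V1, MT, FFC, A4,
STSvp, ...). A bundled region-of-interest list groups perceptual parcels
into visual, auditory, and audiovisual sets spanning the dorsal, ventral,
and lateral visual streams and the auditory hierarchy; labels outside the
list are retained and tagged "other".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Perceptual regions of interest grouped by modality.
PERCEPTUAL_ROIS: dict[str, tuple[str, ...]] = {
    "visual": (
        "V1", "V2", "V3", "V4", "V3A", "V4t", "V7", "MT", "MST", "LO1", "LO2",
        "LO3", "FFC", "VVC", "PIT", "VMV1", "VMV2", "VMV3", "PH", "IFSa",
    ),
    "auditory": (
        "A1", "LBelt", "MBelt", "PBelt", "RI", "A4", "A5", "TA2", "STGa",
        "IFSp",
    ),
    "audiovisual": (
        "STSvp", "STSdp", "STSva", "STSda", "TPOJ1", "TPOJ2", "TPOJ3", "PF",
    ),
}


def roi_group(parcel: str) -> str:
    """ROI-group tag for a parcel name (hemisphere prefix ignored)."""
    stripped = parcel
    for prefix in ("L_", "R_"):
        if stripped.startswith(prefix):
            stripped = stripped[len(prefix):]
    for group, names in PERCEPTUAL_ROIS.items():
        if stripped in names:
            return group
    return "other"


def _hemisphere(parcel: str, explicit: str | None = None) -> str:
    if explicit and str(explicit).strip() in ("L", "R", "subcortical"):
        return str(explicit).strip()
    if parcel.startswith("L_"):
        return "L"
    if parcel.startswith("R_"):
        return "R"
    return "subcortical"


@dataclass
class ParcelAtlas:
    """Grayordinate-to-parcel mapping with hemisphere and ROI-group tags."""

    labels: np.ndarray                  # (G,) parcel label per grayordinate
    parcels: pd.DataFrame               # parcel, hemisphere, roi_group

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.parcels["parcel"].duplicated().any():
            raise ValueError("duplicate parcel entries in atlas table")

    @property
    def n_grayordinates(self) -> int:
        return len(self.labels)

    @property
    def parcel_names(self) -> list[str]:
        return self.parcels["parcel"].tolist()

    def hemisphere(self, parcel: str) -> str:
        row = self.parcels.loc[self.parcels["parcel"] == parcel, "hemisphere"]
        if row.empty:
            raise KeyError(f"parcel {parcel!r} not in atlas")
        return row.iloc[0]


def atlas_from_labels(labels) -> ParcelAtlas:
    """Build an atlas directly from a per-grayordinate label array."""
    labels = np.asarray(labels, dtype=object)
    names = sorted(pd.unique(labels))
    parcels = pd.DataFrame({
        "parcel": names,
        "hemisphere": [_hemisphere(n) for n in names],
        "roi_group": [roi_group(n) for n in names],
    })
    return ParcelAtlas(labels=labels, parcels=parcels)


def read_atlas(path: str | Path) -> ParcelAtlas:
    """Read a grayordinate-to-parcel table.

    Accepts a TSV with columns ``grayordinate`` and ``label`` (optional
    ``hemisphere``); hemisphere is otherwise inferred from an ``L_``/``R_``
    label prefix, defaulting to subcortical. A grayordinate listed twice is
    rejected.
    """
    path = Path(path)
    if path.name.endswith(".dlabel.nii"):
        import nibabel as nib  # optional CIFTI layer

        img = nib.load(str(path))
        axis = img.header.get_axis(0)
        label_table = next(iter(axis.label.values())) if hasattr(axis, "label") else {}
        keys = np.asarray(img.get_fdata()).astype(int).ravel()
        labels = np.array([label_table.get(k, ("", None))[0] for k in keys],
                          dtype=object)
        return atlas_from_labels(labels)
    df = pd.read_csv(path, sep="\t")
    if not {"grayordinate", "label"}.issubset(df.columns):
        raise ValueError("atlas TSV needs 'grayordinate' and 'label' columns")
    if df["grayordinate"].duplicated().any():
        raise ValueError("duplicate grayordinate labels in atlas")
    df = df.sort_values("grayordinate").reset_index(drop=True)
    labels = df["label"].to_numpy(dtype=object)
    names = sorted(pd.unique(labels))
    hemi_col = df["hemisphere"] if "hemisphere" in df.columns else None
    hemis = []
    for n in names:
        explicit = None
        if hemi_col is not None:
            explicit = df.loc[df["label"] == n, "hemisphere"].iloc[0]
        hemis.append(_hemisphere(n, explicit))
    parcels = pd.DataFrame({
        "parcel": names, "hemisphere": hemis,
        "roi_group": [roi_group(n) for n in names],
    })
    return ParcelAtlas(labels=labels, parcels=parcels)


def write_atlas(path: str | Path, atlas: ParcelAtlas) -> None:
    hemi = {r.parcel: r.hemisphere for r in atlas.parcels.itertuples()}
    pd.DataFrame({
        "grayordinate": np.arange(atlas.n_grayordinates),
        "label": atlas.labels,
        "hemisphere": [hemi[l] for l in atlas.labels],
    }).to_csv(path, sep="\t", index=False)
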
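"""Phenotype handling: Sensory Subset Score and analysis-group assignment.

The Sensory Subset Score (SSS) is a 0-12 composite of three Social
Responsiveness Scale (SRS-2) items (20, 42, 58) and one Social Communication
Questionnaire (SCQ) item (14), targeting sensory-related traits. Analysis
groups are assigned from the clinician consensus label: autism spectrum
disorder (ASD), no diagnosis (nonASD), or excluded; co-occurring ADHD does
not exclude a participant from the ASD group and is tracked as a stratum.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

logger = logging.getLogger(__name__)

LABEL_ASD = "Autism Spectrum Disorder"
LABEL_NONASD = "No Diagnosis Given"
EXCLUDED_LABELS = (
    "No Diagnosis Given: Incomplete Eval",
    "No Diagnosis Given: No Reason Given",
)

_SRS_CODES = {0, 1, 2, 3}
# The SCQ item is binary; under the combined response legend Yes codes to the
# top of the scale (3) and No to the bottom (0).
_SCQ_CODES = {"yes": 3, "no": 0, 0: 0, 3: 3}


def _is_missing(x) -> bool:
    if x is None:
        return True
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return False


def sensory_subset_score(item20, item42, item58, scq14) -> int | None:
    """Sum the three SRS-2 sensory items and the coded SCQ item 14.

    SRS items take codes 0 (No/Not True) through 3 (Almost Always True); the
    SCQ item accepts Yes/No or the already-coded values {0, 3}. Any missing
    item makes the whole score missing (``None``) — no partial sums. The score
    ranges from 0 to 12.
    """
    items = (item20, item42, item58)
    if any(_is_missing(x) for x in items) or _is_missing(scq14):
        return None
    coded = []
    for x in items:
        xi = int(x)
        if xi != x or xi not in _SRS_CODES:
            raise ValueError(f"SRS item code {x!r} not in {{0, 1, 2, 3}}")
        coded.append(xi)
    key = scq14.strip().lower() if isinstance(scq14, str) else int(scq14)
    if key not in _SCQ_CODES:
        raise ValueError(f"SCQ item 14 response {scq14!r} must be Yes/No or 0/3")
    return sum(coded) + _SCQ_CODES[key]


def assign_groups(records: pd.DataFrame, label_col: str = "consensus_label") -> pd.DataFrame:
    """Assign analysis groups and ADHD strata from consensus labels.

    Returns a copy with ``group`` in {ASD, nonASD, excluded}, a boolean
    ``adhd`` flag, and ``adhd_stratum`` in {ASD+ADHD, ASD-ADHD, nonASD, excluded}.
    Unrecognized or empty labels are excluded with a logged reason; every row
    lands in exactly one group.
    """
    out = records.copy()
    groups, strata = [], []
    adhd_col = out["adhd"] if "adhd" in out else pd.Series(False, index=out.index)
    for idx, label in out[label_col].items():
        adhd = bool(adhd_col.loc[idx]) if not _is_missing(adhd_col.loc[idx]) else False
        if _is_missing(label) or str(label).strip() == "":
            logger.info("row %s excluded: empty consensus label", idx)
            groups.append("excluded")
            strata.append("excluded")
            continue
        label = str(label).strip()
        if label == LABEL_ASD:
            groups.append("ASD")
            strata.append("ASD+ADHD" if adhd else "ASD-ADHD")
        elif label == LABEL_NONASD:
            groups.append("nonASD")
            strata.append("nonASD")
        elif label in EXCLUDED_LABELS:
            logger.info("row %s excluded: label %r", idx, label)
            groups.append("excluded")
            strata.append("excluded")
        else:
            logger.info("row %s excluded: unrecognized label %r", idx, label)
            groups.append("excluded")
            strata.append("excluded")
    out["group"] = groups
    out["adhd"] = [
        bool(a) if not _is_missing(a) else False for a in adhd_col
    ]
    out["adhd_stratum"] = strata
    return out
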
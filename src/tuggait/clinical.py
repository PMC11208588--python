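"""Clinical metadata, eligibility, motor-subtype and affected-side labeling.

Patients are classified as tremor-dominant (TD), postural-instability /
gait-difficulty dominant (PIGD) or indeterminate (IND) from the ratio of the
mean tremor-component to the mean PIGD-component MDS-UPDRS item scores:
ratio >= 1.15 -> TD, ratio <= 0.9 -> PIGD, otherwise IND.  The more-affected
side (MAS) is the side with the larger total of the bradykinesia items
3.4-3.8 (upper body: 3.4, 3.5, 3.6; lower body: 3.7, 3.8).

The item sets for the two components follow the standard Stebbins scheme and
are configurable, since scale revisions and study conventions vary:

* TD component: 2.10, 3.15a, 3.15b, 3.16a, 3.16b, 3.17a-e, 3.18
* PIGD component: 2.12, 2.13, 3.10, 3.11, 3.12
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TD_ITEMS = (
    "2_10", "3_15a", "3_15b", "3_16a", "3_16b",
    "3_17a", "3_17b", "3_17c", "3_17d", "3_17e", "3_18",
)
PIGD_ITEMS = ("2_12", "2_13", "3_10", "3_11", "3_12")

#: bradykinesia items scored per side, used for the MAS determination
BRADYKINESIA_ITEMS = ("3_4", "3_5", "3_6", "3_7", "3_8")
UPPER_BRADY_ITEMS = ("3_4", "3_5", "3_6")

GROUPS = ("HC", "TD", "PIGD", "IND")

TD_RATIO_THRESHOLD = 1.15
PIGD_RATIO_THRESHOLD = 0.9

AGE_MIN, AGE_MAX = 40, 80
MMSE_MIN = 24


@dataclass
class SubjectMeta:
    """Demographics and clinical scores for one subject.

    ``updrs`` maps item codes to scores in [0, 4].  Side-scored items carry a
    ``_r`` / ``_l`` suffix (e.g. ``3_4_r``).  ``is_patient`` distinguishes PD
    patients from healthy controls (controls are never subtyped).
    """

    subject_id: str
    age: float
    sex: str = "F"
    height_cm: float = np.nan
    weight_kg: float = np.nan
    mmse: float = 30.0
    is_patient: bool = False
    hy_stage: float = 0.0
    disease_duration_months: float = np.nan
    updrs: dict[str, float] = field(default_factory=dict)
    updrs_part3_total: float = np.nan

    def item(self, code: str) -> float:
        return float(self.updrs.get(code, np.nan))


@dataclass
class SubjectLabels:
    subject_id: str
    group: str                      # HC / TD / PIGD / IND
    td_pigd_ratio: float            # NaN for controls
    mas_side: str                   # 'left' / 'right' / 'none'
    eligible: bool
    exclusion_reason: str = ""


class ClassificationError(ValueError):
    pass


def _item_mean(meta: SubjectMeta, items) -> float:
    vals = []
    for code in items:
        v = meta.item(code)
        if np.isnan(v):
            raise ClassificationError(f"{meta.subject_id}: missing UPDRS item {code}")
        vals.append(v)
    return float(np.mean(vals))


def classify_subtype(meta: SubjectMeta, td_items=TD_ITEMS, pigd_items=PIGD_ITEMS):
    """Motor subtype and TD/PIGD ratio for a patient.

    Returns ``(group, ratio)``.  Boundary values are inclusive: ratio >= 1.15
    is TD and ratio <= 0.9 is PIGD.  A zero PIGD mean with a positive TD mean
    gives an infinite ratio (TD); both means zero is indeterminate.
    """
    if not meta.is_patient:
        raise ClassificationError("healthy controls are not subtyped")
    td = _item_mean(meta, td_items)
    pigd = _item_mean(meta, pigd_items)
    if pigd == 0.0:
        if td > 0.0:
            return "TD", np.inf
        return "IND", np.nan
    ratio = td / pigd
    if ratio >= TD_RATIO_THRESHOLD:
        return "TD", ratio
    if ratio <= PIGD_RATIO_THRESHOLD:
        return "PIGD", ratio
    return "IND", ratio


def determine_mas(meta: SubjectMeta) -> str:
    """More-affected side from the bradykinesia items 3.4-3.8.

    Ties break to the side with the larger upper-body subtotal; a full tie
    defaults to the right side.  Controls have no MAS ('none').
    """
    if not meta.is_patient:
        return "none"
    totals = {}
    upper = {}
    for side, sfx in (("right", "_r"), ("left", "_l")):
        vals = [meta.item(it + sfx) for it in BRADYKINESIA_ITEMS]
        if any(np.isnan(v) for v in vals):
            raise ClassificationError(
                f"{meta.subject_id}: missing side-scored bradykinesia item"
            )
        totals[side] = sum(vals)
        upper[side] = sum(meta.item(it + sfx) for it in UPPER_BRADY_ITEMS)
    if totals["right"] != totals["left"]:
        return max(totals, key=totals.get)
    if upper["right"] != upper["left"]:
        return max(upper, key=upper.get)
    return "right"


def filter_eligibility(meta: SubjectMeta) -> tuple[bool, str]:
    """Study eligibility: age in [40, 80] (bounds inclusive) and MMSE >= 24."""
    if np.isnan(meta.age):
        return False, "missing age"
    if np.isnan(meta.mmse):
        return False, "missing mmse"
    if meta.age < AGE_MIN or meta.age > AGE_MAX:
        return False, "age"
    if meta.mmse < MMSE_MIN:
        return False, "mmse"
    return True, ""


def label_subject(meta: SubjectMeta) -> SubjectLabels:
    """Full labeling: eligibility, subtype (patients), MAS side."""
    eligible, reason = filter_eligibility(meta)
    if not meta.is_patient:
        return SubjectLabels(meta.subject_id, "HC", np.nan, "none", eligible, reason)
    try:
        group, ratio = classify_subtype(meta)
        mas = determine_mas(meta)
    except ClassificationError as exc:
        return SubjectLabels(meta.subject_id, "IND", np.nan, "none", False,
                             f"classification: {exc}")
    return SubjectLabels(meta.subject_id, group, ratio, mas, eligible, reason)


# ----------------------------------------------------------------------
# Metadata table round trip
# ----------------------------------------------------------------------
_BASE_COLS = ("subject_id", "age", "sex", "height_cm", "weight_kg", "mmse",
              "is_patient", "hy_stage", "disease_duration_months",
              "updrs_part3_total")


def metadata_to_frame(metas: list[SubjectMeta]) -> pd.DataFrame:
    """One CSV row per subject; UPDRS items become ``updrs_<code>`` columns."""
    item_cols = sorted({k for m in metas for k in m.updrs})
    rows = []
    for m in metas:
        row = {c: getattr(m, c) for c in _BASE_COLS}
        for k in item_cols:
            row[f"updrs_{k}"] = m.updrs.get(k, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_metadata(df: pd.DataFrame) -> list[SubjectMeta]:
    metas = []
    item_cols = [c for c in df.columns if c.startswith("updrs_") and c != "updrs_part3_total"]
    for _, row in df.iterrows():
        updrs = {c[len("updrs_"):]: float(row[c]) for c in item_cols if pd.notna(row[c])}
        metas.append(SubjectMeta(
            subject_id=str(row["subject_id"]),
            age=float(row["age"]),
            sex=str(row.get("sex", "F")),
            height_cm=float(row.get("height_cm", np.nan)),
            weight_kg=float(row.get("weight_kg", np.nan)),
            mmse=float(row["mmse"]),
            is_patient=bool(row["is_patient"]),
            hy_stage=float(row.get("hy_stage", 0.0)),
            disease_duration_months=float(row.get("disease_duration_months", np.nan)),
            updrs=updrs,
            updrs_part3_total=float(row.get("updrs_part3_total", np.nan)),
        ))
    return metas


def labels_to_frame(labels: list[SubjectLabels]) -> pd.DataFrame:
    return pd.DataFrame([l.__dict__ for l in labels])
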
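"""Subtype classification, affected-side determination and eligibility."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tuggait.clinical import (
    BRADYKINESIA_ITEMS,
    PIGD_ITEMS,
    TD_ITEMS,
    SubjectMeta,
    classify_subtype,
    determine_mas,
    filter_eligibility,
    label_subject,
)


def _patient(td_score=1.0, pigd_score=1.0, brady_r=None, brady_l=None, **kw):
    updrs = {it: td_score for it in TD_ITEMS}
    updrs.update({it: pigd_score for it in PIGD_ITEMS})
    brady_r = brady_r if brady_r is not None else [1] * 5
    brady_l = brady_l if brady_l is not None else [1] * 5
    for it, r, l in zip(BRADYKINESIA_ITEMS, brady_r, brady_l):
        updrs[it + "_r"] = r
        updrs[it + "_l"] = l
    defaults = dict(subject_id="P1", age=65.0, mmse=28.0, is_patient=True)
    defaults.update(kw)
    return SubjectMeta(updrs=updrs, **defaults)


@pytest.mark.parametrize("td,pigd,expected_group,expected_ratio", [
    (1.20, 1.00, "TD", 1.20),        # above the TD threshold
    (0.45, 0.50, "PIGD", 0.90),      # PIGD boundary is inclusive
    (1.15, 1.00, "TD", 1.15),        # TD boundary is inclusive
    (1.00, 1.00, "IND", 1.00),       # between thresholds
    (1.14, 1.00, "IND", 1.14),
])
def test_subtype_thresholds(td, pigd, expected_group, expected_ratio):
    group, ratio = classify_subtype(_patient(td_score=td, pigd_score=pigd))
    assert group == expected_group
    assert ratio == pytest.approx(expected_ratio)


def test_subtype_zero_denominator():
    group, ratio = classify_subtype(_patient(td_score=2.0, pigd_score=0.0))
    assert group == "TD" and np.isinf(ratio)
    group, ratio = classify_subtype(_patient(td_score=0.0, pigd_score=0.0))
    assert group == "IND" and np.isnan(ratio)


@settings(max_examples=50, deadline=None)
@given(td=st.floats(0.05, 4.0), pigd=st.floats(0.05, 4.0),
       scale=st.floats(0.1, 10.0))
def test_classification_scale_invariance(td, pigd, scale):
    """Multiplying all item scores by a positive constant preserves the group."""
    g1, _ = classify_subtype(_patient(td_score=td, pigd_score=pigd))
    g2, _ = classify_subtype(_patient(td_score=td * scale, pigd_score=pigd * scale))
    assert g1 == g2
    assert g1 in ("TD", "PIGD", "IND")


def test_mas_strict_majority():
    meta = _patient(brady_r=[2, 1, 1, 1, 1], brady_l=[0, 1, 0, 1, 0])
    assert determine_mas(meta) == "right"


def test_mas_tiebreak_exhaustive():
    """Against brute-force: equal totals resolve by the upper-body subtotal,
    full ties default right.  Enumerated over small two-item score tables."""
    for ur, lr, ul, ll in itertools.product(range(3), repeat=4):
        # items: 3.4 (upper) and 3.7 (lower) carry the scores, rest zero
        meta = _patient(brady_r=[ur, 0, 0, lr, 0], brady_l=[ul, 0, 0, ll, 0])
        got = determine_mas(meta)
        tot_r, tot_l = ur + lr, ul + ll
        if tot_r != tot_l:
            expected = "right" if tot_r > tot_l else "left"
        elif ur != ul:
            expected = "right" if ur > ul else "left"
        else:
            expected = "right"
        assert got == expected, (ur, lr, ul, ll)


def test_hc_has_no_mas_and_is_never_subtyped():
    hc = SubjectMeta(subject_id="H1", age=66.0, mmse=28.0, is_patient=False)
    assert determine_mas(hc) == "none"
    labels = label_subject(hc)
    assert labels.group == "HC" and labels.mas_side == "none"
    assert np.isnan(labels.td_pigd_ratio)


@pytest.mark.parametrize("age,mmse,eligible,reason", [
    (66, 28, True, ""),
    (80, 24, True, ""),       # bounds inclusive
    (40, 30, True, ""),
    (39, 30, False, "age"),
    (81, 30, False, "age"),
    (66, 23, False, "mmse"),
    (np.nan, 28, False, "missing age"),
])
def test_eligibility(age, mmse, eligible, reason):
    meta = SubjectMeta(subject_id="S", age=age, mmse=mmse)
    got_ok, got_reason = filter_eligibility(meta)
    assert got_ok == eligible
    assert got_reason == reason


def test_missing_item_excludes_from_classification():
    meta = _patient()
    del meta.updrs["3_15a"]
    labels = label_subject(meta)
    assert not labels.eligible
    assert "classification" in labels.exclusion_reason
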
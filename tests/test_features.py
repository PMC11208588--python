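"""Feature catalog: registry, event arithmetic, indices, recovery, assembly."""

import numpy as np
import pytest

from tuggait import registry
from tuggait.clinical import SubjectLabels
from tuggait.features import (
    SIDES,
    SidedFeatures,
    assemble_subject_features,
    asymmetry_index,
    double_support_pct,
    extract_trial_features,
    map_to_mas_las,
    phase_coordination,
    retained_cycles,
    symbolic_symmetry_index,
    temporal_features,
    truth_features,
)


def _labels(mas="none", group="HC"):
    return SubjectLabels("S", group, np.nan, mas, True, "")


# ----------------------------------------------------------------------
# Registry
# ----------------------------------------------------------------------
def test_registry_catalog():
    assert len(registry.FEATURE_NAMES) == 64
    counts = {}
    for name in registry.FEATURE_NAMES:
        counts[registry.FEATURE_CATEGORY[name]] = \
            counts.get(registry.FEATURE_CATEGORY[name], 0) + 1
    assert counts == {"lower": 31, "trunk_lumbar": 12, "upper": 8, "postural": 13}
    assert registry.feature_unit("MAS Swing (%)") == "%"
    assert registry.feature_unit("Turning-Average Steps") == ""


# ----------------------------------------------------------------------
# Event arithmetic
# ----------------------------------------------------------------------
def test_temporal_arithmetic_fixture():
    """HS at 0.0/1.1/2.2/3.3/4.4, TO 0.66 s after each HS: cycle 1.1 s,
    swing 40%, stance 60%."""
    hs_i = np.array([0.0, 1.1, 2.2, 3.3, 4.4])
    to_i = np.array([-0.44, 0.66, 1.76, 2.86, 3.96])
    hs_c = hs_i + 0.55
    out = temporal_features(hs_i, to_i, hs_c, cycles=[0, 1, 2, 3])
    assert out["gait_cycle_s"] == pytest.approx(1.1)
    assert out["swing_pct"] == pytest.approx(40.0)
    assert out["stance_pct"] == pytest.approx(60.0)
    assert out["swing_pct"] + out["stance_pct"] == 100.0
    assert out["cadence_spm"] == pytest.approx(60.0 / 0.55)

    to_c = hs_c - 0.44 + 1.1  # contralateral TO inside each cycle
    ds = double_support_pct(hs_i, hs_c, np.sort(to_c), to_i, [0, 1, 2])
    # symmetric 40% swing: DS = 2*stance - 100 = 20%
    assert ds == pytest.approx(20.0, abs=1e-9)


def test_symmetric_gait_equal_cadence(hc_trial, protocol):
    _, gt = hc_trial
    sf = truth_features(gt, protocol)
    assert sf.sided["Cadence (step/min)"]["left"] == pytest.approx(
        sf.sided["Cadence (step/min)"]["right"], rel=1e-6)


# ----------------------------------------------------------------------
# Asymmetry / symmetry indices
# ----------------------------------------------------------------------
def test_asymmetry_index_examples():
    assert asymmetry_index(1.0, 1.0) == 0.0
    assert asymmetry_index(1.1, 1.0) == pytest.approx(100 * np.log(1.1))
    assert asymmetry_index(1.1, 1.0) == pytest.approx(asymmetry_index(1.0, 1.1),
                                                      abs=1e-12)
    assert np.isnan(asymmetry_index(-1.0, 1.0))


def test_symbolic_symmetry_index():
    assert symbolic_symmetry_index(np.array([1.0, 1.0]), np.array([1.0, 1.0])) == 0.0
    got = symbolic_symmetry_index(np.array([3.0]), np.array([1.0]))
    assert got == pytest.approx(50.0)
    a, b = np.array([2.0, 3.0]), np.array([1.0, 4.0])
    assert symbolic_symmetry_index(a, b) == symbolic_symmetry_index(b, a)


def test_phase_coordination_examples():
    # perfect anti-phase: contralateral HS exactly mid-stride
    hs_l = np.arange(0.0, 10.0, 1.0)
    hs_r = hs_l + 0.5
    mpd, pci = phase_coordination(hs_l, hs_r, list(range(9)))
    assert mpd == pytest.approx(0.0, abs=1e-9)
    assert pci == pytest.approx(0.0, abs=1e-9)

    # constant 0.6 offset: phi = 216 deg, CV = 0, PCI = MPD = 20
    hs_l = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    hs_r = np.array([0.6, 1.6, 2.6, 3.6, 4.6, 5.6])
    mpd, pci = phase_coordination(hs_l, hs_r, list(range(6)))
    assert mpd == pytest.approx(20.0)
    assert pci == pytest.approx(20.0)


def test_pci_matches_brute_force(rng):
    """Pipeline PCI equals an independent step-by-step recomputation."""
    for _ in range(20):
        n = 12
        hs_l = np.cumsum(rng.uniform(0.9, 1.3, n))
        hs_r = hs_l[:-1] + rng.uniform(0.3, 0.7, n - 1)
        cycles = list(range(n - 1))
        mpd, pci = phase_coordination(hs_l, hs_r, cycles)

        # oracle: explicit loop over strides
        phis = []
        for c in cycles:
            inside = [t for t in hs_r if hs_l[c] < t < hs_l[c + 1]]
            if inside:
                phis.append(360.0 * (inside[0] - hs_l[c]) / (hs_l[c + 1] - hs_l[c]))
        mean = sum(phis) / len(phis)
        p_abs = 100.0 * sum(abs(p - 180.0) for p in phis) / len(phis) / 180.0
        sd = (sum((p - mean) ** 2 for p in phis) / (len(phis) - 1)) ** 0.5
        assert mpd == pytest.approx(p_abs, abs=1e-12)
        assert pci == pytest.approx(p_abs + 100.0 * sd / mean, abs=1e-10)


# ----------------------------------------------------------------------
# End-to-end recovery on a noiseless trial
# ----------------------------------------------------------------------
def _tolerance(name: str, truth: float) -> float:
    unit = registry.feature_unit(name)
    tol = 0.02 * abs(truth)
    if unit in ("°", "%"):
        tol = max(tol, 0.5)  # absolute floor for near-zero angles/indices
    return tol


@pytest.mark.parametrize("fixture_name,mas", [("hc_trial", "none"),
                                              ("td_trial", "left")])
def test_noiseless_feature_recovery(request, protocol, fixture_name, mas):
    """Signal-path extraction reproduces the truth channel within 2%
    (0.5 absolute for near-zero angle/index values)."""
    trial, gt = request.getfixturevalue(fixture_name)
    sig = map_to_mas_las(extract_trial_features(trial, protocol=protocol), mas)
    tru = map_to_mas_las(truth_features(gt, protocol), mas)
    failures = []
    for name in registry.FEATURE_NAMES:
        s, t = sig.values[name], tru.values[name]
        if np.isnan(t):
            assert np.isnan(s), f"{name}: truth undefined but signal gave {s}"
            continue
        if abs(s - t) > _tolerance(name, t):
            failures.append((name, s, t))
    assert not failures, failures


def test_swing_stance_sum_everywhere(td_trial, protocol):
    trial, _ = td_trial
    fv = map_to_mas_las(extract_trial_features(trial, protocol=protocol), "left")
    for side in ("MAS", "LAS"):
        assert fv.values[f"{side} Swing (%)"] + fv.values[f"{side} Stance (%)"] \
            == pytest.approx(100.0, abs=1e-9)


def test_mirrored_subject_has_zero_asymmetry(hc_trial, protocol):
    """Perfectly mirrored gait: all asymmetry/symmetry indices near zero and
    invariant under left-right relabeling."""
    _, gt = hc_trial
    sf = truth_features(gt, protocol)
    for name in ("Stride Velocity Asymmetry (%)", "Swing Asymmetry (%)",
                 "Stance Asymmetry (%)", "Shank RoM Asymmetry (%)",
                 "Arm Velocity Asymmetry (%)"):
        assert abs(sf.bilateral[name]) < 0.5
    left = map_to_mas_las(sf, "left").values
    right = map_to_mas_las(sf, "right").values
    for name in registry.LOWER_BILATERAL + registry.UPPER_BILATERAL:
        assert left[name] == pytest.approx(right[name], abs=1e-12)


# ----------------------------------------------------------------------
# Subject-level assembly
# ----------------------------------------------------------------------
def _toy_sided(swing_l=38.0, swing_r=40.0, arm_pv_l=150.0, arm_pv_r=170.0):
    sf = SidedFeatures()
    for stem in registry.LOWER_SIDED + registry.UPPER_SIDED:
        for side in SIDES:
            sf.set_side(stem, side, 1.0)
    sf.set_side("Swing (%)", "left", swing_l)
    sf.set_side("Swing (%)", "right", swing_r)
    sf.set_side("Stance (%)", "left", 100 - swing_l)
    sf.set_side("Stance (%)", "right", 100 - swing_r)
    sf.set_side("Arm Peak Velocity (°/s)", "left", arm_pv_l)
    sf.set_side("Arm Peak Velocity (°/s)", "right", arm_pv_r)
    for name in (registry.LOWER_BILATERAL + registry.TRUNK_LUMBAR_FEATURES
                 + registry.UPPER_BILATERAL + registry.POSTURAL_FEATURES):
        sf.bilateral[name] = 2.0
    return sf


def test_two_identical_trials_mean_is_identity():
    sf = _toy_sided()
    fv1 = assemble_subject_features([sf], _labels())
    fv2 = assemble_subject_features([sf, sf], _labels())
    for name in registry.FEATURE_NAMES:
        assert fv1.values[name] == pytest.approx(fv2.values[name], abs=1e-12)


def test_hc_side_averaging():
    fv = assemble_subject_features([_toy_sided()], _labels("none"))
    assert fv.values["MAS Swing (%)"] == pytest.approx(39.0)
    assert fv.values["LAS Swing (%)"] == pytest.approx(39.0)
    assert fv.values["MAS Stance (%)"] == pytest.approx(61.0)


def test_mas_left_mapping_takes_left_wrist():
    fv = assemble_subject_features(
        [_toy_sided(arm_pv_l=111.0, arm_pv_r=222.0)],
        _labels("left", "TD"))
    assert fv.values["MAS Arm Peak Velocity (°/s)"] == pytest.approx(111.0)
    assert fv.values["LAS Arm Peak Velocity (°/s)"] == pytest.approx(222.0)


def test_missing_feature_propagates_with_flag():
    sf = _toy_sided()
    sf.bilateral["Phase Coordination Index (%)"] = float("nan")
    fv = assemble_subject_features([sf, sf], _labels())
    assert np.isnan(fv.values["Phase Coordination Index (%)"])
    assert "Phase Coordination Index (%)" in fv.qc.get("missing", [])


def test_retained_cycles_drop_bout_edges():
    hs = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    phases = {"walk_out": (0.0, 6.5)}
    assert retained_cycles(hs, phases) == [1, 2, 3, 4]
    assert retained_cycles(hs, phases, drop_edge=False) == [0, 1, 2, 3, 4, 5]
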
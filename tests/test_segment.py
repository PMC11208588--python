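"""Event detection and TUG phase segmentation against the truth channel."""

import numpy as np
import pytest

from tuggait import (
    SegmentationError,
    TugProtocol,
    detect_gait_events,
    detect_turns,
    segment_tug,
    synthesize_trial,
)
from tuggait.trial import CHANNELS, SITES, ImuTrial

from conftest import healthy_phenotype, tremor_dominant_phenotype


def _event_errors_ms(events, gt):
    errs = []
    for side in ("left", "right"):
        det, tru = events.sides[side], gt.sides[side]
        assert len(det.hs) == len(tru.hs), f"{side}: HS count mismatch"
        assert len(det.to) == len(tru.to), f"{side}: TO count mismatch"
        errs.extend(np.abs(det.hs - tru.hs) * 1000)
        errs.extend(np.abs(det.to - tru.to) * 1000)
    return np.asarray(errs)


def test_noiseless_events_within_30_ms(hc_trial):
    trial, gt = hc_trial
    errs = _event_errors_ms(detect_gait_events(trial), gt)
    assert errs.max() <= 30.0


def test_asymmetric_jittered_events_within_30_ms(td_trial):
    trial, gt = td_trial
    errs = _event_errors_ms(detect_gait_events(trial), gt)
    assert errs.max() <= 30.0


def test_stationary_trial_flagged():
    n = 1000
    t = np.arange(n) / 100.0
    streams = {s: np.tile([0.0, 0.0, 1.0, 0.0, 0.0, 0.0], (n, 1)) for s in SITES}
    trial = ImuTrial("S", "T", 100.0, t, streams)
    events = detect_gait_events(trial)
    for side in ("left", "right"):
        assert len(events.sides[side].hs) == 0
        assert "insufficient strides" in events.sides[side].flags
    with pytest.raises(SegmentationError, match="turn not found"):
        segment_tug(trial, events)


def test_stride_count_matches_construction(protocol):
    """1.0 s stride over both 5 m legs -> mean steady inter-HS interval 1.0 s."""
    ph = healthy_phenotype(stride_time_s=1.0)
    trial, gt = synthesize_trial(ph, protocol, seed=2)
    events = detect_gait_events(trial)
    for side in ("left", "right"):
        hs = events.sides[side].hs
        assert len(hs) == len(gt.sides[side].hs)
        d = np.diff(hs)
        steady = d[np.abs(d - 1.0) < 0.15]
        assert np.mean(steady) == pytest.approx(1.0, abs=5e-3)


def test_turn_duration_and_yaw(td_trial):
    trial, gt = td_trial
    turns = detect_turns(trial)
    assert len(turns) == len(gt.turns) == 2
    for det, tru in zip(turns, gt.turns):
        assert det["duration"] == pytest.approx(tru["duration"], abs=0.1)
        assert 150.0 <= abs(det["yaw_deg"]) <= 210.0
        assert det["peak_dps"] == pytest.approx(tru["peak_dps"], rel=0.02)


def test_phase_assembly_matches_truth(td_trial):
    trial, gt = td_trial
    phases = segment_tug(trial, detect_gait_events(trial))
    for name in ("sist", "walk_out", "turn", "walk_back", "pre_sit_turn", "stsi"):
        a, b = phases.intervals[name]
        ta, tb = gt.phases[name]
        assert a == pytest.approx(ta, abs=0.12)
        assert b == pytest.approx(tb, abs=0.12)
    ordered = sorted(phases.intervals.values())
    for (a1, b1), (a2, b2) in zip(ordered, ordered[1:]):
        assert b1 <= a2 + 1e-9
    total = sum(b - a for a, b in phases.intervals.values())
    assert total <= trial.duration_s


def test_gyro_bias_invariance(hc_trial):
    """Adding a constant gyro bias <= 1 deg/s leaves event times unchanged."""
    trial, _ = hc_trial
    ref = detect_gait_events(trial)
    biased_streams = {}
    for site in SITES:
        arr = trial.streams[site].copy()
        arr[:, 3:] += 1.0
        biased_streams[site] = arr
    biased = ImuTrial(trial.subject_id, trial.trial_id, trial.fs_hz,
                      trial.t, biased_streams)
    got = detect_gait_events(biased)
    for side in ("left", "right"):
        np.testing.assert_allclose(got.sides[side].hs, ref.sides[side].hs,
                                   atol=5e-3)
        np.testing.assert_allclose(got.sides[side].to, ref.sides[side].to,
                                   atol=5e-3)


@pytest.mark.parametrize("seed", [101, 202, 303, 404])
def test_event_alternation_property(protocol, seed):
    """Detected events alternate TO->HS per side for random valid phenotypes."""
    rng = np.random.default_rng(seed)
    ph = tremor_dominant_phenotype(
        stride_time_s=float(rng.uniform(0.95, 1.3)),
        step_timing_jitter_cv=float(rng.uniform(0.0, 0.05)),
        amp_jitter_cv_shank=float(rng.uniform(0.0, 0.2)),
        sensor_noise_sd_gyro_dps=float(rng.uniform(0.0, 3.0)),
    )
    trial, _ = synthesize_trial(ph, protocol, seed=seed)
    events = detect_gait_events(trial)
    for side in ("left", "right"):
        ev = events.sides[side]
        merged = np.empty(2 * len(ev.hs))
        merged[0::2] = ev.to
        merged[1::2] = ev.hs
        assert np.all(np.diff(merged) > 0)


def test_events_tagged_with_phases(td_trial):
    trial, _ = td_trial
    events = detect_gait_events(trial)
    phases = segment_tug(trial, events)
    frame = events.to_frame(phases)
    assert set(frame.columns) == {"event", "side", "time_s", "phase"}
    tags = set(frame["phase"])
    assert {"walk_out", "walk_back", "turn"} <= tags
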
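"""TUG segmentation: gait events, turns, chair transfers, phase assembly.

Gait events follow the classic shank-gyroscope scheme: in the sagittal shank
angular velocity, each gait cycle shows a dominant positive mid-swing peak;
heel strike (HS) is the first prominent negative peak after mid-swing and toe
off (TO) the last prominent negative peak before it.  Turns are found on the
lumbar yaw rate with a threshold + hysteresis rule validated by the
integrated yaw angle; chair transfers are found from the trunk pitch-velocity
envelope at the start and end of the trial.  Phase edges produced by
threshold crossings are refined by extrapolating the velocity ramp to zero,
which removes most of the corner rounding introduced by zero-phase filtering.

Timebase is seconds from trial start; intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .trial import GYR_RANGE_DPS, ImuTrial

#: zero-phase low-pass cutoffs (Hz)
F_EVENTS = 5.0     # gait-event detection on shank gyro
F_ENVELOPE = 1.5   # turn / transfer envelopes
F_VALUES = 12.0    # channels used for peak-magnitude feature extraction

TURN_THRESHOLD_DPS = 15.0
TURN_RELEASE_DPS = 5.0
TURN_MIN_DURATION_S = 0.5
TURN_MIN_YAW_DEG = 90.0
TRANSFER_THRESHOLD_DPS = 3.0


class SegmentationError(RuntimeError):
    pass


def lowpass(y: np.ndarray, fs: float, fc: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass."""
    sos = signal.butter(order, fc, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, y)


# ----------------------------------------------------------------------
# Orientation estimation
# ----------------------------------------------------------------------
def complementary_tilt(acc_num, acc_den, gyro_dps, fs, alpha=0.01, sign=1.0):
    """First-order complementary filter fusing gyro integration with the
    accelerometer tilt estimate ``atan2(sign * acc_num, acc_den)`` (degrees).
    """
    th_acc = np.rad2deg(np.arctan2(sign * acc_num, acc_den))
    dt = 1.0 / fs
    u = (1.0 - alpha) * gyro_dps * dt + alpha * th_acc
    b, a = [1.0], [1.0, -(1.0 - alpha)]
    # steady-state initialization at the first accelerometer tilt estimate
    zi = signal.lfilter_zi(b, a) * (alpha * th_acc[0])
    th, _ = signal.lfilter(b, a, u, zi=zi)
    return th


def sagittal_tilt(trial: ImuTrial, site: str, alpha: float = 0.01) -> np.ndarray:
    """Pitch (anterior-positive tilt) of a site, degrees."""
    acc = trial.acc(site)
    return complementary_tilt(acc[:, 0], acc[:, 2], trial.gyr(site)[:, 1],
                              trial.fs_hz, alpha, sign=-1.0)


def coronal_tilt(trial: ImuTrial, site: str, alpha: float = 0.01) -> np.ndarray:
    """Roll (left-positive lean) of a site, degrees."""
    acc = trial.acc(site)
    return complementary_tilt(acc[:, 1], acc[:, 2], trial.gyr(site)[:, 0],
                              trial.fs_hz, alpha, sign=1.0)


def yaw_angle(trial: ImuTrial, site: str) -> np.ndarray:
    """Yaw from gyro integration (degrees, arbitrary origin)."""
    gz = trial.gyr(site)[:, 2]
    out = np.concatenate([[0.0], np.cumsum((gz[1:] + gz[:-1]) / 2.0)]) / trial.fs_hz
    return out


# ----------------------------------------------------------------------
# Gait events
# ----------------------------------------------------------------------
@dataclass
class SideEvents:
    hs: np.ndarray
    to: np.ndarray
    flags: list = field(default_factory=list)


@dataclass
class GaitEventTable:
    """Per-side heel-strike and toe-off times (seconds).

    ``to[i]`` precedes ``hs[i]``; the swing of step *i* is ``(to[i], hs[i])``.
    """

    sides: dict[str, SideEvents]
    flags: list = field(default_factory=list)

    def to_frame(self, phases: "TugPhases | None" = None) -> pd.DataFrame:
        rows = []
        for side, ev in self.sides.items():
            for kind in ("hs", "to"):
                for t in getattr(ev, kind):
                    rows.append({"event": kind.upper(), "side": side, "time_s": t,
                                 "phase": phases.phase_at(t) if phases else ""})
        return pd.DataFrame(rows).sort_values("time_s", ignore_index=True)


def _parabolic_refine(y: np.ndarray, i: int, fs: float) -> float:
    """Sub-sample peak location via 3-point parabola (returns seconds)."""
    if i <= 0 or i >= len(y) - 1:
        return i / fs
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return i / fs
    return (i + 0.5 * (a - c) / denom) / fs


def detect_gait_events(trial: ImuTrial) -> GaitEventTable:
    """Detect per-side HS/TO from the ankle sagittal gyroscope."""
    fs = trial.fs_hz
    sides = {}
    flags = []
    for side, site in (("left", "ankle_l"), ("right", "ankle_r")):
        raw = trial.gyr(site)[:, 1].copy()
        saturated = np.abs(raw) >= GYR_RANGE_DPS - 0.5
        if saturated.any():
            raw[saturated] = 0.0
            flags.append(f"{side}: saturated gyro samples masked")
        y = lowpass(raw, fs, F_EVENTS)
        y = y - np.median(y)  # bias/detrend contract
        # wider-band copy for sub-sample peak timing (coarse-to-fine)
        y_fine = lowpass(raw, fs, F_VALUES)
        y_fine = y_fine - np.median(y_fine)

        top = np.percentile(np.abs(y), 99)
        if top < 20.0:
            sides[side] = SideEvents(np.array([]), np.array([]),
                                     ["insufficient strides"])
            flags.append(f"{side}: no gait activity")
            continue
        ms_idx, _ = signal.find_peaks(y, height=0.35 * top,
                                      distance=int(0.4 * fs),
                                      prominence=0.25 * top)
        neg_idx, _ = signal.find_peaks(-y, prominence=max(10.0, 0.05 * top))
        if len(ms_idx) < 3:
            sides[side] = SideEvents(np.array([]), np.array([]),
                                     ["insufficient strides"])
            flags.append(f"{side}: fewer than 3 swing cycles")
            continue

        hs, to = [], []
        for k, ms in enumerate(ms_idx):
            after = neg_idx[(neg_idx > ms) & (neg_idx < ms + int(0.9 * fs))]
            before_lo = ms_idx[k - 1] if k > 0 else 0
            before = neg_idx[(neg_idx < ms) & (neg_idx > before_lo)]
            if len(after) == 0 or len(before) == 0:
                continue
            w = int(0.08 * fs)

            def fine(i):
                lo, hi = max(i - w, 1), min(i + w + 1, len(y_fine) - 1)
                j = lo + int(np.argmin(y_fine[lo:hi]))
                return _parabolic_refine(-y_fine, j, fs)

            hs.append(fine(after[0]))
            to.append(fine(before[-1]))
        sides[side] = SideEvents(np.asarray(hs), np.asarray(to))
    return GaitEventTable(sides=sides, flags=flags)


# ----------------------------------------------------------------------
# Phase detection
# ----------------------------------------------------------------------
@dataclass
class TugPhases:
    """Ordered phase intervals, half-open [start, end) in seconds."""

    intervals: dict[str, tuple[float, float]]
    warnings: list = field(default_factory=list)

    def phase_at(self, t: float) -> str:
        for name, (a, b) in self.intervals.items():
            if a <= t < b:
                return name
        return ""

    def walking(self):
        return [(n, iv) for n, iv in self.intervals.items()
                if n in ("walk_out", "walk_back")]

    def turning(self):
        return [(n, iv) for n, iv in self.intervals.items()
                if n in ("turn", "pre_sit_turn")]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"phase": n, "start_s": a, "end_s": b}
             for n, (a, b) in sorted(self.intervals.items(), key=lambda kv: kv[1][0])]
        )


def _ramp_zero_crossing(t, y, i_lo, i_hi, rising):
    """Extrapolate the near-linear ramp between two indices to its zero."""
    if i_hi - i_lo < 3:
        return t[i_lo if rising else i_hi]
    seg_t = t[i_lo:i_hi]
    seg_y = y[i_lo:i_hi]
    A = np.vstack([seg_t, np.ones_like(seg_t)]).T
    m, b = np.linalg.lstsq(A, seg_y, rcond=None)[0]
    if m == 0:
        return seg_t[0]
    return -b / m


def _refine_pulse_edges(t, y_abs, i0, i1, fs, strong_frac=0.05):
    """Refine the [i0, i1) edges of a |velocity| pulse by ramp extrapolation.

    Each edge is fitted on the samples between 30% and 70% of the *local*
    sub-pulse peak nearest that edge (the linear part of a trapezoid ramp),
    and the fitted line is extrapolated to zero.  ``strong_frac`` sets the
    sub-lobe detection level relative to the pulse maximum (single-lobed
    pulses can use a high level to ignore unrelated neighbouring activity).
    """
    gmax = y_abs[i0:i1].max()
    # anchor each edge on the outermost sustained sub-lobe (robust to flat
    # trapezoid plateaus, where peak prominence is ill-defined)
    strong = y_abs[i0:i1] > max(3.0, strong_frac * gmax)
    min_run = max(3, int(0.08 * fs))
    runs = []
    k = 0
    n_reg = i1 - i0
    while k < n_reg:
        if not strong[k]:
            k += 1
            continue
        j = k
        while j < n_reg and strong[j]:
            j += 1
        if j - k >= min_run:
            runs.append((k, j))
        k = j
    if not runs:
        runs = [(0, n_reg)]
    r0, r1 = runs[0], runs[-1]
    p_rise = i0 + r0[0] + int(np.argmax(y_abs[i0 + r0[0]:i0 + r0[1]]))
    p_fall = i0 + r1[0] + int(np.argmax(y_abs[i0 + r1[0]:i0 + r1[1]]))

    def one_edge(rising):
        if rising:
            lo_i, hi_i, peak = i0, p_rise, y_abs[p_rise]
        else:
            lo_i, hi_i, peak = p_fall, i1 - 1, y_abs[p_fall]
        band = (y_abs[lo_i:hi_i + 1] >= 0.3 * peak) & (y_abs[lo_i:hi_i + 1] <= 0.7 * peak)
        idx = np.flatnonzero(band) + lo_i
        if len(idx) < 3:
            return t[i0] if rising else t[i1 - 1]
        # keep the contiguous run adjacent to the sub-pulse peak
        if rising:
            rev = idx[::-1]
            run = rev[np.concatenate([[True], -np.diff(rev) == 1]).cumprod().astype(bool)][::-1]
        else:
            run = idx[np.concatenate([[True], np.diff(idx) == 1]).cumprod().astype(bool)]
        if len(run) < 3:
            run = idx[-3:] if rising else idx[:3]
        return _ramp_zero_crossing(t, y_abs, run[0], run[-1] + 1, rising)

    start, end = one_edge(True), one_edge(False)
    if not np.isfinite(start) or not np.isfinite(end) or end <= start:
        return float(t[i0]), float(t[i1 - 1])
    # extrapolation must stay near the detected region
    start = float(np.clip(start, t[i0] - 0.3, t[min(p_rise, i1 - 1)]))
    end = float(np.clip(end, t[max(p_fall, i0)], t[i1 - 1] + 0.3))
    return start, end


def detect_turns(trial: ImuTrial) -> list[dict]:
    """Candidate turns on the lumbar yaw rate; each dict carries start, end,
    duration, integrated yaw and peak yaw rate."""
    fs = trial.fs_hz
    t = trial.t
    raw = trial.gyr("lumbar")[:, 2]
    y = lowpass(raw, fs, F_ENVELOPE)
    y_signed = lowpass(raw, fs, F_VALUES)        # wide band: edge + peak reads
    y_val = np.abs(y_signed)
    y_ref = y_val
    ya = np.abs(y)
    above = ya > TURN_THRESHOLD_DPS
    turns = []
    i = 0
    n = len(ya)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and ya[j] > TURN_RELEASE_DPS:
            j += 1
        # expand backwards to the release level too
        k = i
        while k > 0 and ya[k - 1] > TURN_RELEASE_DPS:
            k -= 1
        yaw_region = np.trapezoid(y[k:j], t[k:j])
        start, end = _refine_pulse_edges(t, y_ref, k, j, fs, strong_frac=0.35)
        dur = end - start
        if dur >= TURN_MIN_DURATION_S and abs(yaw_region) >= TURN_MIN_YAW_DEG:
            # integrated yaw from the wide-band copy over the refined window
            # plus a small margin, so the ramp tails are fully captured
            iw = slice(np.searchsorted(t, start - 0.25),
                       np.searchsorted(t, end + 0.25))
            yaw = float(np.trapezoid(y_signed[iw], t[iw]))
            turns.append({"start": start, "end": end, "duration": dur,
                          "yaw_deg": yaw,
                          "peak_dps": float(y_val[k:j].max())})
        i = j + 1
    return turns


def _detect_transfer(t, y_env, y_ref, fs, lo_s, hi_s):
    """One chair transfer inside the search window [lo_s, hi_s)."""
    i0, i1 = np.searchsorted(t, lo_s), np.searchsorted(t, hi_s)
    if i1 - i0 < 5:
        return None
    ya = np.abs(y_env[i0:i1])
    if ya.max() < TRANSFER_THRESHOLD_DPS:
        return None
    active = ya > TRANSFER_THRESHOLD_DPS
    # merge active sub-lobes separated by < 0.8 s
    idx = np.flatnonzero(active)
    groups = []
    g0 = idx[0]
    prev = idx[0]
    for k in idx[1:]:
        if k - prev > int(0.8 * fs):
            groups.append((g0, prev))
            g0 = k
        prev = k
    groups.append((g0, prev))
    # take the run of groups containing the global maximum
    imax = int(np.argmax(ya))
    sel = [g for g in groups if not (g[1] < imax - int(3.0 * fs) or g[0] > imax + int(3.0 * fs))]
    a = min(g[0] for g in sel) + i0
    b = max(g[1] for g in sel) + i0 + 1
    start, end = _refine_pulse_edges(t, np.abs(y_ref), a, b, fs)
    return {"start": float(start), "end": float(end),
            "duration": float(end - start)}


def segment_tug(trial: ImuTrial, events: GaitEventTable) -> TugPhases:
    """Assemble TUG phases from turns, transfers and the gait-event span."""
    fs = trial.fs_hz
    t = trial.t
    warnings = []

    turns = detect_turns(trial)
    if not turns:
        raise SegmentationError("turn not found")

    ev_times = np.concatenate([
        np.concatenate([ev.hs, ev.to]) for ev in events.sides.values()
    ]) if events.sides else np.array([])
    first_ev = float(ev_times.min()) if len(ev_times) else turns[0]["start"]
    last_ev = float(ev_times.max()) if len(ev_times) else turns[-1]["end"]

    pitch_raw = trial.gyr("chest")[:, 1]
    pitch_vel = lowpass(pitch_raw, fs, F_ENVELOPE)
    pitch_ref = lowpass(pitch_raw, fs, F_VALUES)
    sist = _detect_transfer(t, pitch_vel, pitch_ref, fs, 0.0, max(first_ev - 0.05, 0.3))
    # the stand-to-sit search starts after both the last gait event and the
    # last turn, clear of the residual walking trunk oscillation
    stsi_lo = max(last_ev + 0.3, turns[-1]["end"] + 0.25)
    stsi = _detect_transfer(t, pitch_vel, pitch_ref, fs, stsi_lo, t[-1])
    if sist is None:
        warnings.append("no initial sit-to-stand transfer detected")
    if stsi is None:
        warnings.append("no final stand-to-sit transfer detected")

    snap = lambda x: float(np.round(x * fs) / fs)
    intervals = {}
    if sist:
        intervals["sist"] = (snap(sist["start"]), snap(sist["end"]))
    walk_start = snap(sist["end"]) if sist else 0.0

    mid_turns = [tu for tu in turns]
    t1 = mid_turns[0]
    intervals["walk_out"] = (walk_start, snap(t1["start"]))
    intervals["turn"] = (snap(t1["start"]), snap(t1["end"]))
    if len(mid_turns) > 1:
        t2 = mid_turns[1]
        intervals["walk_back"] = (snap(t1["end"]), snap(t2["start"]))
        intervals["pre_sit_turn"] = (snap(t2["start"]), snap(t2["end"]))
        back_end = snap(t2["end"])
    else:
        back_end = snap(stsi["start"]) if stsi else last_ev
        intervals["walk_back"] = (snap(t1["end"]), back_end)
    if stsi:
        intervals["stsi"] = (snap(stsi["start"]), snap(stsi["end"]))

    # resolve any overlap by precedence transfers > turns > walking
    ordered = sorted(intervals.items(), key=lambda kv: kv[1][0])
    for (n1, iv1), (n2, iv2) in zip(ordered, ordered[1:]):
        if iv1[1] > iv2[0]:
            warnings.append(f"overlap between {n1} and {n2} resolved")
            prio = {"sist": 3, "stsi": 3, "turn": 2, "pre_sit_turn": 2}
            if prio.get(n1, 1) >= prio.get(n2, 1):
                intervals[n2] = (iv1[1], max(iv2[1], iv1[1]))
            else:
                intervals[n1] = (iv1[0], iv2[0])

    return TugPhases(intervals=intervals, warnings=warnings)
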
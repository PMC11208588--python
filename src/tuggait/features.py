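"""The 64-feature gait/postural catalog computed from a segmented TUG trial.

Steady-state gait features use straight-walk gait cycles only: cycles fully
inside a walking phase, with the first and last cycle of each walking bout
dropped to exclude acceleration/deceleration transients.  Turning cycles
contribute only to the turning metrics.

Asymmetry indices use the log-ratio convention ``100 * |ln(x_MAS / x_LAS)|``
(zero iff the sides are equal, symmetric under side exchange).  The Symbolic
Symmetry Index is implemented as the normalized per-cycle amplitude
asymmetry ``100 * mean(|A_L - A_R| / (A_L + A_R))`` over paired left/right
cycles, where A is the swing angular amplitude of the shank or the arm.

The same aggregation code runs on two inputs: the signal path (detected
events + estimated orientations) and the simulator truth channel, which makes
round-trip recovery a meaningful end-to-end check of the signal processing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import registry
from .kinematics import arm_cycle_kinematics, plane_cycle_stats, shank_cycle_kinematics
from .segment import (
    F_VALUES,
    GaitEventTable,
    TugPhases,
    coronal_tilt,
    detect_gait_events,
    detect_turns,
    lowpass,
    sagittal_tilt,
    segment_tug,
    yaw_angle,
)
from .trial import ImuTrial

G0 = 9.80665  # m/s^2 per g

MIN_PHASE_SAMPLES = 5   # minimum left-right phase samples for the PCI block
MIN_CYCLES = 3          # minimum straight-walk cycles per side

SIDES = ("left", "right")


@dataclass
class SidedFeatures:
    """Per-trial features before MAS/LAS mapping.

    ``sided[stem][side]`` holds side-specific values (stems are the registry
    display stems, e.g. ``"Swing (%)"``); ``bilateral`` holds side-free
    features under their final registry names.
    """

    sided: dict = field(default_factory=dict)
    bilateral: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)

    def set_side(self, stem: str, side: str, value: float) -> None:
        self.sided.setdefault(stem, {})[side] = float(value)


@dataclass
class FeatureVector:
    """Final 64-entry feature mapping for one subject (or one mapped trial)."""

    values: dict[str, float]
    qc: dict = field(default_factory=dict)

    def validate(self) -> None:
        names = set(self.values)
        expected = set(registry.FEATURE_NAMES)
        if names != expected:
            extra = sorted(names - expected)
            missing = sorted(expected - names)
            raise ValueError(f"feature set mismatch; extra={extra} missing={missing}")
        for side in ("MAS", "LAS"):
            sw = self.values[f"{side} Swing (%)"]
            st = self.values[f"{side} Stance (%)"]
            if not (np.isnan(sw) or np.isnan(st)):
                assert abs(sw + st - 100.0) < 1e-9

    def to_series(self) -> pd.Series:
        return pd.Series({n: self.values[n] for n in registry.FEATURE_NAMES})


# ----------------------------------------------------------------------
# Cycle bookkeeping
# ----------------------------------------------------------------------
def retained_cycles(hs: np.ndarray, phases: TugPhases | dict,
                    drop_edge="both") -> list[int]:
    """Indices of straight-walk cycles, minus bout-edge transients.

    Cycle *c* is ``[hs[c], hs[c+1])``; it is retained when fully inside one
    walking phase.  ``drop_edge`` selects the transient policy: ``"both"``
    drops each bout's first and last cycle when the bout can spare them
    (short bouts keep the terminal cycle), ``"first"`` drops only the start
    transient (used for phase coordination, which needs every stable stride
    but must exclude the step pattern right after standing up or turning),
    and ``False`` keeps everything.
    """
    if drop_edge is True:
        drop_edge = "both"
    intervals = phases.intervals if isinstance(phases, TugPhases) else phases
    walk = [iv for n, iv in intervals.items() if n in ("walk_out", "walk_back")]
    per_bout: dict[int, list[int]] = {}
    for c in range(len(hs) - 1):
        for b, (a, e) in enumerate(walk):
            if hs[c] >= a and hs[c + 1] <= e:
                per_bout.setdefault(b, []).append(c)
                break
    out = []
    for b, idx in sorted(per_bout.items()):
        if drop_edge is False:
            out.extend(idx)
        elif drop_edge == "first":
            out.extend(idx[1:] if len(idx) > 1 else idx)
        elif len(idx) > 3:          # bout can spare both transients
            out.extend(idx[1:-1])
        elif len(idx) > 1:          # short bout: drop the start transient only
            out.extend(idx[1:])
        else:
            out.extend(idx)
    return out


def asymmetry_index(a: float, b: float) -> float:
    """Log-ratio asymmetry, percent: ``100 |ln(a/b)|``; NaN if non-positive."""
    if not (a > 0 and b > 0) or math.isnan(a) or math.isnan(b):
        return float("nan")
    return 100.0 * abs(math.log(a / b))


def symbolic_symmetry_index(amp_l: np.ndarray, amp_r: np.ndarray) -> float:
    """100 * mean over paired cycles of |A_L - A_R| / (A_L + A_R)."""
    n = min(len(amp_l), len(amp_r))
    if n == 0:
        return float("nan")
    al, ar = np.asarray(amp_l[:n], float), np.asarray(amp_r[:n], float)
    ok = np.isfinite(al) & np.isfinite(ar) & (al + ar > 0)
    if not ok.any():
        return float("nan")
    return float(100.0 * np.mean(np.abs(al[ok] - ar[ok]) / (al[ok] + ar[ok])))


# ----------------------------------------------------------------------
# Feature blocks operating on event times
# ----------------------------------------------------------------------
def temporal_features(hs_i, to_i, hs_c, cycles) -> dict:
    """Temporal block for one side given its retained cycle indices.

    ``hs_i``/``to_i`` are the ipsilateral event arrays (``to_i[k]`` precedes
    ``hs_i[k]``), ``hs_c`` the contralateral heel strikes.
    """
    out = {k: float("nan") for k in
           ("gait_cycle_s", "cadence_spm", "swing_pct", "stance_pct", "double_support_pct")}
    if len(cycles) < MIN_CYCLES:
        return out
    ct = np.array([hs_i[c + 1] - hs_i[c] for c in cycles])
    swing = np.array([(hs_i[c + 1] - to_i[c + 1]) / (hs_i[c + 1] - hs_i[c]) for c in cycles])
    out["gait_cycle_s"] = float(ct.mean())
    out["swing_pct"] = float(100.0 * swing.mean())
    out["stance_pct"] = 100.0 - out["swing_pct"]

    # step time ending on this side: previous contralateral HS -> ipsilateral HS
    steps = []
    for c in cycles:
        t_hs = hs_i[c + 1]
        k = np.searchsorted(hs_c, t_hs)
        if k > 0:
            steps.append(t_hs - hs_c[k - 1])
    if steps:
        out["cadence_spm"] = float(60.0 / np.mean(steps))
    return out


def double_support_pct(hs_i, hs_c, to_c, to_i, cycles) -> float:
    """Both double-support sub-phases as a percentage of the gait cycle."""
    vals = []
    for c in cycles:
        a, b = hs_i[c], hs_i[c + 1]
        # initial DS: ipsi HS -> next contralateral TO
        k = np.searchsorted(to_c, a)
        if k >= len(to_c) or to_c[k] >= b:
            continue
        ds1 = to_c[k] - a
        # terminal DS: contralateral HS -> ipsilateral TO (to_i[c+1])
        m = np.searchsorted(hs_c, a)
        if m >= len(hs_c) or hs_c[m] >= b:
            continue
        ds2 = to_i[c + 1] - hs_c[m]
        if ds1 < 0 or ds2 < 0:
            continue
        vals.append(100.0 * (ds1 + ds2) / (b - a))
    return float(np.mean(vals)) if vals else float("nan")


def phase_coordination(hs_ref, hs_other, cycles) -> tuple[float, float]:
    """(Mean Phase Difference %, Phase Coordination Index %).

    For each retained reference-side stride, phi = 360 * (contralateral HS -
    stride start) / stride duration.  MPD = 100 * mean|phi - 180| / 180;
    PCI adds the phase coefficient of variation 100 * SD(phi)/mean(phi).
    """
    phis = []
    for c in cycles:
        a, b = hs_ref[c], hs_ref[c + 1]
        k = np.searchsorted(hs_other, a, side="right")
        if k >= len(hs_other) or hs_other[k] >= b:
            continue
        phis.append(360.0 * (hs_other[k] - a) / (b - a))
    if len(phis) < MIN_PHASE_SAMPLES:
        return float("nan"), float("nan")
    phis = np.asarray(phis)
    p_abs = 100.0 * np.mean(np.abs(phis - 180.0)) / 180.0
    phi_cv = 100.0 * np.std(phis, ddof=1) / np.mean(phis)
    return float(p_abs), float(p_abs + phi_cv)


# ----------------------------------------------------------------------
# Signal-path kinematic inputs
# ----------------------------------------------------------------------
def _zupt_foot_positions(trial: ImuTrial, side: str) -> list[tuple[float, float]]:
    """(time, x-position) of foot placements from ZUPT double integration.

    Stance is where the foot gyro is quiet and the accelerometer magnitude is
    near 1 g; each swing's world-frame acceleration is double-integrated with
    a linear velocity-drift correction (velocity returns to zero at the next
    stance).  Positions accumulate from the feet-together start of the trial.
    """
    site = f"foot_{side[0]}"
    fs = trial.fs_hz
    acc = trial.acc(site)
    gyr = trial.gyr(site)
    a_w = (acc - np.array([0.0, 0.0, 1.0])) * G0  # sensor frame ~ world frame
    quiet = (np.max(np.abs(gyr), axis=1) < 10.0) & \
            (np.abs(np.linalg.norm(acc, axis=1) - 1.0) < 0.05)
    # a stance must be sustained: drop quiet runs shorter than ~0.1 s
    k = int(0.05 * fs)
    if k > 0:
        from scipy.ndimage import binary_opening
        quiet = binary_opening(quiet, structure=np.ones(2 * k + 1))

    pos = 0.0
    placements = []
    n = len(quiet)
    i = 0
    dt = 1.0 / fs
    while i < n:
        if quiet[i]:
            i += 1
            continue
        j = i
        while j < n and not quiet[j]:
            j += 1
        # swing run [i, j): integrate with end-velocity correction
        seg = a_w[i:j, 0]
        v = np.cumsum(seg) * dt
        if len(v) > 1:
            v = v - np.linspace(0.0, v[-1], len(v))
        dx = float(np.sum(v) * dt)
        pos += dx
        placements.append((trial.t[min(j, n - 1)], pos))
        i = j
    return placements


def _step_lengths_from_placements(plc_l, plc_r, phases) -> dict:
    """Per-side mean step length (cm) over straight-walk steps."""
    events = sorted(
        [(t, "left", x) for t, x in plc_l] + [(t, "right", x) for t, x in plc_r]
    )
    intervals = phases.intervals if isinstance(phases, TugPhases) else phases
    walk = [iv for n, iv in intervals.items() if n in ("walk_out", "walk_back")]
    out = {"left": [], "right": []}
    for (t0, s0, x0), (t1, s1, x1) in zip(events, events[1:]):
        if s0 == s1:
            continue
        in_walk = any(a <= t1 <= b for a, b in walk)
        if in_walk:
            out[s1].append(abs(x1 - x0) * 100.0)
    return {s: (float(np.mean(v)) if v else float("nan")) for s, v in out.items()}


# ----------------------------------------------------------------------
# Assembly of a sided per-trial feature set
# ----------------------------------------------------------------------
def _finish_sided(
    sf: SidedFeatures,
    hs, to, cycles, pci_cycles,
    shank_cyc, arm_cyc, plane_stats,
    step_len_cm, steps_per_walk, walk_distance_m,
    turn_list, transfer_stats,
) -> SidedFeatures:
    """Fold per-side inputs into the sided feature structure.

    All inputs are plain arrays/dicts so the simulator truth channel and the
    signal path can share this code.
    """
    # --- temporal + shank + arm, per side ---
    for s in SIDES:
        o = "right" if s == "left" else "left"
        cyc = cycles[s]
        tf = temporal_features(hs[s], to[s], hs[o], cyc)
        sf.set_side("Gait Cycle time (s)", s, tf["gait_cycle_s"])
        sf.set_side("Cadence (step/min)", s, tf["cadence_spm"])
        sf.set_side("Swing (%)", s, tf["swing_pct"])
        sf.set_side("Stance (%)", s, tf["stance_pct"])
        sf.set_side("Double Support (%)", s,
                    double_support_pct(hs[s], hs[o], to[o], to[s], cyc))

        fwd, bwd, pv = shank_cyc[s]
        sel = [c for c in cyc if c < len(fwd)]
        sf.set_side("Shank Forward Swing Maximum (°)", s,
                    float(np.nanmean(fwd[sel])) if sel else float("nan"))
        sf.set_side("Shank Backward Swing Maximum (°)", s,
                    float(np.nanmean(bwd[sel])) if sel else float("nan"))
        sf.set_side("Peak Shank Angular Velocity (°/s)", s,
                    float(np.nanmean(pv[sel])) if sel else float("nan"))

        afwd, abwd, apv = arm_cyc[s]
        sel = [c for c in cyc if c < len(afwd)]
        sf.set_side("Arm Forward Swing Maximum (°)", s,
                    float(np.nanmean(afwd[sel])) if sel else float("nan"))
        sf.set_side("Arm Backward Swing Maximum (°)", s,
                    float(np.nanmean(abwd[sel])) if sel else float("nan"))
        sf.set_side("Arm Peak Velocity (°/s)", s,
                    float(np.nanmean(apv[sel])) if sel else float("nan"))

        # spatial: path-length stride, placement-based step length
        if steps_per_walk:
            stride_cm = float(np.mean(
                [200.0 * walk_distance_m / n for n in steps_per_walk if n > 0]
            ))
        else:
            stride_cm = float("nan")
        sf.set_side("Stride Length (cm)", s, stride_cm)
        gct = tf["gait_cycle_s"]
        sf.set_side("Stride Velocity (m/s)", s,
                    stride_cm / 100.0 / gct if gct and np.isfinite(gct) else float("nan"))
        sf.set_side("Step Length (cm)", s, step_len_cm.get(s, float("nan")))

    sv = sf.sided
    # --- bilateral lower-body indices ---
    pairs = {
        "Stride Velocity Asymmetry (%)": "Stride Velocity (m/s)",
        "Stride Length Asymmetry (%)": "Stride Length (cm)",
        "Swing Asymmetry (%)": "Swing (%)",
        "Stance Asymmetry (%)": "Stance (%)",
        "Peak Shank Angular Velocity Asymmetry (%)": "Peak Shank Angular Velocity (°/s)",
    }
    for name, stem in pairs.items():
        sf.bilateral[name] = asymmetry_index(sv[stem]["left"], sv[stem]["right"])
    rom = {s: sv["Shank Forward Swing Maximum (°)"][s]
           - sv["Shank Backward Swing Maximum (°)"][s] for s in SIDES}
    sf.bilateral["Shank RoM Asymmetry (%)"] = asymmetry_index(rom["left"], rom["right"])

    amp = {}
    for s in SIDES:
        fwd, bwd, _ = shank_cyc[s]
        sel = [c for c in cycles[s] if c < len(fwd)]
        amp[s] = (fwd[sel] - bwd[sel]) if sel else np.array([])
    sf.bilateral["Shank Symbolic Symmetry Index (%)"] = \
        symbolic_symmetry_index(amp["left"], amp["right"])
    aamp = {}
    for s in SIDES:
        afwd, abwd, _ = arm_cyc[s]
        sel = [c for c in cycles[s] if c < len(afwd)]
        aamp[s] = (afwd[sel] - abwd[sel]) if sel else np.array([])
    sf.bilateral["Arm Symbolic Symmetry Index (%)"] = \
        symbolic_symmetry_index(aamp["left"], aamp["right"])
    sf.bilateral["Arm Velocity Asymmetry (%)"] = asymmetry_index(
        sv["Arm Peak Velocity (°/s)"]["left"], sv["Arm Peak Velocity (°/s)"]["right"])

    mpd, pci = phase_coordination(hs["left"], hs["right"], pci_cycles)
    sf.bilateral["Mean Phase Difference (%)"] = mpd
    sf.bilateral["Phase Coordination Index (%)"] = pci

    # --- trunk / lumbar ---
    for sensor, label in (("trunk", "Trunk"), ("lumbar", "Lumbar")):
        for plane, plabel in (("coronal", "Coronal"), ("sagittal", "Sagittal"),
                              ("transverse", "Transverse")):
            rom_arr, pv_arr = plane_stats[f"{sensor}_{plane}"]
            sf.bilateral[f"{label} {plabel} RoM (°)"] = \
                float(np.nanmean(rom_arr)) if len(rom_arr) else float("nan")
            sf.bilateral[f"{label} {plabel} Peak Velocity (°/s)"] = \
                float(np.nanmean(pv_arr)) if len(pv_arr) else float("nan")

    # --- postural transitions ---
    if turn_list:
        durs = np.array([tu["duration"] for tu in turn_list], float)
        peaks = np.array([tu["peak_dps"] for tu in turn_list], float)
        yaws = np.array([abs(tu.get("yaw_deg", 180.0)) for tu in turn_list], float)
        steps_n = np.array([tu["steps"] for tu in turn_list], float)
        sf.bilateral["Turning-Average Duration (s)"] = float(durs.mean())
        sf.bilateral["Turning-Peak Velocity (°/s)"] = float(peaks.mean())
        sf.bilateral["Turning-Average Angular Velocity (°/s)"] = float((yaws / durs).mean())
        sf.bilateral["Turning-Average Steps"] = float(steps_n.mean())
        with np.errstate(divide="ignore"):
            sf.bilateral["Turning-Average Step Duration (s)"] = \
                float(np.mean(durs / np.maximum(steps_n, 1)))
    else:
        for k in ("Turning-Average Duration (s)", "Turning-Peak Velocity (°/s)",
                  "Turning-Average Angular Velocity (°/s)", "Turning-Average Steps",
                  "Turning-Average Step Duration (s)"):
            sf.bilateral[k] = float("nan")
        sf.qc.setdefault("flags", []).append("no turn detected")

    for key, label in (("sist", "SiSt"), ("stsi", "StSi")):
        tr = transfer_stats.get(key)
        if tr is None:
            for k in ("Duration (s)", "Trunk Sagittal Peak Velocity (°/s)",
                      "Trunk Lean Backward Maximum (°)", "Trunk Lean Forward Maximum (°)"):
                sf.bilateral[f"{label}-{k}"] = float("nan")
            sf.qc.setdefault("flags", []).append(f"no {label} transfer")
            continue
        sf.bilateral[f"{label}-Duration (s)"] = tr["duration"]
        sf.bilateral[f"{label}-Trunk Sagittal Peak Velocity (°/s)"] = tr["peak_velocity_dps"]
        sf.bilateral[f"{label}-Trunk Lean Backward Maximum (°)"] = tr["lean_bwd_max_deg"]
        sf.bilateral[f"{label}-Trunk Lean Forward Maximum (°)"] = tr["lean_fwd_max_deg"]

    sf.qc["cycles_per_side"] = {s: len(cycles[s]) for s in SIDES}
    return sf


# ----------------------------------------------------------------------
# Public extraction paths
# ----------------------------------------------------------------------
def extract_trial_features(
    trial: ImuTrial,
    events: GaitEventTable | None = None,
    phases: TugPhases | None = None,
    protocol=None,
) -> SidedFeatures:
    """Signal-path extraction: events, phases and kinematics from the streams."""
    from .phenotype import TugProtocol

    protocol = protocol or TugProtocol()
    events = events or detect_gait_events(trial)
    phases = phases or segment_tug(trial, events)

    hs = {s: events.sides[s].hs for s in SIDES}
    to = {s: events.sides[s].to for s in SIDES}
    cycles = {s: retained_cycles(hs[s], phases) for s in SIDES}

    fs = trial.fs_hz
    shank_cyc, arm_cyc = {}, {}
    for s in SIDES:
        th_sh = sagittal_tilt(trial, f"ankle_{s[0]}")
        om_sh = lowpass(trial.gyr(f"ankle_{s[0]}")[:, 1], fs, F_VALUES)
        shank_cyc[s] = shank_cycle_kinematics(trial.t, th_sh, om_sh, hs[s], to[s]) \
            if len(hs[s]) > 1 else (np.array([]), np.array([]), np.array([]))
        th_a = sagittal_tilt(trial, f"wrist_{s[0]}")
        om_a = lowpass(trial.gyr(f"wrist_{s[0]}")[:, 1], fs, F_VALUES)
        arm_cyc[s] = arm_cycle_kinematics(trial.t, th_a, om_a, hs[s]) \
            if len(hs[s]) > 1 else (np.array([]), np.array([]), np.array([]))

    # trunk / lumbar per-plane cycle stats over retained left cycles
    base = hs["left"]
    cyc_iv = [(base[c], base[c + 1]) for c in cycles["left"]]
    plane_stats = {}
    for sensor, site in (("trunk", "chest"), ("lumbar", "lumbar")):
        th = {
            "coronal": coronal_tilt(trial, site),
            "sagittal": sagittal_tilt(trial, site),
            "transverse": yaw_angle(trial, site),
        }
        for i, plane in enumerate(("coronal", "sagittal", "transverse")):
            om = lowpass(trial.gyr(site)[:, i], fs, F_VALUES)
            plane_stats[f"{sensor}_{plane}"] = plane_cycle_stats(
                trial.t, th[plane], om, cyc_iv)

    # spatial inputs
    all_hs = np.sort(np.concatenate([hs["left"], hs["right"]]))
    steps_per_walk = []
    for name, (a, b) in phases.walking():
        steps_per_walk.append(int(((all_hs >= a) & (all_hs < b)).sum()))
    plc_l = _zupt_foot_positions(trial, "left")
    plc_r = _zupt_foot_positions(trial, "right")
    step_len_cm = _step_lengths_from_placements(plc_l, plc_r, phases)

    # turning details (with step counts from the event table)
    turn_list = []
    for tu in detect_turns(trial):
        k = int(((all_hs >= tu["start"]) & (all_hs < tu["end"])).sum())
        turn_list.append({**tu, "steps": k})

    # transfers: trunk pitch statistics inside the detected windows
    pitch = sagittal_tilt(trial, "chest")
    pitch_vel = lowpass(trial.gyr("chest")[:, 1], fs, F_VALUES)
    transfer_stats = {}
    for key in ("sist", "stsi"):
        if key not in phases.intervals:
            continue
        a, b = phases.intervals[key]
        m = (trial.t >= a) & (trial.t < b)
        transfer_stats[key] = {
            "duration": b - a,
            "peak_velocity_dps": float(np.abs(pitch_vel[m]).max()),
            "lean_fwd_max_deg": float(pitch[m].min()),
            "lean_bwd_max_deg": float(pitch[m].max()),
        }

    sf = SidedFeatures()
    pci_cycles = retained_cycles(hs["left"], phases, drop_edge="first")
    return _finish_sided(sf, hs, to, cycles, pci_cycles, shank_cyc, arm_cyc,
                         plane_stats, step_len_cm, steps_per_walk,
                         protocol.distance_m, turn_list, transfer_stats)


def truth_features(gt, protocol=None) -> SidedFeatures:
    """Ground-truth path: identical aggregation on the simulator truth channel."""
    from .phenotype import TugProtocol

    protocol = protocol or TugProtocol()
    hs = {s: gt.sides[s].hs for s in SIDES}
    to = {s: gt.sides[s].to for s in SIDES}
    cycles = {s: retained_cycles(hs[s], gt.phases) for s in SIDES}

    shank_cyc = {s: (gt.sides[s].shank_fwd, gt.sides[s].shank_bwd, gt.sides[s].shank_pv)
                 for s in SIDES}
    arm_cyc = {s: (gt.sides[s].arm_fwd, gt.sides[s].arm_bwd, gt.sides[s].arm_pv)
               for s in SIDES}

    left_cycles = cycles["left"]
    plane_stats = {
        k: (v[0][left_cycles], v[1][left_cycles]) for k, v in gt.plane_cycles.items()
    }

    steps_per_walk = []
    step_lists = {"left": [], "right": []}
    for name in ("walk_out", "walk_back"):
        a, b = gt.phases[name]
        in_phase = [st for st in gt.steps if a <= st["hs"] < b]
        steps_per_walk.append(len(in_phase))
        for st in in_phase:
            step_lists[st["side"]].append(st["step_length_m"] * 100.0)
    step_len_cm = {s: (float(np.mean(v)) if v else float("nan"))
                   for s, v in step_lists.items()}

    turn_list = [{"duration": tu["duration"], "peak_dps": tu["peak_dps"],
                  "yaw_deg": 180.0, "steps": tu["steps"]} for tu in gt.turns]
    transfer_stats = {
        k: {"duration": tr["duration"], "peak_velocity_dps": tr["peak_velocity_dps"],
            "lean_fwd_max_deg": tr["lean_fwd_max_deg"],
            "lean_bwd_max_deg": tr["lean_bwd_max_deg"]}
        for k, tr in gt.transfers.items()
    }

    sf = SidedFeatures()
    pci_cycles = retained_cycles(hs["left"], gt.phases, drop_edge="first")
    return _finish_sided(sf, hs, to, cycles, pci_cycles, shank_cyc, arm_cyc,
                         plane_stats, step_len_cm, steps_per_walk,
                         protocol.distance_m, turn_list, transfer_stats)


# ----------------------------------------------------------------------
# MAS/LAS mapping and subject-level assembly
# ----------------------------------------------------------------------
def map_to_mas_las(sf: SidedFeatures, mas_side: str) -> FeatureVector:
    """Map sided stems onto MAS/LAS names; controls average the two sides."""
    values = {}
    for stem in registry.LOWER_SIDED + registry.UPPER_SIDED:
        lv = sf.sided.get(stem, {}).get("left", float("nan"))
        rv = sf.sided.get(stem, {}).get("right", float("nan"))
        if mas_side == "none":
            vals = [v for v in (lv, rv) if not np.isnan(v)]
            mas_v = las_v = float(np.mean(vals)) if vals else float("nan")
        elif mas_side == "left":
            mas_v, las_v = lv, rv
        else:
            mas_v, las_v = rv, lv
        values[f"MAS {stem}"] = mas_v
        values[f"LAS {stem}"] = las_v
    for name in (registry.LOWER_BILATERAL + registry.TRUNK_LUMBAR_FEATURES
                 + registry.UPPER_BILATERAL + registry.POSTURAL_FEATURES):
        values[name] = sf.bilateral.get(name, float("nan"))
    fv = FeatureVector(values=values, qc=dict(sf.qc))
    fv.validate()
    return fv


def assemble_subject_features(trial_features: list[SidedFeatures], labels) -> FeatureVector:
    """Element-wise mean across a subject's trials, then MAS/LAS mapping.

    ``labels`` is a ``SubjectLabels`` (its ``mas_side`` drives the mapping;
    controls use 'none' and get the side average).  Features undefined in all
    trials propagate as NaN with a QC flag.
    """
    if not trial_features:
        raise ValueError("at least one trial is required")
    merged = SidedFeatures()
    stems = set()
    for tf in trial_features:
        stems.update(tf.sided)
    for stem in stems:
        for side in SIDES:
            vals = [tf.sided.get(stem, {}).get(side, float("nan"))
                    for tf in trial_features]
            with np.errstate(invalid="ignore"):
                merged.set_side(stem, side, np.nanmean(vals) if not
                                all(np.isnan(v) for v in vals) else float("nan"))
    names = set()
    for tf in trial_features:
        names.update(tf.bilateral)
    for name in names:
        vals = [tf.bilateral.get(name, float("nan")) for tf in trial_features]
        merged.bilateral[name] = (float(np.nanmean(vals))
                                  if not all(np.isnan(v) for v in vals) else float("nan"))
    flags = [f for tf in trial_features for f in tf.qc.get("flags", [])]
    if flags:
        merged.qc["flags"] = flags
    missing = [n for n, v in merged.bilateral.items() if isinstance(v, float) and np.isnan(v)]
    if missing:
        merged.qc["missing"] = missing
    # keep swing + stance = 100 exact after averaging
    for side in SIDES:
        sw = merged.sided.get("Swing (%)", {}).get(side, float("nan"))
        if np.isfinite(sw):
            merged.set_side("Stance (%)", side, 100.0 - sw)
    return map_to_mas_las(merged, getattr(labels, "mas_side", "none"))
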
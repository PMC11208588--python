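"""Synthetic TUG trial generator with an exact ground-truth channel.

The simulator builds a deterministic event schedule first (chair transfers,
steps, turns), then renders per-segment angle trajectories as sums of analytic
Gaussian angular-velocity lobes placed at the scheduled events, so that the
gyroscope is the exact analytic derivative of the angle track and both are
known in closed form.  Accelerometers read the gravity projection through the
segment orientation; foot sensors additionally carry the translational motion
term so that zero-velocity-update integration can recover foot placements.

The ground truth records phase intervals, per-side heel-strike (HS) and
toe-off (TO) times, foot placements, and the realized per-cycle kinematic
extrema, all pre-noise and exact at the commanded schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .kinematics import arm_cycle_kinematics, plane_cycle_stats, shank_cycle_kinematics
from .phenotype import GaitPhenotype, PhenotypeError, TugProtocol
from .trial import ImuTrial, quantize

G0 = 9.80665  # m/s^2 per g

_SPLIT_HS = 0.6  # fraction of the stance descent carried by the foot-flat lobe

WALK_PHASES = ("walk_out", "walk_back")
TURN_PHASES = ("turn", "pre_sit_turn")


# ----------------------------------------------------------------------
# Ground-truth containers
# ----------------------------------------------------------------------
@dataclass
class SideTruth:
    """Per-side true events and realized per-cycle kinematics.

    ``to[i]`` is the toe-off that precedes ``hs[i]``; the swing interval of
    step *i* is ``(to[i], hs[i])``.  Per-cycle arrays have length
    ``len(hs) - 1`` and describe cycle *c* = ``[hs[c], hs[c+1])``.
    """

    hs: np.ndarray
    to: np.ndarray
    shank_fwd: np.ndarray
    shank_bwd: np.ndarray
    shank_pv: np.ndarray
    arm_fwd: np.ndarray
    arm_bwd: np.ndarray
    arm_pv: np.ndarray


@dataclass
class GroundTruth:
    mas_side: str
    phases: dict[str, tuple[float, float]]
    sides: dict[str, SideTruth]
    steps: list[dict]
    turns: list[dict]
    transfers: dict[str, dict]
    trunk_lumbar: dict[str, float]
    stride_length_m: float
    phenotype: GaitPhenotype = field(repr=False)
    #: left-side gait-cycle intervals used as the trunk/lumbar cycle base
    cycle_list: list = field(default_factory=list)
    #: '{sensor}_{plane}' -> (per-cycle RoM, per-cycle peak |velocity|)
    plane_cycles: dict = field(default_factory=dict)

    def events_in_phase(self, side: str, phase: str) -> np.ndarray:
        a, b = self.phases[phase]
        hs = self.sides[side].hs
        return hs[(hs >= a) & (hs < b)]

    # -- JSON sidecar ---------------------------------------------------
    def to_json(self, path=None) -> str:
        def arr(a):
            return np.asarray(a, dtype=float).tolist()

        doc = {
            "mas_side": self.mas_side,
            "phases": {k: [float(v[0]), float(v[1])] for k, v in self.phases.items()},
            "sides": {
                s: {k: arr(getattr(st, k)) for k in (
                    "hs", "to", "shank_fwd", "shank_bwd", "shank_pv",
                    "arm_fwd", "arm_bwd", "arm_pv")}
                for s, st in self.sides.items()
            },
            "steps": self.steps,
            "turns": self.turns,
            "transfers": self.transfers,
            "trunk_lumbar": self.trunk_lumbar,
            "stride_length_m": self.stride_length_m,
            "phenotype": {k: v for k, v in self.phenotype.__dict__.items()},
            "cycle_list": [[float(a), float(b)] for a, b in self.cycle_list],
            "plane_cycles": {k: [arr(v[0]), arr(v[1])] for k, v in self.plane_cycles.items()},
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        sides = {
            s: SideTruth(**{k: np.asarray(v, dtype=float) for k, v in d.items()})
            for s, d in doc["sides"].items()
        }
        return cls(
            mas_side=doc["mas_side"],
            phases={k: tuple(v) for k, v in doc["phases"].items()},
            sides=sides,
            steps=doc["steps"],
            turns=doc["turns"],
            transfers=doc["transfers"],
            trunk_lumbar=doc["trunk_lumbar"],
            stride_length_m=doc["stride_length_m"],
            phenotype=GaitPhenotype(**doc["phenotype"]),
            cycle_list=[tuple(c) for c in doc.get("cycle_list", [])],
            plane_cycles={
                k: (np.asarray(v[0]), np.asarray(v[1]))
                for k, v in doc.get("plane_cycles", {}).items()
            },
        )


# ----------------------------------------------------------------------
# Analytic signal primitives
# ----------------------------------------------------------------------
def _emit_lobes(t: np.ndarray, lobes) -> tuple[np.ndarray, np.ndarray]:
    """Sum Gaussian velocity lobes; return (omega, theta) evaluated on ``t``.

    Each lobe is ``(center_s, area_deg, sigma_s)``; theta is the exact
    analytic integral, so omega == d(theta)/dt identically.
    """
    om = np.zeros_like(t)
    th = np.zeros_like(t)
    inv_sqrt2pi = 1.0 / np.sqrt(2.0 * np.pi)
    for c, a, s in lobes:
        i0 = np.searchsorted(t, c - 6.0 * s)
        i1 = np.searchsorted(t, c + 6.0 * s)
        u = (t[i0:i1] - c) / s
        om[i0:i1] += a * inv_sqrt2pi / s * np.exp(-0.5 * u * u)
        th[i0:i1] += a * 0.5 * (1.0 + erf(u / np.sqrt(2.0)))
        th[i1:] += a
    return om, th


def _trap_pulse(t, t0, dur, peak, ramp, ramp_dn=None):
    """Trapezoidal velocity pulse (optionally asymmetric ramps); returns
    (omega, theta) with theta -> area = peak * (dur - (ramp + ramp_dn)/2)."""
    if ramp_dn is None:
        ramp_dn = ramp
    area = peak * (dur - 0.5 * (ramp + ramp_dn))
    s = t - t0
    om = np.zeros_like(t)
    th = np.zeros_like(t)
    m1 = (s >= 0) & (s < ramp)
    m2 = (s >= ramp) & (s < dur - ramp_dn)
    m3 = (s >= dur - ramp_dn) & (s < dur)
    m4 = s >= dur
    om[m1] = peak * s[m1] / ramp
    om[m2] = peak
    om[m3] = peak * (dur - s[m3]) / ramp_dn
    th[m1] = 0.5 * peak * s[m1] ** 2 / ramp
    th[m2] = 0.5 * peak * ramp + peak * (s[m2] - ramp)
    th[m3] = area - 0.5 * peak * (dur - s[m3]) ** 2 / ramp_dn
    th[m4] = area
    return om, th


def _oscillation_lobes(cycles, rom, pv, lead_T):
    """Lobes for a ±RoM/2 per-cycle oscillation over contiguous cycle bouts.

    ``cycles`` is a list of (start, end) gait-cycle intervals, grouped into
    bouts wherever consecutive cycles are non-contiguous.  Interior lobes have
    area RoM and a width chosen so their peak rate equals ``pv``.
    """
    if rom <= 0 or not cycles:
        return []
    # width floor keeps the commanded peak inside the analysis band
    sigma = max(rom / (pv * np.sqrt(2.0 * np.pi)), 0.04)
    lobes = []
    prev_end = None
    for (a, b) in cycles:
        T = b - a
        if prev_end is None or a - prev_end > 1e-9:
            # new bout: lead-in from 0 to +RoM/2 just before the bout
            if prev_end is not None:
                lobes.append((prev_end + 0.25 * lead_T, -rom / 2.0, sigma))
            lobes.append((a - 0.20 * T, rom / 2.0, sigma))
        # +R/2 at a+0.25T, -R/2 at a+0.75T
        lobes.append((a + 0.5 * T, -rom, sigma))
        lobes.append((b, rom, sigma))
        prev_end = b
    # final return to neutral: after the last cycle theta sits at +R/2
    lobes.append((prev_end + 0.25 * lead_T, -rom / 2.0, sigma))
    return lobes


# ----------------------------------------------------------------------
# Schedule
# ----------------------------------------------------------------------
@dataclass
class _Schedule:
    t_end: float
    phases: dict
    steps: list            # dicts: side, hs, phase, step_length_m, position, prev_position
    turns: list            # dicts: start, end, peak_dps, ramp_s, steps, direction
    transfers: dict        # name -> dict(start, dur, d1, d2, d3, pv, fwd, bwd)
    side_hs: dict          # side -> np.ndarray of HS times
    side_to: dict
    stride_length_m: float
    sl_realized: dict      # side -> realized mean step length (m)


def _side_param(ph: GaitPhenotype, stem: str, side: str, mas_side: str, suffix: str = "") -> float:
    which = "mas" if side == mas_side else "las"
    return getattr(ph, f"{stem}_{which}{suffix}")


def _build_schedule(ph: GaitPhenotype, prot: TugProtocol, rng, mas_side: str) -> _Schedule:
    T = ph.stride_time_s
    tau = {}
    tau[mas_side] = ph.step_phase_fraction_mas * T
    other = "right" if mas_side == "left" else "left"
    tau[other] = T - tau[mas_side]

    sl = {s: _side_param(ph, "step_length", s, mas_side, "_cm") / 100.0 for s in ("left", "right")}
    stride_m = sl["left"] + sl["right"]
    dist = prot.distance_m

    n_steps = max(4, round(2.0 * dist / stride_m))
    first_side = "left"

    def walk_steps(n, start_side):
        sides, s = [], start_side
        for _ in range(n):
            sides.append(s)
            s = "right" if s == "left" else "left"
        return sides

    out_sides = walk_steps(n_steps, first_side)
    # scale per-side step lengths so each walking leg covers the course exactly
    n_by = {s: out_sides.count(s) for s in ("left", "right")}
    factor = dist / (n_by["left"] * sl["left"] + n_by["right"] * sl["right"])
    sl_real = {s: sl[s] * factor for s in ("left", "right")}

    def jit():
        if ph.step_timing_jitter_cv == 0:
            return 0.0
        return float(np.clip(rng.normal(0.0, ph.step_timing_jitter_cv), -3 * ph.step_timing_jitter_cv, 3 * ph.step_timing_jitter_cv))

    steps = []
    turns = []
    k_turn = max(1, int(round(ph.turn_steps)))
    tau_t = ph.turn_duration_s / k_turn
    ramp = ph.turn_duration_s - 180.0 / ph.turn_peak_velocity_dps

    t_sist = prot.initial_sit_s
    sist_end = t_sist + ph.sist_duration_s
    t_walk0 = sist_end + prot.stand_pause_s

    pos = {"left": 0.0, "right": 0.0}
    t_cur = t_walk0
    last_side = None

    def add_walk_leg(sides, direction, phase):
        nonlocal t_cur, last_side
        for s in sides:
            t_cur = t_cur + tau[s] * (1.0 + jit())
            newpos = pos["right" if s == "left" else "left"] + direction * sl_real[s]
            steps.append({
                "side": s, "hs": t_cur, "phase": phase,
                "step_length_m": abs(newpos - pos["right" if s == "left" else "left"]),
                "position": newpos, "prev_position": pos[s],
            })
            pos[s] = newpos
            last_side = s

    def add_turn(phase):
        nonlocal t_cur, last_side
        start = t_cur + 0.15
        side = "right" if last_side == "left" else "left"
        for i in range(k_turn):
            hs = start + (i + 0.5) * tau_t
            jig = 0.04 if i % 2 == 0 else -0.04
            newpos = pos[side] + jig
            steps.append({
                "side": side, "hs": hs, "phase": phase,
                "step_length_m": abs(jig), "position": newpos, "prev_position": pos[side],
            })
            pos[side] = newpos
            last_side = side
            side = "right" if side == "left" else "left"
        end = start + ph.turn_duration_s
        turns.append({
            "start": start, "end": end, "peak_dps": ph.turn_peak_velocity_dps,
            "ramp_s": ramp, "steps": k_turn, "direction": 1.0,
            "duration": ph.turn_duration_s,
        })
        t_cur = end
        return start, end

    add_walk_leg(out_sides, +1.0, "walk_out")
    t1a, t1b = add_turn("turn")
    back_sides = walk_steps(n_steps, "right" if last_side == "left" else "left")
    add_walk_leg(back_sides, -1.0, "walk_back")
    if prot.include_presit_turn:
        t2a, t2b = add_turn("pre_sit_turn")
    else:
        t2a = t2b = t_cur
    t_stsi = t2b + prot.pre_sit_pause_s
    stsi_end = t_stsi + ph.stsi_duration_s
    t_end = stsi_end + prot.end_pause_s

    phases = {
        "sist": (t_sist, sist_end),
        "walk_out": (sist_end, t1a),
        "turn": (t1a, t1b),
        "walk_back": (t1b, t2a),
        "stsi": (t_stsi, stsi_end),
    }
    if prot.include_presit_turn:
        phases["pre_sit_turn"] = (t2a, t2b)

    # per-side HS and TO times
    side_hs, side_to = {}, {}
    for s in ("left", "right"):
        hs = np.array([st["hs"] for st in steps if st["side"] == s])
        swing = _side_param(ph, "swing_fraction", s, mas_side)
        to = np.empty_like(hs)
        to[0] = hs[0] - swing * T
        if len(hs) > 1:
            to[1:] = hs[:-1] + (1.0 - swing) * np.diff(hs)
        side_hs[s], side_to[s] = hs, to

    def trans(name):
        dur = getattr(ph, f"{name}_duration_s")
        pv = getattr(ph, f"{name}_peak_velocity_dps")
        fwd = getattr(ph, f"{name}_lean_fwd_max_deg")
        bwd = getattr(ph, f"{name}_lean_bwd_max_deg")
        d2 = (bwd - fwd) / (0.7 * pv)
        rest = dur - d2
        # outer segments: wide enough to be band-limited AND slow enough
        # that their peaks stay below the commanded main-lobe velocity
        # (outer ramp 0.3*d, inner ramp 0.1*d -> peak_i = lean_i / (0.8 d_i))
        need1 = abs(fwd) / (0.76 * pv)
        need3 = bwd / (0.76 * pv)
        d1 = max(0.35, need1, rest * abs(fwd) / (abs(fwd) + bwd))
        d3 = rest - d1
        if d3 < max(0.35, need3):
            d3 = max(0.35, need3)
            d1 = max(rest - d3, need1, 0.3)
        return {"dur": dur, "d1": d1, "d2": d2, "d3": d3, "pv": pv, "fwd": fwd, "bwd": bwd}

    transfers = {"sist": {"start": t_sist, **trans("sist")},
                 "stsi": {"start": t_stsi, **trans("stsi")}}

    return _Schedule(
        t_end=t_end, phases=phases, steps=steps, turns=turns, transfers=transfers,
        side_hs=side_hs, side_to=side_to,
        stride_length_m=stride_m * factor, sl_realized=sl_real,
    )


# ----------------------------------------------------------------------
# Per-segment track builders
# ----------------------------------------------------------------------
def _jitter_series(n, cv, rng):
    if cv == 0 or n == 0:
        return np.ones(n)
    eta = 1.0 + rng.normal(0.0, cv, size=n)
    return np.clip(eta, 0.25, 1.75)


def _shank_track(t, hs, to, fwd, bwd, pv, swing_T, ev_sigma,
                 hs_off=None, to_off=None):
    """Shank sagittal angle/rate: per-cycle forward/backward extrema with
    negative velocity peaks at HS and TO and a mid-swing positive peak.

    fwd/bwd/pv are per-step arrays aligned with ``hs`` (value reached at that
    HS / during the swing ending at that HS).  ``hs_off``/``to_off`` shift the
    event lobe centers so the realized negative peaks land exactly on the
    scheduled event times despite neighbouring-lobe overlap.
    """
    if hs_off is None:
        hs_off = np.zeros(len(hs))
    if to_off is None:
        to_off = np.zeros(len(to))
    lobes = []
    prev_level = 0.0  # standing
    for i in range(len(hs)):
        b = bwd[i]
        f = fwd[i]
        # descent to backward extreme: at lead TO it is a single lobe from
        # standing; afterwards it is split between the previous HS and this TO
        if i == 0:
            lobes.append((to[0] + to_off[0], b - prev_level, ev_sigma))
        else:
            drop = prev_level - b
            lobes.append((hs[i - 1] + hs_off[i - 1], -_SPLIT_HS * drop, ev_sigma))
            lobes.append((to[i] + to_off[i], -(1.0 - _SPLIT_HS) * drop, ev_sigma))
        # swing rise to the forward extreme, peak velocity pv[i]; the lobe
        # width is capped so it stays separated from the event lobes
        area = f - b
        sigma = area / (pv[i] * np.sqrt(2.0 * np.pi))
        sigma = float(np.clip(sigma, 0.015, 0.24 * max(hs[i] - to[i], 0.1)))
        lobes.append(((to[i] + hs[i]) / 2.0, area, sigma))
        prev_level = f
    # final heel strike still shows its foot-flat lobe; the rest of the
    # descent is a gentle return to standing, well clear of the HS peak
    lobes.append((hs[-1] + hs_off[-1], -_SPLIT_HS * prev_level, ev_sigma))
    lobes.append((hs[-1] + 1.5 * swing_T, -(1.0 - _SPLIT_HS) * prev_level, 3.0 * ev_sigma))
    return _emit_lobes(t, lobes)


def _peak_time_errors(t, y, events, fs):
    """Time offsets of the local maxima of ``y`` nearest each event (s)."""
    err = np.zeros(len(events))
    w = int(0.08 * fs)
    for i, e in enumerate(events):
        k = int(round(e * fs))
        lo, hi = max(k - w, 1), min(k + w, len(y) - 2)
        if hi <= lo:
            continue
        j = lo + int(np.argmax(y[lo:hi]))
        a, b, c = y[j - 1], y[j], y[j + 1]
        den = a - 2 * b + c
        frac = 0.5 * (a - c) / den if den != 0 else 0.0
        err[i] = (j + frac) / fs - e
    return err


def _arm_track(t, hs, fwd, bwd, pv, T_nom):
    """Arm sagittal angle/rate: backward extreme at each ipsilateral HS,
    forward extreme mid-cycle; anterior-positive sign convention."""
    lobes = []
    sig = lambda area, p: max(abs(area) / (p * np.sqrt(2.0 * np.pi)), 0.05)
    # lead-in from hanging rest (0) to the first backward extreme
    lobes.append((hs[0] - 0.25 * T_nom, bwd[0], sig(max(abs(bwd[0]), 2.0), pv[0])))
    for c in range(len(hs) - 1):
        a, b = hs[c], hs[c + 1]
        Tc = b - a
        up = fwd[c] - bwd[c]
        down = bwd[min(c + 1, len(bwd) - 1)] - fwd[c]
        lobes.append((a + 0.25 * Tc, up, sig(up, pv[c])))
        lobes.append((a + 0.75 * Tc, down, sig(down, pv[c])))
    lobes.append((hs[-1] + 0.3 * T_nom, -bwd[-1], sig(max(abs(bwd[-1]), 2.0), pv[-1])))
    return _emit_lobes(t, lobes)


def _foot_motion(t, steps_for_side, to, hs, fs):
    """World-frame foot kinematics: (x, z, ax, az) with raised-cosine swing
    velocity and a sine-squared vertical lift; stationary during stance."""
    x = np.zeros_like(t)
    z = np.zeros_like(t)
    ax = np.zeros_like(t)
    az = np.zeros_like(t)
    lift = 0.05
    cur = steps_for_side[0]["prev_position"] if steps_for_side else 0.0
    x[:] = cur
    for i, st in enumerate(steps_for_side):
        t0, t1 = to[i], hs[i]
        Tsw = t1 - t0
        dx = st["position"] - st["prev_position"]
        i0, i1 = np.searchsorted(t, t0), np.searchsorted(t, t1)
        u = (t[i0:i1] - t0) / Tsw
        x[i0:i1] = st["prev_position"] + dx * (u - np.sin(2 * np.pi * u) / (2 * np.pi))
        x[i1:] = st["position"]
        vmax = 2.0 * dx / Tsw
        ax[i0:i1] = vmax * np.pi / Tsw * np.sin(2 * np.pi * u)
        z[i0:i1] = lift * 0.5 * (1 - np.cos(2 * np.pi * u))
        az[i0:i1] = lift * 2 * np.pi ** 2 / Tsw ** 2 * np.cos(2 * np.pi * u)
    return x, z, ax, az


def _tilt_accel(theta_sag_deg, phi_cor_deg=None):
    """Gravity reaction in the sensor frame for pitch/roll in degrees."""
    th = np.deg2rad(theta_sag_deg)
    ph = np.deg2rad(phi_cor_deg) if phi_cor_deg is not None else 0.0
    ax = -np.sin(th)
    ay = np.sin(ph) * np.cos(th) if phi_cor_deg is not None else np.zeros_like(th)
    az = np.cos(th) * (np.cos(ph) if phi_cor_deg is not None else 1.0)
    return ax, ay, az


# ----------------------------------------------------------------------
# Main entry points
# ----------------------------------------------------------------------
def synthesize_trial(
    phenotype: GaitPhenotype,
    protocol: TugProtocol | None = None,
    seed: int = 0,
    mas_side: str = "left",
    subject_id: str = "S000",
    trial_id: str = "T1",
) -> tuple[ImuTrial, GroundTruth]:
    """Render one synthetic TUG trial and its exact ground truth.

    Deterministic given ``seed``; ground-truth event times and realized
    per-cycle values are pre-noise and exact at the commanded schedule.
    """
    prot = protocol or TugProtocol()
    phenotype.validate(prot)
    if mas_side not in ("left", "right"):
        raise PhenotypeError("mas_side must be 'left' or 'right'")
    rng = np.random.default_rng(seed)

    sched = _build_schedule(phenotype, prot, rng, mas_side)
    fs = prot.fs_hz
    n = int(np.ceil(sched.t_end * fs)) + 1
    t = np.arange(n) / fs

    ph = phenotype
    T = ph.stride_time_s
    ev_sigma = float(np.clip(0.045 * T, 0.03, 0.06))

    streams = {}
    truth_sides = {}

    # ---- per-side shank / arm / thigh / foot -------------------------
    for s in ("left", "right"):
        hs, to = sched.side_hs[s], sched.side_to[s]
        m = len(hs)
        fwd0 = _side_param(ph, "shank_fwd_max_deg", s, mas_side)
        bwd0 = _side_param(ph, "shank_bwd_max_deg", s, mas_side)
        pv0 = _side_param(ph, "shank_peak_velocity_dps", s, mas_side)
        eta = _jitter_series(m, ph.amp_jitter_cv_shank, rng)
        rng0 = fwd0 - bwd0
        fwd = fwd0 + (eta - 1.0) * rng0 / 2.0
        bwd = bwd0 - (eta - 1.0) * rng0 / 2.0
        pv = pv0 * (1.0 + 0.25 * (eta - 1.0))  # velocity varies less than amplitude
        swing_T = _side_param(ph, "swing_fraction", s, mas_side) * T
        # Fixed-point correction: neighbouring lobes overlap, so the realized
        # extrema undershoot the targets; 3 sweeps pull them to the commanded
        # values within ~0.1 deg.
        F_t, B_t, P_t = fwd.copy(), bwd.copy(), pv.copy()
        hs_off = np.zeros(len(hs))
        to_off = np.zeros(len(to))
        for _ in range(18):
            om_sh, th_sh = _shank_track(t, hs, to, F_t, B_t, P_t, swing_T,
                                        ev_sigma, hs_off, to_off)
            sf, sb, sp = shank_cycle_kinematics(t, th_sh, om_sh, hs, to)
            # damped, clamped updates: overlapping lobes couple neighbouring
            # cycles, and near the feasibility edge the fixed point may not
            # exist -- the clamps keep the rendered signal physiologic and
            # the truth channel records whatever is realized
            F_t[1:] = np.clip(F_t[1:] + 0.8 * (fwd[1:] - sf),
                              fwd[1:] - 15.0, fwd[1:] + 15.0)
            B_t[1:] = np.clip(B_t[1:] + 0.8 * (bwd[1:] - sb),
                              bwd[1:] - 15.0, bwd[1:] + 15.0)
            P_t[1:] = np.clip(P_t[1:] * np.clip(pv[1:] / np.maximum(sp, 1.0),
                                                0.5, 2.0) ** 0.8,
                              0.5 * pv[1:], 1.8 * pv[1:])
            hs_off -= np.clip(_peak_time_errors(t, -om_sh, hs, fs), -0.03, 0.03)
            to_off -= np.clip(_peak_time_errors(t, -om_sh, to, fs), -0.03, 0.03)
            # the cumulative shift must never move a lobe off its event
            np.clip(hs_off, -0.05, 0.05, out=hs_off)
            np.clip(to_off, -0.05, 0.05, out=to_off)
        om_sh, th_sh = _shank_track(t, hs, to, F_t, B_t, P_t, swing_T,
                                    ev_sigma, hs_off, to_off)

        afwd0 = _side_param(ph, "arm_fwd_max_deg", s, mas_side)
        abwd0 = _side_param(ph, "arm_bwd_max_deg", s, mas_side)
        apv0 = _side_param(ph, "arm_peak_velocity_dps", s, mas_side)
        aeta = _jitter_series(m, ph.amp_jitter_cv_arm, rng)
        arng = afwd0 - abwd0
        afwd = afwd0 + (aeta - 1.0) * arng / 2.0
        abwd = abwd0 - (aeta - 1.0) * arng / 2.0
        apv = apv0 * (1.0 + 0.25 * (aeta - 1.0))
        om_arm, th_arm = _arm_track(t, hs, afwd, abwd, apv, T)

        # thigh: fixed modest pendulum, not carried in the ground truth
        om_th, th_th = _arm_track(t, hs, np.full(m, 15.0), np.full(m, -15.0),
                                  np.full(m, 110.0), T)

        steps_s = [st for st in sched.steps if st["side"] == s]
        fx, fz, fax, faz = _foot_motion(t, steps_s, to, hs, fs)
        # small foot pitch activity during swing (netting zero angle)
        foot_lobes = []
        for i in range(m):
            tsw = hs[i] - to[i]
            foot_lobes.append((to[i] + 0.25 * tsw, 4.0, 0.04))
            foot_lobes.append((to[i] + 0.75 * tsw, -4.0, 0.04))
        om_ft, th_ft = _emit_lobes(t, foot_lobes)

        for site, om, th in ((f"ankle_{s[0]}", om_sh, th_sh),
                             (f"wrist_{s[0]}", om_arm, th_arm),
                             (f"thigh_{s[0]}", om_th, th_th)):
            ax, ay, az = _tilt_accel(th)
            arr = np.column_stack([ax, ay, az, np.zeros(n), om, np.zeros(n)])
            streams[site] = arr

        axf, ayf, azf = _tilt_accel(th_ft)
        foot = np.column_stack([
            axf + fax / G0, ayf, azf + faz / G0,
            np.zeros(n), om_ft, np.zeros(n),
        ])
        streams[f"foot_{s[0]}"] = foot

        # realized per-cycle truth, measured on the analytic (pre-noise)
        # tracks with the same window rules the extraction path uses
        sf, sb, sp = shank_cycle_kinematics(t, th_sh, om_sh, hs, to)
        af, ab, ap = arm_cycle_kinematics(t, th_arm, om_arm, hs)
        truth_sides[s] = SideTruth(
            hs=hs, to=to,
            shank_fwd=sf, shank_bwd=sb, shank_pv=sp,
            arm_fwd=af, arm_bwd=ab, arm_pv=ap,
        )

    # ---- trunk and lumbar --------------------------------------------
    hs_ref = sched.side_hs["left"]
    all_cycles = list(zip(hs_ref[:-1], hs_ref[1:]))
    turn_windows = [(tu["start"] - 0.35, tu["end"] + 0.35) for tu in sched.turns]

    def away_from_turns(c):
        return all(c[1] <= a or c[0] >= b for a, b in turn_windows)

    trans_cycles = [c for c in all_cycles if away_from_turns(c)]

    tl_truth = {}
    plane_truth = {}
    for sensor in ("trunk", "lumbar"):
        tracks = {}
        for plane in ("coronal", "sagittal", "transverse"):
            rom = getattr(ph, f"{sensor}_{plane}_rom_deg")
            pv = getattr(ph, f"{sensor}_{plane}_pv_dps")
            cycles = trans_cycles if plane == "transverse" else all_cycles
            om, th = _emit_lobes(t, _oscillation_lobes(cycles, rom, pv, T))
            tracks[plane] = [om, th]
            tl_truth[f"{sensor}_{plane}_rom_deg"] = rom
            tl_truth[f"{sensor}_{plane}_pv_dps"] = pv

        # turns ride on the transverse (yaw) channel
        for tu in sched.turns:
            om, th = _trap_pulse(t, tu["start"], tu["duration"],
                                 tu["peak_dps"] * tu["direction"], tu["ramp_s"])
            tracks["transverse"][0] += om
            tracks["transverse"][1] += th

        # chair transfers ride on the sagittal (pitch) channel; the lumbar
        # sensor sees an attenuated copy of the trunk excursion
        gain = 1.0 if sensor == "trunk" else 0.7
        for name, tr in sched.transfers.items():
            t0 = tr["start"]
            # outer segments carry their wide ramp on the outer edge only
            segs = (
                (t0, tr["d1"], tr["fwd"], 0.3, 0.1),
                (t0 + tr["d1"], tr["d2"], tr["bwd"] - tr["fwd"], 0.3, 0.3),
                (t0 + tr["d1"] + tr["d2"], tr["d3"], -tr["bwd"], 0.1, 0.3),
            )
            for (s0, d, area, r_up, r_dn) in segs:
                ramp_up, ramp_dn = r_up * d, r_dn * d
                peak = area / (d - 0.5 * (ramp_up + ramp_dn))
                om, th = _trap_pulse(t, s0, d, gain * peak, ramp_up, ramp_dn)
                tracks["sagittal"][0] += om
                tracks["sagittal"][1] += th

        for plane in ("coronal", "sagittal", "transverse"):
            om, th = tracks[plane]
            plane_truth[f"{sensor}_{plane}"] = plane_cycle_stats(t, th, om, all_cycles)

        axs, ays, azs = _tilt_accel(tracks["sagittal"][1], tracks["coronal"][1])
        site = "chest" if sensor == "trunk" else "lumbar"
        streams[site] = np.column_stack([
            axs, ays, azs,
            tracks["coronal"][0], tracks["sagittal"][0], tracks["transverse"][0],
        ])

    # ---- noise, clipping, quantization --------------------------------
    for site, arr in streams.items():
        if ph.sensor_noise_sd_acc_g > 0:
            arr[:, :3] += rng.normal(0.0, ph.sensor_noise_sd_acc_g, size=(n, 3))
        if ph.sensor_noise_sd_gyro_dps > 0:
            arr[:, 3:] += rng.normal(0.0, ph.sensor_noise_sd_gyro_dps, size=(n, 3))
        streams[site] = quantize(arr)

    trial = ImuTrial(subject_id=subject_id, trial_id=trial_id, fs_hz=fs, t=t,
                     streams=streams)
    trial.validate()

    transfers_truth = {
        name: {
            "start": tr["start"], "end": tr["start"] + tr["dur"],
            "duration": tr["dur"], "peak_velocity_dps": tr["pv"],
            "lean_fwd_max_deg": tr["fwd"], "lean_bwd_max_deg": tr["bwd"],
        }
        for name, tr in sched.transfers.items()
    }
    turns_truth = [
        {"start": tu["start"], "end": tu["end"], "duration": tu["duration"],
         "peak_dps": tu["peak_dps"], "steps": tu["steps"]}
        for tu in sched.turns
    ]

    gt = GroundTruth(
        mas_side=mas_side,
        phases=sched.phases,
        sides=truth_sides,
        steps=[{k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in st.items()} for st in sched.steps],
        turns=turns_truth,
        transfers=transfers_truth,
        trunk_lumbar=tl_truth,
        stride_length_m=sched.stride_length_m,
        phenotype=phenotype,
        cycle_list=[(float(a), float(b)) for a, b in all_cycles],
        plane_cycles=plane_truth,
    )
    return trial, gt


def synthesize_truth(
    phenotype: GaitPhenotype,
    protocol: TugProtocol | None = None,
    seed: int = 0,
    mas_side: str = "left",
) -> GroundTruth:
    """Ground truth only, without rendering sensor streams.

    Uses the same schedule and per-cycle jitter draws as
    :func:`synthesize_trial`; per-cycle kinematic values are the commanded
    (jittered) targets, which the rendered track matches to ~0.1 deg.  Useful
    for cohort-level studies where only the truth channel is analyzed.
    """
    prot = protocol or TugProtocol()
    phenotype.validate(prot)
    if mas_side not in ("left", "right"):
        raise PhenotypeError("mas_side must be 'left' or 'right'")
    rng = np.random.default_rng(seed)
    sched = _build_schedule(phenotype, prot, rng, mas_side)
    ph = phenotype

    truth_sides = {}
    for s in ("left", "right"):
        hs, to = sched.side_hs[s], sched.side_to[s]
        m = len(hs)
        fwd0 = _side_param(ph, "shank_fwd_max_deg", s, mas_side)
        bwd0 = _side_param(ph, "shank_bwd_max_deg", s, mas_side)
        pv0 = _side_param(ph, "shank_peak_velocity_dps", s, mas_side)
        eta = _jitter_series(m, ph.amp_jitter_cv_shank, rng)
        rng0 = fwd0 - bwd0
        fwd = fwd0 + (eta - 1.0) * rng0 / 2.0
        bwd = bwd0 - (eta - 1.0) * rng0 / 2.0
        pv = pv0 * (1.0 + 0.25 * (eta - 1.0))  # velocity varies less than amplitude
        afwd0 = _side_param(ph, "arm_fwd_max_deg", s, mas_side)
        abwd0 = _side_param(ph, "arm_bwd_max_deg", s, mas_side)
        apv0 = _side_param(ph, "arm_peak_velocity_dps", s, mas_side)
        aeta = _jitter_series(m, ph.amp_jitter_cv_arm, rng)
        arng = afwd0 - abwd0
        afwd = afwd0 + (aeta - 1.0) * arng / 2.0
        abwd = abwd0 - (aeta - 1.0) * arng / 2.0
        apv = apv0 * (1.0 + 0.25 * (aeta - 1.0))
        # cycle c = [hs[c], hs[c+1]): shank extrema come from swing c+1,
        # arm extrema from the cycle-start HS (same alignment as the
        # rendered-track measurement)
        truth_sides[s] = SideTruth(
            hs=hs, to=to,
            shank_fwd=fwd[1:m], shank_bwd=bwd[1:m], shank_pv=pv[1:m],
            arm_fwd=afwd[: m - 1], arm_bwd=abwd[: m - 1], arm_pv=apv[: m - 1],
        )

    hs_ref = sched.side_hs["left"]
    all_cycles = list(zip(hs_ref[:-1], hs_ref[1:]))
    nc = len(all_cycles)
    tl_truth, plane_truth = {}, {}
    for sensor in ("trunk", "lumbar"):
        for plane in ("coronal", "sagittal", "transverse"):
            rom = getattr(ph, f"{sensor}_{plane}_rom_deg")
            pv = getattr(ph, f"{sensor}_{plane}_pv_dps")
            tl_truth[f"{sensor}_{plane}_rom_deg"] = rom
            tl_truth[f"{sensor}_{plane}_pv_dps"] = pv
            plane_truth[f"{sensor}_{plane}"] = (np.full(nc, rom), np.full(nc, pv))

    transfers_truth = {
        name: {
            "start": tr["start"], "end": tr["start"] + tr["dur"],
            "duration": tr["dur"], "peak_velocity_dps": tr["pv"],
            "lean_fwd_max_deg": tr["fwd"], "lean_bwd_max_deg": tr["bwd"],
        }
        for name, tr in sched.transfers.items()
    }
    turns_truth = [
        {"start": tu["start"], "end": tu["end"], "duration": tu["duration"],
         "peak_dps": tu["peak_dps"], "steps": tu["steps"]}
        for tu in sched.turns
    ]
    return GroundTruth(
        mas_side=mas_side,
        phases=sched.phases,
        sides=truth_sides,
        steps=[{k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in st.items()} for st in sched.steps],
        turns=turns_truth,
        transfers=transfers_truth,
        trunk_lumbar=tl_truth,
        stride_length_m=sched.stride_length_m,
        phenotype=phenotype,
        cycle_list=[(float(a), float(b)) for a, b in all_cycles],
        plane_cycles=plane_truth,
    )
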
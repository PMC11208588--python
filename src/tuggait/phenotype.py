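"""Phenotype and protocol parameter containers for the TUG simulator.

A :class:`GaitPhenotype` is the complete kinematic recipe for one subject:
bilateral spatio-temporal gait parameters, per-segment angular excursions and
peak angular velocities, turn and chair-transfer parameters, and noise/jitter
levels.  Parameters are expressed in more-affected-side (MAS) / less-affected
side (LAS) terms; the simulator maps them onto left/right.

Defaults correspond to a typical healthy older adult walking at a comfortable
pace over a 5 m course.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


class PhenotypeError(ValueError):
    """Raised when a phenotype violates its invariants or is kinematically degenerate."""


@dataclass
class TugProtocol:
    """Timed Up and Go protocol geometry and timing.

    ``distance_m`` is the one-way walkway length (walked once out, once back).
    """

    distance_m: float = 5.0
    fs_hz: float = 100.0
    include_presit_turn: bool = True
    initial_sit_s: float = 0.5
    stand_pause_s: float = 0.5
    pre_sit_pause_s: float = 0.5
    end_pause_s: float = 0.5
    max_duration_s: float = 120.0

    def validate(self) -> None:
        if self.distance_m <= 0:
            raise PhenotypeError("protocol distance must be positive")
        if self.fs_hz <= 0:
            raise PhenotypeError("sampling rate must be positive")


@dataclass
class GaitPhenotype:
    # --- temporal structure ---
    stride_time_s: float = 1.11
    step_phase_fraction_mas: float = 0.5  # MAS step time as a fraction of stride
    swing_fraction_mas: float = 0.3938
    swing_fraction_las: float = 0.3938
    # --- spatial ---
    step_length_mas_cm: float = 58.26
    step_length_las_cm: float = 58.26
    # --- shank (ankle-mounted sensor) sagittal kinematics ---
    shank_fwd_max_deg_mas: float = 23.31
    shank_fwd_max_deg_las: float = 23.31
    shank_bwd_max_deg_mas: float = -47.42
    shank_bwd_max_deg_las: float = -47.42
    shank_peak_velocity_dps_mas: float = 329.07
    shank_peak_velocity_dps_las: float = 329.07
    # --- arm (wrist-mounted sensor) sagittal kinematics ---
    arm_fwd_max_deg_mas: float = 38.24
    arm_fwd_max_deg_las: float = 38.24
    arm_bwd_max_deg_mas: float = 0.12
    arm_bwd_max_deg_las: float = 0.12
    arm_peak_velocity_dps_mas: float = 175.97
    arm_peak_velocity_dps_las: float = 175.97
    # --- trunk (chest sensor) oscillation per anatomical plane ---
    trunk_coronal_rom_deg: float = 5.7
    trunk_coronal_pv_dps: float = 25.74
    trunk_sagittal_rom_deg: float = 5.31
    trunk_sagittal_pv_dps: float = 36.43
    trunk_transverse_rom_deg: float = 11.06
    trunk_transverse_pv_dps: float = 44.03
    # --- lumbar (lower-back sensor) oscillation per anatomical plane ---
    lumbar_coronal_rom_deg: float = 5.75
    lumbar_coronal_pv_dps: float = 44.7
    lumbar_sagittal_rom_deg: float = 7.32
    lumbar_sagittal_pv_dps: float = 69.51
    lumbar_transverse_rom_deg: float = 9.13
    lumbar_transverse_pv_dps: float = 56.21
    # --- turning ---
    turn_duration_s: float = 1.43
    turn_peak_velocity_dps: float = 157.52
    turn_steps: int = 2
    # --- chair transfers ---
    sist_duration_s: float = 1.73
    sist_peak_velocity_dps: float = 85.06
    sist_lean_fwd_max_deg: float = -19.45
    sist_lean_bwd_max_deg: float = 20.85
    stsi_duration_s: float = 2.38
    stsi_peak_velocity_dps: float = 79.16
    stsi_lean_fwd_max_deg: float = -18.86
    stsi_lean_bwd_max_deg: float = 20.8
    # --- variability and noise ---
    step_timing_jitter_cv: float = 0.0
    amp_jitter_cv_shank: float = 0.0
    amp_jitter_cv_arm: float = 0.0
    sensor_noise_sd_acc_g: float = 0.0
    sensor_noise_sd_gyro_dps: float = 0.0

    # ------------------------------------------------------------------
    def side(self, name: str, which: str) -> float:
        """Value of a sided parameter, ``which`` in {'mas','las'}."""
        return getattr(self, f"{name}_{which}")

    def replace(self, **kw) -> "GaitPhenotype":
        return dataclasses.replace(self, **kw)

    # ------------------------------------------------------------------
    def validate(self, protocol: TugProtocol | None = None) -> None:
        """Check invariants and kinematic feasibility; raise PhenotypeError."""
        p = self
        if p.stride_time_s <= 0:
            raise PhenotypeError("stride_time_s must be > 0")
        for w in ("mas", "las"):
            sf = p.side("swing_fraction", w)
            if not 0.0 < sf < 1.0:
                raise PhenotypeError(f"swing_fraction_{w} must lie in (0, 1)")
            if getattr(p, f"step_length_{w}_cm") <= 0:
                raise PhenotypeError(f"step_length_{w}_cm must be > 0")
            if p.side("shank_bwd_max_deg", w) >= p.side("shank_fwd_max_deg", w):
                raise PhenotypeError("shank backward maximum must lie below forward maximum")
            if p.side("arm_bwd_max_deg", w) >= p.side("arm_fwd_max_deg", w):
                raise PhenotypeError("arm backward maximum must lie below forward maximum")
            if p.side("shank_peak_velocity_dps", w) <= 0:
                raise PhenotypeError("shank peak velocity must be > 0")
            if p.side("arm_peak_velocity_dps", w) <= 0:
                raise PhenotypeError("arm peak velocity must be > 0")
        if not 0.2 < p.step_phase_fraction_mas < 0.8:
            raise PhenotypeError("step_phase_fraction_mas must lie in (0.2, 0.8)")
        if p.turn_steps < 1:
            raise PhenotypeError("turn_steps must be >= 1")
        if p.turn_duration_s <= 0:
            raise PhenotypeError("turn_duration_s must be > 0")
        for nm in ("step_timing_jitter_cv", "amp_jitter_cv_shank", "amp_jitter_cv_arm",
                   "sensor_noise_sd_acc_g", "sensor_noise_sd_gyro_dps"):
            if getattr(p, nm) < 0:
                raise PhenotypeError(f"{nm} must be >= 0")

        # Walking speed sanity: reject degenerate phenotypes.
        stride_m = (p.step_length_mas_cm + p.step_length_las_cm) / 100.0
        speed = stride_m / p.stride_time_s
        if not 0.1 <= speed <= 3.0:
            raise PhenotypeError(
                f"implied walking speed {speed:.2f} m/s outside the accepted 0.1-3 m/s range"
            )

        # Swing-lobe feasibility: the angular excursion must be reachable at the
        # commanded peak velocity inside the available swing window.
        for w in ("mas", "las"):
            T = p.stride_time_s
            swing = p.side("swing_fraction", w) * T
            rng = p.side("shank_fwd_max_deg", w) - p.side("shank_bwd_max_deg", w)
            if rng / p.side("shank_peak_velocity_dps", w) > 0.8 * swing:
                raise PhenotypeError("shank peak velocity too low for the commanded excursion")
            arng = p.side("arm_fwd_max_deg", w) - p.side("arm_bwd_max_deg", w)
            if arng / p.side("arm_peak_velocity_dps", w) > 0.42 * T:
                raise PhenotypeError("arm peak velocity too low for the commanded excursion")
        for sensor in ("trunk", "lumbar"):
            for plane in ("coronal", "sagittal", "transverse"):
                rom = getattr(p, f"{sensor}_{plane}_rom_deg")
                pv = getattr(p, f"{sensor}_{plane}_pv_dps")
                if rom < 0 or pv < 0:
                    raise PhenotypeError("trunk/lumbar RoM and peak velocity must be >= 0")
                if rom > 0 and rom / pv > 0.35 * p.stride_time_s:
                    raise PhenotypeError(
                        f"{sensor} {plane} peak velocity too low for the commanded RoM"
                    )

        # Turn trapezoid feasibility: plateau must exceed the mean rate but stay
        # below the triangular-profile limit.
        lo, hi = 180.0 / p.turn_duration_s, 360.0 / p.turn_duration_s
        if not lo < p.turn_peak_velocity_dps < hi:
            raise PhenotypeError(
                "turn peak velocity must lie between the mean (180/duration) and "
                "twice the mean angular rate"
            )
        if p.turn_duration_s - 180.0 / p.turn_peak_velocity_dps < 0.09:
            raise PhenotypeError(
                "turn peak velocity implies near-vertical yaw ramps; lower the "
                "peak or lengthen the turn"
            )

        # Transfer profiles: three trapezoidal-velocity segments must fit.
        for tr in ("sist", "stsi"):
            dur = getattr(p, f"{tr}_duration_s")
            pv = getattr(p, f"{tr}_peak_velocity_dps")
            fwd = getattr(p, f"{tr}_lean_fwd_max_deg")
            bwd = getattr(p, f"{tr}_lean_bwd_max_deg")
            if dur <= 0 or pv <= 0:
                raise PhenotypeError(f"{tr} duration and peak velocity must be > 0")
            if not (fwd < 0 < bwd):
                raise PhenotypeError(f"{tr} lean maxima must straddle upright (fwd<0<bwd)")
            d2 = (bwd - fwd) / (0.7 * pv)
            if d2 < 0.25:
                raise PhenotypeError(
                    f"{tr} peak velocity too high for the commanded lean excursion"
                )
            rest = dur - d2
            if rest <= max((abs(fwd) + bwd) / (0.76 * pv) + 0.02, 0.75):
                raise PhenotypeError(
                    f"{tr} transfer infeasible: excursions too large for duration/peak velocity"
                )

        if protocol is not None:
            protocol.validate()
            n_steps = 2.0 * protocol.distance_m * 100.0 / (
                p.step_length_mas_cm + p.step_length_las_cm
            )
            walk_s = 2 * n_steps * p.stride_time_s / 2.0
            total = (
                protocol.initial_sit_s + p.sist_duration_s + protocol.stand_pause_s
                + walk_s + 2 * p.turn_duration_s + protocol.pre_sit_pause_s
                + p.stsi_duration_s + protocol.end_pause_s
            )
            if total > protocol.max_duration_s:
                raise PhenotypeError(
                    f"trial would last {total:.0f}s, beyond the {protocol.max_duration_s:.0f}s cap"
                )
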
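"""Shared fixtures: canonical phenotypes and pre-rendered trials."""

import numpy as np
import pytest

from tuggait import GaitPhenotype, TugProtocol, synthesize_trial


def healthy_phenotype(**overrides) -> GaitPhenotype:
    """Canonical symmetric healthy-control phenotype (noise and jitter off)."""
    return GaitPhenotype().replace(**overrides)


def tremor_dominant_phenotype(**overrides) -> GaitPhenotype:
    """Asymmetric tremor-dominant-like phenotype with reduced MAS arm swing."""
    ph = GaitPhenotype(
        swing_fraction_mas=0.4128, swing_fraction_las=0.3883,
        step_length_mas_cm=59.27, step_length_las_cm=59.26,
        shank_fwd_max_deg_mas=20.68, shank_fwd_max_deg_las=22.69,
        shank_bwd_max_deg_mas=-42.05, shank_bwd_max_deg_las=-41.56,
        shank_peak_velocity_dps_mas=302.58, shank_peak_velocity_dps_las=324.01,
        arm_fwd_max_deg_mas=33.04, arm_fwd_max_deg_las=40.21,
        arm_bwd_max_deg_mas=15.92, arm_bwd_max_deg_las=1.58,
        arm_peak_velocity_dps_mas=155.14, arm_peak_velocity_dps_las=177.6,
        trunk_coronal_rom_deg=4.3, lumbar_coronal_rom_deg=3.8,
        turn_duration_s=1.49, turn_peak_velocity_dps=142.49, turn_steps=3,
        sist_duration_s=1.52, sist_peak_velocity_dps=66.22,
        sist_lean_bwd_max_deg=14.5, sist_lean_fwd_max_deg=-20.56,
        stsi_duration_s=1.74, stsi_peak_velocity_dps=61.53,
        stsi_lean_bwd_max_deg=10.14, stsi_lean_fwd_max_deg=-21.89,
        step_phase_fraction_mas=0.515,
    )
    return ph.replace(**overrides)


@pytest.fixture(scope="session")
def protocol():
    return TugProtocol()


@pytest.fixture(scope="session")
def hc_trial(protocol):
    """Noiseless healthy trial with its ground truth."""
    return synthesize_trial(healthy_phenotype(), protocol, seed=11)


@pytest.fixture(scope="session")
def td_trial(protocol):
    """Noiseless asymmetric trial (MAS = left) with jitter, plus ground truth."""
    ph = tremor_dominant_phenotype(step_timing_jitter_cv=0.03,
                                   amp_jitter_cv_shank=0.15,
                                   amp_jitter_cv_arm=0.35)
    return synthesize_trial(ph, protocol, seed=23, mas_side="left")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
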
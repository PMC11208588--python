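"""Catalog of the 64 gait and postural features extracted from a TUG trial.

The catalog is partitioned into four categories: 31 lower-body features,
12 trunk/lumbar features, 8 upper-body features, and 13 postural-transition
features (turning plus the two chair transfers).  Side-specific features are
reported for the more-affected (MAS) and less-affected (LAS) body side; for
healthy controls the two sides are averaged into both slots.
"""

from __future__ import annotations

LOWER = "lower"
TRUNK_LUMBAR = "trunk_lumbar"
UPPER = "upper"
POSTURAL = "postural"

#: Side-specific lower-body feature stems (each expands to a MAS and LAS entry).
LOWER_SIDED = (
    "Step Length (cm)",
    "Stride Velocity (m/s)",
    "Stride Length (cm)",
    "Gait Cycle time (s)",
    "Cadence (step/min)",
    "Double Support (%)",
    "Swing (%)",
    "Stance (%)",
    "Shank Forward Swing Maximum (°)",
    "Shank Backward Swing Maximum (°)",
    "Peak Shank Angular Velocity (°/s)",
)

#: Bilateral lower-body features (asymmetry / coordination indices).
LOWER_BILATERAL = (
    "Stride Velocity Asymmetry (%)",
    "Stride Length Asymmetry (%)",
    "Swing Asymmetry (%)",
    "Stance Asymmetry (%)",
    "Shank RoM Asymmetry (%)",
    "Peak Shank Angular Velocity Asymmetry (%)",
    "Shank Symbolic Symmetry Index (%)",
    "Mean Phase Difference (%)",
    "Phase Coordination Index (%)",
)

TRUNK_LUMBAR_FEATURES = tuple(
    f"{sensor} {plane} {kind}"
    for sensor in ("Trunk", "Lumbar")
    for plane in ("Coronal", "Sagittal", "Transverse")
    for kind in ("Peak Velocity (°/s)", "RoM (°)")
)

UPPER_SIDED = (
    "Arm Peak Velocity (°/s)",
    "Arm Forward Swing Maximum (°)",
    "Arm Backward Swing Maximum (°)",
)

UPPER_BILATERAL = (
    "Arm Velocity Asymmetry (%)",
    "Arm Symbolic Symmetry Index (%)",
)

POSTURAL_FEATURES = (
    "Turning-Average Duration (s)",
    "Turning-Peak Velocity (°/s)",
    "Turning-Average Step Duration (s)",
    "Turning-Average Angular Velocity (°/s)",
    "Turning-Average Steps",
    "SiSt-Duration (s)",
    "SiSt-Trunk Sagittal Peak Velocity (°/s)",
    "SiSt-Trunk Lean Backward Maximum (°)",
    "SiSt-Trunk Lean Forward Maximum (°)",
    "StSi-Duration (s)",
    "StSi-Trunk Sagittal Peak Velocity (°/s)",
    "StSi-Trunk Lean Backward Maximum (°)",
    "StSi-Trunk Lean Forward Maximum (°)",
)


def _expand_sides(stems):
    out = []
    for stem in stems:
        out.append(f"MAS {stem}")
        out.append(f"LAS {stem}")
    return tuple(out)


LOWER_FEATURES = _expand_sides(LOWER_SIDED) + LOWER_BILATERAL
UPPER_FEATURES = _expand_sides(UPPER_SIDED) + UPPER_BILATERAL

#: Ordered tuple of all 64 feature names.
FEATURE_NAMES = (
    LOWER_FEATURES + TRUNK_LUMBAR_FEATURES + UPPER_FEATURES + POSTURAL_FEATURES
)

#: feature name -> category
FEATURE_CATEGORY = {}
for _n in LOWER_FEATURES:
    FEATURE_CATEGORY[_n] = LOWER
for _n in TRUNK_LUMBAR_FEATURES:
    FEATURE_CATEGORY[_n] = TRUNK_LUMBAR
for _n in UPPER_FEATURES:
    FEATURE_CATEGORY[_n] = UPPER
for _n in POSTURAL_FEATURES:
    FEATURE_CATEGORY[_n] = POSTURAL

CATEGORY_COUNTS = {LOWER: 31, TRUNK_LUMBAR: 12, UPPER: 8, POSTURAL: 13}


def feature_unit(name: str) -> str:
    """Unit string parsed from the canonical feature name ('' for counts)."""
    if name.endswith(")"):
        return name[name.rfind("(") + 1 : -1]
    return ""


assert len(FEATURE_NAMES) == 64
assert len(set(FEATURE_NAMES)) == 64
for _cat, _k in CATEGORY_COUNTS.items():
    assert sum(1 for v in FEATURE_CATEGORY.values() if v == _cat) == _k
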
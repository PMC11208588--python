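"""Trial container and on-disk trial format.

One TUG recording is a set of ten tri-axial accelerometer + gyroscope streams
sampled at a common rate (100 Hz by default).  Sensor axis convention, fixed
per site in the neutral standing pose:

* ``x`` anterior (forward), ``y`` left, ``z`` superior (up);
* sagittal-plane rotation is about ``y`` (``gyr_y``), coronal about ``x``
  (``gyr_x``), transverse/yaw about ``z`` (``gyr_z``);
* the accelerometer reports the gravito-inertial reaction in g, so a sensor at
  rest upright reads ``(0, 0, +1)`` g.

The trial file is one CSV per trial with columns
``time_s, site, acc_x_g, acc_y_g, acc_z_g, gyr_x_dps, gyr_y_dps, gyr_z_dps``.
Samples are clipped to the device measuring range (±8 g, ±2000 °/s) and
quantized at the device resolution (0.00024 g, 0.06 °/s), which the CSV digit
counts preserve losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical sensor sites in file order.
SITES = (
    "chest",
    "lumbar",
    "wrist_l",
    "wrist_r",
    "thigh_l",
    "thigh_r",
    "ankle_l",
    "ankle_r",
    "foot_l",
    "foot_r",
)

CHANNELS = ("acc_x_g", "acc_y_g", "acc_z_g", "gyr_x_dps", "gyr_y_dps", "gyr_z_dps")

ACC_RANGE_G = 8.0
GYR_RANGE_DPS = 2000.0
ACC_LSB_G = 0.00024
GYR_LSB_DPS = 0.06


class TrialFormatError(ValueError):
    """Raised when a trial file violates the trial CSV schema."""


def quantize(data: np.ndarray) -> np.ndarray:
    """Clip to the device range and round to the device resolution.

    ``data`` is an (n, 6) array ordered acc(3), gyro(3).
    """
    out = np.empty_like(data, dtype=float)
    acc = np.clip(data[:, :3], -ACC_RANGE_G, ACC_RANGE_G)
    gyr = np.clip(data[:, 3:], -GYR_RANGE_DPS, GYR_RANGE_DPS)
    out[:, :3] = np.round(acc / ACC_LSB_G) * ACC_LSB_G
    out[:, 3:] = np.round(gyr / GYR_LSB_DPS) * GYR_LSB_DPS
    return out


@dataclass
class ImuTrial:
    """One TUG recording: ten labeled (n, 6) sensor streams on a shared timebase."""

    subject_id: str
    trial_id: str
    fs_hz: float
    t: np.ndarray
    streams: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def acc(self, site: str) -> np.ndarray:
        """(n, 3) accelerometer stream in g."""
        return self.streams[site][:, :3]

    def gyr(self, site: str) -> np.ndarray:
        """(n, 3) gyroscope stream in °/s."""
        return self.streams[site][:, 3:]

    def validate(self) -> None:
        missing = [s for s in SITES if s not in self.streams]
        if missing:
            raise TrialFormatError(f"missing sensor site(s): {', '.join(missing)}")
        for site, arr in self.streams.items():
            if arr.shape != (len(self.t), 6):
                raise TrialFormatError(f"stream {site} shape {arr.shape} != ({len(self.t)}, 6)")
        if np.any(np.diff(self.t) <= 0):
            raise TrialFormatError("timestamps must be strictly increasing")


def write_trial(trial: ImuTrial, path) -> None:
    """Write a trial to the long-format CSV trial file.

    Digit counts are chosen so quantized samples round-trip exactly
    (acc: 5 decimals for the 0.00024 g LSB, gyro: 2 decimals for 0.06 °/s).
    """
    frames = []
    for site in SITES:
        df = pd.DataFrame(trial.streams[site], columns=list(CHANNELS))
        df.insert(0, "site", site)
        df.insert(0, "time_s", trial.t)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["time_s"] = out["time_s"].map(lambda v: f"{v:.4f}")
    for c in CHANNELS:
        dig = 5 if c.startswith("acc") else 2
        out[c] = out[c].map(lambda v, d=dig: f"{v:.{d}f}")
    out.to_csv(path, index=False)


def read_trial(path, rate_tolerance: float = 0.01) -> ImuTrial:
    """Read a trial CSV, checking schema, sites, monotonicity, and rate drift.

    ``rate_tolerance`` is the accepted relative deviation of each inter-sample
    gap from the median sampling interval.
    """
    df = pd.read_csv(path)
    required = {"time_s", "site", *CHANNELS}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise TrialFormatError(f"missing column(s): {', '.join(sorted(missing_cols))}")
    sites_present = set(df["site"].unique())
    missing = [s for s in SITES if s not in sites_present]
    if missing:
        raise TrialFormatError(f"missing sensor site(s): {', '.join(missing)}")

    streams = {}
    t_ref = None
    for site in SITES:
        sub = df[df["site"] == site]
        t = sub["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise TrialFormatError(f"non-monotone timestamps in site {site}")
        dt = np.diff(t)
        med = float(np.median(dt))
        if med <= 0:
            raise TrialFormatError(f"degenerate timebase in site {site}")
        if np.any(np.abs(dt - med) > rate_tolerance * med + 1e-9):
            raise TrialFormatError(
                f"sampling-rate drift beyond {rate_tolerance:.1%} tolerance in site {site}"
            )
        if t_ref is None:
            t_ref = t
        elif len(t) != len(t_ref) or not np.allclose(t, t_ref, atol=1e-6):
            raise TrialFormatError(f"site {site} timebase differs from the first site")
        streams[site] = sub[list(CHANNELS)].to_numpy(dtype=float)

    fs = 1.0 / float(np.median(np.diff(t_ref)))
    import os

    stem = os.path.splitext(os.path.basename(str(path)))[0]
    trial = ImuTrial(subject_id=stem, trial_id=stem, fs_hz=fs, t=t_ref, streams=streams)
    trial.validate()
    return trial
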
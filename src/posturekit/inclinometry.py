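"""Wearable inclinometry: accelerometer streams in, kyphosis series out.

Two 3-axis accelerometers worn on the spine act as inclinometers: the
upper-back sensor (between T1 and T2) gives the alpha angle, the mid-back
sensor (between T12 and L1) the beta angle, and their sum is the kyphosis
angle.  Forward flexion of each sensor's X-axis is positive, so a kyphotic
back yields positive alpha and beta.

Streams arrive as CSV at a nominal 1 Hz.  The two sensor clocks are not
assumed synchronized; samples are paired by nearest timestamp within a
tolerance (default 0.5 s, half the sampling interval).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SensorFormatError, SensorOrderingError
from .geometry import (
    AccelerationSample,
    InclinationPair,
    kyphosis_angle,
    tilt_from_acceleration,
)
from .session import Quality, SessionSeries

__all__ = [
    "SensorRole",
    "SensorStream",
    "KyphosisSample",
    "read_sensor_csv",
    "pair_streams",
    "estimate_static_offset",
    "write_kyphosis_csv",
]

logger = logging.getLogger(__name__)

_ACCEL_COLUMNS = ("t_s", "ax_g", "ay_g", "az_g")


class SensorRole(str, enum.Enum):
    UPPER_BACK = "upper_back"  # T1/T2 -> alpha
    MID_BACK = "mid_back"      # T12/L1 -> beta


@dataclass
class SensorStream:
    """Ordered acceleration samples from one spine-mounted sensor."""

    role: SensorRole
    samples: list[AccelerationSample] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples])

    def tilts_deg(self) -> np.ndarray:
        """Per-sample X-axis inclination, degrees."""
        return np.array([tilt_from_acceleration(s) for s in self.samples])


@dataclass(frozen=True)
class KyphosisSample:
    """One second of spinal posture; ``ka_deg = alpha + beta`` when complete."""

    t: float
    alpha_deg: float | None
    beta_deg: float | None
    ka_deg: float | None
    quality: Quality


def read_sensor_csv(path: str | Path, role: SensorRole | str) -> SensorStream:
    """Parse one sensor CSV into a validated :class:`SensorStream`.

    The primary dialect carries raw acceleration (columns ``t_s, ax_g,
    ay_g, az_g``).  Devices that expose only a pre-computed inclination may
    instead provide ``t_s, tilt_deg``; such rows are converted to the
    equivalent unit gravity vector so the downstream path is identical.

    Rows with non-finite values are dropped (with a logged count);
    timestamps must be strictly increasing after dropping.
    """
    role = SensorRole(role)
    df = pd.read_csv(path)
    tilt_dialect = "tilt_deg" in df.columns and "t_s" in df.columns
    if not tilt_dialect:
        missing = [c for c in _ACCEL_COLUMNS if c not in df.columns]
        if missing:
            raise SensorFormatError(
                f"{path}: missing column(s) {missing}; expected {_ACCEL_COLUMNS} "
                "or the (t_s, tilt_deg) dialect"
            )
        df = df[list(_ACCEL_COLUMNS)]
    else:
        df = df[["t_s", "tilt_deg"]]

    n_raw = len(df)
    df = df[np.isfinite(df).all(axis=1)]
    if len(df) < n_raw:
        logger.warning("%s: dropped %d row(s) with non-finite values", path, n_raw - len(df))

    t = df["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise SensorOrderingError(f"{path}: timestamps are not strictly increasing")

    stream = SensorStream(role=role)
    if tilt_dialect:
        for ti, tilt in zip(t, df["tilt_deg"].to_numpy(dtype=float)):
            rad = math.radians(tilt)
            stream.samples.append(
                AccelerationSample(t=float(ti), ax=math.sin(rad), ay=0.0, az=-math.cos(rad))
            )
    else:
        for row in df.itertuples(index=False):
            stream.samples.append(
                AccelerationSample(
                    t=float(row.t_s), ax=float(row.ax_g),
                    ay=float(row.ay_g), az=float(row.az_g),
                )
            )
    return stream


def estimate_static_offset(stream: SensorStream, t_start: float, t_end: float) -> float:
    """Mean tilt over a still period, usable as a per-sensor zero offset."""
    tilts = [
        tilt_from_acceleration(s) for s in stream.samples if t_start <= s.t <= t_end
    ]
    if not tilts:
        raise SensorFormatError(f"no samples in still period [{t_start}, {t_end}]")
    return float(np.mean(tilts))


def pair_streams(
    upper: SensorStream,
    mid: SensorStream,
    tolerance_s: float = 0.5,
    alpha_offset_deg: float = 0.0,
    beta_offset_deg: float = 0.0,
) -> SessionSeries[KyphosisSample]:
    """Pair the two sensor streams into a kyphosis-angle time series.

    For each upper-back timestamp the nearest mid-back sample within
    ``tolerance_s`` supplies beta; matched samples are complete and carry
    ``ka = alpha + beta``, unmatched ones are partial (alpha only).  The
    optional offsets subtract a previously captured static zero; both
    default to 0 (no calibration step).
    """
    if upper.role == mid.role:
        raise SensorFormatError(f"both streams claim role {upper.role.value}")
    series: SessionSeries[KyphosisSample] = SessionSeries()
    if not upper.samples or not mid.samples:
        logger.warning("empty sensor stream(s): no kyphosis samples produced")
        return series

    mid_t = mid.times
    if upper.times[-1] < mid_t[0] - tolerance_s or upper.times[0] > mid_t[-1] + tolerance_s:
        logger.warning("sensor streams cover disjoint time ranges; empty series")
        return series

    mid_tilts = mid.tilts_deg() - beta_offset_deg
    for s in upper.samples:
        alpha = tilt_from_acceleration(s) - alpha_offset_deg
        j = int(np.searchsorted(mid_t, s.t))
        best, best_dt = None, tolerance_s
        for k in (j - 1, j):
            if 0 <= k < len(mid_t):
                dt = abs(mid_t[k] - s.t)
                if dt <= best_dt:
                    best, best_dt = k, dt
        if best is None:
            series.samples.append(
                KyphosisSample(t=s.t, alpha_deg=alpha, beta_deg=None,
                               ka_deg=None, quality=Quality.PARTIAL)
            )
        else:
            beta = float(mid_tilts[best])
            ka = kyphosis_angle(InclinationPair(alpha_deg=alpha, beta_deg=beta))
            series.samples.append(
                KyphosisSample(t=s.t, alpha_deg=alpha, beta_deg=beta,
                               ka_deg=ka, quality=Quality.COMPLETE)
            )
    return series


def write_kyphosis_csv(series: SessionSeries[KyphosisSample], path: str | Path) -> None:
    """Write the long-format CSV (t_s, alpha_deg, beta_deg, ka_deg, quality)."""
    df = series.to_dataframe()
    if df.empty:
        df = df.reindex(columns=["t", "alpha_deg", "beta_deg", "ka_deg", "quality"])
    df = df.rename(columns={"t": "t_s"})
    df.to_csv(path, index=False, float_format="%.6f")
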
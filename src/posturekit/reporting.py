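"""Session aggregation and method-agreement statistics.

Per-minute aggregation condenses a 1 Hz session into box-plot statistics
(min, quartiles, max per started minute); quartiles use linear
interpolation between order statistics (the "type 7" rule), which is
recorded in report metadata for reproducibility.

Agreement between a candidate and a reference angle series is summarized
by the Pearson correlation with its qualitative band (|r| >= 0.90 very
high, 0.70-0.89 high, 0.50-0.69 moderate, below 0.50 low), the two-tailed
p-value, the squared correlation as a percentage, and the mean absolute
percentage error (MAPE) reported as a fraction — a MAPE at or below 0.05
is conventionally read as excellent agreement.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptySessionError, UndefinedCorrelationError
from .session import SessionSeries

__all__ = [
    "MinuteAggregate",
    "CorrelationBand",
    "ValidationStats",
    "aggregate_minutes",
    "pearson_with_band",
    "mape",
    "validate_series",
    "histogram_counts",
    "export_report",
]

logger = logging.getLogger(__name__)

QUARTILE_METHOD = "linear"  # numpy name for the type-7 rule


@dataclass(frozen=True)
class MinuteAggregate:
    """Box-plot statistics of one angle channel over one started minute."""

    channel: str
    minute_index: int
    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float


class CorrelationBand(str, enum.Enum):
    VERY_HIGH = "very_high"  # |r| in [0.90, 1.00]
    HIGH = "high"            # |r| in [0.70, 0.90)
    MODERATE = "moderate"    # |r| in [0.50, 0.70)
    LOW = "low"              # |r| below 0.50


def _band(r: float) -> CorrelationBand:
    a = abs(r)
    if a >= 0.90:
        return CorrelationBand.VERY_HIGH
    if a >= 0.70:
        return CorrelationBand.HIGH
    if a >= 0.50:
        return CorrelationBand.MODERATE
    return CorrelationBand.LOW


@dataclass(frozen=True)
class ValidationStats:
    """Paired-series agreement: Pearson r (with band), MAPE, R^2."""

    r: float
    r_band: CorrelationBand
    p_two_tailed: float
    r_squared_pct: float
    n: int
    mape: float | None = None  # fraction, e.g. 0.05 = 5%

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "r_band": self.r_band.value,
            "p_two_tailed": self.p_two_tailed,
            "r_squared_pct": self.r_squared_pct,
            "n": self.n,
            "mape": self.mape,
            "mape_pct": None if self.mape is None else 100.0 * self.mape,
        }


def _series_frame(series) -> pd.DataFrame:
    if isinstance(series, SessionSeries):
        df = series.to_dataframe()
        return df.rename(columns={"t": "t_s"})
    return pd.DataFrame(series)


def aggregate_minutes(
    series,
    channels: Sequence[str] | None = None,
) -> list[MinuteAggregate]:
    """Per-minute box-plot statistics for each angle channel.

    ``series`` is a :class:`SessionSeries` or a DataFrame with a ``t_s``
    column; channels default to every ``*_deg`` column present.  Absent
    (NaN) samples are excluded from n; minutes with no valid samples are
    omitted.
    """
    df = _series_frame(series)
    if df.empty:
        return []
    if channels is None:
        channels = [c for c in df.columns if c.endswith("_deg")]
    minutes = (df["t_s"] // 60).astype(int)
    out: list[MinuteAggregate] = []
    for channel in channels:
        values = pd.to_numeric(df[channel], errors="coerce")
        for minute, group in values.groupby(minutes):
            valid = group.dropna().to_numpy()
            if valid.size == 0:
                continue
            q1, med, q3 = np.quantile(valid, [0.25, 0.5, 0.75], method=QUARTILE_METHOD)
            out.append(
                MinuteAggregate(
                    channel=channel, minute_index=int(minute), n=int(valid.size),
                    min=float(valid.min()), q1=float(q1), median=float(med),
                    q3=float(q3), max=float(valid.max()),
                )
            )
    return out


def pearson_with_band(x: Sequence[float], y: Sequence[float]) -> ValidationStats:
    """Pearson correlation of two paired series, with qualitative band.

    The two-tailed p-value comes from the exact t-distribution reference
    of the sample correlation under bivariate normality.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise UndefinedCorrelationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise UndefinedCorrelationError(f"need at least 3 pairs, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance series")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return ValidationStats(
        r=r,
        r_band=_band(r),
        p_two_tailed=float(res.pvalue),
        r_squared_pct=100.0 * r * r,
        n=int(x.size),
    )


def mape(reference: Sequence[float], candidate: Sequence[float]) -> float:
    """Mean absolute percentage error, as a fraction of the reference.

    ``mean(|ref - cand| / |ref|)`` over paired samples.  Pairs whose
    reference value is zero are excluded (with a logged count) since the
    percentage error is undefined there; if every reference value is zero
    the error is undefined and a ValueError is raised.
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    if ref.shape != cand.shape:
        raise ValueError(f"length mismatch: {ref.shape} vs {cand.shape}")
    nonzero = ref != 0
    n_zero = int((~nonzero).sum())
    if n_zero:
        if n_zero == ref.size:
            raise ValueError("MAPE undefined: all reference values are zero")
        logger.warning("MAPE: excluded %d pair(s) with zero reference value", n_zero)
    return float(np.mean(np.abs(ref[nonzero] - cand[nonzero]) / np.abs(ref[nonzero])))


def validate_series(reference: Sequence[float], candidate: Sequence[float]) -> ValidationStats:
    """Full agreement panel: Pearson r + band + p, R^2 percent, and MAPE."""
    base = pearson_with_band(reference, candidate)
    return ValidationStats(
        r=base.r, r_band=base.r_band, p_two_tailed=base.p_two_tailed,
        r_squared_pct=base.r_squared_pct, n=base.n,
        mape=mape(reference, candidate),
    )


def histogram_counts(values: Sequence[float], bin_deg: float = 1.0) -> pd.DataFrame:
    """Histogram of an angle channel with fixed-width bins (default 1 degree).

    Returns a frame with ``bin_left``, ``bin_right``, ``count``; empty bins
    inside the data range are included, NaNs ignored.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    lo = math.floor(arr.min() / bin_deg) * bin_deg
    hi = math.ceil(arr.max() / bin_deg) * bin_deg
    if hi == lo:
        hi = lo + bin_deg
    edges = np.arange(lo, hi + bin_deg / 2, bin_deg)
    counts, _ = np.histogram(arr, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


REPORT_SCHEMA_VERSION = "1"


def export_report(
    summary,
    aggregates: Sequence[MinuteAggregate],
    stats: dict[str, ValidationStats] | None,
    outdir: str | Path,
    series=None,
    plots: bool = False,
) -> dict[str, Path]:
    """Write the machine-readable session report bundle.

    Produces ``report.json`` (summary + agreement statistics + metadata),
    ``minutes.csv`` (per-minute box statistics), and, when the raw series
    is given, ``angles.csv`` plus per-channel ``histogram.csv`` (1-degree
    bins) and optional PNG plots (time-series trace, per-minute boxes,
    histogram).  Returns the mapping of artifact name to path.
    """
    if summary is None and not aggregates:
        raise EmptySessionError("nothing to report: empty session")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "quartile_method": QUARTILE_METHOD,
        "summary": summary.to_dict() if summary is not None else None,
        "agreement": {k: v.to_dict() for k, v in stats.items()} if stats else None,
        "n_minute_aggregates": len(aggregates),
    }
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    written["report"] = report_path

    minutes_df = pd.DataFrame([vars(a) for a in aggregates])
    minutes_path = outdir / "minutes.csv"
    minutes_df.to_csv(minutes_path, index=False)
    written["minutes"] = minutes_path

    if series is not None:
        df = _series_frame(series)
        angles_path = outdir / "angles.csv"
        df.to_csv(angles_path, index=False)
        written["angles"] = angles_path
        hist_frames = []
        for channel in (c for c in df.columns if c.endswith("_deg")):
            h = histogram_counts(pd.to_numeric(df[channel], errors="coerce"))
            h.insert(0, "channel", channel)
            hist_frames.append(h)
        if hist_frames:
            hist_path = outdir / "histogram.csv"
            pd.concat(hist_frames, ignore_index=True).to_csv(hist_path, index=False)
            written["histogram"] = hist_path
        if plots:
            written.update(_write_plots(df, aggregates, outdir))
    return written


def _write_plots(df: pd.DataFrame, aggregates, outdir: Path) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: dict[str, Path] = {}
    channels = [c for c in df.columns if c.endswith("_deg")]
    if not channels:
        return written

    fig, ax = plt.subplots(figsize=(8, 4))
    for channel in channels:
        ax.plot(df["t_s"], pd.to_numeric(df[channel], errors="coerce"), label=channel)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("angle (deg)")
    ax.legend()
    trace_path = outdir / "trace.png"
    fig.savefig(trace_path, dpi=100)
    plt.close(fig)
    written["trace_plot"] = trace_path

    fig, ax = plt.subplots(figsize=(8, 4))
    for channel in channels:
        groups = [
            pd.to_numeric(df.loc[(df["t_s"] // 60) == m, channel], errors="coerce").dropna()
            for m in sorted((df["t_s"] // 60).astype(int).unique())
        ]
        groups = [g for g in groups if len(g)]
        if groups:
            ax.boxplot(groups)
            break  # one channel per box figure keeps the axes readable
    ax.set_xlabel("minute")
    ax.set_ylabel("angle (deg)")
    box_path = outdir / "minutes_box.png"
    fig.savefig(box_path, dpi=100)
    plt.close(fig)
    written["box_plot"] = box_path

    fig, ax = plt.subplots(figsize=(8, 4))
    for channel in channels:
        values = pd.to_numeric(df[channel], errors="coerce").dropna()
        if len(values):
            ax.hist(values, bins=30, alpha=0.6, label=channel)
    ax.set_xlabel("angle (deg)")
    ax.set_ylabel("count")
    ax.legend()
    hist_path = outdir / "histogram.png"
    fig.savefig(hist_path, dpi=100)
    plt.close(fig)
    written["histogram_plot"] = hist_path
    return written
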
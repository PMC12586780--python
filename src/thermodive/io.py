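"""Tag-series input/output and preprocessing.

Biologging packages on free-swimming fish record depth, ambient water
temperature and (via an implanted stalk sensor) deep-muscle temperature,
natively at 1-s intervals.  Analyses run on 1-min data: the first hours
after capture are discarded (capture stress perturbs both behaviour and
muscle temperature) and the record is either block-averaged (for water
column profiles) or subsampled (for heat-model fitting) to a 1-min step.

This module defines the :class:`TagSeries` container, CSV round-tripping,
the capture trim, resampling, and whole-deployment thermal summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical CSV column order for tag series
TAG_COLUMNS = ["time_min", "depth_m", "ta_c", "tb_c"]

_TEMP_LO, _TEMP_HI = -5.0, 45.0


@dataclass(frozen=True)
class TagSeries:
    """Uniformly sampled tag record: depth, ambient and muscle temperature.

    Parameters
    ----------
    time : array of float
        Minutes since deployment; strictly increasing with a uniform step.
    depth : array of float
        Depth in metres, non-negative.
    ta : array of float
        Ambient water temperature, degrees C.
    tb : array of float
        Muscle temperature, degrees C.
    """

    time: np.ndarray
    depth: np.ndarray
    ta: np.ndarray
    tb: np.ndarray

    def __post_init__(self) -> None:
        for name in ("time", "depth", "ta", "tb"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = self.time.size
        if n < 2:
            raise ValueError("tag series needs at least two samples")
        for name in ("depth", "ta", "tb"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name!r} length differs from time")
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in channel {name!r}")
        if not np.all(np.isfinite(self.time)):
            raise ValueError("non-finite time values")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValueError("time must be strictly increasing")
        if np.ptp(steps) > 1e-9:
            raise ValueError("time step must be uniform (within 1e-9 min)")
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative")
        for name in ("ta", "tb"):
            t = getattr(self, name)
            if t.min() <= _TEMP_LO or t.max() >= _TEMP_HI:
                raise ValueError(
                    f"{name} outside plausible open interval "
                    f"({_TEMP_LO}, {_TEMP_HI}) degC"
                )

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def step(self) -> float:
        """Sampling interval in minutes."""
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        """Recorded span in minutes (first to last sample)."""
        return float(self.time[-1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time,
                "depth_m": self.depth,
                "ta_c": self.ta,
                "tb_c": self.tb,
            }
        )


@dataclass(frozen=True)
class ThermalSummary:
    """Deployment-level depth/temperature statistics.

    ``diff_*`` blocks describe the muscle-minus-ambient temperature
    difference; ``frac_tb_above_ta`` is the fraction of samples where the
    muscle is strictly warmer than the water.
    """

    depth_mean: float
    depth_range: tuple[float, float]
    ta_mean: float
    ta_range: tuple[float, float]
    tb_mean: float
    tb_range: tuple[float, float]
    diff_mean: float
    diff_min: float
    diff_max: float
    frac_tb_above_ta: float
    n: int = field(default=0)

    def to_dict(self) -> dict:
        return {
            "depth_mean": self.depth_mean,
            "depth_min": self.depth_range[0],
            "depth_max": self.depth_range[1],
            "ta_mean": self.ta_mean,
            "ta_min": self.ta_range[0],
            "ta_max": self.ta_range[1],
            "tb_mean": self.tb_mean,
            "tb_min": self.tb_range[0],
            "tb_max": self.tb_range[1],
            "diff_mean": self.diff_mean,
            "diff_min": self.diff_min,
            "diff_max": self.diff_max,
            "frac_tb_above_ta": self.frac_tb_above_ta,
            "n": self.n,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def write_tag_series(series: TagSeries, path: str | Path) -> None:
    """Write a tag series as CSV with the canonical header."""
    series.to_frame().to_csv(path, index=False)


def read_tag_series(path: str | Path) -> TagSeries:
    """Read and validate a tag-series CSV.

    Rows containing any non-finite field are dropped (the count is logged);
    missing columns and non-monotone time raise ``ValueError``.
    """
    df = pd.read_csv(path)
    missing = [c for c in TAG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")
    df = df[TAG_COLUMNS].apply(pd.to_numeric, errors="coerce")
    good = np.isfinite(df.to_numpy(dtype=float)).all(axis=1)
    n_bad = int((~good).sum())
    if n_bad:
        logger.warning("dropped %d row(s) with non-finite fields from %s", n_bad, path)
        df = df.loc[good]
    return TagSeries(
        time=df["time_min"].to_numpy(),
        depth=df["depth_m"].to_numpy(),
        ta=df["ta_c"].to_numpy(),
        tb=df["tb_c"].to_numpy(),
    )


def trim_capture_effect(
    series: TagSeries, hours: float = 6.0, rezero: bool = True
) -> TagSeries:
    """Drop the initial post-capture window from a deployment.

    Samples with ``time >= hours * 60`` (minutes) are kept.  By default the
    time axis is re-zeroed at the first retained sample, so downstream
    stages see an analysis window starting at t = 0.
    """
    if hours < 0:
        raise ValueError("trim window must be non-negative")
    if hours == 0:
        return series
    cutoff = series.time[0] + hours * 60.0
    keep = series.time >= cutoff
    if keep.sum() < 2:
        raise ValueError(
            f"series ({series.duration:.1f} min) lies entirely within the "
            f"{hours} h trim window"
        )
    time = series.time[keep]
    if rezero:
        time = time - time[0]
    return TagSeries(time, series.depth[keep], series.ta[keep], series.tb[keep])


def resample(series: TagSeries, interval: float = 1.0, mode: str = "subsample") -> TagSeries:
    """Reduce a tag series to a coarser uniform step.

    ``mode='average'`` takes block means over each interval (used for water
    column profiles); ``mode='subsample'`` keeps the first sample of each
    interval (used for heat-model fitting).  The interval must be an integer
    multiple of the native step; an incomplete trailing block is dropped.
    """
    if mode not in ("average", "subsample"):
        raise ValueError(f"unknown mode {mode!r}")
    step = series.step
    if interval < step - 1e-9:
        raise ValueError(f"interval {interval} min finer than native step {step} min")
    ratio = interval / step
    k = int(round(ratio))
    if abs(ratio - k) > 1e-6:
        raise ValueError(
            f"interval {interval} min is not a multiple of the native step {step} min"
        )
    if k == 1:
        return series
    n_blocks = series.n // k
    if n_blocks < 2:
        raise ValueError("fewer than two complete blocks after resampling")
    if series.n % k:
        logger.debug("resample: dropping %d trailing sample(s)", series.n % k)

    def blocks(x: np.ndarray) -> np.ndarray:
        return x[: n_blocks * k].reshape(n_blocks, k)

    time = blocks(series.time)[:, 0]
    if mode == "subsample":
        pick = lambda x: blocks(x)[:, 0]  # noqa: E731
    else:
        pick = lambda x: blocks(x).mean(axis=1)  # noqa: E731
    return TagSeries(time, pick(series.depth), pick(series.ta), pick(series.tb))


def thermal_summary(series: TagSeries) -> ThermalSummary:
    """Whole-deployment statistics of depth, temperatures and their difference.

    The time-above-ambient fraction uses a strict inequality (tb > ta), so a
    perfectly equilibrated fish scores 0.
    """
    diff = series.tb - series.ta
    return ThermalSummary(
        depth_mean=float(series.depth.mean()),
        depth_range=(float(series.depth.min()), float(series.depth.max())),
        ta_mean=float(series.ta.mean()),
        ta_range=(float(series.ta.min()), float(series.ta.max())),
        tb_mean=float(series.tb.mean()),
        tb_range=(float(series.tb.min()), float(series.tb.max())),
        diff_mean=float(diff.mean()),
        diff_min=float(diff.min()),
        diff_max=float(diff.max()),
        frac_tb_above_ta=float((diff > 0).mean()),
        n=series.n,
    )
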
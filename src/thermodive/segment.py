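"""Thermocline detection and below-thermocline dive extraction.

The thermocline separating the warm mixed layer from cold deep water is
found per deployment from the tag's own depth-temperature record: 1-min
data are grouped into 1-m depth bins, bin means are smoothed with a
moving average spanning 20 m, and the thermocline is the depth of the
steepest (most negative) vertical temperature gradient of the smoothed
profile.  Deep dives are maximal excursions below that depth; very short
excursions (<= 10 min) are discarded as noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TagSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThermalProfile:
    """Depth-binned ambient temperature structure of one deployment."""

    bin_centers: np.ndarray   # m, contiguous 1-m bins, ascending
    mean_ta: np.ndarray       # raw per-bin mean, degC
    smoothed_ta: np.ndarray   # moving-average smoothed, degC
    occupancy: np.ndarray     # samples per bin (0 where interpolated)
    n_filled: int = 0         # empty interior bins filled by interpolation

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_m": self.bin_centers,
                "mean_ta_c": self.mean_ta,
                "smoothed_ta_c": self.smoothed_ta,
                "occupancy": self.occupancy,
            }
        )


@dataclass(frozen=True)
class DiveEvent:
    """One maximal below-thermocline excursion."""

    start: float      # min
    end: float        # min
    max_depth: float  # m
    min_ta: float     # degC encountered during the dive

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("dive end must be after start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def build_profile(
    series: TagSeries, bin_width: float = 1.0, smooth_half_width_m: float = 10.0
) -> ThermalProfile:
    """Depth-binned, smoothed ambient temperature profile.

    Samples are grouped into ``bin_width``-m depth bins over the occupied
    depth range; empty interior bins are filled by linear interpolation
    between neighbouring bin means before smoothing (the fill count is
    recorded and logged).  Smoothing is a centred moving average over all
    bins within ``smooth_half_width_m`` of each bin centre, truncated at
    the profile edges.

    Requires at least 30 m of depth coverage, otherwise the smoothed
    gradient is meaningless.
    """
    depth, ta = series.depth, series.ta
    coverage = float(depth.max() - depth.min())
    if coverage < 30.0:
        raise ValueError(
            f"only {coverage:.1f} m of depth coverage; need >= 30 m to smooth"
        )
    first = int(np.floor(depth.min() / bin_width))
    last = int(np.floor(depth.max() / bin_width))
    idx = np.clip(np.floor(depth / bin_width).astype(int), first, last) - first
    nb = last - first + 1
    occupancy = np.bincount(idx, minlength=nb)
    sums = np.bincount(idx, weights=ta, minlength=nb)
    centers = (np.arange(first, last + 1) + 0.5) * bin_width

    mean_ta = np.full(nb, np.nan)
    occ = occupancy > 0
    mean_ta[occ] = sums[occ] / occupancy[occ]
    n_filled = int((~occ).sum())
    if n_filled:
        logger.info("build_profile: interpolating %d empty interior bin(s)", n_filled)
        mean_ta[~occ] = np.interp(centers[~occ], centers[occ], mean_ta[occ])

    half_bins = int(round(smooth_half_width_m / bin_width))
    csum = np.concatenate([[0.0], np.cumsum(mean_ta)])
    lo = np.maximum(np.arange(nb) - half_bins, 0)
    hi = np.minimum(np.arange(nb) + half_bins, nb - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)

    return ThermalProfile(
        bin_centers=centers, mean_ta=mean_ta, smoothed_ta=smoothed,
        occupancy=occupancy, n_filled=n_filled,
    )


def detect_thermocline(profile: ThermalProfile) -> float:
    """Depth of the steepest temperature gradient in the smoothed profile.

    The gradient is estimated by first differences of adjacent smoothed
    bins; the returned depth is the midpoint of the maximizing bin pair.
    Smoothing turns a sharp interface into a linear ramp whose gradient is
    constant, so exact ties are resolved to the centre of the shallowest
    maximal run of tied bins (recovering the interface depth for a step
    profile); for a perfectly linear profile, where every pair ties, this
    returns the profile midpoint.  An all-equal profile has no gradient
    and raises.
    """
    if profile.n_bins < 21:
        raise ValueError("need >= 21 smoothed bins to locate a thermocline")
    s = profile.smoothed_ta
    c = profile.bin_centers
    grad = np.abs(np.diff(s) / np.diff(c))
    gmax = grad.max()
    if gmax <= 1e-12:
        raise ValueError("no gradient: profile is constant")
    tied = grad >= gmax * (1.0 - 1e-9)
    start = int(np.argmax(tied))
    length = int(np.argmin(tied[start:])) if not tied[start:].all() else tied.size - start
    i = start + (length - 1) // 2
    return float(0.5 * (c[i] + c[i + 1]))


def extract_dives(
    series: TagSeries, thermocline: float, min_duration: float = 10.0
) -> list[DiveEvent]:
    """Maximal below-thermocline excursions longer than ``min_duration``.

    A dive is a maximal run of consecutive samples with depth strictly
    below (deeper than) the thermocline; separate runs are never merged,
    so a brief return above the thermocline splits a dive in two.  Runs
    lasting ``min_duration`` or less are excluded (the threshold is
    inclusive: a run of exactly 10 min is dropped at the default).  A run's
    duration is the time it covers, i.e. samples x step.
    """
    if thermocline < series.depth.min():
        raise ValueError(
            f"thermocline {thermocline} m is shallower than the whole record "
            f"(min depth {series.depth.min():.1f} m); every sample would be a dive"
        )
    below = series.depth > thermocline
    step = series.step
    events: list[DiveEvent] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], below.view(np.int8), [0]])))
    for i0, i1 in zip(edges[::2], edges[1::2]):  # i1 is one past the run end
        duration = (i1 - i0) * step
        if duration <= min_duration:
            continue
        events.append(
            DiveEvent(
                start=float(series.time[i0]),
                end=float(series.time[i0] + duration),
                max_depth=float(series.depth[i0:i1].max()),
                min_ta=float(series.ta[i0:i1].min()),
            )
        )
    return events


def dives_to_frame(dives: list[DiveEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_min": d.start,
                "end_min": d.end,
                "duration_min": d.duration,
                "max_depth_m": d.max_depth,
                "min_ta_c": d.min_ta,
            }
            for d in dives
        ],
        columns=["start_min", "end_min", "duration_min", "max_depth_m", "min_ta_c"],
    )


def dive_statistics(dives: list[DiveEvent]) -> dict:
    """Mean and (min, max) of dive duration and maximum depth."""
    if not dives:
        raise ValueError("no dives to summarize")
    dur = np.array([d.duration for d in dives])
    dep = np.array([d.max_depth for d in dives])
    return {
        "n_dives": len(dives),
        "duration_mean": float(dur.mean()),
        "duration_range": (float(dur.min()), float(dur.max())),
        "max_depth_mean": float(dep.mean()),
        "max_depth_range": (float(dep.min()), float(dep.max())),
    }
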
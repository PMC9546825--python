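"""Dive-pattern classification and time-at-depth binning.

Sperm whale foraging dives show a descent, a roughly constant-depth
bottom phase where most prey capture happens, and an ascent. Events whose
click-depth series contain all three phases and last more than 5 minutes
are classed U-shaped, and split by maximum click depth into shallow
(< 800 m), medium (800–1600 m) and deep (> 1600 m). Click depths are
also binned at 400 m intervals — coarse enough to absorb unknown
horizontal movement and depth uncertainty — to build time-at-depth
profiles, locate the bottom-phase bin, and compare the 90th-percentile
depth bin against the seafloor bin (water-column vs near-seafloor
foraging).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DivePattern",
    "DepthClass",
    "DiveClassification",
    "DepthBinProfile",
    "classify_dive",
    "bin_time_at_depth",
    "bottom_phase_bin",
    "seafloor_proximity",
]

BIN_WIDTH_M = 400.0
U_MIN_DURATION_MIN = 5.0
SHALLOW_MAX_M = 800.0
MEDIUM_MAX_M = 1600.0
#: minimum net depth excursion (m) for a descent/ascent leg
EXCURSION_M = 200.0
#: minimum bottom-phase duration (s)
PLATEAU_MIN_S = 120.0


class DivePattern(str, enum.Enum):
    U_shaped = "U_shaped"
    flat_shallow = "flat_shallow"
    ascending = "ascending"
    descending = "descending"
    none = "none"


class DepthClass(str, enum.Enum):
    shallow = "shallow"  # max click depth < 800 m
    medium = "medium"    # 800–1600 m
    deep = "deep"        # > 1600 m


@dataclass
class DiveClassification:
    pattern: DivePattern
    depth_class: DepthClass | None
    max_click_depth_m: float
    duration_min: float
    # plateau (bottom phase) extent, indices into the click series
    plateau_slice: slice | None = None
    plateau_median_depth_m: float = np.nan


@dataclass
class DepthBinProfile:
    """Time spent per 400-m depth bin over one event."""

    bin_lower_edges_m: np.ndarray
    seconds: np.ndarray
    proportions: np.ndarray
    total_retained_s: float
    bottom_phase_bin: str | None = None
    p90_bin_lower_m: float = np.nan
    water_column_flag: str | None = None

    def to_frame(self, event_id=0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_id": event_id,
                "bin_lower_m": self.bin_lower_edges_m,
                "seconds": self.seconds,
                "proportion": self.proportions,
            }
        )


def _depth_class(max_depth: float) -> DepthClass:
    if max_depth < SHALLOW_MAX_M:
        return DepthClass.shallow
    if max_depth <= MEDIUM_MAX_M:
        return DepthClass.medium
    return DepthClass.deep


def classify_dive(
    click_depths,
    click_times_s,
    *,
    smooth_window: int = 11,
    excursion_m: float = EXCURSION_M,
    plateau_min_s: float = PLATEAU_MIN_S,
) -> DiveClassification:
    """Categorize one event's click-depth series by dive shape.

    The series is smoothed with a rolling median, then tested for a
    descent (net increase ≥ 200 m before the bottom phase), a plateau
    (within 200 m of the maximum for ≥ 2 min) and an ascent (net decrease
    ≥ 200 m after it). Events with all three phases lasting > 5 min are
    U-shaped; otherwise descending / ascending / flat-shallow (range
    < 200 m and max < 800 m) / none. Fewer than 8 points → ``none``.
    """
    z = np.asarray(click_depths, dtype=float)
    t = np.asarray(click_times_s, dtype=float)
    if z.size != t.size:
        raise ValueError("depths and times must align")
    duration_min = float((t[-1] - t[0]) / 60.0) if t.size else 0.0
    max_depth = float(z.max()) if z.size else 0.0
    if z.size < 8:
        return DiveClassification(DivePattern.none, None, max_depth, duration_min)

    s = pd.Series(z).rolling(smooth_window, center=True, min_periods=1).median().to_numpy()
    smax = float(s.max())
    overall_range = float(s.max() - s.min())

    # plateau: contiguous span within `excursion_m` of the (smoothed) maximum
    near_max = s >= smax - excursion_m
    i_first = int(np.argmax(near_max))
    i_last = int(len(s) - 1 - np.argmax(near_max[::-1]))
    plateau = slice(i_first, i_last + 1)
    plateau_dur = float(t[i_last] - t[i_first])
    plateau_median = float(np.median(z[plateau]))

    descent = s[i_first] - s[0] >= excursion_m or smax - s[0] >= excursion_m
    ascent = s[i_last] - s[-1] >= excursion_m or smax - s[-1] >= excursion_m
    # phases must actually precede/follow the plateau
    descent = descent and i_first > 0
    ascent = ascent and i_last < len(s) - 1

    if descent and ascent and plateau_dur >= plateau_min_s and duration_min > U_MIN_DURATION_MIN:
        return DiveClassification(
            DivePattern.U_shaped, _depth_class(max_depth), max_depth, duration_min,
            plateau, plateau_median,
        )
    net = s[-1] - s[0]
    if net >= excursion_m:
        return DiveClassification(DivePattern.descending, None, max_depth, duration_min)
    if net <= -excursion_m:
        return DiveClassification(DivePattern.ascending, None, max_depth, duration_min)
    if overall_range < excursion_m and max_depth < SHALLOW_MAX_M:
        return DiveClassification(DivePattern.flat_shallow, None, max_depth, duration_min)
    return DiveClassification(DivePattern.none, None, max_depth, duration_min)


def bin_time_at_depth(
    click_depths,
    click_times_s,
    bin_m: float = BIN_WIDTH_M,
    max_gap_s: float = 120.0,
) -> DepthBinProfile:
    """Allocate event time to half-open 400-m depth bins.

    Each inter-click interval no longer than ``max_gap_s`` is credited to
    the bin of its *starting* click's depth; longer gaps (detection
    dropouts) are discarded. Proportions are over retained time only.
    """
    z = np.asarray(click_depths, dtype=float)
    t = np.asarray(click_times_s, dtype=float)
    if z.size != t.size:
        raise ValueError("depths and times must align")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("click times must be strictly increasing")
    if t.size < 2:
        return DepthBinProfile(np.empty(0), np.empty(0), np.empty(0), 0.0)

    dt = np.diff(t)
    keep = dt <= max_gap_s
    idx = np.floor(z[:-1][keep] / bin_m).astype(int)
    dur = dt[keep]
    if idx.size == 0:
        return DepthBinProfile(np.empty(0), np.empty(0), np.empty(0), 0.0)
    n_bins = int(idx.max()) + 1
    seconds = np.bincount(idx, weights=dur, minlength=n_bins)
    total = float(seconds.sum())
    props = seconds / total if total > 0 else seconds
    edges = np.arange(n_bins) * bin_m
    occupied = seconds > 0
    return DepthBinProfile(edges[occupied], seconds[occupied], props[occupied], total)


def bottom_phase_bin(
    profile_or_median,
    classification: DiveClassification | None = None,
    bin_m: float = BIN_WIDTH_M,
) -> str:
    """400-m bin of the bottom phase, reported in the field's groups.

    Groups are ``400-800``, ``800-1200`` and ``>1200`` (m); applies only
    to U-shaped dives.
    """
    if classification is not None:
        if classification.pattern is not DivePattern.U_shaped:
            raise ValueError("bottom phase is defined only for U-shaped dives")
        median = classification.plateau_median_depth_m
    else:
        median = float(profile_or_median)
    lower = np.floor(median / bin_m) * bin_m
    if lower >= 1200.0:
        return ">1200"
    return f"{int(lower)}-{int(lower + bin_m)}"


def seafloor_proximity(
    click_depths,
    seafloor_depth_m: float,
    bin_m: float = BIN_WIDTH_M,
) -> str:
    """Water-column vs near-seafloor foraging from 400-m bins.

    The whale forages in the water column when the upper edge of the bin
    holding the 90th-percentile click depth is more than 400 m above the
    lower edge of the bin holding the seafloor; otherwise it is near the
    seafloor. When the percentile bin is *deeper* than the seafloor bin
    the seafloor depth or the deepest click depths must be wrong, and
    ``"inconsistent"`` is returned.
    """
    z = np.asarray(click_depths, dtype=float)
    p90 = float(np.percentile(z, 90))
    p90_bin = np.floor(p90 / bin_m)
    sf_bin = np.floor(seafloor_depth_m / bin_m)
    if p90_bin > sf_bin:
        return "inconsistent"
    p90_upper = (p90_bin + 1) * bin_m
    sf_lower = sf_bin * bin_m
    if sf_lower - p90_upper > bin_m:
        return "water_column"
    return "near_seafloor"
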
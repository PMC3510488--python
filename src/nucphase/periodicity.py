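"""Peak detection and periodicity estimation for distance histograms.

Two periods coexist in nucleosome distance auto-correlation profiles: main
peaks every nucleosome repeat length (~160 bp in budding yeast) and a fine
structure of sub-peaks every ~10 bp reflecting rotationally related
overlapping positions. Both are estimated the same way: find local maxima
of the (smoothed) histogram, assign each peak a harmonic index, and fit an
ordinary least-squares line of position on index; the slope is the period.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .dac import DistanceHistogram

__all__ = [
    "PeakList",
    "PeakFit",
    "EnvelopeReport",
    "find_peaks",
    "fit_period",
    "assign_indices",
    "envelope_discontinuity",
]


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean; edge windows are truncated, not padded."""
    if window <= 1:
        return np.asarray(values, dtype=float)
    s = pd.Series(values, dtype=float)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


@dataclass
class PeakList:
    """Local maxima of a smoothed distance histogram."""

    positions: np.ndarray  # bp, strictly increasing
    heights: np.ndarray  # smoothed histogram value at each peak
    prominences: np.ndarray
    smoothing_window: int

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_bp": self.positions,
                "height": self.heights,
                "prominence": self.prominences,
            }
        )


def find_peaks(
    h: DistanceHistogram,
    smoothing_window: int = 3,
    min_prominence: float = 0.05,
    search_range: tuple[int, int] | None = None,
) -> PeakList:
    """Local maxima of the moving-average-smoothed histogram.

    ``min_prominence`` is a fraction of the median smoothed value inside
    the search range (a scale-free local baseline); peaks less prominent
    than that are discarded. The default search range starts at 5 bp,
    skipping the flagged self-distance bin and its shoulder.
    """
    values = h.values
    if smoothing_window >= len(values):
        raise ValueError("histogram shorter than the smoothing window")
    lo, hi = search_range if search_range is not None else (5, h.max_distance)
    lo = max(lo, 1)
    hi = min(hi, h.max_distance)
    smoothed = moving_average(values, smoothing_window)
    segment = smoothed[lo : hi + 1]
    if not np.any(segment > 0):
        empty = np.array([], dtype=float)
        return PeakList(empty.astype(int), empty, empty, smoothing_window)
    baseline = float(np.median(segment))
    threshold = min_prominence * baseline if baseline > 0 else 0.0
    idx, props = signal.find_peaks(segment, prominence=threshold or None)
    return PeakList(
        positions=idx + lo,
        heights=segment[idx],
        prominences=props.get("prominences", np.zeros(len(idx))),
        smoothing_window=smoothing_window,
    )


@dataclass
class PeakFit:
    """OLS fit of peak position (bp) on harmonic index; slope = period."""

    peak_positions: np.ndarray
    harmonic_indices: np.ndarray
    slope: float
    intercept: float
    r: float

    def slope_display(self, decimals: int = 2) -> float:
        """Slope rounded for reporting (2 dp for sub-peak fits, 0 for main)."""
        return float(np.round(self.slope, decimals))

    def to_json(self) -> str:
        return json.dumps(
            {
                "slope_bp": self.slope,
                "intercept_bp": self.intercept,
                "r": self.r,
                "n_points": int(len(self.peak_positions)),
                "positions": [float(p) for p in self.peak_positions],
                "indices": [int(i) for i in self.harmonic_indices],
            },
            indent=2,
        )

    def summary(self) -> str:
        return (
            f"period fit: slope = {self.slope:.4f} bp/index, "
            f"intercept = {self.intercept:.2f} bp, r = {self.r:.4f}, "
            f"n = {len(self.peak_positions)}"
        )


def fit_period(positions, indices) -> PeakFit:
    """Ordinary least squares of peak position on harmonic index.

    Repeated indices are allowed (e.g. a split first peak contributes
    several positions at index 1).
    """
    positions = np.asarray(positions, dtype=float)
    indices = np.asarray(indices, dtype=float)
    if len(positions) != len(indices):
        raise ValueError("positions and indices must have equal length")
    if len(positions) < 2:
        raise ValueError("need at least two peaks to fit a period")
    if np.all(indices == indices[0]):
        raise ValueError("degenerate fit: all harmonic indices identical")
    if np.any(indices < 1):
        raise ValueError("harmonic indices must be positive")
    res = stats.linregress(indices, positions)
    return PeakFit(
        peak_positions=positions,
        harmonic_indices=indices.astype(int),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
    )


def assign_indices(positions, approximate_period: float) -> np.ndarray:
    """Nearest-harmonic index for each peak: round(position / period).

    All members of a split peak lying within half a period of one period
    share index 1. A position that would round to index 0 (below half the
    period) raises, prompting a better period guess.
    """
    if approximate_period <= 0:
        raise ValueError("approximate_period must be positive")
    positions = np.asarray(positions, dtype=float)
    idx = np.floor(positions / approximate_period + 0.5).astype(int)
    if np.any(idx < 1):
        bad = positions[idx < 1]
        raise ValueError(
            f"positions {bad.tolist()} round to harmonic 0 for period "
            f"{approximate_period}; supply a smaller period guess"
        )
    return idx


@dataclass
class EnvelopeReport:
    """Continuity diagnosis of the sub-peak envelope of a DAC profile.

    The envelope is the sequence of histogram values at the sub-peak
    positions. A population mixing arrays of different spacings shows a
    sharp upward step in this envelope (around 80-90 bp for a 160 bp vs
    180-250 bp mixture); a uniformly spaced population does not.
    """

    subpeak_positions: np.ndarray
    envelope_values: np.ndarray
    discontinuity_location: float | None
    discontinuity_score: float
    threshold: float

    @property
    def is_discontinuous(self) -> bool:
        return self.discontinuity_location is not None


def envelope_discontinuity(
    h: DistanceHistogram,
    subpeaks: PeakList,
    probe_range: tuple[float, float] = (70.0, 100.0),
    threshold: float = 3.0,
) -> EnvelopeReport:
    """Score the largest upward jump of the sub-peak envelope.

    The score is the maximum positive difference between consecutive
    envelope values whose midpoint lies inside ``probe_range``, normalized
    by the median absolute consecutive change outside the probe range (so
    it is invariant under scaling of the histogram). The reported location
    is the midpoint of the two sub-peaks flanking the jump, or None when
    the score does not exceed ``threshold``.
    """
    pos = np.asarray(subpeaks.positions, dtype=float)
    if len(pos) < 5:
        raise ValueError("need at least 5 sub-peaks to judge the envelope")
    if pos[0] > probe_range[0] or pos[-1] < probe_range[1]:
        raise ValueError(
            f"sub-peaks ({pos[0]:.0f}..{pos[-1]:.0f} bp) do not span the "
            f"probe range {probe_range}"
        )
    env = h.values[pos.astype(int)]
    diffs = np.diff(env)
    mids = (pos[:-1] + pos[1:]) / 2.0
    inside = (mids >= probe_range[0]) & (mids <= probe_range[1])
    if not np.any(inside) or not np.any(~inside):
        raise ValueError("probe range must split the envelope differences")
    outside_changes = np.abs(diffs[~inside])
    baseline = float(np.median(outside_changes))
    if baseline == 0:
        baseline = max(float(np.mean(outside_changes)), np.finfo(float).tiny)
    in_diffs = diffs[inside]
    best = int(np.argmax(in_diffs))
    score = float(max(in_diffs[best], 0.0) / baseline)
    location = float(mids[inside][best]) if score > threshold else None
    return EnvelopeReport(
        subpeak_positions=pos,
        envelope_values=env,
        discontinuity_location=location,
        discontinuity_score=score,
        threshold=threshold,
    )
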
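"""Inter-nucleosome distance auto-correlation (DAC) and cross-correlation (DCC).

The DAC histogram records, for every distance d, the number of (multiplicity-
weighted) pairs of nucleosome anchor positions separated by d on the same
chromosome: two positions occurring 5 and 10 times contribute 5 x 10 = 50 to
their separating distance. "Summed up for both strands" is realised as the
sum of a left-anchor histogram and a right-anchor histogram (for strandless
paired-end fragments the fragment start on the minus strand is the right
end). The coincidence-number variant clamps every positional count to 1
before the same pair sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .fragments import FragmentSet, Gene

__all__ = [
    "PositionCountTable",
    "DistanceHistogram",
    "position_counts",
    "compute_dac",
    "compute_dcc",
    "restrict_to_regions",
]

ChromCounts = dict[str, "np.ndarray"]  # chrom -> (positions, counts) pair


def _tabulate(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos, cnt = np.unique(positions, return_counts=True)
    return pos.astype(np.int64), cnt.astype(np.int64)


@dataclass
class PositionCountTable:
    """Occurrence counts of fragment anchor coordinates, per chromosome.

    ``left`` holds the anchors read in the forward direction (fragment
    starts, or round-up dyads); ``right`` holds the parallel anchors seen
    from the other strand (fragment last bases, or round-down dyads), used
    for the both-strands sum.
    """

    left: dict[str, tuple[np.ndarray, np.ndarray]]
    right: dict[str, tuple[np.ndarray, np.ndarray]]
    anchor_mode: str = "start"
    n_fragments: int | None = None

    def total(self) -> int:
        return int(sum(c.sum() for _, c in self.left.values()))

    def chroms(self) -> list[str]:
        return sorted(self.left)

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[tuple[str, int], int],
        anchor_mode: str = "start",
        right_counts: Mapping[tuple[str, int], int] | None = None,
    ) -> "PositionCountTable":
        """Build a table directly from {(chrom, position): count}.

        When ``right_counts`` is omitted the right-anchor table mirrors the
        left one (as it would for fragments of one fixed length, up to an
        irrelevant constant shift).
        """

        def pack(mapping: Mapping[tuple[str, int], int]) -> dict:
            per: dict[str, list[tuple[int, int]]] = {}
            for (chrom, pos), c in mapping.items():
                if c < 1:
                    raise ValueError("all counts must be >= 1")
                per.setdefault(chrom, []).append((pos, c))
            out = {}
            for chrom, items in per.items():
                items.sort()
                pos = np.array([p for p, _ in items], dtype=np.int64)
                cnt = np.array([c for _, c in items], dtype=np.int64)
                if len(np.unique(pos)) != len(pos):
                    raise ValueError(f"duplicate positions on {chrom}")
                out[chrom] = (pos, cnt)
            return out

        left = pack(counts)
        right = pack(right_counts) if right_counts is not None else {
            c: (p.copy(), k.copy()) for c, (p, k) in left.items()
        }
        total = int(sum(c.sum() for _, c in left.values()))
        return cls(left=left, right=right, anchor_mode=anchor_mode,
                   n_fragments=total)


def position_counts(fs: FragmentSet, anchor_mode: str = "start") -> PositionCountTable:
    """Tabulate fragment anchor coordinates with multiplicity.

    anchor_mode 'start': left anchors are fragment starts; right anchors are
    fragment last bases (the minus-strand starts). anchor_mode 'center':
    left anchors are round-half-up dyads; right anchors are the
    round-half-down centers (the dyad as seen from the minus strand). For
    odd fragment lengths the two center anchors coincide.
    """
    if len(fs) == 0:
        raise ValueError("cannot tabulate an empty fragment set")
    if anchor_mode not in ("start", "center"):
        raise ValueError(f"anchor_mode must be 'start' or 'center', got {anchor_mode!r}")
    df = fs.df
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    if anchor_mode == "start":
        left_pos, right_pos = starts, ends - 1
    else:
        lengths = ends - starts
        left_pos = starts + lengths // 2          # round-half-up central base
        right_pos = starts + (lengths - 1) // 2   # round-half-down
    left: dict = {}
    right: dict = {}
    chroms = df["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        m = chroms == chrom
        left[str(chrom)] = _tabulate(left_pos[m])
        right[str(chrom)] = _tabulate(right_pos[m])
    return PositionCountTable(left=left, right=right, anchor_mode=anchor_mode,
                              n_fragments=len(fs))


@dataclass
class DistanceHistogram:
    """Distance -> correlation weight, for d = 0..max_distance.

    ``values`` is the both-strands sum (left + right anchors);
    ``values_left``/``values_right`` are the single-anchor histograms. The
    d = 0 bin is defined (within-position pair count for DAC) but flagged:
    plotting and peak finding skip it by default.
    """

    max_distance: int
    values_left: np.ndarray
    values_right: np.ndarray
    mode: str  # "DAC" | "DCC"
    weighting: str  # "multiplicative" | "coincidence"
    anchor_mode: str

    @property
    def values(self) -> np.ndarray:
        return self.values_left + self.values_right

    @property
    def distances(self) -> np.ndarray:
        return np.arange(self.max_distance + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_bp": self.distances,
                "value": self.values,
                "mode": self.mode,
                "weighting": self.weighting,
                "anchor_mode": self.anchor_mode,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DistanceHistogram":
        df = pd.read_csv(path, sep="\t")
        values = df["value"].to_numpy(dtype=float)
        half = values / 2.0
        return cls(
            max_distance=int(df["distance_bp"].max()),
            values_left=half,
            values_right=half,
            mode=str(df["mode"].iloc[0]),
            weighting=str(df["weighting"].iloc[0]),
            anchor_mode=str(df["anchor_mode"].iloc[0]),
        )

    def plot(self, ax=None, skip_self: bool = True, **kwargs):
        """Line plot of the histogram (d >= 1 unless skip_self=False)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        lo = 1 if skip_self else 0
        ax.plot(self.distances[lo:], self.values[lo:], **kwargs)
        ax.set_xlabel("distance (bp)")
        ax.set_ylabel(f"{self.mode} value")
        return ax


def _anchor_autocorr(
    table: dict[str, tuple[np.ndarray, np.ndarray]],
    max_distance: int,
    clamp: bool,
) -> np.ndarray:
    """Sum over chromosomes of sum_i c_i * c_(i+d) for d = 0..max_distance,
    with the d = 0 bin replaced by the within-position pair count
    sum_i c_i (c_i - 1) / 2."""
    out = np.zeros(max_distance + 1)
    for chrom, (pos, cnt) in table.items():
        c = np.minimum(cnt, 1) if clamp else cnt
        lo, hi = int(pos[0]), int(pos[-1])
        span = hi - lo
        x = np.zeros(span + 1)
        x[pos - lo] = c
        if span == 0:
            corr = np.array([float(c[0]) ** 2])
        else:
            # full autocorrelation; lag d sits at index span + d
            corr = fftconvolve(x, x[::-1])[span : span + max_distance + 1]
        n = min(len(corr), max_distance + 1)
        out[:n] += np.rint(corr[:n])
        # replace the squared-sum diagonal with within-position pairs
        out[0] += float((c * (c - 1) // 2).sum()) - np.rint(corr[0])
    return out


def compute_dac(
    t: PositionCountTable,
    max_distance: int,
    weighting: str = "multiplicative",
) -> DistanceHistogram:
    """Distance auto-correlation of one position-count table.

    For d >= 1 the value at d is the sum over same-chromosome unordered
    position pairs (i < j, j - i = d) of c_i * c_j, computed on the left
    anchors and on the right anchors and summed ("both strands"). With
    weighting='coincidence' counts are clamped to 1 first (each occupied
    position counted once). values[0] is the within-position pair count
    sum c(c-1)/2 per anchor set; it is flagged as a self-distance and
    skipped by default in plots and peak searches.
    """
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    if weighting not in ("multiplicative", "coincidence"):
        raise ValueError(f"unknown weighting {weighting!r}")
    clamp = weighting == "coincidence"
    left = _anchor_autocorr(t.left, max_distance, clamp)
    right = _anchor_autocorr(t.right, max_distance, clamp)
    return DistanceHistogram(
        max_distance=max_distance,
        values_left=left,
        values_right=right,
        mode="DAC",
        weighting=weighting,
        anchor_mode=t.anchor_mode,
    )


def _anchor_crosscorr(
    ta: dict[str, tuple[np.ndarray, np.ndarray]],
    tb: dict[str, tuple[np.ndarray, np.ndarray]],
    chroms: Iterable[str],
    max_distance: int,
) -> np.ndarray:
    out = np.zeros(max_distance + 1)
    for chrom in chroms:
        pa, ca = ta[chrom]
        pb, cb = tb[chrom]
        lo = int(min(pa[0], pb[0]))
        hi = int(max(pa[-1], pb[-1]))
        span = hi - lo
        x = np.zeros(span + 1)
        y = np.zeros(span + 1)
        x[pa - lo] = ca
        y[pb - lo] = cb
        # cross[k] at index span + k equals sum_i x_i * y_(i+k)
        cross = fftconvolve(x, y[::-1])
        center = span
        out[0] += np.rint(cross[center])
        dmax = min(max_distance, span)
        if dmax >= 1:
            plus = np.rint(cross[center + 1 : center + dmax + 1])
            minus = np.rint(cross[center - dmax : center])[::-1]
            out[1 : dmax + 1] += plus + minus
    return out


def compute_dcc(
    a: PositionCountTable, b: PositionCountTable, max_distance: int
) -> DistanceHistogram:
    """Distance cross-correlation between two datasets.

    values[d] sums c_x * c_y over ordered same-chromosome pairs (x from a,
    y from b) with |x - y| = d; the d = 0 bin (shared positions) is
    included. Chromosomes absent from either table are dropped with a
    warning.
    """
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    if a.anchor_mode != b.anchor_mode:
        raise ValueError("anchor_mode mismatch between datasets")
    shared = sorted(set(a.left) & set(b.left))
    only = set(a.left) ^ set(b.left)
    if only:
        warnings.warn(
            f"chromosome universes differ; ignoring {sorted(only)}", stacklevel=2
        )
    if not shared:
        raise ValueError("no shared chromosomes between datasets")
    left = _anchor_crosscorr(a.left, b.left, shared, max_distance)
    right = _anchor_crosscorr(a.right, b.right, shared, max_distance)
    return DistanceHistogram(
        max_distance=max_distance,
        values_left=left,
        values_right=right,
        mode="DCC",
        weighting="multiplicative",
        anchor_mode=a.anchor_mode,
    )


def restrict_to_regions(fs: FragmentSet, genes: list[Gene], pad: int = 200) -> FragmentSet:
    """Keep fragments whose midpoint falls within pad bp of any gene body.

    The window is [body_start - pad, body_end + pad) per gene (0-based
    half-open); a fragment inside several genes is kept once, with its
    multiplicity preserved.
    """
    if not genes:
        raise ValueError("empty gene list")
    if pad < 0:
        raise ValueError("pad must be >= 0")
    dyads = fs.dyads
    chroms = fs.df["chrom"].to_numpy()
    keep = np.zeros(len(fs), dtype=bool)
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        per_chrom.setdefault(g.chrom, []).append((g.body_start - pad, g.body_end + pad))
    for chrom, spans in per_chrom.items():
        spans.sort()
        # merge overlapping windows, then vectorized membership test
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([s for s, _ in merged])
        ends = np.array([e for _, e in merged])
        m = chroms == chrom
        idx = np.searchsorted(starts, dyads[m], side="right") - 1
        ok = (idx >= 0) & (dyads[m] < ends[np.clip(idx, 0, len(ends) - 1)])
        keep[m] |= ok
    return fs._derive(keep, f"regions[{len(genes)} genes, pad={pad}]")
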
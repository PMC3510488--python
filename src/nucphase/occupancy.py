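"""Normalized nucleosome occupancy tracks, TSS composites, dyad histograms.

Occupancy at a nucleotide is the number of nucleosomal fragments covering
it, divided by the genome-wide mean coverage per base pair, so the
genome-wide mean of the normalized track is 1. Composite profiles average
the track across genes after flipping minus-strand genes so positive
offsets always run with transcription.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import FragmentSet, Gene, GenomicInterval

__all__ = [
    "OccupancyTrack",
    "CompositeProfile",
    "DyadHistogram",
    "occupancy_track",
    "composite_tss_profile",
    "dyad_histogram",
]


@dataclass
class OccupancyTrack:
    """Per-chromosome normalized occupancy arrays (genome mean = 1)."""

    tracks: dict[str, np.ndarray]
    normalization_constant: float  # mean raw coverage per bp across the genome

    def raw(self, chrom: str) -> np.ndarray:
        return self.tracks[chrom] * self.normalization_constant

    def genome_mean(self) -> float:
        total = sum(t.sum() for t in self.tracks.values())
        length = sum(len(t) for t in self.tracks.values())
        return float(total / length)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.tracks):
                t = self.tracks[chrom]
                # run-length encode constant stretches
                change = np.flatnonzero(np.diff(t) != 0) + 1
                bounds = np.concatenate(([0], change, [len(t)]))
                for s, e in zip(bounds[:-1], bounds[1:]):
                    fh.write(f"{chrom}\t{s}\t{e}\t{t[s]:.6g}\n")


def occupancy_track(fs: FragmentSet, genome_lengths: dict[str, int]) -> OccupancyTrack:
    """Raw per-bp coverage divided by the genome-wide mean coverage."""
    if len(fs) == 0:
        raise ValueError("cannot build an occupancy track from an empty set")
    coverage: dict[str, np.ndarray] = {
        chrom: np.zeros(length + 1) for chrom, length in genome_lengths.items()
    }
    df = fs.df
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in coverage:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        length = genome_lengths[chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if starts.min() < 0 or ends.max() > length:
            raise ValueError(f"fragment beyond the end of {chrom}")
        diff = coverage[chrom]
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
    tracks = {c: np.cumsum(d[:-1]) for c, d in coverage.items()}
    total = sum(t.sum() for t in tracks.values())
    glen = sum(genome_lengths.values())
    norm = total / glen
    return OccupancyTrack(
        tracks={c: t / norm for c, t in tracks.items()},
        normalization_constant=float(norm),
    )


@dataclass
class CompositeProfile:
    """Mean normalized occupancy across genes, aligned on the TSS.

    Offsets are bp relative to the TSS (offset 0), negative upstream,
    in the direction of transcription.
    """

    offsets: np.ndarray
    values: np.ndarray
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset_bp": self.offsets, "mean_occupancy": self.values,
             "n_genes": self.n_genes}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        ax.plot(self.offsets, self.values, **kwargs)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlabel("position relative to TSS (bp)")
        ax.set_ylabel("mean normalized occupancy")
        return ax


def composite_tss_profile(
    track: OccupancyTrack,
    genes: list[Gene],
    window: tuple[int, int] = (500, 2000),
) -> CompositeProfile:
    """Unweighted per-gene mean of the track around each TSS.

    ``window = (upstream, downstream)`` in bp; genes whose window would
    cross a chromosome boundary are dropped with a warning rather than
    padded.
    """
    up, down = window
    if up < 0 or down < 0:
        raise ValueError("window extents must be non-negative")
    width = up + down + 1
    acc = np.zeros(width)
    used = 0
    dropped = 0
    for g in genes:
        if g.chrom not in track.tracks:
            dropped += 1
            continue
        t = track.tracks[g.chrom]
        tss = g.tss
        if g.strand == "+":
            lo, hi = tss - up, tss + down + 1
            if lo < 0 or hi > len(t):
                dropped += 1
                continue
            acc += t[lo:hi]
        else:
            lo, hi = tss - down, tss + up + 1
            if lo < 0 or hi > len(t):
                dropped += 1
                continue
            acc += t[lo:hi][::-1]
        used += 1
    if dropped:
        warnings.warn(f"dropped {dropped} gene(s) with out-of-bounds windows",
                      stacklevel=2)
    if used == 0:
        raise ValueError("no usable genes for the composite profile")
    return CompositeProfile(
        offsets=np.arange(-up, down + 1), values=acc / used, n_genes=used
    )


@dataclass
class DyadHistogram:
    """Per-bp counts of fragment midpoints (dyads) within one region."""

    region: GenomicInterval
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        pos = np.arange(self.region.start, self.region.end)
        return pd.DataFrame(
            {
                "chrom": self.region.chrom,
                "position_1based": pos + 1,
                "dyad_count": self.counts,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def dyad_histogram(fs: FragmentSet, region: GenomicInterval) -> DyadHistogram:
    """Count fragment dyads (round-half-up central base) per position."""
    if region.end <= region.start:
        raise ValueError("empty region")
    dyads = fs.dyads
    chroms = fs.df["chrom"].to_numpy()
    m = (chroms == region.chrom) & (dyads >= region.start) & (dyads < region.end)
    counts = np.bincount(dyads[m] - region.start, minlength=region.end - region.start)
    return DyadHistogram(region=region, counts=counts.astype(np.int64))
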
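"""Fragments, genes and genome sequences: parsing, filtering, coordinate rules.

All internal coordinates are 0-based half-open (BED convention). Report
output intended for comparison with genome-browser coordinates is 1-based
inclusive. The single midpoint ("dyad") convention used package-wide is the
central base of the fragment, rounded *up* when the fragment length is even:
in 0-based coordinates ``dyad = start + length // 2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Fragment",
    "FragmentSet",
    "Gene",
    "GenomeSeq",
    "GenomicInterval",
    "read_fragments",
    "filter_fragments",
    "read_genes",
    "read_genome",
    "write_bed",
    "parse_region",
]


class ParseError(ValueError):
    """A record in an input file could not be interpreted."""


@dataclass(frozen=True, slots=True)
class Fragment:
    """A nucleosomal DNA fragment as a strandless genomic interval.

    ``strand`` records an analysis orientation (e.g. the transcription
    direction of the gene a +1 nucleosome belongs to), not a property of the
    double-stranded fragment itself.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("fragment chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start (got {self.start}..{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def dyad(self) -> int:
        """Central base (0-based), rounded up for even lengths.

        Equivalent to the 1-based round-half-up midpoint: a 147-bp fragment
        with 1-based first base s has dyad s+73; a 148-bp fragment has dyad
        s+74.
        """
        return self.start + self.length // 2


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    @classmethod
    def from_1based(cls, chrom: str, first: int, last: int) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (browser/report style)."""
        return cls(chrom, first - 1, last)

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class FragmentSet:
    """A multiset of fragments with an append-only filter history.

    Duplicate fragments are semantically meaningful (they are independent
    sequencing observations of nucleosomes at the same position) and are
    never collapsed. Internally backed by a DataFrame with columns
    ``chrom``, ``start``, ``end``, ``strand``.
    """

    def __init__(
        self,
        fragments: pd.DataFrame | Iterable[Fragment],
        genome_id: str = "",
        provenance: list[dict] | None = None,
    ) -> None:
        if isinstance(fragments, pd.DataFrame):
            df = fragments.reset_index(drop=True)
            if "strand" not in df.columns:
                df = df.assign(strand="+")
            df = df[["chrom", "start", "end", "strand"]]
        else:
            rows = [(f.chrom, f.start, f.end, f.strand) for f in fragments]
            df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
            if df.empty:
                df = df.astype({"start": np.int64, "end": np.int64})
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and (df["end"] <= df["start"]).any():
            bad = int((df["end"] <= df["start"]).sum())
            raise ValueError(f"{bad} fragment(s) with end <= start")
        self._df = df
        self.genome_id = genome_id
        self.provenance: list[dict] = list(provenance or [])

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[Fragment]:
        for row in self._df.itertuples(index=False):
            yield Fragment(row.chrom, int(row.start), int(row.end), row.strand)

    @property
    def df(self) -> pd.DataFrame:
        """Read-only view of the backing table (chrom, start, end, strand)."""
        return self._df

    @property
    def lengths(self) -> np.ndarray:
        return (self._df["end"] - self._df["start"]).to_numpy()

    @property
    def dyads(self) -> np.ndarray:
        """0-based dyad positions (round-half-up central base)."""
        return (self._df["start"] + (self._df["end"] - self._df["start"]) // 2).to_numpy()

    def chroms(self) -> list[str]:
        return sorted(self._df["chrom"].unique())

    def _derive(self, mask_or_df, step: str) -> "FragmentSet":
        df = self._df[mask_or_df] if not isinstance(mask_or_df, pd.DataFrame) else mask_or_df
        prov = self.provenance + [
            {"filter": step, "n_before": len(self._df), "n_after": len(df)}
        ]
        return FragmentSet(df, genome_id=self.genome_id, provenance=prov)

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.provenance, columns=["filter", "n_before", "n_after"])


# ---------------------------------------------------------------------------
# Gene annotation


@dataclass(frozen=True, slots=True)
class Gene:
    gene_id: str
    chrom: str
    body_start: int
    body_end: int
    strand: str
    induction_fold: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.body_end <= self.body_start:
            raise ValueError(f"gene {self.gene_id}: body_start must precede body_end")
        if self.induction_fold is not None and self.induction_fold <= 0:
            raise ValueError(f"gene {self.gene_id}: induction fold must be positive")

    @property
    def tss(self) -> int:
        """0-based coordinate of the first transcribed base."""
        return self.body_start if self.strand == "+" else self.body_end - 1

    def transcript_coord(self, pos: int) -> int:
        """Position in transcription coordinates where the TSS is +1.

        There is no coordinate 0: the base immediately upstream of the TSS
        is -1. Works for either strand.
        """
        offset = pos - self.tss if self.strand == "+" else self.tss - pos
        return offset + 1 if offset >= 0 else offset


# ---------------------------------------------------------------------------
# Genome sequence


_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclass
class GenomeSeq:
    """Uppercase per-chromosome nucleotide strings over {A,C,G,T,N}."""

    seqs: dict[str, str]

    def __post_init__(self) -> None:
        self._arrays: dict[str, np.ndarray] = {}
        for name, s in self.seqs.items():
            if not s:
                raise ValueError(f"chromosome {name!r} has empty sequence")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.seqs.items()}

    def array(self, chrom: str) -> np.ndarray:
        """Sequence as a uint8 array of ASCII codes (cached)."""
        if chrom not in self._arrays:
            self._arrays[chrom] = np.frombuffer(
                self.seqs[chrom].encode("ascii"), dtype=np.uint8
            )
        return self._arrays[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self.seqs[chrom]) or end <= start:
            raise IndexError(f"slice {chrom}:{start}-{end} out of bounds")
        return self.seqs[chrom][start:end]

    @staticmethod
    def revcomp(seq: str) -> str:
        return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


def read_genome(path: str | Path) -> GenomeSeq:
    """Read a FASTA file into memory, uppercasing sequences."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate chromosome name {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ParseError(f"no FASTA records in {path}")
    return GenomeSeq(seqs)


# ---------------------------------------------------------------------------
# Fragment readers / writers


def _read_bed(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start ({start}, {end})")
            rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _read_bedpe(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 BEDPE columns")
            c1, c2 = parts[0], parts[3]
            if c1 != c2:
                raise ParseError(
                    f"{path}:{lineno}: mate chromosomes differ ({c1} vs {c2})"
                )
            try:
                s1, e1, s2, e2 = (int(parts[i]) for i in (1, 2, 4, 5))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            start, end = min(s1, s2), max(e1, e2)
            if end <= start:
                raise ParseError(f"{path}:{lineno}: degenerate pair span")
            rows.append((c1, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _read_sam(path: Path) -> pd.DataFrame:
    """One fragment per properly paired template (positive template length).

    Secondary and supplementary alignments are skipped; the mate with
    negative template length is skipped so each template is counted once.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_proper_pair or read.template_length <= 0:
                continue
            start = read.reference_start
            rows.append((read.reference_name, start, start + read.template_length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


_READERS = {"BED": _read_bed, "BEDPE": _read_bedpe, "SAM": _read_sam}


def read_fragments(
    path: str | Path, format: str | None = None, genome_id: str = ""
) -> FragmentSet:
    """Read nucleosomal fragments from BED, BEDPE or SAM.

    ``format`` is inferred from the file suffix when not given. For SAM
    input one fragment is produced per properly paired template, with
    length equal to the absolute template length.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"bed": "BED", "bedpe": "BEDPE", "sam": "SAM", "bam": "SAM"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path}")
    fmt = format.upper()
    if fmt not in _READERS:
        raise ValueError(f"unknown format {format!r}; expected BED, BEDPE or SAM")
    df = _READERS[fmt](path)
    fs = FragmentSet(df, genome_id=genome_id)
    fs.provenance.append({"filter": f"read:{fmt}:{path.name}", "n_before": len(df),
                          "n_after": len(df)})
    return fs


def write_bed(fs: FragmentSet, path: str | Path) -> None:
    fs.df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Filtering


def filter_fragments(
    fs: FragmentSet,
    min_len: int,
    max_len: int,
    exclude: Sequence[GenomicInterval] = (),
) -> FragmentSet:
    """Keep fragments with min_len <= length <= max_len (inclusive) whose
    midpoint lies outside every excluded interval.

    The canonical use is selecting core-particle-length fragments
    (147-152 bp) and dropping the repetitive rDNA locus. Multiplicities are
    preserved; the filter is idempotent.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    lengths = fs.lengths
    keep = (lengths >= min_len) & (lengths <= max_len)
    if exclude:
        dyads = fs.dyads
        chroms = fs.df["chrom"].to_numpy()
        for iv in exclude:
            inside = (chroms == iv.chrom) & (dyads >= iv.start) & (dyads < iv.end)
            keep &= ~inside
    step = f"length[{min_len},{max_len}]" + (
        f"+exclude[{len(exclude)}]" if exclude else ""
    )
    return fs._derive(keep, step)


def parse_region(text: str) -> GenomicInterval:
    """Parse 'chrom:first-last' in 1-based inclusive coordinates."""
    chrom, _, span = text.partition(":")
    if not span:
        raise ValueError(f"malformed region {text!r}; expected chrom:first-last")
    first, _, last = span.replace(",", "").partition("-")
    return GenomicInterval.from_1based(chrom, int(first), int(last))


# ---------------------------------------------------------------------------
# Gene table


def read_genes(path: str | Path) -> list[Gene]:
    """Read a gene table (TSV: gene_id, chrom, start, end, strand[, fold]).

    A header line starting with 'gene_id' is accepted and skipped.
    Coordinates are 0-based half-open gene-body spans; the TSS is the left
    end for '+' genes and the right end for '-' genes.
    """
    path = Path(path)
    genes: list[Gene] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "gene_id":
                continue
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected >=5 columns")
            gene_id, chrom, start_s, end_s, strand = parts[:5]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: missing or bad strand {strand!r}")
            fold: float | None = None
            if len(parts) >= 6 and parts[5] != "":
                fold = float(parts[5])
                if fold <= 0:
                    raise ParseError(f"{path}:{lineno}: non-positive fold {fold}")
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                gene = Gene(gene_id, chrom, int(start_s), int(end_s), strand, fold)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            genes.append(gene)
    if not genes:
        raise ParseError(f"no gene records in {path}")
    return genes


def write_genes(genes: Iterable[Gene], path: str | Path) -> None:
    rows = [
        (g.gene_id, g.chrom, g.body_start, g.body_end, g.strand,
         "" if g.induction_fold is None else g.induction_fold)
        for g in genes
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "fold"]
    ).to_csv(path, sep="\t", index=False)
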
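"""Sequence and interval plumbing shared by every pipeline stage.

Coordinates are 0-based half-open (BED convention) throughout. Sequences
are uppercase over the alphabet {A, C, G, T, N}; any other IUPAC code is
masked to N on input and N never matches a motif nor contributes a k-mer.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

_VALID = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Genome:
    """A set of named contigs holding uppercase A/C/G/T/N sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            if set(seq) - _VALID:
                raise ValueError(f"contig {name!r} has bases outside A/C/G/T/N")

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open, BED-compatible."""

    contig: str
    start: int
    end: int
    strand: str = "."
    label: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Region") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class FeatureTrack:
    """A named collection of regions, kept sorted by (contig, start).

    Regions may overlap one another (e.g. histone-mark peaks from
    replicate experiments).
    """

    name: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: (r.contig, r.start, r.end))
        # precomputed per-contig arrays for binary-search overlap queries
        self._starts: dict[str, list[int]] = {}
        self._maxend: dict[str, list[int]] = {}
        for r in self.regions:
            self._starts.setdefault(r.contig, []).append(r.start)
            ends = self._maxend.setdefault(r.contig, [])
            ends.append(max(r.end, ends[-1]) if ends else r.end)
    def __len__(self) -> int:
        return len(self.regions)


def revcomp(seq: str) -> str:
    """Reverse complement over A/C/G/T/N; an involution."""
    if set(seq) - _VALID:
        raise ValueError("sequence has bases outside A/C/G/T/N")
    return seq.translate(_RC_TABLE)[::-1]


def gc_content(seq: str) -> float:
    """G+C fraction of the non-N bases; error on empty or all-N input."""
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - _VALID:
        raise ValueError("sequence has bases outside A/C/G/T/N")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("GC content undefined for all-N sequence")
    return (seq.count("G") + seq.count("C")) / denom


def overlaps_any(query: Region, track: FeatureTrack) -> bool:
    """True iff the query shares >= 1 bp with any track region.

    Strand-blind. Uses a sorted-start / running-max-end binary search so
    that overlapping track regions are handled correctly.
    """
    starts = track._starts.get(query.contig)
    if not starts:
        return False
    # candidates are regions with start < query.end
    hi = bisect_right(starts, query.end - 1)
    if hi == 0:
        return False
    # any of them reaches past query.start iff the running max end does
    return track._maxend[query.contig][hi - 1] > query.start


def read_fasta(path: str | Path) -> Genome:
    """Read a multi-record FASTA into a Genome.

    Lowercase bases are uppercased; IUPAC ambiguity codes fall back to N.
    Duplicate record names and empty files are hard errors.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        seq = _NON_ACGTN.sub("N", str(rec.seq).upper())
        contigs[rec.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[Region]:
    """Read BED3/BED4/BED5/BED6 into Regions."""
    regions: list[Region] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            regions.append(
                Region(
                    contig=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    label=f[3] if len(f) > 3 else "",
                    score=float(f[4]) if len(f) > 4 and f[4] != "." else 0.0,
                    strand=f[5] if len(f) > 5 else ".",
                )
            )
    return regions


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    """Write BED6 (contig, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.label or '.'}\t"
                f"{r.score:g}\t{r.strand}\n"
            )


def write_bedgraph(
    intervals: Sequence[tuple[str, int, int, float]], path: str | Path
) -> None:
    """Write a bedGraph; intervals must be sorted and non-overlapping."""
    prev: tuple[str, int] | None = None
    for contig, start, end, _ in intervals:
        if start >= end:
            raise ValueError("bedGraph interval with non-positive width")
        if prev is not None and prev[0] == contig and start < prev[1]:
            raise ValueError("bedGraph intervals unsorted or overlapping")
        if prev is not None and prev[0] > contig:
            raise ValueError("bedGraph contigs unsorted")
        prev = (contig, end)
    with open(path, "w") as fh:
        for contig, start, end, value in intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{value:g}\n")
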
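"""Genomic interval model, BED/narrowPeak I/O, overlap arithmetic and shuffling.

All coordinates are 0-based half-open ``[start, end)``, the BED convention.
Strand is carried through I/O but ignored by every overlap operation.
"""

from __future__ import annotations

import bisect
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomeTable",
    "IntervalIndex",
    "read_intervals",
    "write_bed",
    "read_genome_table",
    "overlap_any",
    "overlaps_any",
    "filter_enhancer_candidates",
    "promoters_from_tss",
    "shuffle_intervals",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A chrom/start/end span; the universal unit for peaks, bins, TADs, variants."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap: [0,100) and [100,200) do NOT overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeTable:
    """Mapping chromosome name -> length in bp."""

    entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.entries.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.entries

    def __getitem__(self, chrom: str) -> int:
        return self.entries[chrom]

    def chroms(self) -> list[str]:
        return list(self.entries)

    def validate(self, intervals: Iterable[GenomicInterval]) -> None:
        for iv in intervals:
            if iv.chrom not in self.entries:
                raise ValueError(f"unknown chromosome {iv.chrom}")
            if iv.end > self.entries[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {self.entries[iv.chrom]}"
                )


def read_genome_table(path) -> GenomeTable:
    """Read a two-column (chrom, length) chrom-sizes table."""
    entries: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            chrom, length = fields[0], int(fields[1])
            if chrom in entries:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {chrom}")
            entries[chrom] = length
    return GenomeTable(entries)


def _parse_bed_line(fields: Sequence[str], fmt: str) -> GenomicInterval:
    chrom = fields[0]
    start, end = int(fields[1]), int(fields[2])
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    if fmt == "narrowPeak":
        if len(fields) < 7:
            raise ValueError("narrowPeak requires >= 7 columns")
        score = float(fields[6])  # signalValue; col 5 is capped at 1000
    else:
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-", ".") else None
    return GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)


def read_intervals(path, format: str = "bed") -> list[GenomicInterval]:
    """Read BED or ENCODE narrowPeak records, in file order.

    BED coordinates are taken verbatim as 0-based half-open. For narrowPeak
    the score comes from signalValue (column 7).
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown format {format!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                out.append(_parse_bed_line(fields, format))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write BED6 rows (headerless, tab-separated); missing fields become '.'/'0'."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = "0" if iv.score is None else format(iv.score, ".6g")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{score}\t{iv.strand or '.'}\n"
            )


class IntervalIndex:
    """Sorted-start index with prefix-max ends for O(log n) overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._index: dict[str, tuple[list[int], np.ndarray]] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            starts = [s for s, _ in spans]
            ends = np.array([e for _, e in spans], dtype=np.int64)
            self._index[chrom] = (starts, np.maximum.accumulate(ends))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        entry = self._index.get(chrom)
        if entry is None:
            return False
        starts, prefix_max_end = entry
        # subjects with start < query end; overlap iff any of them ends > query start
        i = bisect.bisect_left(starts, end)
        return i > 0 and int(prefix_max_end[i - 1]) > start


def overlap_any(query: GenomicInterval, subjects: Iterable[GenomicInterval]) -> bool:
    """True iff ``query`` shares >= 1 bp with any subject (half-open semantics)."""
    if isinstance(subjects, IntervalIndex):
        return subjects.overlaps(query.chrom, query.start, query.end)
    return IntervalIndex(subjects).overlaps(query.chrom, query.start, query.end)


def overlaps_any(
    queries: Sequence[GenomicInterval], subjects: Iterable[GenomicInterval]
) -> np.ndarray:
    """Vectorised overlap_any: boolean array, one entry per query."""
    idx = subjects if isinstance(subjects, IntervalIndex) else IntervalIndex(subjects)
    return np.array([idx.overlaps(q.chrom, q.start, q.end) for q in queries], dtype=bool)


def filter_enhancer_candidates(
    peaks: Sequence[GenomicInterval],
    blacklist: Iterable[GenomicInterval],
    promoters: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Drop peaks overlapping blacklisted regions or promoter windows.

    Promoters are expected as TSS-centered windows (see promoters_from_tss).
    Order of the surviving peaks is preserved.
    """
    bl = IntervalIndex(blacklist)
    pr = IntervalIndex(promoters)
    return [
        p
        for p in peaks
        if not bl.overlaps(p.chrom, p.start, p.end)
        and not pr.overlaps(p.chrom, p.start, p.end)
    ]


def promoters_from_tss(
    tss: Iterable[GenomicInterval],
    flank: int,
    genome: GenomeTable | None = None,
) -> list[GenomicInterval]:
    """Expand 1-bp TSS records into symmetric promoter windows [tss-flank, tss+flank).

    Windows are clipped at position 0 and (when a genome table is given) at the
    chromosome end.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    out = []
    for iv in tss:
        pos = iv.start
        start = max(0, pos - flank)
        end = pos + flank
        if genome is not None and iv.chrom in genome:
            end = min(end, genome[iv.chrom])
        out.append(replace(iv, start=start, end=end))
    return out


def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    genome: GenomeTable,
    seed: int,
    excluded: Sequence[GenomicInterval] | None = None,
    max_rejections: int = 1000,
) -> list[GenomicInterval]:
    """Randomly re-place intervals on the genome, preserving their lengths.

    Placement is uniform over eligible start positions; the chromosome is drawn
    proportional to its number of eligible positions for the interval's length.
    Candidates overlapping ``excluded`` are rejected and redrawn, up to
    ``max_rejections`` attempts per interval.
    """
    rng = np.random.default_rng(seed)
    chroms = genome.chroms()
    lengths = np.array([genome[c] for c in chroms], dtype=np.int64)
    excl = IntervalIndex(excluded) if excluded else None

    out: list[GenomicInterval] = []
    for iv in intervals:
        size = len(iv)
        eligible = np.maximum(lengths - size + 1, 0)
        total = eligible.sum()
        if total == 0:
            raise ValueError(
                f"interval of length {size} does not fit on any chromosome"
            )
        probs = eligible / total
        placed = False
        for _ in range(max_rejections):
            ci = rng.choice(len(chroms), p=probs)
            start = int(rng.integers(0, eligible[ci]))
            if excl is not None and excl.overlaps(chroms[ci], start, start + size):
                continue
            out.append(replace(iv, chrom=chroms[ci], start=start, end=start + size))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place interval of length {size} after "
                f"{max_rejections} rejections against the excluded set"
            )
    return out
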
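"""Genomic-interval algebra, step signal tracks, threshold peak calling and I/O.

All coordinates are 0-based half-open (BED dialect). Readers of 1-based
formats must convert at the boundary; nothing downstream ever sees 1-based
coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "SignalTrack",
    "intersect",
    "merge",
    "call_peaks_threshold",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "extract_sequence",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span with optional BED6 annotations."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be +, - or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class IntervalSet:
    """An ordered collection of intervals sorted by (chrom, start, end).

    Sortedness is established at construction and preserved by every
    operation in this module.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=GenomicInterval.sort_key
        )

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals)"

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def total_bases(self) -> int:
        """Total covered bases, counting overlaps once (union length)."""
        return sum(len(iv) for iv in merge(self, 0))

    def _check_sorted(self) -> None:
        keys = [iv.sort_key() for iv in self.intervals]
        if keys != sorted(keys):
            raise ValueError("interval set is not sorted by (chrom, start, end)")


def intersect(
    a: IntervalSet, b: IntervalSet
) -> list[tuple[GenomicInterval, list[GenomicInterval]]]:
    """Pair every interval of `a` with all intervals of `b` sharing >= 1 base.

    Intervals of `a` without a partner are paired with an empty list.
    Half-open semantics: [0, 10) and [10, 20) do not overlap.
    """
    a._check_sorted()
    b._check_sorted()
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[tuple[GenomicInterval, list[GenomicInterval]]] = []
    for iv in a:
        partners = [o for o in by_chrom.get(iv.chrom, ()) if iv.overlaps(o)]
        out.append((iv, partners))
    return out


def merge(s: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Collapse runs of intervals whose gaps are <= max_gap into single spans.

    Touching intervals (gap 0) merge at max_gap = 0; the output is disjoint
    and idempotent under repeated merging.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    merged: list[GenomicInterval] = []
    for chrom, group in itertools.groupby(s, key=lambda iv: iv.chrom):
        cur_start = cur_end = None
        for iv in group:
            if cur_end is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_end is not None:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(merged)


class SignalTrack:
    """Per-chromosome step signal with bedGraph semantics.

    Steps are (start, end, value) with non-overlapping spans per chromosome;
    bases not covered by any step have implicit value 0.
    """

    def __init__(
        self, steps: dict[str, Sequence[tuple[int, int, float]]] | None = None
    ) -> None:
        self.steps: dict[str, list[tuple[int, int, float]]] = {}
        if steps:
            for chrom, chrom_steps in steps.items():
                ordered = sorted(chrom_steps)
                for (s0, e0, _), (s1, _, _) in zip(ordered, ordered[1:]):
                    if s1 < e0:
                        raise ValueError(
                            f"overlapping steps on {chrom}: "
                            f"[{s0},{e0}) and starting at {s1}"
                        )
                for s0, e0, v in ordered:
                    if e0 <= s0:
                        raise ValueError(f"empty step [{s0},{e0}) on {chrom}")
                    if v < 0:
                        raise ValueError(f"negative signal {v} on {chrom}")
                self.steps[chrom] = [
                    (int(s), int(e), float(v)) for s, e, v in ordered
                ]

    def chroms(self) -> list[str]:
        return sorted(self.steps)

    def value_at(self, chrom: str, pos: int) -> float:
        for s, e, v in self.steps.get(chrom, ()):
            if s <= pos < e:
                return v
        return 0.0


def call_peaks_threshold(
    track: SignalTrack, threshold: float, min_length: int = 1
) -> IntervalSet:
    """Call peaks as maximal runs of bases with signal >= threshold.

    Mirrors genome-browser style thresholding: a peak is a maximal interval
    with signal >= threshold at every base and length >= min_length; its
    score is the maximum signal inside it and its name encodes the summit
    (leftmost base attaining the maximum).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if min_length < 1:
        raise ValueError(f"min_length must be >= 1, got {min_length}")
    peaks: list[GenomicInterval] = []
    for chrom, steps in track.steps.items():
        run_start = None
        run_end = None
        run_max = 0.0
        run_summit = None
        for s, e, v in steps:
            qualifies = v >= threshold
            if qualifies and run_end == s:
                run_end = e
                if v > run_max:
                    run_max, run_summit = v, s
            elif qualifies:
                if run_start is not None and run_end - run_start >= min_length:
                    peaks.append(
                        GenomicInterval(
                            chrom, run_start, run_end,
                            name=f"summit={run_summit}", score=run_max,
                        )
                    )
                run_start, run_end, run_max, run_summit = s, e, v, s
        if run_start is not None and run_end - run_start >= min_length:
            peaks.append(
                GenomicInterval(
                    chrom, run_start, run_end,
                    name=f"summit={run_summit}", score=run_max,
                )
            )
    return IntervalSet(peaks)


def peak_summit(peak: GenomicInterval) -> int:
    """Summit recorded by call_peaks_threshold, else the interval midpoint."""
    if peak.name and peak.name.startswith("summit="):
        return int(peak.name.split("=", 1)[1])
    return peak.midpoint


# ---------------------------------------------------------------------------
# I/O: BED, bedGraph, FASTA
# ---------------------------------------------------------------------------

_HEADER_PREFIXES = ("track", "browser", "#")


def read_bed(path) -> IntervalSet:
    """Read BED3/BED6. Tolerates track/browser/# header lines."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(_HEADER_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 and fields[3] != "." else None
                score = (
                    float(fields[4])
                    if len(fields) > 4 and fields[4] != "."
                    else None
                )
                strand = fields[5] if len(fields) > 5 else "."
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return IntervalSet(intervals)


def write_bed(s: IntervalSet, path) -> None:
    """Write BED (6 columns when any annotation is present, else 3)."""
    bed6 = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in s
    )
    with open(path, "w") as fh:
        for iv in s:
            if bed6:
                score = "." if iv.score is None else f"{iv.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{iv.name or '.'}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedgraph(path) -> SignalTrack:
    steps: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(_HEADER_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(
                    f"{path}: line {lineno}: bedGraph needs 4 fields, "
                    f"got {len(fields)}"
                )
            try:
                steps.setdefault(fields[0], []).append(
                    (int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return SignalTrack(steps)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for s, e, v in track.steps[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {contig: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_sequence(genome: dict[str, str], interval: GenomicInterval) -> str:
    """Extract the interval's sequence; minus strand is reverse-complemented."""
    if interval.chrom not in genome:
        raise KeyError(f"contig {interval.chrom!r} not in genome")
    contig = genome[interval.chrom]
    if interval.end > len(contig):
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            f"extends beyond contig length {len(contig)}"
        )
    seq = contig[interval.start : interval.end].upper()
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq
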
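"""Coordinate types, interval algebra and flat-file readers.

Everything downstream (breakpoint detection, chromatin-state tracks,
permutation association, Hi-C anchors) speaks in terms of three types
defined here:

* :class:`GenomeTable` — the coordinate universe: ordered chromosome
  names with lengths.
* :class:`GenomicInterval` — one half-open, 0-based interval (BED
  convention) with an optional label and score.
* :class:`RegionSet` — a named, genome-validated collection of
  intervals, kept sorted by (chromosome order, start, end, label).

All coordinates are 0-based half-open throughout; readers for 1-based
formats convert at the boundary.  Region sets are strandless —
orientation is carried only by syntenic fragments, which have their own
type in :mod:`grr.synteny`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import GenomeMismatchError, ParseError, ValidationError

__all__ = [
    "GenomeTable",
    "GenomicInterval",
    "RegionSet",
    "read_genome_table",
    "write_genome_table",
    "read_region_set",
    "write_region_set",
    "read_bedgraph",
    "merge_intervals",
    "coverage_fraction",
    "intersect",
    "complement",
]


@dataclass(frozen=True)
class GenomeTable:
    """Ordered chromosome names and lengths (bp).

    The order of ``entries`` is the canonical chromosome order used for
    sorting intervals and laying out genome-wide matrices.
    """

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in genome table")
        for name, length in self.entries:
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "_lengths", dict(self.entries))
        object.__setattr__(self, "_order", {n: i for i, n in enumerate(names)})

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeTable":
        return cls(tuple(lengths.items()))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def order(self, chrom: str) -> int:
        try:
            return self._order[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """Half-open interval [start, end) on one chromosome, 0-based."""

    chrom: str
    start: int
    end: int
    label: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def distance_to(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between two intervals; 0 if they touch or overlap; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


class RegionSet:
    """A named set of genome-validated intervals, sorted deterministically.

    Sorting key is (chromosome order in the genome table, start, end,
    label); this makes every downstream computation reproducible
    regardless of input order.
    """

    def __init__(self, name: str, intervals: Iterable[GenomicInterval], genome: GenomeTable):
        self.name = name
        self.genome = genome
        ivs = list(intervals)
        for iv in ivs:
            if iv.chrom not in genome:
                raise ValidationError(
                    f"interval on unknown chromosome {iv.chrom!r} in region set {name!r}"
                )
            if iv.end > genome.length(iv.chrom):
                raise ValidationError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length "
                    f"{genome.length(iv.chrom)} in region set {name!r}"
                )
        ivs.sort(key=lambda iv: (genome.order(iv.chrom), iv.start, iv.end, iv.label or ""))
        self.intervals: list[GenomicInterval] = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RegionSet)
            and self.intervals == other.intervals
            and self.genome == other.genome
        )

    def __repr__(self) -> str:
        return f"RegionSet({self.name!r}, n={len(self)})"

    def with_name(self, name: str) -> "RegionSet":
        return RegionSet(name, self.intervals, self.genome)

    def by_chromosome(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, in sorted order."""
        out: dict[str, list[list[int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, [[], []])
            out[iv.chrom][0].append(iv.start)
            out[iv.chrom][1].append(iv.end)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in out.items()
        }

    def total_span(self) -> int:
        """Total bp covered after self-merge (overlaps counted once)."""
        total = 0
        for starts, ends in _merged_arrays(self).values():
            total += int((ends - starts).sum())
        return total


# ---------------------------------------------------------------------------
# readers / writers


def read_genome_table(path) -> GenomeTable:
    """Read a 2-column tab-delimited genome table (name, length)."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(path, lineno, f"expected 2 columns, got {len(parts)}")
            try:
                length = int(parts[1])
            except ValueError:
                raise ParseError(path, lineno, f"non-integer length {parts[1]!r}") from None
            entries.append((parts[0], length))
    if not entries:
        raise ParseError(path, 0, "empty genome table")
    return GenomeTable(tuple(entries))


def write_genome_table(genome: GenomeTable, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.entries:
            fh.write(f"{name}\t{length}\n")


def read_region_set(path, genome: GenomeTable, name: str | None = None) -> RegionSet:
    """Read a BED3/BED6-dialect file into a validated RegionSet.

    Columns beyond the third are optional: column 4 is kept as the
    interval label, column 5 as a numeric score.  Malformed lines raise
    :class:`ParseError` with the line number; intervals on chromosomes
    absent from ``genome`` or out of bounds raise
    :class:`ValidationError`.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, f"expected >=3 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if not (0 <= start < end):
                raise ParseError(path, lineno, f"invalid interval [{start}, {end})")
            label = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    score = float(parts[4])
                except ValueError:
                    raise ParseError(path, lineno, f"non-numeric score {parts[4]!r}") from None
            intervals.append(GenomicInterval(parts[0], start, end, label, score))
    return RegionSet(name or Path(path).stem, intervals, genome)


def write_region_set(rs: RegionSet, path) -> None:
    """Write BED; emits 6 columns when any interval has a label or score."""
    rich = any(iv.label is not None or iv.score is not None for iv in rs)
    with open(path, "w") as fh:
        for iv in rs:
            if rich:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t{score}\t.\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedgraph(path, genome: GenomeTable, name: str = "bedgraph") -> RegionSet:
    """Read a 4-column bedGraph into a RegionSet with scores (e.g. mappability)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(path, lineno, f"expected 4 columns, got {len(parts)}")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise ParseError(path, lineno, "bad bedGraph record") from None
            intervals.append(GenomicInterval(parts[0], start, end, None, value))
    return RegionSet(name, intervals, genome)


# ---------------------------------------------------------------------------
# interval algebra


def _merged_arrays(rs: RegionSet, max_gap: int = 0) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge intervals within ``max_gap`` per chromosome; returns sorted arrays."""
    out = {}
    for chrom, (starts, ends) in rs.by_chromosome().items():
        # already sorted by start (RegionSet invariant)
        ms, me = [], []
        cs, ce = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - ce <= max_gap:
                ce = max(ce, int(e))
            else:
                ms.append(cs)
                me.append(ce)
                cs, ce = int(s), int(e)
        ms.append(cs)
        me.append(ce)
        out[chrom] = (np.asarray(ms, dtype=np.int64), np.asarray(me, dtype=np.int64))
    return out


def merge_intervals(rs: RegionSet, max_gap: int = 0) -> RegionSet:
    """Union of intervals, joining any two within ``max_gap`` bp on one chromosome.

    The output is sorted and pairwise non-overlapping.  Labels and
    scores are dropped (a merged interval has no single provenance).
    """
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    merged = []
    for chrom, (starts, ends) in _merged_arrays(rs, max_gap).items():
        merged.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return RegionSet(rs.name, merged, rs.genome)


def coverage_fraction(
    rs: RegionSet, genome: GenomeTable | None = None, per_chromosome: bool = False
):
    """Fraction of the genome covered by ``rs`` after self-merge.

    With ``per_chromosome=True`` returns a dict chromosome -> fraction
    of that chromosome's length (all chromosomes in the genome table,
    including uncovered ones).
    """
    genome = genome or rs.genome
    if len(genome) == 0:
        raise ValidationError("empty genome table")
    covered = {c: 0 for c in genome.names}
    for chrom, (starts, ends) in _merged_arrays(rs).items():
        covered[chrom] = int((ends - starts).sum())
    if per_chromosome:
        return {c: covered[c] / genome.length(c) for c in genome.names}
    return sum(covered.values()) / genome.total_length


def intersect(a: RegionSet, b: RegionSet, name: str | None = None) -> RegionSet:
    """Exact base-pair intersection of two region sets (both self-merged first)."""
    if a.genome != b.genome:
        raise GenomeMismatchError("region sets are on different genomes")
    am, bm = _merged_arrays(a), _merged_arrays(b)
    out = []
    for chrom in set(am) & set(bm):
        s1, e1 = am[chrom]
        s2, e2 = bm[chrom]
        i = j = 0
        while i < len(s1) and j < len(s2):
            lo = max(s1[i], s2[j])
            hi = min(e1[i], e2[j])
            if lo < hi:
                out.append(GenomicInterval(chrom, int(lo), int(hi)))
            if e1[i] < e2[j]:
                i += 1
            else:
                j += 1
    return RegionSet(name or f"{a.name}&{b.name}", out, a.genome)


def complement(rs: RegionSet, name: str | None = None) -> RegionSet:
    """Genome minus the (self-merged) region set."""
    out = []
    merged = _merged_arrays(rs)
    for chrom in rs.genome.names:
        length = rs.genome.length(chrom)
        pos = 0
        if chrom in merged:
            for s, e in zip(*merged[chrom]):
                if s > pos:
                    out.append(GenomicInterval(chrom, pos, int(s)))
                pos = max(pos, int(e))
        if pos < length:
            out.append(GenomicInterval(chrom, pos, length))
    return RegionSet(name or f"not_{rs.name}", out, rs.genome)
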
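"""Ancestral karyotypes, evolutionary breakpoint regions and rearrangement rates.

The comparative-genomics half of the toolkit.  Inputs are per-lineage
syntenic fragment maps: for each reconstructed ancestor, an ordered set
of reference-genome intervals, each tagged with the ancestral
chromosome, the coordinates it occupies there, and its orientation.
From these the module

* curates reconstructed ancestral chromosome fragments (RACFs) into
  karyotypes by joining fragment ends that are adjacent and collinear
  in a guide genome (:func:`curate_racfs`),
* classifies RACFs into chromosomes versus unplaced fragments by a
  minimum chromosome size (:func:`classify_chromosomes`, default
  26 Mbp),
* detects evolutionary breakpoint regions (EBRs) where ancestral
  adjacency is disrupted on the reference, types them as inversion or
  inter-chromosomal, and assigns each to the most recent branch on
  which it appears (:func:`detect_ebrs`),
* ages EBRs relative to a named split (:func:`classify_ebr_age`),
* counts inversions, fusions and fissions between two karyotypes by
  rendering one as a signed sequence of blocks of the other
  (:func:`count_rearrangements`),
* converts per-branch EBR counts and branch times (My) into
  rearrangement rates with a chi-square excess test
  (:func:`compute_rates`),
* extracts multispecies homologous syntenic blocks
  (:func:`detect_mshsbs`) and ancestral syntenic associations
  (:func:`detect_syntenic_associations`).

Coordinates follow the conventions of :mod:`grr.genome` (0-based
half-open).  Orientation is ``+`` when reference and ancestral
coordinates increase together, ``-`` otherwise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GenomeMismatchError, ParseError, ValidationError
from .genome import GenomeTable, GenomicInterval, RegionSet

__all__ = [
    "SyntenicFragment",
    "SyntenicFragmentMap",
    "AncestralKaryotype",
    "EBR",
    "EventCounts",
    "RateTable",
    "SyntenicAssociation",
    "read_fragment_map",
    "write_fragment_map",
    "write_ebrs",
    "karyotype_from_map",
    "curate_racfs",
    "classify_chromosomes",
    "detect_ebrs",
    "classify_ebr_age",
    "count_rearrangements",
    "compute_rates",
    "detect_mshsbs",
    "detect_syntenic_associations",
    "chain_from_newick",
]

MIN_CHROM_SIZE = 26_000_000  # smallest chromosome across the assemblies compared
DEFAULT_RESOLUTION = 300_000  # syntenic fragment resolution of the reconstruction


@dataclass(frozen=True)
class SyntenicFragment:
    """One block of conserved synteny: a reference interval and where it
    sits in an ancestral genome."""

    ref: GenomicInterval
    ancestor_chrom: str
    ancestor_start: int
    ancestor_end: int
    orientation: str  # '+' or '-'
    racf_id: str | None = None

    def __post_init__(self):
        if self.orientation not in ("+", "-"):
            raise ValidationError(f"orientation must be '+' or '-', got {self.orientation!r}")
        if not (0 <= self.ancestor_start < self.ancestor_end):
            raise ValidationError(
                f"empty ancestral span [{self.ancestor_start}, {self.ancestor_end})"
            )

    @property
    def racf(self) -> str:
        return self.racf_id if self.racf_id is not None else self.ancestor_chrom


class SyntenicFragmentMap:
    """All syntenic fragments of one lineage (ancestor) on the reference.

    Fragments are kept sorted by reference position and must not overlap
    on the reference.
    """

    def __init__(
        self,
        lineage: str,
        fragments: Iterable[SyntenicFragment],
        genome: GenomeTable,
        resolution: int = DEFAULT_RESOLUTION,
    ):
        self.lineage = lineage
        self.genome = genome
        self.resolution = resolution
        frs = sorted(fragments, key=lambda f: (genome.order(f.ref.chrom), f.ref.start))
        for a, b in zip(frs, frs[1:]):
            if a.ref.chrom == b.ref.chrom and b.ref.start < a.ref.end:
                raise ValidationError(
                    f"fragments overlap on reference at {a.ref.chrom}:{b.ref.start}"
                )
        self.fragments: list[SyntenicFragment] = frs

    def __len__(self):
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def by_ref_chrom(self) -> dict[str, list[SyntenicFragment]]:
        out: dict[str, list[SyntenicFragment]] = {}
        for f in self.fragments:
            out.setdefault(f.ref.chrom, []).append(f)
        return out

    def ancestor_extent(self) -> dict[str, tuple[int, int]]:
        """Observed (min, max) ancestral coordinates per ancestral chromosome."""
        ext: dict[str, tuple[int, int]] = {}
        for f in self.fragments:
            lo, hi = ext.get(f.ancestor_chrom, (f.ancestor_start, f.ancestor_end))
            ext[f.ancestor_chrom] = (min(lo, f.ancestor_start), max(hi, f.ancestor_end))
        return ext


@dataclass
class AncestralKaryotype:
    """Curated RACFs of one ancestor: ordered signed fragment lists plus a
    chromosome/unplaced status per RACF."""

    lineage: str
    racfs: list[tuple[str, list[SyntenicFragment]]]
    genome: GenomeTable
    chromosome_status: dict[str, str] = field(default_factory=dict)  # racf_id -> status
    conflicts: list[str] = field(default_factory=list)

    def racf_length(self, racf_id: str) -> int:
        for rid, frs in self.racfs:
            if rid == racf_id:
                return sum(len(f.ref) for f in frs)
        raise KeyError(racf_id)

    @property
    def n_chromosomes(self) -> int:
        return sum(1 for s in self.chromosome_status.values() if s == "chromosome")


@dataclass(frozen=True)
class EBR:
    """An evolutionary breakpoint region on the reference genome."""

    interval: GenomicInterval
    lineage: str
    type: str  # 'inversion' | 'inter_chromosomal'
    age_class: str | None = None  # 'ancestral' | 'recent' | 'reference_specific'

    def __post_init__(self):
        if self.type not in ("inversion", "inter_chromosomal"):
            raise ValidationError(f"unknown EBR type {self.type!r}")


@dataclass(frozen=True)
class EventCounts:
    """Rearrangements on one branch between two reconstructed ancestors."""

    parent: str
    child: str
    inversions: int
    fusions: int
    fissions: int
    conserved_chromosomes: int
    branch_time: float | None = None

    @property
    def inter_chromosomal(self) -> int:
        return self.fusions + self.fissions

    @property
    def total(self) -> int:
        return self.inversions + self.inter_chromosomal


@dataclass
class RateTable:
    """Per-branch EBR rates plus the global average and a chi-square
    goodness-of-fit test of homogeneous rates across branches."""

    branches: pd.DataFrame  # index: branch; columns: ebr_count, branch_time, rate, residual
    total_ebrs: int
    total_time: float
    average_rate: float
    chi2: float
    pvalue: float
    df: int

    def to_tsv(self, path) -> None:
        self.branches.to_csv(path, sep="\t", index_label="branch")


@dataclass(frozen=True)
class SyntenicAssociation:
    """Two reference chromosomes carrying material of one ancestral chromosome."""

    lineage: str
    chrom_a: str
    chrom_b: str
    ancestor_chrom: str
    support: tuple[GenomicInterval, ...]

    def __post_init__(self):
        if self.chrom_a == self.chrom_b:
            raise ValidationError("a syntenic association needs two distinct chromosomes")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.chrom_a, self.chrom_b)


# ---------------------------------------------------------------------------
# I/O: 9-column fragment map TSV and EBR BED6


def read_fragment_map(path, genome: GenomeTable, resolution: int = DEFAULT_RESOLUTION):
    """Read a 9-column fragment map: ref_chr, ref_start, ref_end, lineage,
    anc_chr, anc_start, anc_end, orientation, racf_id."""
    fragments = []
    lineage = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError(path, lineno, f"expected 9 columns, got {len(parts)}")
            try:
                rs, re_, as_, ae = int(parts[1]), int(parts[2]), int(parts[5]), int(parts[6])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            lineage = parts[3]
            fragments.append(
                SyntenicFragment(
                    GenomicInterval(parts[0], rs, re_),
                    parts[4], as_, ae, parts[7],
                    parts[8] if parts[8] != "." else None,
                )
            )
    if lineage is None:
        raise ParseError(path, 0, "empty fragment map")
    return SyntenicFragmentMap(lineage, fragments, genome, resolution)


def write_fragment_map(m: SyntenicFragmentMap, path) -> None:
    with open(path, "w") as fh:
        for f in m.fragments:
            fh.write(
                f"{f.ref.chrom}\t{f.ref.start}\t{f.ref.end}\t{m.lineage}\t"
                f"{f.ancestor_chrom}\t{f.ancestor_start}\t{f.ancestor_end}\t"
                f"{f.orientation}\t{f.racf or '.'}\n"
            )


def write_ebrs(ebrs: Sequence[EBR], path) -> None:
    """Write EBRs as BED6: name = lineage:type:age, score = length."""
    with open(path, "w") as fh:
        for e in ebrs:
            name = f"{e.lineage}:{e.type}:{e.age_class or 'NA'}"
            fh.write(
                f"{e.interval.chrom}\t{e.interval.start}\t{e.interval.end}\t"
                f"{name}\t{len(e.interval)}\t.\n"
            )


# ---------------------------------------------------------------------------
# collinear block reduction (shared by EBR detection, msHSBs and counting)


@dataclass(frozen=True)
class _Block:
    ref_chrom: str
    ref_start: int
    ref_end: int
    anc_chrom: str
    anc_start: int
    anc_end: int
    orientation: str


def _anc_gap(a: _Block | SyntenicFragment, b: _Block | SyntenicFragment) -> int | None:
    """Ancestral-coordinate gap implied by reading a then b along the
    reference; None when not comparable (different chromosome/orientation)."""
    ca = a.anc_chrom if isinstance(a, _Block) else a.ancestor_chrom
    cb = b.anc_chrom if isinstance(b, _Block) else b.ancestor_chrom
    if ca != cb or a.orientation != b.orientation:
        return None
    a_s = a.anc_start if isinstance(a, _Block) else a.ancestor_start
    a_e = a.anc_end if isinstance(a, _Block) else a.ancestor_end
    b_s = b.anc_start if isinstance(b, _Block) else b.ancestor_start
    b_e = b.anc_end if isinstance(b, _Block) else b.ancestor_end
    if a.orientation == "+":
        return b_s - a_e
    return a_s - b_e


def _collinear_blocks(m: SyntenicFragmentMap, slack: int) -> dict[str, list[_Block]]:
    """Merge reference-consecutive fragments that are collinear and
    ancestrally adjacent (ancestral gap matching the reference gap within
    ``slack``), per reference chromosome."""
    out: dict[str, list[_Block]] = {}
    for chrom, frs in m.by_ref_chrom().items():
        blocks: list[_Block] = []
        cur = _Block(
            chrom, frs[0].ref.start, frs[0].ref.end,
            frs[0].ancestor_chrom, frs[0].ancestor_start, frs[0].ancestor_end,
            frs[0].orientation,
        )
        for f in frs[1:]:
            gap_anc = _anc_gap(cur, f)
            gap_ref = f.ref.start - cur.ref_end
            if gap_anc is not None and abs(gap_anc - gap_ref) <= slack and gap_anc >= -slack:
                cur = _Block(
                    chrom, cur.ref_start, f.ref.end, cur.anc_chrom,
                    min(cur.anc_start, f.ancestor_start),
                    max(cur.anc_end, f.ancestor_end),
                    cur.orientation,
                )
            else:
                blocks.append(cur)
                cur = _Block(
                    chrom, f.ref.start, f.ref.end, f.ancestor_chrom,
                    f.ancestor_start, f.ancestor_end, f.orientation,
                )
        blocks.append(cur)
        out[chrom] = blocks
    return out


# ---------------------------------------------------------------------------
# EBR detection


@dataclass
class _Candidate:
    chrom: str
    start: int
    end: int
    type: str
    internal: bool
    signatures: tuple[tuple[str, int], ...]  # broken ancestral adjacencies (anc_chrom, pos)


def _facing_coord(b: _Block, side: str) -> int:
    """Ancestral coordinate exposed by a block at its left or right
    reference side."""
    if side == "right":
        return b.anc_end if b.orientation == "+" else b.anc_start
    return b.anc_start if b.orientation == "+" else b.anc_end


def _is_broken(b: _Block, side: str, extent: dict[str, tuple[int, int]], slack: int) -> bool:
    """True when the ancestral chromosome demonstrably continues beyond the
    coordinate a block exposes at ``side`` — i.e. the junction breaks an
    ancestral adjacency rather than sitting at an ancestral terminus."""
    lo, hi = extent[b.anc_chrom]
    p = _facing_coord(b, side)
    outward_increasing = (side == "right") == (b.orientation == "+")
    if outward_increasing:
        return hi - p > slack
    return p - lo > slack


def _map_candidates(m: SyntenicFragmentMap, slack: int) -> list[_Candidate]:
    extent = m.ancestor_extent()
    cands: list[_Candidate] = []
    for chrom, blocks in _collinear_blocks(m, slack).items():
        chrom_len = m.genome.length(chrom)
        # internal junctions between consecutive blocks
        for a, b in zip(blocks, blocks[1:]):
            gap_anc = _anc_gap(a, b)
            gap_ref = b.ref_start - a.ref_end
            if gap_anc is not None and abs(gap_anc - gap_ref) <= slack and gap_anc >= -slack:
                continue  # collinear hole in coverage, not a breakpoint
            etype = "inversion" if a.anc_chrom == b.anc_chrom else "inter_chromosomal"
            sigs = []
            if _is_broken(a, "right", extent, slack):
                sigs.append((a.anc_chrom, _facing_coord(a, "right")))
            if _is_broken(b, "left", extent, slack):
                sigs.append((b.anc_chrom, _facing_coord(b, "left")))
            start, end = a.ref_end, max(b.ref_start, a.ref_end + 1)
            cands.append(_Candidate(chrom, start, end, etype, True, tuple(sigs)))
        # reference chromosome termini: a terminal block whose ancestral
        # chromosome continues beyond the terminus marks a fission-type break
        first, last = blocks[0], blocks[-1]
        if _is_broken(first, "left", extent, slack):
            end = max(first.ref_start, 1)
            cands.append(
                _Candidate(chrom, 0, end, "inter_chromosomal", False,
                           ((first.anc_chrom, _facing_coord(first, "left")),))
            )
        if _is_broken(last, "right", extent, slack):
            start = min(last.ref_end, chrom_len - 1)
            cands.append(
                _Candidate(chrom, start, chrom_len, "inter_chromosomal", False,
                           ((last.anc_chrom, _facing_coord(last, "right")),))
            )
    return cands


def _dedupe_by_signature(cands: list[_Candidate], tol: int) -> list[_Candidate]:
    """Collapse candidates that record the same broken ancestral adjacency.

    One physical fission appears once per broken end it leaves visible (a
    reference terminus, or a junction when the loose end was later fused
    elsewhere); those occurrences share a signature and are reported as a
    single EBR.  Internal junctions are never collapsed with one another —
    each real junction is its own breakpoint region (an inversion's two
    flanks stay distinct).
    """

    def same_sig(s1, s2):
        return s1[0] == s2[0] and abs(s1[1] - s2[1]) <= tol

    kept: list[_Candidate] = []
    for c in sorted(cands, key=lambda c: (not c.internal, c.chrom, c.start)):
        drop = False
        for k in kept:
            if c.internal and k.internal:
                continue
            if any(same_sig(s1, s2) for s1 in c.signatures for s2 in k.signatures):
                drop = True
                break
        if not drop:
            kept.append(c)
    return kept


def detect_ebrs(
    maps: Sequence[SyntenicFragmentMap],
    reference: GenomeTable,
    reference_name: str = "reference",
    slack: int | None = None,
) -> list[EBR]:
    """Detect EBRs from curated fragment maps ordered ancestral -> recent.

    For each map, a candidate breakpoint is emitted wherever ancestral
    adjacency is disrupted on the reference: between consecutive
    fragments mapping to different ancestral chromosomes or to
    non-adjacent/inverted coordinates of the same one, and at reference
    chromosome termini where the ancestral chromosome demonstrably
    continues.  Candidates overlapping across maps are reduced to their
    common intersection and the EBR is assigned to the most recent
    branch on which the disruption appears: a disruption visible in map
    ``i`` but absent from map ``i+1`` arose on the branch between them,
    so it is labelled with the lineage of map ``i+1`` (or with
    ``reference_name`` when visible in the most recent map).

    ``slack`` is the tolerance (bp) for ancestral-adjacency arithmetic;
    it defaults to the coarsest map resolution.
    """
    if not maps:
        return []
    for m in maps:
        if m.genome != maps[0].genome:
            raise GenomeMismatchError("fragment maps are on different reference genomes")
    if slack is None:
        slack = max(m.resolution for m in maps)
    chain = [m.lineage for m in maps] + [reference_name]

    per_map: list[list[_Candidate]] = [
        _dedupe_by_signature(_map_candidates(m, slack), tol=slack) for m in maps
    ]

    # cluster candidates across maps by reference overlap
    tagged = [(i, c) for i, cl in enumerate(per_map) for c in cl]
    tagged.sort(key=lambda t: (reference.order(t[1].chrom), t[1].start, t[1].end))
    clusters: list[list[tuple[int, _Candidate]]] = []
    for i, c in tagged:
        if clusters:
            _, prev = clusters[-1][-1]
            hi = max(x[1].end for x in clusters[-1])
            if prev.chrom == c.chrom and c.start < hi:
                clusters[-1].append((i, c))
                continue
        clusters.append([(i, c)])

    ebrs = []
    for cluster in clusters:
        i_star, lead = max(cluster, key=lambda t: t[0])
        start = max(c.start for _, c in cluster)
        end = min(c.end for _, c in cluster)
        if start >= end:  # no common core; fall back to the defining candidate
            start, end = lead.start, lead.end
        ebrs.append(
            EBR(GenomicInterval(lead.chrom, start, end), chain[i_star + 1], lead.type)
        )
    ebrs.sort(key=lambda e: (reference.order(e.interval.chrom), e.interval.start))
    return ebrs


def classify_ebr_age(
    ebrs: Sequence[EBR], split_branch: str, lineage_order: Sequence[str]
) -> list[EBR]:
    """Partition EBRs by when they occurred relative to a named split.

    ``lineage_order`` lists branch labels ancestral -> recent with the
    reference last.  Branches strictly before ``split_branch`` are
    ``ancestral``; the terminal reference branch is
    ``reference_specific``; everything in between is ``recent``.
    """
    order = {name: i for i, name in enumerate(lineage_order)}
    if split_branch not in order:
        raise ValidationError(f"unknown split branch {split_branch!r}")
    split_i, last_i = order[split_branch], len(lineage_order) - 1
    out = []
    for e in ebrs:
        if e.lineage not in order:
            raise ValidationError(f"EBR on unknown branch {e.lineage!r}")
        i = order[e.lineage]
        if i == last_i:
            age = "reference_specific"
        elif i < split_i:
            age = "ancestral"
        else:
            age = "recent"
        out.append(replace(e, age_class=age))
    return out


# ---------------------------------------------------------------------------
# RACF curation


def karyotype_from_map(m: SyntenicFragmentMap) -> AncestralKaryotype:
    """Group a fragment map into RACFs (by racf_id, default the ancestral
    chromosome), ordering fragments along the ancestral coordinates."""
    groups: dict[str, list[SyntenicFragment]] = {}
    for f in m.fragments:
        groups.setdefault(f.racf, []).append(f)
    racfs = [
        (rid, sorted(frs, key=lambda f: f.ancestor_start))
        for rid, frs in sorted(groups.items())
    ]
    return AncestralKaryotype(m.lineage, racfs, m.genome)


def _terminal_fragment(frs: list[SyntenicFragment], side: str) -> SyntenicFragment:
    return frs[0] if side == "head" else frs[-1]


def _join_evidence(
    fa: SyntenicFragment, fb: SyntenicFragment, guide: SyntenicFragmentMap | None, gap: int
) -> bool:
    """Collinearity evidence for joining across the junction fa|fb (fa left
    of fb on the reference).  ``guide=None`` means the reference itself:
    collinear iff orientations agree.  An ancestor guide supports the join
    iff one of its fragments spans the junction."""
    if guide is None:
        return fa.orientation == fb.orientation
    left, right = fa.ref.end - 1, fb.ref.start
    for g in guide.by_ref_chrom().get(fa.ref.chrom, []):
        if g.ref.start <= left and right < g.ref.end:
            return True
    return False


def curate_racfs(
    m: SyntenicFragmentMap,
    guides: Sequence[SyntenicFragmentMap | None] = (None,),
    max_join_gap: int = 500_000,
) -> AncestralKaryotype:
    """Deterministic stand-in for manual RACF merging.

    Two RACFs are joined iff terminal fragments of theirs are adjacent on
    the reference (gap <= ``max_join_gap``) with consistent orientation,
    and at least one guide shows the junction as collinear.  ``None`` in
    ``guides`` denotes the reference itself.  When one RACF end admits
    two incompatible joins, both are refused and the conflict recorded in
    ``AncestralKaryotype.conflicts``.
    """
    k = karyotype_from_map(m)
    racfs = dict(k.racfs)
    ids = list(racfs)

    # each RACF exposes a head and a tail end; find admissible joins
    def exposed_side(f: SyntenicFragment, frs: list[SyntenicFragment], ref_side: str):
        """Which RACF end (head/tail) fragment ``f`` exposes on the given
        reference side, or None if f is not terminal there."""
        outward_increasing = (ref_side == "right") == (f.orientation == "+")
        if outward_increasing:
            return "tail" if f is frs[-1] else None
        return "head" if f is frs[0] else None

    joins: list[tuple[tuple[str, str], tuple[str, str]]] = []
    for ra, rb in itertools.combinations(ids, 2):
        for fa in (racfs[ra][0], racfs[ra][-1]):
            for fb in (racfs[rb][0], racfs[rb][-1]):
                if fa.ref.chrom != fb.ref.chrom:
                    continue
                left, right = (fa, fb) if fa.ref.end <= fb.ref.start else (fb, fa)
                if right.ref.start - left.ref.end > max_join_gap:
                    continue
                la, lb = (ra, rb) if left is fa else (rb, ra)
                side_l = exposed_side(left, racfs[la], "right")
                side_r = exposed_side(right, racfs[lb], "left")
                if side_l is None or side_r is None:
                    continue
                if left.orientation != right.orientation:
                    continue
                if any(_join_evidence(left, right, g, max_join_gap) for g in guides):
                    j = ((la, side_l), (lb, side_r))
                    if j not in joins:
                        joins.append(j)

    # refuse ends with conflicting evidence
    end_uses: dict[tuple[str, str], int] = {}
    for e1, e2 in joins:
        end_uses[e1] = end_uses.get(e1, 0) + 1
        end_uses[e2] = end_uses.get(e2, 0) + 1
    conflicts = [e for e, n in end_uses.items() if n > 1]
    admissible = [j for j in joins if j[0] not in conflicts and j[1] not in conflicts]
    conflict_msgs = [f"conflicting joins at RACF end {e[0]}:{e[1]}; all refused" for e in conflicts]

    # apply joins by chaining fragment lists
    merged: dict[str, list[SyntenicFragment]] = dict(racfs)
    alias = {rid: rid for rid in ids}

    def find(r):
        while alias[r] != r:
            r = alias[r]
        return r

    for (ra, sa), (rb, sb) in admissible:
        ka, kb = find(ra), find(rb)
        if ka == kb:
            continue
        fa, fb = merged.pop(ka), merged.pop(kb)
        if sa == "head":
            fa = list(reversed(fa))
        if sb == "tail":
            fb = list(reversed(fb))
        new_id = f"{ka}+{kb}"
        merged[new_id] = fa + fb
        alias[ka] = alias[kb] = alias.setdefault(new_id, new_id)

    out = AncestralKaryotype(
        m.lineage,
        sorted(merged.items()),
        m.genome,
        conflicts=conflict_msgs,
    )
    for msg in conflict_msgs:
        warnings.warn(msg, stacklevel=2)
    return out


def classify_chromosomes(
    k: AncestralKaryotype, min_chrom_size: int = MIN_CHROM_SIZE
) -> AncestralKaryotype:
    """Label each RACF ``chromosome`` when its summed fragment length is at
    least ``min_chrom_size`` (boundary inclusive), else ``unplaced``."""
    status = {
        rid: ("chromosome" if sum(len(f.ref) for f in frs) >= min_chrom_size else "unplaced")
        for rid, frs in k.racfs
    }
    return AncestralKaryotype(k.lineage, k.racfs, k.genome, status, list(k.conflicts))


# ---------------------------------------------------------------------------
# rearrangement counting between two karyotypes


def _signed_parent_blocks(
    child_frs: list[SyntenicFragment],
    parent_blocks: dict[str, list[_Block]],
    slack: int,
) -> list[tuple[str, int, int, int]]:
    """Render one child chromosome (its fragments ordered along child
    coordinates) as a signed sequence of parent blocks, composed through
    the shared reference coordinates."""
    seq: list[tuple[str, int, int, int]] = []
    for f in child_frs:
        pieces = []
        for p in parent_blocks.get(f.ref.chrom, []):
            lo, hi = max(f.ref.start, p.ref_start), min(f.ref.end, p.ref_end)
            if lo >= hi:
                continue
            if p.orientation == "+":
                ps, pe = p.anc_start + (lo - p.ref_start), p.anc_start + (hi - p.ref_start)
            else:
                ps, pe = p.anc_start + (p.ref_end - hi), p.anc_start + (p.ref_end - lo)
            sign = 1 if f.orientation == p.orientation else -1
            pieces.append((lo, p.anc_chrom, ps, pe, sign))
        pieces.sort(key=lambda x: x[0], reverse=(f.orientation == "-"))
        seq.extend((c, ps, pe, s) for _, c, ps, pe, s in pieces)
    # merge consecutive blocks that are parent-adjacent with the same sign
    merged: list[tuple[str, int, int, int]] = []
    for c, ps, pe, s in seq:
        if merged:
            mc, mps, mpe, ms = merged[-1]
            if mc == c and ms == s:
                adjacent = abs(ps - mpe) <= slack if s == 1 else abs(mps - pe) <= slack
                if adjacent:
                    merged[-1] = (mc, min(mps, ps), max(mpe, pe), ms)
                    continue
        merged.append((c, ps, pe, s))
    return merged


def _negative_runs(seq: list[tuple[str, int, int, int]]) -> int:
    """Maximal runs of negative-sign blocks internal to one parent
    chromosome."""
    runs, run = 0, None
    for c, _, _, s in seq + [(None, 0, 0, 1)]:
        if s == -1 and (run is None or run == c):
            run = c
        else:
            if run is not None:
                runs += 1
            run = c if s == -1 else None
    return runs


def count_rearrangements(
    parent: AncestralKaryotype,
    child: AncestralKaryotype,
    slack: int | None = None,
    branch_time: float | None = None,
) -> EventCounts:
    """Count inversions, fusions and fissions on the branch parent -> child.

    Each child chromosome is rendered as a signed sequence of parent
    blocks.  Inversions are maximal negative-sign runs internal to one
    parent chromosome; a fusion is counted at each junction joining
    blocks of two distinct parent chromosomes; a parent chromosome split
    across k > 1 child chromosomes contributes k - 1 fissions; a child
    chromosome made of a single whole parent chromosome with uniform
    sign is conserved.
    """
    if parent.genome != child.genome:
        raise GenomeMismatchError("karyotypes are on different reference genomes")
    if slack is None:
        slack = DEFAULT_RESOLUTION
    parent_map = SyntenicFragmentMap(
        parent.lineage, [f for _, frs in parent.racfs for f in frs], parent.genome
    )
    parent_blocks = _collinear_blocks(parent_map, slack)
    parent_extent = parent_map.ancestor_extent()

    inversions = fusions = 0
    chrom_homes: dict[str, set[str]] = {}
    renders: dict[str, list[tuple[str, int, int, int]]] = {}
    for child_id, frs in child.racfs:
        seq = _signed_parent_blocks(frs, parent_blocks, slack)
        renders[child_id] = seq
        for c, *_ in seq:
            chrom_homes.setdefault(c, set()).add(child_id)
        # fusions: junctions between different parent chromosomes
        for (c1, *_), (c2, *_) in zip(seq, seq[1:]):
            if c1 != c2:
                fusions += 1
        # inversions: maximal negative runs within one parent chromosome.
        # A whole chromosome's orientation is arbitrary, so read it in the
        # direction giving the fewer inversions (parsimony).
        flipped = [(c, ps, pe, -s) for c, ps, pe, s in reversed(seq)]
        inversions += min(_negative_runs(seq), _negative_runs(flipped))

    fissions = sum(len(homes) - 1 for homes in chrom_homes.values())

    conserved = 0
    for child_id, seq in renders.items():
        if len(seq) != 1:
            continue
        c, ps, pe, s = seq[0]
        lo, hi = parent_extent[c]
        if len(chrom_homes[c]) == 1 and ps - lo <= slack and hi - pe <= slack:
            conserved += 1

    return EventCounts(
        parent.lineage, child.lineage, inversions, fusions, fissions, conserved, branch_time
    )


# ---------------------------------------------------------------------------
# rates and the chi-square excess test


def compute_rates(
    counts: Mapping[str, int],
    times: Mapping[str, float],
    total_time: float | None = None,
    total_count: int | None = None,
) -> RateTable:
    """Per-branch rearrangement rates (EBR/My) and a chi-square test of
    rate homogeneity across branches.

    ``counts`` and ``times`` map branch name -> EBR count / branch length
    in My.  The global average defaults to sum(counts)/sum(times) over
    the branches carrying a time, but both totals can be overridden —
    useful when the overall average is defined over the full tree depth
    while per-branch times cover only part of it.  The chi-square
    goodness-of-fit compares observed per-branch counts with expected
    counts proportional to branch time (df = branches - 1); per-branch
    standardised residuals flag branches in excess.
    """
    branches = [b for b in counts if b in times]
    for b in branches:
        if times[b] <= 0:
            raise ValidationError(f"branch {b!r} has non-positive time {times[b]}")
        if counts[b] < 0:
            raise ValidationError(f"branch {b!r} has negative count {counts[b]}")
    obs = np.array([counts[b] for b in branches], dtype=float)
    t = np.array([times[b] for b in branches], dtype=float)
    if total_count is None:
        total_count = int(sum(counts.values()))
    if total_time is None:
        total_time = float(t.sum())
    if total_time <= 0:
        raise ValidationError("total time must be positive")
    average_rate = total_count / total_time

    if len(branches) >= 2 and obs.sum() > 0:
        expected = obs.sum() * t / t.sum()
        chi2, pvalue = stats.chisquare(obs, expected)
        residuals = (obs - expected) / np.sqrt(expected)
        df = len(branches) - 1
    else:
        chi2, pvalue, residuals, df = float("nan"), float("nan"), np.full(len(obs), np.nan), 0

    table = pd.DataFrame(
        {
            "ebr_count": obs.astype(int),
            "branch_time": t,
            "rate": obs / t,
            "residual": residuals,
        },
        index=pd.Index(branches, name="branch"),
    )
    return RateTable(table, total_count, total_time, average_rate, float(chi2), float(pvalue), df)


# ---------------------------------------------------------------------------
# msHSBs and syntenic associations


def detect_mshsbs(
    maps: Sequence[SyntenicFragmentMap],
    min_size: int = DEFAULT_RESOLUTION,
    slack: int | None = None,
    name: str = "msHSB",
) -> RegionSet:
    """Maximal reference intervals covered by a single collinear,
    uninterrupted block in every map, at least ``min_size`` long."""
    if len(maps) < 2:
        raise ValidationError("msHSB detection needs at least two maps")
    if slack is None:
        slack = max(m.resolution for m in maps)
    genome = maps[0].genome
    pieces: dict[str, list[tuple[int, int]]] | None = None
    for m in maps:
        if m.genome != genome:
            raise GenomeMismatchError("fragment maps are on different reference genomes")
        blocks = {
            c: [(b.ref_start, b.ref_end) for b in bl]
            for c, bl in _collinear_blocks(m, slack).items()
        }
        if pieces is None:
            pieces = blocks
            continue
        nxt: dict[str, list[tuple[int, int]]] = {}
        for c in set(pieces) & set(blocks):
            xs, ys = pieces[c], blocks[c]
            i = j = 0
            acc = []
            while i < len(xs) and j < len(ys):
                lo, hi = max(xs[i][0], ys[j][0]), min(xs[i][1], ys[j][1])
                if lo < hi:
                    acc.append((lo, hi))
                if xs[i][1] < ys[j][1]:
                    i += 1
                else:
                    j += 1
            if acc:
                nxt[c] = acc
        pieces = nxt
    intervals = [
        GenomicInterval(c, s, e, label=name)
        for c, ivs in (pieces or {}).items()
        for s, e in ivs
        if e - s >= min_size
    ]
    return RegionSet(name, intervals, genome)


def detect_syntenic_associations(
    k: AncestralKaryotype, min_support: int = DEFAULT_RESOLUTION
) -> list[SyntenicAssociation]:
    """Ancestral chromosomes whose fragments (each >= ``min_support``)
    land on two or more reference chromosomes, one association per
    unordered reference-chromosome pair."""
    out: dict[tuple[str, str, str], list[GenomicInterval]] = {}
    for rid, frs in k.racfs:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for f in frs:
            if len(f.ref) >= min_support:
                by_chrom.setdefault(f.ref.chrom, []).append(f.ref)
        chroms = sorted(by_chrom, key=k.genome.order)
        for ca, cb in itertools.combinations(chroms, 2):
            out.setdefault((rid, ca, cb), []).extend(by_chrom[ca] + by_chrom[cb])
    return [
        SyntenicAssociation(k.lineage, ca, cb, rid, tuple(support))
        for (rid, ca, cb), support in sorted(out.items())
    ]


# ---------------------------------------------------------------------------
# species-tree helper


def chain_from_newick(path, reference_leaf: str) -> tuple[list[str], dict[str, float]]:
    """Extract the ancestor chain (root -> reference leaf) and branch times
    (My) from a Newick tree with labelled internal nodes.

    Returns (ordered labels ending at the reference leaf, branch label ->
    time above that node).
    """
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick")
    leaf = None
    for taxon_leaf in tree.leaf_node_iter():
        if taxon_leaf.taxon and taxon_leaf.taxon.label == reference_leaf:
            leaf = taxon_leaf
            break
    if leaf is None:
        raise ValidationError(f"reference leaf {reference_leaf!r} not in tree")
    chain, times = [], {}
    node = leaf
    while node is not None:
        label = node.taxon.label if node.taxon else node.label
        if label:
            chain.append(label)
            if node.edge.length is not None:
                times[label] = float(node.edge.length)
        node = node.parent_node
    chain.reverse()
    return chain, times
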
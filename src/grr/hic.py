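"""Long-range interaction (LRI) calling from binned Hi-C contact matrices,
and their overlay on ancestral synteny.

Contact matrices are symmetric, non-negative, binned at a fixed
resolution (default 50 kbp) and normalised to a common sequencing depth
(default 100 million reads).  The caller selects bin pairs with a
contact value above a threshold separated by at least a minimum
distance on the same chromosome (default 10 Mbp), discards bins of low
mappability (< 0.5), and merges surviving bins into anchor regions:
these are the intra-chromosomal LRIs.  Inter-chromosomal partners of an
anchor are found by standardising the anchor's contact values against
all bins on other chromosomes and keeping partners with z above a
threshold (default 3).  Significance of an anchor set's genome-wide
interaction level is assessed against shuffled region sets of identical
lengths placed per chromosome.

The evolutionary overlay asks which ancestral syntenic associations
(two present-day chromosomes sharing one ancestral chromosome) are
connected by inter-LRIs, which same-ancestor block pairs on one
chromosome are connected by intra-LRIs, and how close each LRI sits to
an evolutionary breakpoint region.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import GenomeMismatchError, ParseError, ValidationError
from .genome import GenomeTable, GenomicInterval, RegionSet
from .synteny import EBR, AncestralKaryotype, SyntenicAssociation

__all__ = [
    "ContactMatrix",
    "MappabilityTrack",
    "LRICall",
    "LRIGraph",
    "ConnectionReport",
    "read_ginteractions",
    "write_ginteractions",
    "write_bedpe",
    "normalize_contacts",
    "call_intra_lris",
    "filter_cell_specific",
    "call_inter_lris",
    "shuffle_interaction_zscore",
    "overlap_with_ancestral_synteny",
    "build_lri_graph",
]

DEFAULT_RESOLUTION = 50_000
VALUE_THRESHOLD = 100.0
MIN_DISTANCE = 10_000_000
MIN_MAPPABILITY = 0.5
TARGET_TOTAL = 1e8


class ContactMatrix:
    """Symmetric binned contact matrix over a genome table.

    The bin grid tiles every chromosome of ``genome`` at ``resolution``
    (last bin may be short).  A single-chromosome genome table gives an
    intra-chromosomal matrix; several chromosomes give a genome-wide one.
    """

    def __init__(
        self,
        genome: GenomeTable,
        matrix: np.ndarray,
        resolution: int = DEFAULT_RESOLUTION,
        cell_type: str | None = None,
        check: bool = True,
    ):
        self.genome = genome
        self.resolution = resolution
        self.cell_type = cell_type
        bins = []
        for chrom in genome.names:
            length = genome.length(chrom)
            for start in range(0, length, resolution):
                bins.append((chrom, start, min(start + resolution, length)))
        self.bins = pd.DataFrame(bins, columns=["chrom", "start", "end"])
        m = np.asarray(matrix, dtype=float)
        if m.shape != (len(self.bins), len(self.bins)):
            raise ValidationError(
                f"matrix shape {m.shape} does not match bin grid ({len(self.bins)} bins)"
            )
        if check:
            if (m < 0).any():
                raise ValidationError("contact values must be non-negative")
            if not np.allclose(m, m.T):
                raise ValidationError("contact matrix must be symmetric")
        self.matrix = m
        self._chrom_of = self.bins["chrom"].to_numpy()
        self._slices = {
            c: slice(int(i.min()), int(i.max()) + 1)
            for c, i in self.bins.groupby("chrom", sort=False).indices.items()
        }

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def scope(self) -> str:
        return "intra" if len(self.genome) == 1 else "genome_wide"

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices[chrom]

    def bin_interval(self, i: int) -> GenomicInterval:
        row = self.bins.iloc[i]
        return GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))

    def bins_overlapping(self, iv: GenomicInterval) -> np.ndarray:
        sl = self._slices[iv.chrom]
        starts = self.bins["start"].to_numpy()[sl]
        ends = self.bins["end"].to_numpy()[sl]
        mask = (starts < iv.end) & (ends > iv.start)
        return np.arange(sl.start, sl.stop)[mask]

    def total_contacts(self) -> float:
        """Genome-wide total counting each bin pair once (diagonal included)."""
        return float((self.matrix.sum() + np.trace(self.matrix)) / 2)

    def same_grid(self, other: "ContactMatrix") -> bool:
        return self.genome == other.genome and self.resolution == other.resolution


@dataclass
class MappabilityTrack:
    """Per-bin mappability fraction aligned to a contact-matrix grid."""

    genome: GenomeTable
    resolution: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValidationError("mappability values must lie in [0, 1]")

    @classmethod
    def uniform(cls, genome: GenomeTable, resolution: int = DEFAULT_RESOLUTION,
                value: float = 1.0) -> "MappabilityTrack":
        n = sum(-(-genome.length(c) // resolution) for c in genome.names)
        return cls(genome, resolution, np.full(n, value))

    @classmethod
    def from_bedgraph(cls, track: RegionSet, resolution: int = DEFAULT_RESOLUTION,
                      default: float = 1.0) -> "MappabilityTrack":
        """Average a scored region set (bedGraph) onto the bin grid;
        uncovered bins take ``default``."""
        genome = track.genome
        n = sum(-(-genome.length(c) // resolution) for c in genome.names)
        acc = np.zeros(n)
        cov = np.zeros(n)
        offsets, off = {}, 0
        for c in genome.names:
            offsets[c] = off
            off += -(-genome.length(c) // resolution)
        for iv in track:
            b0, b1 = iv.start // resolution, -(-iv.end // resolution)
            for b in range(b0, b1):
                lo = max(iv.start, b * resolution)
                hi = min(iv.end, (b + 1) * resolution)
                acc[offsets[iv.chrom] + b] += (iv.score or 0.0) * (hi - lo)
                cov[offsets[iv.chrom] + b] += hi - lo
        values = np.where(cov > 0, acc / np.maximum(cov, 1), default)
        return cls(genome, resolution, values)

    def aligned_to(self, m: ContactMatrix) -> bool:
        return self.genome == m.genome and self.resolution == m.resolution and len(
            self.values
        ) == m.n_bins


@dataclass(frozen=True)
class LRICall:
    """One called long-range interaction between two anchor regions."""

    kind: str  # 'intra' | 'inter'
    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    value: float
    z: float | None = None
    cell_type: str | None = None

    def __post_init__(self):
        if self.kind == "intra" and self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValidationError("intra-LRI anchors must share a chromosome")
        if self.kind == "inter" and self.anchor_a.chrom == self.anchor_b.chrom:
            raise ValidationError("inter-LRI anchors must be on different chromosomes")

    @property
    def span(self) -> int | None:
        if self.kind != "intra":
            return None
        return abs(self.anchor_b.midpoint - self.anchor_a.midpoint)


# ---------------------------------------------------------------------------
# I/O


def read_ginteractions(path, genome: GenomeTable, resolution: int = DEFAULT_RESOLUTION,
                       cell_type: str | None = None) -> ContactMatrix:
    """Read a 7-column ginteractions TSV (chr1 start1 end1 chr2 start2
    end2 value) into a dense symmetric matrix."""
    n = sum(-(-genome.length(c) // resolution) for c in genome.names)
    offsets, off = {}, 0
    for c in genome.names:
        offsets[c] = off
        off += -(-genome.length(c) // resolution)
    m = np.zeros((n, n))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ParseError(path, lineno, f"expected 7 columns, got {len(parts)}")
            c1, s1, c2, s2, v = parts[0], int(parts[1]), parts[3], int(parts[4]), float(parts[6])
            if c1 not in genome or c2 not in genome:
                raise ParseError(path, lineno, f"unknown chromosome {c1!r} or {c2!r}")
            i = offsets[c1] + s1 // resolution
            j = offsets[c2] + s2 // resolution
            m[i, j] = v
            m[j, i] = v
    return ContactMatrix(genome, m, resolution, cell_type)


def write_ginteractions(m: ContactMatrix, path, include_zeros: bool = False) -> None:
    iu = np.triu_indices(m.n_bins)
    with open(path, "w") as fh:
        for i, j in zip(*iu):
            v = m.matrix[i, j]
            if v == 0 and not include_zeros:
                continue
            a, b = m.bins.iloc[i], m.bins.iloc[j]
            fh.write(
                f"{a['chrom']}\t{a['start']}\t{a['end']}\t"
                f"{b['chrom']}\t{b['start']}\t{b['end']}\t{v:g}\n"
            )


def write_bedpe(calls: Sequence[LRICall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            z = "." if c.z is None else f"{c.z:.3f}"
            fh.write(
                f"{c.anchor_a.chrom}\t{c.anchor_a.start}\t{c.anchor_a.end}\t"
                f"{c.anchor_b.chrom}\t{c.anchor_b.start}\t{c.anchor_b.end}\t"
                f"{c.kind}\t{c.value:g}\t{z}\t{c.cell_type or '.'}\n"
            )


# ---------------------------------------------------------------------------
# calling


def normalize_contacts(raw: ContactMatrix, target_total: float = TARGET_TOTAL) -> ContactMatrix:
    """Scale a matrix so its genome-wide contact total equals
    ``target_total`` (depth normalisation, e.g. to 100 M reads)."""
    total = raw.total_contacts()
    if total <= 0:
        raise ValidationError("cannot normalise a matrix with zero total contacts")
    return ContactMatrix(raw.genome, raw.matrix * (target_total / total), raw.resolution,
                         raw.cell_type, check=False)


def _merge_bins(bin_ids: np.ndarray, m: ContactMatrix, merge_gap: int) -> list[tuple[int, int]]:
    """Merge sorted bin indices (same chromosome) into runs allowing up to
    ``merge_gap`` unselected bins between members; returns (lo, hi) bin
    index ranges, inclusive."""
    runs = []
    lo = hi = int(bin_ids[0])
    for b in bin_ids[1:]:
        if b - hi <= merge_gap + 1:
            hi = int(b)
        else:
            runs.append((lo, hi))
            lo = hi = int(b)
    runs.append((lo, hi))
    return runs


def _range_interval(m: ContactMatrix, lo: int, hi: int) -> GenomicInterval:
    a, b = m.bins.iloc[lo], m.bins.iloc[hi]
    return GenomicInterval(a["chrom"], int(a["start"]), int(b["end"]))


def call_intra_lris(
    m: ContactMatrix,
    map_track: MappabilityTrack | None = None,
    value_threshold: float = VALUE_THRESHOLD,
    min_distance: int = MIN_DISTANCE,
    min_mappability: float = MIN_MAPPABILITY,
    merge_gap: int = 1,
) -> tuple[list[LRICall], RegionSet]:
    """Call intra-chromosomal LRIs from a depth-normalised matrix.

    Bin pairs on one chromosome with value > ``value_threshold`` and
    midpoint separation >= ``min_distance`` are selected; bins with
    mappability < ``min_mappability`` are discarded first.  Surviving
    bins merge into anchor regions (joining across up to ``merge_gap``
    unselected bins) and each anchor pair is reported once with its
    maximum supporting value.
    """
    if map_track is not None and not map_track.aligned_to(m):
        raise ValidationError("mappability track not aligned to the matrix bin grid")
    mappable = (map_track.values >= min_mappability) if map_track is not None else np.ones(
        m.n_bins, bool
    )

    calls: list[LRICall] = []
    anchors: list[GenomicInterval] = []
    for chrom in m.genome.names:
        sl = m.chrom_slice(chrom)
        sub = m.matrix[sl, sl]
        k = sub.shape[0]
        i, j = np.triu_indices(k, k=1)
        dist = (j - i) * m.resolution
        ok = (sub[i, j] > value_threshold) & (dist >= min_distance)
        ok &= mappable[sl][i] & mappable[sl][j]
        if not ok.any():
            continue
        i, j = i[ok] + sl.start, j[ok] + sl.start
        sel = np.unique(np.concatenate([i, j]))
        runs = _merge_bins(sel, m, merge_gap)
        anchors.extend(_range_interval(m, lo, hi) for lo, hi in runs)

        def run_of(b):
            for ridx, (lo, hi) in enumerate(runs):
                if lo <= b <= hi:
                    return ridx
            raise AssertionError("selected bin outside all runs")

        best: dict[tuple[int, int], float] = {}
        for bi, bj in zip(i, j):
            key = tuple(sorted((run_of(bi), run_of(bj))))
            best[key] = max(best.get(key, -np.inf), float(m.matrix[bi, bj]))
        base = len(anchors) - len(runs)
        for (ra, rb), v in sorted(best.items()):
            calls.append(
                LRICall("intra", anchors[base + ra], anchors[base + rb], v,
                        cell_type=m.cell_type)
            )

    for c in calls:  # defensive: a call must never violate the gates
        assert c.span is None or c.span >= min_distance - m.resolution
    anchor_set = RegionSet(f"{m.cell_type or 'sample'}_intra_lri_anchors", anchors, m.genome)
    return calls, anchor_set


def _pair_value(m: ContactMatrix, a: GenomicInterval, b: GenomicInterval) -> float:
    ia, ib = m.bins_overlapping(a), m.bins_overlapping(b)
    if len(ia) == 0 or len(ib) == 0:
        return 0.0
    return float(m.matrix[np.ix_(ia, ib)].max())


def filter_cell_specific(
    calls: Sequence[LRICall],
    other_matrices: Sequence[ContactMatrix],
    absence_factor: float = 0.5,
    value_threshold: float = VALUE_THRESHOLD,
) -> list[LRICall]:
    """Keep calls whose anchor pair is quantitatively absent in every
    other cell type: its value there must stay below
    ``absence_factor * value_threshold``."""
    if not other_matrices:
        warnings.warn("no other matrices supplied; all calls retained", stacklevel=2)
        return list(calls)
    for om in other_matrices[1:]:
        if not om.same_grid(other_matrices[0]):
            raise GenomeMismatchError("other matrices are not on one bin grid")
    kept = []
    for c in calls:
        absent = True
        for om in other_matrices:
            if c.anchor_a.chrom not in om.genome or c.anchor_b.chrom not in om.genome:
                raise GenomeMismatchError("call anchors not on the other matrices' genome")
            if _pair_value(om, c.anchor_a, c.anchor_b) >= absence_factor * value_threshold:
                absent = False
                break
        if absent:
            kept.append(c)
    return kept


def call_inter_lris(
    gm: ContactMatrix,
    anchors: RegionSet,
    z_threshold: float = 3.0,
    merge_gap: int = 1,
    global_reference: bool = False,
) -> list[LRICall]:
    """Call inter-chromosomal partners of intra-LRI anchors.

    For each anchor, its mean contact profile over all bins on other
    chromosomes is standardised — against that anchor's own
    inter-chromosomal distribution by default, or against the pooled
    distribution over all anchors with ``global_reference=True`` —
    and partner bins with z > ``z_threshold`` are merged into partner
    regions (one call per anchor-partner pair, carrying the peak z).
    """
    if anchors.genome != gm.genome:
        raise GenomeMismatchError("anchors not on the matrix genome")
    if gm.scope != "genome_wide":
        raise ValidationError("inter-LRI calling needs a genome-wide matrix")

    profiles = []
    for anchor in anchors:
        ia = gm.bins_overlapping(anchor)
        other = gm._chrom_of != anchor.chrom
        if len(ia) == 0 or not other.any():
            warnings.warn(f"anchor {anchor} has no inter-chromosomal coverage; skipped",
                          stacklevel=2)
            profiles.append(None)
            continue
        profiles.append((gm.matrix[ia].mean(axis=0), other))

    if global_reference:
        pooled = np.concatenate(
            [prof[other] for p in profiles if p is not None for prof, other in [p]]
        )
        g_mean, g_sd = pooled.mean(), pooled.std(ddof=1)

    calls: list[LRICall] = []
    for anchor, p in zip(anchors, profiles):
        if p is None:
            continue
        prof, other = p
        vals = prof[other]
        mean, sd = (g_mean, g_sd) if global_reference else (vals.mean(), vals.std(ddof=1))
        if sd == 0:
            warnings.warn(f"anchor {anchor}: flat inter-chromosomal profile; skipped",
                          stacklevel=2)
            continue
        zrow = (prof - mean) / sd
        hits = np.flatnonzero(other & (zrow > z_threshold))
        if len(hits) == 0:
            continue
        for chrom in pd.unique(gm._chrom_of[hits]):
            sel = hits[gm._chrom_of[hits] == chrom]
            for lo, hi in _merge_bins(sel, gm, merge_gap):
                partner = _range_interval(gm, lo, hi)
                calls.append(
                    LRICall("inter", anchor, partner,
                            float(prof[lo:hi + 1].max()), float(zrow[lo:hi + 1].max()),
                            gm.cell_type)
                )
    return calls


def shuffle_interaction_zscore(
    anchors: RegionSet,
    gm: ContactMatrix,
    n_sets: int = 1000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """z-score of an anchor set's total inter-chromosomal interaction
    against shuffled region sets.

    ``n_sets`` region sets with the anchors' lengths are placed uniformly
    at random, each region staying on its own chromosome (shuffle
    semantics); a region longer than its chromosome is re-placed on a
    random chromosome that can host it.  The statistic is the summed
    inter-chromosomal contact value of all bins covered by the set.
    Returns (z, null distribution).
    """
    if len(anchors) == 0:
        raise ValidationError("empty anchor set")
    if anchors.genome != gm.genome:
        raise GenomeMismatchError("anchors not on the matrix genome")

    # per-bin total contact with all bins on other chromosomes
    inter_val = np.empty(gm.n_bins)
    for chrom in gm.genome.names:
        sl = gm.chrom_slice(chrom)
        inter_val[sl] = gm.matrix[sl].sum(axis=1) - gm.matrix[sl, sl].sum(axis=1)

    starts_all = gm.bins["start"].to_numpy()
    ends_all = gm.bins["end"].to_numpy()

    def set_value(intervals: Iterable[GenomicInterval]) -> float:
        # weight each bin by its overlap fraction so the statistic is
        # invariant to how regions sit on the bin grid
        total = 0.0
        for iv in intervals:
            ids = gm.bins_overlapping(iv)
            if len(ids) == 0:
                continue
            frac = (
                np.minimum(ends_all[ids], iv.end) - np.maximum(starts_all[ids], iv.start)
            ) / (ends_all[ids] - starts_all[ids])
            total += float((inter_val[ids] * frac).sum())
        return total

    obs = set_value(anchors)
    rng = np.random.default_rng(seed)
    names = gm.genome.names
    null = np.empty(n_sets)
    for s in range(n_sets):
        placed = []
        for iv in anchors:
            ell = len(iv)
            chrom = iv.chrom
            if gm.genome.length(chrom) < ell:
                hosts = [c for c in names if gm.genome.length(c) >= ell]
                if not hosts:
                    raise ValidationError(f"no chromosome can host a {ell} bp region")
                chrom = hosts[rng.integers(len(hosts))]
                warnings.warn(f"region of {ell} bp re-placed on {chrom}", stacklevel=2)
            start = int(rng.integers(0, gm.genome.length(chrom) - ell + 1))
            placed.append(GenomicInterval(chrom, start, start + ell))
        null[s] = set_value(placed)
    sd = null.std(ddof=1)
    z = float("nan") if sd == 0 else float((obs - null.mean()) / sd)
    return z, null


# ---------------------------------------------------------------------------
# overlay on ancestral synteny


@dataclass
class ConnectionReport:
    """How called LRIs relate to ancestral chromosome configurations."""

    associations: pd.DataFrame  # one row per syntenic association
    intra_connections: pd.DataFrame  # same-ancestor block pairs on one chromosome
    lri_ebr: pd.DataFrame  # per LRI: nearest EBR distance and class
    connected_fraction: float
    proximal_fraction: float


def _ancestral_blocks(k: AncestralKaryotype, min_support: int) -> dict[str, dict[str, list]]:
    """ancestor chromosome -> reference chromosome -> ref intervals."""
    out: dict[str, dict[str, list[GenomicInterval]]] = {}
    for rid, frs in k.racfs:
        for f in frs:
            if len(f.ref) >= min_support:
                out.setdefault(f.ancestor_chrom, {}).setdefault(f.ref.chrom, []).append(f.ref)
    return out


def _overlaps_any(iv: GenomicInterval, blocks: Iterable[GenomicInterval]) -> bool:
    return any(iv.overlaps(b) for b in blocks)


def overlap_with_ancestral_synteny(
    lris: Sequence[LRICall],
    associations: Sequence[SyntenicAssociation],
    karyotype: AncestralKaryotype,
    ebrs: Sequence[EBR],
    proximity: int = 2_000_000,
    min_support: int = 300_000,
) -> ConnectionReport:
    """Overlay LRI calls on ancestral syntenies and EBRs.

    A syntenic association (chrA, chrB) is *connected* when some
    inter-LRI joins descendant blocks of its supporting ancestral
    chromosome on both chromosomes.  Same-ancestor block pairs on one
    reference chromosome are connected by intra-LRIs linking the two
    blocks.  Each LRI is annotated with its nearest-EBR distance and
    classed as spanning (anchor overlaps an EBR), proximal (nearest EBR
    closer than ``proximity``) or distal; each association is classed by
    its rearrangement context (single_fission when its reference
    chromosomes carry only the supporting ancestor's material,
    single_fusion for pure within-chromosome fusions, else complex).
    """
    blocks = _ancestral_blocks(karyotype, min_support)
    inter = [c for c in lris if c.kind == "inter"]
    intra = [c for c in lris if c.kind == "intra"]

    # which ancestor chromosomes contribute to each reference chromosome
    anc_on_ref: dict[str, set[str]] = {}
    for anc, per_ref in blocks.items():
        for rc in per_ref:
            anc_on_ref.setdefault(rc, set()).add(anc)

    rows = []
    for assoc in associations:
        if assoc.ancestor_chrom not in blocks:
            raise ValidationError(
                f"association references unknown ancestral chromosome "
                f"{assoc.ancestor_chrom!r}"
            )
        ba = blocks[assoc.ancestor_chrom].get(assoc.chrom_a, [])
        bb = blocks[assoc.ancestor_chrom].get(assoc.chrom_b, [])
        support = [
            c for c in inter
            if (_overlaps_any(c.anchor_a, ba) and _overlaps_any(c.anchor_b, bb))
            or (_overlaps_any(c.anchor_a, bb) and _overlaps_any(c.anchor_b, ba))
        ]
        ref_chroms = set(blocks[assoc.ancestor_chrom])
        pure = all(anc_on_ref.get(rc, set()) == {assoc.ancestor_chrom} for rc in ref_chroms)
        rows.append(
            dict(
                lineage=assoc.lineage, chrom_a=assoc.chrom_a, chrom_b=assoc.chrom_b,
                ancestor_chrom=assoc.ancestor_chrom, connected=bool(support),
                n_supporting_lris=len(support),
                context="single_fission" if pure and len(ref_chroms) > 1 else "complex",
            )
        )
    assoc_df = pd.DataFrame(
        rows, columns=["lineage", "chrom_a", "chrom_b", "ancestor_chrom", "connected",
                       "n_supporting_lris", "context"],
    )

    # intra connections: same-ancestor block pairs on one reference chromosome
    irows = []
    for anc, per_ref in sorted(blocks.items()):
        for rc, ivs in sorted(per_ref.items()):
            if len(ivs) < 2:
                continue
            fused_from = anc_on_ref.get(rc, set())
            pure_fusion = all(len(blocks[a]) == 1 for a in fused_from)
            for b1, b2 in itertools.combinations(sorted(ivs, key=lambda x: x.start), 2):
                support = [
                    c for c in intra
                    if c.anchor_a.chrom == rc
                    and ((c.anchor_a.overlaps(b1) and c.anchor_b.overlaps(b2))
                         or (c.anchor_a.overlaps(b2) and c.anchor_b.overlaps(b1)))
                ]
                irows.append(
                    dict(ancestor_chrom=anc, chrom=rc, block_a=f"{b1.start}-{b1.end}",
                         block_b=f"{b2.start}-{b2.end}", connected=bool(support),
                         n_supporting_lris=len(support),
                         context="single_fusion" if pure_fusion and len(fused_from) > 1
                         else "complex")
                )
    intra_df = pd.DataFrame(
        irows, columns=["ancestor_chrom", "chrom", "block_a", "block_b", "connected",
                        "n_supporting_lris", "context"],
    )

    # per-LRI nearest EBR
    lrows = []
    for c in lris:
        dists, span = [], False
        for anchor in (c.anchor_a, c.anchor_b):
            for e in ebrs:
                if e.interval.chrom != anchor.chrom:
                    continue
                d = anchor.distance_to(e.interval)
                dists.append(d)
                if d == 0 and anchor.overlaps(e.interval):
                    span = True
        nearest = min(dists) if dists else None
        if span:
            cls = "spanning"
        elif nearest is not None and nearest < proximity:
            cls = "proximal"
        else:
            cls = "distal"
        lrows.append(
            dict(kind=c.kind, anchor_a=str(c.anchor_a.chrom), a_start=c.anchor_a.start,
                 anchor_b=str(c.anchor_b.chrom), b_start=c.anchor_b.start,
                 nearest_ebr_bp=nearest, ebr_class=cls)
        )
    lri_df = pd.DataFrame(
        lrows, columns=["kind", "anchor_a", "a_start", "anchor_b", "b_start",
                        "nearest_ebr_bp", "ebr_class"],
    )

    connected_fraction = float(assoc_df["connected"].mean()) if len(assoc_df) else float("nan")
    near = lri_df["ebr_class"].isin(["proximal", "spanning"]) if len(lri_df) else pd.Series([])
    proximal_fraction = float(near.mean()) if len(lri_df) else float("nan")
    return ConnectionReport(assoc_df, intra_df, lri_df, connected_fraction, proximal_fraction)


@dataclass
class LRIGraph:
    """Anchor-level interaction graph; hubs are anchors of degree >= 2.

    Edges are exactly the called pairs — no transitive closure: A-B and
    A-C never imply B-C.
    """

    graph: nx.Graph

    @property
    def hubs(self) -> list[tuple[str, int, int]]:
        return sorted(n for n, d in self.graph.degree if d >= 2)

    def degree(self, anchor: GenomicInterval) -> int:
        return self.graph.degree[(anchor.chrom, anchor.start, anchor.end)]

    def write_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\tkind\tvalue\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write("\t".join(map(str, [*u, *v, d["kind"], d["value"]])) + "\n")


def build_lri_graph(calls: Sequence[LRICall]) -> LRIGraph:
    """Graph whose nodes are anchor regions and edges the called pairs."""
    g = nx.Graph()
    for c in calls:
        u = (c.anchor_a.chrom, c.anchor_a.start, c.anchor_a.end)
        v = (c.anchor_b.chrom, c.anchor_b.start, c.anchor_b.end)
        g.add_edge(u, v, kind=c.kind, value=c.value)
    return LRIGraph(g)
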
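"""Synthetic data generators with planted ground truth.

Every pipeline input can be generated here at desk scale, so each
analysis stage is testable against a known answer without any external
download:

* :func:`simulate_rearrangement_history` evolves a root karyotype down a
  chain of ancestors by planted inversions, fusions and fissions, and
  expresses every ancestor as a syntenic fragment map on the resulting
  reference genome — exactly the input of EBR detection — together with
  the reference coordinates of every planted breakpoint.
* :func:`simulate_state_segmentations` draws three correlated
  chromatin-state tracks whose three-cell-type combination coverages hit
  configured targets.
* :func:`simulate_contact_matrix` builds Poisson contact matrices with
  power-law distance decay, a flat inter-chromosomal background, planted
  long-range hub pairs and optional low-mappability patches.
* :func:`simulate_associated_regions` places a region set with a tunable
  enrichment rho inside an anchor set (rho = 0 is the independence
  null; a fraction rho/(1+rho) of regions is forced inside anchors).

All generators are pure functions of their configuration, seed
included: the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .genome import GenomeTable, GenomicInterval, RegionSet, write_genome_table, write_region_set
from .states import StateSegmentation, write_segmentation
from .synteny import (
    AncestralKaryotype,
    SyntenicFragment,
    SyntenicFragmentMap,
    karyotype_from_map,
    write_fragment_map,
)

__all__ = [
    "RearrangementConfig",
    "PlantedEvent",
    "RearrangementSimulation",
    "simulate_rearrangement_history",
    "score_ebr_recovery",
    "StateSimConfig",
    "StateSimulation",
    "simulate_state_segmentations",
    "HubPair",
    "ContactSimConfig",
    "ContactSimulation",
    "simulate_contact_matrix",
    "RegionSimConfig",
    "RegionSimulation",
    "simulate_associated_regions",
]


# ===========================================================================
# rearrangement histories
# ===========================================================================

_MB = 1_000_000


@dataclass
class RearrangementConfig:
    """A chain phylogeny with per-branch planted events.

    ``lineages`` are the reconstructed ancestors ordered root -> recent;
    the reference leaf descends from the last of them.  Branches are
    keyed by their child (the next lineage, or ``reference_name`` for
    the terminal branch).  In clean mode every breakpoint keeps
    ``min_event_spacing`` bp from all previous breakpoints and
    chromosome ends, inversion spans within one branch never overlap,
    and an inversion never spans a junction created earlier on the same
    branch — together these guarantee that every planted event leaves
    its own detectable footprint.
    """

    seed: int = 0
    root_chromosomes: dict[str, int] = field(
        default_factory=lambda: {"R1": 60 * _MB, "R2": 50 * _MB, "R3": 45 * _MB, "R4": 40 * _MB}
    )
    lineages: tuple[str, ...] = ("anc1", "anc2", "anc3")
    reference_name: str = "reference"
    events_per_branch: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "anc2": {"inversions": 1, "fusions": 1, "fissions": 0},
            "anc3": {"inversions": 1, "fusions": 0, "fissions": 1},
            "reference": {"inversions": 1, "fusions": 0, "fissions": 0},
        }
    )
    branch_times: dict[str, float] = field(
        default_factory=lambda: {"anc2": 8.0, "anc3": 6.0, "reference": 10.0}
    )
    resolution: int = 300_000
    edge_gap: int = 40_000  # bp removed around each fragment junction (coverage gap)
    min_event_spacing: int = 1_000_000
    clean: bool = True

    @property
    def chain(self) -> list[str]:
        return list(self.lineages) + [self.reference_name]


@dataclass
class PlantedEvent:
    branch: str  # child lineage of the branch the event occurred on
    kind: str  # 'inversion' | 'fusion' | 'fission'
    cuts: list[tuple[str, int]]  # root-coordinate cut positions
    junction: frozenset | None = None  # fusion: the two joined root edges
    ref_loci: list[tuple[str, int]] = field(default_factory=list)


# a genome is a list of chromosomes; a chromosome is a list of signed
# root segments (root_chrom, root_start, root_end, sign)
_Seg = tuple[str, int, int, int]


def _chrom_len(segs: list[_Seg]) -> int:
    return sum(e - s for _, s, e, _ in segs)


def _root_pos(segs: list[_Seg], pos: int) -> tuple[str, int]:
    """Root coordinate of a cut at chromosome coordinate ``pos``."""
    off = 0
    for rchr, rs, re_, sign in segs:
        ln = re_ - rs
        if pos <= off + ln:
            within = pos - off
            return (rchr, rs + within) if sign == 1 else (rchr, re_ - within)
        off += ln
    raise AssertionError("cut position beyond chromosome")


def _split(segs: list[_Seg], pos: int) -> tuple[list[_Seg], list[_Seg]]:
    left: list[_Seg] = []
    right: list[_Seg] = []
    off = 0
    for seg in segs:
        rchr, rs, re_, sign = seg
        ln = re_ - rs
        if off + ln <= pos:
            left.append(seg)
        elif off >= pos:
            right.append(seg)
        else:
            w = pos - off
            if sign == 1:
                left.append((rchr, rs, rs + w, 1))
                right.append((rchr, rs + w, re_, 1))
            else:
                left.append((rchr, re_ - w, re_, -1))
                right.append((rchr, rs, re_ - w, -1))
        off += ln
    return left, right


def _invert(segs: list[_Seg], a: int, b: int) -> list[_Seg]:
    left, rest = _split(segs, a)
    mid, right = _split(rest, b - a)
    mid = [(rchr, rs, re_, -sign) for rchr, rs, re_, sign in reversed(mid)]
    return left + mid + right


def _right_edge(seg: _Seg) -> tuple[str, int]:
    rchr, rs, re_, sign = seg
    return (rchr, re_) if sign == 1 else (rchr, rs)


def _left_edge(seg: _Seg) -> tuple[str, int]:
    rchr, rs, re_, sign = seg
    return (rchr, rs) if sign == 1 else (rchr, re_)


@dataclass
class RearrangementSimulation:
    """Everything downstream stages need: reference genome, per-ancestor
    fragment maps (root -> recent), karyotypes, and the planted truth."""

    config: RearrangementConfig
    reference: GenomeTable
    maps: list[SyntenicFragmentMap]
    events: list[PlantedEvent]

    @property
    def chain(self) -> list[str]:
        return self.config.chain

    @property
    def branch_event_counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for e in self.events:
            d = out.setdefault(e.branch, {"inversions": 0, "fusions": 0, "fissions": 0})
            d[e.kind + "s"] += 1
        return out

    def karyotypes(self) -> dict[str, AncestralKaryotype]:
        ks = {m.lineage: karyotype_from_map(m) for m in self.maps}
        ident = SyntenicFragmentMap(
            self.config.reference_name,
            [
                SyntenicFragment(GenomicInterval(c, 0, self.reference.length(c)), c, 0,
                                 self.reference.length(c), "+")
                for c in self.reference.names
            ],
            self.reference,
            self.config.resolution,
        )
        ks[self.config.reference_name] = karyotype_from_map(ident)
        return ks

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome_table(self.reference, outdir / "genome.tsv")
        for m in self.maps:
            write_fragment_map(m, outdir / f"map_{m.lineage}.tsv")
        truth = [
            dict(branch=e.branch, kind=e.kind, cuts=e.cuts, ref_loci=e.ref_loci)
            for e in self.events
        ]
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def simulate_rearrangement_history(cfg: RearrangementConfig) -> RearrangementSimulation:
    """Evolve the root genome down the chain and express every ancestor as
    a fragment map on the final reference.

    See :class:`RearrangementConfig` for the clean-mode guarantees.
    Raises when a branch demands more events than admissible breakpoints
    remain.
    """
    rng = np.random.default_rng(cfg.seed)
    spacing = cfg.min_event_spacing
    genome: list[list[_Seg]] = [[(c, 0, ln, 1)] for c, ln in cfg.root_chromosomes.items()]
    used: set[tuple[str, int]] = set()
    for c, ln in cfg.root_chromosomes.items():
        used.add((c, 0))
        used.add((c, ln))

    def admissible(rp: tuple[str, int]) -> bool:
        if not cfg.clean:
            return all(p != rp for p in used)
        return all(c != rp[0] or abs(p - rp[1]) >= spacing for c, p in used)

    def sample_cut(segs: list[_Seg], lo: int, hi: int, attempts: int = 2000) -> int | None:
        for _ in range(attempts):
            pos = int(rng.integers(lo, hi))
            if admissible(_root_pos(segs, pos)):
                return pos
        return None

    snapshots: dict[str, list[list[_Seg]]] = {cfg.lineages[0]: [list(c) for c in genome]}
    events: list[PlantedEvent] = []

    for child in cfg.chain[1:]:
        spec = cfg.events_per_branch.get(child, {})
        branch_junctions: set[frozenset] = set()
        inv_spans: dict[int, list[tuple[int, int]]] = {}

        for _ in range(spec.get("fissions", 0)):
            cands = [i for i, c in enumerate(genome) if _chrom_len(c) >= 2 * spacing]
            pos = None
            rng.shuffle(cands)
            for i in cands:
                pos = sample_cut(genome[i], spacing, _chrom_len(genome[i]) - spacing + 1)
                if pos is not None:
                    break
            if pos is None:
                raise ValidationError(f"branch {child}: no admissible fission breakpoint")
            rp = _root_pos(genome[i], pos)
            used.add(rp)
            left, right = _split(genome[i], pos)
            genome[i] = left
            genome.append(right)
            events.append(PlantedEvent(child, "fission", [rp]))

        for _ in range(spec.get("fusions", 0)):
            if len(genome) < 2:
                raise ValidationError(f"branch {child}: fusion needs two chromosomes")
            order = list(range(len(genome)))
            rng.shuffle(order)
            done = False
            for i, j in [(a, b) for a in order for b in order if a != b]:
                e1, e2 = _right_edge(genome[i][-1]), _left_edge(genome[j][0])
                if e1[0] == e2[0] and e1[1] == e2[1]:
                    continue  # would silently restore a root adjacency
                junction = frozenset([e1, e2])
                genome[i] = genome[i] + genome[j]
                del genome[j]
                branch_junctions.add(junction)
                events.append(PlantedEvent(child, "fusion", [], junction))
                done = True
                break
            if not done:
                raise ValidationError(f"branch {child}: no admissible fusion")

        for _ in range(spec.get("inversions", 0)):
            cands = [i for i, c in enumerate(genome) if _chrom_len(c) >= 3 * spacing]
            rng.shuffle(cands)
            placed = False
            for i in cands:
                ln = _chrom_len(genome[i])
                for _ in range(2000):
                    a = int(rng.integers(spacing, ln - 2 * spacing + 1))
                    b = int(rng.integers(a + spacing, ln - spacing + 1))
                    if any(not (b <= s or e <= a) for s, e in inv_spans.get(i, [])):
                        continue
                    ra, rb = _root_pos(genome[i], a), _root_pos(genome[i], b)
                    if not (admissible(ra) and admissible(rb)):
                        continue
                    # never span a junction created earlier on this branch
                    off, spans_new = 0, False
                    for s1, s2 in zip(genome[i], genome[i][1:]):
                        off += s1[2] - s1[1]
                        if a < off < b and frozenset(
                            [_right_edge(s1), _left_edge(s2)]
                        ) in branch_junctions:
                            spans_new = True
                            break
                    if spans_new:
                        continue
                    used.update([ra, rb])
                    inv_spans.setdefault(i, []).append((a, b))
                    genome[i] = _invert(genome[i], a, b)
                    events.append(PlantedEvent(child, "inversion", [ra, rb]))
                    placed = True
                    break
                if placed:
                    break
            if not placed:
                raise ValidationError(f"branch {child}: no admissible inversion")

        if child != cfg.reference_name:
            snapshots[child] = [list(c) for c in genome]

    # --- the leaf genome becomes the reference coordinate system
    order = sorted(range(len(genome)), key=lambda i: -_chrom_len(genome[i]))
    leaf = [genome[i] for i in order]
    ref_names = [f"chr{i + 1}" for i in range(len(leaf))]
    reference = GenomeTable(tuple((n, _chrom_len(c)) for n, c in zip(ref_names, leaf)))

    # reference layout of every leaf segment, per root chromosome
    leaf_index: dict[str, list[tuple[int, int, str, int, int]]] = {}
    # root chrom -> [(root_start, root_end, ref_chrom, ref_start, sign)]
    for name, segs in zip(ref_names, leaf):
        off = 0
        for rchr, rs, re_, sign in segs:
            leaf_index.setdefault(rchr, []).append((rs, re_, name, off, sign))
            off += re_ - rs
    for lst in leaf_index.values():
        lst.sort()

    # resolve planted breakpoints to reference coordinates via the leaf
    # boundary table (internal junctions and chromosome termini)
    boundary: list[tuple[str, int, tuple | None, tuple | None]] = []
    for name, segs in zip(ref_names, leaf):
        off = 0
        prev = None
        for k, seg in enumerate(segs):
            boundary.append((name, off, prev, _left_edge(seg)))
            off += seg[2] - seg[1]
            prev = _right_edge(seg)
        boundary.append((name, off, prev, None))
    for ev in events:
        loci: list[tuple[str, int]] = []
        if ev.kind == "fusion":
            for name, pos, le, re_ in boundary:
                if le is not None and re_ is not None and frozenset([le, re_]) == ev.junction:
                    loci.append((name, pos))
        else:
            for cut in ev.cuts:
                for name, pos, le, re_ in boundary:
                    if le == cut or re_ == cut:
                        loci.append((name, pos))
        ev.ref_loci = sorted(set(loci))

    # --- express each ancestor on the reference
    trim = cfg.edge_gap // 2
    maps: list[SyntenicFragmentMap] = []
    for lineage in cfg.lineages:
        node = snapshots[lineage]
        raw: list[SyntenicFragment] = []
        for ci, segs in enumerate(node):
            anc_name = f"{lineage}.{ci + 1}"
            off = 0
            for rchr, rs, re_, nsign in segs:
                for lrs, lre, ref_chrom, ref_off, lsign in leaf_index.get(rchr, []):
                    lo, hi = max(rs, lrs), min(re_, lre)
                    if lo >= hi:
                        continue
                    if lsign == 1:
                        ref_lo, ref_hi = ref_off + (lo - lrs), ref_off + (hi - lrs)
                    else:
                        ref_lo, ref_hi = ref_off + (lre - hi), ref_off + (lre - lo)
                    if nsign == 1:
                        anc_lo, anc_hi = off + (lo - rs), off + (hi - rs)
                    else:
                        anc_lo, anc_hi = off + (re_ - hi), off + (re_ - lo)
                    raw.append(
                        SyntenicFragment(
                            GenomicInterval(ref_chrom, ref_lo, ref_hi),
                            anc_name, anc_lo, anc_hi,
                            "+" if lsign == nsign else "-",
                            anc_name,
                        )
                    )
                off += re_ - rs
        # merge exactly collinear neighbours, then trim fragment edges to
        # leave the coverage gaps real reconstructions show at breakpoints
        from .synteny import _collinear_blocks  # shared reduction

        tmp = SyntenicFragmentMap(lineage, raw, reference, cfg.resolution)
        frags = []
        for chrom, blocks in _collinear_blocks(tmp, 0).items():
            for b in blocks:
                if b.ref_end - b.ref_start <= 2 * trim + 1:
                    continue
                frags.append(
                    SyntenicFragment(
                        GenomicInterval(chrom, b.ref_start + trim, b.ref_end - trim),
                        b.anc_chrom, b.anc_start + trim, b.anc_end - trim,
                        b.orientation, b.anc_chrom,
                    )
                )
        maps.append(SyntenicFragmentMap(lineage, frags, reference, cfg.resolution))

    return RearrangementSimulation(cfg, reference, maps, events)


def score_ebr_recovery(ebrs, sim: RearrangementSimulation, tol: int | None = None):
    """Recall/precision of detected EBRs against planted breakpoints.

    An event is recovered when one of its reference loci falls inside a
    detected EBR (within ``tol`` bp, default the configured edge gap); a
    detected EBR is a true positive when it contains some planted locus.
    Returns (recall, precision, per-event branch-correctness fraction).
    """
    tol = sim.config.edge_gap if tol is None else tol

    def contains(e, locus):
        c, p = locus
        return e.interval.chrom == c and e.interval.start - tol <= p <= e.interval.end + tol

    hit, branch_ok = 0, 0
    for ev in sim.events:
        matches = [e for e in ebrs if any(contains(e, l) for l in ev.ref_loci)]
        if matches:
            hit += 1
            if any(e.lineage == ev.branch for e in matches):
                branch_ok += 1
    recall = hit / len(sim.events) if sim.events else 1.0
    branch_frac = branch_ok / len(sim.events) if sim.events else 1.0
    tp = sum(
        1 for e in ebrs
        if any(any(contains(e, l) for l in ev.ref_loci) for ev in sim.events)
    )
    precision = tp / len(ebrs) if ebrs else 1.0
    return recall, precision, branch_frac


# ===========================================================================
# chromatin-state tracks
# ===========================================================================


@dataclass
class StateSimConfig:
    """Three correlated segmentations with designed triplet coverages.

    ``combo_design`` maps post-background-merge triplet labels (e.g.
    ``"E0-E0-E2"``) to target genome-coverage fractions; remaining mass
    is the all-background triplet.  Emitted tracks carry raw labels: a
    cell whose triplet component is E0 receives one of the raw
    background states at random, so the background-merge step is
    exercised downstream.  Segment lengths are geometric with mean
    ``mean_segment_bins`` bins.
    """

    seed: int = 0
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    bin_size: int = 200
    mean_segment_bins: float = 25.0
    combo_design: dict[str, float] = field(
        default_factory=lambda: {"E0-E0-E2": 0.20, "E2-E2-E2": 0.05, "E0-E4-E4": 0.10}
    )
    background_states: tuple[str, ...] = ("E1", "E3", "E7")
    alphabet: tuple[str, ...] = ("E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8")
    cell_types: tuple[str, ...] = ("spermatogonia", "spermatocytes", "spermatids")
    missing_fraction: float = 0.0  # fraction of segments blanked in one random cell


@dataclass
class StateSimulation:
    config: StateSimConfig
    genome: GenomeTable
    segmentations: tuple[StateSegmentation, StateSegmentation, StateSegmentation]
    realized_coverage: dict[str, float]  # triplet -> realised genome fraction

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome_table(self.genome, outdir / "genome.tsv")
        for seg in self.segmentations:
            write_segmentation(seg, outdir / f"states_{seg.cell_type}.bed")
        (outdir / "truth.json").write_text(json.dumps(self.realized_coverage, indent=1))


def simulate_state_segmentations(cfg: StateSimConfig) -> StateSimulation:
    total_target = sum(cfg.combo_design.values())
    if total_target > 1:
        raise ValidationError(f"designed coverages sum to {total_target} > 1")
    rng = np.random.default_rng(cfg.seed)
    genome = GenomeTable.from_dict(cfg.chromosomes)
    background_triplet = "E0-E0-E0"
    labels = list(cfg.combo_design) + [background_triplet]
    probs = np.array(list(cfg.combo_design.values()) + [1 - total_target])

    per_cell: list[dict[str, np.ndarray]] = [dict(), dict(), dict()]
    alpha_index = {s: i for i, s in enumerate(cfg.alphabet)}
    bg_codes = np.array([alpha_index[s] for s in cfg.background_states])
    realized_bins: dict[str, int] = {lab: 0 for lab in labels}
    total_bins = 0
    for chrom, length in cfg.chromosomes.items():
        n = -(-length // cfg.bin_size)
        total_bins += n
        cells = [np.empty(n, dtype=np.int16) for _ in range(3)]
        pos = 0
        while pos < n:
            seg_len = min(n - pos, 1 + rng.geometric(1 / cfg.mean_segment_bins))
            triplet = labels[rng.choice(len(labels), p=probs)]
            parts = triplet.split("-")
            for ci, state in enumerate(parts):
                if state == "E0":
                    code = int(bg_codes[rng.integers(len(bg_codes))])
                else:
                    code = alpha_index[state]
                cells[ci][pos : pos + seg_len] = code
            realized_bins[triplet] += seg_len
            if cfg.missing_fraction > 0 and rng.random() < cfg.missing_fraction:
                cells[int(rng.integers(3))][pos : pos + seg_len] = -1
            pos += seg_len
        for ci in range(3):
            per_cell[ci][chrom] = cells[ci]

    segs = tuple(
        StateSegmentation(ct, genome, per_cell[ci], cfg.alphabet, cfg.bin_size)
        for ci, ct in enumerate(cfg.cell_types)
    )
    realized = {lab: realized_bins[lab] / total_bins for lab in labels}
    return StateSimulation(cfg, genome, segs, realized)


# ===========================================================================
# contact matrices
# ===========================================================================


@dataclass(frozen=True)
class HubPair:
    """A planted long-range contact hub between two loci."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int

    @property
    def kind(self) -> str:
        return "intra" if self.chrom_a == self.chrom_b else "inter"


@dataclass
class ContactSimConfig:
    """Poisson contact matrix: power-law decay within chromosomes, flat
    background between them, planted hubs, optional low-mappability
    patches.  In recoverable mode an intra hub closer than the caller's
    minimum distance is refused outright."""

    seed: int = 0
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 50 * _MB, "chr2": 40 * _MB, "chr3": 30 * _MB}
    )
    resolution: int = 50_000
    decay_exponent: float = 1.0
    depth: float = 50.0  # expected contacts at distance 0
    inter_background: float = 0.5
    hubs: tuple[HubPair, ...] = ()
    hub_delta: float = 250.0  # added expected value at a hub (>= 2x caller threshold)
    hub_size_bins: int = 3
    low_mappability_patches: tuple[tuple[str, int, int], ...] = ()
    min_hub_distance: int = 10_000_000
    recoverable: bool = True
    cell_type: str = "spermatids"


@dataclass
class ContactSimulation:
    config: ContactSimConfig
    genome: GenomeTable
    matrix: "object"  # ContactMatrix (imported lazily to avoid a cycle)
    mappability: "object"  # MappabilityTrack
    hub_anchors: list[tuple[GenomicInterval, GenomicInterval, str]]

    def write(self, outdir) -> None:
        from pathlib import Path

        from .hic import write_ginteractions

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome_table(self.genome, outdir / "genome.tsv")
        write_ginteractions(self.matrix, outdir / "contacts.ginteractions.tsv")
        res = self.config.resolution
        with open(outdir / "mappability.bedgraph", "w") as fh:
            i = 0
            for chrom in self.genome.names:
                for start in range(0, self.genome.length(chrom), res):
                    end = min(start + res, self.genome.length(chrom))
                    fh.write(f"{chrom}\t{start}\t{end}\t{self.mappability.values[i]:g}\n")
                    i += 1
        truth = [
            dict(kind=k, anchor_a=[a.chrom, a.start, a.end], anchor_b=[b.chrom, b.start, b.end])
            for a, b, k in self.hub_anchors
        ]
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def simulate_contact_matrix(cfg: ContactSimConfig) -> ContactSimulation:
    from .hic import ContactMatrix, MappabilityTrack  # local import: hic depends on synteny

    rng = np.random.default_rng(cfg.seed)
    genome = GenomeTable.from_dict(cfg.chromosomes)
    res = cfg.resolution
    nbins = {c: -(-genome.length(c) // res) for c in genome.names}
    offsets, off = {}, 0
    for c in genome.names:
        offsets[c] = off
        off += nbins[c]
    n = off

    mu = np.full((n, n), cfg.inter_background)
    for c in genome.names:
        k = nbins[c]
        d = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        sl = slice(offsets[c], offsets[c] + k)
        mu[sl, sl] = cfg.depth * (1.0 + d) ** (-cfg.decay_exponent)

    anchors: list[tuple[GenomicInterval, GenomicInterval, str]] = []
    half = cfg.hub_size_bins // 2
    for hub in cfg.hubs:
        if hub.kind == "intra" and cfg.recoverable:
            if abs(hub.pos_b - hub.pos_a) < cfg.min_hub_distance:
                raise ValidationError(
                    f"intra hub at {hub.chrom_a}:{hub.pos_a}-{hub.pos_b} closer than "
                    f"{cfg.min_hub_distance} bp: undetectable by design"
                )
        ia = offsets[hub.chrom_a] + hub.pos_a // res
        ib = offsets[hub.chrom_b] + hub.pos_b // res
        ra = slice(max(offsets[hub.chrom_a], ia - half),
                   min(offsets[hub.chrom_a] + nbins[hub.chrom_a], ia + half + 1))
        rb = slice(max(offsets[hub.chrom_b], ib - half),
                   min(offsets[hub.chrom_b] + nbins[hub.chrom_b], ib + half + 1))
        mu[ra, rb] += cfg.hub_delta
        mu[rb, ra] += cfg.hub_delta
        anchors.append(
            (
                GenomicInterval(hub.chrom_a, (ra.start - offsets[hub.chrom_a]) * res,
                                min((ra.stop - offsets[hub.chrom_a]) * res,
                                    genome.length(hub.chrom_a))),
                GenomicInterval(hub.chrom_b, (rb.start - offsets[hub.chrom_b]) * res,
                                min((rb.stop - offsets[hub.chrom_b]) * res,
                                    genome.length(hub.chrom_b))),
                hub.kind,
            )
        )

    iu = np.triu_indices(n)
    draws = rng.poisson(mu[iu]).astype(float)
    m = np.zeros((n, n))
    m[iu] = draws
    m.T[iu] = draws

    mapp = np.ones(n)
    for chrom, start, end in cfg.low_mappability_patches:
        b0 = offsets[chrom] + start // res
        b1 = offsets[chrom] + -(-end // res)
        mapp[b0:b1] = 0.3

    cm = ContactMatrix(genome, m, res, cfg.cell_type)
    track = MappabilityTrack(genome, res, mapp)
    return ContactSimulation(cfg, genome, cm, track, anchors)


# ===========================================================================
# associated region sets
# ===========================================================================


@dataclass
class RegionSimConfig:
    """Region sets with tunable enrichment in an anchor set.

    With enrichment ``rho``, each region is placed inside a uniformly
    chosen anchor with probability rho/(1+rho) and uniformly on the
    genome otherwise, so rho = 0 is exact independence and large rho
    concentrates the set in the anchors.
    """

    seed: int = 0
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 50 * _MB, "chr2": 50 * _MB, "chr3": 50 * _MB}
    )
    n_regions: int = 150
    length_range: tuple[int, int] = (10_000, 30_000)
    rho: float = 0.0
    name: str = "simulated"


@dataclass
class RegionSimulation:
    config: RegionSimConfig
    regions: RegionSet
    n_inside_anchors: int

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_region_set(self.regions, outdir / f"{self.config.name}.bed")
        (outdir / "truth.json").write_text(
            json.dumps(dict(rho=self.config.rho, n_inside=self.n_inside_anchors))
        )


def _uniform_place(rng: np.random.Generator, genome: GenomeTable, length: int):
    sizes = np.array([max(0, genome.length(c) - length + 1) for c in genome.names])
    total = sizes.sum()
    if total <= 0:
        raise ValidationError(f"no chromosome can host a {length} bp region")
    u = int(rng.integers(0, total))
    cum = np.cumsum(sizes)
    idx = int(np.searchsorted(cum, u, side="right"))
    start = u - (cum[idx - 1] if idx else 0)
    return genome.names[idx], int(start)


def simulate_associated_regions(
    cfg: RegionSimConfig, anchor: RegionSet | None = None
) -> RegionSimulation:
    rng = np.random.default_rng(cfg.seed)
    genome = anchor.genome if anchor is not None else GenomeTable.from_dict(cfg.chromosomes)
    p_inside = cfg.rho / (1 + cfg.rho)
    if p_inside > 0 and anchor is None:
        raise ValidationError("rho > 0 needs an anchor set")
    intervals = []
    n_inside = 0
    for i in range(cfg.n_regions):
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        if anchor is not None and rng.random() < p_inside:
            hosts = [iv for iv in anchor if len(iv) >= length]
            if not hosts:
                raise ValidationError(
                    f"no anchor can host a {length} bp region"
                )
            host = hosts[int(rng.integers(len(hosts)))]
            start = host.start + int(rng.integers(0, len(host) - length + 1))
            intervals.append(GenomicInterval(host.chrom, start, start + length))
            n_inside += 1
        else:
            chrom, start = _uniform_place(rng, genome, length)
            intervals.append(GenomicInterval(chrom, start, start + length))
    return RegionSimulation(cfg, RegionSet(cfg.name, intervals, genome), n_inside)
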
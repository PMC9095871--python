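"""Chromatin-state segmentations and three-cell-type state combinations.

Hidden-state genome segmentations (one per germ-cell type:
spermatogonia, primary spermatocytes, round spermatids) are
post-processed into a single track of ordered state triplets:

1. the dominant background states are relabelled to a joint ``E0``
   (:func:`relabel_background`),
2. the three tracks are combined bin-by-bin wherever all three carry a
   label, adjacent equal triplets merged (:func:`combine_states`),
3. triplets above a genome-coverage threshold are selected
   (:func:`select_frequent_combos`), and per-chromosome coverages
   tabulated (:func:`per_chromosome_combo_coverage`).

Segmentations are fixed-width binned tracks (default 200 bp); the
final bin of a chromosome may be short.  The state alphabet and the
identity of background states are configuration, not constants — they
depend on the segmentation model that produced the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .genome import GenomeTable, GenomicInterval

__all__ = [
    "DEFAULT_BACKGROUND",
    "StateSegmentation",
    "StateComboTrack",
    "read_segmentation",
    "write_segmentation",
    "relabel_background",
    "combine_states",
    "select_frequent_combos",
    "per_chromosome_combo_coverage",
]

DEFAULT_BIN_SIZE = 200
DEFAULT_BACKGROUND = frozenset({"E1", "E3", "E7"})
MISSING = -1


def _n_bins(length: int, bin_size: int) -> int:
    return -(-length // bin_size)


class StateSegmentation:
    """A fixed-bin chromatin-state track for one cell type.

    Stored per chromosome as an integer code array over ``alphabet``;
    ``-1`` marks bins without a state call.
    """

    def __init__(
        self,
        cell_type: str,
        genome: GenomeTable,
        codes: Mapping[str, np.ndarray],
        alphabet: Sequence[str],
        bin_size: int = DEFAULT_BIN_SIZE,
    ):
        self.cell_type = cell_type
        self.genome = genome
        self.bin_size = bin_size
        self.alphabet = list(alphabet)
        self.codes: dict[str, np.ndarray] = {}
        for chrom in genome.names:
            n = _n_bins(genome.length(chrom), bin_size)
            arr = codes.get(chrom)
            if arr is None:
                arr = np.full(n, MISSING, dtype=np.int16)
            arr = np.asarray(arr, dtype=np.int16)
            if len(arr) != n:
                raise ValidationError(
                    f"{chrom}: expected {n} bins at {bin_size} bp, got {len(arr)}"
                )
            self.codes[chrom] = arr

    @classmethod
    def from_intervals(
        cls,
        cell_type: str,
        genome: GenomeTable,
        intervals: Iterable[GenomicInterval],
        alphabet: Sequence[str] | None = None,
        bin_size: int = DEFAULT_BIN_SIZE,
    ) -> "StateSegmentation":
        """Rasterise labelled intervals onto the bin grid.  Interval
        boundaries must fall on bin edges (chromosome ends excepted)."""
        ivs = list(intervals)
        if alphabet is None:
            alphabet = sorted({iv.label for iv in ivs if iv.label})
        index = {lab: i for i, lab in enumerate(alphabet)}
        codes = {
            c: np.full(_n_bins(genome.length(c), bin_size), MISSING, dtype=np.int16)
            for c in genome.names
        }
        for iv in ivs:
            if iv.label not in index:
                raise ValidationError(f"state {iv.label!r} not in alphabet {list(alphabet)}")
            if iv.start % bin_size:
                raise ValidationError(
                    f"interval start {iv.start} not aligned to {bin_size} bp bins"
                )
            if iv.end % bin_size and iv.end != genome.length(iv.chrom):
                raise ValidationError(f"interval end {iv.end} not aligned to {bin_size} bp bins")
            codes[iv.chrom][iv.start // bin_size : _n_bins(iv.end, bin_size)] = index[iv.label]
        return cls(cell_type, genome, codes, alphabet, bin_size)

    def labelled_fraction(self) -> float:
        lab = sum(int((arr != MISSING).sum()) for arr in self.codes.values())
        total = sum(len(arr) for arr in self.codes.values())
        return lab / total

    def to_intervals(self) -> list[GenomicInterval]:
        """Run-length encode back to labelled intervals."""
        out = []
        for chrom in self.genome.names:
            arr = self.codes[chrom]
            length = self.genome.length(chrom)
            if not len(arr):
                continue
            edges = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], edges])
            ends = np.concatenate([edges, [len(arr)]])
            for s, e in zip(starts, ends):
                code = arr[s]
                if code == MISSING:
                    continue
                out.append(
                    GenomicInterval(
                        chrom,
                        int(s) * self.bin_size,
                        min(int(e) * self.bin_size, length),
                        self.alphabet[code],
                    )
                )
        return out


def read_segmentation(
    path,
    cell_type: str,
    genome: GenomeTable,
    alphabet: Sequence[str] | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> StateSegmentation:
    """Read a 4-column BED segmentation (chrom, start, end, state)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(path, lineno, f"expected 4 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            intervals.append(GenomicInterval(parts[0], start, end, parts[3]))
    return StateSegmentation.from_intervals(cell_type, genome, intervals, alphabet, bin_size)


def write_segmentation(seg: StateSegmentation, path) -> None:
    with open(path, "w") as fh:
        for iv in seg.to_intervals():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def relabel_background(
    seg: StateSegmentation,
    background: Iterable[str] = DEFAULT_BACKGROUND,
    joint_state: str = "E0",
) -> StateSegmentation:
    """Merge the dominant background states into one joint state.

    Every label in ``background`` becomes ``joint_state``; all other
    labels are unchanged.  Idempotent: relabelling twice equals once.
    """
    background = set(background)
    unknown = background - set(seg.alphabet) - {joint_state}
    if unknown and joint_state not in seg.alphabet:
        # already-merged alphabets lack the raw background states; that is
        # fine (idempotence), but a raw alphabet must know every label
        raise ValidationError(f"background states {sorted(unknown)} not in alphabet")
    new_alpha = [joint_state] + [s for s in seg.alphabet if s not in background and s != joint_state]
    remap = np.full(len(seg.alphabet) + 1, MISSING, dtype=np.int16)  # [-1] stays missing
    for i, lab in enumerate(seg.alphabet):
        remap[i] = 0 if lab in background or lab == joint_state else new_alpha.index(lab)
    codes = {c: remap[arr] for c, arr in seg.codes.items()}
    return StateSegmentation(seg.cell_type, seg.genome, codes, new_alpha, seg.bin_size)


@dataclass
class StateComboTrack:
    """Merged intervals labelled with an ordered per-cell-type state
    triplet, plus a genome-coverage table per triplet."""

    intervals: list[GenomicInterval]
    coverage: pd.Series  # triplet label -> genome fraction
    genome: GenomeTable
    cell_types: tuple[str, ...]
    bin_size: int
    labelled_denominator: bool = False

    @property
    def total_coverage(self) -> float:
        return float(self.coverage.sum())

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def combine_states(
    seg_a: StateSegmentation,
    seg_b: StateSegmentation,
    seg_c: StateSegmentation,
    labelled_denominator: bool = False,
) -> StateComboTrack:
    """Combine three segmentations into an ordered-triplet track.

    A bin contributes only where all three cell types carry a state;
    bins missing a state in any cell type are removed.  Adjacent bins
    with the same triplet are merged.  Coverage fractions are computed
    against the full genome length by default, or against the jointly
    labelled length with ``labelled_denominator=True``.
    """
    segs = (seg_a, seg_b, seg_c)
    for s in segs[1:]:
        if s.genome != seg_a.genome or s.bin_size != seg_a.bin_size:
            raise ValidationError("segmentations disagree on genome or bin grid")
    genome, bin_size = seg_a.genome, seg_a.bin_size

    intervals: list[GenomicInterval] = []
    covered_bp: dict[str, int] = {}
    labelled_bp = 0
    for chrom in genome.names:
        arrs = [s.codes[chrom] for s in segs]
        ok = (arrs[0] != MISSING) & (arrs[1] != MISSING) & (arrs[2] != MISSING)
        if not ok.any():
            continue
        length = genome.length(chrom)
        n = len(arrs[0])
        # run-length encode the triplet sequence, treating missing as a break
        key = np.where(ok, arrs[0].astype(np.int64) * 10_000**2
                       + arrs[1].astype(np.int64) * 10_000
                       + arrs[2].astype(np.int64), -1)
        edges = np.flatnonzero(np.diff(key)) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [n]])
        for s, e in zip(starts, ends):
            if key[s] < 0:
                continue
            bp = min(int(e) * bin_size, length) - int(s) * bin_size
            label = "-".join(seg.alphabet[seg.codes[chrom][s]] for seg in segs)
            intervals.append(
                GenomicInterval(chrom, int(s) * bin_size, min(int(e) * bin_size, length), label)
            )
            covered_bp[label] = covered_bp.get(label, 0) + bp
            labelled_bp += bp

    denom = labelled_bp if labelled_denominator else genome.total_length
    if denom == 0:
        raise ValidationError("empty denominator: no jointly labelled bins")
    coverage = pd.Series(covered_bp, dtype=float).sort_values(ascending=False) / denom
    return StateComboTrack(
        intervals, coverage, genome,
        tuple(s.cell_type for s in segs), bin_size, labelled_denominator,
    )


def select_frequent_combos(
    track: StateComboTrack,
    min_coverage: float = 0.001,
    always_keep: Iterable[str] = ("E6-E6-E6",),
) -> StateComboTrack:
    """Keep triplet combinations covering more than ``min_coverage`` of the
    genome; combinations in ``always_keep`` are retained regardless (by
    default the trivalent all-mark state)."""
    always_keep = set(always_keep)
    keep = {t for t, c in track.coverage.items() if c > min_coverage} | (
        always_keep & set(track.coverage.index)
    )
    return StateComboTrack(
        [iv for iv in track.intervals if iv.label in keep],
        track.coverage[track.coverage.index.isin(keep)],
        track.genome,
        track.cell_types,
        track.bin_size,
        track.labelled_denominator,
    )


def per_chromosome_combo_coverage(track: StateComboTrack) -> pd.DataFrame:
    """Coverage fraction of each triplet on each chromosome (rows:
    chromosomes in genome order; denominator: chromosome length)."""
    combos = list(track.coverage.index)
    out = pd.DataFrame(0.0, index=track.genome.names, columns=combos)
    for iv in track.intervals:
        if iv.label in out.columns:
            out.loc[iv.chrom, iv.label] += len(iv)
    lengths = pd.Series({c: track.genome.length(c) for c in track.genome.names})
    return out.div(lengths, axis=0)
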
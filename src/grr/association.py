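"""Permutation-based association between genomic region sets.

The test asks whether a query region set overlaps a target region set
more (or less) than expected if the query regions were placed at
random.  For each permutation, regions with the query's lengths are
placed uniformly at random on the genome (never crossing a chromosome
boundary, optionally avoiding a mask); the statistic is the number of
query regions overlapping at least one target region.  The observed
statistic is standardised against the permuted distribution,

    z = (obs - mean_perm) / sd_perm,

with an add-one empirical p-value, two-sided by doubling the smaller
tail.  For grids of many query and target sets
(:func:`multi_association`) the empirical p-values are
Benjamini-Hochberg adjusted over the whole grid, z-scores with adjusted
p above a threshold are zeroed, and the surviving z-scores are
normalised by sqrt(n_query) so that differently sized region sets are
comparable.

A base-pair variant (:func:`fold_enrichment_test`) uses overlapping
base pairs as the statistic and reports observed/expected fold
enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import GenomeMismatchError, ValidationError
from .genome import GenomeTable, GenomicInterval, RegionSet, complement, merge_intervals

__all__ = [
    "AssociationResult",
    "AssociationMatrix",
    "permutation_overlap_test",
    "fold_enrichment_test",
    "multi_association",
]


# ---------------------------------------------------------------------------
# placement machinery: linearised genome with per-length admissible space


class _Placer:
    """Uniform placement of fixed-length regions on a genome.

    Works on a linearised coordinate system over admissible intervals
    (whole chromosomes, or the complement of a mask).  With
    ``per_chromosome=True`` each region is re-placed uniformly on its own
    chromosome (bedtools-shuffle-with-chrom semantics); otherwise it may
    land anywhere (regioneR-style randomisation).
    """

    def __init__(self, genome: GenomeTable, mask: RegionSet | None = None,
                 per_chromosome: bool = False):
        self.genome = genome
        self.per_chromosome = per_chromosome
        if mask is None:
            spaces = [(c, 0, genome.length(c)) for c in genome.names]
        else:
            if mask.genome != genome:
                raise GenomeMismatchError("mask is on a different genome")
            spaces = [(iv.chrom, iv.start, iv.end) for iv in complement(mask)]
        self.spaces = spaces
        offsets, off = {}, 0
        for c in genome.names:
            offsets[c] = off
            off += genome.length(c)
        self.offsets = offsets
        self.total = off

    def linearise(self, chroms, starts):
        return np.asarray([self.offsets[c] for c in chroms]) + np.asarray(starts)

    def sample(self, rng: np.random.Generator, lengths: np.ndarray, n_perm: int,
               home_chroms: Sequence[str] | None = None) -> np.ndarray:
        """(n_perm, n) linearised start positions for regions of the given
        lengths; ``home_chroms`` pins each region to its chromosome."""
        n = len(lengths)
        out = np.empty((n_perm, n), dtype=np.int64)
        for i, ell in enumerate(lengths):
            if self.per_chromosome:
                spaces = [s for s in self.spaces if s[0] == home_chroms[i]]
            else:
                spaces = self.spaces
            sizes = np.array([max(0, e - s - ell + 1) for _, s, e in spaces], dtype=np.int64)
            total = int(sizes.sum())
            if total <= 0:
                raise ValidationError(
                    f"no admissible placement for a region of {ell} bp"
                )
            cum = np.concatenate([[0], np.cumsum(sizes)])
            u = rng.integers(0, total, size=n_perm)
            j = np.searchsorted(cum, u, side="right") - 1
            local = u - cum[j]
            lin = np.array(
                [self.offsets[spaces[k][0]] + spaces[k][1] for k in range(len(spaces))],
                dtype=np.int64,
            )
            out[:, i] = lin[j] + local
        return out


def _target_arrays(target: RegionSet, placer: _Placer):
    """Linearised, merged target intervals plus cumulative covered bp."""
    merged = merge_intervals(target)
    ts = placer.linearise([iv.chrom for iv in merged], [iv.start for iv in merged])
    te = placer.linearise([iv.chrom for iv in merged], [iv.end for iv in merged])
    cum = np.concatenate([[0], np.cumsum(te - ts)])
    return ts, te, cum


def _count_hits(starts: np.ndarray, lengths: np.ndarray, ts, te) -> np.ndarray:
    """Per-row count of regions overlapping >=1 merged target interval."""
    ends = starts + lengths
    idx = np.searchsorted(ts, ends, side="left")
    hit = (idx > 0) & (te[np.maximum(idx - 1, 0)] > starts)
    return hit.sum(axis=-1)


def _covered_bp(x: np.ndarray, ts, te, cum) -> np.ndarray:
    """Total target-covered bp in [0, x) of the linearised genome."""
    j = np.searchsorted(ts, x, side="right") - 1
    res = np.where(j >= 0, cum[np.maximum(j, 0)], 0).astype(np.int64)
    inside = np.clip(x - ts[np.maximum(j, 0)], 0, (te - ts)[np.maximum(j, 0)])
    return res + np.where(j >= 0, inside, 0)


def _overlap_bp(starts: np.ndarray, lengths: np.ndarray, ts, te, cum) -> np.ndarray:
    return (_covered_bp(starts + lengths, ts, te, cum) - _covered_bp(starts, ts, te, cum)).sum(
        axis=-1
    )


# ---------------------------------------------------------------------------
# results


@dataclass
class AssociationResult:
    """Outcome of one permutation overlap test."""

    observed: float
    perm_mean: float
    perm_sd: float
    z: float
    p: float
    n_query: int
    n_perm: int
    seed: int
    statistic: str = "n_overlapping_regions"
    fold_enrichment: float | None = None
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate and not (0 < self.p <= 1):
            raise ValidationError(f"empirical p out of range: {self.p}")


@dataclass
class AssociationMatrix:
    """Query x target grid of permutation-test outcomes.

    ``z`` holds zeroed z-scores (zero wherever the BH-adjusted p exceeds
    the threshold), ``z_raw`` the unthresholded values, and
    ``normalized_z`` the zeroed z divided by sqrt(n_query).
    """

    z: pd.DataFrame
    z_raw: pd.DataFrame
    normalized_z: pd.DataFrame
    p: pd.DataFrame
    adjusted_p: pd.DataFrame
    n_query: pd.Series
    n_perm: int
    seed: int
    zero_threshold: float

    def to_long(self) -> pd.DataFrame:
        rows = []
        for q in self.z.index:
            for t in self.z.columns:
                rows.append(
                    dict(query=q, target=t, z=self.z.loc[q, t], z_raw=self.z_raw.loc[q, t],
                         normalized_z=self.normalized_z.loc[q, t], p=self.p.loc[q, t],
                         adjusted_p=self.adjusted_p.loc[q, t], n_query=self.n_query[q],
                         n_perm=self.n_perm, seed=self.seed)
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path, wide: bool = False) -> None:
        if wide:
            self.normalized_z.to_csv(path, sep="\t", index_label="query")
        else:
            self.to_long().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tests


def _empirical_p(perm: np.ndarray, obs: float, n_perm: int) -> float:
    p_hi = (1 + int((perm >= obs).sum())) / (n_perm + 1)
    p_lo = (1 + int((perm <= obs).sum())) / (n_perm + 1)
    return min(1.0, 2 * min(p_hi, p_lo))


def permutation_overlap_test(
    query: RegionSet,
    target: RegionSet,
    genome: GenomeTable | None = None,
    mask: RegionSet | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    per_chromosome: bool = False,
) -> AssociationResult:
    """Permutation test of region-count overlap between two region sets.

    The statistic counts query regions overlapping at least one target
    region.  ``n_perm`` length-preserving random placements build the
    null; p is add-one empirical, two-sided by doubling the smaller
    tail.  A zero permuted standard deviation flags the result as
    degenerate (z undefined).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if len(query) == 0:
        raise ValidationError("query region set is empty")
    genome = genome or query.genome
    if target.genome != genome or query.genome != genome:
        raise GenomeMismatchError("query/target not on the given genome")

    placer = _Placer(genome, mask, per_chromosome)
    ts, te, cum = _target_arrays(target, placer)
    lengths = np.array([len(iv) for iv in query], dtype=np.int64)
    obs_starts = placer.linearise([iv.chrom for iv in query], [iv.start for iv in query])
    obs = int(_count_hits(obs_starts, lengths, ts, te))

    rng = np.random.default_rng(seed)
    perm_starts = placer.sample(rng, lengths, n_perm, [iv.chrom for iv in query])
    perm = _count_hits(perm_starts, lengths, ts, te)

    mean, sd = float(perm.mean()), float(perm.std(ddof=1))
    degenerate = sd == 0
    z = float("nan") if degenerate else (obs - mean) / sd
    p = _empirical_p(perm, obs, n_perm)
    return AssociationResult(obs, mean, sd, z, p, len(query), n_perm, seed,
                             degenerate=degenerate)


def fold_enrichment_test(
    query: RegionSet,
    target: RegionSet,
    genome: GenomeTable | None = None,
    mask: RegionSet | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    per_chromosome: bool = False,
) -> AssociationResult:
    """Permutation test on overlapping base pairs, reporting fold
    enrichment = observed bp / mean permuted bp."""
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if len(query) == 0:
        raise ValidationError("query region set is empty")
    genome = genome or query.genome
    if target.genome != genome or query.genome != genome:
        raise GenomeMismatchError("query/target not on the given genome")

    placer = _Placer(genome, mask, per_chromosome)
    ts, te, cum = _target_arrays(target, placer)
    lengths = np.array([len(iv) for iv in query], dtype=np.int64)
    obs_starts = placer.linearise([iv.chrom for iv in query], [iv.start for iv in query])
    obs = int(_overlap_bp(obs_starts, lengths, ts, te, cum))

    rng = np.random.default_rng(seed)
    perm_starts = placer.sample(rng, lengths, n_perm, [iv.chrom for iv in query])
    perm = _overlap_bp(perm_starts, lengths, ts, te, cum)

    mean, sd = float(perm.mean()), float(perm.std(ddof=1))
    degenerate = sd == 0 or mean == 0
    z = float("nan") if sd == 0 else (obs - mean) / sd
    fold = None if mean == 0 else obs / mean
    p = _empirical_p(perm, obs, n_perm)
    return AssociationResult(obs, mean, sd, z, p, len(query), n_perm, seed,
                             statistic="overlap_bp", fold_enrichment=fold,
                             degenerate=degenerate)


def multi_association(
    queries: Sequence[RegionSet],
    targets: Sequence[RegionSet],
    genome: GenomeTable | None = None,
    mask: RegionSet | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    zero_threshold: float = 0.005,
    per_chromosome: bool = False,
) -> AssociationMatrix:
    """Grid of permutation overlap tests with BH adjustment and z
    normalisation.

    Empirical p-values are Benjamini-Hochberg adjusted over the full
    grid; wherever the adjusted p exceeds ``zero_threshold`` the z-score
    is set to 0, and the surviving z is divided by sqrt(n_query).
    Degenerate cells (zero permuted sd) are excluded from the BH family
    with a warning and reported as NaN.  Placements are generated once
    per query and reused across targets, so the whole matrix is a
    deterministic function of ``seed``.
    """
    if not queries or not targets:
        raise ValidationError("need at least one query and one target set")
    genome = genome or queries[0].genome
    for rs in list(queries) + list(targets):
        if rs.genome != genome:
            raise GenomeMismatchError(f"region set {rs.name!r} not on the shared genome")

    placer = _Placer(genome, mask, per_chromosome)
    tarrays = [_target_arrays(t, placer) for t in targets]
    qnames = [q.name for q in queries]
    tnames = [t.name for t in targets]

    z_raw = pd.DataFrame(np.nan, index=qnames, columns=tnames)
    pvals = pd.DataFrame(np.nan, index=qnames, columns=tnames)
    rng = np.random.default_rng(seed)
    for q in queries:
        lengths = np.array([len(iv) for iv in q], dtype=np.int64)
        obs_starts = placer.linearise([iv.chrom for iv in q], [iv.start for iv in q])
        perm_starts = placer.sample(rng, lengths, n_perm, [iv.chrom for iv in q])
        for tname, (ts, te, cum) in zip(tnames, tarrays):
            obs = int(_count_hits(obs_starts, lengths, ts, te))
            perm = _count_hits(perm_starts, lengths, ts, te)
            mean, sd = float(perm.mean()), float(perm.std(ddof=1))
            if sd == 0:
                warnings.warn(
                    f"degenerate cell ({q.name!r}, {tname!r}): zero permuted sd; "
                    "excluded from BH family", stacklevel=2,
                )
                continue
            z_raw.loc[q.name, tname] = (obs - mean) / sd
            pvals.loc[q.name, tname] = _empirical_p(perm, obs, n_perm)

    flat = pvals.to_numpy().ravel()
    ok = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    adjusted = pd.DataFrame(adj.reshape(pvals.shape), index=qnames, columns=tnames)

    z = z_raw.where(adjusted <= zero_threshold, 0.0).where(~z_raw.isna(), np.nan)
    n_query = pd.Series({q.name: len(q) for q in queries})
    normalized = z.div(np.sqrt(n_query), axis=0)
    return AssociationMatrix(z, z_raw, normalized, pvals, adjusted, n_query,
                             n_perm, seed, zero_threshold)
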
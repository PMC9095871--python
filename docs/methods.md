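# Methods

This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, what the
synthetic generators emulate, and the limits of what the test suite
demonstrates.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention); readers for
1-based formats convert at the boundary.  Region sets are strandless —
in this pipeline orientation matters only for syntenic fragments,
which carry it explicitly.  Intervals are always sorted by (chromosome
order in the genome table, start, end, label), so every downstream
computation is deterministic regardless of input order.  Merge,
intersection and coverage are implemented directly on sorted integer
arrays; they are validated in the test suite against per-base boolean
masks and a union-find oracle.

## Ancestral karyotypes and EBR detection

**Inputs.** Per-ancestor syntenic fragment maps on a reference genome:
9-column TSV (ref_chr, ref_start, ref_end, lineage, anc_chr,
anc_start, anc_end, orientation, racf_id).  Orientation is `+` when
reference and ancestral coordinates increase together.  The ancestors
form a chain ordered root → recent, ending at the reference leaf;
that is the shape of the phylogeny the analysis consumes (each map is
expressed against the same reference).

**RACF curation.** Reconstruction tools over-fragment ancestral
chromosomes, and the original curation of such fragments is typically
manual.  Here it is a deterministic rule: two RACFs are joined iff
terminal fragments of theirs are adjacent on the reference (gap ≤
`max_join_gap`, default 500 kbp — chosen to tolerate the 300 kbp
fragment resolution) with consistent orientation, and at least one
guide shows the junction as collinear.  The reference itself is a
guide (collinear = equal orientations); a closer-ancestor map is a
guide when one of its fragments spans the junction.  A RACF end with
two admissible joins is a conflict: both joins are refused and
logged.  RACFs are classified as chromosomes when their summed
fragment length is ≥ 26 Mbp (boundary inclusive), the conserved
lower bound of mammalian chromosome size; smaller RACFs are unplaced.

**EBR detection.** Within each map, reference-consecutive fragments
that are collinear and ancestrally adjacent (ancestral gap equal to
the reference gap within a slack, default the map resolution) are
merged into blocks.  Breakpoint candidates are then emitted at

* junctions between consecutive blocks — typed `inversion` when both
  sides map to one ancestral chromosome, `inter_chromosomal`
  otherwise; and
* reference chromosome termini whose terminal block's ancestral
  chromosome demonstrably continues beyond the terminus (the
  signature of a fission).

Each candidate records which ancestral adjacencies it breaks
(ancestral chromosome + coordinate).  One physical fission leaves its
broken adjacency visible at up to two reference loci (two termini, or
a terminus plus a later fusion junction); candidates sharing a broken
adjacency are collapsed to one EBR, preferring real junctions over
termini.  Junction candidates are never collapsed with one another —
an inversion's two flanks are two EBRs, which is also why a lineage
can report more inversion EBRs than inversions.

A disruption that arose on the branch X → Y is visible in the map of
X and every older ancestor, and absent from Y onwards.  Candidates
overlapping across maps are therefore clustered, reduced to their
common intersection, and assigned to the lineage one step more recent
than the youngest map showing the disruption (the terminal reference
branch when the disruption is visible in every map).  Age
classification relative to a named split S partitions branches into
`ancestral` (strictly older than S), `recent` (S up to the last
internal branch) and `reference_specific` (the terminal branch); the
partition is exhaustive and disjoint by construction.

**Rearrangement counting.** Each child chromosome is rendered as a
signed sequence of parent blocks by composing both karyotypes through
the shared reference coordinates and merging parent-adjacent pieces
of equal sign.  Fusions are junctions joining two distinct parent
chromosomes; a parent chromosome split over k > 1 child chromosomes
contributes k − 1 fissions; inversions are maximal negative-sign runs
internal to one parent chromosome, with the whole-chromosome
orientation (which is arbitrary) chosen to minimise the count.  A
child chromosome consisting of one whole parent chromosome of uniform
sign is conserved.  This parsimony reading is exact for histories of
non-overlapping events; heavily overlapping inversions on one branch
can be under-counted, which is why the clean-mode generator keeps
same-branch inversion spans disjoint.

**Rates.** Per-branch rate = EBR count / branch time (My).  The
global average divides total EBRs by total time; because the root
branch of a published tree may carry counts without a tabulated time,
`compute_rates` accepts an explicit total tree depth for the average
(the bundled rodent table uses 73 My).  Rate homogeneity is tested by
χ² goodness-of-fit of observed per-branch counts against expectations
proportional to branch time (df = branches − 1); per-branch
standardised residuals identify the branches in excess.  The paper
states only "χ² test" for the excess of the fastest branch; the
goodness-of-fit with residuals is the minimal formulation matching a
statement that one branch exceeds the average.

**msHSBs and syntenic associations.** Multispecies homologous
syntenic blocks are maximal reference intervals lying within a single
collinear block of every map (pairwise interval intersection across
maps), filtered to ≥ 300 kbp by default — the reconstruction
resolution, as no explicit minimum is published.  msHSBs and EBRs are
disjoint by construction.  A syntenic association is an ancestral
chromosome whose fragments (each ≥ a support threshold) land on two
or more reference chromosomes; one association per unordered
chromosome pair.

## Chromatin-state combinations

Segmentations are fixed-bin tracks (default 200 bp).  The dominant
background states (configurable, default {E1, E3, E7}) are merged
into a joint E0; the operation is idempotent.  Three cell-type tracks
are combined bin-wise into ordered triplets only where all three
carry a label; bins missing a state in any cell type are removed, and
adjacent equal triplets merge.  Coverage fractions are computed
against the full genome length by default (a flag switches to the
jointly-labelled length; the published phrasing does not disambiguate
the denominator, and full-genome matches the spirit of "genomic
coverage").  Frequent-combination selection keeps triplets above 0.1%
coverage plus an always-keep set (default the trivalent E6-E6-E6,
which is biologically interesting at any coverage).

## Permutation association

The statistic is the number of query regions overlapping ≥ 1 target
region (region-count semantics; a base-pair variant reports fold
enrichment = observed bp / mean permuted bp).  Each permutation
places length-preserved regions uniformly at random — anywhere on the
genome by default, never crossing a chromosome boundary, optionally
avoiding a mask; a per-chromosome mode reproduces shuffle-with-
chromosome semantics.  z = (obs − mean)/sd of the permuted values
(sd with one delta degree of freedom); the empirical p is add-one
((1 + more-extreme)/(n+1)) and two-sided by doubling the smaller
tail, capped at 1 — so p = 0 is impossible and the test is valid at
finite permutation counts.  Zero permuted sd flags the cell as
degenerate.

For query×target grids, p-values are Benjamini–Hochberg adjusted over
the whole matrix (degenerate cells excluded with a warning), z is set
to 0 wherever the adjusted p exceeds a threshold (default 0.005; the
published methods use 0.005 while a results passage says p < 0.05, so
the procedural value is the default and the other is a flag), and the
surviving z is divided by √n_query so differently sized query sets
are comparable.  Placements are generated once per query and reused
across targets; the entire matrix is a deterministic function of the
seed.

## Hi-C long-range interactions

Contact matrices are symmetric, binned (default 50 kbp), and
depth-normalised by scaling the genome-wide contact total (upper
triangle including the diagonal) to a target (default 10⁸).  The
intra-LRI caller selects bin pairs with value > 100 on the
normalised scale separated by ≥ 10 Mbp, discards bins with
mappability < 0.5, merges surviving bins into anchors across up to
one unselected bin (the smallest gap that yields the multi-bin,
sub-megabase anchors the method is meant to produce), and reports
each anchor pair once with its maximum supporting value.
Cell-specificity keeps a call only when its anchor-pair value in
every other cell type stays below half the calling threshold — a
quantitative contract for "absent elsewhere".

Inter-chromosomal partners of an anchor are found by standardising
the anchor's mean contact profile against all bins on other
chromosomes and keeping partners with z > 3.  The reference
population for that z is not published; the default standardises
per-anchor against the anchor's own inter-chromosomal distribution
(the minimal self-contained choice), with a pooled-global alternative
behind a flag.  Note that hard z-thresholding of a Poisson background
passes a small number of noise bins per anchor by construction; the
planted-hub signal exceeds them by an order of magnitude.

Anchor-set significance: 1000 shuffled region sets with the anchors'
lengths, each region re-placed uniformly on its own chromosome; the
statistic is the summed inter-chromosomal contact value of covered
bins, weighted by the fraction of each bin covered so the statistic
is invariant to bin-grid alignment; z is the observed statistic
standardised against the shuffled distribution.

The overlay declares a syntenic association *connected* when an
inter-LRI joins descendant blocks of its supporting ancestral
chromosome on both reference chromosomes (anchor overlap; a proximity
radius is exposed for looser matching), and a same-ancestor block
pair on one chromosome connected when an intra-LRI links the blocks.
Each LRI is classed against EBRs as spanning (anchor overlaps an
EBR), proximal (nearest EBR < 2 Mbp) or distal; each association's
rearrangement context is `single_fission` when its reference
chromosomes carry only the supporting ancestor's material,
`single_fusion` for pure within-chromosome fusions, else `complex`.
The anchor graph has exactly the called pairs as edges — no
transitive closure — with hubs at degree ≥ 2.

## Synthetic generators

All generators are pure functions of their configuration (seed
included) and emit exactly the formats the analysis reads, plus
ground truth sufficient to score every downstream stage.

* **Rearrangement histories.**  A root genome (default four
  chromosomes, 40–60 Mbp) evolves down a chain of three ancestors to
  the reference leaf by per-branch inversions (random interval, sign
  flip), fusions (head-to-tail concatenation) and fissions (split);
  defaults plant one fusion, one fission and three inversions across
  the branches.  In clean mode breakpoints keep ≥ 1 Mbp from all
  previous breakpoints and chromosome ends, same-branch inversion
  spans are disjoint, an inversion never spans a junction created
  earlier on its branch, and a fusion never silently restores a root
  adjacency — together these make every planted event separately
  detectable, a property the tests then verify rather than assume.
  Each ancestor is expressed on the reference by composing segment
  maps through root coordinates; exactly collinear neighbours are
  merged, and each fragment is trimmed by 20 kbp per side to emulate
  the coverage gaps real reconstructions show at breakpoints (the
  EBR intervals are exactly these gaps).  The truth records every
  event's reference loci — up to two for a fission, whose single
  physical breakpoint is visible at two chromosome ends.
* **State tracks** draw genome segments with geometric lengths (mean
  25 bins of 200 bp on a 10 Mbp genome) and assign each segment a
  designed triplet; cells whose component is E0 receive one of the
  raw background states at random, so the background-merge step is
  exercised downstream.  Realised coverages are recorded as truth.
* **Contact matrices** have expected value depth·(1+d)^(−α) within
  chromosomes (default depth 50, α = 1 at 50 kbp bins — a decay
  scale on which the default caller thresholds yield zero calls
  without planted signal), a flat inter-chromosomal background
  (0.5), Poisson sampling, planted hubs adding 250 expected contacts
  over 3-bin blocks (≥ 2× the caller threshold), and optional
  low-mappability patches.  Recoverable mode refuses an intra hub
  closer than the caller's minimum distance.
* **Region sets** place each region inside a uniformly chosen anchor
  with probability ρ/(1+ρ) and uniformly on the genome otherwise;
  ρ = 0 is exact independence.

What the generators do *not* emulate: real repeat and GC landscapes,
reconstruction noise in fragment maps (mis-assigned fragments,
overlapping events), distance-dependent Hi-C artefacts beyond a
single power law, and genome-scale input sizes.  Passing closure
tests therefore demonstrate algorithmic correctness on data
satisfying the stated assumptions, not end-to-end accuracy on real
genomes — the published genome-scale tallies (total msHSBs, LRI
counts, state-coverage percentages) depend on external assemblies and
sequencing data and are deliberately out of numeric scope.

## Problem sizes and numerical choices

The default study sizes — 20 histories for breakpoint closure, 500
null region-set pairs at 1000 permutations for calibration (150
query regions of 10–30 kbp against 300 targets of 30 kbp on a
150 Mbp genome, sized so the overlap-count null spans many discrete
atoms and the empirical p is near-uniform), 20 null and 10
hub-planted contact matrices of ~120 Mbp at 50 kbp — are the
package's desk-scale verification conditions; all are configuration,
not constants.  Ties in interval sorting break by (end, label);
empirical p-values are add-one; permutation sds use ddof = 1; the
26 Mbp chromosome boundary is inclusive; division-by-zero cases
(zero permuted sd, zero contact totals, empty anchor sets) raise or
flag degeneracy rather than returning silent zeros.

## Known limitations

* The phylogeny is a chain of ancestors to one reference leaf, which
  is the structure per-ancestor fragment maps on a single reference
  encode; general branching trees would need maps on several leaves.
* Inversion counting is parsimony-based and can under-count heavily
  overlapping same-branch inversions.
* The EBR "minimum size shared across all lineages" rule is read as
  the intersection of overlapping candidates across lineages; a
  genome-wide minimum-size reading would be a one-line change where
  the cluster is reduced.
* One physical event detectable against several ancestors is counted
  once, on the most recent branch showing it; published per-ancestor
  tallies may have resolved such cases differently.
* Whether unplaced RACFs join EBR calling is not published; here all
  fragments in a map participate.
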
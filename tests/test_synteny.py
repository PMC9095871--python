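"""Ancestral karyotype curation, EBR detection/typing and rate arithmetic."""

import pytest

from grr.errors import ValidationError
from grr.genome import GenomeTable, GenomicInterval
from grr.simulate import RearrangementConfig, simulate_rearrangement_history, score_ebr_recovery
from grr.synteny import (
    SyntenicFragment,
    SyntenicFragmentMap,
    classify_chromosomes,
    classify_ebr_age,
    compute_rates,
    count_rearrangements,
    curate_racfs,
    detect_ebrs,
    detect_mshsbs,
    detect_syntenic_associations,
    karyotype_from_map,
)

MB = 1_000_000


@pytest.fixture
def ref_genome():
    return GenomeTable((("chrA", 100 * MB), ("chrB", 80 * MB)))


def frag(genome_chrom, rs, re, anc, as_, ae, orient="+", racf=None):
    return SyntenicFragment(GenomicInterval(genome_chrom, rs, re), anc, as_, ae, orient, racf)


def identity_map(lineage, genome, resolution=300_000):
    frs = [
        frag(c, 0, genome.length(c), f"{lineage}.{i+1}", 0, genome.length(c))
        for i, c in enumerate(genome.names)
    ]
    return SyntenicFragmentMap(lineage, frs, genome, resolution)


# ---------------------------------------------------------------------------
# curation


class TestCuration:
    def test_adjacent_collinear_racfs_join(self, ref_genome):
        m = SyntenicFragmentMap("anc", [
            frag("chrA", 0, 40 * MB, "r1", 0, 40 * MB, "+", "r1"),
            frag("chrA", 40 * MB + 100_000, 90 * MB, "r2", 0, 50 * MB - 100_000, "+", "r2"),
        ], ref_genome)
        k = curate_racfs(m, guides=[None])
        assert len(k.racfs) == 1
        rid, frs = k.racfs[0]
        assert len(frs) == 2 and not k.conflicts

    def test_single_racf_unchanged(self, ref_genome):
        m = SyntenicFragmentMap(
            "anc", [frag("chrA", 0, 40 * MB, "r1", 0, 40 * MB, "+", "r1")], ref_genome
        )
        k = curate_racfs(m, guides=[None])
        assert len(k.racfs) == 1 and k.racfs[0][1] == m.fragments

    def test_opposite_orientation_blocks_join(self, ref_genome):
        m = SyntenicFragmentMap("anc", [
            frag("chrA", 0, 40 * MB, "r1", 0, 40 * MB, "+", "r1"),
            frag("chrA", 40 * MB + 100_000, 90 * MB, "r2", 0, 50 * MB - 100_000, "-", "r2"),
        ], ref_genome)
        assert len(curate_racfs(m, guides=[None]).racfs) == 2

    def test_distant_racfs_not_joined(self, ref_genome):
        m = SyntenicFragmentMap("anc", [
            frag("chrA", 0, 40 * MB, "r1", 0, 40 * MB, "+", "r1"),
            frag("chrA", 42 * MB, 90 * MB, "r2", 0, 48 * MB, "+", "r2"),
        ], ref_genome)
        assert len(curate_racfs(m, guides=[None], max_join_gap=500_000).racfs) == 2

    def test_conflicting_joins_refused(self, ref_genome):
        m = SyntenicFragmentMap("anc", [
            frag("chrA", 0, 10 * MB, "r1", 0, 10 * MB, "+", "r1"),
            frag("chrA", 10 * MB + 50_000, 10 * MB + 200_000, "r2", 0, 150_000, "+", "r2"),
            frag("chrA", 10 * MB + 400_000, 20 * MB, "r3", 0, 9_600_000, "+", "r3"),
        ], ref_genome)
        with pytest.warns(UserWarning, match="conflicting joins"):
            k = curate_racfs(m, guides=[None])
        assert len(k.racfs) == 3  # no join applied at a contested end
        assert k.conflicts

    def test_ancestor_guide_spanning_fragment_supports_join(self, ref_genome):
        m = SyntenicFragmentMap("anc", [
            frag("chrA", 0, 40 * MB, "r1", 0, 40 * MB, "+", "r1"),
            frag("chrA", 40 * MB + 100_000, 90 * MB, "r2", 0, 50 * MB - 100_000, "+", "r2"),
        ], ref_genome)
        guide = identity_map("closer", ref_genome)  # spans the junction
        # reference evidence disabled: only the ancestor guide can support
        k = curate_racfs(m, guides=[guide])
        assert len(k.racfs) == 1


class TestChromosomeClassification:
    @pytest.mark.parametrize(
        "length,status",
        [(27 * MB, "chromosome"), (25 * MB, "unplaced"), (26 * MB, "chromosome")],
    )
    def test_26_mbp_boundary_inclusive(self, ref_genome, length, status):
        m = SyntenicFragmentMap(
            "anc", [frag("chrA", 0, length, "r1", 0, length, "+", "r1")], ref_genome
        )
        k = classify_chromosomes(karyotype_from_map(m))
        assert k.chromosome_status["r1"] == status


# ---------------------------------------------------------------------------
# EBR detection


class TestDetectEbrs:
    def test_identity_maps_give_no_ebrs(self, ref_genome):
        maps = [identity_map(l, ref_genome) for l in ("anc1", "anc2")]
        assert detect_ebrs(maps, ref_genome) == []

    def test_single_inversion_gives_two_flank_ebrs(self):
        cfg = RearrangementConfig(
            seed=11, lineages=("anc1",),
            events_per_branch={"reference": {"inversions": 1}},
        )
        sim = simulate_rearrangement_history(cfg)
        ebrs = detect_ebrs(sim.maps, sim.reference, cfg.reference_name)
        assert len(ebrs) == 2
        assert all(e.type == "inversion" and e.lineage == "reference" for e in ebrs)
        recall, precision, branch_ok = score_ebr_recovery(ebrs, sim)
        assert recall == precision == branch_ok == 1.0

    def test_single_fission_gives_one_interchromosomal_ebr(self):
        cfg = RearrangementConfig(
            seed=5, lineages=("anc1",),
            events_per_branch={"reference": {"fissions": 1}},
        )
        sim = simulate_rearrangement_history(cfg)
        ebrs = detect_ebrs(sim.maps, sim.reference, cfg.reference_name)
        assert len(ebrs) == 1 and ebrs[0].type == "inter_chromosomal"
        recall, precision, _ = score_ebr_recovery(ebrs, sim)
        assert recall == precision == 1.0

    def test_single_fusion_gives_one_interchromosomal_ebr(self):
        cfg = RearrangementConfig(
            seed=5, lineages=("anc1",),
            events_per_branch={"reference": {"fusions": 1}},
        )
        sim = simulate_rearrangement_history(cfg)
        ebrs = detect_ebrs(sim.maps, sim.reference, cfg.reference_name)
        assert len(ebrs) == 1 and ebrs[0].type == "inter_chromosomal"

    def test_branch_assignment_is_most_recent(self):
        cfg = RearrangementConfig(seed=2)
        sim = simulate_rearrangement_history(cfg)
        ebrs = detect_ebrs(sim.maps, sim.reference, cfg.reference_name)
        _, _, branch_ok = score_ebr_recovery(ebrs, sim)
        assert branch_ok == 1.0
        # no double assignment: every EBR carries exactly one branch label
        per_branch = {}
        for e in ebrs:
            per_branch[e.lineage] = per_branch.get(e.lineage, 0) + 1
        assert sum(per_branch.values()) == len(ebrs)


class TestAgeClassification:
    def test_partition_matches_definition(self):
        cfg = RearrangementConfig(seed=4)
        sim = simulate_rearrangement_history(cfg)
        ebrs = detect_ebrs(sim.maps, sim.reference, cfg.reference_name)
        aged = classify_ebr_age(ebrs, "anc3", sim.chain)
        classes = {e.age_class for e in aged}
        assert classes <= {"ancestral", "recent", "reference_specific"}
        for e in aged:
            if e.lineage == "reference":
                assert e.age_class == "reference_specific"
            elif sim.chain.index(e.lineage) < sim.chain.index("anc3"):
                assert e.age_class == "ancestral"
            else:
                assert e.age_class == "recent"
        n = sum(1 for e in aged if e.age_class == "ancestral")
        r = sum(1 for e in aged if e.age_class == "recent")
        s = sum(1 for e in aged if e.age_class == "reference_specific")
        assert n + r + s == len(ebrs)

    def test_unknown_branch_rejected(self):
        with pytest.raises(ValidationError):
            classify_ebr_age([], "nowhere", ["a", "b"])


# ---------------------------------------------------------------------------
# rearrangement counting and rates


class TestCountRearrangements:
    def test_identity_is_zero_vector(self, ref_genome):
        k = karyotype_from_map(identity_map("anc", ref_genome))
        ec = count_rearrangements(k, k)
        assert (ec.inversions, ec.fusions, ec.fissions) == (0, 0, 0)
        assert ec.conserved_chromosomes == len(ref_genome)

    def test_single_fusion_counted(self):
        cfg = RearrangementConfig(
            seed=5, lineages=("anc1",),
            events_per_branch={"reference": {"fusions": 1}},
        )
        sim = simulate_rearrangement_history(cfg)
        ks = sim.karyotypes()
        ec = count_rearrangements(ks["anc1"], ks["reference"])
        assert (ec.inversions, ec.fusions, ec.fissions) == (0, 1, 0)

    def test_fusion_fission_antisymmetric(self):
        cfg = RearrangementConfig(
            seed=5, lineages=("anc1",),
            events_per_branch={"reference": {"fissions": 1}},
        )
        sim = simulate_rearrangement_history(cfg)
        ks = sim.karyotypes()
        fwd = count_rearrangements(ks["anc1"], ks["reference"])
        rev = count_rearrangements(ks["reference"], ks["anc1"])
        assert (fwd.fissions, fwd.fusions) == (1, 0)
        assert (rev.fusions, rev.fissions) == (1, 0)

    def test_planted_history_counts_recovered(self):
        cfg = RearrangementConfig(
            seed=21,
            events_per_branch={
                "anc2": {"inversions": 2, "fusions": 1, "fissions": 0},
                "anc3": {"inversions": 1, "fusions": 0, "fissions": 2},
                "reference": {"inversions": 1, "fusions": 0, "fissions": 0},
            },
        )
        sim = simulate_rearrangement_history(cfg)
        ks = sim.karyotypes()
        for parent, child in zip(sim.chain, sim.chain[1:]):
            ec = count_rearrangements(ks[parent], ks[child])
            planted = sim.branch_event_counts.get(
                child, {"inversions": 0, "fusions": 0, "fissions": 0}
            )
            assert (ec.inversions, ec.fusions, ec.fissions) == (
                planted["inversions"], planted["fusions"], planted["fissions"]
            )


class TestRates:
    def test_printed_rate_arithmetic(self):
        rt = compute_rates({"fast": 30, "slow": 13}, {"fast": 1.1, "slow": 12.3})
        assert round(rt.branches.loc["fast", "rate"], 2) == 27.27
        assert round(rt.branches.loc["slow", "rate"], 2) == 1.06

    def test_zero_count_gives_zero_rate(self):
        rt = compute_rates({"b": 0, "c": 5}, {"b": 3.0, "c": 5.0})
        assert rt.branches.loc["b", "rate"] == 0.0

    def test_rate_times_time_round_trips(self):
        counts = {"a": 7, "b": 19, "c": 3}
        times = {"a": 2.5, "b": 8.0, "c": 1.25}
        rt = compute_rates(counts, times)
        for b in counts:
            assert rt.branches.loc[b, "rate"] * times[b] == pytest.approx(counts[b])

    def test_excess_branch_has_positive_residual_and_small_p(self):
        rt = compute_rates({"hot": 30, "a": 5, "b": 6}, {"hot": 1.0, "a": 10.0, "b": 10.0})
        assert rt.branches.loc["hot", "residual"] > 3
        assert rt.pvalue < 0.001

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValidationError):
            compute_rates({"a": 1}, {"a": 0.0})

    def test_total_time_override(self):
        rt = compute_rates({"a": 2, "root": 2}, {"a": 1.0}, total_time=4.0)
        assert rt.average_rate == 1.0 and rt.total_ebrs == 4


# ---------------------------------------------------------------------------
# msHSBs and syntenic associations


class TestMsHsbs:
    def test_identity_maps_return_whole_genome(self, ref_genome):
        maps = [identity_map(l, ref_genome) for l in ("anc1", "anc2")]
        ms = detect_mshsbs(maps, min_size=MB)
        assert {(iv.chrom, iv.start, iv.end) for iv in ms} == {
            (c, 0, ref_genome.length(c)) for c in ref_genome.names
        }

    def test_planted_breakpoint_splits_block(self):
        cfg = RearrangementConfig(
            seed=11, lineages=("anc1", "anc2"),
            events_per_branch={"anc2": {"inversions": 1}},
        )
        sim = simulate_rearrangement_history(cfg)
        ms = detect_mshsbs(sim.maps, min_size=MB)
        loci = [l for ev in sim.events for l in ev.ref_loci]
        for chrom, pos in loci:
            assert not any(
                iv.chrom == chrom and iv.start < pos < iv.end for iv in ms
            ), "an msHSB crosses a planted breakpoint"

    def test_min_size_filter(self, ref_genome):
        maps = [identity_map(l, ref_genome) for l in ("anc1", "anc2")]
        assert len(detect_mshsbs(maps, min_size=200 * MB)) == 0

    def test_mshsbs_disjoint_from_ebrs(self):
        from grr.genome import RegionSet, intersect

        cfg = RearrangementConfig(seed=3)
        sim = simulate_rearrangement_history(cfg)
        ms = detect_mshsbs(sim.maps, min_size=300_000)
        ebrs = detect_ebrs(sim.maps, sim.reference, cfg.reference_name)
        ebr_rs = RegionSet("ebrs", [e.interval for e in ebrs], sim.reference)
        assert len(intersect(ms, ebr_rs)) == 0


class TestSyntenicAssociations:
    def test_split_ancestor_yields_pair(self, ref_genome):
        m = SyntenicFragmentMap("anc", [
            frag("chrA", 0, 30 * MB, "c1", 0, 30 * MB, "+", "c1"),
            frag("chrB", 0, 20 * MB, "c1", 30 * MB, 50 * MB, "+", "c1"),
        ], ref_genome)
        assoc = detect_syntenic_associations(karyotype_from_map(m))
        assert [(a.ancestor_chrom, a.pair) for a in assoc] == [("c1", ("chrA", "chrB"))]

    def test_contained_ancestor_yields_none(self, ref_genome):
        m = identity_map("anc", ref_genome)
        assert detect_syntenic_associations(karyotype_from_map(m)) == []

    def test_three_way_split_yields_all_pairs(self):
        import itertools

        genome = GenomeTable((("chr2", 50 * MB), ("chr13", 40 * MB), ("chr15", 30 * MB)))
        m = SyntenicFragmentMap("anc", [
            frag("chr2", 0, 10 * MB, "cX", 0, 10 * MB, "+", "cX"),
            frag("chr13", 0, 10 * MB, "cX", 10 * MB, 20 * MB, "+", "cX"),
            frag("chr15", 0, 10 * MB, "cX", 20 * MB, 30 * MB, "+", "cX"),
        ], genome)
        assoc = detect_syntenic_associations(karyotype_from_map(m))
        expected = set(itertools.combinations(["chr2", "chr13", "chr15"], 2))
        assert {a.pair for a in assoc} == expected and len(assoc) == 3

    def test_min_support_filters_slivers(self, ref_genome):
        m = SyntenicFragmentMap("anc", [
            frag("chrA", 0, 30 * MB, "c1", 0, 30 * MB, "+", "c1"),
            frag("chrB", 0, 100_000, "c1", 30 * MB, 30 * MB + 100_000, "+", "c1"),
        ], ref_genome)
        assert detect_syntenic_associations(karyotype_from_map(m), min_support=300_000) == []
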
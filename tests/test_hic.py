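"""Contact-matrix normalisation, LRI calling gates and the anchor graph."""

import numpy as np
import pytest

from grr.errors import GenomeMismatchError, ValidationError
from grr.genome import GenomeTable, GenomicInterval, RegionSet
from grr.hic import (
    ContactMatrix,
    MappabilityTrack,
    build_lri_graph,
    call_inter_lris,
    call_intra_lris,
    filter_cell_specific,
    normalize_contacts,
    read_ginteractions,
    shuffle_interaction_zscore,
    write_ginteractions,
)
from grr.simulate import ContactSimConfig, HubPair, simulate_contact_matrix

MB = 1_000_000
RES = 50_000


@pytest.fixture
def small_genome():
    return GenomeTable((("chr1", 30 * MB), ("chr2", 20 * MB)))


def empty_matrix(genome, fill=0.0):
    n = sum(-(-genome.length(c) // RES) for c in genome.names)
    return np.full((n, n), fill)


class TestNormalize:
    def test_scaling_halves_double_depth(self, small_genome):
        m = empty_matrix(small_genome, 4.0)
        cm = ContactMatrix(small_genome, m, RES)
        total = cm.total_contacts()
        out = normalize_contacts(cm, target_total=total / 2)
        assert np.allclose(out.matrix, 2.0)

    def test_already_at_target_unchanged(self, small_genome):
        cm = ContactMatrix(small_genome, empty_matrix(small_genome, 1.0), RES)
        out = normalize_contacts(cm, target_total=cm.total_contacts())
        assert np.allclose(out.matrix, cm.matrix)

    def test_post_total_matches_target(self, small_genome, rng):
        n = sum(-(-small_genome.length(c) // RES) for c in small_genome.names)
        m = rng.poisson(3.0, size=(n, n)).astype(float)
        m = (m + m.T) / 2
        cm = ContactMatrix(small_genome, m, RES)
        out = normalize_contacts(cm, target_total=1e8)
        assert out.total_contacts() == pytest.approx(1e8)

    def test_zero_total_rejected(self, small_genome):
        cm = ContactMatrix(small_genome, empty_matrix(small_genome), RES)
        with pytest.raises(ValidationError):
            normalize_contacts(cm)


class TestMatrixValidation:
    def test_asymmetry_rejected(self, small_genome):
        m = empty_matrix(small_genome)
        m[0, 1] = 5
        with pytest.raises(ValidationError):
            ContactMatrix(small_genome, m, RES)

    def test_negative_values_rejected(self, small_genome):
        m = empty_matrix(small_genome)
        m[0, 0] = -1
        with pytest.raises(ValidationError):
            ContactMatrix(small_genome, m, RES)

    def test_ginteractions_round_trip(self, small_genome, tmp_path, rng):
        n = sum(-(-small_genome.length(c) // RES) for c in small_genome.names)
        m = rng.poisson(0.3, size=(n, n)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        cm = ContactMatrix(small_genome, m, RES)
        p = tmp_path / "m.ginteractions.tsv"
        write_ginteractions(cm, p)
        back = read_ginteractions(p, small_genome, RES)
        assert np.array_equal(back.matrix, cm.matrix)


def planted_pair_matrix(genome, pa, pb, value=150.0, chrom="chr1"):
    m = empty_matrix(genome)
    i = pa // RES
    j = pb // RES
    m[i, j] = m[j, i] = value
    return ContactMatrix(genome, m, RES, "spermatids")


class TestIntraCalling:
    def test_all_below_threshold_gives_no_calls(self, small_genome):
        cm = ContactMatrix(small_genome, empty_matrix(small_genome, 50.0), RES)
        calls, anchors = call_intra_lris(cm)
        assert calls == [] and len(anchors) == 0

    def test_planted_distal_pair_recovered(self, small_genome):
        cm = planted_pair_matrix(small_genome, 5 * MB, 25 * MB)
        calls, anchors = call_intra_lris(cm)
        assert len(calls) == 1
        c = calls[0]
        assert c.anchor_a.start <= 5 * MB < c.anchor_a.end
        assert c.anchor_b.start <= 25 * MB < c.anchor_b.end
        assert c.value == 150.0 and c.kind == "intra"

    def test_distance_gate(self, small_genome):
        cm = planted_pair_matrix(small_genome, 5 * MB, 10 * MB)  # 5 Mbp apart
        calls, _ = call_intra_lris(cm)
        assert calls == []

    def test_mappability_gate(self, small_genome):
        cm = planted_pair_matrix(small_genome, 5 * MB, 25 * MB)
        track = MappabilityTrack.uniform(small_genome, RES)
        track.values[5 * MB // RES] = 0.4
        calls, _ = call_intra_lris(cm, track)
        assert calls == []

    def test_adjacent_bins_merge_into_one_anchor(self, small_genome):
        m = empty_matrix(small_genome)
        for i in (100, 101, 103):  # merge_gap=1 joins across the hole at 102
            m[i, 500] = m[500, i] = 150.0
        cm = ContactMatrix(small_genome, m, RES)
        calls, anchors = call_intra_lris(cm)
        assert len([a for a in anchors if a.start == 100 * RES]) == 1
        assert len(calls) == 1

    def test_transposition_invariant(self, small_genome):
        cm = planted_pair_matrix(small_genome, 5 * MB, 25 * MB)
        cm_t = ContactMatrix(small_genome, cm.matrix.T.copy(), RES, "spermatids")
        a, _ = call_intra_lris(cm)
        b, _ = call_intra_lris(cm_t)
        assert a == b


class TestCellSpecificity:
    def test_absent_elsewhere_retained(self, small_genome):
        cm = planted_pair_matrix(small_genome, 5 * MB, 25 * MB)
        other = planted_pair_matrix(small_genome, 5 * MB, 25 * MB, value=10.0)
        calls, _ = call_intra_lris(cm)
        assert filter_cell_specific(calls, [other]) == calls

    def test_present_elsewhere_dropped(self, small_genome):
        cm = planted_pair_matrix(small_genome, 5 * MB, 25 * MB)
        other = planted_pair_matrix(small_genome, 5 * MB, 25 * MB, value=150.0)
        calls, _ = call_intra_lris(cm)
        assert filter_cell_specific(calls, [other]) == []

    def test_no_other_matrices_vacuous_with_warning(self, small_genome):
        cm = planted_pair_matrix(small_genome, 5 * MB, 25 * MB)
        calls, _ = call_intra_lris(cm)
        with pytest.warns(UserWarning, match="no other matrices"):
            assert filter_cell_specific(calls, []) == calls


class TestInterCalling:
    def test_uniform_inter_row_gives_no_calls(self, small_genome):
        cm = ContactMatrix(small_genome, empty_matrix(small_genome, 2.0), RES)
        anchors = RegionSet("a", [GenomicInterval("chr1", 5 * MB, 5 * MB + RES)], small_genome)
        assert call_inter_lris(cm, anchors) == []

    def test_planted_hotspot_recovered(self, small_genome, rng):
        n = sum(-(-small_genome.length(c) // RES) for c in small_genome.names)
        m = rng.poisson(1.0, size=(n, n)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        i = 5 * MB // RES
        j = 600 + (10 * MB) // RES  # chr2:10M (chr1 has 600 bins)
        m[i, j] = m[j, i] = 50.0
        cm = ContactMatrix(small_genome, m, RES)
        anchors = RegionSet("a", [GenomicInterval("chr1", 5 * MB, 5 * MB + RES)], small_genome)
        calls = call_inter_lris(cm, anchors)
        hits = [c for c in calls if c.anchor_b.chrom == "chr2"
                and c.anchor_b.start <= 10 * MB < c.anchor_b.end]
        assert hits and hits[0].z > 3

    def test_z_matches_hand_computation(self, small_genome):
        # toy anchor row over chr2: values 1..9 then a spike of 100
        m = empty_matrix(small_genome)
        i = 0
        chr2_bins = np.arange(600, 600 + 400)
        vals = np.zeros(400)
        vals[:9] = np.arange(1, 10)
        vals[9] = 100.0
        m[i, chr2_bins] = vals
        m[chr2_bins, i] = vals
        cm = ContactMatrix(small_genome, m, RES)
        anchors = RegionSet("a", [GenomicInterval("chr1", 0, RES)], small_genome)
        calls = call_inter_lris(cm, anchors)
        mu, sd = vals.mean(), vals.std(ddof=1)
        assert calls and max(c.z for c in calls) == pytest.approx((100 - mu) / sd)


class TestShuffleZ:
    def test_constant_matrix_gives_no_signal(self, small_genome):
        cm = ContactMatrix(small_genome, empty_matrix(small_genome, 2.0), RES)
        anchors = RegionSet("a", [GenomicInterval("chr1", 5 * MB, 5 * MB + 3 * RES),
                                  GenomicInterval("chr2", 2 * MB, 2 * MB + 3 * RES)],
                            small_genome)
        z, _ = shuffle_interaction_zscore(anchors, cm, n_sets=100, seed=0)
        assert np.isnan(z) or abs(z) < 2

    def test_deterministic_given_seed(self):
        sim = simulate_contact_matrix(ContactSimConfig(seed=3))
        anchors = RegionSet(
            "a", [GenomicInterval("chr1", 5 * MB, 5 * MB + 3 * RES)], sim.genome
        )
        z1, null1 = shuffle_interaction_zscore(anchors, sim.matrix, n_sets=50, seed=4)
        z2, null2 = shuffle_interaction_zscore(anchors, sim.matrix, n_sets=50, seed=4)
        assert z1 == z2 and np.array_equal(null1, null2)

    def test_hub_anchors_significant_random_not(self):
        hubs = (HubPair("chr1", 10 * MB, "chr1", 35 * MB),
                HubPair("chr1", 10 * MB, "chr3", 15 * MB))
        sim = simulate_contact_matrix(ContactSimConfig(seed=8, hubs=hubs))
        calls, anchors = call_intra_lris(sim.matrix, sim.mappability)
        z, _ = shuffle_interaction_zscore(anchors, sim.matrix, n_sets=200, seed=1)
        assert z > 3
        rng = np.random.default_rng(0)
        ivs = []
        for _ in range(len(anchors)):
            c = sim.genome.names[rng.integers(3)]
            s = int(rng.integers(0, sim.genome.length(c) - 3 * RES))
            ivs.append(GenomicInterval(c, s, s + 3 * RES))
        z_rand, _ = shuffle_interaction_zscore(
            RegionSet("r", ivs, sim.genome), sim.matrix, n_sets=200, seed=2
        )
        assert abs(z_rand) < 3


class TestGraph:
    def test_hub_flagged_and_no_transitive_edge(self):
        from grr.hic import LRICall

        a = GenomicInterval("chr1", 0, RES)
        b = GenomicInterval("chr1", 20 * MB, 20 * MB + RES)
        c = GenomicInterval("chr1", 40 * MB, 40 * MB + RES)
        calls = [LRICall("intra", a, b, 150.0), LRICall("intra", a, c, 120.0)]
        g = build_lri_graph(calls)
        assert g.hubs == [("chr1", 0, RES)]
        assert not g.graph.has_edge(("chr1", 20 * MB, 20 * MB + RES),
                                    ("chr1", 40 * MB, 40 * MB + RES))

    def test_single_call_two_degree_one_nodes(self):
        from grr.hic import LRICall

        a = GenomicInterval("chr1", 0, RES)
        b = GenomicInterval("chr2", 0, RES)
        g = build_lri_graph([LRICall("inter", a, b, 9.0)])
        assert dict(g.graph.degree).values() == {1: 1}.keys() or set(
            dict(g.graph.degree).values()
        ) == {1}

    def test_degrees_match_adjacency_oracle(self, rng):
        from grr.hic import LRICall

        anchors = [GenomicInterval("chr1", i * MB, i * MB + RES) for i in range(0, 60, 12)]
        n = len(anchors)
        adj = np.zeros((n, n), dtype=int)
        calls = []
        for _ in range(10):
            i, j = rng.integers(n), rng.integers(n)
            if i == j:
                continue
            adj[i, j] = adj[j, i] = 1
            calls.append(LRICall("intra", anchors[min(i, j)], anchors[max(i, j)], 150.0))
        g = build_lri_graph(calls)
        for i, a in enumerate(anchors):
            if adj[i].sum():
                assert g.degree(a) == adj[i].sum()
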
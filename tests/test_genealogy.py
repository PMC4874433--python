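"""Lineage tracing, TMRCA conventions, Newick export and CSV round-trips."""

import io

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tissuecoal import (
    Genealogy,
    LineageCurve,
    coalescence_probability,
    excess_lineages,
    read_genealogy_csv,
    tmrca,
    to_newick,
    trace_lineages,
    write_genealogy_csv,
)
from tissuecoal.neutral import GrowthSchedule, WFParams, simulate_wf

from _oracles import tmrca_from_counts, trace_lineage_counts


def wf_genealogy(N, G, seed):
    return simulate_wf(WFParams(GrowthSchedule("constant", N=N), G=G, seed=seed))


def disjoint_chains(n, G):
    """n founders, each continuing its own single-cell lineage for G generations."""
    parent = []
    generation = []
    coords = []
    for g in range(G + 1):
        for i in range(n):
            parent.append(-1 if g == 0 else (g - 1) * n + i)
            generation.append(g)
            coords.append((g, i))
    return Genealogy(parent=np.array(parent), generation=np.array(generation),
                     coords=np.array(coords))


class TestTraceLineages:
    def test_single_chain_has_one_lineage_at_every_depth(self, chain_genealogy):
        curve = trace_lineages(chain_genealogy, 10)
        assert curve.counts.tolist() == [1] * 11
        assert curve.tmrca == 0  # a one-cell sample is its own MRCA

    def test_disjoint_lineages_never_coalesce(self):
        curve = trace_lineages(disjoint_chains(4, 5), 5)
        assert curve.counts.tolist() == [4] * 6
        assert curve.tmrca is None
        assert not curve.coalesced

    def test_star_counts(self, star_genealogy):
        curve = trace_lineages(star_genealogy, 1)
        assert curve.counts.tolist() == [5, 1]
        assert curve.tmrca == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("N,G", [(5, 50), (4, 40), (6, 60)])
    def test_matches_set_based_oracle(self, N, G, seed):
        g = wf_genealogy(N, G, seed)
        curve = trace_lineages(g, G)
        expected = trace_lineage_counts(list(g.parent), list(g.generation), G)
        assert curve.counts.tolist() == expected
        assert tmrca(g, G) == tmrca_from_counts(expected)

    def test_fixture_curve_matches_frozen_oracle_output(self, wf_tiny,
                                                        wf_tiny_golden):
        assert trace_lineages(wf_tiny, 20).counts.tolist() == \
            wf_tiny_golden.tolist()

    def test_sample_generation_out_of_range(self, star_genealogy):
        with pytest.raises(ValueError):
            trace_lineages(star_genealogy, 2)

    def test_sample_beyond_recorded_history_is_an_error(self):
        with pytest.raises(ValueError):
            trace_lineages(disjoint_chains(2, 3), 99)


class TestTmrcaConvention:
    def test_paper_lineage_depth_convention(self):
        """A sample at generation 200 with its MRCA in generation 96 has
        TMRCA 104 (generation differences, not absolute labels)."""
        parent, generation, coords = [], [], []
        for g in range(97):  # single chain up to generation 96
            parent.append(g - 1 if g else -1)
            generation.append(g)
            coords.append((g, 0))
        mrca = 96
        # two independent chains from the generation-96 cell to generation 200
        last = [mrca, mrca]
        for g in range(97, 201):
            for b in range(2):
                parent.append(last[b])
                generation.append(g)
                coords.append((g, b))
                last[b] = len(parent) - 1
        g = Genealogy(parent=np.array(parent), generation=np.array(generation),
                      coords=np.array(coords))
        assert tmrca(g, 200) == 104

    def test_full_founder_sample_is_depth_zero(self, chain_genealogy):
        assert tmrca(chain_genealogy, 0) == 0


class TestExcessAndCoalescenceProbability:
    def test_excess_examples(self):
        curve = LineageCurve(sample_generation=3,
                             counts=np.array([5, 3, 1, 1]))
        assert excess_lineages(curve).tolist() == [4, 2, 0, 0]
        assert (excess_lineages(curve) + 1 == curve.counts).all()

    def test_all_or_none_coalesced(self, star_genealogy, chain_genealogy):
        coalesced = [trace_lineages(star_genealogy, 1)] * 3
        assert coalescence_probability(coalesced, 1) == 1.0
        open_curves = [trace_lineages(disjoint_chains(3, 4), 4)] * 5
        assert coalescence_probability(open_curves, 4) == 0.0

    def test_matches_per_replicate_oracle(self):
        curves, oracle_tmrcas = [], []
        for seed in range(10):
            g = wf_genealogy(5, 60, 100 + seed)
            curves.append(trace_lineages(g, 60))
            oracle_tmrcas.append(tmrca_from_counts(
                trace_lineage_counts(list(g.parent), list(g.generation), 60)))
        for depth in (5, 10, 25, 60):
            expected = sum(t is not None and t <= depth
                           for t in oracle_tmrcas) / 10
            assert coalescence_probability(curves, depth) == expected

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            coalescence_probability([], 1)


class TestNewick:
    def test_two_siblings(self):
        g = Genealogy(parent=np.array([-1, 0, 0]),
                      generation=np.array([0, 1, 1]),
                      coords=np.array([[0, 0], [1, 0], [1, 1]]))
        assert to_newick(g, 1) == "(c1:1,c2:1);"

    def test_single_sampled_cell_zero_length_tree(self, chain_genealogy):
        assert to_newick(chain_genealogy, 10) == "c10;"

    @pytest.mark.parametrize("seed", [0, 7, 13])
    def test_round_trip_leaf_count_and_depth(self, seed):
        g = wf_genealogy(4, 40, seed)
        curve = trace_lineages(g, 40)
        assert curve.coalesced
        tree = dendropy.Tree.get(data=to_newick(g, 40), schema="newick")
        leaves = tree.leaf_nodes()
        assert len(leaves) == curve.sample_size
        depths = {leaf.distance_from_root() for leaf in leaves}
        assert depths == {float(curve.tmrca)}

    def test_forest_for_non_coalescing_sample(self):
        g = disjoint_chains(3, 4)
        trees = to_newick(g, 4).splitlines()
        assert len(trees) == 3
        assert all(t.endswith(";") for t in trees)


class TestCsvRoundTrip:
    @pytest.mark.parametrize("fixture", ["wf-tiny", "eden-tiny"])
    def test_round_trip(self, fixture, tmp_path):
        from tissuecoal.runner import make_fixture
        g = make_fixture(fixture)
        path = tmp_path / "g.csv"
        write_genealogy_csv(g, path)
        g2 = read_genealogy_csv(path)
        assert np.array_equal(g.parent, g2.parent)
        assert np.array_equal(g.generation, g2.generation)
        assert np.array_equal(g.coords, g2.coords)

    def test_founders_have_empty_parent_field(self, star_genealogy, tmp_path):
        path = tmp_path / "g.csv"
        write_genealogy_csv(star_genealogy, path)
        first_row = path.read_text().splitlines()[1]
        assert first_row.split(",")[1] == ""


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=6),
       st.integers(min_value=1, max_value=30),
       st.integers(min_value=0, max_value=10_000))
def test_lineage_curve_invariants_hold_for_random_genealogies(N, G, seed):
    """Counts are non-increasing, start at the sample size and stay >= 1."""
    g = wf_genealogy(N, G, seed)
    curve = trace_lineages(g, G)
    assert curve.counts.size == G + 1
    assert curve.counts[0] == N
    assert (np.diff(curve.counts) <= 0).all()
    assert curve.counts[-1] >= 1
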
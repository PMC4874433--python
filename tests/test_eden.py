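"""Eden growth: event rules, invariants, diffusion guard and completion."""

from collections import Counter, deque

import numpy as np
import pytest

from tissuecoal.eden import (
    EdenParams,
    LatticeConfig,
    SimState,
    complete_generation,
    run_state,
    simulate_eden,
    step_diffusion,
    step_growth,
)


def bounded(N, G, **kw):
    return EdenParams(lattice=LatticeConfig("bounded", 2, N), G=G, **kw)


def unbounded(G, **kw):
    return EdenParams(lattice=LatticeConfig("unbounded", 2), G=G,
                      init="single-seed", **kw)


def assert_state_invariants(state: SimState):
    """Boundary and candidate sets match recomputation; cluster connected."""
    occ = state.occ
    boundary = {s for s in occ
                if any(n not in occ for n in state.neighbours(s))}
    candidates = set()
    for s in occ:
        for n in state.neighbours(s):
            if n not in occ:
                candidates.add(n)
    assert set(state.boundary) == boundary
    assert set(state.candidates) == candidates
    # connectivity by BFS over occupied sites
    start = next(iter(occ))
    seen = {start}
    queue = deque([start])
    while queue:
        s = queue.popleft()
        for n in state.neighbours(s):
            if n in occ and n not in seen:
                seen.add(n)
                queue.append(n)
    assert len(seen) == len(occ)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            LatticeConfig("bounded", 2, 1)
        with pytest.raises(ValueError):
            LatticeConfig("toroidal", 2, 8)
        with pytest.raises(ValueError):
            bounded(4, 10, seed=0, p_move=-0.5)
        with pytest.raises(ValueError):
            bounded(4, 10, seed=0, variant="eden-d")
        with pytest.raises(ValueError):
            bounded(4, 10, seed=0, complete=11)


class TestKernel:
    def test_same_seed_bit_identical(self):
        for params in (bounded(6, 40, seed=5, p_move=1.0),
                       unbounded(25, seed=5)):
            a = simulate_eden(params)
            b = simulate_eden(params)
            assert np.array_equal(a.genealogy.parent, b.genealogy.parent)
            assert np.array_equal(a.genealogy.coords, b.genealogy.coords)
            assert np.array_equal(a.occupied, b.occupied)

    def test_zero_hop_rate_identical_to_plain_growth(self):
        a = simulate_eden(bounded(6, 40, seed=8, p_move=0.0))
        b = simulate_eden(bounded(6, 40, seed=8))
        assert np.array_equal(a.genealogy.parent, b.genealogy.parent)
        assert np.array_equal(a.genealogy.coords, b.genealogy.coords)

    def test_single_seed_first_event(self):
        """From a lone founder the first child is generation 1 and lands on
        each of the four neighbours with equal probability."""
        hits = Counter()
        for seed in range(400):
            res = simulate_eden(unbounded(1, seed=seed))
            g = res.genealogy
            assert g.n_cells == 2
            assert g.generation[1] == 1
            assert g.parent[1] == 0
            hits[tuple(g.coords[1])] += 1
        assert set(hits) == {(1, 0), (-1, 0), (0, 1), (0, -1)}
        for site in hits:
            assert abs(hits[site] / 400 - 0.25) < 0.1

    def test_full_layer_first_event_parent_is_cell_below(self):
        """Width-3 strip: the first growth event fills one of the three
        depth-1 sites (uniformly) and its parent is the founder beneath."""
        hits = Counter()
        for seed in range(600):
            res = simulate_eden(bounded(3, 1, seed=seed))
            g = res.genealogy
            child = g.n_cells - 1
            assert g.generation[child] == 1
            depth, y = g.coords[child]
            assert depth == 1
            assert g.parent[child] == y  # founder at transverse position y
            hits[int(y)] += 1
        for y in (0, 1, 2):
            assert abs(hits[y] / 600 - 1 / 3) < 0.08

    @pytest.mark.parametrize("seed", range(6))
    def test_genealogy_invariants_sweep(self, seed):
        res = simulate_eden(bounded(10, 50, seed=seed, p_move=1.0))
        res.genealogy.validate()

    def test_stop_at_first_cell_of_generation_g(self):
        res = simulate_eden(bounded(5, 30, seed=2))
        assert res.genealogy.max_generation == 30
        assert (res.genealogy.generation == 30).sum() == 1

    def test_single_seed_from_one_growth_event(self):
        res = simulate_eden(unbounded(1, seed=3))
        assert res.n_events == 1

    def test_boundary_from_result_matches_recomputation(self):
        res = simulate_eden(bounded(8, 30, seed=4, p_move=1.0))
        occ = {tuple(c) for c in res.occupied}
        N = 8
        expected = set()
        for (d, y) in occ:
            nbrs = [(d + 1, y), (d - 1, y), (d, (y + 1) % N), (d, (y - 1) % N)]
            if any(n not in occ and n[0] >= 0 for n in nbrs):
                expected.add((d, y))
        assert {tuple(c) for c in res.boundary} == expected


class TestCompletion:
    def test_completed_generation_is_final_and_idempotent(self):
        state = complete_generation(SimState(unbounded(5, seed=11)), 5)
        count = sum(g == 5 for g in state.generation)
        assert all(state.generation[state.occ[b]] >= 5 for b in state.boundary)
        for _ in range(300):  # keep growing: the census may not change
            step_growth(state)
        assert sum(g == 5 for g in state.generation) == count

    def test_kernel_completion_census_is_reproducible(self):
        a = simulate_eden(unbounded(20, seed=7, complete=20))
        b = simulate_eden(unbounded(20, seed=7, complete=20))
        assert a.genealogy.generation_counts()[20] == \
            b.genealogy.generation_counts()[20]

    def test_bounded_generation_census_bounds(self):
        res = simulate_eden(bounded(5, 10, seed=1, complete=10))
        n10 = res.genealogy.generation_counts()[10]
        assert 1 <= n10 <= res.genealogy.n_cells


class TestReferenceImplementation:
    @pytest.mark.parametrize("params", [
        bounded(6, 25, seed=1, p_move=0.8),
        bounded(4, 30, seed=2),
        unbounded(12, seed=3, p_move=0.5),
    ])
    def test_invariants_after_run(self, params):
        state = run_state(params)
        assert_state_invariants(state)
        state.to_genealogy().validate()

    def test_invariants_hold_throughout_a_diffusive_run(self):
        state = SimState(bounded(5, 10**9, seed=4, p_move=2.0))
        for _ in range(400):
            step_growth(state)
            step_diffusion(state)
            assert_state_invariants(state)

    def test_two_cell_column_stays_attached(self):
        """The connectivity guard: with only two cells, every accepted hop
        must leave them von-Neumann adjacent."""
        state = SimState(unbounded(10**9, seed=5))
        step_growth(state)  # two cells total
        for _ in range(300):
            step_diffusion(state)
            (a, b) = state.occ
            assert abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1

    def test_diffusion_preserves_ids_and_generations(self):
        state = SimState(bounded(5, 10**9, seed=6, p_move=0.0))
        for _ in range(40):
            step_growth(state)
        gens_before = list(state.generation)
        ids_before = set(state.occ.values())
        for _ in range(200):
            step_diffusion(state)
        assert list(state.generation) == gens_before
        assert set(state.occ.values()) == ids_before


class TestDiffusionEnsembleStatistics:
    def test_transverse_occupancy_uniform(self):
        """Diffusive strip: occupancy pooled over an ensemble is uniform
        across the width (chi-square goodness of fit)."""
        from scipy import stats
        N = 20
        counts = np.zeros(N)
        total = 0
        for seed in range(30):
            res = simulate_eden(bounded(N, 60, seed=900 + seed, p_move=1.0))
            y = res.genealogy.coords[:, 1]
            counts += np.bincount(y, minlength=N)
            total += y.size
        chi2, p = stats.chisquare(counts)
        assert p > 1e-3, f"transverse occupancy non-uniform (p={p})"
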
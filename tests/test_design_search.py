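"""Local search, simulated annealing, exchange algorithm, greedy strategies,
Latin-hypercube constructors."""

import itertools

import numpy as np
import pytest

from ekdesign import (
    CandidateSet,
    CovarianceKernel,
    Design,
    GPModel,
    SAConfig,
    criterion_pair,
    exchange_search,
    greedy_augment,
    j_alpha,
    local_optimize,
    maximin_lh,
    mek,
    pareto_sample_sa,
    perturbed_lh_sample,
    sa_optimize,
)
from ekdesign.design_search import _Tableau
from ekdesign.ek_criteria import ek_variance_many
from ekdesign.gp_core import kriging_weights_many

SMALL_MODEL = GPModel(CovarianceKernel("exponential", {"nu": 2.0}))


def spread_objective(design: Design) -> float:
    """Concave toy objective: negative mean squared distance to the centroid
    complement — rewards spread-out designs."""
    from scipy.spatial.distance import pdist

    return float(pdist(design.sites).min())


class TestLocalOptimize:
    def test_objective_never_decreases(self, grid4, rng):
        idx = rng.choice(16, 3, replace=False)
        d0 = Design(grid4.points[idx])
        before = spread_objective(d0)
        out = local_optimize(d0, spread_objective, grid4)
        assert spread_objective(out) >= before

    def test_fixed_point_returned_unchanged(self, grid4):
        d0 = Design(grid4.points[[0, 3, 12]])       # three corners: maximal spread
        out = local_optimize(d0, spread_objective, grid4)
        assert spread_objective(out) == pytest.approx(spread_objective(d0))

    def test_reaches_rook_local_optimum(self, grid4):
        """The returned design admits no improving single rook move — checked
        exhaustively."""
        d0 = Design(grid4.points[[5, 6, 9]])
        out = local_optimize(d0, spread_objective, grid4)
        idx = grid4.index_of(out.sites)
        val = spread_objective(out)
        for i in range(3):
            for y in grid4.neighbors[idx[i]]:
                if y < 0 or y in idx:
                    continue
                trial = idx.copy()
                trial[i] = y
                assert spread_objective(Design(grid4.points[trial])) <= val + 1e-12

    def test_fast_path_matches_reference(self, grid4):
        """The JIT J_alpha local search agrees with the generic implementation
        run on the same objective."""
        alpha = 0.7
        tab = _Tableau(grid4, SMALL_MODEL)

        d0 = Design(grid4.points[[1, 6, 11]])
        ref = local_optimize(
            d0, lambda d: j_alpha(d, SMALL_MODEL, alpha), grid4
        )
        from ekdesign.design_search import _local_opt_idx

        idx = np.ascontiguousarray(grid4.index_of(d0.sites), dtype=np.int64)
        ind = np.zeros(16, dtype=bool)
        ind[idx] = True
        J, _ = _local_opt_idx(
            idx, ind, grid4.neighbors.astype(np.int64),
            tab.Cq, tab.dCq, tab.Fq, tab.sigma2, alpha,
        )
        assert J == pytest.approx(j_alpha(ref, SMALL_MODEL, alpha), rel=1e-12)
        assert sorted(idx.tolist()) == sorted(grid4.index_of(ref.sites).tolist())

    def test_tableau_pair_matches_reference(self, grid4, rng):
        tab = _Tableau(grid4, SMALL_MODEL)
        idx = np.sort(rng.choice(16, 4, replace=False))
        got = tab.pair(idx.astype(np.int64))
        want = criterion_pair(Design(grid4.points[idx]), SMALL_MODEL)
        assert got[0] == pytest.approx(want[0], rel=1e-10)
        assert got[1] == pytest.approx(want[1], rel=1e-10)


class TestSimulatedAnnealing:
    def test_reproducible_and_traced(self, grid4):
        cfg = SAConfig(T0=0.5, r=0.9, Nmax=60, seed=3)
        a = sa_optimize(SMALL_MODEL, grid4, 3, 0.8, cfg)
        b = sa_optimize(SMALL_MODEL, grid4, 3, 0.8, cfg)
        assert a.best_value == b.best_value
        assert np.array_equal(a.best_design.sites, b.best_design.sites)
        assert len(a.trace) == 60

    def test_best_value_not_below_initial(self, grid4, lh7):
        cfg = SAConfig(T0=0.5, r=0.9, Nmax=40, seed=1)
        init = Design(grid4.points[[0, 5, 10]])
        res = sa_optimize(SMALL_MODEL, grid4, 3, 0.9, cfg, init=init)
        assert res.best_value >= j_alpha(init, SMALL_MODEL, 0.9) - 1e-12

    def test_running_best_is_monotone(self, grid4):
        cfg = SAConfig(T0=0.5, r=0.9, Nmax=80, seed=5)
        res = sa_optimize(SMALL_MODEL, grid4, 3, 0.7, cfg)
        best = -np.inf
        for _, e, _ in res.trace:
            best = max(best, e)
        assert res.best_value == pytest.approx(best)

    def test_best_value_consistent_with_design(self, grid4):
        cfg = SAConfig(T0=0.5, r=0.9, Nmax=50, seed=9)
        res = sa_optimize(SMALL_MODEL, grid4, 3, 0.65, cfg)
        assert res.best_value == pytest.approx(
            j_alpha(res.best_design, SMALL_MODEL, 0.65), rel=1e-10
        )


class TestParetoSampleSA:
    def test_single_alpha_selection_trivial(self, grid4):
        cfg = SAConfig(T0=0.5, r=0.9, Nmax=40, seed=2)
        front, sel = pareto_sample_sa(SMALL_MODEL, grid4, 3, [1.0], cfg)
        assert sel.counters["ek_evaluations"] == 1
        assert len(front) == 1

    def test_selected_minimises_mek_over_front(self, grid4):
        cfg = SAConfig(T0=0.5, r=0.9, Nmax=60, seed=4)
        front, sel = pareto_sample_sa(
            SMALL_MODEL, grid4, 3, [0.5, 0.75, 1.0], cfg
        )
        assert sel.best_value <= mek(sel.best_design, SMALL_MODEL, grid4).value + 1e-12


class TestExchange:
    def test_stops_when_no_exchange_improves(self, example_model, grid25):
        """Start from the front-restricted optimum: a re-run from it stops at
        the first scan and returns it unchanged."""
        lh = maximin_lh(7)
        first = exchange_search(lh, example_model, grid25, "front")
        again = exchange_search(first.best_design, example_model, grid25, "front")
        assert again.counters["updates"] == 0
        assert again.counters["iterations"] == 1
        assert np.array_equal(
            np.sort(grid25.index_of(again.best_design.sites)),
            np.sort(grid25.index_of(first.best_design.sites)),
        )

    def test_hull_never_costlier_than_front_per_scan(self, example_model, grid25):
        lh = maximin_lh(7)
        front = exchange_search(lh, example_model, grid25, "front")
        hull = exchange_search(lh, example_model, grid25, "hull")
        assert hull.trace[0]["n_ek"] <= front.trace[0]["n_ek"]
        assert hull.best_value >= front.best_value - 1e-9

    def test_small_instance_reaches_one_exchange_local_optimum(self):
        """On Q=16, n=3 the final design cannot be improved by any single
        exchange (brute-force check over all 3*13 exchanges)."""
        cands = CandidateSet.grid(4)
        d0 = Design(cands.points[[0, 5, 10]])
        res = exchange_search(d0, SMALL_MODEL, cands, "front")
        final = res.best_value
        idx = cands.index_of(res.best_design.sites)
        for i in range(3):
            for q in range(16):
                if q in idx:
                    continue
                trial = idx.copy()
                trial[i] = q
                v = mek(Design(cands.points[trial]), SMALL_MODEL, cands).value
                assert v >= final - 1e-10

    def test_counter_contract(self, example_model, grid25):
        lh = maximin_lh(7)
        res = exchange_search(lh, example_model, grid25, "hull")
        assert res.counters["ek_evaluations"] == 1 + sum(
            t["n_ek"] for t in res.trace
        )
        assert res.counters["iterations"] == len(res.trace)


class TestGreedy:
    def test_added_site_interpolated(self, example_model, grid25, lh7):
        seq = greedy_augment(lh7, example_model, grid25, "S1", k_max=2)
        d1 = seq[1]
        _, rho2 = ek_variance_many(d1.sites[-1:], d1, example_model)
        assert rho2[0] == pytest.approx(0.0, abs=1e-10)

    def test_s1_max_rho2_nonincreasing(self, example_model, grid25, lh7):
        seq = greedy_augment(lh7, example_model, grid25, "S1", k_max=6)
        maxima = []
        for d in seq:
            _, rho2 = ek_variance_many(grid25.points, d, example_model)
            maxima.append(rho2.max())
        assert all(a >= b - 1e-10 for a, b in zip(maxima, maxima[1:]))

    def test_strategies_converge_for_large_k(self, example_model, grid25, lh7):
        """The gap between the S1 and S2 M_EK trajectories shrinks as the
        design grows (the correction term fades with n)."""
        k = 15
        s1 = greedy_augment(lh7, example_model, grid25, "S1", k_max=k)
        s2 = greedy_augment(lh7, example_model, grid25, "S2", k_max=k)
        gap = [
            abs(
                mek(a, example_model, grid25).value
                - mek(b, example_model, grid25).value
            )
            for a, b in zip(s1, s2)
        ]
        assert gap[k] < gap[3]


class TestLatinHypercube:
    def test_n2_diagonal_pair(self):
        d = maximin_lh(2)
        from scipy.spatial.distance import pdist

        assert pdist(d.sites)[0] == pytest.approx(np.sqrt(2))

    def test_output_is_latin_hypercube(self):
        for n in (5, 7):
            d = maximin_lh(n)
            for axis in range(2):
                levels = np.sort(np.round(d.sites[:, axis] * (n - 1)).astype(int))
                assert levels.tolist() == list(range(n))

    def test_n7_matches_exhaustive_oracle(self, lh7):
        """Exhaustive 7!-search oracle (maximin then minimax) reproduces the
        shipped 7-point design."""
        from scipy.spatial.distance import cdist, pdist

        g = np.linspace(0, 1, 25)
        grid = np.column_stack([a.ravel() for a in np.meshgrid(g, g, indexing="ij")])
        lev = np.arange(7) / 6
        best = None
        for perm in itertools.permutations(range(7)):
            pts = np.column_stack([lev, lev[list(perm)]])
            key = (-pdist(pts).min(), cdist(grid, pts).min(axis=1).max())
            if best is None or key < best[0]:
                best = (key, pts)
        assert np.allclose(np.sort(best[1], axis=0), np.sort(lh7.sites, axis=0))

    def test_exhaustive_cap(self):
        with pytest.raises(ValueError):
            maximin_lh(10)

    def test_perturbed_lh_properties(self):
        d0 = perturbed_lh_sample(7, 0.0, seed=1)
        for axis in range(2):
            levels = np.sort(np.round(d0.sites[:, axis] * 6).astype(int))
            assert levels.tolist() == list(range(7))
        d = perturbed_lh_sample(7, 0.1, seed=2)
        assert ((d.sites >= 0) & (d.sites <= 1)).all()
        assert np.array_equal(
            d.sites, perturbed_lh_sample(7, 0.1, seed=2).sites
        )
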
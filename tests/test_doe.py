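import numpy as np
import pytest
from scipy.stats import kstest

from kgsdl.doe import (HistoricalData, SearchSpace, _nsga2, _thompson_sample,
                       fit_surrogates, gather_history, hypervolume, lhs_batch,
                       pareto_front, pareto_mask, propose_random, propose_tsemo)
from kgsdl.kg_store import (ExperimentStatus, Graph, Iri, KG,
                            PerformanceIndicator, ReactionCondition,
                            ReactionExperiment, write_experiment)


@pytest.fixture
def space():
    return SearchSpace(bounds={"equiv_acetone": (5.0, 50.0),
                               "equiv_naoh": (0.05, 0.5),
                               "residence_time": (2.0, 10.0),
                               "temperature": (30.0, 70.0)})


def brute_force_pareto(yields, costs):
    """O(n^2) pairwise-dominance oracle (independent of the production sweep)."""
    n = len(yields)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (yields[j] >= yields[i] and costs[j] <= costs[i]
                    and (yields[j] > yields[i] or costs[j] < costs[i])):
                mask[i] = False
                break
    seen = set()
    for i in range(n):
        if mask[i]:
            key = (yields[i], costs[i])
            if key in seen:
                mask[i] = False
            seen.add(key)
    return mask


def mc_hypervolume(points, ref, n_samples, rng):
    """Monte-Carlo oracle for the 2-D dominated area."""
    pts = np.asarray(points, float)
    y_ref, c_ref = ref
    y_hi = pts[:, 0].max()
    c_lo = pts[:, 1].min()
    area = (y_hi - y_ref) * (c_ref - c_lo)
    if area <= 0:
        return 0.0, 0.0
    ys = rng.uniform(y_ref, y_hi, n_samples)
    cs = rng.uniform(c_lo, c_ref, n_samples)
    dominated = np.zeros(n_samples, dtype=bool)
    for py, pc in pts:
        dominated |= (ys <= py) & (cs >= pc)
    p = dominated.mean()
    sigma = area * np.sqrt(p * (1 - p) / n_samples)
    return p * area, sigma


class TestSearchSpace:
    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SearchSpace(bounds={"equiv_acetone": (5.0, 5.0),
                                "equiv_naoh": (0.05, 0.5),
                                "residence_time": (2.0, 10.0),
                                "temperature": (30.0, 70.0)})

    def test_missing_variable_rejected(self):
        with pytest.raises(ValueError, match="missing bounds"):
            SearchSpace(bounds={"equiv_acetone": (5.0, 50.0)})


class TestProposeRandom:
    def test_deterministic_per_seed(self, space):
        a = propose_random(space, np.random.default_rng(1))
        b = propose_random(space, np.random.default_rng(1))
        assert a == b

    def test_bounds_and_uniformity(self, space):
        rng = np.random.default_rng(0)
        draws = np.array([propose_random(space, rng).as_array()
                          for _ in range(10_000)])
        lo, hi = space.lower, space.upper
        assert np.all(draws >= lo) and np.all(draws <= hi)
        for dim in range(4):
            u = (draws[:, dim] - lo[dim]) / (hi[dim] - lo[dim])
            assert kstest(u, "uniform").pvalue > 0.01

    def test_lhs_one_sample_per_stratum(self, space):
        n = 16
        batch = lhs_batch(space, n, np.random.default_rng(3))
        x = np.array([c.as_array() for c in batch])
        u = space.to_unit(x)
        for dim in range(4):
            strata = np.floor(u[:, dim] * n).astype(int)
            assert sorted(strata) == list(range(n))


class TestSurrogates:
    def test_known_function_recovery(self, space, rng):
        x_unit = rng.uniform(size=(30, 4))
        x = space.from_unit(x_unit)
        y = np.sum(x_unit**2, axis=1)
        pair = fit_surrogates((x, np.column_stack([y, y + 1.0])), space, rng)
        pred = pair.yield_model.predict(x_unit)
        assert np.max(np.abs(pred - y)) < 1e-3

    def test_duplicate_inputs_no_numerical_failure(self, space, rng):
        x = np.tile(space.from_unit(np.full((1, 4), 0.5)), (10, 1))
        y = rng.normal(50.0, 2.0, size=10)
        pair = fit_surrogates((x, np.column_stack([y, y])), space, rng)
        _, _, noise = pair.yield_model.hyperparameters()
        assert noise > 1e-9

    def test_below_n_init_rejected(self, space, rng):
        x = space.from_unit(rng.uniform(size=(1, 4)))
        with pytest.raises(ValueError, match="n_init"):
            fit_surrogates((x, np.array([[50.0, 3.0]])), space, rng)

    def test_constant_objective_falls_back_with_warning(self, space, rng):
        x = space.from_unit(rng.uniform(size=(10, 4)))
        y = np.column_stack([np.full(10, 7.0), rng.normal(size=10)])
        with pytest.warns(UserWarning, match="degenerate"):
            pair = fit_surrogates((x, y), space, rng)
        assert pair.yield_model.constant
        assert np.allclose(pair.yield_model.predict(rng.uniform(size=(5, 4))), 7.0)

    def test_thompson_sample_tracks_posterior(self, space, rng):
        x_unit = rng.uniform(size=(40, 4))
        y = 10.0 * np.sum(x_unit, axis=1)
        pair = fit_surrogates((space.from_unit(x_unit), np.column_stack([y, y])),
                              space, rng)
        samples = np.array([_thompson_sample(pair.yield_model, rng, 400)(x_unit)
                            for _ in range(8)])
        # samples concentrate near the (noiseless) training targets
        assert np.median(np.abs(samples - y)) < 1.0


class TestPareto:
    def test_hand_checked_front(self):
        front = pareto_front([(90, 5), (80, 3), (70, 4)])
        assert {tuple(p) for p in front.points} == {(90.0, 5.0), (80.0, 3.0)}

    def test_identical_points_single_representative(self):
        front = pareto_front([(50, 2)] * 4)
        assert len(front.points) == 1

    def test_matches_brute_force_oracle(self, rng):
        y = rng.uniform(0, 100, 500)
        c = rng.uniform(1, 6, 500)
        assert np.array_equal(pareto_mask(y, c), brute_force_pareto(y, c))

    def test_ties_against_oracle(self, rng):
        y = rng.integers(0, 6, 200).astype(float)
        c = rng.integers(0, 6, 200).astype(float)
        assert np.array_equal(pareto_mask(y, c), brute_force_pareto(y, c))


class TestHypervolume:
    def test_single_rectangle(self):
        assert hypervolume([(1.0, 1.0)], (0.0, 2.0)) == pytest.approx(1.0)

    def test_empty_front_zero(self):
        assert hypervolume(np.empty((0, 2)), (0.0, 2.0)) == 0.0

    def test_undominated_reference_rejected(self):
        with pytest.raises(ValueError, match="reference point"):
            hypervolume([(1.0, 3.0)], (0.0, 2.0))

    def test_new_nondominated_point_strictly_increases(self, rng):
        pts = [(60.0, 3.0), (80.0, 4.0)]
        ref = (0.0, 6.0)
        base = hypervolume(pts, ref)
        assert hypervolume(pts + [(90.0, 5.0)], ref) > base
        assert hypervolume(pts + [(70.0, 2.0)], ref) > base

    def test_matches_monte_carlo_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 21))
            pts = np.column_stack([rng.uniform(10, 90, n), rng.uniform(1, 5, n)])
            ref = (0.0, 6.0)
            exact = hypervolume(pts, ref)
            est, sigma = mc_hypervolume(pts, ref, 200_000, rng)
            assert abs(exact - est) < max(3 * sigma, 1e-9)


class TestTsemo:
    def _fitted(self, space, seed=0):
        rng = np.random.default_rng(seed)
        x_unit = rng.uniform(size=(12, 4))
        x = space.from_unit(x_unit)
        y = 100.0 * (1 - np.prod((x_unit - 0.5)**2 + 0.5, axis=1))
        c = 1.0 + 3.0 * x_unit[:, 0]
        pair = fit_surrogates((x, np.column_stack([y, c])), space,
                              np.random.default_rng(seed))
        front = pareto_front(np.column_stack([y, c]), reference_point=(0.0, 10.0))
        return pair, front

    def test_deterministic_per_seed(self, space):
        pair, front = self._fitted(space)
        a = propose_tsemo(pair, space, front, np.random.default_rng(5),
                          n_spectral=100, nsga_pop=20, nsga_gen=10)
        b = propose_tsemo(pair, space, front, np.random.default_rng(5),
                          n_spectral=100, nsga_pop=20, nsga_gen=10)
        assert a == b

    def test_proposal_within_bounds(self, space):
        pair, front = self._fitted(space)
        for seed in range(5):
            cond = propose_tsemo(pair, space, front, np.random.default_rng(seed),
                                 n_spectral=100, nsga_pop=20, nsga_gen=10)
            assert space.contains(cond)

    def test_failure_falls_back_to_random(self, space):
        pair, front = self._fitted(space)
        broken = pareto_front([(50.0, 3.0)], reference_point=(60.0, 2.0))
        with pytest.warns(UserWarning, match="falling back to random"):
            cond = propose_tsemo(pair, space, broken, np.random.default_rng(0),
                                 n_spectral=100, nsga_pop=20, nsga_gen=10)
        assert space.contains(cond)

    def test_toy_biobjective_convergence(self):
        # convex bi-objective quadratics on [0,1]^2 with a known Pareto set
        space = SearchSpace(bounds={"equiv_acetone": (0.001, 1.0),
                                    "equiv_naoh": (0.001, 1.0),
                                    "residence_time": (0.001, 1.0),
                                    "temperature": (0.001, 1.0)})

        def f_yield(x):  # maximise
            return 100.0 * (1.0 - (x[..., 0] - 0.2)**2 - (x[..., 1] - 0.5)**2)

        def f_cost(x):   # minimise
            return 1.0 + (x[..., 0] - 0.8)**2 + (x[..., 1] - 0.5)**2

        grid_axes = np.meshgrid(*[np.linspace(0, 1, 40)] * 2)
        grid = np.column_stack([grid_axes[0].ravel(), grid_axes[1].ravel(),
                                np.full(1600, 0.5), np.full(1600, 0.5)])
        ref = (0.0, 3.0)
        true_front = pareto_front(
            np.column_stack([f_yield(grid), f_cost(grid)]), reference_point=ref)
        true_hv = hypervolume(true_front.points, ref)

        rng = np.random.default_rng(7)
        x = np.array([c.as_array() for c in lhs_batch(space, 8, rng)])
        y = np.column_stack([f_yield(x), f_cost(x)])
        for _ in range(30):
            pair = fit_surrogates((x, y), space, rng)
            front = pareto_front(y, reference_point=ref)
            cond = propose_tsemo(pair, space, front, rng,
                                 n_spectral=150, nsga_pop=40, nsga_gen=30)
            xn = cond.as_array()[None, :]
            x = np.vstack([x, xn])
            y = np.vstack([y, [f_yield(xn)[0], f_cost(xn)[0]]])
        attained = hypervolume(pareto_front(y, reference_point=ref).points, ref)
        assert attained >= 0.95 * true_hv


class TestGatherHistory:
    def _experiment(self, g, i, yield_pct, abnormal=False, analysed=True):
        ind = None
        status = ExperimentStatus.Proposed
        if analysed:
            ind = PerformanceIndicator(yield_pct, 3.0, abnormal)
            status = ExperimentStatus.Analysed
        exp = ReactionExperiment(
            iri=Iri(KG + f"ReactionExperiment/{i}"),
            condition=ReactionCondition(10, 0.1, 5, 50), status=status,
            assigned_lab=Iri(KG + "Lab/x") if analysed else None,
            assigned_equipment=Iri(KG + "Lab/x/rig") if analysed else None,
            indicators=ind)
        write_experiment(g, exp)
        return exp

    def test_fresh_campaign_empty(self):
        assert len(gather_history(Graph())) == 0

    def test_abnormal_excluded(self):
        g = Graph()
        for i in range(9):
            self._experiment(g, i, 50.0 + i)
        self._experiment(g, 9, 3500.0, abnormal=True)
        history = gather_history(g)
        assert len(history) == 9
        assert all(not e.indicators.abnormal_flag for e in history.experiments)

    def test_zero_yield_included(self):
        g = Graph()
        self._experiment(g, 0, 0.0)
        assert len(gather_history(g)) == 1

    def test_unanalysed_excluded(self):
        g = Graph()
        self._experiment(g, 0, 50.0)
        self._experiment(g, 1, 0.0, analysed=False)
        assert len(gather_history(g)) == 1

    def test_history_type_rejects_abnormal(self):
        g = Graph()
        exp = self._experiment(g, 0, 3500.0, abnormal=True)
        with pytest.raises(ValueError, match="abnormal"):
            HistoricalData(experiments=[exp])
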
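import itertools

import numpy as np
import pytest

import landcarbon as lc
from landcarbon.errors import AllocationError, ValidationError
from landcarbon.synthetic import DriverField
from landcarbon.transition import _scaled_matrix, transition_area_matrix


class TestEstimateTransitionMatrix:
    def test_no_change_identity(self, small_maps):
        m = small_maps[2020]
        tm = lc.estimate_transition_matrix(m, m, 10)
        np.testing.assert_allclose(tm.P, np.eye(len(m.class_codes)))

    def test_toy_counts(self, toy_map_pair):
        t1, t2 = toy_map_pair
        tm = lc.estimate_transition_matrix(t1, t2, 10)
        np.testing.assert_allclose(tm.P, [[0.5, 0.5], [0.0, 1.0]])

    def test_rows_sum_to_one(self, small_maps):
        tm = lc.estimate_transition_matrix(small_maps[2000], small_maps[2010], 10)
        np.testing.assert_allclose(tm.P.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_origin_row_becomes_identity_and_flagged(self, map_factory):
        t1 = map_factory(np.array([[1, 1], [2, 2]]))
        t2 = map_factory(np.array([[1, 1], [2, 1]]))
        with pytest.warns(UserWarning, match="identity rows"):
            tm = lc.estimate_transition_matrix(t1, t2, 5)
        assert tm.identity_rows == (3,)
        assert tm.P[2, 2] == 1.0

    def test_all_nodata_error(self):
        m = lc.LulcMap(np.full((2, 2), 255, dtype=np.uint8), (1, 2))
        with pytest.raises(ValidationError):
            lc.estimate_transition_matrix(m, m, 5)

    def test_exhaustive_oracle_on_2x2_pairs(self):
        """Eq-by-hand oracle over every pair of 2x2 two-class maps."""
        codes = (1, 2)
        maps = [np.array(p, dtype=np.uint8).reshape(2, 2)
                for p in itertools.product(codes, repeat=4)]
        for d1 in maps:
            for d2 in maps:
                m1 = lc.LulcMap(d1, codes)
                m2 = lc.LulcMap(d2, codes)
                tm = lc.estimate_transition_matrix(m1, m2, 1)
                for i, ci in enumerate(codes):
                    n_i = int(np.sum(d1 == ci))
                    for j, cj in enumerate(codes):
                        n_ij = int(np.sum((d1 == ci) & (d2 == cj)))
                        expected = n_ij / n_i if n_i else float(i == j)
                        assert tm.P[i, j] == pytest.approx(expected, abs=1e-12)

    def test_parameter_recovery_from_synthetic_chain(self):
        sc = lc.SyntheticScenario(
            grid_rows=400, grid_cols=400, class_codes=(1, 2, 3, 4, 5, 6),
            epoch_years=(2000, 2010),
            true_transition_matrices=(np.eye(6),),
            class_prevalence=(0.5, 0.5, 0, 0, 0, 0), seed=5,
        )
        m1 = lc.generate_initial_lulc(sc)
        M = np.eye(6)
        M[0] = [0.85, 0.1, 0.05, 0, 0, 0]
        M[1] = [0.15, 0.75, 0.05, 0.05, 0, 0]
        m2 = lc.evolve_lulc(m1, M, seed=5)
        tm = lc.estimate_transition_matrix(m1, m2, 10)
        for i in range(6):
            n_i = tm.origin_totals[i]
            if n_i < 10**4:
                continue
            for j in range(6):
                se = np.sqrt(M[i, j] * (1 - M[i, j]) / n_i)
                assert abs(tm.P[i, j] - M[i, j]) <= 3 * se + 1e-12


class TestMarkovProject:
    def test_identity_unchanged(self):
        v = np.array([10.0, 20.0, 30.0])
        np.testing.assert_allclose(lc.markov_project(v, np.eye(3), 7), v)

    def test_single_multiply(self):
        v = np.array([100.0, 0.0])
        M = np.array([[0.9, 0.1], [0.0, 1.0]])
        np.testing.assert_allclose(lc.markov_project(v, M, 1), [90.0, 10.0])

    def test_total_conserved(self):
        rng = np.random.default_rng(3)
        M = rng.random((4, 4))
        M /= M.sum(axis=1, keepdims=True)
        v = np.array([5.0, 10.0, 0.0, 85.0])
        for n in (1, 3, 10):
            assert lc.markov_project(v, M, n).sum() == pytest.approx(v.sum())

    def test_stationary_convergence(self):
        # irreducible aperiodic chain: v M^n -> stationary distribution
        M = np.array([[0.7, 0.2, 0.1], [0.3, 0.5, 0.2], [0.2, 0.3, 0.5]])
        evals, evecs = np.linalg.eig(M.T)
        stat = np.real(evecs[:, np.argmin(np.abs(evals - 1))])
        stat = stat / stat.sum()
        v = np.array([1.0, 0.0, 0.0])
        out = lc.markov_project(v, M, 500)
        assert np.max(np.abs(out - stat)) < 1e-6

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            lc.markov_project(np.ones(2), np.eye(3), 1)

    def test_negative_vector_rejected(self):
        with pytest.raises(ValidationError):
            lc.markov_project(np.array([-1.0, 1.0]), np.eye(2), 1)


class TestTransitionAreaMatrix:
    def test_row_sums_equal_current_counts(self):
        counts = np.array([1003.0, 250.0, 47.0])
        M = np.array([[0.6, 0.3, 0.1], [0.2, 0.7, 0.1], [0.05, 0.15, 0.8]])
        demand = transition_area_matrix(counts, M)
        np.testing.assert_array_equal(demand.sum(axis=1), counts.astype(int))
        assert np.all(demand >= 0)

    def test_expected_counts_within_one(self):
        counts = np.array([1000.0, 500.0])
        M = np.array([[0.33, 0.67], [0.5, 0.5]])
        demand = transition_area_matrix(counts, M)
        assert np.all(np.abs(demand - counts[:, None] * M) < 1.0)


class TestScaledMatrix:
    def make_tm(self, P, interval):
        counts = (np.asarray(P) * 1000).astype(int)
        return lc.TransitionMatrix(P, counts, tuple(range(len(P))), interval)

    def test_whole_multiple_is_matrix_power(self):
        P = np.array([[0.9, 0.1], [0.05, 0.95]])
        tm = self.make_tm(P, 10)
        np.testing.assert_allclose(_scaled_matrix(tm, 30), np.linalg.matrix_power(P, 3))

    def test_fraction_interpolates_between_powers(self):
        P = np.array([[0.9, 0.1], [0.05, 0.95]])
        tm = self.make_tm(P, 10)
        M = _scaled_matrix(tm, 15)
        expected = 0.5 * P + 0.5 * np.linalg.matrix_power(P, 2)
        np.testing.assert_allclose(M, expected / expected.sum(axis=1, keepdims=True))
        np.testing.assert_allclose(M.sum(axis=1), 1.0)


class TestTrainTransitionPotential:
    def drivers(self, shape, seed=0):
        rng = np.random.default_rng(seed)
        grad = np.linspace(0, 1, shape[0] * shape[1]).reshape(shape)
        noise = rng.random(shape)
        return [DriverField("elevation", grad, "m"), DriverField("slope", noise, "deg")]

    def test_threshold_labels_recovered(self):
        shape = (60, 60)
        drivers = self.drivers(shape)
        labels = (drivers[0].raster > 0.7).astype(float)
        model = lc.train_transition_potential(drivers, labels, seed=0,
                                              rms_target=0.01, max_iterations=500)
        assert model.testing_rmse < 0.1
        pot = model.predict_potential(drivers)
        assert pot[drivers[0].raster > 0.8].mean() > pot[drivers[0].raster < 0.5].mean()
        assert np.all((pot >= 0) & (pot <= 1))

    def test_pure_noise_rmse_near_label_sd(self):
        shape = (50, 50)
        rng = np.random.default_rng(1)
        drivers = [DriverField("slope", rng.random(shape), "deg")]
        labels = (rng.random(shape) < 0.5).astype(float)
        model = lc.train_transition_potential(drivers, labels, seed=1,
                                              rms_target=0.01, max_iterations=100)
        # balanced labels have sd 0.5; an uninformative model can't beat it by much
        assert abs(model.testing_rmse - 0.5) < 0.1

    def test_identical_seed_identical_weights(self):
        shape = (30, 30)
        drivers = self.drivers(shape, seed=2)
        labels = (drivers[0].raster > 0.5).astype(float)
        kw = dict(rms_target=0.01, max_iterations=50, seed=9)
        a = lc.train_transition_potential(drivers, labels, **kw)
        b = lc.train_transition_potential(drivers, labels, **kw)
        for wa, wb in zip(a.estimator.coefs_, b.estimator.coefs_):
            np.testing.assert_array_equal(wa, wb)

    def test_single_class_labels_error(self):
        drivers = self.drivers((10, 10))
        with pytest.raises(ValidationError):
            lc.train_transition_potential(drivers, np.zeros((10, 10)), seed=0)

    def test_rmse_reported_finite(self):
        drivers = self.drivers((30, 30))
        labels = (drivers[0].raster > 0.5).astype(float)
        model = lc.train_transition_potential(drivers, labels, seed=0, max_iterations=50)
        assert np.isfinite(model.training_rmse) and np.isfinite(model.testing_rmse)
        assert model.stopping["iterations_run"] <= 50


class TestAllocateChange:
    def test_zero_demand_identity(self, small_maps):
        m = small_maps[2020]
        k = len(m.class_codes)
        demand = np.diag(m.class_vector().astype(int))
        out = lc.allocate_change(m, None, demand, seed=0)
        np.testing.assert_array_equal(out.data, m.data)

    def test_exact_conversion_uniform_potential(self, map_factory):
        m = map_factory(np.ones((10, 10)))
        demand = np.array([[90, 10, 0], [0, 0, 0], [0, 0, 0]])
        out = lc.allocate_change(m, None, demand, seed=1)
        assert int(np.sum(out.data == 2)) == 10
        assert int(np.sum(out.data == 1)) == 90

    def test_determinism(self, map_factory):
        m = map_factory(np.ones((10, 10)))
        demand = np.array([[80, 15, 5], [0, 0, 0], [0, 0, 0]])
        a = lc.allocate_change(m, None, demand, seed=4)
        b = lc.allocate_change(m, None, demand, seed=4)
        np.testing.assert_array_equal(a.data, b.data)

    def test_monotone_gradient_selects_top_ranked(self, map_factory):
        m = map_factory(np.ones((8, 8)))
        gradient = np.arange(64, dtype=float).reshape(8, 8)
        demand = np.array([[52, 12, 0], [0, 0, 0], [0, 0, 0]])
        out = lc.allocate_change(m, {(1, 2): gradient}, demand, seed=0)
        # brute-force oracle: top-12 gradient pixels convert
        expected = np.argsort(-gradient.ravel(), kind="stable")[:12]
        converted = np.flatnonzero(out.data.ravel() == 2)
        assert set(converted) == set(expected)

    def test_tie_break_by_flat_index(self, map_factory):
        m = map_factory(np.ones((4, 4)))
        flat_potential = np.zeros((4, 4))
        demand = np.array([[13, 3, 0], [0, 0, 0], [0, 0, 0]])
        out = lc.allocate_change(m, {(1, 2): flat_potential}, demand, seed=0)
        converted = np.flatnonzero(out.data.ravel() == 2)
        np.testing.assert_array_equal(converted, [0, 1, 2])

    def test_excess_demand_names_transition(self, map_factory):
        m = map_factory(np.ones((3, 3)))
        demand = np.zeros((3, 3), dtype=int)
        demand[0, 1] = 100
        with pytest.raises(AllocationError, match="class 1"):
            lc.allocate_change(m, None, demand, seed=0)

    def test_pixel_count_conserved(self, small_maps):
        m = small_maps[2020]
        M = lc.estimate_transition_matrix(small_maps[2010], small_maps[2020], 10).P
        demand = transition_area_matrix(m.class_vector(), M)
        out = lc.allocate_change(m, None, demand, seed=2)
        assert out.class_vector().sum() == m.class_vector().sum()
        np.testing.assert_array_equal(out.class_vector(), demand.sum(axis=0))


class TestProjectLulc:
    def test_stationary_scenario_identity(self, small_maps):
        m = small_maps[2020]
        projected, probs = lc.project_lulc({2000: m, 2010: m}, None, 2020, seed=0)
        np.testing.assert_array_equal(projected.data, m.data)
        sums = np.nansum(probs.probabilities, axis=0)
        np.testing.assert_allclose(sums[m.valid_mask], 1.0, atol=1e-6)

    def test_projected_areas_track_markov_demand(self, small_maps):
        maps = {y: small_maps[y] for y in (2000, 2010)}
        projected, _ = lc.project_lulc(maps, None, 2030, seed=1)
        tm = lc.estimate_transition_matrix(small_maps[2000], small_maps[2010], 10)
        expected = lc.markov_project(small_maps[2010].class_vector(), tm.P, 2)
        np.testing.assert_allclose(projected.class_vector(), expected, atol=3)

    def test_projected_areas_within_multinomial_se_of_truth(self, small_scenario, small_maps):
        # known-matrix oracle: projection of epoch 3 from epochs 1-2
        M = small_scenario.true_transition_matrices[0]
        calib = {y: small_maps[y] for y in (2000, 2010)}
        projected, _ = lc.project_lulc(calib, None, 2020, seed=0)
        v = small_maps[2010].class_vector()
        expected = v @ M
        n = v.sum()
        for i in range(len(expected)):
            p = expected[i] / n
            se = np.sqrt(n * p * (1 - p))
            # estimation + allocation noise: 3 SE of the one-step multinomial
            assert abs(projected.class_vector()[i] - expected[i]) <= 3 * se + 3

    def test_target_before_last_observation_error(self, small_maps):
        with pytest.raises(ValidationError):
            lc.project_lulc({2000: small_maps[2000], 2010: small_maps[2010]}, None, 2005)

    def test_single_epoch_error(self, small_maps):
        with pytest.raises(ValidationError):
            lc.project_lulc({2010: small_maps[2010]}, None, 2020)
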
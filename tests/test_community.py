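import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lepmon import (accumulation_curve, cca, fit_reciprocal_log, ice_estimate,
                    morisita_horn, nmds)


class TestIce:
    def test_no_infrequent_species_equals_observed(self):
        M = np.ones((6, 12), dtype=int)  # every species in all 12 samples
        res = ice_estimate(M, cutoff=10)
        assert res.ice == pytest.approx(res.observed) == 6
        assert res.s_infrequent == 0

    def test_hand_worked_toy_matrix(self):
        # 5 species x 5 samples; with cutoff 3: one frequent (5 incidences),
        # one at 3, three uniques -> C=0.5, m_infr=3, gamma2=1, ICE=15
        M = np.array([[1, 1, 1, 1, 1],
                      [1, 1, 1, 0, 0],
                      [1, 0, 0, 0, 0],
                      [0, 1, 0, 0, 0],
                      [0, 0, 1, 0, 0]])
        res = ice_estimate(M, cutoff=3)
        assert res.s_frequent == 1 and res.s_infrequent == 4
        assert res.coverage == pytest.approx(0.5)
        assert res.cv_squared == pytest.approx(1.0)
        assert res.ice == pytest.approx(15.0)

    def test_ice_at_least_observed(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            M = rng.random((30, 15)) < rng.uniform(0.05, 0.5)
            M = M[M.sum(axis=1) > 0]
            if M.shape[0] < 2:
                continue
            try:
                res = ice_estimate(M)
            except ValueError:
                continue  # zero-coverage case is declared undefined
            assert res.ice >= res.observed - 1e-9

    def test_zero_coverage_undefined(self):
        M = np.eye(4, dtype=int)  # every species a unique
        with pytest.raises(ValueError, match="undefined"):
            ice_estimate(M)


class TestAccumulation:
    def test_single_sample(self):
        M = np.array([[1], [0], [1]])
        with pytest.raises(ValueError):
            ice_estimate(M)  # needs 2 samples, accumulation does not
        curve = accumulation_curve(M, n_rand=10, seed=0)
        assert curve["mean_richness"].iloc[0] == 2

    def test_identical_samples_flat(self):
        M = np.tile([[1], [1], [0]], (1, 6))
        curve = accumulation_curve(M, n_rand=20, seed=1)
        np.testing.assert_allclose(curve["mean_richness"], 2.0)

    def test_monotone_and_terminates_at_observed(self):
        rng = np.random.default_rng(2)
        M = rng.random((40, 20)) < 0.15
        observed = int((M.sum(axis=1) > 0).sum())
        curve = accumulation_curve(M, n_rand=50, seed=3)
        assert (np.diff(curve["mean_richness"]) >= -1e-12).all()
        assert curve["mean_richness"].iloc[-1] == pytest.approx(observed)


class TestCurveFit:
    def test_exact_recovery(self):
        x = np.linspace(5, 500, 40)
        y = 1.0 / (0.5 - 0.05 * np.log(x))
        fit = fit_reciprocal_log(x, y)
        assert fit.a == pytest.approx(0.5, abs=1e-6)
        assert fit.b == pytest.approx(-0.05, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.comparison[0][0] == "reciprocal_log"

    def test_constant_positive_y(self):
        x = np.linspace(2, 100, 25)
        fit = fit_reciprocal_log(x, np.full(25, 4.0))
        assert fit.b == pytest.approx(0.0, abs=1e-6)
        assert 1 / fit.a == pytest.approx(4.0, abs=1e-6)

    def test_zero_y_rejected(self):
        with pytest.raises(ValueError):
            fit_reciprocal_log(np.array([2., 3, 4]), np.zeros(3))

    def test_non_increasing_x_rejected(self):
        with pytest.raises(ValueError):
            fit_reciprocal_log(np.array([5., 4, 6]), np.array([1., 2, 3]))

    def test_ranking_deterministic(self):
        x = np.linspace(10, 400, 30)
        y = 4 * (1 - np.exp(-0.01 * x))
        a = fit_reciprocal_log(x, y)
        b = fit_reciprocal_log(x, y)
        assert a.comparison == b.comparison


class TestMorisitaHorn:
    def test_hand_worked_value(self):
        assert morisita_horn([10, 0, 10], [5, 5, 10]) == pytest.approx(300 / 350)

    def test_proportional_is_one(self):
        a = np.array([3., 7, 1, 9])
        assert morisita_horn(a, 3 * a) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        assert morisita_horn([5, 0, 2, 0], [0, 3, 0, 8]) == 0.0

    @given(st.lists(st.integers(0, 50), min_size=3, max_size=8),
           st.integers(1, 20))
    @settings(deadline=None, max_examples=40)
    def test_symmetric_and_scale_invariant(self, counts, factor):
        a = np.array(counts, dtype=float)
        b = np.roll(a, 1) + 1
        if a.sum() == 0:
            return
        assert morisita_horn(a, b) == pytest.approx(morisita_horn(b, a))
        assert morisita_horn(a * factor, b) == pytest.approx(
            morisita_horn(a, b))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            morisita_horn([0, 0], [1, 2])


class TestNmds:
    def test_gradient_recovered(self):
        # sites along an unsaturated 1-D abundance gradient (all site pairs
        # share species, so Bray-Curtis does not plateau); axis 1 sorts them
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_sites, n_species = 12, 25
            grad = np.linspace(0, 10, n_sites)
            optima = rng.uniform(-2, 12, n_species)
            mu = 200 * np.exp(-((grad[:, None] - optima[None, :]) ** 2) / 30)
            comm = rng.poisson(mu).astype(float)
            comm = comm[:, comm.sum(axis=0) > 0]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = nmds(pd.DataFrame(comm), seed=seed)
            rho = abs(stats.spearmanr(res.scores.iloc[:, 0], grad).statistic)
            hits += rho == 1.0
        assert hits >= 9

    def test_identical_rows_degenerate(self):
        comm = pd.DataFrame([[5, 5, 0], [5, 5, 0], [0, 1, 9], [2, 2, 2]],
                            dtype=float)
        with pytest.warns(UserWarning, match="degenerate"):
            res = nmds(comm, seed=0)
        assert res.degenerate

    def test_too_few_objects(self):
        with pytest.raises(ValueError):
            nmds(pd.DataFrame([[1, 2], [3, 4]]), seed=0)

    def test_stress_nonnegative_and_reproducible(self, records):
        annual = records.groupby(["year", "species_id"])["count"].sum().unstack(
            fill_value=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = nmds(annual, seed=5)
            b = nmds(annual, seed=5)
        assert a.stress >= 0
        assert a.stress == b.stress


class TestCca:
    def _community(self, seed=0, n=24, groups=False):
        rng = np.random.default_rng(seed)
        if groups:
            mu = np.vstack([np.tile([40, 5, 5, 40, 1, 1.], (n // 2, 1)),
                            np.tile([5, 40, 40, 5, 1, 1.], (n // 2, 1))])
        else:
            mu = np.full((n, 6), 15.0)
        comm = pd.DataFrame(rng.poisson(mu).astype(float),
                            index=[f"s{i}" for i in range(n)])
        return rng, comm

    def test_orthogonal_covariate_low_fraction(self):
        rng, comm = self._community(seed=1)
        X = pd.DataFrame({"noise": rng.normal(size=len(comm))},
                         index=comm.index)
        res = cca(comm, X, n_perm=99, seed=0)
        assert res.constrained_fraction < 0.25
        assert res.p_value > 0.05

    def test_group_structure_captured(self):
        rng, comm = self._community(seed=2, groups=True)
        X = pd.DataFrame({"group": np.repeat([0.0, 1.0], len(comm) // 2)},
                         index=comm.index)
        res = cca(comm, X, n_perm=99, seed=0)
        assert res.constrained_fraction > 0.5
        assert res.p_value <= 0.05

    def test_p_value_in_unit_interval(self):
        rng, comm = self._community(seed=3)
        X = pd.DataFrame({"a": rng.normal(size=len(comm)),
                          "b": rng.normal(size=len(comm))}, index=comm.index)
        res = cca(comm, X, n_perm=49, seed=1)
        assert 0 < res.p_value <= 1

    def test_collinear_covariates_dropped(self):
        rng, comm = self._community(seed=4)
        z = rng.normal(size=len(comm))
        X = pd.DataFrame({"a": z, "b": 2 * z}, index=comm.index)
        with pytest.warns(UserWarning, match="collinear"):
            res = cca(comm, X, n_perm=29, seed=2)
        assert res.dropped_covariates == ["b"]
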
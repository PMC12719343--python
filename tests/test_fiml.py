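import itertools
import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from conftest import UNIVARIATE, simulate, univariate_truth
from twinpath.cohort import FamilyRecord, Member, TwinDataset
from twinpath.fiml import (FimlError, FimlObjective,
                           conditional_ordinal_moments, dataset_m2ll,
                           family_loglik, mvn_rectangle_probability)
from twinpath.model import VariableSpec, build_ace_model, \
    model_from_components


def random_corr(rng, k):
    A = rng.normal(size=(k, k))
    cov = A @ A.T + k * np.eye(k)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


class TestRectangleProbability:
    def test_total_mass_is_one(self):
        cov = random_corr(np.random.default_rng(0), 3)
        p = mvn_rectangle_probability(
            np.zeros(3), cov, [-np.inf] * 3, [np.inf] * 3)
        assert p == pytest.approx(1.0)

    def test_univariate_symmetry(self):
        p = mvn_rectangle_probability([0.0], [[1.0]], [-np.inf], [0.0])
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_orthant_arcsine_closed_form(self):
        # P(X1>0, X2>0) = 1/4 + arcsin(rho)/(2 pi); at rho=1/2 this is 1/3
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        p = mvn_rectangle_probability([0, 0], cov, [0, 0],
                                      [np.inf, np.inf])
        assert p == pytest.approx(1.0 / 3.0, abs=1e-6)
        for rho in (-0.7, 0.2, 0.85):
            cov = np.array([[1.0, rho], [rho, 1.0]])
            p = mvn_rectangle_probability([0, 0], cov, [0, 0],
                                          [np.inf, np.inf])
            assert p == pytest.approx(0.25 + math.asin(rho) / (2 * math.pi),
                                      abs=1e-6)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_against_monte_carlo_oracle(self, k):
        rng = np.random.default_rng(40 + k)
        n_mc = 400_000
        for rep in range(12):
            cov = random_corr(rng, k)
            mean = rng.normal(scale=0.5, size=k)
            lower = rng.normal(size=k) - 1.0
            upper = lower + rng.uniform(0.5, 3.0, size=k)
            lower[rng.random(k) < 0.3] = -np.inf
            upper[rng.random(k) < 0.3] = np.inf
            bad = lower >= upper
            lower[bad] = -np.inf
            p = mvn_rectangle_probability(mean, cov, lower, upper)
            x = rng.multivariate_normal(mean, cov, size=n_mc)
            inside = np.all((x > lower) & (x < upper), axis=1)
            p_mc = inside.mean()
            se = math.sqrt(max(p_mc * (1 - p_mc), 1e-12) / n_mc)
            assert abs(p - p_mc) < 3 * se + 1e-5

    def test_matches_scipy_cdf_inclusion_exclusion(self):
        # independent dual route through scipy's own MVN CDF
        rng = np.random.default_rng(9)
        for k in (2, 3, 4):
            cov = random_corr(rng, k)
            lower = rng.normal(size=k) - 1.0
            upper = lower + rng.uniform(1.0, 2.5, size=k)
            p = mvn_rectangle_probability(np.zeros(k), cov, lower, upper)
            ref = 0.0
            mvn = multivariate_normal(mean=np.zeros(k), cov=cov)
            for corners in itertools.product([0, 1], repeat=k):
                pt = np.where(np.array(corners) == 1, upper, lower)
                ref += (-1) ** (k - sum(corners)) * mvn.cdf(pt)
            assert p == pytest.approx(ref, abs=5e-5)

    def test_dimension_limit_and_bad_bounds(self):
        with pytest.raises(FimlError, match="dimension"):
            mvn_rectangle_probability(
                np.zeros(9), np.eye(9), np.zeros(9) - 1, np.zeros(9) + 1)
        with pytest.raises(FimlError, match="lower"):
            mvn_rectangle_probability([0.0], [[1.0]], [1.0], [0.0])

    def test_doubly_infinite_coordinates_marginalized(self):
        cov = random_corr(np.random.default_rng(2), 3)
        p3 = mvn_rectangle_probability(
            np.zeros(3), cov, [-np.inf, -1.0, -np.inf],
            [np.inf, 1.0, np.inf])
        p1 = mvn_rectangle_probability([0.0], [[1.0]], [-1.0], [1.0])
        assert p3 == pytest.approx(p1, abs=1e-9)


class TestConditionalMoments:
    def test_independence_leaves_marginals(self):
        cov = np.diag([1.0, 2.0, 3.0])
        mean = np.array([0.5, -1.0, 2.0])
        cm, cc = conditional_ordinal_moments(mean, cov, [(0, 5.0)])
        assert np.allclose(cm, mean[1:])
        assert np.allclose(cc, np.diag([2.0, 3.0]))

    def test_bivariate_textbook_identity(self):
        rho = 0.6
        cov = np.array([[1.0, rho], [rho, 1.0]])
        cm, cc = conditional_ordinal_moments([0, 0], cov, [(0, 1.0)])
        assert cm[0] == pytest.approx(rho)
        assert cc[0, 0] == pytest.approx(1 - rho * rho)

    def test_six_dimensional_vs_matrix_inverse_oracle(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(6, 6))
        cov = A @ A.T + 6 * np.eye(6)
        mean = rng.normal(size=6)
        obs = [(1, 0.3), (4, -1.1), (5, 0.7)]
        cm, cc = conditional_ordinal_moments(mean, cov, obs)
        idx_c = [1, 4, 5]
        idx_r = [0, 2, 3]
        Scc_inv = np.linalg.inv(cov[np.ix_(idx_c, idx_c)])
        Src = cov[np.ix_(idx_r, idx_c)]
        vals = np.array([v for _, v in obs])
        ref_m = mean[idx_r] + Src @ Scc_inv @ (vals - mean[idx_c])
        ref_c = cov[np.ix_(idx_r, idx_r)] - Src @ Scc_inv @ Src.T
        assert np.allclose(cm, ref_m)
        assert np.allclose(cc, ref_c)

    def test_duplicate_indices_rejected(self):
        with pytest.raises(FimlError):
            conditional_ordinal_moments(
                [0, 0], np.eye(2), [(0, 1.0), (0, 2.0)])


CONT2 = (VariableSpec("x1", "continuous"), VariableSpec("x2", "continuous"))


def _cont_model(rng):
    m = build_ace_model(CONT2, active_components=("A", "E"))
    th = m.pack() + rng.uniform(-0.2, 0.4, size=m.n_free_params)
    return m.unpack(th)


class TestFamilyLoglik:
    def test_all_missing_family_contributes_zero(self):
        m = build_ace_model(UNIVARIATE, active_components=("A", "E"))
        fam = FamilyRecord("F1", "MZ", [Member({"y": np.nan}, {}),
                                        Member({"y": np.nan}, {})])
        lv = family_loglik(fam, m)
        assert lv.loglik == 0.0
        assert lv.n_families_used == 0

    def test_continuous_pair_matches_closed_form_density(self):
        rng = np.random.default_rng(8)
        m = _cont_model(rng)
        mom = m.expected_moments("DZ")
        x = np.array([0.4, -1.2, 0.9, 0.1])
        fam = FamilyRecord("F1", "DZ", [
            Member({"x1": x[0], "x2": x[1]}, {}),
            Member({"x1": x[2], "x2": x[3]}, {}),
        ])
        lv = family_loglik(fam, m)
        ref = multivariate_normal(mean=mom.mean, cov=mom.cov).logpdf(x)
        assert lv.loglik == pytest.approx(ref, abs=1e-10)

    def test_affected_singleton_at_zero_threshold(self):
        m = build_ace_model(UNIVARIATE, active_components=("A", "E"))
        m.thresholds["y"] = 0.0
        fam = FamilyRecord("F1", "MZ", [Member({"y": 1.0}, {})])
        lv = family_loglik(fam, m)
        assert lv.loglik == pytest.approx(math.log(0.5), abs=1e-9)


class TestDatasetM2ll:
    def _tiny_ds(self):
        truth = model_from_components(
            (VariableSpec("a", "binary_liability"),
             VariableSpec("b", "binary_liability")),
            {"a": {"A": 0.5, "E": 0.5}, "b": {"A": 0.3, "E": 0.7}},
            {"A": np.array([[1.0, 0.6], [0.6, 1.0]]),
             "E": np.array([[1.0, 0.2], [0.2, 1.0]])},
            thresholds={"a": 0.3, "b": -0.4})
        fams = [
            FamilyRecord("F1", "MZ", [Member({"a": 1.0, "b": 0.0}, {}),
                                      Member({"a": 0.0, "b": 0.0}, {})]),
            FamilyRecord("F2", "DZ", [Member({"a": 1.0, "b": 1.0}, {}),
                                      Member({"a": 1.0, "b": 0.0}, {})]),
            FamilyRecord("F3", "DZ", [Member({"a": 0.0, "b": np.nan}, {}),
                                      Member({"a": np.nan, "b": 1.0}, {})]),
        ]
        ds = TwinDataset(truth.variables, fams)
        return truth, ds

    def test_duplicated_dataset_doubles_m2ll(self):
        truth, ds = self._tiny_ds()
        twice = TwinDataset(ds.variables, ds.families + [
            FamilyRecord(f.family_id + "b", f.zygosity, f.members)
            for f in ds.families])
        assert dataset_m2ll(truth, twice) == pytest.approx(
            2.0 * dataset_m2ll(truth, ds), rel=1e-12)

    def test_family_order_invariance(self):
        truth, ds = self._tiny_ds()
        rev = TwinDataset(ds.variables, list(reversed(ds.families)))
        assert dataset_m2ll(truth, rev) == pytest.approx(
            dataset_m2ll(truth, ds), rel=1e-13)

    def test_matches_monte_carlo_likelihood_oracle(self):
        truth, ds = self._tiny_ds()
        rng = np.random.default_rng(77)
        n_mc = 2_000_000
        ll_mc = 0.0
        var_mc = 0.0
        for fam in ds.families:
            mom = truth.expected_moments(fam.zygosity)
            draws = rng.multivariate_normal(mom.mean, mom.cov, size=n_mc)
            match = np.ones(n_mc, dtype=bool)
            for m_i, member in enumerate(fam.members):
                for v_i, name in enumerate(("a", "b")):
                    y = member.phenotypes.get(name, np.nan)
                    if not np.isfinite(y):
                        continue
                    liab = draws[:, m_i * 2 + v_i]
                    tau = truth.thresholds[name]
                    match &= (liab > tau) if y == 1.0 else (liab <= tau)
            p = match.mean()
            ll_mc += math.log(p)
            var_mc += (1 - p) / (n_mc * p)
        m2ll = dataset_m2ll(truth, ds)
        se = 2.0 * math.sqrt(var_mc)
        assert abs(m2ll - (-2.0 * ll_mc)) < 3 * se

    def test_pattern_probabilities_sum_to_one(self):
        truth, _ = self._tiny_ds()
        total = 0.0
        for pattern in itertools.product([0.0, 1.0], repeat=4):
            fam = FamilyRecord("F", "DZ", [
                Member({"a": pattern[0], "b": pattern[1]}, {}),
                Member({"a": pattern[2], "b": pattern[3]}, {})])
            total += math.exp(family_loglik(fam, truth).loglik)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_likelihood_prefers_generating_parameters(self):
        truth = univariate_truth(A=0.5, prevalence=0.3)
        ds, _ = simulate(truth, 1500, 1500, seed=31)
        base = dataset_m2ll(truth, ds)
        rng = np.random.default_rng(4)
        worse = 0
        for _ in range(8):
            pert = truth.copy()
            pert.thresholds["y"] += rng.normal(0, 0.15)
            pert.paths["A"][0, 0] = np.clip(
                pert.paths["A"][0, 0] + rng.normal(0, 0.15), 0.05, 0.95)
            pert._apply_scale_constraint()
            if dataset_m2ll(pert, ds) > base:
                worse += 1
        assert worse >= 7
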
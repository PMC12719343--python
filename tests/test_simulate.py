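import math

import numpy as np
import pytest
from scipy.special import ndtr

from conftest import UNIVARIATE, simulate, trivariate_truth, univariate_truth
from twinpath.cohort import CohortError, write_cohort
from twinpath.model import VariableSpec, model_from_components
from twinpath.simulate import (SimulationConfig, SimulationError,
                               apply_gating, simulate_ace_cohort,
                               simulate_polygenic_pairs, study_config)


def _corr(a, b):
    return float(np.corrcoef(a, b)[0, 1])


@pytest.fixture(scope="module")
def big_truth():
    variables = (VariableSpec("y", "binary_liability"),)
    model = model_from_components(
        variables, {"y": {"A": 0.5, "C": 0.2, "E": 0.3}}, {},
        thresholds={"y": 0.9945})
    _, truth = simulate(model, 50_000, 50_000, seed=55)
    return truth


class TestLatentSharing:

    def test_mz_additive_values_identical(self, big_truth):
        a = big_truth.component_values["MZ"]["A"][:, :, 0]
        assert np.array_equal(a[:, 0], a[:, 1])

    def test_dz_additive_correlation_half(self, big_truth):
        a = big_truth.component_values["DZ"]["A"][:, :, 0]
        r = _corr(a[:, 0], a[:, 1])
        se = 1.0 / math.sqrt(a.shape[0])
        assert abs(r - 0.5) < 3 * se

    def test_shared_environment_duplicated(self, big_truth):
        for zyg in ("MZ", "DZ"):
            c = big_truth.component_values[zyg]["C"][:, :, 0]
            assert np.array_equal(c[:, 0], c[:, 1])

    def test_unique_environment_uncorrelated(self, big_truth):
        for zyg in ("MZ", "DZ"):
            e = big_truth.component_values[zyg]["E"][:, :, 0]
            r = _corr(e[:, 0], e[:, 1])
            assert abs(r) < 3.0 / math.sqrt(e.shape[0])

    def test_mz_dz_covariance_ratio_two(self, big_truth):
        covs = {}
        for zyg in ("MZ", "DZ"):
            a = big_truth.component_values[zyg]["A"][:, :, 0]
            covs[zyg] = float(np.cov(a[:, 0], a[:, 1])[0, 1])
        assert covs["MZ"] / covs["DZ"] == pytest.approx(
            2.0, abs=3 * 0.01 * 2)


class TestThresholdCalibration:
    def test_prevalence_matches_normal_cdf(self):
        tau = 0.9945
        truth = model_from_components(
            UNIVARIATE, {"y": {"A": 0.4, "E": 0.6}}, {},
            thresholds={"y": tau})
        ds, _ = simulate(truth, 10_000, 10_000, seed=71)
        vals = ds.values("y")
        obs = vals[np.isfinite(vals)]
        expected = float(ndtr(-tau))
        se = math.sqrt(expected * (1 - expected) / obs.size)
        assert abs(obs.mean() - expected) < 3 * se
        assert expected == pytest.approx(0.16, abs=0.001)

    def test_independent_phenotype_has_no_twin_correlation(self):
        truth = model_from_components(
            UNIVARIATE, {"y": {"E": 1.0}}, {}, thresholds={"y": 0.5})
        ds, _ = simulate(truth, 4000, 4000, seed=72)
        for zyg in ("MZ", "DZ"):
            pairs = ds.pair_values("y", zyg)
            r = _corr(pairs[:, 0], pairs[:, 1])
            assert abs(r) < 3.0 / math.sqrt(pairs.shape[0])


class TestDeterminism:
    def test_identical_seed_identical_bytes(self, tmp_path):
        outs = []
        for _ in range(2):
            ds, _ = simulate(trivariate_truth(), 60, 60, seed=123,
                             singleton_fraction=0.2,
                             missing_fraction={"prs": 0.1})
            buf = tmp_path / "o.csv"
            write_cohort(ds, str(buf))
            outs.append(buf.read_bytes())
        assert outs[0] == outs[1]

    def test_different_seed_differs(self):
        ds1, _ = simulate(univariate_truth(), 50, 50, seed=1)
        ds2, _ = simulate(univariate_truth(), 50, 50, seed=2)
        assert not np.array_equal(ds1.values("y"), ds2.values("y"),
                                  equal_nan=True)


class TestPolygenicPairs:
    def test_mz_scores_identical(self):
        _, prs = simulate_polygenic_pairs(2000, "MZ", 300, seed=5)
        assert np.array_equal(prs[:, 0], prs[:, 1])

    def test_dz_score_correlation_half(self):
        _, prs = simulate_polygenic_pairs(20_000, "DZ", 1000, seed=6)
        r = _corr(prs[:, 0], prs[:, 1])
        assert abs(r - 0.5) < 3.0 / math.sqrt(prs.shape[0])

    def test_single_locus_matches_exhaustive_enumeration(self):
        # Sibling allele-count correlation at one locus, freq 1/2, by
        # enumerating all parental genotype pairs and transmissions.
        freq = 0.5
        hw = {0: (1 - freq) ** 2, 1: 2 * freq * (1 - freq), 2: freq ** 2}
        transmit = {0: {0: 1.0}, 2: {1: 1.0}, 1: {0: 0.5, 1: 0.5}}
        moments = np.zeros(5)  # E[s1], E[s2], E[s1 s2], E[s1^2], E[s2^2]
        for gm, pm in hw.items():
            for gf, pf in hw.items():
                pg = pm * pf
                for a1m, p1m in transmit[gm].items():
                    for a1f, p1f in transmit[gf].items():
                        for a2m, p2m in transmit[gm].items():
                            for a2f, p2f in transmit[gf].items():
                                w = pg * p1m * p1f * p2m * p2f
                                s1, s2 = a1m + a1f, a2m + a2f
                                moments += w * np.array(
                                    [s1, s2, s1 * s2, s1 ** 2, s2 ** 2])
        e1, e2, e12, e11, e22 = moments
        rho_exact = (e12 - e1 * e2) / math.sqrt(
            (e11 - e1 ** 2) * (e22 - e2 ** 2))
        assert rho_exact == pytest.approx(0.5, abs=1e-12)
        g, _ = simulate_polygenic_pairs(60_000, "DZ", 1, seed=8,
                                        freq_range=(0.5, 0.5))
        # weights are a scalar multiple at one locus; correlation unaffected
        r = _corr(g[:, 0], g[:, 1])
        assert abs(r - rho_exact) < 3.0 / math.sqrt(g.shape[0])

    def test_latent_and_locus_routes_agree(self):
        variables = (VariableSpec("prs", "continuous",
                                  components_allowed=("A",)),)
        model = model_from_components(variables, {"prs": {"A": 1.0}}, {})
        _, truth = simulate(model, 20_000, 20_000, seed=9)
        latent_dz = truth.component_values["DZ"]["A"][:, :, 0]
        r_latent = _corr(latent_dz[:, 0], latent_dz[:, 1])
        _, prs = simulate_polygenic_pairs(20_000, "DZ", 800, seed=10)
        r_locus = _corr(prs[:, 0], prs[:, 1])
        assert abs(r_latent - r_locus) < 6.0 / math.sqrt(20_000)

    def test_invalid_inputs(self):
        with pytest.raises(SimulationError):
            simulate_polygenic_pairs(10, "OS", 5, seed=1)
        with pytest.raises(SimulationError):
            simulate_polygenic_pairs(10, "MZ", 0, seed=1)


class TestGating:
    def _gated_ds(self, seed=44):
        return simulate(trivariate_truth(), 400, 400, seed=seed,
                        gating_screen="mdd", gating_dependents=("si",))

    def test_unendorsed_screen_blanks_dependents(self):
        ds, _ = self._gated_ds()
        for fam in ds.families:
            for m in fam.members:
                if m.phenotypes["mdd"] == 0.0:
                    assert np.isnan(m.phenotypes["si"])

    def test_observed_fraction_tracks_screen_prevalence(self):
        ds, _ = self._gated_ds()
        mdd = ds.values("mdd")
        si = ds.values("si")
        prev = np.nanmean(mdd)
        frac = np.isfinite(si).mean()
        n = np.isfinite(mdd).sum()
        assert abs(frac - prev) < 3 * math.sqrt(prev * (1 - prev) / n)

    def test_all_endorsed_is_identity(self):
        ds, _ = simulate(trivariate_truth(), 30, 30, seed=45)
        for fam in ds.families:
            for m in fam.members:
                m.phenotypes["mdd"] = 1.0
        out = apply_gating(ds, "mdd", ("si",))
        assert np.allclose(out.values("si"), ds.values("si"),
                           equal_nan=True)

    def test_screen_cannot_be_dependent(self):
        ds, _ = simulate(trivariate_truth(), 10, 10, seed=46)
        with pytest.raises(CohortError):
            apply_gating(ds, "mdd", ("mdd", "si"))


class TestConfigValidation:
    def test_nonunit_ordinal_variance_rejected(self):
        truth = univariate_truth()
        truth.paths["A"][0, 0] = 0.9
        truth.paths["E"][0, 0] = 0.9  # variance 1.62: unidentified scale
        with pytest.raises(SimulationError, match="variance"):
            simulate_ace_cohort(SimulationConfig(
                n_mz_pairs=10, n_dz_pairs=10, model=truth, seed=1))

    def test_seed_mandatory_and_counts_nonnegative(self):
        with pytest.raises(SimulationError):
            SimulationConfig(n_mz_pairs=-1, n_dz_pairs=0,
                             model=univariate_truth(), seed=1)
        with pytest.raises(SimulationError):
            SimulationConfig(n_mz_pairs=1, n_dz_pairs=1,
                             model=univariate_truth(), seed=None)


@pytest.fixture(scope="module")
def study_ds():
    ds, _ = simulate_ace_cohort(study_config(seed=90))
    return ds


class TestStudyConfig:

    def test_study_scale_counts(self, study_ds):
        mdd_pairs = study_ds.pair_values("mdd")
        complete = int(np.isfinite(mdd_pairs).all(axis=1).sum())
        assert 820 <= complete <= 980        # ~900 complete diagnosis pairs
        si_pairs = study_ds.pair_values("si")
        si_complete = int(np.isfinite(si_pairs).all(axis=1).sum())
        assert 100 <= si_complete <= 220     # ~150 complete item pairs

    def test_diagnosis_prevalence_in_study_range(self, study_ds):
        vals = study_ds.values("mdd")
        prev = np.nanmean(vals)
        assert 0.14 <= prev <= 0.23

    def test_conditional_item_endorsement(self, study_ds):
        mdd = study_ds.values("mdd")
        rates = {}
        for item in ("si", "sp", "sa"):
            v = study_ds.values(item)
            mask = np.isfinite(v) & (mdd == 1)
            rates[item] = float(np.nanmean(v[mask]))
        assert 0.30 <= rates["si"] <= 0.48
        assert 0.08 <= rates["sp"] <= 0.22
        assert 0.02 <= rates["sa"] <= 0.13

    def test_ages_within_cohort_range(self, study_ds):
        ages = [m.covariates["age"] for f in study_ds.families
                for m in f.members]
        assert min(ages) >= 19.0 and max(ages) <= 39.0
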
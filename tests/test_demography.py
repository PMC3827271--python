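"""Priors, calibration, TMRCA regression, classification, and reporting."""

import math
import warnings

import numpy as np
import pytest

from ursabc import demography as dm
from ursabc.coalsim import DemographicParams
from ursabc.kabc import PosteriorEstimate
from ursabc.seqio import HaplotypeMatrix
from ursabc.sumstats import mtdna_binspec


class TestPriors:
    def test_log_scale_variance_is_ln2(self):
        spec = dm.PriorSpec()
        assert spec.log_sigma2 == pytest.approx(math.log(2.0))
        assert spec.log_mu(30_000) == pytest.approx(math.log(30_000) - math.log(2) / 2)

    def test_draws_are_positive(self, rng):
        for _ in range(100):
            p = dm.sample_priors(dm.PriorSpec(), rng)
            assert p.n_uar > 0 and p.n_uma > 0 and p.t_div > 0

    def test_moments_match_mu_and_mu_squared(self, rng):
        mu = 30_000.0
        draws = np.array([dm.sample_priors(dm.PriorSpec(mu_n_uar=mu), rng).n_uar
                          for _ in range(100_000)])
        assert draws.mean() == pytest.approx(mu, rel=0.02)
        assert draws.var() == pytest.approx(mu**2, rel=0.10)

    def test_invalid_mean_rejected(self):
        with pytest.raises(ValueError):
            dm.PriorSpec(mu_n_uar=0.0)


class TestTajimaNei:
    def test_identical_sequences_have_zero_distance(self):
        assert dm.tajima_nei_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_small_divergence_approximates_p(self, rng):
        bases = np.array(list("ACGT"))
        a = "".join(rng.choice(bases, size=2000))
        b = list(a)
        for i in rng.choice(2000, size=10, replace=False):
            b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
        d = dm.tajima_nei_distance(a, "".join(b))
        assert d == pytest.approx(10 / 2000, rel=0.05)

    def test_matches_independent_formula_evaluation(self, rng):
        bases = "ACGT"
        a = "".join(rng.choice(list(bases), size=1000))
        b = list(a)
        for i in rng.choice(1000, size=60, replace=False):
            b[i] = rng.choice([c for c in bases if c != b[i]])
        b = "".join(b)
        # independent step-by-step evaluation of the published correction
        n = len(a)
        counts = {c: (a.count(c) + b.count(c)) / (2 * n) for c in bases}
        x = {}
        for i in range(n):
            if a[i] != b[i]:
                key = tuple(sorted((a[i], b[i])))
                x[key] = x.get(key, 0) + 1 / n
        p = sum(x.values())
        h = sum(v**2 / (2 * counts[k[0]] * counts[k[1]]) for k, v in x.items())
        b_coef = 0.5 * (1 - sum(v**2 for v in counts.values()) + p**2 / h)
        expected = -b_coef * math.log(1 - p / b_coef)
        assert dm.tajima_nei_distance(a, b) == pytest.approx(expected, rel=1e-12)

    def test_gapped_columns_are_skipped(self):
        assert dm.tajima_nei_distance("AC-T", "ACNT") == 0.0


class TestCalibration:
    def test_zero_distance_gives_zero_rate(self):
        assert dm.calibrate_mutation_rate(0.0, 12e6).rate == 0.0

    def test_worked_example(self):
        est = dm.calibrate_mutation_rate(0.0631, 12e6, 10.0)
        assert est.rate == pytest.approx(0.0631 / (2 * 1.2e6))

    def test_shipped_calibration_constants(self):
        assert dm.ADNA_MUTATION_RATE == 1.314e-8
        assert dm.MTDNA_MUTATION_RATE_SET1 == 7.036e-8
        assert dm.MTDNA_MUTATION_RATE_SET2 == 7.838e-8
        assert dm.GENERATION_YEARS == 10.0


class TestBranchClassification:
    def matrix(self, rows, n_uar=3, n_uma=5):
        return HaplotypeMatrix(data=np.array(rows), site_positions=np.arange(1, len(rows) + 1),
                               n_uar=n_uar, n_uma=n_uma)

    def test_classification_rules(self):
        m = self.matrix([
            [1, 1, 0, 0, 0, 0, 0, 0],  # brown only
            [0, 0, 0, 1, 1, 1, 1, 1],  # fixed derived in polar, absent in brown
            [0, 0, 0, 1, 1, 0, 0, 0],  # polymorphic within polar
            [1, 0, 0, 1, 0, 0, 0, 0],  # shared
        ])
        counts = dm.classify_branch_mutations(m, brown=[0, 1, 2], polar=[3, 4, 5, 6, 7])
        assert counts.brown_lineage == 1
        assert counts.ancestral_polar == 1
        assert counts.polar_lineage == 1
        assert counts.shared == 1
        assert counts.total == m.n_sites

    def test_empty_group_rejected(self):
        m = self.matrix([[1, 0, 0, 0, 0, 0, 0, 0]])
        with pytest.raises(ValueError):
            dm.classify_branch_mutations(m, brown=[], polar=[1])


class TestLineageSpecs:
    def test_keyword_specs(self):
        assert dm.resolve_lineages("uma", 9, 26) == list(range(9, 35))
        assert dm.resolve_lineages("uar1+uma", 9, 26) == [0] + list(range(9, 35))

    def test_absent_samples_rejected(self):
        with pytest.raises(ValueError):
            dm.resolve_lineages([0, 99], 9, 26)
        with pytest.raises(ValueError):
            dm.resolve_lineages([3], 9, 26)


class TestTmrcaAbc:
    def test_pair_tmrca_recovers_analytic_mean(self, rng):
        """Two lineages in a constant-size population of K chromosomes have
        E[TMRCA] = K generations; the regression's averaged posterior mean
        over observations drawn from the same model must sit near K."""
        k = 20_000.0
        config = dm.ModelConfig(mode="mtDNA", n_loci=1, locus_length=3000,
                                n_uar=1, n_uma=1, mu_per_site=5e-8)
        fitted = DemographicParams(n_uar=k, n_uma=k, t_div=1e-6)
        model = dm.make_model(config)
        estimates = []
        for trial in range(50):
            obs = model(fitted.as_array(), rng)
            est = dm.estimate_tmrca_abc(obs, fitted, [0, 1], config, n=300,
                                        seed=rng, lambda_grid=[1e-4, 1e-2],
                                        cv_subsample=300)
            estimates.append(est.tmrca_years / dm.GENERATION_YEARS)
        assert np.mean(estimates) == pytest.approx(k, rel=0.15)
        assert min(estimates) > 0

    def test_recombining_model_rejected(self):
        config = dm.ModelConfig(mode="aDNA")
        with pytest.raises(ValueError):
            dm.estimate_tmrca_abc(np.zeros(64), DemographicParams(1e4, 1e4, 1e5),
                                  "uma", config, n=10, seed=0)


class TestInferenceContracts:
    def test_layout_mismatch_rejected(self):
        config = dm.ModelConfig(mode="mtDNA", n_uar=9, n_uma=26)
        with pytest.raises(ValueError):
            dm.infer_demography(np.zeros(5), dm.MTDNA_PRIOR, config, n=10, r=1, seed=0)

    def test_mtdna_binspec_resolution(self):
        config = dm.ModelConfig(mode="mtDNA", n_uar=4, n_uma=10,
                                binspec=mtdna_binspec(4, 10, exclude_fixed=True))
        assert config.resolved_binspec().dimension == 53


class TestPriorSensitivity:
    def cheap_config(self):
        return dm.ModelConfig(mode="mtDNA", n_loci=4, locus_length=2000,
                              n_uar=4, n_uma=4, mu_per_site=5e-8)

    def test_single_mu_equals_direct_run(self, rng):
        config = self.cheap_config()
        model = dm.make_model(config)
        obs = model(np.array([20_000.0, 8_000.0, 30_000.0]), rng)
        fixed = dm.PriorSpec(mu_n_uar=30_000, mu_n_uma=10_000, mu_t_div=100_000)
        table = dm.prior_sensitivity(obs, "n_uma", [15_000.0], fixed, config,
                                     n=150, r=1, seed=5)
        direct = dm.infer_demography(
            obs, dm.PriorSpec(mu_n_uar=30_000, mu_n_uma=15_000, mu_t_div=100_000),
            config, n=150, r=1, seed=np.random.SeedSequence(5).spawn(1)[0])
        assert len(table) == 1
        assert table.loc[0, "n_uma_mean"] == pytest.approx(direct.mean[1])

    def test_posterior_spread_shrinks_relative_to_priors(self, rng):
        config = self.cheap_config()
        model = dm.make_model(config)
        obs = model(np.array([20_000.0, 8_000.0, 30_000.0]), rng)
        grid = [5_000.0, 40_000.0, 120_000.0]
        table = dm.prior_sensitivity(obs, "n_uar", grid,
                                     dm.PriorSpec(), config, n=400, r=1, seed=2)
        posterior_spread = table["n_uar_mean"].max() - table["n_uar_mean"].min()
        prior_spread = max(grid) - min(grid)
        assert posterior_spread < prior_spread

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            dm.prior_sensitivity(np.zeros(3), "n_uar", [], dm.PriorSpec(),
                                 self.cheap_config())


class TestDerivedQuantities:
    def estimate(self, values):
        return PosteriorEstimate(mean=np.array(values), sd=np.zeros(3), r=1, n=0)

    def test_equal_sizes_give_unit_ratio(self):
        adna = self.estimate([10_000.0, 10_000.0, 50_000.0])
        mt = {"set": self.estimate([20_000.0, 20_000.0, 50_000.0])}
        rep = dm.report_derived_quantities(adna, mt, mtdna_values_are="N_mtDNA")
        assert rep["mtDNA"]["set"]["ratio_uar"] == pytest.approx(1.0)

    def test_raw_values_are_halved(self):
        adna = self.estimate([10_000.0, 10_000.0, 50_000.0])
        mt = {"set": self.estimate([40_000.0, 40_000.0, 50_000.0])}
        rep = dm.report_derived_quantities(adna, mt, mtdna_values_are="raw")
        assert rep["mtDNA"]["set"]["n_mtdna_uar"] == pytest.approx(20_000.0)
        assert rep["mtDNA"]["set"]["ratio_uar"] == pytest.approx(1.0)

    def test_missing_adna_warns_and_omits_ratios(self):
        mt = {"set": self.estimate([40_000.0, 40_000.0, 50_000.0])}
        with pytest.warns(UserWarning, match="ratios omitted"):
            rep = dm.report_derived_quantities(None, mt)
        assert "ratio_uar" not in rep["mtDNA"]["set"]

    def test_year_conversion_rounds_to_two_decimals(self):
        adna = self.estimate([1.0, 1.0, 136_597.0])
        rep = dm.report_derived_quantities(adna)
        assert rep["aDNA"]["t_mya"] == 1.37
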
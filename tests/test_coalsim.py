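"""Coalescent engine checks against closed-form expectations and msprime."""

import numpy as np
import pytest

from ursabc.coalsim import (
    DemographicParams,
    LocusConfig,
    expected_tmrca,
    from_ms_scaling,
    sample_tmrca,
    simulate_locus,
    to_ms_scaling,
    watterson_expected_s,
)
from ursabc.seqio import four_gamete_scan
from ursabc.sumstats import joint_sfs


def single_pop_locus(n, k, theta, length=1000, recomb="zero"):
    """A constant-size population of K chromosomes with locus theta = 2 K mu."""
    mu_site = theta / (2.0 * k) / length
    params = DemographicParams(n_uar=k, n_uma=k, t_div=1e12)
    locus = LocusConfig(length=length, mu_per_site=mu_site, recombination=recomb,
                        ploidy_mode="haploid-mtDNA", n_uar=n, n_uma=0)
    return params, locus


class TestValidation:
    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            DemographicParams(0, 1000, 1)
        with pytest.raises(ValueError):
            DemographicParams(1000, 1000, -5)

    def test_bad_locus_config_rejected(self):
        with pytest.raises(ValueError):
            LocusConfig(length=0)
        with pytest.raises(ValueError):
            LocusConfig(recombination="free")

    def test_no_samples_is_an_error(self):
        params, locus = single_pop_locus(2, 100, 1.0)
        locus = LocusConfig(length=locus.length, mu_per_site=locus.mu_per_site,
                            recombination="zero", ploidy_mode="haploid-mtDNA",
                            n_uar=0, n_uma=0)
        with pytest.raises(ValueError):
            simulate_locus(params, locus, seed=0)


class TestSingleLineage:
    def test_one_sample_has_no_segregating_sites(self):
        params, _ = single_pop_locus(2, 100, 5.0)
        locus = LocusConfig(length=1000, mu_per_site=1e-3, recombination="zero",
                            ploidy_mode="haploid-mtDNA", n_uar=1, n_uma=0)
        matrix, genealogy = simulate_locus(params, locus, seed=0)
        assert matrix.n_sites == 0
        assert genealogy.tmrca == 0.0


class TestSampleTmrca:
    def test_requires_two_lineages(self):
        with pytest.raises(ValueError):
            sample_tmrca(1, 100.0, seed=0)

    def test_pair_mean_is_one_coalescent_unit(self, rng):
        draws = [sample_tmrca(2, 1.0, seed=rng) for _ in range(20_000)]
        assert np.mean(draws) == pytest.approx(1.0, abs=3 * np.std(draws) / np.sqrt(len(draws)))

    def test_n10_mean_matches_telescoping_sum(self, rng):
        draws = [sample_tmrca(10, 1.0, seed=rng) for _ in range(20_000)]
        assert np.mean(draws) == pytest.approx(1.8, abs=3 * np.std(draws) / np.sqrt(len(draws)))

    def test_mean_increases_with_n_toward_two(self, rng):
        means = []
        for n in (2, 5, 10, 40):
            draws = [sample_tmrca(n, 1.0, seed=rng) for _ in range(8_000)]
            means.append(np.mean(draws))
        assert all(a < b for a, b in zip(means, means[1:]))
        assert means[-1] < 2.0


class TestMsScaling:
    def test_round_trip(self):
        params = DemographicParams(40_000, 8_000, 120_000)
        locus = LocusConfig()
        ms = to_ms_scaling(params, locus)
        back = from_ms_scaling(ms["theta"], ms["t_div"], ms["size_uar"],
                               ms["size_uma"], locus, n0=params.n_uar)
        assert back.n_uar == pytest.approx(params.n_uar)
        assert back.n_uma == pytest.approx(params.n_uma)
        assert back.t_div == pytest.approx(params.t_div)

    def test_theta_is_4N_mu_for_diploids(self):
        params = DemographicParams(10_000, 10_000, 1)
        locus = LocusConfig(length=500, mu_per_site=1e-8)
        ms = to_ms_scaling(params, locus)
        assert ms["theta"] == pytest.approx(4 * 10_000 * 1e-8 * 500)
        assert ms["rho"] == pytest.approx(ms["theta"])


class TestConstantSizeOracles:
    """Quick versions; the 20,000-replicate suite lives in the acceptance tests."""

    def test_mean_tmrca_matches_2k_1_minus_1_over_n(self, rng):
        params, locus = single_pop_locus(10, 1000, 2.0)
        draws = [simulate_locus(params, locus, seed=rng)[1].tmrca for _ in range(5_000)]
        se = np.std(draws) / np.sqrt(len(draws))
        assert np.mean(draws) == pytest.approx(expected_tmrca(1000, 10), abs=3 * se)

    def test_mean_s_matches_watterson(self, rng):
        params, locus = single_pop_locus(10, 1000, 2.0)
        draws = [simulate_locus(params, locus, seed=rng)[0].n_sites for _ in range(5_000)]
        se = np.std(draws) / np.sqrt(len(draws))
        assert np.mean(draws) == pytest.approx(watterson_expected_s(2.0, 10), abs=3 * se)

    def test_pairwise_diversity_matches_theta(self, rng):
        params, locus = single_pop_locus(8, 500, 3.0)
        pis = []
        for _ in range(4_000):
            m, _ = simulate_locus(params, locus, seed=rng)
            if m.n_sites == 0:
                pis.append(0.0)
                continue
            c = m.data.sum(axis=1)
            n = m.n_chromosomes
            pis.append(float(np.sum(2 * c * (n - c)) / (n * (n - 1))))
        se = np.std(pis) / np.sqrt(len(pis))
        assert np.mean(pis) == pytest.approx(3.0, abs=3 * se)


class TestDivergenceModel:
    def test_ancient_split_leaves_no_shared_derived_alleles(self, rng):
        params = DemographicParams(10_000, 10_000, 1e7)
        locus = LocusConfig(length=1000, mu_per_site=1e-8, recombination="zero",
                            ploidy_mode="haploid-mtDNA", n_uar=6, n_uma=6)
        shared = 0
        for _ in range(200):
            m, _ = simulate_locus(params, locus, seed=rng)
            js = joint_sfs(m)
            shared += js[1:6, 1:6].sum()  # polymorphic-in-both cells
        assert shared == 0

    def test_zero_recombination_is_four_gamete_compatible(self, rng):
        params = DemographicParams(40_000, 8_000, 120_000)
        locus = LocusConfig(length=2000, mu_per_site=5e-8, recombination="zero",
                            n_uar=10, n_uma=10)
        for _ in range(150):
            m, _ = simulate_locus(params, locus, seed=rng)
            assert four_gamete_scan(m) == []

    def test_genealogy_is_ultrametric_and_subset_consistent(self, rng):
        params = DemographicParams(40_000, 8_000, 120_000)
        locus = LocusConfig(length=500, recombination="zero", n_uar=5, n_uma=5)
        _, g = simulate_locus(params, locus, seed=rng)
        assert g.node_time[: g.n_leaves].max() == 0.0  # leaves at the present
        assert (np.diff(g.node_time[g.n_leaves:]) >= 0).all()  # coalescences ordered
        assert g.tmrca_of(range(g.n_leaves)) == pytest.approx(g.tmrca)
        assert g.tmrca_of([0, 1]) <= g.tmrca
        # split happened at t_div at the latest for cross-population pairs
        assert g.tmrca_of([0, 9]) >= params.t_div
        assert g.newick().endswith(";")


class TestMsprimeCrossCheck:
    """Independent-simulator oracle on the two-population model."""

    def test_mean_segregating_sites_agree(self, rng):
        msprime = pytest.importorskip("msprime")
        params = DemographicParams(40_000, 8_000, 120_000)
        locus = LocusConfig(length=500, mu_per_site=1.314e-8,
                            recombination="equal-to-mu", n_uar=18, n_uma=18)
        ours = np.array([simulate_locus(params, locus, seed=rng)[0].n_sites
                         for _ in range(2_000)])
        dem = msprime.Demography()
        dem.add_population(name="uar", initial_size=40_000)
        dem.add_population(name="uma", initial_size=8_000)
        dem.add_population(name="anc", initial_size=40_000)
        dem.add_population_split(time=120_000, derived=["uar", "uma"], ancestral="anc")
        theirs = []
        reps = msprime.sim_ancestry(samples={"uar": 9, "uma": 9}, demography=dem,
                                    sequence_length=500, recombination_rate=1.314e-8,
                                    num_replicates=2_000, random_seed=99)
        for ts in reps:
            mts = msprime.sim_mutations(ts, rate=1.314e-8, random_seed=None)
            theirs.append(mts.num_sites)
        theirs = np.array(theirs)
        se = np.sqrt(ours.var() / len(ours) + theirs.var() / len(theirs))
        assert ours.mean() == pytest.approx(theirs.mean(), abs=4 * se)
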
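import numpy as np

import pytest
from scipy import stats


from barrierscan.divergence import fst_scan, fst_means
from barrierscan.synthetic_data import (
    CHC_PEAKS,
    SONG_TRAITS,
    PopulationSpec,
    SimulationConfig,
    simulate_forward_region,
    simulate_phenotypes,
    simulate_snp_dataset,
)


def four_pop_config(seed, alpha=0.0, n_sites=2000, f_between=0.10,
                    f_within=0.005, n=20):
    pops = [
        PopulationSpec("A1", "speciesA", "allopatric", -20, 146, n),
        PopulationSpec("A2", "speciesA", "sympatric", -25, 152, n),
        PopulationSpec("B1", "speciesB", "sympatric", -25, 152, n),
        PopulationSpec("B2", "speciesB", "allopatric", -35, 150, n),
    ]
    return SimulationConfig(
        seed=seed, populations=pops, n_sites=n_sites, f_between=f_between,
        f_within=f_within, alpha=alpha, missing_rate=0.0, outgroup_samples=0,
    )


class TestSnpDataset:
    def test_mean_fst_tracks_drift_parameter(self):
        """Balding-Nichols expectation: mean per-site WC F_ST between the
        species approximates F_between."""
        means = []
        for seed in range(10):
            gm, pm, _ = simulate_snp_dataset(four_pop_config(seed))
            a = pm[pm.species == "speciesA"].index.tolist()
            b = pm[pm.species == "speciesB"].index.tolist()
            means.append(fst_means(fst_scan(gm, [a, b]))["mean_of_ratios"])
        assert abs(np.mean(means) - 0.10) < 0.03

    def test_species_wide_mixing_collapses_fst(self):
        """Mixing both species' frequencies everywhere must strictly lower
        between-species differentiation, seed by seed."""
        for seed in range(10):
            cfg0 = four_pop_config(seed)
            # alpha applies to sympatric populations; make every population
            # sympatric so mixing acts genome-wide
            for p in cfg0.populations:
                p.context = "sympatric"
            cfgA = four_pop_config(seed)
            for p in cfgA.populations:
                p.context = "sympatric"
            cfgA.alpha = 0.5
            gm0, pm0, _ = simulate_snp_dataset(cfg0)
            gmA, pmA, _ = simulate_snp_dataset(cfgA)
            a = pm0[pm0.species == "speciesA"].index.tolist()
            b = pm0[pm0.species == "speciesB"].index.tolist()
            f0 = fst_means(fst_scan(gm0, [a, b]))["mean_of_ratios"]
            fA = fst_means(fst_scan(gmA, [a, b]))["mean_of_ratios"]
            assert fA < f0

    def test_no_drift_limit_within_species(self):
        cfg = four_pop_config(0, f_within=0.001)
        gm, pm, _ = simulate_snp_dataset(cfg)
        a1 = pm[pm.population == "A1"].index.tolist()
        a2 = pm[pm.population == "A2"].index.tolist()
        f = fst_means(fst_scan(gm, [a1, a2]))["mean_of_ratios"]
        assert f < 0.01

    def test_reproducible_and_roles_partition(self):
        def build():
            cfg = four_pop_config(3)
            cfg.barrier_fraction = 0.02
            cfg.barrier_f = 0.6
            return simulate_snp_dataset(cfg)

        a, b = build(), build()
        np.testing.assert_array_equal(a[0].dosage, b[0].dosage)
        truth = a[2]
        cfg = four_pop_config(3)
        assert len(truth) == a[0].n_sites
        assert set(truth["role"]).issubset({"neutral", "barrier", "introgressed"})
        assert (truth["role"] == "barrier").sum() == int(0.02 * cfg.n_sites)

    def test_invalid_barrier_f_rejected(self):
        cfg = four_pop_config(0)
        with pytest.raises(ValueError):
            SimulationConfig(
                seed=0, populations=cfg.populations, barrier_fraction=0.1,
                barrier_f=0.05, f_between=0.10,
            )

    def test_hardy_weinberg_within_population(self):
        gm, pm, truth = simulate_snp_dataset(four_pop_config(1, n_sites=300))
        a1 = pm[pm.population == "A1"].index.tolist()
        idx = gm.sample_indices(a1)
        d = gm.dosage[:, idx]
        freq = truth["freq_A1"].to_numpy()
        rejected = 0
        tested = 0
        for s in range(gm.n_sites):
            p = freq[s]
            if p < 0.1 or p > 0.9:
                continue
            n = len(idx)
            expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
            observed = np.bincount(d[s], minlength=3)[:3]
            chi2 = ((observed - expected) ** 2 / expected).sum()
            tested += 1
            if stats.chi2.sf(chi2, 2) < 0.05:
                rejected += 1
        assert rejected / tested < 0.12  # ~nominal 5% plus chi-square approx


class TestForwardRegion:
    def test_zero_mutation_rate_no_sites(self):
        reg = simulate_forward_region(
            n_diploid=30, region_bp=10_000, mu=0.0, rec=1e-6,
            generations=50, seed=1,
        )
        assert len(reg.positions) == 0

    def test_no_recombination_haplotypes_are_founder_sets(self):
        """With r = 0 every haplotype's mutation set must be nested: sites
        never recombine onto new backgrounds, so any two haplotypes are
        either disjoint-or-nested mosaics of the mutation genealogy."""
        reg = simulate_forward_region(
            n_diploid=40, region_bp=50_000, mu=5e-7, rec=0.0,
            generations=300, seed=2,
        )
        H = reg.haplotypes
        # under no recombination, the gene genealogy at every site is the
        # same tree: the matrix must pass the three-gamete test
        S = H.shape[1]
        for a in range(S):
            for b in range(a + 1, S):
                pats = {(x, y) for x, y in zip(H[:, a], H[:, b])}
                assert len(pats & {(0, 1), (1, 0), (1, 1)}) < 3

    def test_conditioned_sweep_reaches_high_frequency(self):
        ok = 0
        for seed in range(10):
            reg = simulate_forward_region(
                n_diploid=100, region_bp=100_000, mu=1e-6, rec=1e-6,
                generations=400,
                selection={"pos": 50_000, "s": 0.1, "f_target": 0.85},
                seed=seed,
            )
            if reg.sweep_final_freq is not None and reg.sweep_final_freq > 0.8:
                ok += 1
        assert ok >= 8

    def test_negative_selection_rejected(self):
        with pytest.raises(ValueError):
            simulate_forward_region(selection={"pos": 1, "s": -0.5}, seed=0)

    def test_reproducible(self):
        kw = dict(n_diploid=30, region_bp=20_000, mu=5e-7, rec=5e-7,
                  generations=100, seed=9)
        a = simulate_forward_region(**kw)
        b = simulate_forward_region(**kw)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        np.testing.assert_array_equal(a.positions, b.positions)


class TestPhenotypes:
    @pytest.fixture
    def small_gm(self, rng):
        from conftest import make_matrix

        dosage = rng.binomial(2, 0.4, size=(300, 400)).astype(np.int8)
        return make_matrix(dosage)

    def test_variance_partition(self, small_gm):
        """A single QTL scaled for 20% of variance yields regression R^2
        near 0.2."""
        site = 17
        dos = small_gm.dosage[site].astype(float)
        var_g = dos.var()
        # effect beta: beta^2 var_g / (beta^2 var_g + 1) = 0.2
        beta = np.sqrt(0.2 / (0.8 * var_g))
        r2s = []
        for seed in range(10):
            pheno, _ = simulate_phenotypes(
                small_gm, {"song_duration": [(site, beta)]},
                h2_polygenic=0.0, noise_sd=1.0, seed=seed,
            )
            y = pheno["song_duration"].to_numpy()
            r2s.append(np.corrcoef(y, dos)[0, 1] ** 2)
        assert abs(np.mean(r2s) - 0.2) < 0.05

    def test_null_traits_uncorrelated(self, small_gm):
        pheno, _ = simulate_phenotypes(small_gm, {}, h2_polygenic=0.0,
                                       seed=1)
        n = small_gm.n_samples
        y = pheno["carrier_frequency"].to_numpy()
        for site in range(0, 300, 50):
            r = np.corrcoef(y, small_gm.dosage[site])[0, 1]
            assert abs(r) < 3 / np.sqrt(n)

    def test_chc_peaks_positive_and_complete(self, small_gm):
        pheno, _ = simulate_phenotypes(small_gm, seed=0)
        assert len(pheno) == small_gm.n_samples
        assert set(SONG_TRAITS + CHC_PEAKS + ["mass", "pronotum"]) <= set(
            pheno.columns
        )
        assert (pheno[CHC_PEAKS].to_numpy() > 0).all()
        assert np.isfinite(pheno.to_numpy()).all()

    def test_covariates_correlate_with_designated_trait(self, small_gm):
        pheno, _ = simulate_phenotypes(small_gm, seed=3)
        r = np.corrcoef(pheno["mass"], pheno["long_chirp_pulse_duration"])[0, 1]
        assert r > 0.2

    def test_bad_h2_rejected(self, small_gm):
        with pytest.raises(ValueError):
            simulate_phenotypes(small_gm, h2_polygenic=1.5, seed=0)

    def test_truth_table_records_qtls(self, small_gm):
        _, truth = simulate_phenotypes(
            small_gm, {"song_duration": [(3, 0.5), (7, -0.2)]}, seed=0
        )
        assert len(truth) == 2
        assert (truth["role"] == "qtl").all()
        assert set(truth["site_index"]) == {3, 7}
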
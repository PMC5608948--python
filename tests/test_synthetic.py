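"""Generator correctness: divergence model, determinism, truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from omicdiv import wright_fst_array
from omicdiv.fst import frequencies_from_genotypes, fst_table
from omicdiv.io_qc import filter_call_rate
from omicdiv.synthetic import (
    CohortDesign,
    simulate_balding_nichols_frequencies,
    simulate_cohort,
    simulate_genotypes,
    simulate_multiallelic_locus,
    simulate_quantitative_platform,
)


class TestBaldingNichols:
    def test_no_divergence_limit(self, rng):
        p = rng.uniform(0.2, 0.8, size=500)
        f = simulate_balding_nichols_frequencies(p, 1e-6, n_pops=3, rng=1)
        # essentially all loci stay within 0.01 of the ancestral frequency
        assert np.mean(np.all(np.abs(f - p[:, None]) < 1e-2, axis=1)) > 0.99

    def test_mean_fst_recovers_divergence_parameter(self):
        # Monte-Carlo band established by an independent large-replicate run
        # of the same beta model: at F=0.01 the mean k-population F_ST of
        # the *frequencies themselves* concentrates near F
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.95, size=10_000)
        f = simulate_balding_nichols_frequencies(p, 0.01, n_pops=3, rng=rng)
        mean_fst = float(np.nanmean(wright_fst_array(f)))
        assert 0.005 <= mean_fst <= 0.02

    def test_determinism(self, rng):
        p = np.full(100, 0.3)
        a = simulate_balding_nichols_frequencies(p, 0.05, n_pops=3, rng=42)
        b = simulate_balding_nichols_frequencies(p, 0.05, n_pops=3, rng=42)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("bad_F", [0.0, 1.0, -0.1])
    def test_degenerate_F_rejected(self, bad_F):
        with pytest.raises(ValueError):
            simulate_balding_nichols_frequencies(np.array([0.5]), bad_F, n_pops=3)

    def test_boundary_frequency_rejected(self):
        with pytest.raises(ValueError):
            simulate_balding_nichols_frequencies(np.array([0.0]), 0.01, n_pops=3)

    def test_mean_fst_monotone_in_F(self):
        # parameter recovery: mean per-SNP F_ST increases with simulated F
        rng = np.random.default_rng(9)
        p = rng.uniform(0.05, 0.95, size=4000)
        means = []
        for F in (0.001, 0.01, 0.05, 0.1):
            f = simulate_balding_nichols_frequencies(p, F, n_pops=3, rng=13)
            means.append(float(np.nanmean(wright_fst_array(f))))
        assert means == sorted(means)


class TestGenotypes:
    def test_fixed_zero_frequency(self):
        design = CohortDesign(n_per_pop=(10, 10, 10), n_snps=1, missing_rate=0.0, seed=0)
        freqs = np.array([[0.0, 0.5, 1.0]])
        g = simulate_genotypes(freqs, design, rng=0)
        pops = g.sample_meta["population"]
        assert (g.dosages[pops == "Chinese"].to_numpy() == 0).all()
        assert (g.dosages[pops == "Indian"].to_numpy() == 2).all()

    def test_no_missing_at_rate_zero(self, small_design):
        design = CohortDesign(**{**small_design.__dict__, "missing_rate": 0.0})
        freqs = np.full((design.n_snps, 3), 0.4)
        g = simulate_genotypes(freqs, design, rng=1)
        assert not g.dosages.isna().any().any()

    def test_sample_frequency_within_binomial_se(self):
        design = CohortDesign(
            n_per_pop=(10_000, 10, 10), n_snps=5, missing_rate=0.0, seed=0
        )
        freqs = np.full((5, 3), 0.3)
        g = simulate_genotypes(freqs, design, rng=3)
        chinese = g.dosages[g.sample_meta["population"] == "Chinese"]
        se = np.sqrt(0.3 * 0.7 / (2 * 10_000))
        obs = chinese.mean(axis=0) / 2
        assert np.all(np.abs(obs - 0.3) < 3 * se)

    def test_dosage_domain(self, small_cohort):
        vals = small_cohort.genotypes.dosages.to_numpy().ravel()
        vals = vals[~np.isnan(vals)]
        assert set(np.unique(vals)) <= {0.0, 1.0, 2.0}

    def test_deterministic_positions(self, small_cohort, small_design):
        meta = small_cohort.genotypes.snp_meta
        assert meta["pos"].iloc[0] == 1
        assert (np.diff(meta["pos"].iloc[:100]) == 5_000).all()


class TestMultiallelic:
    def test_fixed_allele_everywhere(self):
        design = CohortDesign(n_per_pop=(5, 5, 5), seed=0)
        freqs = np.zeros((3, 4))
        freqs[:, 2] = 1.0
        tbl = simulate_multiallelic_locus(freqs, design, "HLA-T", rng=0)
        assert (tbl["allele1"] == "HLA-T*03").all()
        assert (tbl["allele2"] == "HLA-T*03").all()

    def test_non_simplex_rejected(self):
        design = CohortDesign(n_per_pop=(5, 5, 5))
        with pytest.raises(ValueError):
            simulate_multiallelic_locus(np.full((3, 4), 0.3), design, rng=0)

    def test_observed_frequencies_within_multinomial_se(self):
        design = CohortDesign(n_per_pop=(5_000, 5_000, 5_000), seed=0)
        rng = np.random.default_rng(1)
        freqs = rng.dirichlet(np.ones(3), size=3)
        tbl = simulate_multiallelic_locus(freqs, design, "HLA-T", rng=2)
        pops = tbl["sample"].str.rsplit("_", n=1).str[0]
        for i, pop in enumerate(design.pop_labels):
            sub = tbl[pops == pop]
            alleles = pd.concat([sub["allele1"], sub["allele2"]])
            n = len(alleles)
            for a in range(3):
                target = freqs[i, a]
                se = np.sqrt(target * (1 - target) / n)
                obs = (alleles == f"HLA-T*{a + 1:02d}").mean()
                assert abs(obs - target) < 4 * se + 1e-9

    def test_same_seed_identical(self):
        design = CohortDesign(n_per_pop=(20, 20, 20))
        freqs = np.full((3, 4), 0.25)
        a = simulate_multiallelic_locus(freqs, design, rng=7)
        b = simulate_multiallelic_locus(freqs, design, rng=7)
        pd.testing.assert_frame_equal(a, b)


class TestQuantitativePlatform:
    def test_block_r2_within_monte_carlo_band(self):
        design = CohortDesign(
            n_per_pop=(100, 100, 100), block_r2=0.9, n_lipids=40,
            n_blocks=5, block_size=4, n_diff_features=0, missing_rate=0.0, seed=3,
        )
        cohort = simulate_cohort(design)
        r2s = []
        for members in cohort.truth["lipid"]["blocks"].values():
            sub = cohort.lipid_matrix[members].to_numpy()
            c = np.corrcoef(sub.T) ** 2
            iu = np.triu_indices_from(c, k=1)
            r2s += list(c[iu])
        assert 0.8 <= np.median(r2s) <= 0.95

    def test_truth_bookkeeping_of_shifts(self, small_cohort, small_design):
        truth = small_cohort.truth["mirna"]["shifted_features"]
        assert len(truth) == small_design.n_diff_features
        assert all(v["shift_sd"] == small_design.effect_size for v in truth.values())
        assert set(truth) <= set(small_cohort.mirna_matrix.columns)

    def test_planted_shift_visible_in_group_means(self, small_cohort):
        pops = small_cohort.covariates["population"]
        truth = small_cohort.truth["mirna"]["shifted_features"]
        feat, info = next(iter(truth.items()))
        y = small_cohort.mirna_matrix[feat]
        shifted_mean = y[pops == info["population"]].mean()
        other_mean = y[pops != info["population"]].mean()
        assert shifted_mean - other_mean > 0.5  # 1 SD planted, noise ~0.1 SE

    def test_missingness_drives_variable_qc(self):
        # plant 30% missingness on a quarter of the features; the 20%
        # missingness filter must drop exactly those
        design = CohortDesign(n_per_pop=(50, 50, 50), missing_rate=0.0, seed=4)
        cov = simulate_cohort(design).covariates
        rng = np.random.default_rng(8)
        m, _ = simulate_quantitative_platform(design, "mirna", cov, rng=rng)
        victims = list(m.columns[: len(m.columns) // 4])
        mask = rng.random((len(m), len(victims))) < 0.3
        m[victims] = m[victims].mask(pd.DataFrame(mask, index=m.index, columns=victims))
        kept, stage = filter_call_rate(m, 0.2, rule="missing_gt")
        assert set(stage.removed_ids) == set(victims)


class TestCohortDeterminismAndConsistency:
    def test_same_seed_byte_identical(self, tmp_path, small_design):
        a = simulate_cohort(small_design)
        b = simulate_cohort(small_design)
        pd.testing.assert_frame_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.lipid_matrix, b.lipid_matrix)
        pd.testing.assert_frame_equal(a.hla_table, b.hla_table)
        da = a.write(tmp_path / "a")
        db = b.write(tmp_path / "b")
        for key in da:
            assert open(da[key], "rb").read() == open(db[key], "rb").read()

    def test_row_sets_consistent_across_platforms(self, small_cohort):
        idx = set(small_cohort.covariates.index)
        assert set(small_cohort.genotypes.dosages.index) == idx
        assert set(small_cohort.lipid_matrix.index) == idx
        assert set(small_cohort.mirna_matrix.index) == idx
        assert set(small_cohort.hla_table["sample"]) == idx

    def test_downstream_fst_tracks_design_target(self, default_cohort):
        pops = default_cohort.covariates["population"]
        freqs = frequencies_from_genotypes(default_cohort.genotypes.dosages, pops)
        fst = fst_table(freqs)["fst"]
        # genotype sampling noise adds ~1/(2N) on top of the drift target
        assert 0.005 < fst.mean() < 0.03
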
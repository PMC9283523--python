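"""Association engine, permutation scheme, FDR and conditional analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nkqtl import eqtl
from nkqtl import simdata as sd
from nkqtl.eqtl import MapConfig


def _toy_genotypes(X, chrom="1", spacing=1000):
    n, m = X.shape
    ids = [f"v{j + 1}" for j in range(m)]
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * spacing,
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(X.mean(0) / 2, 1 - X.mean(0) / 2),
            "is_copy_number": False,
        },
        index=pd.Index(ids, name="variant"),
    )
    dos = pd.DataFrame(X, index=[f"S{i}" for i in range(n)], columns=ids)
    return sd.GenotypeMatrix(dosages=dos, variants=meta)


class TestRankNormal:
    def test_three_point_quantiles(self):
        out = eqtl.rank_normal([5, 1, 9])
        expect = stats.norm.ppf([3 / 6, 1 / 6, 5 / 6])
        assert np.allclose(out, expect, atol=1e-3)
        assert np.allclose(out, [0, -0.9674, 0.9674], atol=1e-3)

    def test_invariant_to_monotone_transform(self, rng):
        x = rng.normal(size=41)
        assert np.allclose(eqtl.rank_normal(x), eqtl.rank_normal(np.exp(3 * x) + 7))

    def test_zero_mean_for_odd_n(self, rng):
        x = rng.normal(size=31)
        assert abs(eqtl.rank_normal(x).mean()) < 1e-9

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            eqtl.rank_normal([2.0, 2.0, 2.0])


class TestResidualise:
    def test_intercept_only_centres(self, rng):
        y = rng.normal(size=30)
        assert np.allclose(eqtl.residualise(y, None), y - y.mean())

    def test_residuals_orthogonal_to_covariates(self, rng):
        Y = rng.normal(size=(50, 3))
        C = rng.normal(size=(50, 4))
        R = eqtl.residualise(Y, C)
        assert np.all(np.abs(R.T @ C) < 1e-8)

    def test_exact_linear_combination_vanishes(self, rng):
        C = rng.normal(size=(40, 2))
        y = 3.0 + C @ np.array([1.5, -2.0])
        assert np.all(np.abs(eqtl.residualise(y, C)) < 1e-10)

    def test_rank_deficient_covariates_identified(self, rng):
        C = rng.normal(size=(30, 2))
        C = np.column_stack([C, C[:, 0] + C[:, 1]])
        with pytest.raises(ValueError, match="column"):
            eqtl.residualise(rng.normal(size=30), C)


class TestVariantQC:
    def test_low_maf_removed(self, rng):
        X = np.zeros((200, 2))
        X[:4, 0] = 1.0  # maf 0.01
        X[:, 1] = rng.binomial(2, 0.3, 200)
        gm = _toy_genotypes(X)
        out = eqtl.qc_variants(gm, MapConfig())
        assert "v1" not in out.dosages.columns

    def test_all_heterozygous_fails_hwe(self):
        X = np.column_stack([np.ones(100), np.tile([0, 1, 1, 2], 25)])
        gm = _toy_genotypes(X)
        # chi2 = 100 against 25/50/25 expectation, p ~ 1.5e-23
        assert eqtl.hwe_chisq_p(X[:, 0]) == pytest.approx(stats.chi2.sf(100, 1), rel=1e-9)
        out = eqtl.qc_variants(gm, MapConfig())
        assert "v1" not in out.dosages.columns

    def test_light_missingness_retained_and_imputed(self, rng):
        x = rng.binomial(2, 0.3, 200).astype(float)
        x[:2] = np.nan  # 1% missing
        gm = _toy_genotypes(x[:, None])
        out = eqtl.qc_variants(gm, MapConfig())
        assert "v1" in out.dosages.columns
        assert np.isfinite(out.dosages["v1"]).all()

    def test_all_removed_warns(self):
        X = np.zeros((100, 1))
        X[0, 0] = 1.0
        with pytest.warns(UserWarning, match="all variants removed"):
            out = eqtl.qc_variants(_toy_genotypes(X), MapConfig())
        assert out.n_variants == 0


class TestNominalScan:
    def test_perfect_association(self, rng):
        g = rng.binomial(2, 0.4, 100).astype(float)
        gm = _toy_genotypes(g[:, None])
        res = eqtl.nominal_scan(g, gm)
        assert res.loc["v1", "beta"] == pytest.approx(1.0)
        assert res.loc["v1", "p_nominal"] < 1e-12

    def test_matches_pearson_correlation_test(self, rng):
        for _ in range(50):
            n = int(rng.integers(20, 120))
            g = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
            y = rng.normal(size=n)
            gm = _toy_genotypes(g[:, None])
            res = eqtl.nominal_scan(y, gm)
            _, p_ref = stats.pearsonr(g, y)
            assert abs(res.loc["v1", "p_nominal"] - p_ref) < 1e-10

    def test_constant_dosage_flagged_untestable(self, rng):
        X = np.column_stack([np.full(50, 2.0), rng.binomial(2, 0.3, 50)])
        res = eqtl.nominal_scan(rng.normal(size=50), _toy_genotypes(X))
        assert not res.loc["v1", "testable"]
        assert res.loc["v2", "testable"]


class TestPermutationGeneP:
    def test_beta_mle_recovers_known_shape(self, rng):
        x = rng.beta(1.2, 300.0, size=10_000)
        a, b = eqtl.fit_beta_mle(x)
        assert abs(a - 1.2) / 1.2 < 0.10
        assert abs(b - 300.0) / 300.0 < 0.10

    def test_empirical_and_beta_p_agree(self, rng):
        cfg = MapConfig(n_perm=300, seed=0)
        mismatches = 0
        for rep in range(40):
            g = rng.binomial(2, 0.3, (120, 15)).astype(float)
            y = rng.normal(size=120)
            fit = eqtl.permutation_gene_p(y, _toy_genotypes(g), cfg, rng=np.random.default_rng(rep))
            mc_se = np.sqrt(fit.p_empirical * (1 - fit.p_empirical) / cfg.n_perm)
            mismatches += abs(fit.p_beta - fit.p_empirical) > 2 * mc_se + 1 / cfg.n_perm
        assert mismatches <= 4  # ~2*SE bound should hold for the vast majority

    def test_too_few_permutations_rejected(self, rng):
        g = rng.binomial(2, 0.3, (60, 5)).astype(float)
        with pytest.raises(ValueError):
            eqtl.permutation_gene_p(rng.normal(size=60), _toy_genotypes(g), MapConfig(n_perm=10))


class TestQvalues:
    def test_bh_hand_example_with_pi0_one(self):
        q = eqtl.qvalues([0.01, 0.02, 0.5], pi0=1.0)
        assert np.allclose(q, [0.03, 0.03, 0.5])

    def test_all_ones(self):
        assert np.all(eqtl.qvalues(np.ones(20)) == 1.0)

    def test_monotone_in_sorted_p(self, rng):
        p = rng.uniform(size=200)
        q = eqtl.qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            eqtl.qvalues([])


class TestBestProbe:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["gene", "probe", "p_min_obs", "lead_pos"])

    def test_single_probe_identity(self):
        df = self._frame([("g1", "p1", 1e-4, 100)])
        assert eqtl.best_probe(df)["probe"].tolist() == ["p1"]

    def test_most_significant_probe_retained(self):
        df = self._frame([("g1", "pA", 1e-3, 100), ("g1", "pB", 1e-8, 200)])
        assert eqtl.best_probe(df)["probe"].tolist() == ["pB"]

    def test_deterministic_position_tiebreak(self):
        df = self._frame([("g1", "pB", 1e-5, 300), ("g1", "pA", 1e-5, 100)])
        out1 = eqtl.best_probe(df)
        out2 = eqtl.best_probe(df.iloc[::-1])
        assert out1["probe"].tolist() == out2["probe"].tolist() == ["pA"]


class TestConditionalScan:
    def _planted(self, seed, variants, slopes):
        rng = np.random.default_rng(seed)
        cfg = sd.SimConfig(
            n_samples=300, n_variants=60, n_genes=2, cell_types=("NK",), ld_rho=0.6,
            maf_range=(0.2, 0.5), seed=seed,
        )
        gm = sd.simulate_genotypes(cfg)
        y = rng.normal(size=300)
        for v, s in zip(variants, slopes):
            y = y + s * gm.dosages[v].to_numpy()
        return gm, eqtl.rank_normal(y)

    def test_single_planted_variant_yields_one_tagging_signal(self):
        hits = 0
        for seed in range(25):
            gm, y = self._planted(seed, ["var000030"], [0.8])
            sigs = eqtl.conditional_scan(y, gm, 1e-4, MapConfig(), gene="g")
            if len(sigs) == 1:
                g1 = gm.dosages[sigs[0].lead_variant]
                r2 = np.corrcoef(g1, gm.dosages["var000030"])[0, 1] ** 2
                hits += r2 > 0.8
        assert hits >= 0.9 * 25 - 2

    def test_two_unlinked_strong_variants_recovered(self):
        ok = 0
        for seed in range(20):
            # variants on different chromosomes: unlinked by construction
            gm, y = self._planted(seed, ["var000010", "var000045"], [0.9, 0.9])
            sigs = eqtl.conditional_scan(y, gm, 1e-4, MapConfig(), gene="g")
            ok += len(sigs) == 2
        assert ok >= 0.9 * 20 - 1

    def test_null_gene_yields_no_signals(self, rng):
        g = rng.binomial(2, 0.3, (200, 40)).astype(float)
        y = eqtl.rank_normal(rng.normal(size=200))
        assert eqtl.conditional_scan(y, _toy_genotypes(g), 1e-5, MapConfig()) == []


class TestPipeline:
    def test_invariant_to_sample_order_and_affine_rescaling(self, small_cohort):
        cfg, gm, truth, tables = small_cohort
        nk = tables[0]
        mc = MapConfig(n_perm=100, seed=5)
        base = eqtl.map_cis(nk, gm, mc)

        # affine rescale of the raw phenotypes
        scaled = sd.PhenotypeTable(values=nk.values * 7.0 - 3.0, probes=nk.probes)
        res_scaled = eqtl.map_cis(scaled, gm, mc)
        assert np.allclose(base["p_beta"], res_scaled["p_beta"])

        # permute samples jointly in phenotypes and genotypes
        perm = np.random.default_rng(1).permutation(nk.values.index.to_numpy())
        nk_p = sd.PhenotypeTable(values=nk.values.loc[perm], probes=nk.probes)
        gm_p = sd.GenotypeMatrix(dosages=gm.dosages.loc[perm], variants=gm.variants)
        res_perm = eqtl.map_cis(nk_p, gm_p, mc)
        assert np.allclose(base["p_beta"], res_perm["p_beta"])

    def test_select_pc_count(self, rng):
        cfg = sd.SimConfig(
            n_samples=200, n_variants=120, n_genes=12, cell_types=("NK",),
            n_expression_pcs_noise=3, pc_noise_sd=2.0, noise_sd=0.5, seed=9,
        )
        gm = sd.simulate_genotypes(cfg)
        truth = sd.TruthTable(
            cis_effects=[sd.CisEffect(f"GENE{k:04d}", f"var{10 * k:06d}", 0.5) for k in (1, 3, 5, 7)]
        )
        (tab,) = sd.simulate_multicell_expression(gm, cfg, truth)
        mc = MapConfig(n_perm=100, seed=2)
        assert eqtl.select_pc_count(tab, gm, [4], mc) == 4
        chosen = eqtl.select_pc_count(tab, gm, [0, 3], mc, n_perm=100)
        assert chosen == 3  # PC adjustment removes the planted confounding


class TestAuxiliaryTests:
    def test_logit_slope_sign_follows_monotone_proportions(self):
        res = eqtl.logit_lrt([0.1, 0.2, 0.35, 0.5, 0.65], [0, 0, 1, 1, 2])
        assert res.slope > 0

    def test_logit_lrt_null_uniform(self, rng):
        ps = []
        props = rng.uniform(0.2, 0.8, size=40)
        for _ in range(1000):
            g = rng.permutation(np.repeat([0, 1, 2], [18, 16, 6])).astype(float)
            ps.append(eqtl.logit_lrt(props, g).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_tiny_perfect_fit_significant(self):
        x = np.array([0.0, 1.0, 2.0])
        pr = 1 / (1 + np.exp(-(x - 1)))
        assert eqtl.logit_lrt(pr, x).p < 0.05

    def test_boundary_proportions_clamped(self):
        res = eqtl.logit_lrt([0.0, 0.5, 1.0], [0.0, 1.0, 2.0])
        assert res.clamped

    def test_ase_chisq_hand_example(self):
        chi2, p = eqtl.ase_chisq((48, 48), (90, 6))
        assert chi2 == pytest.approx(45.45, abs=0.1)
        assert p < 1e-10

    def test_ase_equal_ratios_null(self):
        chi2, p = eqtl.ase_chisq((50, 50), (50, 50))
        assert chi2 == 0 and p == 1
        chi2, _ = eqtl.ase_chisq((50, 50), (500, 500))
        assert chi2 == 0
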
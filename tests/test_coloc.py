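"""Wakefield ABFs, coloc/moloc posteriors, specificity rule, RTC, mediation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nkqtl import coloc
from nkqtl import simdata as sd


def _stats_table(betas, ses, pos=None, chrom="1"):
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    m = len(betas)
    pos = np.arange(1, m + 1) * 1000 if pos is None else pos
    z = betas / ses
    t = pd.DataFrame(
        {
            "snp": [f"v{i}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "a1": "G",
            "a2": "A",
            "beta": betas,
            "se": ses,
            "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
            "n": 1000,
            "maf": 0.3,
        }
    ).set_index("snp", drop=False)
    return sd.SummaryStatsTable(table=t)


class TestWakefieldABF:
    def test_null_z_gives_negative_labf(self):
        assert coloc.wakefield_abf(0.0, 0.1, 0.0225) < 0

    def test_direct_formula_evaluation(self):
        # z = 5, V = 0.01, W = 0.0225
        expect = 0.5 * np.log(0.01 / 0.0325) + 0.5 * 25 * 0.0225 / 0.0325
        assert coloc.wakefield_abf(0.5, 0.1, 0.0225) == pytest.approx(expect)
        assert expect == pytest.approx(8.06, abs=0.01)

    def test_vanishing_prior_variance_limit(self):
        assert abs(coloc.wakefield_abf(0.5, 0.1, 1e-12)) < 1e-6

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            coloc.wakefield_abf(0.1, 0.0, 0.02)


class TestPairwiseColoc:
    def test_single_shared_variant(self):
        s1 = _stats_table([0.8], [0.1])
        s2 = _stats_table([0.8], [0.1])
        res = coloc.coloc_abf(s1, s2)
        assert res.pp3 == 0.0
        assert res.pp4 > 0.99

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        l1 = rng.normal(0, 3, 3)
        l2 = rng.normal(0, 3, 3)
        p1 = p2 = 1e-4
        p12 = 1e-5
        res = coloc.coloc_from_labf(l1, l2, p1, p2, p12)
        # brute force over causal-variant placements
        b1, b2 = np.exp(l1), np.exp(l2)
        h0 = 1.0
        h1 = p1 * b1.sum()
        h2 = p2 * b2.sum()
        h3 = p1 * p2 * sum(b1[i] * b2[j] for i, j in itertools.product(range(3), range(3)) if i != j)
        h4 = p12 * float(b1 @ b2)
        tot = h0 + h1 + h2 + h3 + h4
        expect = np.array([h0, h1, h2, h3, h4]) / tot
        assert np.allclose(res.posteriors, expect, atol=1e-9)

    def test_double_null_favors_pp0(self):
        s1 = _stats_table([0.001] * 5, [0.1] * 5)
        s2 = _stats_table([-0.001] * 5, [0.1] * 5)
        res = coloc.coloc_abf(s1, s2)
        assert res.pp0 > 0.9

    def test_posteriors_sum_to_one_and_variant_order_invariant(self):
        rng = np.random.default_rng(7)
        l1, l2 = rng.normal(0, 2, 20), rng.normal(0, 2, 20)
        res = coloc.coloc_from_labf(l1, l2)
        assert res.posteriors.sum() == pytest.approx(1.0, abs=1e-9)
        perm = rng.permutation(20)
        res_p = coloc.coloc_from_labf(l1[perm], l2[perm])
        assert np.allclose(res.posteriors, res_p.posteriors, atol=1e-12)

    def test_allele_flip_harmonisation(self):
        s1 = _stats_table([0.5, 0.1], [0.1, 0.1])
        t2 = _stats_table([-0.5, 0.1], [0.1, 0.1]).table.copy()
        t2.loc["v0", ["a1", "a2"]] = ["A", "G"]  # swapped alleles, flipped sign
        s2 = sd.SummaryStatsTable(table=t2)
        aligned = coloc.harmonise([s1, s2])
        assert aligned[1]["beta"].iloc[0] == pytest.approx(0.5)


class TestMultiTrait:
    def test_configuration_counts(self):
        for d, expect in ((2, 5), (3, 15), (5, 203)):
            traits = tuple("ABCDE"[:d])
            assert sum(1 for _ in coloc.enumerate_configurations(traits)) == expect

    def test_two_trait_case_equals_pairwise_coloc(self):
        rng = np.random.default_rng(11)
        l1, l2 = rng.normal(0, 2, 30), rng.normal(0, 2, 30)
        pair = coloc.coloc_from_labf(l1, l2, 1e-4, 1e-4, 1e-6)
        multi = coloc.multi_trait_coloc({"NK": l1, "CD4": l2}, focal="NK",
                                        block_priors={1: 1e-4, 2: 1e-6})
        d = dict(zip(multi.configurations, multi.posteriors))
        assert d[()] == pytest.approx(pair.pp0, abs=1e-9)
        assert d[(("NK",),)] == pytest.approx(pair.pp1, abs=1e-9)
        assert d[(("CD4",),)] == pytest.approx(pair.pp2, abs=1e-9)
        assert d[(("CD4",), ("NK",))] == pytest.approx(pair.pp3, abs=1e-9)
        assert d[(("CD4", "NK"),)] == pytest.approx(pair.pp4, abs=1e-9)

    def test_focal_specific_signal_detected(self):
        # strong focal signal at one variant, other traits null
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = 50
            z_nk = rng.normal(0, 1, m)
            z_nk[10] = 8.0
            labfs = {"NK": 0.5 * z_nk**2 * 0.7 - 0.6}
            for other in ("CD4", "CD8", "MONO"):
                z = rng.normal(0, 1, m)
                labfs[other] = 0.5 * z**2 * 0.7 - 0.6
            res = coloc.multi_trait_coloc(labfs, focal="NK")
            hits += res.pp_nk_specific > 0.8
        assert hits >= 18

    def test_posteriors_normalised(self):
        rng = np.random.default_rng(3)
        labfs = {t: rng.normal(0, 2, 25) for t in ("NK", "CD4", "CD8")}
        res = coloc.multi_trait_coloc(labfs, focal="NK")
        assert res.posteriors.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.pp_nk_specific + res.pp_nk_shared <= 1 + 1e-12

    def test_too_many_traits_rejected(self):
        labfs = {f"T{i}": np.zeros(5) for i in range(6)}
        with pytest.raises(ValueError):
            coloc.multi_trait_coloc(labfs, focal="T0")


class TestSpecificityCall:
    def _moloc(self, pp_spec, pp_shared, best_alone):
        best = (("NK",),) if best_alone else (("CD4", "NK"),)
        return coloc.MolocResult(
            traits=("CD4", "NK"), focal="NK", configurations=[best], posteriors=np.array([1.0]),
            best_configuration=best, pp_focal_specific=pp_spec, pp_focal_shared=pp_shared,
        )

    def test_rule_application(self):
        assert coloc.specificity_call(self._moloc(0.95, 0.02, True)).call == "specific"
        assert coloc.specificity_call(self._moloc(0.02, 0.95, False)).call == "shared"
        assert coloc.specificity_call(self._moloc(0.6, 0.3, True)).call == "ambiguous"
        # high specific posterior but best model is sharing -> not specific
        assert coloc.specificity_call(self._moloc(0.85, 0.1, False)).call == "ambiguous"


def _interval_cohort(seed, n=300, m=30, rho=0.8):
    cfg = sd.SimConfig(
        n_samples=n, n_variants=m, n_genes=2, cell_types=("NK",), ld_rho=rho,
        maf_range=(0.2, 0.5), n_chromosomes=1, seed=seed,
    )
    return sd.simulate_genotypes(cfg)


class TestRTC:
    def test_gwas_snp_equal_esnp_scores_one(self):
        gm = _interval_cohort(1)
        rng = np.random.default_rng(0)
        y = gm.dosages["var000010"].to_numpy() + rng.normal(size=300)
        res = coloc.rtc(y, gm, "var000010", "var000010")
        assert res.rank == 0 and res.score == 1.0

    def test_unlinked_gwas_snp_scores_uniformly(self):
        scores = []
        for seed in range(200):
            gm = _interval_cohort(seed, n=150, m=20, rho=0.0)
            rng = np.random.default_rng(seed + 1000)
            y = 0.7 * gm.dosages["var000005"].to_numpy() + rng.normal(size=150)
            res = coloc.rtc(y, gm, "var000005", "var000015")
            scores.append(res.score)
        assert stats.kstest(scores, "uniform").pvalue > 0.01

    def test_shared_causal_high_score(self):
        high = 0
        for seed in range(20):
            gm = _interval_cohort(seed, rho=0.9)
            rng = np.random.default_rng(seed + 2000)
            causal = gm.dosages["var000010"].to_numpy()
            y = 1.0 * causal + rng.normal(size=300)
            # the GWAS hit is an LD partner of the causal variant
            res = coloc.rtc(y, gm, "var000010", "var000011")
            high += res.score > 0.9
        assert high >= 11

    def test_single_snp_interval_rejected(self):
        gm = _interval_cohort(2).subset(["var000001"])
        with pytest.raises(ValueError):
            coloc.rtc(np.zeros(300), gm, "var000001", "var000001")


class TestMediation:
    def test_identical_statistics_maximise_pp4(self):
        s = _stats_table(np.linspace(-0.5, 0.5, 10), np.full(10, 0.08))
        res = coloc.mediation_coloc(s, s)
        c = coloc.coloc_abf(s, s)
        assert res.pp4 == max(c.posteriors)

    def test_distinct_causal_variants_favor_pp3(self):
        rng = np.random.default_rng(4)
        z1 = rng.normal(0, 1, 40)
        z2 = rng.normal(0, 1, 40)
        z1[5] = 9.0
        z2[30] = 9.0
        s1 = _stats_table(z1 * 0.05, np.full(40, 0.05))
        s2 = _stats_table(z2 * 0.05, np.full(40, 0.05))
        res = coloc.coloc_abf(s1, s2)
        assert res.pp3 > max(res.pp0, res.pp1, res.pp2, res.pp4)
        med = coloc.mediation_coloc(s1, s2)
        assert not med.mediated
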
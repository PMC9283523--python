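"""Trans mapping: filters, joint-permutation FDR, grouping, artefact screens."""

import numpy as np
import pandas as pd
import pytest

from nkqtl import eqtl, trans
from nkqtl import simdata as sd


def _toy_genotypes(X, positions=None, chrom="1"):
    n, m = X.shape
    ids = [f"v{j + 1}" for j in range(m)]
    pos = positions if positions is not None else np.arange(1, m + 1) * 1000
    meta = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G",
         "maf": np.minimum(X.mean(0) / 2, 1 - X.mean(0) / 2), "is_copy_number": False},
        index=pd.Index(ids, name="variant"),
    )
    return sd.GenotypeMatrix(
        dosages=pd.DataFrame(X, index=[f"S{i}" for i in range(n)], columns=ids), variants=meta
    )


class TestRepeatExclusion:
    def test_coordinate_convention(self, rng):
        X = rng.binomial(2, 0.3, (20, 3)).astype(float)
        gm = _toy_genotypes(X, positions=[100, 201, 500])
        track = pd.DataFrame({"chrom": ["1"], "start": [99], "end": [200]})
        out = trans.exclude_repeat_snps(gm, track)
        # 1-based 100 is inside [99,200); 201 is the first base after the interval
        assert list(out.dosages.columns) == ["v2", "v3"]

    def test_boundary_snp_retained(self, rng):
        X = rng.binomial(2, 0.3, (20, 2)).astype(float)
        gm = _toy_genotypes(X, positions=[200, 201])
        track = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [200]})
        out = trans.exclude_repeat_snps(gm, track)
        assert list(out.dosages.columns) == ["v2"]

    def test_empty_track_identity(self, rng):
        X = rng.binomial(2, 0.3, (20, 3)).astype(float)
        gm = _toy_genotypes(X)
        out = trans.exclude_repeat_snps(gm, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert out.dosages.equals(gm.dosages)

    def test_malformed_bed_reports_line_number(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("1\t10\t20\n1\t30\n")
        from nkqtl.io import read_bed_track

        with pytest.raises(ValueError, match="line 2"):
            read_bed_track(bad)


def _network_cohort(seed=3, n=300, slope=0.9):
    cfg = sd.SimConfig(
        n_samples=n, n_variants=600, n_genes=12, cell_types=("NK",), ld_rho=0.3, seed=seed
    )
    gm = sd.simulate_genotypes(cfg)
    truth = sd.TruthTable(
        cis_effects=[sd.CisEffect("GENE0001", "var000011", 1.2)],
        trans_edges=[sd.TransEdge("GENE0001", f"GENE{k:04d}", slope) for k in (2, 4, 6, 8, 10)],
    )
    (tab,) = sd.simulate_multicell_expression(gm, cfg, truth)
    adj = eqtl.adjust_phenotypes(tab, 0)
    return gm, tab, adj


class TestTransScan:
    def test_planted_network_recovered(self):
        gm, tab, adj = _network_cohort()
        hits, fdr = trans.trans_scan(adj, tab.probes, gm, n_perm=200, seed=1)
        targets = {f"GENE{k:04d}" for k in (2, 4, 6, 8, 10)}
        assert targets <= set(hits["gene"])
        assert fdr.fdr_at_threshold <= 0.05

    def test_null_hit_count_poisson_calibrated(self, rng):
        # expected count of p < 1e-5 pairs among eligible tests under the null
        cfg = sd.SimConfig(n_samples=200, n_variants=500, n_genes=20, cell_types=("NK",), seed=21)
        gm = sd.simulate_genotypes(cfg)
        (tab,) = sd.simulate_multicell_expression(gm, cfg, sd.TruthTable())
        adj = eqtl.adjust_phenotypes(tab, 0)
        from nkqtl.trans import _eligibility

        n_elig = int(_eligibility(gm.variants, tab.probes, 5e6).sum())
        hits, _ = trans.trans_scan(adj, tab.probes, gm, n_perm=50, seed=2, fdr=1.1)
        # with FDR cap disabled, every p < 1e-5 candidate comes through
        lam = n_elig * 1e-5
        assert len(hits) <= lam + 4 * np.sqrt(lam) + 3

    def test_nearby_pairs_not_tested(self):
        gm, tab, adj = _network_cohort()
        from nkqtl.trans import _eligibility

        elig = _eligibility(gm.variants, tab.probes, 5e6)
        meta = gm.variants
        for j, pid in enumerate(tab.probes.index):
            prow = tab.probes.loc[pid]
            close = (
                (meta["chrom"] == prow["chrom"]) & (np.abs(meta["pos"] - prow["tss"]) <= 4e6)
            ).to_numpy()
            assert not elig[close, j].any()

    def test_reduces_to_cis_scan_without_distance_filter(self):
        gm, tab, adj = _network_cohort()
        pid = "GENE0001_p1_NK"
        y = adj[pid].to_numpy()
        scan = eqtl.nominal_scan(y, gm)
        hits, _ = trans.trans_scan(
            adj[[pid]], tab.probes.loc[[pid]], gm, min_distance=0, n_perm=50, seed=0, fdr=1.1
        )
        merged = hits.set_index("variant").join(scan, rsuffix="_cis")
        assert np.allclose(merged["p_nominal"], merged["p_nominal_cis"], atol=1e-12)


class TestCrossmap:
    def test_exact_substring_flagged(self, rng):
        win = "".join(rng.choice(list("ACGT"), 500))
        probe = win[100:150]
        flag = trans.crossmap_screen("p", probe, win)
        assert flag.min_mismatches == 0 and flag.flagged

    def test_reverse_complement_detected(self, rng):
        win = "".join(rng.choice(list("ACGT"), 500))
        sub = win[200:250]
        rc = sub.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        flag = trans.crossmap_screen("p", rc, win)
        assert flag.min_mismatches == 0 and flag.flagged

    def test_matches_brute_force_enumeration(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(100):
            probe = "".join(rng.choice(list("ACGT"), 50))
            win = "".join(rng.choice(list("ACGT"), 1000))
            best = min(
                sum(a != b for a, b in zip(win[i : i + 50], s))
                for s in (probe, probe.translate(comp)[::-1])
                for i in range(1000 - 50 + 1)
            )
            assert trans.crossmap_screen("p", probe, win).min_mismatches == best

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            trans.crossmap_screen("p", "ACGTN" * 10, "ACGT" * 100)


class TestGrouping:
    def _hits(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "chrom", "pos", "variant", "p_nominal"]
        )

    def test_chain_rule(self):
        hits = self._hits(
            [("g", "1", 100_000, "a", 1e-9), ("g", "1", 900_000, "b", 1e-8), ("g", "1", 2_500_000, "c", 1e-7)]
        )
        loci = trans.group_trans_loci(hits)
        assert len(loci) == 2
        assert set(loci.iloc[0]["members"]) == {"a", "b"}
        assert set(loci.iloc[1]["members"]) == {"c"}

    def test_single_hit_single_locus(self):
        loci = trans.group_trans_loci(self._hits([("g", "2", 5, "x", 1e-9)]))
        assert len(loci) == 1 and loci.iloc[0]["peak_variant"] == "x"

    def test_chromosomes_never_merge(self):
        hits = self._hits([("g", "1", 100, "a", 1e-9), ("g", "2", 150, "b", 1e-9)])
        assert len(trans.group_trans_loci(hits)) == 2

    def test_idempotent_and_order_invariant(self, rng):
        rows = [("g", "1", int(p), f"v{i}", 1e-8) for i, p in enumerate(rng.integers(1, 5_000_000, 30))]
        hits = self._hits(rows)
        a = trans.group_trans_loci(hits)
        b = trans.group_trans_loci(hits.sample(frac=1, random_state=0))
        assert a["members"].tolist() == b["members"].tolist()


class TestConditionalTrans:
    def test_ld_partners_collapse_to_single_signal(self):
        cfg = sd.SimConfig(
            n_samples=400, n_variants=40, n_genes=2, cell_types=("NK",), ld_rho=0.9,
            maf_range=(0.3, 0.5), seed=13,
        )
        gm = sd.simulate_genotypes(cfg)
        rng = np.random.default_rng(0)
        y = 1.0 * gm.dosages["var000010"].to_numpy() + rng.normal(size=400)
        members = [f"var{j:06d}" for j in range(8, 14)]
        res = trans.conditional_trans(y, gm, members, "var000010", threshold=1e-4)
        assert len(res) == 0

    def test_two_independent_variants_leave_residual_signal(self):
        cfg = sd.SimConfig(
            n_samples=400, n_variants=40, n_genes=2, cell_types=("NK",), ld_rho=0.0,
            maf_range=(0.3, 0.5), seed=14,
        )
        gm = sd.simulate_genotypes(cfg)
        rng = np.random.default_rng(1)
        y = (
            0.8 * gm.dosages["var000010"].to_numpy()
            + 0.8 * gm.dosages["var000012"].to_numpy()
            + rng.normal(size=400)
        )
        res = trans.conditional_trans(y, gm, ["var000010", "var000011", "var000012"], "var000010", 1e-4)
        assert "var000012" in res.index

    def test_conditioning_on_causal_marks_it_untestable(self):
        cfg = sd.SimConfig(n_samples=200, n_variants=10, n_genes=2, cell_types=("NK",), seed=15)
        gm = sd.simulate_genotypes(cfg)
        y = gm.dosages["var000003"].to_numpy() + np.random.default_rng(2).normal(size=200)
        res = trans.conditional_trans(y, gm, ["var000003", "var000005"], "var000003", 0.5)
        assert "var000003" not in res.index


class TestCopyNumberTrans:
    def test_constant_copy_number_untestable(self):
        cfg = sd.SimConfig(n_samples=100, n_variants=10, n_genes=2, cell_types=("NK",), seed=16)
        gm = sd.simulate_genotypes(cfg)
        gm = sd.simulate_copy_number_locus(gm, [0, 0, 1, 0, 0], seed=1)
        (tab,) = sd.simulate_multicell_expression(gm, cfg, sd.TruthTable())
        adj = eqtl.adjust_phenotypes(tab, 0)
        with pytest.raises(ValueError, match="constant"):
            trans.copy_number_trans(adj, tab.probes, gm, "KIR_CN")
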
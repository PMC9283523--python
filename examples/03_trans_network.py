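"""Recover a trans network and trace it to its cis mediator.

A cis variant regulates GENE0001; GENE0001 expression feeds five distal
genes.  The trans scan (1,000 joint permutations) should find all five
targets, group their eSNPs into loci, and colocalisation of the mediator's
cis statistics with each target's trans statistics should flag mediation
(PP4 > 0.8).  A copy-number locus drives a further 3-gene network that
disappears after conditioning on the true copy number.
"""

import numpy as np
from scipy import stats

from nkqtl import coloc, eqtl, trans
from nkqtl import simdata as sd

cfg = sd.SimConfig(n_samples=400, n_variants=800, n_genes=20, ld_rho=0.4, seed=8)
gm = sd.simulate_genotypes(cfg)
gm = sd.simulate_copy_number_locus(gm, [0.1, 0.2, 0.4, 0.2, 0.1], seed=9)
genes = sd.gene_annotation(cfg, gm)
med_var = sd.nearest_variant(gm, *genes.loc["GENE0001", ["chrom", "tss"]])
targets = [f"GENE{k:04d}" for k in (2, 4, 6, 8, 10)]
cn_targets = [f"GENE{k:04d}" for k in (12, 14, 16)]
truth = sd.TruthTable(
    cis_effects=[sd.CisEffect("GENE0001", med_var, 1.2)],
    trans_edges=[sd.TransEdge("GENE0001", t, 0.8) for t in targets],
    copy_number_effects=[sd.CopyNumberEffect("KIR_CN", tuple(cn_targets), 0.8)],
)
(tab,) = sd.simulate_multicell_expression(gm, cfg, truth)
adj = eqtl.adjust_phenotypes(tab, 0)

snps = gm.subset(gm.variants.index[~gm.variants["is_copy_number"]])
hits, fdr = trans.trans_scan(adj, tab.probes, snps, n_perm=1000, seed=4)
print(f"trans threshold p <= {fdr.threshold:.2e} (estimated FDR {fdr.fdr_at_threshold:.3f})")
print(f"genes with trans hits: {sorted(hits['gene'].unique())} (planted: {targets})")
loci = trans.group_trans_loci(hits)
print(f"{len(loci)} trans loci after 1 Mb chain grouping")

# cis-mediation: coloc of mediator cis stats vs target trans stats
pm = tab.probes.loc["GENE0001_p1_NK"]
win = eqtl.cis_window_variants(snps, pm["chrom"], int(pm["tss"]), "+", 1_000_000)
sub = snps.subset(win)


def scan_stats(y):
    sc = eqtl.nominal_scan(y, sub, win)
    z = (sc["beta"] / sc["se"]).to_numpy()
    import pandas as pd

    meta = sub.variants
    tbl = pd.DataFrame(
        {"snp": win, "chrom": meta["chrom"].to_numpy(), "pos": meta["pos"].to_numpy(),
         "a1": meta["alt"].to_numpy(), "a2": meta["ref"].to_numpy(),
         "beta": sc["beta"].to_numpy(), "se": sc["se"].to_numpy(), "z": z,
         "p": 2 * stats.norm.sf(np.abs(z)), "n": cfg.n_samples, "maf": meta["maf"].to_numpy()}
    ).set_index("snp", drop=False)
    return sd.SummaryStatsTable(table=tbl)


cis_stats = scan_stats(adj["GENE0001_p1_NK"].to_numpy())
for t in targets:
    med = coloc.mediation_coloc(cis_stats, scan_stats(adj[f"{t}_p1_NK"].to_numpy()),
                                mediator_gene="GENE0001", target_gene=t)
    print(f"  {t}: mediation PP4 = {med.pp4:.3f} -> mediated = {med.mediated}")

# copy-number trans network, then condition on the true driver
cn_hits, _ = trans.copy_number_trans(adj, tab.probes, gm, "KIR_CN", n_perm=1000, seed=5)
print(f"copy-number network genes: {sorted(cn_hits['gene'].unique())} (planted: {cn_targets})")
cond, _ = trans.trans_scan(adj, tab.probes, gm.subset(["KIR_CN"]), n_perm=200, seed=6,
                           condition_on=gm.dosages["KIR_CN"].to_numpy())
print(f"hits remaining after conditioning on the true copy number: {len(cond)} (expect 0)")
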
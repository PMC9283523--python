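"""Colocalise an eQTL with a GWAS trait: Wakefield ABFs, PP0-PP4, and RTC.

Two GWAS scenarios against the same simulated eQTL: one trait shares the
causal variant (expect PP4 high, RTC score near 1), one has a distinct
causal variant in the region (expect PP3 high, RTC score unremarkable).
"""

import numpy as np

from nkqtl import coloc
from nkqtl import simdata as sd

cfg = sd.SimConfig(n_samples=500, n_variants=150, n_genes=2, ld_rho=0.7,
                   maf_range=(0.1, 0.5), n_chromosomes=1, seed=21)
gm = sd.simulate_genotypes(cfg)
eqtl_causal = gm.variants.index[70]
other_causal = gm.variants.index[20]


def gwas(causal, seed, n=60_000):
    maf = gm.variants.loc[causal, "maf"]
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n)
    return sd.simulate_gwas_stats(gm, causal, 8.0 * se, n, seed=seed)


eqtl_stats = gwas(eqtl_causal, seed=1, n=500)  # stands in for the cis scan summary
for label, causal in (("shared-causal trait", eqtl_causal), ("distinct-causal trait", other_causal)):
    res = coloc.coloc_abf(eqtl_stats, gwas(causal, seed=2))
    print(f"{label}: PP0..PP4 = {np.round(res.posteriors, 3)}")

# RTC from individual-level data: how completely does residualising the
# phenotype on the GWAS hit abolish the eQTL?
rng = np.random.default_rng(5)
y = 0.8 * gm.dosages[eqtl_causal].to_numpy() + rng.normal(size=cfg.n_samples)
esnp = gm.variants.index[71]  # LD partner tagging the causal variant
for label, gwas_hit in (("GWAS hit in LD with eQTL", gm.variants.index[72]),
                        ("unlinked GWAS hit", gm.variants.index[5])):
    r = coloc.rtc(y, gm, esnp, gwas_hit)
    print(f"{label}: RTC = {r.score:.3f} (rank {r.rank} of {r.n_interval}; > 0.9 is significant)")
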
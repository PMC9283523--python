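"""Call NK-cell-specific eQTL by multi-trait colocalisation across 5 cell types.

For each of two loci — one with an NK-only causal variant, one shared by all
cell types — build per-cell-type association summary statistics, enumerate
every sharing configuration (203 for five traits) and apply the decision
rule: "specific" needs posterior > 0.8 that the NK eQTL is shared with no
other cell type AND the NK-alone configuration to be the single best model.
"""

import numpy as np

from nkqtl import coloc
from nkqtl import simdata as sd

cfg = sd.SimConfig(n_samples=400, n_variants=150, n_genes=2, ld_rho=0.5,
                   maf_range=(0.1, 0.5), n_chromosomes=1, seed=3)
gm = sd.simulate_genotypes(cfg)
causal = gm.variants.index[60]
# cohort sizes of the five immune-cell datasets being compared
cells = {"NK": 245, "CD4": 282, "CD8": 271, "MONO": 414, "NEUT": 101}


def stats_for(z_target, n, seed):
    maf = gm.variants.loc[causal, "maf"]
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n)
    return sd.simulate_gwas_stats(gm, causal, z_target * se, n, seed=seed)


for scenario, z_others in (("NK-specific", 0.0), ("shared", 8.0)):
    labfs = {}
    for i, (cell, n) in enumerate(cells.items()):
        z = 8.0 if cell == "NK" else z_others
        labfs[cell] = coloc.abf_from_stats(stats_for(z, n, seed=hash(scenario) % 1000 + i)).to_numpy()
    res = coloc.multi_trait_coloc(labfs, focal="NK")
    call = coloc.specificity_call(res, gene="GENE0001")
    print(f"{scenario} locus ({len(res.configurations)} configurations enumerated):")
    print(f"  PP(NK not shared) = {res.pp_nk_specific:.3f}, PP(NK shared) = {res.pp_nk_shared:.3f}")
    print(f"  best configuration: {res.best_configuration} -> call: {call.call}")
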
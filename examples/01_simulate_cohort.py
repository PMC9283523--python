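"""Simulate a multi-cell-type eQTL cohort with planted truth and write it to disk.

Builds 245 samples x 1,000 LD-structured variants, NK and CD4 expression for
20 genes with one shared and one NK-specific cis effect, plus a KIR-like
copy-number locus, then writes VCF / phenotype BED / truth TSV / YAML config.
"""

import tempfile
from pathlib import Path

from nkqtl import io
from nkqtl import simdata as sd

cfg = sd.SimConfig(
    n_samples=245, n_variants=1000, n_genes=20, cell_types=("NK", "CD4"),
    ld_rho=0.6, seed=1,
)
gm = sd.simulate_genotypes(cfg)
gm = sd.simulate_copy_number_locus(gm, [0.05, 0.2, 0.5, 0.2, 0.05], seed=2)
genes = sd.gene_annotation(cfg, gm)

truth = sd.TruthTable(
    cis_effects=[
        sd.CisEffect("GENE0001", sd.nearest_variant(gm, *genes.loc["GENE0001", ["chrom", "tss"]]), 0.8),
        sd.CisEffect("GENE0002", sd.nearest_variant(gm, *genes.loc["GENE0002", ["chrom", "tss"]]), 0.8,
                     cell_types=("NK",)),
    ]
)
tables = sd.simulate_multicell_expression(gm, cfg, truth)

out = Path(tempfile.mkdtemp(prefix="nkqtl_cohort_"))
io.write_vcf(gm, out / "genotypes.vcf")
for tab in tables:
    io.write_phenotype_bed(tab, out / f"expression_{tab.cell_type}.bed")
io.write_truth_tsv(truth, out / "truth.tsv")
io.write_sim_config(cfg, out / "sim.yaml")

print(f"wrote cohort to {out}")
print(f"{gm.n_samples} samples, {gm.n_variants} variants "
      f"({int(gm.variants['is_copy_number'].sum())} copy-number locus)")
print(f"cell types: {[t.cell_type for t in tables]}, probes per table: {tables[0].values.shape[1]}")
print("planted effects:", [(e.gene, e.variant, e.cell_types or 'all') for e in truth.cis_effects])
# The truth table is the ground truth downstream examples try to recover.
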
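# nkqtl

Cell-type-resolved eQTL analysis in Python: cis and trans mapping with
permutation-based gene-level inference, multi-cell-type colocalisation for
calling cell-type-specific regulatory variants, trans-network cis-mediation,
GWAS colocalisation and enrichment, transcriptome-wide association (TWAS),
and analytic study-power design — all testable end to end on synthetic
cohorts with planted, recorded truth.

The package is aimed at statistical geneticists who want the full inference
architecture of an immune-cell eQTL study (the motivating design is an
NK-cell cohort of n = 245 European adults compared against CD4⁺/CD8⁺ T
cells, monocytes and neutrophils) as a reusable, unit-tested library rather
than a chain of heterogeneous command-line tools.

## What it computes

- **Cis mapping** (`nkqtl.eqtl`): additive model y = α + βg + ε per probe
  over a ±1 Mb window around the strand-aware TSS, after expression-PC
  residualisation and rank-normal transformation. The gene-level p is the
  Beta(a, b)-approximated tail of the permutation null of the window-wide
  minimum nominal p (the FastQTL/QTLtools scheme); FDR by Storey q-values;
  probes collapse to genes by best nominal association; independent signals
  by forward–backward stepwise conditioning. Variant QC: MAF ≥ 0.04,
  HWE χ² p ≥ 1e−6, missingness ≤ 2%.
- **Trans mapping** (`nkqtl.trans`): all pairs > 5 Mb or cross-chromosome,
  significance threshold from 1,000 joint phenotype-matrix permutations
  (FDR(t) = E[null hits]/observed hits), repeat-region SNP exclusion,
  an ungapped both-strand Hamming cross-mapping screen for probe artefacts
  (≤ 6 mismatches flags), 1 Mb chain grouping into loci, single-signal
  conditional testing, and copy-number-dosage mapping (e.g. KIR2DS4del).
- **Colocalisation** (`nkqtl.coloc`): Wakefield log approximate Bayes
  factors lABF = ½log(V/(V+W)) + ½z²W/(V+W); pairwise PP0–PP4; exhaustive
  multi-trait configuration enumeration (203 configurations for 5 cell
  types) with the specificity decision rule (PP(not shared) > 0.8 and the
  focal-alone model best); RTC scores from lead SNPs only; cis-mediation
  calls for trans signals (PP4 > 0.8).
- **Enrichment** (`nkqtl.enrich`): 1 kb annotation-density profiles,
  phenotype-permutation overlap enrichment, Fisher-exact GWAS-trait
  colocalisation enrichment against a null trait, hypergeometric pathways.
- **TWAS** (`nkqtl.twas`): cis h² by single-component REML with a 50:50
  χ²₀:χ²₁ LRT gate, 5-fold cross-validated weights (top1, ridge/BLUP,
  lasso, elastic net), Z = w′z/√(w′Rw), conditional pruning of correlated
  genes, and distance-based novelty flags.
- **Power** (`nkqtl.power`): exact noncentral-t power for the per-allele
  slope test and the minimum detectable MAF for a target power.
- **Synthetic data** (`nkqtl.simdata`): LD-structured genotypes (first-order
  haplotype copying), multi-cell expression with planted shared,
  cell-specific, conditional, trans-mediated and copy-number effects, and
  LD-consistent GWAS summary statistics — every planted effect recorded in
  a truth table.

## Worked example

`examples/04_cell_type_specificity.py` simulates an NK-only and an
all-shared eQTL across five immune cell types (n = 245, 282, 271, 414, 101)
and applies the multi-trait colocalisation decision rule:

```
NK-specific locus (203 configurations enumerated):
  PP(NK not shared) = 0.968, PP(NK shared) = 0.032
  best configuration: (('NK',),) -> call: specific
shared locus (203 configurations enumerated):
  PP(NK not shared) = 0.000, PP(NK shared) = 1.000
  best configuration: (('CD4', 'CD8', 'MONO', 'NEUT', 'NK'),) -> call: shared
```

The first locus is called NK-specific because 96.8% of the posterior lies
on configurations where the NK eQTL shares a causal variant with no other
cell type *and* the single best configuration is "NK alone"; the second
concentrates all posterior mass on one five-way shared causal variant.

The other examples walk through cohort simulation and file formats (01),
cis mapping with conditional signals (02), trans-network recovery and
cis-mediation (03), GWAS coloc and RTC (05), TWAS (06), and power plus
enrichment (07). Each prints the numbers it computes with a note on what
they mean.

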
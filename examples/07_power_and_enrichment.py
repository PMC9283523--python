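"""Study power design and enrichment machinery.

Part 1 reproduces the analytic design numbers: with 245 samples, per-allele
effect 0.13 and total SD 0.13, the study has 80% power down to MAF 0.08 for
the cis burden (100 x 18,000 tests) and MAF 0.12 for the genome-wide trans
burden (18,000 x 1e6 tests).

Part 2 runs the Fisher colocalisation-enrichment and hypergeometric pathway
tests on small planted examples.
"""

from nkqtl import enrich
from nkqtl.power import PowerSpec, min_maf_for_power, slr_power

for label, n_tests in (("cis", 100 * 18_000), ("trans", 18_000 * 1_000_000)):
    alpha = 0.05 / n_tests
    maf = min_maf_for_power(245, 0.13, 0.13, alpha, target=0.80)
    pw = slr_power(PowerSpec(n=245, maf=0.25, slope=0.13, sigma_y=0.13, alpha=alpha)).power
    print(f"{label}: 80% power for MAF > {maf} (at MAF 0.25 power is {pw:.3f})")

# GWAS-trait colocalisation enrichment vs the null trait (height):
# 8/20 eQTL colocalise with the trait, 2/20 with the null trait
res = enrich.coloc_enrichment([True] * 8 + [False] * 12, [True] * 2 + [False] * 18,
                              trait="autoimmune trait")
print(f"\ncoloc enrichment: OR = {res.odds_ratio:.1f}, Fisher p = {res.p:.3f}, "
      f"eligible = {res.eligible}")

# pathway enrichment of 3 specific-eQTL genes in a 5-gene pathway
background = [f"g{i}" for i in range(1000)]
query = ["g1", "g2", "g3", "g500", "g600"]
pathways = {"NK cytotoxicity": ["g1", "g2", "g3", "g10", "g11"]}
pw_res = enrich.pathway_hypergeom(query, pathways, background)
print(f"pathway overlap {int(pw_res['overlap'].iloc[0])}/5, "
      f"hypergeometric p = {pw_res['p'].iloc[0]:.2e}")
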
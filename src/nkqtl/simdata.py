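"""Synthetic genotype / expression / GWAS data with planted, recorded truth.

Every downstream stage of the toolkit (cis and trans eQTL mapping,
colocalisation, TWAS, enrichment) is exercised on data from this module, so
all of it is generated with an explicit truth table: which variants regulate
which genes, in which cell types, at what slope.

The generative model is deliberately simple and documented:

* Genotypes: two latent haplotypes per sample; allele frequencies drawn
  uniformly from ``maf_range``; linkage disequilibrium from a first-order
  copying process — each haplotype's allele at variant *j* copies its allele
  at variant *j − 1* with probability ``ld_rho`` and is otherwise a fresh
  Bernoulli draw.  For equal adjacent frequencies the dosage correlation of
  adjacent variants is exactly ``ld_rho``, and marginally every variant is
  in Hardy–Weinberg equilibrium at its frequency.
* Expression: additive per-allele effects plus an (optional) batch term,
  low-rank principal-component noise shared across genes, and iid Gaussian
  noise.  Cell-type-specific effects enter only the listed cell types.
* GWAS summary statistics: the causal variant's z-score is propagated to
  every variant through the sample LD correlation, with LD-correlated unit
  Gaussian noise, and converted to (beta, se) on the standardised-genotype
  scale with se = 1/sqrt(2·maf·(1−maf)·n).
* Copy-number loci: integer copy numbers 0–4 drawn iid from supplied
  frequencies, mimicking a multi-allelic structural variant such as the
  KIR2DS4 deletion used for copy-number-dosage trans mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "TruthTable",
    "CisEffect",
    "TransEdge",
    "GwasCausal",
    "CopyNumberEffect",
    "GenotypeMatrix",
    "PhenotypeTable",
    "SummaryStatsTable",
    "simulate_genotypes",
    "simulate_multicell_expression",
    "simulate_gwas_stats",
    "simulate_copy_number_locus",
    "gene_annotation",
    "nearest_variant",
]


# ---------------------------------------------------------------------------
# configuration and truth records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate a cohort of 245 genotyped individuals with array
    expression in several purified immune cell types; variants are laid out
    on two chromosomes at ``variant_spacing`` intervals so that every gene
    has a well-populated 1 Mb cis window.
    """

    n_samples: int = 245
    n_variants: int = 1000
    n_genes: int = 20
    cell_types: tuple[str, ...] = ("NK",)
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    n_expression_pcs_noise: int = 0
    pc_noise_sd: float = 1.0
    batch_effect_sd: float = 0.0
    noise_sd: float = 1.0
    n_probes_per_gene: int = 1
    probe_noise_sd: float = 0.0
    probe_length: int = 50
    n_chromosomes: int = 2
    variant_spacing: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_variants, self.n_genes) <= 0:
            raise ValueError("n_samples, n_variants and n_genes must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if not self.cell_types:
            raise ValueError("at least one cell type is required")


@dataclass(frozen=True)
class CisEffect:
    """A planted cis-regulatory effect: ``cell_types=None`` means shared by all."""

    gene: str
    variant: str
    slope: float
    cell_types: tuple[str, ...] | None = None
    rank: int = 1


@dataclass(frozen=True)
class TransEdge:
    """Mediated trans effect: target expression gains slope × mediator expression."""

    mediator_gene: str
    target_gene: str
    slope: float


@dataclass(frozen=True)
class GwasCausal:
    trait: str
    variant: str
    slope: float
    shared_with_eqtl: bool = True


@dataclass(frozen=True)
class CopyNumberEffect:
    locus: str
    target_genes: tuple[str, ...]
    slope: float


@dataclass
class TruthTable:
    cis_effects: list[CisEffect] = field(default_factory=list)
    conditional_effects: list[CisEffect] = field(default_factory=list)
    trans_edges: list[TransEdge] = field(default_factory=list)
    gwas_causals: list[GwasCausal] = field(default_factory=list)
    copy_number_effects: list[CopyNumberEffect] = field(default_factory=list)

    def all_cis(self) -> list[CisEffect]:
        return [*self.cis_effects, *self.conditional_effects]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples × variants dosage matrix with per-variant metadata.

    ``dosages`` is indexed by sample id with one column per variant id;
    ``variants`` is indexed by variant id with columns
    ``chrom, pos, ref, alt, maf, is_copy_number`` (``pos`` 1-based,
    strictly increasing within each chromosome).  Copy-number loci carry
    integer dosages in 0–4 and ``maf`` is not defined for them.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def recompute_maf(self) -> pd.Series:
        """Folded allele frequency from the dosage columns (SNPs only)."""
        af = self.dosages.mean(axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def validate(self) -> None:
        snp = ~self.variants["is_copy_number"].to_numpy(bool)
        maf = self.recompute_maf().to_numpy()[snp]
        stored = self.variants["maf"].to_numpy()[snp]
        if not np.allclose(maf, stored, atol=1e-12):
            raise ValueError("stored maf does not match dosage-derived maf")
        for _, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions not strictly increasing within chromosome")

    def subset(self, variant_ids) -> "GenotypeMatrix":
        variant_ids = list(variant_ids)
        return GenotypeMatrix(
            dosages=self.dosages[variant_ids], variants=self.variants.loc[variant_ids]
        )


@dataclass
class PhenotypeTable:
    """Samples × probes expression matrix with probe metadata.

    ``probes`` is indexed by probe id with columns
    ``gene, chrom, tss, strand, cell_type, sequence``.
    """

    values: pd.DataFrame
    probes: pd.DataFrame

    @property
    def cell_type(self) -> str:
        return str(self.probes["cell_type"].iloc[0])

    def validate(self) -> None:
        if not set(self.probes["strand"]).issubset({"+", "-"}):
            raise ValueError("strand must be + or -")
        if self.probes.index.duplicated().any():
            raise ValueError("duplicate probe ids")


@dataclass
class SummaryStatsTable:
    """Per-variant association summary statistics for one trait.

    ``table`` columns: ``snp chrom pos a1 a2 beta se z p n maf``; ``a1`` is
    the effect allele.  For case-control traits ``case_fraction`` is the
    proportion of cases and betas are on the log-odds scale.
    """

    table: pd.DataFrame
    trait_type: str = "quantitative"
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case-control"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "case-control" and self.case_fraction is None:
            raise ValueError("case-control stats require case_fraction")

    def validate(self) -> None:
        t = self.table
        z = t["beta"].to_numpy() / t["se"].to_numpy()
        if not np.allclose(z, t["z"].to_numpy(), atol=1e-9):
            raise ValueError("z != beta/se")
        p = 2.0 * stats.norm.sf(np.abs(z))
        if not np.allclose(p, t["p"].to_numpy(), atol=1e-9):
            raise ValueError("p is not the two-sided normal tail of z")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _variant_layout(config: SimConfig) -> pd.DataFrame:
    """Assign variants to chromosomes with evenly spaced 1-based positions."""
    m = config.n_variants
    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chroms, positions = [], []
    for j in range(m):
        c = j // per_chrom
        k = j % per_chrom
        chroms.append(str(c + 1))
        positions.append((k + 1) * config.variant_spacing)
    ids = [f"var{j + 1:06d}" for j in range(m)]
    return pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": "A", "alt": "G"},
        index=pd.Index(ids, name="variant"),
    )


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw dosages under HWE with first-order haplotype-copying LD."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = config.n_samples, config.n_variants
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)

    hap = np.empty((2 * n, m), dtype=np.int8)
    hap[:, 0] = rng.random(2 * n) < freqs[0]
    new_chrom = np.zeros(m, dtype=bool)
    layout = _variant_layout(config)
    chrom_arr = layout["chrom"].to_numpy()
    new_chrom[1:] = chrom_arr[1:] != chrom_arr[:-1]
    for j in range(1, m):
        fresh = rng.random(2 * n) < freqs[j]
        if config.ld_rho > 0 and not new_chrom[j]:
            copy = rng.random(2 * n) < config.ld_rho
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        else:
            hap[:, j] = fresh

    dos = (hap[:n] + hap[n:]).astype(np.float64)
    samples = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample")
    dosages = pd.DataFrame(dos, index=samples, columns=layout.index)

    af = dosages.mean(axis=0) / 2.0
    meta = layout.copy()
    meta["maf"] = np.minimum(af, 1.0 - af)
    meta["is_copy_number"] = False
    return GenotypeMatrix(dosages=dosages, variants=meta)


def simulate_copy_number_locus(
    genotypes: GenotypeMatrix,
    frequencies,
    locus_id: str = "KIR_CN",
    chrom: str = "19",
    pos: int = 55_000_000,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Append an integer copy-number locus (copies 0..4) drawn iid from ``frequencies``."""
    rng = np.random.default_rng(seed) if rng is None else rng
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.ndim != 1 or len(freqs) != 5:
        raise ValueError("frequencies must give probabilities for copies 0..4")
    if np.any(freqs < 0):
        raise ValueError("frequencies must be non-negative")
    if not np.isclose(freqs.sum(), 1.0):
        raise ValueError("frequencies must sum to 1")
    cn = rng.choice(5, size=genotypes.n_samples, p=freqs).astype(np.float64)
    dosages = genotypes.dosages.copy()
    dosages[locus_id] = cn
    meta = genotypes.variants.copy()
    meta.loc[locus_id] = {
        "chrom": chrom,
        "pos": pos,
        "ref": "N",
        "alt": "<CN>",
        "maf": np.nan,
        "is_copy_number": True,
    }
    return GenotypeMatrix(dosages=dosages, variants=meta)


def gene_annotation(config: SimConfig, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Place genes evenly across the simulated chromosomes, alternating strand."""
    snps = genotypes.variants.loc[~genotypes.variants["is_copy_number"]]
    chrom_span = {c: (g["pos"].min(), g["pos"].max()) for c, g in snps.groupby("chrom", sort=False)}
    chrom_names = list(chrom_span)
    rows = []
    for g in range(config.n_genes):
        c = chrom_names[g % len(chrom_names)]
        lo, hi = chrom_span[c]
        k = g // len(chrom_names)
        n_on_chrom = int(np.ceil(config.n_genes / len(chrom_names)))
        frac = (k + 0.5) / n_on_chrom
        tss = int(lo + frac * (hi - lo))
        rows.append(
            {"gene": f"GENE{g + 1:04d}", "chrom": c, "tss": tss, "strand": "+" if g % 2 == 0 else "-"}
        )
    return pd.DataFrame(rows).set_index("gene")


def simulate_multicell_expression(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    plan: TruthTable,
    rng: np.random.Generator | None = None,
) -> list[PhenotypeTable]:
    """Generate one expression table per cell type with planted effects.

    Per cell type: y_gene = Σ slope·dosage (cis and conditional effects
    active in that cell type) + batch + low-rank PC noise + N(0, noise_sd²),
    then trans edges add slope × mediator expression to the target and
    copy-number effects add slope × copy number.  Probe values are the gene
    value plus probe-specific noise when several probes map to one gene.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    genes = gene_annotation(config, genotypes)
    known_variants = set(genotypes.variants.index)
    for eff in plan.all_cis():
        if eff.gene not in genes.index:
            raise ValueError(f"planted effect references unknown gene {eff.gene!r}")
        if eff.variant not in known_variants:
            raise ValueError(f"planted effect references unknown variant {eff.variant!r}")
        if eff.cell_types is not None and not set(eff.cell_types) <= set(config.cell_types):
            raise ValueError(f"unknown cell type in planted effect for {eff.gene!r}")
    for edge in plan.trans_edges:
        if edge.mediator_gene not in genes.index or edge.target_gene not in genes.index:
            raise ValueError("trans edge references unknown gene")
    for cne in plan.copy_number_effects:
        if cne.locus not in known_variants:
            raise ValueError(f"unknown copy-number locus {cne.locus!r}")
        if not set(cne.target_genes) <= set(genes.index):
            raise ValueError("copy-number effect references unknown gene")

    n = genotypes.n_samples
    batch = rng.integers(0, 2, size=n).astype(float)
    tables: list[PhenotypeTable] = []
    for ct in config.cell_types:
        Y = rng.normal(0.0, config.noise_sd, size=(n, config.n_genes))
        if config.n_expression_pcs_noise > 0:
            k = config.n_expression_pcs_noise
            scores = rng.normal(size=(n, k))
            loadings = rng.normal(0.0, config.pc_noise_sd, size=(k, config.n_genes))
            Y += scores @ loadings
        if config.batch_effect_sd > 0:
            coefs = rng.normal(0.0, config.batch_effect_sd, size=config.n_genes)
            Y += np.outer(batch, coefs)
        gene_idx = {g: i for i, g in enumerate(genes.index)}
        for eff in plan.all_cis():
            if eff.cell_types is None or ct in eff.cell_types:
                Y[:, gene_idx[eff.gene]] += eff.slope * genotypes.dosages[eff.variant].to_numpy()
        for cne in plan.copy_number_effects:
            cn = genotypes.dosages[cne.locus].to_numpy()
            for tg in cne.target_genes:
                Y[:, gene_idx[tg]] += cne.slope * cn
        for edge in plan.trans_edges:
            Y[:, gene_idx[edge.target_gene]] += edge.slope * Y[:, gene_idx[edge.mediator_gene]]

        probe_rows, cols = [], []
        values = np.empty((n, config.n_genes * config.n_probes_per_gene))
        j = 0
        for g, meta in genes.iterrows():
            for pnum in range(config.n_probes_per_gene):
                pid = f"{g}_p{pnum + 1}_{ct}"
                v = Y[:, gene_idx[g]].copy()
                if config.n_probes_per_gene > 1 and config.probe_noise_sd > 0:
                    v += rng.normal(0.0, config.probe_noise_sd, size=n)
                values[:, j] = v
                seq = "".join(rng.choice(list("ACGT"), size=config.probe_length))
                probe_rows.append(
                    {
                        "probe": pid,
                        "gene": g,
                        "chrom": meta["chrom"],
                        "tss": int(meta["tss"]),
                        "strand": meta["strand"],
                        "cell_type": ct,
                        "sequence": seq,
                    }
                )
                cols.append(pid)
                j += 1
        tables.append(
            PhenotypeTable(
                values=pd.DataFrame(values, index=genotypes.dosages.index, columns=cols),
                probes=pd.DataFrame(probe_rows).set_index("probe"),
            )
        )
    return tables


def simulate_gwas_stats(
    genotypes: GenotypeMatrix,
    causal: str,
    slope: float,
    n_gwas: int,
    trait_type: str = "quantitative",
    case_fraction: float | None = None,
    variant_ids=None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> SummaryStatsTable:
    """Summary statistics for a trait with one causal variant.

    z_j = r_j · z_causal + ε_j where r_j is the sample LD correlation with
    the causal variant and ε has unit marginal variance and the same LD
    correlation structure (constructed by projecting white noise through the
    standardised genotype matrix).  ``slope`` is on the standardised
    per-allele scale, so z_causal = slope · sqrt(2·maf·(1−maf)·n_gwas).
    """
    if n_gwas < 2:
        raise ValueError("n_gwas must be >= 2")
    rng = np.random.default_rng(seed) if rng is None else rng
    if variant_ids is None:
        meta = genotypes.variants
        variant_ids = meta.index[~meta["is_copy_number"]].tolist()
    if causal not in variant_ids:
        raise ValueError(f"causal variant {causal!r} not among variants")

    G = genotypes.dosages[variant_ids].to_numpy(float)
    n_ref = G.shape[0]
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    sd[sd == 0] = np.nan
    Gs = (G - mu) / sd
    gc = Gs[:, list(variant_ids).index(causal)]
    r = Gs.T @ gc / n_ref

    maf = genotypes.variants.loc[variant_ids, "maf"].to_numpy(float)
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_gwas)
    z_causal = slope / se[list(variant_ids).index(causal)]

    # LD-correlated unit-variance noise: cov(Gs' u / sqrt(n)) = R
    eps = Gs.T @ rng.normal(size=n_ref) / np.sqrt(n_ref)
    z = r * z_causal + eps
    beta = z * se
    p = 2.0 * stats.norm.sf(np.abs(z))
    meta = genotypes.variants.loc[variant_ids]
    table = pd.DataFrame(
        {
            "snp": variant_ids,
            "chrom": meta["chrom"].to_numpy(),
            "pos": meta["pos"].to_numpy(),
            "a1": meta["alt"].to_numpy(),
            "a2": meta["ref"].to_numpy(),
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "n": n_gwas,
            "maf": maf,
        }
    ).set_index("snp", drop=False)
    return SummaryStatsTable(table=table, trait_type=trait_type, case_fraction=case_fraction)


def nearest_variant(genotypes: GenotypeMatrix, chrom: str, pos: int) -> str:
    """Id of the SNP closest to (chrom, pos) — convenient for planting cis effects."""
    meta = genotypes.variants
    sel = (meta["chrom"] == chrom) & ~meta["is_copy_number"]
    if not sel.any():
        raise ValueError(f"no SNPs on chromosome {chrom!r}")
    sub = meta.loc[sel]
    return str(sub.index[int(np.argmin(np.abs(sub["pos"].to_numpy() - pos)))])
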
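"""Readers and writers for the standard on-disk formats.

Genotypes travel as VCF with a DS (dosage) FORMAT field or as a plain TSV
dosage matrix; expression as a QTLtools-style phenotype BED (0-based
half-open on disk, 1-based TSS internally); GWAS summary statistics,
truth tables, covariates and annotation tracks as TSV/BED; gene sets as
GMT; simulation configs as YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .simdata import GenotypeMatrix, PhenotypeTable, SimConfig, SummaryStatsTable, TruthTable

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_phenotype_bed",
    "read_phenotype_bed",
    "write_truth_tsv",
    "write_sim_config",
    "read_sim_config",
    "read_bed_track",
    "write_gwas_tsv",
    "read_gwas_tsv",
    "read_gmt",
]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 with GT (hard-called) and DS (dosage) per sample."""
    meta = genotypes.variants
    samples = list(genotypes.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in meta["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for vid, row in meta.iterrows():
            ds = genotypes.dosages[vid].to_numpy(float)
            gt = np.rint(ds).astype(int)
            cells = []
            for g, d in zip(gt, ds):
                if np.isnan(d):
                    cells.append("./.:.")
                    continue
                gstr = {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(min(g, 2)), "1/1")
                cells.append(f"{gstr}:{d:.6g}")
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t{row['alt']}\t.\t.\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Load a VCF with a DS FORMAT field (falls back to GT allele counts)."""
    vcf = VCF(str(path))
    samples = vcf.samples
    rows, dosages = [], []
    for rec in vcf:
        try:
            ds = np.asarray(rec.format("DS"), dtype=float).ravel()
        except (KeyError, TypeError, ValueError):
            gts = rec.genotype.array()
            ds = gts[:, 0].clip(0) + gts[:, 1].clip(0)
            ds = ds.astype(float)
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        alt = rec.ALT[0] if rec.ALT else "."
        is_cn = alt.startswith("<")
        af = np.nanmean(ds) / 2.0
        rows.append(
            {
                "variant": vid,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": alt,
                "maf": np.nan if is_cn else min(af, 1.0 - af),
                "is_copy_number": is_cn,
            }
        )
        dosages.append(ds)
    meta = pd.DataFrame(rows).set_index("variant")
    dm = pd.DataFrame(
        np.array(dosages).T, index=pd.Index(samples, name="sample"), columns=meta.index
    )
    return GenotypeMatrix(dosages=dm, variants=meta)


def write_dosage_tsv(genotypes: GenotypeMatrix, dosage_path, meta_path) -> None:
    genotypes.dosages.to_csv(dosage_path, sep="\t")
    genotypes.variants.to_csv(meta_path, sep="\t")


def read_dosage_tsv(dosage_path, meta_path) -> GenotypeMatrix:
    dm = pd.read_csv(dosage_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta["chrom"] = meta["chrom"].astype(str)
    return GenotypeMatrix(dosages=dm, variants=meta)


# ---------------------------------------------------------------------------
# phenotypes (QTLtools-style BED)
# ---------------------------------------------------------------------------


def write_phenotype_bed(phenotypes: PhenotypeTable, path) -> None:
    """chrom, start, end, pid, gid, strand then one column per sample.

    On disk the TSS is 0-based half-open: start = tss − 1, end = tss.
    """
    probes = phenotypes.probes
    vals = phenotypes.values
    with open(path, "w") as fh:
        fh.write("#chr\tstart\tend\tpid\tgid\tstrand\t" + "\t".join(vals.index) + "\n")
        for pid, row in probes.iterrows():
            tss = int(row["tss"])
            expr = "\t".join(f"{v:.6g}" for v in vals[pid].to_numpy())
            fh.write(
                f"{row['chrom']}\t{tss - 1}\t{tss}\t{pid}\t{row['gene']}\t{row['strand']}\t{expr}\n"
            )


def read_phenotype_bed(path, cell_type: str = "") -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={df.columns[0]: "chr"})
    sample_cols = list(df.columns[6:])
    probes = pd.DataFrame(
        {
            "probe": df["pid"],
            "gene": df["gid"],
            "chrom": df["chr"].astype(str),
            "tss": df["end"].astype(int),  # back to 1-based inclusive
            "strand": df["strand"],
            "cell_type": cell_type,
            "sequence": "",
        }
    ).set_index("probe")
    values = pd.DataFrame(
        df[sample_cols].to_numpy(float).T,
        index=pd.Index(sample_cols, name="sample"),
        columns=probes.index,
    )
    return PhenotypeTable(values=values, probes=probes)


# ---------------------------------------------------------------------------
# truth table / config
# ---------------------------------------------------------------------------


def write_truth_tsv(truth: TruthTable, path) -> None:
    rows = []
    for eff in truth.cis_effects:
        rows.append(("cis", eff.gene, eff.variant, eff.slope,
                     ",".join(eff.cell_types) if eff.cell_types else "all", eff.rank))
    for eff in truth.conditional_effects:
        rows.append(("conditional", eff.gene, eff.variant, eff.slope,
                     ",".join(eff.cell_types) if eff.cell_types else "all", eff.rank))
    for e in truth.trans_edges:
        rows.append(("trans_edge", e.mediator_gene, e.target_gene, e.slope, "", ""))
    for g in truth.gwas_causals:
        rows.append(("gwas", g.trait, g.variant, g.slope, str(g.shared_with_eqtl), ""))
    for c in truth.copy_number_effects:
        rows.append(("copy_number", c.locus, ";".join(c.target_genes), c.slope, "", ""))
    pd.DataFrame(rows, columns=["kind", "id1", "id2", "slope", "extra", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def write_sim_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)


def read_sim_config(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("cell_types", "maf_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)


# ---------------------------------------------------------------------------
# tracks, GWAS, gene sets
# ---------------------------------------------------------------------------


def read_bed_track(path, with_label: bool = False) -> pd.DataFrame:
    """BED (0-based half-open); malformed lines are rejected with their number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"malformed BED line {lineno}: start >= end")
            row = {"chrom": parts[0], "start": start, "end": end}
            if with_label:
                row["label"] = parts[3] if len(parts) > 3 else "."
            rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"] + (["label"] if with_label else []))


def write_gwas_tsv(stats: SummaryStatsTable, path) -> None:
    t = stats.table.rename(
        columns={"snp": "SNP", "chrom": "CHR", "pos": "POS", "a1": "A1", "a2": "A2",
                 "beta": "BETA", "se": "SE", "p": "P", "n": "N", "maf": "MAF"}
    )
    cols = ["SNP", "CHR", "POS", "A1", "A2", "BETA", "SE", "P", "N", "MAF"]
    t = t[cols].copy()
    t["TYPE"] = stats.trait_type
    t.to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path) -> SummaryStatsTable:
    df = pd.read_csv(path, sep="\t")
    trait_type = df["TYPE"].iloc[0] if "TYPE" in df else "quantitative"
    z = df["BETA"] / df["SE"]
    table = pd.DataFrame(
        {
            "snp": df["SNP"],
            "chrom": df["CHR"].astype(str),
            "pos": df["POS"].astype(int),
            "a1": df["A1"],
            "a2": df["A2"],
            "beta": df["BETA"].astype(float),
            "se": df["SE"].astype(float),
            "z": z.astype(float),
            "p": df["P"].astype(float),
            "n": df["N"] if "N" in df else np.nan,
            "maf": df["MAF"] if "MAF" in df else np.nan,
        }
    ).set_index("snp", drop=False)
    return SummaryStatsTable(table=table, trait_type=str(trait_type))


def read_gmt(path) -> dict[str, list[str]]:
    """GMT-like TSV: pathway id, description, then member genes."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
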
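"""Cis eQTL mapping: association engine, permutation gene-level p, FDR, conditionals.

The mapping pipeline mirrors the standard array-eQTL workflow: variant QC
(MAF / HWE / missingness), residualisation of expression on expression PCs,
rank-normal transformation, a nominal additive-model scan over the ±1 Mb cis
window of each probe, a seeded permutation scheme whose null minimum-p
distribution is summarised by a fitted Beta(a, b) (the FastQTL
approximation), probe-to-gene collapsing by best nominal association,
Storey q-value FDR across genes, and forward-backward stepwise conditional
analysis for independent signals.

Phenotype adjustment (PCs, rank-normalisation) is performed once before the
scan, so nominal tests use df = n − 2.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, optimize, special, stats

from .simdata import GenotypeMatrix, PhenotypeTable

__all__ = [
    "MapConfig",
    "PermutationFit",
    "ConditionalSignal",
    "qc_variants",
    "rank_normal",
    "residualise",
    "expression_pcs",
    "nominal_scan",
    "permutation_gene_p",
    "qvalues",
    "best_probe",
    "nominal_thresholds",
    "conditional_scan",
    "map_cis",
    "select_pc_count",
    "logit_lrt",
    "ase_chisq",
    "rng_for_phenotype",
]


@dataclass(frozen=True)
class MapConfig:
    """Tuning parameters for cis mapping (defaults follow array-eQTL practice)."""

    cis_window: int = 1_000_000
    maf_min: float = 0.04
    hwe_p_min: float = 1e-6
    missing_max: float = 0.02
    n_perm: int = 10_000
    n_pcs: int = 0
    fdr_level: float = 0.05
    max_signals: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must be in (0, 1)")


@dataclass(frozen=True)
class PermutationFit:
    """Beta-approximated permutation summary for one phenotype."""

    n_perm: int
    a: float
    b: float
    p_empirical: float
    p_beta: float
    p_min_obs: float
    lead_variant: str


@dataclass(frozen=True)
class ConditionalSignal:
    gene: str
    rank: int
    lead_variant: str
    p: float
    beta: float
    retained: bool


def rng_for_phenotype(seed: int, phenotype_id: str) -> np.random.Generator:
    """Per-phenotype RNG derived from (global seed, id hash): order-independent."""
    return np.random.default_rng([seed, zlib.crc32(phenotype_id.encode())])


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------


def hwe_chisq_p(dosage: np.ndarray) -> float:
    """1-df chi-square HWE test on hard-called genotypes (dosage rounded)."""
    g = np.rint(dosage[np.isfinite(dosage)]).astype(int)
    n = len(g)
    if n == 0:
        return 1.0
    counts = np.bincount(np.clip(g, 0, 2), minlength=3)
    p = (2 * counts[2] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(np.sum((counts - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, 1))


def qc_variants(genotypes: GenotypeMatrix, config: MapConfig) -> GenotypeMatrix:
    """Filter SNPs on MAF, HWE and missingness; mean-impute missing dosages after.

    Copy-number loci are exempt from the SNP filters and kept as-is.
    """
    dos = genotypes.dosages
    meta = genotypes.variants
    keep = []
    for vid in dos.columns:
        if meta.loc[vid, "is_copy_number"]:
            keep.append(vid)
            continue
        x = dos[vid].to_numpy(float)
        miss = np.mean(~np.isfinite(x))
        if miss > config.missing_max:
            continue
        obs = x[np.isfinite(x)]
        af = obs.mean() / 2.0
        maf = min(af, 1.0 - af)
        if maf < config.maf_min:
            continue
        if hwe_chisq_p(obs) < config.hwe_p_min:
            continue
        keep.append(vid)
    if not keep:
        warnings.warn("all variants removed by QC", stacklevel=2)
        return GenotypeMatrix(dosages=dos[[]], variants=meta.loc[[]])
    out = dos[keep].copy()
    out = out.fillna(out.mean(axis=0))
    new_meta = meta.loc[keep].copy()
    snp = ~new_meta["is_copy_number"].to_numpy(bool)
    af = out.mean(axis=0).to_numpy() / 2.0
    new_meta.loc[snp, "maf"] = np.minimum(af, 1.0 - af)[snp]
    return GenotypeMatrix(dosages=out, variants=new_meta)


# ---------------------------------------------------------------------------
# phenotype adjustment
# ---------------------------------------------------------------------------


def rank_normal(values) -> np.ndarray:
    """Rank-based inverse normal transform: Phi^-1((rank − 0.5)/n), ties averaged."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-d vector of length >= 3")
    if np.all(x == x[0]):
        raise ValueError("cannot rank-normalise a constant vector")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def residualise(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of columns of ``values`` on [1, covariates].

    Raises on rank-deficient covariates, naming the offending column.
    """
    Y = np.asarray(values, dtype=float)
    one_d = Y.ndim == 1
    if one_d:
        Y = Y[:, None]
    n = Y.shape[0]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        X = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
        R = np.linalg.qr(X, mode="r")
        diag = np.abs(np.diag(R))
        bad = np.where(diag < 1e-10 * max(diag.max(), 1.0))[0]
        if bad.size:
            raise ValueError(
                f"covariate column {bad[0] - 1} is linearly dependent on earlier columns"
            )
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return resid[:, 0] if one_d else resid


def expression_pcs(values: pd.DataFrame, n_pcs: int) -> np.ndarray:
    """Top principal-component scores of a samples × probes expression matrix."""
    if n_pcs == 0:
        return np.empty((values.shape[0], 0))
    X = values.to_numpy(float)
    X = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_pcs, len(s))
    return U[:, :k] * s[:k]


# ---------------------------------------------------------------------------
# nominal scan
# ---------------------------------------------------------------------------


def _corr_stats(y: np.ndarray, G: np.ndarray):
    """Correlation of y with each column of G plus slope/se/t/p, df = n − 2.

    Returns (r, beta, se, t, p, testable).
    """
    n = len(y)
    yc = y - y.mean()
    sy = np.sqrt(yc @ yc)
    Gc = G - G.mean(axis=0)
    sg = np.sqrt(np.einsum("ij,ij->j", Gc, Gc))
    testable = sg > 0
    sg_safe = np.where(testable, sg, np.nan)
    r = (Gc.T @ yc) / (sg_safe * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    denom = np.maximum(1.0 - r**2, 1e-300)
    t = r * np.sqrt(df / denom)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    beta = r * sy / sg_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(np.abs(t) > 0, beta / t, sy / (sg_safe * np.sqrt(df)))
    return r, beta, se, t, p, testable


def nominal_scan(
    phenotype: np.ndarray,
    genotypes: GenotypeMatrix,
    variant_ids=None,
    tss: int | None = None,
) -> pd.DataFrame:
    """Simple-regression association of an adjusted phenotype with each variant."""
    if variant_ids is None:
        variant_ids = list(genotypes.dosages.columns)
    else:
        variant_ids = list(variant_ids)
    if not variant_ids:
        raise ValueError("empty variant subset")
    G = genotypes.dosages[variant_ids].to_numpy(float)
    y = np.asarray(phenotype, dtype=float)
    r, beta, se, t, p, testable = _corr_stats(y, G)
    out = pd.DataFrame(
        {
            "variant": variant_ids,
            "beta": beta,
            "se": se,
            "t": t,
            "p_nominal": p,
            "df": len(y) - 2,
            "testable": testable,
        }
    ).set_index("variant", drop=False)
    if tss is not None:
        out["distance_to_tss"] = genotypes.variants.loc[variant_ids, "pos"].to_numpy() - tss
    return out


def cis_window_variants(
    genotypes: GenotypeMatrix, chrom: str, tss: int, strand: str, window: int
) -> list[str]:
    """Variant ids within ±window of the strand-aware TSS, inclusive bounds."""
    meta = genotypes.variants
    mask = (
        (meta["chrom"] == chrom)
        & (meta["pos"] >= tss - window)
        & (meta["pos"] <= tss + window)
        & ~meta["is_copy_number"]
    )
    return meta.index[mask].tolist()


# ---------------------------------------------------------------------------
# permutation scheme with Beta approximation
# ---------------------------------------------------------------------------


def fit_beta_mle(x: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Beta(a, b) fit with a method-of-moments start."""
    x = np.clip(np.asarray(x, dtype=float), 1e-300, 1.0 - 1e-16)
    m, v = x.mean(), x.var()
    if v <= 0:
        raise ValueError("degenerate sample for beta fit")
    common = m * (1.0 - m) / v - 1.0
    a0 = max(m * common, 1e-3)
    b0 = max((1.0 - m) * common, 1e-3)
    lx = np.log(x).mean()
    l1x = np.log1p(-x).mean()

    def nll(theta):
        a, b = np.exp(theta)
        return -((a - 1.0) * lx + (b - 1.0) * l1x - special.betaln(a, b))

    res = optimize.minimize(nll, np.log([a0, b0]), method="Nelder-Mead")
    a, b = np.exp(res.x)
    return float(a), float(b)


def permutation_gene_p(
    phenotype: np.ndarray,
    cis_genotypes: GenotypeMatrix,
    config: MapConfig,
    rng: np.random.Generator | None = None,
    variant_ids=None,
) -> PermutationFit:
    """Gene-level permutation p with the Beta approximation of the null min-p.

    The observed statistic is the minimum nominal p over the cis window.
    Each of ``config.n_perm`` permutations shuffles sample labels of the
    phenotype and records the null minimum p; a Beta(a, b) is fitted to the
    null sample by MLE and p_beta is its CDF at the observed minimum.
    """
    if config.n_perm < 50:
        raise ValueError("need at least 50 permutations for a stable beta fit")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if variant_ids is None:
        variant_ids = list(cis_genotypes.dosages.columns)
    G = cis_genotypes.dosages[variant_ids].to_numpy(float)
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    df = n - 2

    Gc = G - G.mean(axis=0)
    sg = np.sqrt(np.einsum("ij,ij->j", Gc, Gc))
    testable = sg > 0
    if not testable.any():
        raise ValueError("no testable cis variant")
    Gn = Gc[:, testable] / sg[testable]
    ids = [v for v, t in zip(variant_ids, testable) if t]

    yc = y - y.mean()
    yn = yc / np.sqrt(yc @ yc)
    r_obs = Gn.T @ yn
    i_best = int(np.argmax(np.abs(r_obs)))

    def p_from_absr(absr):
        absr = np.clip(absr, 0.0, 1.0)
        t = absr * np.sqrt(df / np.maximum(1.0 - absr**2, 1e-300))
        return 2.0 * stats.t.sf(t, df)

    p_obs = float(p_from_absr(abs(r_obs[i_best])))

    perm_idx = np.argsort(rng.random((config.n_perm, n)), axis=1)
    Yp = yn[perm_idx].T  # n × n_perm
    null_max_r = np.max(np.abs(Gn.T @ Yp), axis=0)
    null_min_p = p_from_absr(null_max_r)

    a, b = fit_beta_mle(null_min_p)
    p_beta = float(stats.beta.cdf(p_obs, a, b))
    p_emp = float((1 + np.sum(null_min_p <= p_obs)) / (config.n_perm + 1))
    return PermutationFit(
        n_perm=config.n_perm,
        a=a,
        b=b,
        p_empirical=p_emp,
        p_beta=max(p_beta, 1e-300),
        p_min_obs=p_obs,
        lead_variant=ids[i_best],
    )


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with smoothed pi0; falls back to BH (pi0 = 1).

    pi0 is estimated on the lambda grid 0.05..0.95 with a cubic smoothing
    spline evaluated at the largest lambda; estimates >= 1, non-finite or
    non-positive fall back to pi0 = 1 (Benjamini-Hochberg).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    if pi0 is None:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
        try:
            spl = interpolate.UnivariateSpline(lam, pi0_lam, k=3)
            pi0_hat = float(spl(lam[-1]))
        except Exception:
            pi0_hat = 1.0
        pi0 = pi0_hat if np.isfinite(pi0_hat) and 0.0 < pi0_hat < 1.0 else 1.0
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    ps = p[order]
    qs = pi0 * m * ps / np.arange(1, m + 1)
    qs = np.minimum.accumulate(qs[::-1])[::-1]
    q[order] = np.minimum(qs, 1.0)
    return q


# ---------------------------------------------------------------------------
# probe -> gene collapsing and thresholds
# ---------------------------------------------------------------------------


def best_probe(probe_results: pd.DataFrame) -> pd.DataFrame:
    """Per gene, keep the probe with the most significant nominal lead association.

    ``probe_results`` needs columns gene, probe, p_min_obs, lead_pos; ties
    are broken by smaller lead-variant position then lexicographic probe id.
    """
    df = probe_results.sort_values(
        ["gene", "p_min_obs", "lead_pos", "probe"], kind="mergesort"
    )
    return df.groupby("gene", sort=True).head(1).set_index("gene", drop=False)


def nominal_thresholds(gene_results: pd.DataFrame, fdr_level: float = 0.05) -> pd.Series:
    """Per-gene nominal p cutoff for conditional analysis.

    The gene-level significance level is the midpoint between the largest
    p_beta among genes passing the FDR cut and the smallest among those
    failing it (1.0 when every gene passes); each gene's nominal threshold
    is the Beta(a, b) quantile of that level under its own permutation fit.
    """
    passing = gene_results[gene_results["q"] <= fdr_level]
    if passing.empty:
        return pd.Series(np.nan, index=gene_results.index)
    failing = gene_results[gene_results["q"] > fdr_level]
    p_fail = failing["p_beta"].min() if not failing.empty else 1.0
    p_level = 0.5 * (passing["p_beta"].max() + p_fail)
    return pd.Series(
        stats.beta.ppf(p_level, gene_results["a"], gene_results["b"]),
        index=gene_results.index,
    )


# ---------------------------------------------------------------------------
# conditional (forward-backward) analysis
# ---------------------------------------------------------------------------


def _partial_scan(y, G, covariates):
    """Scan after residualising phenotype and dosages on the covariates."""
    k = 0 if covariates is None or covariates.size == 0 else np.atleast_2d(covariates.T).shape[0]
    yr = residualise(y, covariates)
    Gr = residualise(G, covariates)
    n = len(y)
    df = n - 2 - k
    yc = yr - yr.mean()
    sy = np.sqrt(yc @ yc)
    Gc = Gr - Gr.mean(axis=0)
    sg = np.sqrt(np.einsum("ij,ij->j", Gc, Gc))
    testable = sg > 1e-10
    sg_safe = np.where(testable, sg, np.nan)
    r = np.clip((Gc.T @ yc) / (sg_safe * sy), -1.0, 1.0)
    t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    beta = r * sy / sg_safe
    return p, beta, testable


def conditional_scan(
    phenotype: np.ndarray,
    cis_genotypes: GenotypeMatrix,
    gene_threshold: float,
    config: MapConfig,
    gene: str = "",
) -> list[ConditionalSignal]:
    """Forward-backward stepwise search for independent cis signals.

    Forward: add the best remaining variant as long as its conditional
    nominal p beats ``gene_threshold``.  Backward: re-test each signal
    conditioning on all the others, reassign its lead to the best variant,
    and drop signals that no longer pass.
    """
    if not np.isfinite(gene_threshold) or gene_threshold <= 0:
        return []
    y = np.asarray(phenotype, dtype=float)
    ids = list(cis_genotypes.dosages.columns)
    G = cis_genotypes.dosages.to_numpy(float)
    pos = cis_genotypes.variants["pos"].to_numpy()

    def pick_best(p, testable):
        cand = np.where(testable & (p < gene_threshold))[0]
        if cand.size == 0:
            return None
        # ties: smaller p, then smaller position, then id
        order = sorted(cand, key=lambda i: (p[i], pos[i], ids[i]))
        return order[0]

    leads: list[int] = []
    while len(leads) < config.max_signals:
        cov = G[:, leads] if leads else None
        p, beta, testable = _partial_scan(y, G, cov)
        if leads:
            testable[leads] = False
        best = pick_best(p, testable)
        if best is None:
            break
        leads.append(best)
    else:
        warnings.warn(f"max_signals reached for gene {gene!r}", stacklevel=2)

    signals: list[ConditionalSignal] = []
    kept = list(leads)
    for rank, lead in enumerate(list(kept), start=1):
        others = [l for l in kept if l != lead]
        cov = G[:, others] if others else None
        p, beta, testable = _partial_scan(y, G, cov)
        if others:
            testable[others] = False
        best = pick_best(p, testable)
        if best is None:
            kept.remove(lead)
            continue
        signals.append(
            ConditionalSignal(
                gene=gene,
                rank=rank,
                lead_variant=ids[best],
                p=float(p[best]),
                beta=float(beta[best]),
                retained=True,
            )
        )
        if best != lead:
            kept[kept.index(lead)] = best
    # distinct leads guaranteed by exclusion of conditioning variants
    for i, s in enumerate(signals):
        signals[i] = ConditionalSignal(
            gene=s.gene, rank=i + 1, lead_variant=s.lead_variant, p=s.p, beta=s.beta, retained=True
        )
    return signals


# ---------------------------------------------------------------------------
# full cis pipeline
# ---------------------------------------------------------------------------


def adjust_phenotypes(
    phenotypes: PhenotypeTable, n_pcs: int, covariates: np.ndarray | None = None
) -> pd.DataFrame:
    """Residualise on expression PCs (+ optional covariates), then rank-normalise."""
    pcs = expression_pcs(phenotypes.values, n_pcs)
    cov = pcs if covariates is None else np.column_stack([pcs, covariates])
    if cov.size == 0:
        cov = None
    resid = residualise(phenotypes.values.to_numpy(float), cov)
    out = np.column_stack([rank_normal(resid[:, j]) for j in range(resid.shape[1])])
    return pd.DataFrame(out, index=phenotypes.values.index, columns=phenotypes.values.columns)


def map_cis(
    phenotypes: PhenotypeTable,
    genotypes: GenotypeMatrix,
    config: MapConfig,
    covariates: np.ndarray | None = None,
    qc: bool = True,
) -> pd.DataFrame:
    """Cis mapping across all probes, collapsed to genes, with q-values.

    Returns a gene-indexed frame with columns gene, probe, lead_variant,
    lead_pos, beta, p_min_obs, a, b, p_beta, p_empirical, q,
    nominal_threshold.  Genes with no testable cis variant are omitted.
    """
    # canonical sample order makes the permutation null (and hence p_beta)
    # invariant to the order samples arrive in
    order = phenotypes.values.index.sort_values()
    if not genotypes.dosages.index.sort_values().equals(order):
        raise ValueError("phenotype and genotype samples do not match")
    take = phenotypes.values.index.get_indexer(order)
    phenotypes = PhenotypeTable(values=phenotypes.values.loc[order], probes=phenotypes.probes)
    genotypes = GenotypeMatrix(dosages=genotypes.dosages.loc[order], variants=genotypes.variants)
    if covariates is not None:
        covariates = np.asarray(covariates)[take]
    gm = qc_variants(genotypes, config) if qc else genotypes
    adj = adjust_phenotypes(phenotypes, config.n_pcs, covariates)
    rows = []
    for pid, meta in phenotypes.probes.iterrows():
        vids = cis_window_variants(gm, meta["chrom"], int(meta["tss"]), meta["strand"], config.cis_window)
        if not vids:
            continue
        sub = gm.subset(vids)
        y = adj[pid].to_numpy()
        try:
            fit = permutation_gene_p(
                y, sub, config, rng=rng_for_phenotype(config.seed, pid), variant_ids=vids
            )
        except ValueError:
            continue
        scan = nominal_scan(y, sub, vids, tss=int(meta["tss"]))
        lead = fit.lead_variant
        rows.append(
            {
                "gene": meta["gene"],
                "probe": pid,
                "lead_variant": lead,
                "lead_pos": int(gm.variants.loc[lead, "pos"]),
                "beta": float(scan.loc[lead, "beta"]),
                "p_min_obs": fit.p_min_obs,
                "a": fit.a,
                "b": fit.b,
                "p_beta": fit.p_beta,
                "p_empirical": fit.p_empirical,
            }
        )
    if not rows:
        warnings.warn("no genes with testable cis variants", stacklevel=2)
        return pd.DataFrame()
    probe_results = pd.DataFrame(rows)
    gene_results = best_probe(probe_results)
    gene_results["q"] = qvalues(gene_results["p_beta"].to_numpy())
    gene_results["nominal_threshold"] = nominal_thresholds(gene_results, config.fdr_level)
    return gene_results


def select_pc_count(
    phenotypes: PhenotypeTable,
    genotypes: GenotypeMatrix,
    candidates,
    config: MapConfig,
    n_perm: int | None = 200,
) -> int:
    """PC count maximising cis discoveries at the FDR level; ties favour fewer PCs.

    Runs the cis pipeline per candidate count (with a reduced permutation
    budget by default, since only the ranking matters).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate PC counts")
    if len(candidates) == 1:
        return candidates[0]
    best_count, best_hits = None, -1
    for k in sorted(candidates):
        cfg = MapConfig(
            cis_window=config.cis_window,
            maf_min=config.maf_min,
            hwe_p_min=config.hwe_p_min,
            missing_max=config.missing_max,
            n_perm=n_perm or config.n_perm,
            n_pcs=k,
            fdr_level=config.fdr_level,
            max_signals=config.max_signals,
            seed=config.seed,
        )
        res = map_cis(phenotypes, genotypes, cfg)
        hits = 0 if res.empty else int((res["q"] <= config.fdr_level).sum())
        if hits > best_hits:
            best_count, best_hits = k, hits
    return best_count


# ---------------------------------------------------------------------------
# auxiliary small tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogitLrtResult:
    slope: float
    p: float
    clamped: bool


def logit_lrt(proportions, dosage) -> LogitLrtResult:
    """Linear regression of logit-transformed proportions on dosage, LRT p.

    Proportions of exactly 0 or 1 are clamped to 1/(2n) and 1 − 1/(2n) and
    the result flagged.
    """
    pr = np.asarray(proportions, dtype=float)
    g = np.asarray(dosage, dtype=float)
    if pr.shape != g.shape or pr.ndim != 1:
        raise ValueError("proportions and dosage must be 1-d vectors of equal length")
    if np.any((pr < 0) | (pr > 1)):
        raise ValueError("proportions must be in [0, 1]")
    n = len(pr)
    clamped = bool(np.any((pr == 0) | (pr == 1)))
    eps = 1.0 / (2 * n)
    pr = np.clip(pr, eps, 1.0 - eps)
    y = np.log(pr / (1.0 - pr))
    X = np.column_stack([np.ones(n), g])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ coef) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if rss1 <= 0:
        return LogitLrtResult(slope=float(coef[1]), p=0.0, clamped=clamped)
    lrt = n * np.log(rss0 / rss1)
    return LogitLrtResult(slope=float(coef[1]), p=float(stats.chi2.sf(lrt, 1)), clamped=clamped)


def ase_chisq(genomic_counts, cdna_counts) -> tuple[float, float]:
    """1-df chi-square (no continuity correction) comparing allele ratios.

    Contrasts the allele-1:allele-2 ratio in genomic DNA (the 50:50
    expectation baseline) with the ratio observed in cDNA.
    """
    a, b = genomic_counts
    c, d = cdna_counts
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("zero marginal in the 2x2 table")
    n = table.sum()
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = float(num / den)
    return chi2, float(stats.chi2.sf(chi2, 1))
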
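"""Summary-statistics colocalisation and cell-type specificity calling.

Implements the Wakefield approximate-Bayes-factor machinery: pairwise
five-hypothesis colocalisation (PP0–PP4), exhaustive multi-trait
configuration enumeration across up to five cell types, the decision rule
for calling an eQTL specific to the focal cell type, Regulatory Trait
Concordance (RTC) for lead-SNP-only GWAS integration, and the cis-mediation
call for trans signals.

Throughout, the per-variant log approximate Bayes factor for an estimate
(beta, se) with prior effect variance W is

    lABF = 0.5 * log(V / (V + W)) + 0.5 * z^2 * W / (V + W),   V = se^2.

A "configuration" assigns each trait to inactive or to a sharing block;
traits in one block share a single causal variant, distinct blocks have
distinct causal variants.  For two traits the 5 configurations are exactly
the classic coloc hypotheses H0–H4.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .simdata import GenotypeMatrix, SummaryStatsTable

__all__ = [
    "ColocResult",
    "MolocResult",
    "SpecificityCall",
    "RTCResult",
    "MediationResult",
    "wakefield_abf",
    "abf_from_stats",
    "harmonise",
    "coloc_abf",
    "enumerate_configurations",
    "multi_trait_coloc",
    "specificity_call",
    "rtc",
    "mediation_coloc",
]

#: coloc-convention prior effect SDs: 0.15 for a quantitative trait,
#: 0.2 (log-odds) for case-control.
W_QUANT = 0.15**2
W_CC = 0.2**2

#: Per-variant prior that a block of k traits shares a causal variant there.
#: Sizes 1-3 follow the moloc defaults; 4 and 5 extend the geometric decay.
DEFAULT_BLOCK_PRIORS = {1: 1e-4, 2: 1e-6, 3: 1e-7, 4: 10**-7.5, 5: 1e-8}


def wakefield_abf(beta, se, W: float) -> np.ndarray:
    """Natural-log approximate Bayes factor for association at one variant."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if W <= 0:
        raise ValueError("prior variance W must be positive")
    V = se**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(V / (V + W)) + 0.5 * z2 * W / (V + W)


def abf_from_stats(stats_table: SummaryStatsTable, W: float | None = None) -> pd.Series:
    """Per-variant lABF series from a summary-stats table (coloc prior defaults)."""
    if W is None:
        W = W_CC if stats_table.trait_type == "case-control" else W_QUANT
    t = stats_table.table
    return pd.Series(wakefield_abf(t["beta"].to_numpy(), t["se"].to_numpy(), W), index=t.index)


def harmonise(tables: list[SummaryStatsTable], drop_ambiguous: bool = True) -> list[pd.DataFrame]:
    """Align several summary-stats tables on (chrom, pos), matching alleles.

    Effect sizes are flipped where a1/a2 are swapped relative to the first
    table; strand-ambiguous A/T and C/G variants are dropped when
    ``drop_ambiguous``.  Returns per-trait frames over the common variants.
    """
    keyed = []
    for st in tables:
        t = st.table.copy()
        t["key"] = list(zip(t["chrom"], t["pos"]))
        keyed.append(t.set_index("key"))
    common = keyed[0].index
    for t in keyed[1:]:
        common = common.intersection(t.index)
    if len(common) == 0:
        raise ValueError("no overlapping variants between traits")
    ref = keyed[0].loc[common]
    out = []
    ambiguous = {frozenset("AT"), frozenset("CG")}
    keep_mask = np.ones(len(common), dtype=bool)
    aligned = []
    for t in keyed:
        t = t.loc[common].copy()
        same = (t["a1"] == ref["a1"]) & (t["a2"] == ref["a2"])
        swapped = (t["a1"] == ref["a2"]) & (t["a2"] == ref["a1"])
        keep_mask &= (same | swapped).to_numpy()
        flip = swapped.to_numpy()
        t.loc[flip, "beta"] *= -1.0
        t.loc[flip, "z"] *= -1.0
        t.loc[flip, ["a1", "a2"]] = t.loc[flip, ["a2", "a1"]].to_numpy()
        aligned.append(t)
    if drop_ambiguous:
        pairs = [frozenset((x, y)) for x, y in zip(ref["a1"], ref["a2"])]
        keep_mask &= np.array([pr not in ambiguous for pr in pairs])
    if not keep_mask.any():
        raise ValueError("no variants left after allele harmonisation")
    for t in aligned:
        out.append(t[keep_mask])
    return [t.reset_index(drop=True) for t in out]


# ---------------------------------------------------------------------------
# pairwise colocalisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    p1: float
    p2: float
    p12: float
    n_variants: int

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def _coloc_from_labf(l1: np.ndarray, l2: np.ndarray, p1: float, p2: float, p12: float) -> ColocResult:
    n = len(l1)
    S1 = logsumexp(l1)
    S2 = logsumexp(l2)
    S12 = logsumexp(l1 + l2)
    h = np.empty(5)
    h[0] = 0.0
    h[1] = np.log(p1) + S1
    h[2] = np.log(p2) + S2
    if n == 1:
        h[3] = -np.inf
    else:
        # sum over distinct pairs = S1*S2 − S12 (linear scale), done stably
        diff = S12 - (S1 + S2)
        pairs = np.log1p(-np.exp(diff)) if diff < -1e-12 else -np.inf
        h[3] = np.log(p1) + np.log(p2) + S1 + S2 + pairs
    h[4] = np.log(p12) + S12
    post = np.exp(h - logsumexp(h))
    post /= post.sum()
    return ColocResult(*post, p1=p1, p2=p2, p12=p12, n_variants=n)


def coloc_abf(
    stats1: SummaryStatsTable,
    stats2: SummaryStatsTable,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    W1: float | None = None,
    W2: float | None = None,
) -> ColocResult:
    """Five-hypothesis colocalisation of two traits from summary statistics."""
    t1, t2 = harmonise([stats1, stats2])
    l1 = wakefield_abf(t1["beta"].to_numpy(), t1["se"].to_numpy(), W1 or (W_CC if stats1.trait_type == "case-control" else W_QUANT))
    l2 = wakefield_abf(t2["beta"].to_numpy(), t2["se"].to_numpy(), W2 or (W_CC if stats2.trait_type == "case-control" else W_QUANT))
    return _coloc_from_labf(l1, l2, p1, p2, p12)


def coloc_from_labf(l1, l2, p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5) -> ColocResult:
    """Colocalisation directly from aligned per-variant lABF vectors."""
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    if l1.shape != l2.shape:
        raise ValueError("lABF vectors must be aligned")
    return _coloc_from_labf(l1, l2, p1, p2, p12)


# ---------------------------------------------------------------------------
# multi-trait configurations
# ---------------------------------------------------------------------------


def _set_partitions(items: tuple):
    """All partitions of a tuple into non-empty blocks."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(tuple(rest)):
        for i in range(len(part)):
            yield part[:i] + [part[i] + (first,)] + part[i + 1 :]
        yield part + [(first,)]


def enumerate_configurations(traits: tuple[str, ...]):
    """Every assignment of traits to inactive / sharing blocks.

    Yields tuples of blocks (each a sorted tuple of trait labels); the empty
    tuple is the all-null configuration.  The count is sum_k C(d,k)*Bell(k):
    5, 15 and 203 for d = 2, 3 and 5.
    """
    d = len(traits)
    for k in range(d + 1):
        for active in itertools.combinations(traits, k):
            for part in _set_partitions(active):
                yield tuple(sorted(tuple(sorted(b)) for b in part))


@dataclass
class MolocResult:
    traits: tuple[str, ...]
    focal: str
    configurations: list[tuple]
    posteriors: np.ndarray
    best_configuration: tuple
    pp_focal_specific: float
    pp_focal_shared: float

    # aliases matching the NK-centric vocabulary of the analysis
    @property
    def pp_nk_specific(self) -> float:
        return self.pp_focal_specific

    @property
    def pp_nk_shared(self) -> float:
        return self.pp_focal_shared


def multi_trait_coloc(
    labfs: dict[str, np.ndarray],
    focal: str,
    block_priors: dict[int, float] | None = None,
) -> MolocResult:
    """Posterior over all sharing configurations of 2–5 traits at one locus.

    ``labfs`` maps trait label to its per-variant lABF vector (aligned
    across traits).  Evidence for a block is the per-variant sum of the
    product of member ABFs; distinct blocks exclude same-variant
    assignments via pairwise correction (exact for up to two blocks, a
    first-order approximation beyond).  The configuration prior multiplies
    one per-variant block prior per block.
    """
    traits = tuple(sorted(labfs))
    if not 2 <= len(traits) <= 5:
        raise ValueError("multi-trait colocalisation supports 2 to 5 traits")
    if focal not in traits:
        raise ValueError(f"focal trait {focal!r} not among traits")
    priors = DEFAULT_BLOCK_PRIORS if block_priors is None else block_priors
    L = {t: np.asarray(labfs[t], dtype=float) for t in traits}
    m = len(L[traits[0]])
    for t in traits:
        if len(L[t]) != m:
            raise ValueError("lABF vectors must share one variant grid")

    configs = list(enumerate_configurations(traits))
    log_post = np.full(len(configs), -np.inf)
    for ci, config in enumerate(configs):
        lp = 0.0
        block_vecs = []
        for block in config:
            vec = np.sum([L[t] for t in block], axis=0)
            block_vecs.append(vec)
            lp += np.log(priors[len(block)])
        if not block_vecs:
            log_post[ci] = 0.0
            continue
        S = [logsumexp(v) for v in block_vecs]
        log_ev = float(np.sum(S))
        if len(block_vecs) > 1 and m > 1:
            # subtract same-variant collisions between block pairs
            corr = 0.0
            for i, j in itertools.combinations(range(len(block_vecs)), 2):
                coll = logsumexp(block_vecs[i] + block_vecs[j])
                corr += np.exp(coll - S[i] - S[j])
            log_ev += np.log(max(1.0 - corr, 1e-300))
        elif len(block_vecs) > 1 and m == 1:
            log_ev = -np.inf  # cannot place two distinct causal variants
        log_post[ci] = lp + log_ev
    post = np.exp(log_post - logsumexp(log_post))
    post /= post.sum()

    def focal_alone(cfg):
        return any(len(b) == 1 and b[0] == focal for b in cfg)

    def focal_shared(cfg):
        return any(focal in b and len(b) >= 2 for b in cfg)

    pp_spec = float(post[[focal_alone(c) for c in configs]].sum())
    pp_shared = float(post[[focal_shared(c) for c in configs]].sum())
    best = configs[int(np.argmax(post))]
    return MolocResult(
        traits=traits,
        focal=focal,
        configurations=configs,
        posteriors=post,
        best_configuration=best,
        pp_focal_specific=pp_spec,
        pp_focal_shared=pp_shared,
    )


@dataclass(frozen=True)
class SpecificityCall:
    gene: str
    call: str  # specific | shared | ambiguous
    pp_specific: float
    pp_shared: float


def specificity_call(moloc: MolocResult, gene: str = "") -> SpecificityCall:
    """Decision rule for a focal-cell-type-specific eQTL.

    "specific" requires posterior > 0.8 that the focal eQTL is not shared
    with any other cell type AND the single most likely configuration has
    the focal trait active and sharing with none; "shared" requires
    posterior > 0.8 of sharing a block with at least one other cell type;
    anything else is "ambiguous".
    """
    best_alone = any(len(b) == 1 and b[0] == moloc.focal for b in moloc.best_configuration)
    if moloc.pp_focal_specific > 0.8 and best_alone:
        call = "specific"
    elif moloc.pp_focal_shared > 0.8:
        call = "shared"
    else:
        call = "ambiguous"
    return SpecificityCall(
        gene=gene, call=call, pp_specific=moloc.pp_focal_specific, pp_shared=moloc.pp_focal_shared
    )


# ---------------------------------------------------------------------------
# Regulatory Trait Concordance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RTCResult:
    gene: str
    esnp: str
    gwas_snp: str
    n_interval: int
    rank: int
    score: float


def rtc(
    phenotype: np.ndarray,
    interval_genotypes: GenotypeMatrix,
    esnp: str,
    gwas_snp: str,
    gene: str = "",
) -> RTCResult:
    """Regulatory Trait Concordance score for one eQTL / GWAS-hit pair.

    The phenotype is residualised on every SNP of the interval in turn and
    the eSNP association re-tested on the residual; SNPs are ranked by the
    residual |t| ascending (rank 0 = the SNP whose removal most completely
    abolishes the eQTL).  score = (N − rank(GWAS SNP)) / N, so scores near 1
    mean the GWAS hit tags the same signal as the eQTL.
    """
    ids = list(interval_genotypes.dosages.columns)
    if len(ids) < 2:
        raise ValueError("RTC needs an interval of at least 2 SNPs")
    if esnp not in ids or gwas_snp not in ids:
        raise ValueError("eSNP and GWAS SNP must lie within the interval")
    y = np.asarray(phenotype, dtype=float)
    G = interval_genotypes.dosages.to_numpy(float)
    ge = interval_genotypes.dosages[esnp].to_numpy(float)
    stats_k = np.empty(len(ids))
    for k in range(len(ids)):
        yr = residual_1cov(y, G[:, k])
        ger = residual_1cov(ge, G[:, k])
        sg = ger.std()
        if sg < 1e-12:
            stats_k[k] = 0.0
            continue
        r = float(np.corrcoef(yr, ger)[0, 1])
        stats_k[k] = abs(r)
    gi = ids.index(gwas_snp)
    rank = int(np.sum(stats_k < stats_k[gi] - 1e-15))
    n = len(ids)
    return RTCResult(
        gene=gene, esnp=esnp, gwas_snp=gwas_snp, n_interval=n, rank=rank, score=(n - rank) / n
    )


def residual_1cov(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residual of y on [1, x] (fast path used by RTC)."""
    xc = x - x.mean()
    yc = y - y.mean()
    vx = xc @ xc
    if vx < 1e-12:
        return yc
    return yc - (xc @ yc / vx) * xc


# ---------------------------------------------------------------------------
# cis-mediation of trans signals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MediationResult:
    mediator_gene: str
    target_gene: str
    pp4: float
    mediated: bool


def mediation_coloc(
    cis_stats: SummaryStatsTable,
    trans_stats: SummaryStatsTable,
    mediator_gene: str = "",
    target_gene: str = "",
    threshold: float = 0.8,
    **coloc_kwargs,
) -> MediationResult:
    """Colocalise a mediator's cis signal with a target's trans signal.

    A shared causal variant (PP4 > 0.8) supports the trans effect being
    mediated through cis regulation of the mediator gene.
    """
    res = coloc_abf(cis_stats, trans_stats, **coloc_kwargs)
    return MediationResult(
        mediator_gene=mediator_gene,
        target_gene=target_gene,
        pp4=res.pp4,
        mediated=res.pp4 > threshold,
    )
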
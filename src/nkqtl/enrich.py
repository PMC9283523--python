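"""Enrichment machinery around eQTL results.

Three flavours are provided: (1) annotation-density profiles and a
phenotype-permutation overlap enrichment for functional tracks around cis
eSNPs, (2) Fisher-exact enrichment of GWAS-trait colocalisation among eQTL
relative to a null trait, and (3) hypergeometric pathway enrichment of
gene sets against the tested-gene background.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DensityProfile",
    "OverlapEnrichment",
    "ColocEnrichment",
    "PathwayResult",
    "density_profile",
    "overlap_enrichment",
    "coloc_enrichment",
    "pathway_hypergeom",
]


@dataclass
class DensityProfile:
    bin_edges: np.ndarray  # signed distances, 1 kb bins spanning ±span
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class OverlapEnrichment:
    label: str
    observed: int
    null_mean: float
    odds_ratio: float
    p: float
    n_perm: int


@dataclass(frozen=True)
class ColocEnrichment:
    trait: str
    a: int  # colocalised, trait
    b: int  # not colocalised, trait
    c: int  # colocalised, null trait
    d: int  # not colocalised, null trait
    odds_ratio: float
    p: float
    eligible: bool
    or_corrected: bool = False


@dataclass(frozen=True)
class PathwayResult:
    pathway: str
    overlap: int
    pathway_size: int
    query_size: int
    background_size: int
    p: float


# ---------------------------------------------------------------------------
# annotation density around eSNPs
# ---------------------------------------------------------------------------


def density_profile(
    esnps: pd.DataFrame,
    track: pd.DataFrame,
    bin_size: int = 1000,
    span: int = 1_000_000,
) -> DensityProfile:
    """Histogram of signed eSNP-to-annotation distances in 1 kb bins.

    ``esnps`` needs columns chrom/pos (1-based); ``track`` is BED-style
    chrom/start/end (0-based half-open).  The distance of an eSNP to an
    annotation instance is the signed offset to the nearest interval edge
    (0 when the eSNP lies inside the interval); one count per
    (eSNP, instance) pair within ±span.
    """
    edges = np.arange(-span, span + bin_size, bin_size)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for chrom, snp_grp in esnps.groupby("chrom"):
        tr = track[track["chrom"] == chrom]
        if tr.empty:
            continue
        starts = tr["start"].to_numpy() + 1  # 1-based first covered base
        ends = tr["end"].to_numpy()  # 1-based last covered base
        for pos in snp_grp["pos"].to_numpy():
            d = np.where(
                pos < starts, pos - starts, np.where(pos > ends, pos - ends, 0)
            )
            d = d[np.abs(d) < span]
            if d.size:
                counts += np.histogram(d, bins=edges)[0]
    return DensityProfile(bin_edges=edges, counts=counts)


def _overlaps(positions: np.ndarray, chroms: np.ndarray, track: pd.DataFrame) -> np.ndarray:
    """Boolean per (chrom, 1-based pos): inside any track interval."""
    out = np.zeros(len(positions), dtype=bool)
    for chrom, grp in track.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = np.sort(grp["start"].to_numpy())
        ends = grp["end"].to_numpy()[np.argsort(grp["start"].to_numpy())]
        # merge
        ms, me = [], []
        for s, e in zip(starts, ends):
            if me and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        ms, me = np.array(ms), np.array(me)
        pos0 = positions[sel] - 1
        idx = np.searchsorted(ms, pos0, side="right") - 1
        hit = np.zeros(sel.sum(), dtype=bool)
        ok = idx >= 0
        hit[ok] = pos0[ok] < me[idx[ok]]
        out[sel] = hit
    return out


def overlap_enrichment(
    eqtl_phenotypes,
    universe: pd.DataFrame,
    track: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    label: str = "",
) -> OverlapEnrichment:
    """Permutation enrichment of eSNP/annotation overlap.

    ``universe`` maps each *tested* phenotype to its lead-variant position
    (columns phenotype/chrom/pos); ``eqtl_phenotypes`` is the subset called
    significant.  Null draws permute phenotype identities across the
    universe — i.e. redraw which phenotypes are "significant" — keeping the
    lead-position geometry fixed.  p = (1 + #{null ≥ obs}) / (n_perm + 1);
    the odds ratio contrasts observed vs mean-null overlap odds.
    """
    if track.empty:
        raise ValueError("empty annotation track")
    eqtl_phenotypes = list(eqtl_phenotypes)
    k = len(eqtl_phenotypes)
    if k == 0 or not set(eqtl_phenotypes) <= set(universe["phenotype"]):
        raise ValueError("eqtl set must be a non-empty subset of the universe")
    uni = universe.reset_index(drop=True)
    overlap = _overlaps(uni["pos"].to_numpy(), uni["chrom"].to_numpy(), track)
    is_hit = uni["phenotype"].isin(eqtl_phenotypes).to_numpy()
    obs = int(overlap[is_hit].sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    m = len(uni)
    for b in range(n_perm):
        idx = rng.choice(m, size=k, replace=False)
        null[b] = overlap[idx].sum()
    p = float((1 + np.sum(null >= obs)) / (n_perm + 1))
    null_mean = float(null.mean())
    if obs == null_mean:
        oratio = 1.0
    else:
        po = obs / k
        pn = null_mean / k
        if po >= 1.0 or pn <= 0.0:
            oratio = np.inf
        elif po <= 0.0 or pn >= 1.0:
            oratio = 0.0
        else:
            oratio = float((po / (1 - po)) / (pn / (1 - pn)))
    return OverlapEnrichment(
        label=label, observed=obs, null_mean=null_mean, odds_ratio=oratio, p=p, n_perm=n_perm
    )


# ---------------------------------------------------------------------------
# GWAS-trait colocalisation enrichment vs a null trait
# ---------------------------------------------------------------------------


def coloc_enrichment(
    trait_flags,
    null_flags,
    trait: str = "",
    min_eqtl: int = 5,
) -> ColocEnrichment:
    """Fisher exact 2×2 of colocalised vs not, trait against the null trait.

    ``trait_flags`` / ``null_flags`` are boolean sequences over the eQTL
    near the respective trait's loci (True = colocalised, PP4 > 0.8).
    Traits with fewer than ``min_eqtl`` eligible eQTL are marked ineligible
    (to be excluded before FDR).  The odds ratio is the cross-product, with
    a Haldane 0.5 correction when a margin is zero.
    """
    tf = np.asarray(trait_flags, dtype=bool)
    nf = np.asarray(null_flags, dtype=bool)
    a, b = int(tf.sum()), int((~tf).sum())
    c, d = int(nf.sum()), int((~nf).sum())
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = False
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        oratio = (aa * dd) / (bb * cc)
        corrected = True
    else:
        oratio = (a * d) / (b * c)
    return ColocEnrichment(
        trait=trait,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=float(oratio),
        p=float(p),
        eligible=(a + b) >= min_eqtl,
        or_corrected=corrected,
    )


def coloc_enrichment_table(results: list[ColocEnrichment]) -> pd.DataFrame:
    """Assemble per-trait enrichment with BH q across eligible traits only."""
    df = pd.DataFrame([{
        "trait": r.trait, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
        "odds_ratio": r.odds_ratio, "p": r.p, "eligible": r.eligible,
    } for r in results])
    df["q"] = np.nan
    el = df["eligible"].to_numpy()
    if el.any():
        from .eqtl import qvalues

        df.loc[el, "q"] = qvalues(df.loc[el, "p"].to_numpy(), pi0=1.0)
    return df


# ---------------------------------------------------------------------------
# pathway enrichment
# ---------------------------------------------------------------------------


def pathway_hypergeom(query_genes, pathways: dict, background_genes) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each pathway in the query set.

    ``pathways`` maps pathway id to a gene collection.  Pathways are
    restricted to the background; those disjoint from it are skipped with a
    warning.  Returns a frame with p and BH q per pathway.
    """
    query = set(query_genes)
    background = set(background_genes)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    N = len(background)
    n = len(query)
    rows = []
    for pid, genes in pathways.items():
        in_bg = set(genes) & background
        if not in_bg:
            warnings.warn(f"pathway {pid!r} disjoint from background: skipped", stacklevel=2)
            continue
        K = len(in_bg)
        k = len(in_bg & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"pathway": pid, "overlap": k, "pathway_size": K, "query_size": n,
             "background_size": N, "p": p}
        )
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows).set_index("pathway", drop=False)
    from .eqtl import qvalues

    df["q"] = qvalues(df["p"].to_numpy(), pi0=1.0)
    return df
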
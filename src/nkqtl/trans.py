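"""Trans eQTL discovery with joint-permutation FDR, artefact screens and grouping.

Trans associations are tested for every eligible phenotype:variant pair —
eligible meaning the variant lies more than ``min_distance`` (default 5 Mb)
from the probe's TSS or on another chromosome.  The significance threshold
is set empirically: sample labels of the whole phenotype matrix are permuted
jointly (preserving phenotype-phenotype correlation but breaking
genotype-phenotype links) and FDR(t) is estimated as the ratio of the mean
null hit count to the observed hit count at nominal threshold t.

Two artefact filters accompany the scan: SNPs inside repeat regions can be
excluded up front, and the cross-mapping screen flags probes whose sequence
aligns (ungapped, either strand, ≤ 6 mismatches) anywhere in the 10 Mb
region around a trans eSNP — the classic signature of a mis-annotated
paralogous cis effect masquerading as trans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import residualise
from .simdata import GenotypeMatrix, PhenotypeTable

__all__ = [
    "TransFDRResult",
    "CrossmapFlag",
    "exclude_repeat_snps",
    "trans_scan",
    "crossmap_screen",
    "group_trans_loci",
    "conditional_trans",
    "copy_number_trans",
]

REVCOMP = bytes.maketrans(b"ACGT", b"TGCA")


@dataclass(frozen=True)
class TransFDRResult:
    threshold: float
    fdr_at_threshold: float
    n_perm: int


@dataclass(frozen=True)
class CrossmapFlag:
    probe: str
    chrom: str
    start: int
    end: int
    min_mismatches: int
    flagged: bool


# ---------------------------------------------------------------------------
# repeat-region exclusion
# ---------------------------------------------------------------------------


def exclude_repeat_snps(genotypes: GenotypeMatrix, repeat_track: pd.DataFrame) -> GenotypeMatrix:
    """Drop variants whose 1-based position falls in a BED interval.

    ``repeat_track`` columns chrom/start/end are 0-based half-open, so a
    1-based position p is inside [start, end) iff start < p <= end.
    """
    if repeat_track.empty:
        return genotypes
    meta = genotypes.variants
    inside = np.zeros(len(meta), dtype=bool)
    for chrom, grp in repeat_track.groupby("chrom"):
        sel = (meta["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        pos = meta["pos"].to_numpy()[sel]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        # merge to disjoint intervals so a single searchsorted decides membership
        merged_s, merged_e = [], []
        for s, e in zip(starts, ends):
            if merged_e and s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        ms = np.array(merged_s)
        me = np.array(merged_e)
        idx = np.searchsorted(ms, pos - 1, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(len(pos), dtype=bool)
        hit[ok] = (pos[ok] - 1) < me[idx[ok]]
        inside[sel] = hit
    keep = meta.index[~inside].tolist()
    return genotypes.subset(keep)


# ---------------------------------------------------------------------------
# genome-wide trans scan
# ---------------------------------------------------------------------------


def _standardise(M: np.ndarray):
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    ok = sd > 0
    sd_safe = np.where(ok, sd, 1.0)
    return (M - mu) / sd_safe, ok


def _eligibility(variants: pd.DataFrame, probes: pd.DataFrame, min_distance: float) -> np.ndarray:
    """Boolean (n_variants × n_probes): pair is testable in trans."""
    vchrom = variants["chrom"].to_numpy()
    vpos = variants["pos"].to_numpy()
    pchrom = probes["chrom"].to_numpy()
    ptss = probes["tss"].to_numpy()
    diff_chrom = vchrom[:, None] != pchrom[None, :]
    far = np.abs(vpos[:, None] - ptss[None, :]) > min_distance
    return diff_chrom | far


def trans_scan(
    adjusted: pd.DataFrame,
    probes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    min_distance: float = 5_000_000,
    n_perm: int = 1000,
    seed: int = 0,
    fdr: float = 0.05,
    p_prefilter: float = 1e-5,
    condition_on: np.ndarray | None = None,
) -> tuple[pd.DataFrame, TransFDRResult]:
    """All-pairs trans scan with joint-permutation FDR threshold.

    ``adjusted`` is the PC-adjusted, rank-normalised samples × probes matrix
    aligned with ``genotypes``; ``probes`` carries gene/chrom/tss metadata.
    Candidate hits below ``p_prefilter`` are kept for permutation
    bookkeeping; the reported threshold is the largest nominal p with
    estimated FDR ≤ ``fdr``.  Per gene only the most significant probe's
    hits are retained.  ``condition_on`` residualises both phenotypes and
    dosages on a covariate (e.g. a copy-number dosage) before scanning.
    """
    rng = np.random.default_rng(seed)
    Y = adjusted.to_numpy(float)
    G = genotypes.dosages.to_numpy(float)
    if condition_on is not None:
        Y = residualise(Y, condition_on)
        G = residualise(G, condition_on)
    n = Y.shape[0]
    df = n - 2 - (0 if condition_on is None else np.atleast_2d(np.asarray(condition_on).T).shape[0])
    Gs, g_ok = _standardise(G)
    Ys, y_ok = _standardise(Y)
    elig = _eligibility(genotypes.variants, probes, min_distance)
    elig &= g_ok[:, None] & y_ok[None, :]

    def absr_from_p(p):
        t = stats.t.isf(p / 2.0, df)
        return t / np.sqrt(df + t**2)

    def p_from_absr(absr):
        absr = np.clip(absr, 0.0, 1.0)
        t = absr * np.sqrt(df / np.maximum(1.0 - absr**2, 1e-300))
        return 2.0 * stats.t.sf(t, df)

    R = (Gs.T @ Ys) / n
    absR = np.abs(R)
    r_pre = absr_from_p(p_prefilter)
    vi, pi = np.nonzero(elig & (absR >= r_pre))
    if vi.size == 0:
        warnings.warn("no candidate trans pairs below the prefilter", stacklevel=2)
        return pd.DataFrame(), TransFDRResult(np.nan, np.nan, n_perm)

    cand_p = p_from_absr(absR[vi, pi])
    order = np.argsort(cand_p, kind="mergesort")
    vi, pi, cand_p = vi[order], pi[order], cand_p[order]
    cand_r = absr_from_p(cand_p)  # descending |r| thresholds

    # permutations: count null pairs at least as extreme as each candidate
    null_counts = np.zeros(len(cand_p))
    Gf = np.asarray(Gs, dtype=np.float32)
    Yf = np.asarray(Ys, dtype=np.float32)
    for _ in range(n_perm):
        idx = rng.permutation(n)
        Rb = np.abs(Gf.T @ Yf[idx]) / n
        vals = Rb[elig]
        vals = vals[vals >= cand_r[-1]]
        if vals.size:
            vals.sort()
            # count of null |r| >= threshold, for each candidate threshold
            null_counts += vals.size - np.searchsorted(vals, cand_r, side="left")
    obs_counts = np.arange(1, len(cand_p) + 1)
    fdr_est = np.minimum((null_counts / n_perm) / obs_counts, 1.0)
    ok = np.where(fdr_est <= fdr)[0]
    if ok.size == 0:
        warnings.warn("no trans threshold achieves the requested FDR", stacklevel=2)
        return pd.DataFrame(), TransFDRResult(np.nan, float(fdr_est.min()), n_perm)
    last = ok.max()
    threshold = float(cand_p[last])

    keep = slice(0, last + 1)
    var_ids = genotypes.dosages.columns.to_numpy()
    probe_ids = adjusted.columns.to_numpy()
    vpos = genotypes.variants["pos"].to_numpy()
    vchrom = genotypes.variants["chrom"].to_numpy()
    r_sel = R[vi[keep], pi[keep]]
    sy = 1.0  # phenotypes standardised
    sg = G.std(axis=0)[vi[keep]]
    beta = r_sel * sy / np.where(sg > 0, sg, np.nan)
    tstat = r_sel * np.sqrt(df / np.maximum(1.0 - r_sel**2, 1e-300))
    hits = pd.DataFrame(
        {
            "variant": var_ids[vi[keep]],
            "probe": probe_ids[pi[keep]],
            "gene": probes["gene"].to_numpy()[pi[keep]],
            "chrom": vchrom[vi[keep]],
            "pos": vpos[vi[keep]],
            "beta": beta,
            "se": beta / tstat,
            "p_nominal": cand_p[keep],
            "distance": np.abs(vpos[vi[keep]] - probes["tss"].to_numpy()[pi[keep]]),
            "cross_chromosome": vchrom[vi[keep]] != probes["chrom"].to_numpy()[pi[keep]],
        }
    )
    # per gene keep the single most significant probe (mirrors cis --grp-best)
    best = hits.sort_values("p_nominal", kind="mergesort").groupby("gene").head(1)
    hits = hits[hits.set_index(["gene", "probe"]).index.isin(best.set_index(["gene", "probe"]).index)]
    hits = hits.reset_index(drop=True)
    fdr_at = float(fdr_est[last])
    return hits, TransFDRResult(threshold=threshold, fdr_at_threshold=fdr_at, n_perm=n_perm)


# ---------------------------------------------------------------------------
# cross-mapping screen
# ---------------------------------------------------------------------------


def _seq_to_array(seq: str) -> np.ndarray:
    b = seq.upper().encode()
    if set(b) - set(b"ACGT"):
        raise ValueError("sequence contains non-ACGT symbols")
    return np.frombuffer(b, dtype=np.uint8)


def crossmap_screen(
    probe_id: str,
    probe_seq: str,
    window_seq: str,
    chrom: str = "",
    start: int = 0,
    max_mismatch: int = 6,
) -> CrossmapFlag:
    """Minimum ungapped Hamming distance of the probe over all window offsets.

    Both strands are searched (the reverse complement of the probe against
    the forward window); a minimum ≤ ``max_mismatch`` flags the probe as a
    potential cross-mapping artefact.
    """
    p = _seq_to_array(probe_seq)
    w = _seq_to_array(window_seq)
    L, W = len(p), len(w)
    if L < 20:
        raise ValueError("probe must be at least 20 bases")
    if W < L:
        raise ValueError("window shorter than probe")
    windows = np.lib.stride_tricks.sliding_window_view(w, L)
    p_rc = np.frombuffer(probe_seq.upper().encode().translate(REVCOMP)[::-1], dtype=np.uint8)
    mm_fwd = int((windows != p).sum(axis=1).min())
    mm_rev = int((windows != p_rc).sum(axis=1).min())
    mm = min(mm_fwd, mm_rev)
    return CrossmapFlag(
        probe=probe_id,
        chrom=chrom,
        start=start,
        end=start + W,
        min_mismatches=mm,
        flagged=mm <= max_mismatch,
    )


# ---------------------------------------------------------------------------
# locus grouping and conditional testing
# ---------------------------------------------------------------------------


def group_trans_loci(hits: pd.DataFrame, window: int = 1_000_000) -> pd.DataFrame:
    """Chain-link same-gene eSNPs ≤ ``window`` apart into trans loci.

    Returns one row per locus: locus id, gene, chrom, span_start, span_end,
    member variant ids and the peak (smallest-p) member.
    """
    if hits.empty:
        return pd.DataFrame()
    rows = []
    counter = 0
    for (gene, chrom), grp in hits.groupby(["gene", "chrom"], sort=True):
        grp = grp.sort_values(["pos", "variant"], kind="mergesort")
        pos = grp["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > window)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for i in range(len(bounds) - 1):
            seg = grp.iloc[bounds[i] : bounds[i + 1]]
            counter += 1
            peak = seg.loc[seg["p_nominal"].idxmin()]
            rows.append(
                {
                    "locus": f"L{counter:04d}",
                    "gene": gene,
                    "chrom": chrom,
                    "span_start": int(seg["pos"].min()),
                    "span_end": int(seg["pos"].max()),
                    "n_members": len(seg),
                    "members": tuple(seg["variant"]),
                    "peak_variant": peak["variant"],
                    "peak_p": float(peak["p_nominal"]),
                }
            )
    return pd.DataFrame(rows).set_index("locus", drop=False)


def conditional_trans(
    phenotype: np.ndarray,
    genotypes: GenotypeMatrix,
    members,
    peak_variant: str,
    threshold: float,
) -> pd.DataFrame:
    """Re-scan locus members conditioning on the peak eSNP dosage.

    A locus is a single signal when no member passes ``threshold`` after
    conditioning; the returned frame holds the residual hits (possibly
    empty).  The peak itself becomes untestable (zero residual variance).
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("locus must have at least 2 member variants")
    y = np.asarray(phenotype, dtype=float)
    peak = genotypes.dosages[peak_variant].to_numpy(float)
    G = genotypes.dosages[members].to_numpy(float)
    yr = residualise(y, peak)
    Gr = residualise(G, peak)
    n = len(y)
    df = n - 3
    yc = yr - yr.mean()
    sy = np.sqrt(yc @ yc)
    Gc = Gr - Gr.mean(axis=0)
    sg = np.sqrt(np.einsum("ij,ij->j", Gc, Gc))
    testable = sg > 1e-8
    sg_safe = np.where(testable, sg, np.nan)
    r = np.clip((Gc.T @ yc) / (sg_safe * sy), -1.0, 1.0)
    t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame(
        {"variant": members, "p_conditional": p, "testable": testable}
    ).set_index("variant", drop=False)
    return out[out["testable"] & (out["p_conditional"] < threshold)]


def copy_number_trans(
    adjusted: pd.DataFrame,
    probes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    cn_locus: str,
    **kwargs,
) -> tuple[pd.DataFrame, TransFDRResult]:
    """Trans scan using an integer copy-number locus as the dosage.

    The copy-number column must be non-constant; other variants are left out
    of the scan.  Conditioning on another copy-number variable is supported
    through ``condition_on`` (forwarded to :func:`trans_scan`).
    """
    cn = genotypes.dosages[cn_locus].to_numpy(float)
    if np.all(cn == cn[0]):
        raise ValueError(f"copy-number locus {cn_locus!r} is constant: untestable")
    sub = genotypes.subset([cn_locus])
    return trans_scan(adjusted, probes, sub, **kwargs)
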
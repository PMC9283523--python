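"""Transcriptome-wide association: heritability gating, weights, LD-aware Z.

The TWAS pipeline for one gene: (1) estimate cis genetic heritability with
single-component REML on the genomic relationship matrix of cis variants
and keep genes with LRT p < 0.05; (2) learn expression weights from the
cohort by 5-fold cross-validation over several sparse/dense predictors,
keeping the model with the best out-of-fold R²; (3) combine the weights
with GWAS z-scores through the LD matrix, Z = w'z / sqrt(w'Rw); (4) prune
significant genes on a chromosome to a conditionally independent subset via
their predicted-expression correlation; (5) flag genes with no
genome-wide-significant GWAS variant within 1 Mb as novel.

Weights are defined on the standardised-dosage scale throughout, and the LD
matrix R is the in-sample correlation of the same variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.linear_model import ElasticNetCV, LassoCV, Ridge
from sklearn.model_selection import KFold

__all__ = [
    "GRMatrix",
    "HeritabilityResult",
    "WeightModel",
    "TWASAssociation",
    "NoveltyFlag",
    "build_grm",
    "reml_h2",
    "fit_weights",
    "twas_z",
    "conditional_twas",
    "novelty_flag",
]


@dataclass
class GRMatrix:
    K: np.ndarray
    m_variants: int


@dataclass(frozen=True)
class HeritabilityResult:
    h2: float
    lrt: float
    p: float


@dataclass
class WeightModel:
    gene: str
    model: str  # top1 | ridge_blup | lasso | elastic_net
    weights: np.ndarray  # on standardised-dosage scale
    cv_r2: float
    best: bool = False


@dataclass(frozen=True)
class TWASAssociation:
    gene: str
    z: float
    p: float


@dataclass(frozen=True)
class NoveltyFlag:
    gene: str
    trait: str
    nearest_significant_bp: float
    novel: bool


# ---------------------------------------------------------------------------
# GRM and heritability
# ---------------------------------------------------------------------------


def standardise_dosages(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardised dosages; returns (Xs, keep mask) dropping constants."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance variant(s)", stacklevel=2)
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    return Xs, keep


def build_grm(cis_dosages: np.ndarray) -> GRMatrix:
    """Genomic relationship matrix K = X Xᵀ / m from standardised cis dosages."""
    Xs, keep = standardise_dosages(cis_dosages)
    m = Xs.shape[1]
    if m < 2:
        raise ValueError("need at least 2 non-constant cis variants for a GRM")
    return GRMatrix(K=Xs @ Xs.T / m, m_variants=m)


def reml_h2(phenotype: np.ndarray, grm: GRMatrix) -> HeritabilityResult:
    """Single-variance-component REML for y ~ N(0, σ²(h²K + (1−h²)I)).

    The phenotype should already be adjusted for covariates; it is centred
    here and the total variance is profiled out.  The LRT against h² = 0
    uses the 50:50 χ²₀:χ²₁ boundary mixture.
    """
    y = np.asarray(phenotype, dtype=float)
    K = grm.K
    n = len(y)
    if K.shape != (n, n):
        raise ValueError("GRM dimension does not match phenotype")
    if np.allclose(K, np.eye(n), atol=1e-10):
        raise ValueError("GRM is the identity: h2 is unidentifiable")
    yc = y - y.mean()
    D, U = np.linalg.eigh(K)
    yt = U.T @ yc
    nu = n - 1  # one fixed effect (intercept) absorbed

    def negll(h2: float) -> float:
        v = h2 * D + (1.0 - h2)
        v = np.maximum(v, 1e-12)
        s2 = float(np.sum(yt**2 / v)) / nu
        return 0.5 * (np.sum(np.log(v)) + nu * np.log(s2))

    grid = np.linspace(0.0, 1.0, 101)
    vals = np.array([negll(h) for h in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded")
    h2 = float(res.x)
    lrt = float(2.0 * (negll(0.0) - negll(h2)))
    p = 1.0 if lrt <= 0 else float(0.5 * stats.chi2.sf(lrt, 1))
    return HeritabilityResult(h2=h2, lrt=max(lrt, 0.0), p=p)


# ---------------------------------------------------------------------------
# expression weights
# ---------------------------------------------------------------------------


def _fit_model(model: str, X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    n, m = X.shape
    if model == "top1":
        r = X.T @ (y - y.mean()) / n
        w = np.zeros(m)
        j = int(np.argmax(np.abs(r)))
        w[j] = r[j]  # marginal slope on standardised scale
        return w
    if model == "ridge_blup":
        # BLUP-like shrinkage: a modest fixed penalty m/2 works well across
        # architectures without an inner CV loop
        fit = Ridge(alpha=m / 2.0, fit_intercept=True).fit(X, y)
        return fit.coef_
    if model == "lasso":
        fit = LassoCV(cv=5, random_state=seed, alphas=30, max_iter=5000).fit(X, y)
        return fit.coef_
    if model == "elastic_net":
        fit = ElasticNetCV(l1_ratio=0.5, cv=5, random_state=seed, alphas=30, max_iter=5000).fit(
            X, y
        )
        return fit.coef_
    raise ValueError(f"unknown model {model!r}")


def fit_weights(
    phenotype: np.ndarray,
    cis_dosages: np.ndarray,
    gene: str = "",
    models: tuple[str, ...] = ("top1", "ridge_blup", "lasso", "elastic_net"),
    folds: int = 5,
    seed: int = 0,
) -> list[WeightModel]:
    """Cross-validated expression weights; the best model (highest R²) is flagged.

    R² is the pooled out-of-fold 1 − SS_res/SS_tot over a seeded K-fold
    split shared by all models.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError("fewer samples than folds")
    Xs, _ = standardise_dosages(cis_dosages)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xs))
    results = []
    for model in models:
        pred = np.empty(n)
        for tr, te in splits:
            w = _fit_model(model, Xs[tr], y[tr], seed)
            pred[te] = y[tr].mean() + Xs[te] @ w
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        cv_r2 = 1.0 - ss_res / ss_tot
        w_full = _fit_model(model, Xs, y, seed)
        results.append(WeightModel(gene=gene, model=model, weights=w_full, cv_r2=cv_r2))
    best = max(range(len(results)), key=lambda i: results[i].cv_r2)
    results[best].best = True
    return results


# ---------------------------------------------------------------------------
# association and conditional pruning
# ---------------------------------------------------------------------------


def twas_z(
    weights: np.ndarray,
    gwas_z: np.ndarray,
    R: np.ndarray,
    gene: str = "",
    ridge: float = 0.0,
) -> TWASAssociation:
    """TWAS association: Z = w'z / sqrt(w'(R + ridge·I)w), two-sided normal p."""
    w = np.asarray(weights, dtype=float)
    z = np.asarray(gwas_z, dtype=float)
    R = np.asarray(R, dtype=float)
    if not (len(w) == len(z) == R.shape[0] == R.shape[1]):
        raise ValueError("weights, z and R must cover the same variant set")
    denom = float(w @ (R + ridge * np.eye(len(w))) @ w)
    if denom <= 1e-12:
        raise ValueError("degenerate predictor: w'Rw ~ 0")
    Z = float(w @ z) / np.sqrt(denom)
    return TWASAssociation(gene=gene, z=Z, p=float(2.0 * stats.norm.sf(abs(Z))))


def predicted_expression_correlation(weights: dict[str, np.ndarray], R: np.ndarray) -> pd.DataFrame:
    """ρ_jk = w_j'R w_k / sqrt(w_j'R w_j · w_k'R w_k) between genes' predictors."""
    genes = list(weights)
    Wm = np.column_stack([weights[g] for g in genes])
    C = Wm.T @ R @ Wm
    d = np.sqrt(np.diag(C))
    rho = C / np.outer(d, d)
    return pd.DataFrame(rho, index=genes, columns=genes)


def conditional_twas(
    associations: pd.DataFrame,
    weights: dict[str, np.ndarray],
    R: np.ndarray,
    z_threshold: float,
    collinear_rho: float = 0.999,
) -> pd.DataFrame:
    """Greedy conditional selection of independent TWAS genes on one chromosome.

    ``associations`` needs columns gene and z (FDR-significant genes only).
    At each step the largest remaining |Z| is selected; other genes' Z are
    residualised on it via the predicted-expression correlation
    (Z_cond = (Z_j − ρZ_sel)/sqrt(1−ρ²)) and the ρ matrix updated by the
    partial-correlation recursion.  Genes with |ρ| ≥ ``collinear_rho`` to a
    selected gene are marked collinear and never selected.
    """
    df = associations.copy().set_index("gene", drop=False)
    if df.empty:
        raise ValueError("no significant genes to condition")
    rho = predicted_expression_correlation({g: weights[g] for g in df["gene"]}, R)
    z = df["z"].astype(float).copy()
    status = pd.Series("candidate", index=df.index)
    while True:
        cand = status[status == "candidate"].index
        if cand.empty:
            break
        j = z.loc[cand].abs().idxmax()
        if abs(z.loc[j]) < z_threshold:
            break
        status.loc[j] = "independent"
        for k in cand.drop(j):
            r_jk = float(rho.loc[j, k])
            if abs(r_jk) >= collinear_rho:
                status.loc[k] = "collinear"
                continue
            z.loc[k] = (z.loc[k] - r_jk * z.loc[j]) / np.sqrt(1.0 - r_jk**2)
        # partial-correlation update among remaining candidates
        rem = status[status == "candidate"].index
        for a_i, a in enumerate(rem):
            for b in rem[a_i + 1 :]:
                r_ab, r_aj, r_bj = float(rho.loc[a, b]), float(rho.loc[a, j]), float(rho.loc[b, j])
                den = np.sqrt((1 - r_aj**2) * (1 - r_bj**2))
                rho.loc[a, b] = rho.loc[b, a] = (r_ab - r_aj * r_bj) / max(den, 1e-12)
    out = df.copy()
    out["z_conditional"] = z
    out["status"] = status
    out["independent"] = status == "independent"
    return out


def novelty_flag(
    gene: str,
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    gwas_table: pd.DataFrame,
    trait: str = "",
    window: int = 1_000_000,
    p_significant: float = 5e-8,
) -> NoveltyFlag:
    """Novel ⇔ no genome-wide-significant GWAS variant within 1 Mb of the gene.

    The window is inclusive: a significant variant exactly ``window`` bp
    from the gene footprint makes the gene non-novel.
    """
    t = gwas_table
    sig = t[(t["chrom"] == gene_chrom) & (t["p"] < p_significant)]
    if sig.empty:
        return NoveltyFlag(gene=gene, trait=trait, nearest_significant_bp=np.inf, novel=True)
    pos = sig["pos"].to_numpy(float)
    dist = np.where(
        pos < gene_start, gene_start - pos, np.where(pos > gene_end, pos - gene_end, 0.0)
    )
    nearest = float(dist.min())
    return NoveltyFlag(gene=gene, trait=trait, nearest_significant_bp=nearest, novel=nearest > window)
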
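"""Analytic power for single-variant eQTL tests and study-design MAF thresholds.

The test considered is the two-sided t-test of the per-allele slope in a
simple linear regression of expression on allelic dosage.  Under
Hardy-Weinberg equilibrium a variant with minor allele frequency ``maf``
contributes genotype variance ``2*maf*(1-maf)``; ``sigma_y`` is the *total*
outcome standard deviation, so the residual SD is
``sqrt(sigma_y**2 - slope**2 * 2*maf*(1-maf))``.  The non-null distribution
of the t statistic is noncentral t with ``n - 2`` degrees of freedom and
noncentrality ``slope * sqrt(n * 2*maf*(1-maf)) / sigma_e``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = ["PowerSpec", "PowerResult", "slr_power", "min_maf_for_power", "UNACHIEVABLE"]

#: Sentinel returned by :func:`min_maf_for_power` when no MAF reaches the target.
UNACHIEVABLE = "unachievable"


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a single-variant additive-model eQTL test.

    Parameters
    ----------
    n
        Effective sample size.
    maf
        Minor allele frequency of the causal variant, in (0, 0.5].
    slope
        Per-allele effect on expression (expression units per allele).
    sigma_y
        Total outcome standard deviation (not residual SD).
    alpha
        Two-sided significance level, typically a Bonferroni-style
        0.05 / (number of independent tests).
    """

    n: int
    maf: float
    slope: float
    sigma_y: float
    alpha: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3 for a slope t-test (df = n - 2 > 0)")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.sigma_y <= 0:
            raise ValueError("sigma_y must be positive")
        var_g = 2.0 * self.maf * (1.0 - self.maf)
        if self.slope**2 * var_g >= self.sigma_y**2:
            raise ValueError(
                "slope^2 * 2*maf*(1-maf) must be < sigma_y^2 "
                "(residual variance would be non-positive)"
            )


@dataclass(frozen=True)
class PowerResult:
    power: float
    noncentrality: float
    critical_value: float


def _nct_sf(t: float, df: float, ncp: float) -> float:
    """P(T > t) for noncentral t, robust in the far-tail regime.

    scipy's ``nct``/``nctdtr`` can return NaN for moderate df with the
    critical value and noncentrality both large; fall back to quadrature
    over the chi-square mixing variable where that happens.
    """
    val = 1.0 - special.nctdtr(df, ncp, t)
    if math.isfinite(val):
        return float(val)
    # T = (Z + ncp) / sqrt(V/df) with V ~ chi2_df:
    #   P(T > t) = E_V[ Phi(ncp - t*sqrt(V/df)) ]
    npts = 20000
    q = (np.arange(npts) + 0.5) / npts
    v = stats.chi2.ppf(q, df)
    return float(np.mean(stats.norm.sf(t * np.sqrt(v / df) - ncp)))


def slr_power(spec: PowerSpec) -> PowerResult:
    """Exact noncentral-t power of the two-sided per-allele slope test."""
    df = spec.n - 2
    var_g = 2.0 * spec.maf * (1.0 - spec.maf)
    sigma_e = math.sqrt(spec.sigma_y**2 - spec.slope**2 * var_g)
    ncp = spec.slope * math.sqrt(spec.n * var_g) / sigma_e
    tcrit = float(stats.t.ppf(1.0 - spec.alpha / 2.0, df))
    power = _nct_sf(tcrit, df, ncp) + _nct_sf(tcrit, df, -ncp)
    return PowerResult(power=float(power), noncentrality=float(ncp), critical_value=tcrit)


def min_maf_for_power(
    n: int,
    slope: float,
    sigma_y: float,
    alpha: float,
    target: float = 0.80,
    grid_step: float = 0.01,
) -> float | str:
    """Minor allele frequency threshold above which power reaches ``target``.

    Power is monotone increasing in MAF on (0, 0.5], so the threshold is the
    root of ``power(maf) = target``.  The root is located continuously
    (Brent's method) and reported truncated down to the ``grid_step`` grid:
    the study has at least ``target`` power for every MAF strictly greater
    than the returned value.  Returns :data:`UNACHIEVABLE` when even
    MAF = 0.5 falls short of the target.
    """
    if not 0.0 < target < 1.0:
        if target >= 1.0:
            return UNACHIEVABLE  # power of a t-test is < 1 for finite ncp
        raise ValueError("target must be in (0, 1)")

    def pw(maf: float) -> float:
        return slr_power(PowerSpec(n=n, maf=maf, slope=slope, sigma_y=sigma_y, alpha=alpha)).power

    lo, hi = 1e-6, 0.5
    if pw(hi) < target:
        return UNACHIEVABLE
    if pw(lo) >= target:
        return 0.0
    root = optimize.brentq(lambda m: pw(m) - target, lo, hi, xtol=1e-8)
    # floor to the grid; guard against a root sitting on a grid point
    return round(math.floor(root / grid_step + 1e-9) * grid_step, 10)
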
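"""Bivariate LD-score regression: heritability and genetic correlation.

Under a polygenic model, the expected squared association z-score of a
SNP grows linearly with its LD score ℓ (the sum of r² with all other
SNPs): E[z²] = 1 + N·h²·ℓ/M, with M the number of SNPs in the
reference.  Regressing z² on ℓ therefore estimates the SNP heritability
h² from the slope, while confounding inflates the intercept above 1.
For two traits, E[z₁z₂] = √(N₁N₂)·ρ_g·ℓ/M (+ an intercept absorbing
sample overlap), giving the genetic covariance ρ_g and the genetic
correlation rg = ρ_g/√(h₁²·h₂²).  Standard errors come from a
delete-one block jackknife over contiguous SNP blocks.

This is a deliberately compact implementation: no MHC exclusion and no
allele merging against an external reference list (harmonization is the
job of :mod:`mrkit.sumstats`); a constrained-intercept mode is
available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LDScoreTable:
    """Per-SNP LD scores plus the reference SNP count M."""

    df: pd.DataFrame  # columns: snp_id, ld_score
    m_ref: int

    def __post_init__(self):
        if (self.df["ld_score"] < 1).any():
            raise ValueError("LD scores must be ≥ 1 (a SNP is in LD with itself)")
        if self.m_ref < len(self.df):
            raise ValueError("reference M smaller than the table")


@dataclass
class LDSCResult:
    trait1: str
    trait2: str
    h2_1: float
    h2_2: float
    intercept1: float
    intercept2: float
    gencov: float
    gencov_intercept: float
    rg: float
    rg_se: float
    rg_p: float
    n_snp: int
    warning: str | None = None


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray,
              fit_intercept: bool = True):
    """Closed-form weighted least squares of y on x; returns (intercept, slope)."""
    if not fit_intercept:
        return 0.0, float(np.sum(w * x * y) / np.sum(w * x * x))
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    if det <= 0:
        raise ValueError("LD scores are (near-)constant: slope unidentifiable")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swy - slope * swx) / sw
    return float(intercept), float(slope)


def _h2_weights(ell: np.ndarray, n: float, h2: float, m: int,
                intercept: float) -> np.ndarray:
    """Heteroskedasticity weights 1/(ℓ · Var[z²]) given a first-pass fit."""
    mean_z2 = np.maximum(intercept + n * max(h2, 0.0) * ell / m, 0.1)
    return 1.0 / (ell * 2.0 * mean_z2**2)


def ldsc_h2(z: np.ndarray, n: float, ldscores: LDScoreTable,
            constrain_intercept: bool = False):
    """Univariate LD-score regression of z² on ℓ.

    Two-step weighting: a first pass with weights 1/ℓ, then
    heteroskedasticity weights from the first-pass fit.  Returns
    ``(h2, intercept)``; with ``constrain_intercept`` the intercept is
    pinned at 1.
    """
    z = np.asarray(z, dtype=float)
    ell = ldscores.df["ld_score"].to_numpy(float)
    if z.size != ell.size:
        raise ValueError("z-scores and LD scores must align")
    if z.size < 200:
        raise ValueError("LDSC needs ≥200 SNPs")
    m = ldscores.m_ref
    y = z**2
    if constrain_intercept:
        y0, fit_int = y - 1.0, False
    else:
        y0, fit_int = y, True

    w1 = 1.0 / ell
    c0, c1 = _wls_line(ell, y0, w1, fit_intercept=fit_int)
    h2_pass1 = c1 * m / n
    w2 = _h2_weights(ell, n, h2_pass1, m, c0 if fit_int else 1.0)
    c0, c1 = _wls_line(ell, y0, w2, fit_intercept=fit_int)
    intercept = c0 if fit_int else 1.0
    return float(c1 * m / n), float(intercept)


def _rg_components(z1, z2, n1, n2, ell, m, constrain_intercept=False):
    """Point estimates (h2_1, int1, h2_2, int2, gencov, gencov_int) plus
    the final-pass weights for each of the three regressions."""
    h2_1, int1 = ldsc_h2(z1, n1, LDScoreTable(
        pd.DataFrame({"snp_id": range(len(ell)), "ld_score": ell}), m),
        constrain_intercept)
    h2_2, int2 = ldsc_h2(z2, n2, LDScoreTable(
        pd.DataFrame({"snp_id": range(len(ell)), "ld_score": ell}), m),
        constrain_intercept)

    y = z1 * z2
    w1 = 1.0 / ell
    gint0, slope0 = _wls_line(ell, y, w1, fit_intercept=not constrain_intercept)
    # product-moment variance of z1·z2 under the first-pass fit
    a1 = np.maximum(int1 + n1 * max(h2_1, 0) * ell / m, 0.1)
    a2 = np.maximum(int2 + n2 * max(h2_2, 0) * ell / m, 0.1)
    c = slope0 * ell + (gint0 if not constrain_intercept else 0.0)
    w2 = 1.0 / (ell * (a1 * a2 + c**2))
    gint, slope = _wls_line(ell, y, w2, fit_intercept=not constrain_intercept)
    gencov = slope * m / np.sqrt(n1 * n2)

    wz1 = _h2_weights(ell, n1, h2_1, m, int1)
    wz2 = _h2_weights(ell, n2, h2_2, m, int2)
    return (h2_1, int1, h2_2, int2, gencov, gint), (wz1, wz2, w2)


def ldsc_rg(
    z1: np.ndarray, z2: np.ndarray,
    n1: float, n2: float,
    ldscores: LDScoreTable,
    n_blocks: int = 200,
    trait1: str = "trait1", trait2: str = "trait2",
    constrain_intercept: bool = False,
) -> LDSCResult:
    """Genetic correlation between two traits with block-jackknife SE.

    SNPs are assumed pre-aligned (same order in ``z1``, ``z2`` and the
    LD-score table, sorted by genomic position).  The jackknife deletes
    one of ``n_blocks`` contiguous blocks at a time and recomputes rg
    with the full-fit weights held fixed, so the SE is deterministic.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    ell = ldscores.df["ld_score"].to_numpy(float)
    if not (z1.size == z2.size == ell.size):
        raise ValueError("z1, z2 and LD scores must align")
    if z1.size < 200:
        raise ValueError("LDSC needs ≥200 shared SNPs")
    m = ldscores.m_ref
    n_blocks = min(n_blocks, z1.size)

    (h2_1, int1, h2_2, int2, gencov, gint), (wz1, wz2, wg) = _rg_components(
        z1, z2, n1, n2, ell, m, constrain_intercept)

    warning = None
    if h2_1 <= 0 or h2_2 <= 0:
        return LDSCResult(trait1, trait2, h2_1, h2_2, int1, int2, gencov, gint,
                          np.nan, np.nan, np.nan, z1.size,
                          warning="non-positive heritability: rg undefined")
    rg = gencov / np.sqrt(h2_1 * h2_2)
    if abs(rg) > 1:
        warning = "rg outside [-1, 1]"

    # delete-one-block jackknife on the three slope estimates, fixed weights
    fit_int = not constrain_intercept
    blocks = np.array_split(np.arange(z1.size), n_blocks)

    def _slope_terms(x, y, w):
        """Per-observation terms of the closed-form WLS line."""
        return np.stack([w, w * x, w * y, w * x * x, w * x * y])

    t1 = _slope_terms(ell, z1**2 - (0 if fit_int else 1.0), wz1)
    t2 = _slope_terms(ell, z2**2 - (0 if fit_int else 1.0), wz2)
    tg = _slope_terms(ell, z1 * z2, wg)

    def _slope_from(sums):
        sw, swx, swy, swxx, swxy = sums
        if fit_int:
            return (sw * swxy - swx * swy) / (sw * swxx - swx**2)
        return swxy / swxx

    full1, full2, fullg = t1.sum(axis=1), t2.sum(axis=1), tg.sum(axis=1)
    rg_jk = np.empty(len(blocks))
    for b, idx in enumerate(blocks):
        s1 = full1 - t1[:, idx].sum(axis=1)
        s2 = full2 - t2[:, idx].sum(axis=1)
        sg = fullg - tg[:, idx].sum(axis=1)
        h1_b = _slope_from(s1) * m / n1
        h2_b = _slope_from(s2) * m / n2
        gc_b = _slope_from(sg) * m / np.sqrt(n1 * n2)
        if h1_b > 0 and h2_b > 0:
            rg_jk[b] = gc_b / np.sqrt(h1_b * h2_b)
        else:
            rg_jk[b] = rg
    nb = len(blocks)
    rg_se = float(np.sqrt((nb - 1) / nb * np.sum((rg_jk - rg_jk.mean()) ** 2)))
    rg_p = float(2 * stats.norm.sf(abs(rg / rg_se))) if rg_se > 0 else 1.0

    return LDSCResult(trait1, trait2, float(h2_1), float(h2_2), float(int1),
                      float(int2), float(gencov), float(gint), float(rg),
                      rg_se, rg_p, z1.size, warning)
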
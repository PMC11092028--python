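"""Sensitivity analyses: heterogeneity, pleiotropy, directionality, FDR.

For each exposure-outcome pair the pipeline computes Cochran's Q across
the per-SNP Wald ratios, the MR-Egger intercept test, the MR-PRESSO
global/outlier/distortion tests, and the Steiger directionality test;
IVW p-values are then Benjamini–Hochberg corrected within a reporting
family and classified as significant (q < 0.05), suggestive (p < 0.05,
q ≥ 0.05) or null.  Pairs with heterogeneity (Q p < 0.05) or a
directional-pleiotropy signal (Egger intercept p < 0.05) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sumstats import HarmonizedSet
from .instruments import snp_r2


@dataclass
class SensitivityReport:
    """All sensitivity diagnostics for one exposure-outcome pair."""

    exposure: str
    outcome: str
    cochran_q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    presso_global_p: float | None = None
    presso_outliers: list = field(default_factory=list)
    presso_distortion_p: float | None = None
    steiger_correct_direction: bool | None = None
    steiger_p: float | None = None
    fdr_q: float | None = None
    classification: str | None = None  # significant | suggestive | null
    excluded: bool = False
    exclusion_reason: str | None = None


def cochran_q(h: HarmonizedSet, beta_ivw: float):
    """Heterogeneity of the per-SNP ratios around the IVW estimate.

    Q = Σ wᵢ(ratioᵢ − β_IVW)² with wᵢ = (β_expᵢ/se_outᵢ)²; p from
    chi-square with n_snp − 1 degrees of freedom.
    """
    bx, _, by, so = h.arrays()
    if bx.size < 2:
        raise ValueError("Cochran's Q requires ≥2 instruments")
    ratios = by / bx
    w = (bx / so) ** 2
    q = float(np.sum(w * (ratios - beta_ivw) ** 2))
    df = bx.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def heterogeneity_filter(q_pval: float) -> bool:
    """Exclude a pair when the heterogeneity test rejects (strict p < 0.05)."""
    return q_pval < 0.05


def pleiotropy_filter(egger_intercept_p: float) -> bool:
    """Exclude a pair when the Egger intercept departs from zero (p < 0.05)."""
    return egger_intercept_p < 0.05


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slope for every SNP, via sum subtraction."""
    sxy, sxx = np.sum(w * bx * by), np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, alpha: float = 0.05,
              seed: int | None = 0):
    """MR-PRESSO global, outlier and distortion tests.

    The observed statistic is the weighted residual sum of squares of
    the outcome effects around their leave-one-out IVW predictions,
    RSS = Σ wᵢ(β_outᵢ − θ̂₋ᵢ·β_expᵢ)² with wᵢ = 1/se_outᵢ².  Its null
    distribution comes from ``n_sim`` parametric draws
    β_exp* ~ N(β_expᵢ, se_expᵢ), β_out* ~ N(θ̂₋ᵢ·β_expᵢ, se_outᵢ), with
    the leave-one-out slopes recomputed inside each draw.  The global p
    is the +1-smoothed exceedance.  Per-SNP outlier p-values compare
    each observed weighted squared residual to its simulated
    distribution, Bonferroni-adjusted across SNPs and flagged at
    ``alpha``.  When outliers are found, the distortion p compares the
    shift in the IVW estimate after their removal with a null built by
    removing equally many randomly chosen SNPs.

    Returns ``(global_p, outlier_ids, distortion_p)``; ``distortion_p``
    is ``None`` when no outlier is flagged.
    """
    r = h.retained
    bx = r["beta_exp"].to_numpy(float)
    sx = r["se_exp"].to_numpy(float)
    by = r["beta_out"].to_numpy(float)
    so = r["se_out"].to_numpy(float)
    ids = r["snp_id"].to_numpy()
    n = bx.size
    if n < 4:
        raise ValueError("MR-PRESSO requires ≥4 instruments")

    w = 1.0 / so**2
    theta_loo = _loo_ivw(bx, by, w)
    obs_res2 = w * (by - theta_loo * bx) ** 2
    obs_rss = float(obs_res2.sum())

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, n))
    by_sim = rng.normal(theta_loo * bx, so, size=(n_sim, n))
    # leave-one-out slopes within each simulated dataset (vectorized)
    wxy, wxx = w * bx_sim * by_sim, w * bx_sim**2
    theta_sim = (wxy.sum(axis=1, keepdims=True) - wxy) / (
        wxx.sum(axis=1, keepdims=True) - wxx)
    sim_res2 = w * (by_sim - theta_sim * bx_sim) ** 2
    sim_rss = sim_res2.sum(axis=1)

    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (n_sim + 1))

    outlier_p = (1 + np.sum(sim_res2 >= obs_res2, axis=0)) / (n_sim + 1)
    outlier_p_adj = np.minimum(outlier_p * n, 1.0)
    outlier_mask = outlier_p_adj < alpha
    outlier_ids = [str(s) for s in ids[outlier_mask]]

    distortion_p = None
    n_out = int(outlier_mask.sum())
    if 0 < n_out < n - 1:
        def _ivw_slope(mask):
            return np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(w[mask] * bx[mask] ** 2)

        theta_all = _ivw_slope(np.ones(n, bool))
        theta_clean = _ivw_slope(~outlier_mask)
        d_obs = abs(theta_all - theta_clean)
        n_null = 500
        d_null = np.empty(n_null)
        for i in range(n_null):
            drop = rng.choice(n, size=n_out, replace=False)
            m = np.ones(n, bool)
            m[drop] = False
            d_null[i] = abs(theta_all - _ivw_slope(m))
        distortion_p = float((1 + np.sum(d_null >= d_obs)) / (n_null + 1))

    return global_p, outlier_ids, distortion_p


def steiger(h: HarmonizedSet, n_exp: float | None = None,
            n_out: float | None = None):
    """Directionality check: do the instruments explain more variance in
    the exposure than in the outcome?

    R² is summed per SNP on each side (standardized 2·eaf·(1−eaf)·β² for
    a continuous trait with known frequency, z²/(z²+n−2) otherwise); the
    p-value is a two-sample z-test on the difference of the Fisher-z
    transformed correlations √R² at the two sample sizes.
    """
    r = h.retained
    if n_exp is None:
        n_exp = float(np.nanmedian(r["n_exp"]))
    if n_out is None:
        n_out = float(np.nanmedian(r["n_out"]))
    if np.isnan(n_exp) or np.isnan(n_out):
        raise ValueError("Steiger needs sample sizes for both traits")

    r2_exp = sum(
        snp_r2(row.beta_exp, row.se_exp, n_exp, row.eaf, h.exposure_type)
        for row in r.itertuples()
    )
    r2_out = sum(
        snp_r2(row.beta_out, row.se_out, n_out, row.eaf, h.outcome_type)
        for row in r.itertuples()
    )
    r2_exp, r2_out = min(r2_exp, 1 - 1e-12), min(r2_out, 1 - 1e-12)
    z1, z2 = np.arctanh(np.sqrt(r2_exp)), np.arctanh(np.sqrt(r2_out))
    se = np.sqrt(1 / (n_exp - 3) + 1 / (n_out - 3))
    zstat = (z1 - z2) / se
    p = float(2 * stats.norm.sf(abs(zstat)))
    return bool(r2_exp > r2_out), p


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg q-values, mapped back to the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(pval: float, qval: float) -> str:
    """significant (q<0.05) / suggestive (p<0.05, q≥0.05) / null."""
    if not (0 < pval <= 1 and 0 < qval <= 1):
        raise ValueError("p and q must lie in (0, 1]")
    if qval < 0.05:
        return "significant"
    if pval < 0.05:
        return "suggestive"
    return "null"


def sensitivity_report(
    h: HarmonizedSet,
    beta_ivw: float,
    egger_intercept: float | None = None,
    egger_intercept_p: float | None = None,
    presso_n_sim: int = 1000,
    seed: int | None = 0,
    run_presso: bool = True,
) -> SensitivityReport:
    """Assemble heterogeneity/pleiotropy/PRESSO/Steiger diagnostics for a pair.

    Exclusion is flagged when Q p < 0.05 or the Egger intercept p < 0.05;
    FDR and classification are filled in later, family-wise, by the
    pipeline.
    """
    rep = SensitivityReport(exposure=h.exposure_name, outcome=h.outcome_name)
    rep.cochran_q, rep.q_df, rep.q_pval = cochran_q(h, beta_ivw)
    rep.egger_intercept = egger_intercept
    rep.egger_intercept_p = egger_intercept_p

    if run_presso and h.n_snp >= 4:
        rep.presso_global_p, rep.presso_outliers, rep.presso_distortion_p = mr_presso(
            h, n_sim=presso_n_sim, seed=seed)
    try:
        rep.steiger_correct_direction, rep.steiger_p = steiger(h)
    except ValueError:
        rep.steiger_correct_direction, rep.steiger_p = None, None

    if heterogeneity_filter(rep.q_pval):
        rep.excluded = True
        rep.exclusion_reason = "heterogeneity (Q p < 0.05)"
    elif egger_intercept_p is not None and pleiotropy_filter(egger_intercept_p):
        rep.excluded = True
        rep.exclusion_reason = "horizontal pleiotropy (Egger intercept p < 0.05)"
    return rep
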
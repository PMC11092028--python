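"""Two-sample MR causal estimators: IVW, MR-Egger, weighted median, weighted mode.

Each estimator consumes per-SNP exposure and outcome effects that have
been harmonized to a common effect allele, and returns a causal-effect
estimate on the outcome scale per unit exposure (log-odds per exposure
SD for a binary outcome).

The estimators are regression-shaped, so they are written as
scikit-learn style classes: hyper-parameters in ``__init__``, data in
``fit``, results in trailing-underscore attributes.  ``fit`` takes the
exposure effects as ``X`` (shape ``(n,)`` or ``(n, 1)``), the outcome
effects as ``y``, and the standard errors as keyword arguments.  The
module-level functions :func:`ivw`, :func:`egger`,
:func:`weighted_median` and :func:`weighted_mode` are thin wrappers
that consume a :class:`~mrkit.sumstats.HarmonizedSet` and return an
:class:`MRResult` row.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .sumstats import HarmonizedSet, beta_to_or


@dataclass
class MRResult:
    """One estimator's causal estimate for one exposure-outcome pair."""

    exposure: str
    outcome: str
    method: str  # IVW | Egger | WeightedMedian | WeightedMode | WaldRatio
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["or"] = d.pop("or_")
        return d


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float):
    """Per-SNP causal estimate β_out/β_exp with first-order delta-method SE."""
    if beta_exp == 0:
        raise ValueError("Wald ratio undefined for a zero exposure effect")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def _as_1d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X.ravel()
    if X.ndim != 1:
        raise ValueError("X must be 1-d (or a single-column 2-d array) of exposure effects")
    return X


def _check_fit_inputs(X, y, se_out, min_snp, method):
    bx, by = _as_1d(X), np.asarray(y, dtype=float)
    if by.shape != bx.shape:
        raise ValueError("X and y must have the same length")
    if se_out is None:
        raise ValueError("se_out is required")
    so = np.asarray(se_out, dtype=float)
    if so.shape != bx.shape or np.any(so <= 0):
        raise ValueError("se_out must match X in length and be positive")
    if bx.size < min_snp:
        raise ValueError(f"{method} requires ≥{min_snp} instruments, got {bx.size}")
    return bx, by, so


def _normal_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


class IVWEstimator(RegressorMixin, BaseEstimator):
    """Inverse-variance weighted MR.

    Weighted least squares of outcome on exposure effects through the
    origin with weights 1/se_out², equivalently the weighted mean of the
    per-SNP Wald ratios with weights (β_exp/se_out)².  The default is a
    multiplicative random-effects model: the fixed-effect SE is inflated
    by ``sqrt(max(1, Q/(n−1)))``, with Q the Cochran heterogeneity
    statistic.  A single SNP reduces to the Wald ratio.

    Attributes (after fit): ``beta_``, ``se_``, ``pval_``, ``q_``,
    ``q_df_``, ``n_snp_``.
    """

    def __init__(self, random_effects: bool = True):
        self.random_effects = random_effects

    def fit(self, X, y, se_out=None, **_):
        bx, by, so = _check_fit_inputs(X, y, se_out, 1, "IVW")
        if np.any(bx == 0):
            raise ValueError("zero exposure effect among instruments")
        n = bx.size
        self.n_snp_ = n
        if n == 1:
            self.beta_, self.se_ = wald_ratio(bx[0], np.nan, by[0], so[0])
            self.q_, self.q_df_ = 0.0, 0
        else:
            w = 1.0 / so**2
            self.beta_ = float(np.sum(w * bx * by) / np.sum(w * bx**2))
            se_fixed = float(np.sqrt(1.0 / np.sum(w * bx**2)))
            ratios = by / bx
            wq = (bx / so) ** 2
            self.q_ = float(np.sum(wq * (ratios - self.beta_) ** 2))
            self.q_df_ = n - 1
            infl = max(1.0, self.q_ / self.q_df_) if self.random_effects else 1.0
            self.se_ = se_fixed * float(np.sqrt(infl))
        self.pval_ = _normal_p(self.beta_ / self.se_)
        return self

    def predict(self, X):
        return self.beta_ * _as_1d(X)


class EggerEstimator(RegressorMixin, BaseEstimator):
    """MR-Egger: weighted regression with a free intercept.

    The slope is the pleiotropy-adjusted causal estimate; a non-zero
    intercept indicates directional pleiotropy.  Instruments are
    oriented so every exposure effect is positive before fitting.
    Standard errors carry the multiplicative random-effects inflation
    ``sqrt(max(1, RSS_w/(n−2)))`` and p-values use the t distribution
    with n−2 degrees of freedom.

    Attributes: ``beta_``, ``se_``, ``pval_``, ``intercept_``,
    ``intercept_se_``, ``intercept_p_``, ``n_snp_``.
    """

    def __init__(self, random_effects: bool = True):
        self.random_effects = random_effects

    def fit(self, X, y, se_out=None, **_):
        bx, by, so = _check_fit_inputs(X, y, se_out, 3, "Egger")
        # orient so the exposure effect is positive for every instrument
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        n = bx.size
        w = 1.0 / so**2
        # closed-form weighted normal equations for [intercept, slope]
        sw, swx, swy = w.sum(), (w * bx).sum(), (w * by).sum()
        swxx, swxy = (w * bx * bx).sum(), (w * bx * by).sum()
        det = sw * swxx - swx**2
        if det <= 0:
            raise ValueError("degenerate design: exposure effects are collinear")
        intercept = (swxx * swy - swx * swxy) / det
        slope = (sw * swxy - swx * swy) / det
        resid = by - intercept - slope * bx
        rss_w = float(np.sum(w * resid**2))
        sigma2 = max(1.0, rss_w / (n - 2)) if self.random_effects else rss_w / (n - 2)
        var_slope = sigma2 * sw / det
        var_int = sigma2 * swxx / det
        self.n_snp_ = n
        self.beta_ = float(slope)
        self.se_ = float(np.sqrt(var_slope))
        self.pval_ = float(2 * stats.t.sf(abs(self.beta_ / self.se_), n - 2))
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(np.sqrt(var_int))
        self.intercept_p_ = float(
            2 * stats.t.sf(abs(self.intercept_ / self.intercept_se_), n - 2))
        return self

    def predict(self, X):
        return self.intercept_ + self.beta_ * np.abs(_as_1d(X))


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median with the half-weight cumulative convention.

    With ratios sorted, the cumulative standardized weight of the i-th
    ratio is s_i = (Σ_{j≤i} w_j − w_i/2)/Σw; the estimate interpolates
    the sorted ratios linearly at s = 0.5.
    """
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


class WeightedMedianEstimator(RegressorMixin, BaseEstimator):
    """Weighted-median MR: consistent when ≥50% of the weight is valid.

    The estimate is the weighted median of the per-SNP Wald ratios with
    inverse-variance weights (β_exp/se_out)².  The SE comes from a
    parametric bootstrap: ratios are resampled from
    N(ratio_i, se_out_i/|β_exp_i|) with the weights held fixed.

    Attributes: ``beta_``, ``se_``, ``pval_``, ``n_snp_``.
    """

    def __init__(self, n_boot: int = 1000, seed: int | None = 0):
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y, se_out=None, **_):
        bx, by, so = _check_fit_inputs(X, y, se_out, 3, "weighted median")
        if np.any(bx == 0):
            raise ValueError("zero exposure effect among instruments")
        ratios = by / bx
        ratio_se = so / np.abs(bx)
        w = (bx / so) ** 2
        self.n_snp_ = bx.size
        self.beta_ = _weighted_median(ratios, w)
        rng = np.random.default_rng(self.seed)
        boots = rng.normal(ratios, ratio_se, size=(self.n_boot, bx.size))
        est = np.array([_weighted_median(b, w) for b in boots])
        self.se_ = float(np.std(est, ddof=1))
        if self.se_ == 0:
            self.se_ = float(np.finfo(float).tiny)
        self.pval_ = _normal_p(self.beta_ / self.se_)
        return self

    def predict(self, X):
        return self.beta_ * _as_1d(X)


def _mode_of_ratios(ratios, weights, h, grid_size=512):
    """Argmax of the weighted Gaussian-kernel density on a fixed grid."""
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


class WeightedModeEstimator(RegressorMixin, BaseEstimator):
    """Mode-based MR: consistent when the largest group of instruments is valid.

    The per-SNP Wald ratios are smoothed with a Gaussian kernel weighted
    by (β_exp/se_out)²; the estimate is the density argmax on a 512-point
    grid spanning the ratio range ±3 bandwidths.  The bandwidth is
    ``phi`` times the modified Silverman rule
    0.9·min(sd, IQR/1.349)·n^{−1/5}.  Bootstrap SE as for the median.

    Attributes: ``beta_``, ``se_``, ``pval_``, ``bandwidth_``, ``n_snp_``.
    """

    def __init__(self, phi: float = 1.0, n_boot: int = 1000, seed: int | None = 0,
                 grid_size: int = 512):
        self.phi = phi
        self.n_boot = n_boot
        self.seed = seed
        self.grid_size = grid_size

    @staticmethod
    def _bandwidth(ratios: np.ndarray, phi: float) -> float:
        sd = np.std(ratios, ddof=1)
        iqr = np.subtract(*np.percentile(ratios, [75, 25]))
        s = min(sd, iqr / 1.349) if iqr > 0 else sd
        return phi * 0.9 * s * ratios.size ** (-1 / 5)

    def fit(self, X, y, se_out=None, **_):
        bx, by, so = _check_fit_inputs(X, y, se_out, 3, "weighted mode")
        if np.any(bx == 0):
            raise ValueError("zero exposure effect among instruments")
        ratios = by / bx
        ratio_se = so / np.abs(bx)
        w = (bx / so) ** 2
        w = w / w.sum()
        self.n_snp_ = bx.size
        h = self._bandwidth(ratios, self.phi)
        self.bandwidth_ = float(h)
        if h <= 0:  # all ratios identical
            self.beta_ = float(ratios[0])
        else:
            self.beta_ = _mode_of_ratios(ratios, w, h, self.grid_size)
        rng = np.random.default_rng(self.seed)
        boots = rng.normal(ratios, ratio_se, size=(self.n_boot, bx.size))
        est = np.empty(self.n_boot)
        for i, b in enumerate(boots):
            hb = self._bandwidth(b, self.phi)
            est[i] = _mode_of_ratios(b, w, hb, self.grid_size) if hb > 0 else b[0]
        self.se_ = float(np.std(est, ddof=1))
        if self.se_ == 0:
            self.se_ = float(np.finfo(float).tiny)
        self.pval_ = _normal_p(self.beta_ / self.se_)
        return self

    def predict(self, X):
        return self.beta_ * _as_1d(X)


def _result_from(est, h: HarmonizedSet, method: str, n_snp: int) -> MRResult:
    or_, lo, hi = beta_to_or(est.beta_, est.se_)
    res = MRResult(
        exposure=h.exposure_name, outcome=h.outcome_name, method=method,
        beta=est.beta_, se=est.se_, pval=est.pval_,
        or_=or_, ci_low=lo, ci_high=hi, n_snp=n_snp,
    )
    if isinstance(est, EggerEstimator):
        res.intercept = est.intercept_
        res.intercept_se = est.intercept_se_
        res.intercept_p = est.intercept_p_
    return res


def ivw(h: HarmonizedSet, random_effects: bool = True) -> MRResult:
    """Inverse-variance weighted estimate for a harmonized pair."""
    bx, _, by, so = h.arrays()
    est = IVWEstimator(random_effects=random_effects).fit(bx, by, se_out=so)
    method = "IVW" if len(bx) > 1 else "WaldRatio"
    return _result_from(est, h, method, len(bx))


def egger(h: HarmonizedSet, random_effects: bool = True) -> MRResult:
    """MR-Egger slope (and pleiotropy intercept) for a harmonized pair."""
    bx, _, by, so = h.arrays()
    est = EggerEstimator(random_effects=random_effects).fit(bx, by, se_out=so)
    return _result_from(est, h, "Egger", len(bx))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    bx, _, by, so = h.arrays()
    est = WeightedMedianEstimator(n_boot=n_boot, seed=seed).fit(bx, by, se_out=so)
    return _result_from(est, h, "WeightedMedian", len(bx))


def weighted_mode(h: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000,
                  seed: int = 0) -> MRResult:
    bx, _, by, so = h.arrays()
    est = WeightedModeEstimator(phi=phi, n_boot=n_boot, seed=seed).fit(bx, by, se_out=so)
    return _result_from(est, h, "WeightedMode", len(bx))


METHODS = {
    "ivw": ivw,
    "egger": egger,
    "wmedian": weighted_median,
    "wmode": weighted_mode,
}


def run_methods(h: HarmonizedSet, methods=("ivw", "egger", "wmedian", "wmode"),
                seed: int = 0) -> list[MRResult]:
    """Run the requested estimators on one harmonized pair."""
    out = []
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown MR method {m!r}")
        kwargs = {"seed": seed} if m in ("wmedian", "wmode") else {}
        out.append(METHODS[m](h, **kwargs))
    return out
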
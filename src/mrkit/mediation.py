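"""Two-step mediation MR: indirect effect and proportion mediated.

β1 is the exposure→mediator MR estimate, β2 the mediator→outcome
estimate and β3 the exposure→outcome total effect.  The indirect effect
is the product β1·β2 and the proportion mediated is β1·β2/β3.  The
uncertainty of the proportion comes by default from a parametric
bootstrap over the three estimates; a Sobel (delta-method) alternative
is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    beta1: float  # exposure → mediator
    beta2: float  # mediator → outcome
    beta3: float  # exposure → outcome (total)
    indirect: float
    proportion: float
    ci_low: float
    ci_high: float
    pval: float
    inconsistent: bool = False  # proportion outside [-1, 2]


def screen_mediators(gm_mediator, mediator_outcome, gm_outcome,
                     p_threshold: float = 0.05) -> list[tuple]:
    """Intersect the three MR screens into candidate mediation triples.

    Each argument maps a (trait, trait) pair to an object with a
    ``pval`` attribute (an IVW :class:`~mrkit.estimators.MRResult`).
    A triple (exposure, mediator, outcome) is retained only when the
    exposure→mediator, mediator→outcome and exposure→outcome estimates
    are all at least suggestive (p < ``p_threshold``).
    """
    triples = []
    for (exp, med), r1 in gm_mediator.items():
        for (med2, out), r2 in mediator_outcome.items():
            if med2 != med:
                continue
            r3 = gm_outcome.get((exp, out))
            if r3 is None:
                continue
            if r1.pval < p_threshold and r2.pval < p_threshold and r3.pval < p_threshold:
                triples.append((exp, med, out))
    return sorted(triples)


def mediation_effect(beta1: float, beta2: float, beta3: float):
    """Indirect effect β1·β2 and proportion mediated β1·β2/β3."""
    if beta3 == 0:
        raise ValueError("undefined proportion: total effect is zero")
    indirect = beta1 * beta2
    return indirect, indirect / beta3


def sobel_p(beta1: float, se1: float, beta2: float, se2: float) -> float:
    """Two-sided normal test of the indirect effect (Sobel)."""
    var = beta2**2 * se1**2 + beta1**2 * se2**2
    if var == 0:
        return 1.0 if beta1 * beta2 == 0 else 0.0
    z = beta1 * beta2 / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def mediation_ci(
    beta1: float, se1: float,
    beta2: float, se2: float,
    beta3: float, se3: float,
    method: str = "bootstrap",
    n_boot: int = 10_000,
    seed: int | None = 0,
    alpha: float = 0.05,
):
    """CI for the proportion mediated; p-value for the indirect effect.

    ``bootstrap`` (default): the three betas are resampled from
    independent normals (β3 included) and the empirical
    ``alpha/2``/``1−alpha/2`` percentiles of β1·β2/β3 are returned —
    ratio distributions are skewed, so the interval is deliberately
    asymmetric.  ``delta``: first-order variance of β1·β2 propagated to
    the ratio with β3's uncertainty included.
    """
    if min(se1, se2, se3) < 0:
        raise ValueError("standard errors must be non-negative")
    if beta3 == 0:
        raise ValueError("undefined proportion: total effect is zero")
    p = sobel_p(beta1, se1, beta2, se2)
    point = beta1 * beta2 / beta3

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        b1 = rng.normal(beta1, se1, n_boot)
        b2 = rng.normal(beta2, se2, n_boot)
        b3 = rng.normal(beta3, se3, n_boot)
        ok = b3 != 0
        props = b1[ok] * b2[ok] / b3[ok]
        lo, hi = np.percentile(props, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        # a skewed bootstrap can exclude the plug-in point; widen to keep it
        lo, hi = min(lo, point), max(hi, point)
        return float(lo), float(hi), p
    if method == "delta":
        var_ind = beta2**2 * se1**2 + beta1**2 * se2**2
        ind = beta1 * beta2
        # ratio variance by first-order propagation including beta3
        var_prop = var_ind / beta3**2 + ind**2 * se3**2 / beta3**4
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var_prop)
        return float(point - half), float(point + half), p
    raise ValueError(f"unknown CI method {method!r}")


def mediate(
    exposure: str, mediator: str, outcome: str,
    beta1: float, se1: float,
    beta2: float, se2: float,
    beta3: float, se3: float,
    method: str = "bootstrap",
    n_boot: int = 10_000,
    seed: int | None = 0,
) -> MediationResult:
    """Full mediation summary for one screened triple."""
    indirect, proportion = mediation_effect(beta1, beta2, beta3)
    lo, hi, p = mediation_ci(beta1, se1, beta2, se2, beta3, se3,
                             method=method, n_boot=n_boot, seed=seed)
    return MediationResult(
        exposure=exposure, mediator=mediator, outcome=outcome,
        beta1=beta1, beta2=beta2, beta3=beta3,
        indirect=indirect, proportion=proportion,
        ci_low=lo, ci_high=hi, pval=p,
        inconsistent=not (-1.0 <= proportion <= 2.0),
    )
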
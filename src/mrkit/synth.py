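"""Synthetic GWAS summary statistics with known causal ground truth.

Every downstream stage — instrument selection, the four MR estimators,
the sensitivity suite, mediation MR and LDSC — is validated by
parameter recovery on data from this module, so the generator encodes
the causal model explicitly:

* a polygenic exposure: ``n_causal`` SNPs carry true per-allele effects
  drawn so the explained exposure variance sums to ``h2_exposure``;
* an outcome linked by the causal coefficient ``theta`` plus optional
  per-SNP horizontal pleiotropy ``alpha`` (directional or balanced,
  optionally correlated with instrument strength — an InSIDE
  violation) on an ``frac_invalid`` share of the instruments;
* an exposure→mediator→outcome chain with coefficients ``theta1``,
  ``theta2`` and a direct effect, so the true proportion mediated is
  θ₁θ₂/(θ₁θ₂ + θ_direct);
* block-diagonal LD with exponential r² decay, and the matching LD
  scores, for clumping and LDSC;
* sampling noise with SE = 1/√(2·eaf·(1−eaf)·N), the standard
  standardized-genotype scaling, so SEs shrink as 1/√N.

Simulation is at the summary-statistic level (no individual genotypes):
every implemented method consumes summary data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .sumstats import SumStatsTable, SUMSTATS_COLUMNS
from .instruments import LDMatrix
from .ldsc import LDScoreTable

# non-palindromic allele pairs only, so harmonization keeps every SNP
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class SimConfig:
    """Ground-truth parameters of one synthetic study.

    Defaults mirror the real study's structure: a gut-microbiome-scale
    exposure GWAS (N=18,340), a large binary outcome GWAS (N=602,604),
    an anthropometric mediator GWAS (N=100,000), a modest causal effect
    and no pleiotropy unless asked for.
    """

    m_snps: int = 2000
    n_blocks: int = 200
    r2_decay: float = 0.7          # r² between adjacent SNPs in a block
    block_spacing_kb: float = 20_000  # between block starts (beyond the clump window)
    snp_spacing_kb: float = 100       # within a block (inside the clump window)
    n_causal: int = 30
    h2_exposure: float = 0.1       # exposure variance explained by causal SNPs
    theta: float = 0.1             # causal effect exposure → outcome
    frac_invalid: float = 0.0      # share of causal SNPs with pleiotropy
    alpha_mean: float = 0.0        # directional pleiotropy mean (0 → balanced)
    alpha_sd: float = 0.005
    inside_violation: bool = False  # pleiotropy correlated with instrument strength
    theta1: float = 0.2            # exposure → mediator
    theta2: float = 0.3            # mediator → outcome
    theta_direct: float = 0.24     # exposure → outcome, not via mediator
    n_causal_med: int = 30         # mediator's own instruments
    n_exp: int = 18_340
    n_med: int = 100_000
    n_out: int = 602_604
    outcome_binary: bool = True
    h2_trait1: float = 0.3         # LDSC mode
    h2_trait2: float = 0.2
    rg: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_invalid", "h2_exposure", "h2_trait1", "h2_trait2"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1 <= self.rg <= 1:
            raise ValueError("rg must lie in [-1, 1]")
        for name in ("n_exp", "n_med", "n_out"):
            if getattr(self, name) < 100:
                raise ValueError(f"{name} must be ≥ 100")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_causal + self.n_causal_med > self.m_snps:
            raise ValueError("more causal SNPs than SNPs")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Everything needed to score recovery without re-simulating."""

    theta: float
    alpha: np.ndarray                  # per-SNP pleiotropy (0 for valid)
    valid_mask: np.ndarray             # True where the instrument is valid
    causal_idx: np.ndarray             # indices of exposure-causal SNPs
    beta_exp_true: np.ndarray
    theta1: float | None = None
    theta2: float | None = None
    theta_direct: float | None = None
    proportion_mediated: float | None = None
    med_causal_idx: np.ndarray | None = None
    h2_1: float | None = None
    h2_2: float | None = None
    rg: float | None = None


def _positions(cfg: SimConfig):
    """Block id, chromosome and bp position for every SNP."""
    block = np.arange(cfg.m_snps) * cfg.n_blocks // cfg.m_snps
    within = np.arange(cfg.m_snps) - np.searchsorted(block, block)
    chrom = (block % 22 + 1).astype(str)
    pos = (1 + block * cfg.block_spacing_kb * 1000
           + within * cfg.snp_spacing_kb * 1000).astype(float)
    return block, chrom, pos


def simulate_ld(cfg: SimConfig):
    """Block-diagonal LD with exponential decay, plus the LD scores.

    Within a block, r² between SNPs i and j is ``r2_decay**|i−j|``;
    blocks are independent.  Block starts are spaced beyond the default
    10,000-kb clump window while SNPs within a block sit inside it, so
    the matrix exercises both sides of the clumping rule.
    """
    block, chrom, pos = _positions(cfg)
    snp_ids = [f"rs{i + 1}" for i in range(cfg.m_snps)]
    mats = []
    for b in np.unique(block):
        size = int(np.sum(block == b))
        idx = np.arange(size)
        mats.append(cfg.r2_decay ** np.abs(idx[:, None] - idx[None, :]))
    r2 = sparse.block_diag(mats, format="csr")
    ld = LDMatrix(snp_ids, chrom, pos, r2)
    scores = pd.DataFrame({"snp_id": snp_ids, "ld_score": ld.ld_scores()})
    return ld, LDScoreTable(scores, m_ref=cfg.m_snps)


def _sumstats_frame(cfg, rng, snp_ids, chrom, pos, beta_true, se, n):
    """Observed summary statistics: truth plus N(0, se) sampling noise."""
    beta_hat = beta_true + rng.normal(0, se)
    pval = 2 * stats.norm.sf(np.abs(beta_hat / se))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return beta_hat, pval


def _base_frame(snp_ids, chrom, pos, ea, oa, eaf, beta, se, pval, n):
    return pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos_bp": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": pval, "n": float(n),
    })[SUMSTATS_COLUMNS]


def _draw_alleles(rng, m):
    pick = rng.integers(0, len(_ALLELE_PAIRS), m)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pick])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pick])
    return ea, oa


def _exposure_effects(cfg, rng, eaf):
    """Causal indices and true per-allele exposure effects."""
    causal_idx = rng.choice(cfg.m_snps, size=cfg.n_causal + cfg.n_causal_med,
                            replace=False)
    exp_idx = np.sort(causal_idx[:cfg.n_causal])
    med_idx = np.sort(causal_idx[cfg.n_causal:])
    beta_exp = np.zeros(cfg.m_snps)
    var_per_snp = cfg.h2_exposure / cfg.n_causal
    sd = np.sqrt(var_per_snp / (2 * eaf[exp_idx] * (1 - eaf[exp_idx])))
    beta_exp[exp_idx] = rng.normal(0, sd)
    return exp_idx, med_idx, beta_exp


def _pleiotropy(cfg, rng, exp_idx, beta_exp):
    """Per-SNP pleiotropic effect alpha and the valid-instrument mask.

    Directional pleiotropy (``alpha_mean`` ≠ 0) is defined relative to
    the exposure-increasing allele — the orientation MR-Egger fits in —
    so the Egger intercept estimand equals ``alpha_mean`` when every
    instrument is invalid.  The returned ``alpha`` is already on the
    reported-allele scale (sign-coupled to ``beta_exp``).
    """
    alpha = np.zeros(len(beta_exp))
    n_invalid = int(round(cfg.frac_invalid * len(exp_idx)))
    valid = np.ones(len(beta_exp), dtype=bool)
    if n_invalid:
        invalid = rng.choice(exp_idx, size=n_invalid, replace=False)
        a = rng.normal(cfg.alpha_mean, cfg.alpha_sd, n_invalid)
        if cfg.inside_violation:
            # tie pleiotropy to instrument strength (violates InSIDE)
            a = a + 0.5 * cfg.alpha_mean * (
                np.abs(beta_exp[invalid]) / np.abs(beta_exp[exp_idx]).mean() - 1)
        alpha[invalid] = a * np.where(beta_exp[invalid] < 0, -1.0, 1.0)
        valid[invalid] = False
    return alpha, valid


def simulate_pair(cfg: SimConfig):
    """One exposure GWAS, one outcome GWAS and the generating truth.

    ``beta_out,true = theta·beta_exp,true + alpha``; both tables share
    SNP ids, positions, alleles and allele frequencies so harmonization
    is the identity apart from sampling noise.
    """
    rng = np.random.default_rng(cfg.seed)
    _, chrom, pos = _positions(cfg)
    snp_ids = [f"rs{i + 1}" for i in range(cfg.m_snps)]
    eaf = rng.uniform(0.05, 0.95, cfg.m_snps)
    ea, oa = _draw_alleles(rng, cfg.m_snps)

    exp_idx, _, beta_exp = _exposure_effects(cfg, rng, eaf)
    alpha, valid = _pleiotropy(cfg, rng, exp_idx, beta_exp)
    beta_out = cfg.theta * beta_exp + alpha

    se_exp = 1 / np.sqrt(2 * eaf * (1 - eaf) * cfg.n_exp)
    se_out = 1 / np.sqrt(2 * eaf * (1 - eaf) * cfg.n_out)
    bhat_e, p_e = _sumstats_frame(cfg, rng, snp_ids, chrom, pos, beta_exp, se_exp, cfg.n_exp)
    bhat_o, p_o = _sumstats_frame(cfg, rng, snp_ids, chrom, pos, beta_out, se_out, cfg.n_out)

    exposure = SumStatsTable("exposure", "continuous", _base_frame(
        snp_ids, chrom, pos, ea, oa, eaf, bhat_e, se_exp, p_e, cfg.n_exp))
    outcome = SumStatsTable(
        "outcome", "binary" if cfg.outcome_binary else "continuous",
        _base_frame(snp_ids, chrom, pos, ea, oa, eaf, bhat_o, se_out, p_o, cfg.n_out))
    truth = SimTruth(theta=cfg.theta, alpha=alpha, valid_mask=valid,
                     causal_idx=exp_idx, beta_exp_true=beta_exp)
    return exposure, outcome, truth


def simulate_mediation(cfg: SimConfig):
    """Exposure, mediator and outcome GWAS linked by a mediation chain.

    The mediator inherits θ₁·β_exp from the exposure-causal SNPs and has
    ``n_causal_med`` instruments of its own; the outcome receives
    θ_direct·β_exp + θ₂·β_med, so the mediator's own instruments are
    valid instruments for the mediator→outcome leg.  True proportion
    mediated: θ₁θ₂/(θ₁θ₂ + θ_direct).
    """
    rng = np.random.default_rng(cfg.seed)
    _, chrom, pos = _positions(cfg)
    snp_ids = [f"rs{i + 1}" for i in range(cfg.m_snps)]
    eaf = rng.uniform(0.05, 0.95, cfg.m_snps)
    ea, oa = _draw_alleles(rng, cfg.m_snps)

    exp_idx, med_idx, beta_exp = _exposure_effects(cfg, rng, eaf)
    beta_med_own = np.zeros(cfg.m_snps)
    var_per_snp = cfg.h2_exposure / max(cfg.n_causal_med, 1)
    if cfg.n_causal_med:
        sd = np.sqrt(var_per_snp / (2 * eaf[med_idx] * (1 - eaf[med_idx])))
        beta_med_own[med_idx] = rng.normal(0, sd)

    beta_med = cfg.theta1 * beta_exp + beta_med_own
    beta_out = cfg.theta_direct * beta_exp + cfg.theta2 * beta_med

    tables = []
    for name, ttype, beta, n in (
        ("exposure", "continuous", beta_exp, cfg.n_exp),
        ("mediator", "continuous", beta_med, cfg.n_med),
        ("outcome", "binary" if cfg.outcome_binary else "continuous", beta_out, cfg.n_out),
    ):
        se = 1 / np.sqrt(2 * eaf * (1 - eaf) * n)
        bhat, p = _sumstats_frame(cfg, rng, snp_ids, chrom, pos, beta, se, n)
        tables.append(SumStatsTable(name, ttype, _base_frame(
            snp_ids, chrom, pos, ea, oa, eaf, bhat, se, p, n)))

    total = cfg.theta1 * cfg.theta2 + cfg.theta_direct
    truth = SimTruth(
        theta=total, alpha=np.zeros(cfg.m_snps),
        valid_mask=np.ones(cfg.m_snps, bool), causal_idx=exp_idx,
        beta_exp_true=beta_exp, theta1=cfg.theta1, theta2=cfg.theta2,
        theta_direct=cfg.theta_direct,
        proportion_mediated=(cfg.theta1 * cfg.theta2 / total) if total != 0 else np.nan,
        med_causal_idx=med_idx,
    )
    return tables[0], tables[1], tables[2], truth


def harmonized_from_arrays(beta_exp, se_exp, beta_out, se_out,
                           eaf=None, n_exp=1e5, n_out=1e5,
                           exposure="exposure", outcome="outcome"):
    """Wrap raw effect arrays as an already-aligned HarmonizedSet.

    Convenience for estimator-level simulation where allele bookkeeping
    is irrelevant.
    """
    from .sumstats import HarmonizedSet
    m = len(beta_exp)
    if eaf is None:
        eaf = np.full(m, 0.5)
    df = pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(m)],
        "chrom": "1", "pos_bp": np.arange(m, dtype=float) * 1e6,
        "effect_allele": "A", "other_allele": "G", "eaf": eaf,
        "beta_exp": np.asarray(beta_exp, float),
        "se_exp": np.asarray(se_exp, float),
        "p_exp": 2 * stats.norm.sf(np.abs(np.asarray(beta_exp) / np.asarray(se_exp))),
        "beta_out": np.asarray(beta_out, float),
        "se_out": np.asarray(se_out, float),
        "p_out": 2 * stats.norm.sf(np.abs(np.asarray(beta_out) / np.asarray(se_out))),
        "n_exp": float(n_exp), "n_out": float(n_out),
        "flipped": False, "palindromic_dropped": False,
    })
    return HarmonizedSet(exposure, outcome, df)


def simulate_ldsc_pair(cfg: SimConfig):
    """Per-SNP z-scores for two traits with the LDSC moment structure.

    Each SNP's (z₁, z₂) is bivariate normal with
    E[z_k²] = 1 + N_k·h²_k·ℓ/M and E[z₁z₂] = √(N₁N₂)·ρ_g·ℓ/M, where
    ρ_g = rg·√(h²₁h²₂) — exactly the moments LD-score regression fits.
    """
    rng = np.random.default_rng(cfg.seed)
    _, scores = simulate_ld(cfg)
    ell = scores.df["ld_score"].to_numpy(float)
    m = cfg.m_snps
    n1, n2 = cfg.n_exp, cfg.n_out
    gencov = cfg.rg * np.sqrt(cfg.h2_trait1 * cfg.h2_trait2)

    v1 = 1 + n1 * cfg.h2_trait1 * ell / m
    v2 = 1 + n2 * cfg.h2_trait2 * ell / m
    c = np.sqrt(n1 * n2) * gencov * ell / m
    # draw via Cholesky of the per-SNP 2x2 covariance
    u1 = rng.standard_normal(m)
    u2 = rng.standard_normal(m)
    z1 = np.sqrt(v1) * u1
    rho = np.clip(c / np.sqrt(v1 * v2), -1.0, 1.0)
    z2 = np.sqrt(v2) * (rho * u1 + np.sqrt(1 - rho**2) * u2)

    truth = SimTruth(theta=np.nan, alpha=np.zeros(m), valid_mask=np.ones(m, bool),
                     causal_idx=np.array([], int), beta_exp_true=np.zeros(m),
                     h2_1=cfg.h2_trait1, h2_2=cfg.h2_trait2, rg=cfg.rg)
    return z1, z2, scores, truth
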
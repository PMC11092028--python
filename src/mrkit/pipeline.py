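"""Orchestration of the full bidirectional MR study.

Forward MR runs every exposure against every outcome through the
instrument pipeline (p-threshold → LD clumping → F screen → min-SNP
rule), the four estimators, the sensitivity suite, heterogeneity and
pleiotropy exclusions, family-wise BH-FDR and the significant /
suggestive classification.  Reverse MR swaps the roles at the
genome-wide threshold (5e-8).  Mediation MR screens
exposure→mediator→outcome triples and reports the proportion mediated.
Every pair ends up either in the report or in the exclusion log with a
reason, and a fixed configuration (seeds included) reproduces the
output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import SumStatsTable, HarmonizedSet, harmonize, read_sumstats
from .instruments import LDMatrix, select_instruments, read_ld_reference
from .estimators import run_methods, ivw, MRResult
from .sensitivity import sensitivity_report, bh_fdr, classify, SensitivityReport
from .mediation import screen_mediators, mediate
from .ldsc import LDScoreTable, ldsc_rg

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "exposure", "outcome", "method", "n_snp", "beta", "se", "pval",
    "or", "ci_low", "ci_high", "qval", "classification",
    "q_pval", "egger_intercept_p", "steiger_correct_direction", "excluded",
]

SENSITIVITY_COLUMNS = [
    "exposure", "outcome", "cochran_q", "q_df", "q_pval",
    "egger_intercept", "egger_intercept_p",
    "presso_global_p", "presso_outliers", "presso_distortion_p",
    "steiger_correct_direction", "steiger_p",
    "fdr_q", "classification", "excluded", "exclusion_reason",
]


@dataclass
class StudyConfig:
    """Inputs and thresholds for one full study run."""

    exposures: list = field(default_factory=list)   # SumStatsTable
    outcomes: list = field(default_factory=list)
    mediators: list = field(default_factory=list)
    ld: LDMatrix | None = None
    ldscores: LDScoreTable | None = None
    p_exposure: float = 1e-5            # GM feature as exposure
    p_outcome_as_exposure: float = 5e-8  # disease / mediator as exposure
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    f_min: float = 10.0
    min_snps: int = 3
    methods: tuple = ("ivw", "egger", "wmedian", "wmode")
    presso_n_sim: int = 1000
    n_boot: int = 1000
    seed: int = 0
    output_dir: str | Path = "mr_output"


def analyze_pair(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    cfg: StudyConfig,
    p_threshold: float,
    seed: int,
):
    """One exposure→outcome MR with sensitivity diagnostics.

    Returns ``(results, report, exclusion_reason)``; ``results`` is
    empty and the reason set whenever the pair cannot be analyzed
    (too few instruments, no overlap).
    """
    if exposure.trait_name == outcome.trait_name:
        raise ValueError("exposure and outcome are the same trait")
    inst = select_instruments(
        exposure, cfg.ld, p_threshold=p_threshold, r2_max=cfg.clump_r2,
        window_kb=cfg.clump_kb, f_min=cfg.f_min, min_snps=cfg.min_snps)
    if not inst.valid:
        return [], None, inst.invalid_reason

    inst_table = SumStatsTable(exposure.trait_name, exposure.trait_type,
                               inst.df[exposure.df.columns])
    try:
        h = harmonize(inst_table, outcome)
    except ValueError as exc:
        return [], None, str(exc)
    if h.n_snp < cfg.min_snps:
        return [], None, "fewer than three SNPs"

    results = run_methods(h, methods=cfg.methods, seed=seed)
    by_method = {r.method: r for r in results}
    r_ivw = by_method.get("IVW") or by_method.get("WaldRatio") or results[0]
    r_egger = by_method.get("Egger")
    report = sensitivity_report(
        h, r_ivw.beta,
        egger_intercept=r_egger.intercept if r_egger else None,
        egger_intercept_p=r_egger.intercept_p if r_egger else None,
        presso_n_sim=cfg.presso_n_sim, seed=seed)
    return results, report, None


def _result_rows(results: list[MRResult], report: SensitivityReport | None):
    rows = []
    for r in results:
        d = r.to_dict()
        row = {k: d[k] for k in ("exposure", "outcome", "method", "n_snp",
                                 "beta", "se", "pval", "or", "ci_low", "ci_high")}
        row.update({
            "qval": np.nan, "classification": "",
            "q_pval": report.q_pval if report else np.nan,
            "egger_intercept_p": report.egger_intercept_p if report else np.nan,
            "steiger_correct_direction": report.steiger_correct_direction
            if report else None,
            "excluded": report.excluded if report else False,
        })
        rows.append(row)
    return rows


def _run_direction(exposures, outcomes, cfg: StudyConfig, p_threshold: float):
    """Shared driver for the forward and reverse passes."""
    rows, reports, exclusions = [], [], []
    pair_idx = 0
    for outcome in outcomes:
        family_keys, family_pvals = [], []
        out_rows_start = len(rows)
        for exposure in exposures:
            seed = int((cfg.seed * 100_003 + pair_idx) % 2**31)
            pair_idx += 1
            try:
                results, report, reason = analyze_pair(
                    exposure, outcome, cfg, p_threshold, seed)
            except ValueError as exc:
                exclusions.append({"exposure": exposure.trait_name,
                                   "outcome": outcome.trait_name,
                                   "reason": str(exc)})
                continue
            if reason is not None:
                exclusions.append({"exposure": exposure.trait_name,
                                   "outcome": outcome.trait_name, "reason": reason})
                continue
            reports.append(report)
            rows.extend(_result_rows(results, report))
            if report.excluded:
                exclusions.append({"exposure": exposure.trait_name,
                                   "outcome": outcome.trait_name,
                                   "reason": report.exclusion_reason})
            else:
                # primary-method p enters the FDR family for this outcome
                r_ivw = next(r for r in results if r.method in ("IVW", "WaldRatio"))
                family_keys.append((exposure.trait_name, outcome.trait_name))
                family_pvals.append(r_ivw.pval)
        # BH-FDR within the outcome family, post-exclusion
        if family_pvals:
            qvals = bh_fdr(family_pvals)
            qmap = dict(zip(family_keys, qvals))
            for row in rows[out_rows_start:]:
                key = (row["exposure"], row["outcome"])
                if key in qmap and row["method"] in ("IVW", "WaldRatio"):
                    row["qval"] = float(qmap[key])
                    row["classification"] = classify(row["pval"], row["qval"])
            for rep in reports:
                key = (rep.exposure, rep.outcome)
                if key in qmap:
                    rep.fdr_q = float(qmap[key])
                    ivw_p = next(row["pval"] for row in rows
                                 if (row["exposure"], row["outcome"]) == key
                                 and row["method"] in ("IVW", "WaldRatio"))
                    rep.classification = classify(ivw_p, rep.fdr_q)

    report_df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report_df = report_df.sort_values(["exposure", "outcome", "method"],
                                      kind="mergesort").reset_index(drop=True)
    excl_df = pd.DataFrame(exclusions, columns=["exposure", "outcome", "reason"])
    return report_df, excl_df, reports


def run_forward(cfg: StudyConfig):
    """Exposure panel → outcomes at the lenient threshold (default 1e-5)."""
    return _run_direction(cfg.exposures, cfg.outcomes, cfg, cfg.p_exposure)


def run_reverse(cfg: StudyConfig):
    """Outcomes → exposure panel at the genome-wide threshold (5e-8)."""
    return _run_direction(cfg.outcomes, cfg.exposures, cfg,
                          cfg.p_outcome_as_exposure)


def run_mediation_stage(cfg: StudyConfig, forward_report: pd.DataFrame):
    """Two-step mediation MR over every exposure×mediator×outcome triple.

    β1: exposure→mediator (exposure instruments, lenient threshold);
    β2: mediator→outcome (mediator instruments, genome-wide threshold);
    β3: the forward report's IVW total effect.  Triples where any leg
    has p ≥ 0.05 are screened out.
    """
    ivw_fwd = forward_report[
        forward_report["method"].isin(["IVW", "WaldRatio"])
        & ~forward_report["excluded"].astype(bool)]
    gm_outcome = {
        (r["exposure"], r["outcome"]): MRResult(
            r["exposure"], r["outcome"], r["method"], r["beta"], r["se"],
            r["pval"], r["or"], r["ci_low"], r["ci_high"], r["n_snp"])
        for r in ivw_fwd.to_dict("records")
    }

    gm_med, med_out = {}, {}
    pair_idx = 0
    for med in cfg.mediators:
        for exp in cfg.exposures:
            seed = int((cfg.seed * 99_991 + pair_idx) % 2**31)
            pair_idx += 1
            results, rep, reason = analyze_pair(exp, med, cfg, cfg.p_exposure, seed)
            if reason is None and not (rep and rep.excluded):
                gm_med[(exp.trait_name, med.trait_name)] = next(
                    r for r in results if r.method in ("IVW", "WaldRatio"))
        for out in cfg.outcomes:
            seed = int((cfg.seed * 99_991 + pair_idx) % 2**31)
            pair_idx += 1
            results, rep, reason = analyze_pair(
                med, out, cfg, cfg.p_outcome_as_exposure, seed)
            if reason is None and not (rep and rep.excluded):
                med_out[(med.trait_name, out.trait_name)] = next(
                    r for r in results if r.method in ("IVW", "WaldRatio"))

    triples = screen_mediators(gm_med, med_out, gm_outcome)
    rows = []
    for exp_name, med_name, out_name in triples:
        r1 = gm_med[(exp_name, med_name)]
        r2 = med_out[(med_name, out_name)]
        r3 = gm_outcome[(exp_name, out_name)]
        if r3.beta == 0:
            logger.warning("zero total effect for %s→%s; triple skipped",
                           exp_name, out_name)
            continue
        res = mediate(exp_name, med_name, out_name,
                      r1.beta, r1.se, r2.beta, r2.se, r3.beta, r3.se,
                      seed=cfg.seed)
        rows.append({
            "exposure": res.exposure, "mediator": res.mediator,
            "outcome": res.outcome,
            "beta1": res.beta1, "beta2": res.beta2, "beta3": res.beta3,
            "indirect": res.indirect, "proportion": res.proportion,
            "prop_ci_low": res.ci_low, "prop_ci_high": res.ci_high,
            "pval": res.pval, "inconsistent": res.inconsistent,
        })
    cols = ["exposure", "mediator", "outcome", "beta1", "beta2", "beta3",
            "indirect", "proportion", "prop_ci_low", "prop_ci_high",
            "pval", "inconsistent"]
    return pd.DataFrame(rows, columns=cols)


def run_ldsc_stage(cfg: StudyConfig):
    """Bivariate LDSC for every exposure×outcome pair sharing ≥200 SNPs."""
    if cfg.ldscores is None:
        return pd.DataFrame(columns=["trait1", "trait2", "h2_1", "h2_2",
                                     "rg", "rg_se", "rg_p", "n_snp"])
    rows = []
    score_df = cfg.ldscores.df.set_index("snp_id")
    for exp in cfg.exposures:
        for out in cfg.outcomes:
            e = exp.df.set_index("snp_id")
            o = out.df.set_index("snp_id")
            shared = e.index.intersection(o.index).intersection(score_df.index)
            if len(shared) < 200:
                continue
            sub = cfg.ldscores.df[cfg.ldscores.df["snp_id"].isin(shared)]
            order = sub["snp_id"]
            z1 = (e.loc[order, "beta"] / e.loc[order, "se"]).to_numpy()
            z2 = (o.loc[order, "beta"] / o.loc[order, "se"]).to_numpy()
            n1 = float(np.nanmedian(e.loc[order, "n"]))
            n2 = float(np.nanmedian(o.loc[order, "n"]))
            try:
                res = ldsc_rg(z1, z2, n1, n2,
                              LDScoreTable(sub.reset_index(drop=True),
                                           cfg.ldscores.m_ref),
                              trait1=exp.trait_name, trait2=out.trait_name)
            except ValueError as exc:
                logger.warning("LDSC skipped for %s/%s: %s",
                               exp.trait_name, out.trait_name, exc)
                continue
            rows.append({"trait1": res.trait1, "trait2": res.trait2,
                         "h2_1": res.h2_1, "h2_2": res.h2_2, "rg": res.rg,
                         "rg_se": res.rg_se, "rg_p": res.rg_p, "n_snp": res.n_snp})
    return pd.DataFrame(rows, columns=["trait1", "trait2", "h2_1", "h2_2",
                                       "rg", "rg_se", "rg_p", "n_snp"])


def _format_float(x):
    if isinstance(x, float):
        if np.isnan(x):
            return "NA"
        return f"{x:.4g}"
    return x


def write_report(df: pd.DataFrame, path, sidecar: bool = True) -> None:
    """Deterministic TSV (4 significant digits) plus a full-precision JSON sidecar."""
    path = Path(path)
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_format_float)
    out.to_csv(path, sep="\t", index=False)
    if sidecar:
        records = json.loads(df.to_json(orient="records"))
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(records, fh, indent=1, sort_keys=True)


def reports_to_frame(reports: list[SensitivityReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        d = rep.__dict__.copy()
        d["presso_outliers"] = ";".join(d["presso_outliers"] or [])
        rows.append(d)
    return pd.DataFrame(rows, columns=SENSITIVITY_COLUMNS)


def run_all(cfg: StudyConfig, outdir=None) -> dict:
    """Forward + reverse MR, mediation and LDSC; write every report table.

    Returns the paths written.  Running twice with the same config is
    byte-identical.
    """
    outdir = Path(outdir if outdir is not None else cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    fwd, fwd_excl, fwd_reports = run_forward(cfg)
    rev, rev_excl, rev_reports = run_reverse(cfg)
    med = run_mediation_stage(cfg, fwd)
    ldsc_df = run_ldsc_stage(cfg)

    paths = {}
    for name, frame in [
        ("forward_mr", fwd), ("forward_exclusions", fwd_excl),
        ("forward_sensitivity", reports_to_frame(fwd_reports)),
        ("reverse_mr", rev), ("reverse_exclusions", rev_excl),
        ("reverse_sensitivity", reports_to_frame(rev_reports)),
        ("mediation", med), ("ldsc", ldsc_df),
    ]:
        p = outdir / f"{name}.tsv"
        write_report(frame, p)
        paths[name] = p
    logger.info("wrote %d report tables to %s", len(paths), outdir)
    return paths
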
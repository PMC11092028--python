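"""GWAS summary-statistic tables and exposure/outcome harmonization.

The unit of analysis throughout the package is a per-SNP association
record: identifier, genomic position, effect/other allele, effect-allele
frequency, effect size ``beta`` (log-odds for binary traits, trait-SD
units for continuous traits), its standard error, p-value and sample
size.  Two such tables — one for the exposure, one for the outcome —
are merged on SNP id and aligned to a common effect allele before any
Mendelian-randomization estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of a summary-statistics table
SUMSTATS_COLUMNS = [
    "snp_id", "chrom", "pos_bp", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

MANDATORY_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pval"]


@dataclass
class SumStatsTable:
    """Summary statistics for one trait, unique by ``snp_id``."""

    trait_name: str
    trait_type: str  # "binary" | "continuous"
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.trait_name:
            raise ValueError("trait_name must be non-empty")
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.df["snp_id"].duplicated().any():
            dup = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r} in table for {self.trait_name}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_snps(self) -> int:
        return len(self.df)


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a shared effect allele.

    ``df`` holds every SNP present in both inputs, with per-SNP flags
    ``flipped`` (outcome beta negated to match the exposure's effect
    allele) and ``palindromic_dropped`` (strand-ambiguous SNP excluded).
    MR estimation consumes :attr:`retained`.
    """

    exposure_name: str
    outcome_name: str
    df: pd.DataFrame
    exposure_type: str = "continuous"
    outcome_type: str = "binary"

    @property
    def retained(self) -> pd.DataFrame:
        return self.df[~self.df["palindromic_dropped"]].reset_index(drop=True)

    @property
    def n_snp(self) -> int:
        return int((~self.df["palindromic_dropped"]).sum())

    def subset(self, snp_ids) -> "HarmonizedSet":
        """Restrict to the given SNP ids (e.g. post instrument selection)."""
        keep = self.df["snp_id"].isin(set(snp_ids))
        return HarmonizedSet(
            self.exposure_name, self.outcome_name,
            self.df[keep].reset_index(drop=True),
            self.exposure_type, self.outcome_type,
        )

    def arrays(self):
        """(beta_exp, se_exp, beta_out, se_out) for the retained SNPs."""
        r = self.retained
        return (
            r["beta_exp"].to_numpy(float),
            r["se_exp"].to_numpy(float),
            r["beta_out"].to_numpy(float),
            r["se_out"].to_numpy(float),
        )


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating the per-record invariants; return (clean, n_dropped)."""
    n0 = len(df)
    alleles_ok = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    numeric_ok = (
        df["beta"].notna()
        & df["se"].notna() & (df["se"] > 0)
        & df["pval"].notna() & (df["pval"] > 0) & (df["pval"] <= 1)
    )
    eaf_ok = df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))
    n_ok = df["n"].isna() | (df["n"] > 0)
    clean = df[alleles_ok & numeric_ok & eaf_ok & n_ok].reset_index(drop=True)
    return clean, n0 - len(clean)


def read_sumstats(
    path,
    trait_name: str,
    trait_type: str = "continuous",
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> SumStatsTable:
    """Read a delimited summary-statistics file.

    ``column_map`` maps canonical field names (``snp_id``, ``beta``, ...)
    to the column names in the file; identity by default.  Rows failing
    validation (non-positive SE, p outside (0,1], bad alleles) are
    dropped with a logged count; a missing mandatory column is an error.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in ("chrom", "pos_bp", "eaf", "n"):
        if col not in df.columns:
            df[col] = np.nan

    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("pos_bp", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    df = df[SUMSTATS_COLUMNS]
    clean, n_dropped = _validate_rows(df)
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s) on read", trait_name, n_dropped)
    return SumStatsTable(trait_name=trait_name, trait_type=trait_type, df=clean)


def write_sumstats(table: SumStatsTable, path, sep: str = "\t") -> None:
    table.df.to_csv(path, sep=sep, index=False)


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T or C/G variants cannot be strand-resolved from alleles alone."""
    return (a1, a2) in PALINDROMIC_PAIRS


def harmonize(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per SNP.

    Rules, applied to the snp_id intersection:

    * same allele orientation → kept as is;
    * swapped alleles (outcome effect allele equals the exposure's other
      allele) → outcome beta negated, eaf complemented, ``flipped=True``;
    * strand-complement orientations are normalized first (non-palindromic
      SNPs only);
    * palindromic SNPs with missing eaf, or with eaf within
      ``palindrome_eaf_window`` of 0.5 in either table, are excluded
      (``palindromic_dropped=True``); otherwise they are oriented by
      frequency (flip when the two eafs fall on opposite sides of 0.5);
    * incompatible allele pairs are excluded.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValueError("cannot harmonize an empty table")
    exp = exposure.df.set_index("snp_id")
    out = outcome.df.set_index("snp_id")
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise ValueError("no overlapping instruments between "
                         f"{exposure.trait_name} and {outcome.trait_name}")

    rows = []
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        beta_o, eaf_o = o["beta"], o["eaf"]
        flipped = False
        dropped = False

        pal = is_palindromic(ea_e, oa_e)
        if pal:
            eaf_e = e["eaf"]
            near_half = (
                pd.isna(eaf_e) or pd.isna(eaf_o)
                or abs(eaf_e - 0.5) <= palindrome_eaf_window
                or abs(eaf_o - 0.5) <= palindrome_eaf_window
            )
            if {ea_o, oa_o} != {ea_e, oa_e}:
                dropped = True  # incompatible palindromic coding
            elif near_half:
                dropped = True
            else:
                # orient by allele labels first, then check frequency
                if ea_o == oa_e:  # swapped labels
                    beta_o, eaf_o, flipped = -beta_o, 1 - eaf_o, True
                if (eaf_e - 0.5) * (eaf_o - 0.5) < 0:
                    # frequencies disagree: the outcome is on the other strand
                    beta_o, eaf_o = -beta_o, 1 - eaf_o
                    flipped = not flipped
        else:
            # normalize a strand-complement coding of the outcome alleles
            if {ea_o, oa_o} != {ea_e, oa_e}:
                ea_c, oa_c = _COMPLEMENT.get(ea_o, "?"), _COMPLEMENT.get(oa_o, "?")
                if {ea_c, oa_c} == {ea_e, oa_e}:
                    ea_o, oa_o = ea_c, oa_c
                else:
                    dropped = True
            if not dropped:
                if ea_o == ea_e and oa_o == oa_e:
                    pass
                elif ea_o == oa_e and oa_o == ea_e:
                    beta_o = -beta_o
                    if not pd.isna(eaf_o):
                        eaf_o = 1 - eaf_o
                    flipped = True
                else:
                    dropped = True

        rows.append({
            "snp_id": snp,
            "chrom": e["chrom"], "pos_bp": e["pos_bp"],
            "effect_allele": ea_e, "other_allele": oa_e,
            "eaf": e["eaf"],
            "beta_exp": e["beta"], "se_exp": e["se"], "p_exp": e["pval"],
            "beta_out": beta_o, "se_out": o["se"], "p_out": o["pval"],
            "n_exp": e["n"], "n_out": o["n"],
            "flipped": flipped, "palindromic_dropped": dropped,
        })

    hdf = pd.DataFrame(rows)
    if hdf["palindromic_dropped"].all():
        raise ValueError("no overlapping instruments after allele harmonization")
    return HarmonizedSet(
        exposure.trait_name, outcome.trait_name, hdf,
        exposure_type=exposure.trait_type, outcome_type=outcome.trait_type,
    )


def write_harmonized(h: HarmonizedSet, path, sep: str = "\t") -> None:
    h.df.to_csv(path, sep=sep, index=False)


def beta_to_or(beta: float, se: float, alpha: float = 0.05):
    """Odds ratio and Wald confidence interval from a log-odds effect.

    Returns ``(or, ci_low, ci_high)`` with the interval
    ``exp(beta ± z_{1-alpha/2}·se)``.
    """
    if se < 0:
        raise ValueError("se must be non-negative")
    z = stats.norm.ppf(1 - alpha / 2)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))
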
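"""Instrument selection: p-value threshold, LD clumping, F-statistic screen.

A SNP qualifies as an instrument for an exposure when it passes the
association threshold, survives greedy LD clumping against a reference
(r² < ``r2_max`` within ``window_kb``), and has an F statistic of at
least ``f_min``.  An exposure with fewer than ``min_snps`` surviving
instruments is excluded from MR altogether.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .sumstats import SumStatsTable

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Pairwise r² between SNPs, with genomic coordinates for windowing.

    Stored sparsely; absent pairs have r² = 0 and the diagonal is 1 by
    construction.
    """

    snp_ids: list
    chrom: np.ndarray
    pos_bp: np.ndarray
    r2: sparse.csr_matrix  # symmetric, includes unit diagonal
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if self.r2.shape != (len(self.snp_ids),) * 2:
            raise ValueError("r2 matrix shape does not match snp list")

    def __contains__(self, snp_id) -> bool:
        return snp_id in self._index

    def get_r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return float(self.r2[self._index[a], self._index[b]])

    def ld_scores(self) -> np.ndarray:
        """Per-SNP LD score ℓ = Σⱼ r²ᵢⱼ (includes the unit self term)."""
        return np.asarray(self.r2.sum(axis=1)).ravel()

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame, snp_map: pd.DataFrame) -> "LDMatrix":
        """Build from a (snp_a, snp_b, r2) table plus (snp_id, chrom, pos_bp)."""
        ids = snp_map["snp_id"].astype(str).tolist()
        idx = {s: i for i, s in enumerate(ids)}
        m = len(ids)
        rows, cols, vals = [], [], []
        for a, b, v in pairs[["snp_a", "snp_b", "r2"]].itertuples(index=False):
            a, b = str(a), str(b)
            if a not in idx or b not in idx:
                raise ValueError(f"LD pair references unknown SNP {a!r}/{b!r}")
            if not 0 <= v <= 1:
                raise ValueError(f"r2 out of [0,1]: {v}")
            if a == b:
                continue
            rows += [idx[a], idx[b]]
            cols += [idx[b], idx[a]]
            vals += [v, v]
        r2 = sparse.coo_matrix((vals, (rows, cols)), shape=(m, m)).tocsr()
        r2 = r2 + sparse.identity(m, format="csr")
        r2.data = np.minimum(r2.data, 1.0)  # duplicate pairs collapse at the cap
        return cls(ids, snp_map["chrom"].astype(str).to_numpy(),
                   snp_map["pos_bp"].to_numpy(float), r2)

    def to_pairs(self) -> pd.DataFrame:
        coo = sparse.triu(self.r2, k=1).tocoo()
        return pd.DataFrame({
            "snp_a": [self.snp_ids[i] for i in coo.row],
            "snp_b": [self.snp_ids[j] for j in coo.col],
            "r2": coo.data,
        })


@dataclass
class InstrumentSet:
    """Surviving instruments for one exposure, with per-SNP F statistics."""

    exposure_name: str
    df: pd.DataFrame  # sumstats columns + f_stat, clump_index, f_pass
    valid: bool = True
    invalid_reason: str | None = None

    @property
    def snp_ids(self) -> list:
        return self.df["snp_id"].tolist()

    def __len__(self) -> int:
        return len(self.df)


def select_by_pvalue(table: SumStatsTable, threshold: float) -> SumStatsTable:
    """Retain SNPs with p strictly below ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    kept = table.df[table.df["pval"] < threshold].reset_index(drop=True)
    return SumStatsTable(table.trait_name, table.trait_type, kept)


def ld_clump(
    table: SumStatsTable,
    ld: LDMatrix,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> SumStatsTable:
    """Greedy LD clumping: keep index SNPs in ascending p-value order.

    The most significant remaining SNP becomes an index; every other
    remaining SNP on the same chromosome within ``window_kb`` of it with
    r² ≥ ``r2_max`` is removed.  Ties on p are broken by (chrom, pos,
    snp_id) for determinism.  SNPs absent from the LD reference are
    dropped beforehand with a warning.
    """
    df = table.df
    present = df["snp_id"].isin(ld._index)
    if not present.all():
        logger.warning("%s: %d SNP(s) absent from LD reference dropped before clumping",
                       table.trait_name, int((~present).sum()))
        df = df[present]
    if df.empty:
        return SumStatsTable(table.trait_name, table.trait_type, df.reset_index(drop=True))

    order = df.sort_values(
        ["pval", "chrom", "pos_bp", "snp_id"], kind="mergesort"
    ).index.tolist()
    window_bp = window_kb * 1000.0

    removed: set = set()
    kept_rows = []
    for i in order:
        snp = df.at[i, "snp_id"]
        if snp in removed:
            continue
        kept_rows.append(i)
        li = ld._index[snp]
        chrom_i, pos_i = str(df.at[i, "chrom"]), float(df.at[i, "pos_bp"])
        row = ld.r2.getrow(li)
        strong = {ld.snp_ids[j] for j, v in zip(row.indices, row.data) if v >= r2_max}
        for j in order:
            if j == i:
                continue
            snp_j = df.at[j, "snp_id"]
            if snp_j in removed:
                continue
            if str(df.at[j, "chrom"]) != chrom_i:
                continue
            if abs(float(df.at[j, "pos_bp"]) - pos_i) >= window_bp:
                continue
            if snp_j in strong:
                removed.add(snp_j)

    kept = df.loc[sorted(kept_rows)].reset_index(drop=True)
    return SumStatsTable(table.trait_name, table.trait_type, kept)


def snp_r2(beta: float, se: float | None = None, n: float | None = None,
           eaf: float | None = None, trait_type: str = "continuous") -> float:
    """Variance in the trait explained by one SNP.

    Continuous trait with known allele frequency: the standardized-trait
    approximation r² = 2·eaf·(1−eaf)·β² (β in trait-SD units), capped at
    1.  Otherwise r² = z²/(z² + n − 2) from the association z-score,
    which also serves binary traits on the log-odds scale.
    """
    if trait_type == "continuous" and eaf is not None and not np.isnan(eaf):
        return float(min(2 * eaf * (1 - eaf) * beta**2, 1.0))
    if se is not None and n is not None and not (np.isnan(se) or np.isnan(n)):
        z = beta / se
        return float(z**2 / (z**2 + n - 2))
    raise ValueError("insufficient fields for R²: need (beta, eaf) for a "
                     "continuous trait or (beta, se, n)")


def f_statistic(r2: float, k: int, n: float) -> float:
    """Instrument-strength F from explained variance: (R²/K)·(N−K−1)/(1−R²)."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must be in [0, 1)")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    return (r2 / k) * (n - k - 1) / (1 - r2)


def f_statistic_alt(beta: float, se: float) -> float:
    """Fallback F = (β/SE)² when the source lacks a sample size."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def _per_snp_f(row: pd.Series, trait_type: str) -> float:
    """Per-SNP F: primary formula with K=1 when N is known, else β²/SE².

    With K=1 and the z-score R², the primary formula reduces exactly to
    z² = β²/SE², so the two conventions agree whenever both apply.
    """
    n = row.get("n")
    if n is not None and not pd.isna(n) and n > 2:
        r2 = snp_r2(row["beta"], row["se"], n, row.get("eaf"), trait_type)
        if r2 < 1:
            return f_statistic(r2, 1, n)
    return f_statistic_alt(row["beta"], row["se"])


def filter_weak(table: SumStatsTable, f_min: float = 10.0) -> InstrumentSet:
    """Remove SNPs with F < ``f_min``; annotate the survivors."""
    df = table.df.copy()
    if df.empty:
        df["f_stat"] = pd.Series(dtype=float)
        df["f_pass"] = pd.Series(dtype=bool)
        return InstrumentSet(table.trait_name, df)
    df["f_stat"] = df.apply(_per_snp_f, axis=1, trait_type=table.trait_type)
    df["f_pass"] = df["f_stat"] >= f_min
    n_removed = int((~df["f_pass"]).sum())
    if n_removed:
        logger.info("%s: removed %d weak instrument(s) with F < %g",
                    table.trait_name, n_removed, f_min)
    kept = df[df["f_pass"]].reset_index(drop=True)
    return InstrumentSet(table.trait_name, kept)


def require_min_snps(inst: InstrumentSet, min_snps: int = 3) -> InstrumentSet:
    """Mark the set invalid when it has fewer than ``min_snps`` instruments."""
    if len(inst) < min_snps:
        inst.valid = False
        inst.invalid_reason = "fewer than three SNPs" if min_snps == 3 else (
            f"fewer than {min_snps} SNPs")
    return inst


def select_instruments(
    table: SumStatsTable,
    ld: LDMatrix,
    p_threshold: float = 1e-5,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
    f_min: float = 10.0,
    min_snps: int = 3,
) -> InstrumentSet:
    """Full selection pipeline: p-filter → LD clump → F screen → min-SNP rule."""
    t = select_by_pvalue(table, p_threshold)
    t = ld_clump(t, ld, r2_max=r2_max, window_kb=window_kb)
    inst = filter_weak(t, f_min=f_min)
    return require_min_snps(inst, min_snps=min_snps)


def read_ld_reference(pairs_path, snp_map_path, sep: str = "\t") -> LDMatrix:
    """Read an LD reference from a 3-column pair TSV plus a SNP-map TSV."""
    pairs = pd.read_csv(pairs_path, sep=sep)
    snp_map = pd.read_csv(snp_map_path, sep=sep)
    return LDMatrix.from_pairs(pairs, snp_map)


def write_ld_reference(ld: LDMatrix, pairs_path, snp_map_path, sep: str = "\t") -> None:
    ld.to_pairs().to_csv(pairs_path, sep=sep, index=False)
    pd.DataFrame({"snp_id": ld.snp_ids, "chrom": ld.chrom, "pos_bp": ld.pos_bp}
                 ).to_csv(snp_map_path, sep=sep, index=False)
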
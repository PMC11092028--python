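import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrkit.instruments import (
    LDMatrix, select_by_pvalue, ld_clump, snp_r2, f_statistic,
    f_statistic_alt, filter_weak, require_min_snps, select_instruments,
    read_ld_reference, write_ld_reference,
)
from mrkit.synth import SimConfig, simulate_ld
from conftest import make_table


def _ld_from_pairs(snps, pairs):
    """snps: [(id, chrom, pos)], pairs: [(a, b, r2)]."""
    snp_map = pd.DataFrame(snps, columns=["snp_id", "chrom", "pos_bp"])
    pair_df = pd.DataFrame(pairs, columns=["snp_a", "snp_b", "r2"])
    return LDMatrix.from_pairs(pair_df, snp_map)


class TestPvalueFilter:
    def test_strict_threshold(self):
        t = make_table([
            {"snp_id": "rs1", "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01, "pval": 1e-6},
            {"snp_id": "rs2", "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01, "pval": 2e-5},
            {"snp_id": "rs3", "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01, "pval": 1e-5},  # exactly at threshold
        ])
        kept = select_by_pvalue(t, 1e-5)
        assert set(kept.df["snp_id"]) == {"rs1"}

    def test_threshold_one_retains_all(self):
        t = make_table([{"snp_id": f"rs{i}", "effect_allele": "A",
                         "other_allele": "G", "beta": 0.1, "se": 0.01,
                         "pval": p} for i, p in enumerate([0.99, 0.5, 1e-8])])
        assert len(select_by_pvalue(t, 1.0)) == 3


def _clump_table(specs):
    """specs: [(id, chrom, pos, pval)]"""
    return make_table([
        {"snp_id": s, "chrom": c, "pos_bp": float(p), "effect_allele": "A",
         "other_allele": "G", "beta": 0.1, "se": 0.01, "pval": pv}
        for s, c, p, pv in specs])


class TestLDClump:
    def test_correlated_pair_keeps_most_significant(self):
        t = _clump_table([("rs1", "1", 100_000, 1e-8), ("rs2", "1", 150_000, 1e-6)])
        ld = _ld_from_pairs([("rs1", "1", 100_000), ("rs2", "1", 150_000)],
                            [("rs1", "rs2", 0.9)])
        kept = ld_clump(t, ld)
        assert set(kept.df["snp_id"]) == {"rs1"}

    def test_low_r2_pair_kept(self):
        t = _clump_table([("rs1", "1", 100_000, 1e-8), ("rs2", "1", 150_000, 1e-6)])
        ld = _ld_from_pairs([("rs1", "1", 100_000), ("rs2", "1", 150_000)],
                            [("rs1", "rs2", 0.0005)])
        assert len(ld_clump(t, ld)) == 2

    def test_outside_window_kept(self):
        # 15,000 kb apart: high r2 is irrelevant beyond the 10,000 kb window
        t = _clump_table([("rs1", "1", 1, 1e-8), ("rs2", "1", 15_000_001, 1e-6)])
        ld = _ld_from_pairs([("rs1", "1", 1), ("rs2", "1", 15_000_001)],
                            [("rs1", "rs2", 0.9)])
        assert len(ld_clump(t, ld)) == 2

    def test_missing_snp_dropped_with_warning(self, caplog):
        t = _clump_table([("rs1", "1", 1, 1e-8), ("rsX", "1", 2, 1e-6)])
        ld = _ld_from_pairs([("rs1", "1", 1)], [])
        with caplog.at_level("WARNING"):
            kept = ld_clump(t, ld)
        assert set(kept.df["snp_id"]) == {"rs1"}
        assert "absent from LD reference" in caplog.text

    @staticmethod
    def _greedy_oracle(table_df, r2, window_bp, r2_max):
        """Literal greedy-by-p reimplementation on dense arrays."""
        order = table_df.sort_values(["pval", "chrom", "pos_bp", "snp_id"],
                                     kind="mergesort").index.tolist()
        alive = set(order)
        kept = []
        for i in order:
            if i not in alive:
                continue
            kept.append(i)
            for j in list(alive):
                if j == i:
                    continue
                same_chrom = table_df.at[j, "chrom"] == table_df.at[i, "chrom"]
                close = abs(table_df.at[j, "pos_bp"] - table_df.at[i, "pos_bp"]) < window_bp
                if same_chrom and close and r2[i, j] >= r2_max:
                    alive.discard(j)
        return {table_df.at[i, "snp_id"] for i in kept}

    def test_matches_oracle_and_is_independent_set(self, rng):
        for trial in range(20):
            m = int(rng.integers(5, 30))
            pos = np.sort(rng.integers(1, 30_000_000, m))
            chrom = rng.choice(["1", "2"], m)
            pvals = rng.uniform(1e-10, 1e-3, m)
            r2 = np.zeros((m, m))
            for i in range(m):
                for j in range(i + 1, m):
                    if rng.random() < 0.3:
                        r2[i, j] = r2[j, i] = rng.random()
            np.fill_diagonal(r2, 1.0)
            snps = [(f"rs{i}", chrom[i], int(pos[i])) for i in range(m)]
            pairs = [(f"rs{i}", f"rs{j}", r2[i, j])
                     for i in range(m) for j in range(i + 1, m) if r2[i, j] > 0]
            ld = _ld_from_pairs(snps, pairs)
            t = _clump_table([(f"rs{i}", chrom[i], int(pos[i]), pvals[i])
                              for i in range(m)])
            kept = ld_clump(t, ld, r2_max=0.1, window_kb=5000)
            expected = self._greedy_oracle(t.df, r2, 5_000_000, 0.1)
            assert set(kept.df["snp_id"]) == expected
            # no retained pair violates the clump rule (brute force)
            kd = kept.df.set_index("snp_id")
            for a in kd.index:
                for b in kd.index:
                    if a >= b or kd.at[a, "chrom"] != kd.at[b, "chrom"]:
                        continue
                    if abs(kd.at[a, "pos_bp"] - kd.at[b, "pos_bp"]) < 5_000_000:
                        assert ld.get_r2(a, b) < 0.1


class TestSnpR2:
    def test_zero_beta(self):
        assert snp_r2(0.0, 0.01, 1000) == 0.0

    def test_z_form_hand_value(self):
        # z = 10, n = 10,000 → 100/(100 + 9998)
        assert snp_r2(0.1, 0.01, 10_000) == pytest.approx(100 / 10_098)

    def test_eaf_form_hand_value(self):
        assert snp_r2(0.1, eaf=0.5, trait_type="continuous") == pytest.approx(0.005)

    def test_binary_uses_z_form_even_with_eaf(self):
        v = snp_r2(0.1, 0.01, 10_000, eaf=0.5, trait_type="binary")
        assert v == pytest.approx(100 / 10_098)

    def test_insufficient_fields(self):
        with pytest.raises(ValueError, match="insufficient"):
            snp_r2(0.1, trait_type="binary")


class TestFStatistic:
    def test_printed_formula_hand_values(self):
        assert f_statistic(0.02, 5, 18_340) == pytest.approx(
            (0.02 / 5) * (18_340 - 5 - 1) / 0.98)
        assert f_statistic(0.0, 3, 100) == 0.0
        assert f_statistic(0.5, 1, 3) == pytest.approx(1.0)

    def test_sample_size_precondition(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 5, 6)

    def test_alternative_formula(self):
        assert f_statistic_alt(0.05, 0.01) == pytest.approx(25.0)
        assert f_statistic_alt(0.0, 0.01) == 0.0
        assert f_statistic_alt(-0.05, 0.01) == pytest.approx(25.0)

    @given(st.floats(0.001, 0.5), st.integers(1, 10),
           st.integers(100, 100_000))
    @settings(max_examples=50, derandomize=True)
    def test_monotonicity(self, r2, k, n):
        f = f_statistic(r2, k, n)
        assert f_statistic(min(r2 * 1.1, 0.99), k, n) > f      # increasing in r2
        assert f_statistic(r2, k, n + 1000) > f                # increasing in n
        if n > k + 2:
            assert f_statistic(r2, k + 1, n) < f               # decreasing in k


class TestWeakFilter:
    def _table_with_f(self, fvals):
        # no sample size → F = (beta/se)² exactly
        return make_table([
            {"snp_id": f"rs{i}", "effect_allele": "A", "other_allele": "G",
             "beta": np.sqrt(f) * 0.01, "se": 0.01, "pval": 1e-6}
            for i, f in enumerate(fvals)])

    def test_strict_boundary(self):
        inst = filter_weak(self._table_with_f([9.99, 10.0, 25.0]))
        assert len(inst) == 2
        assert np.all(inst.df["f_stat"] >= 10)

    def test_all_strong_identity(self):
        inst = filter_weak(self._table_with_f([11, 12, 13]))
        assert len(inst) == 3

    def test_all_weak_empty(self):
        inst = filter_weak(self._table_with_f([1, 2, 3]))
        assert len(inst) == 0
        assert not require_min_snps(inst).valid

    def test_primary_formula_agrees_with_alt_when_n_known(self):
        # per-SNP F via R² = z²/(z²+n−2) and K=1 equals β²/SE²
        t = make_table([{"snp_id": "rs1", "effect_allele": "A",
                         "other_allele": "G", "beta": 0.05, "se": 0.01,
                         "pval": 1e-6, "n": 50_000}], trait_type="binary")
        inst = filter_weak(t)
        assert inst.df.loc[0, "f_stat"] == pytest.approx(25.0)


class TestMinSnps:
    @pytest.mark.parametrize("n,valid", [(2, False), (3, True), (0, False)])
    def test_boundary(self, n, valid):
        t = make_table([
            {"snp_id": f"rs{i}", "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01, "pval": 1e-6} for i in range(n)] or
            [{"snp_id": "rs0", "effect_allele": "A", "other_allele": "G",
              "beta": 0.1, "se": 0.01, "pval": 1e-6}])
        inst = filter_weak(t)
        if n == 0:
            inst.df = inst.df.iloc[:0]
        assert require_min_snps(inst).valid is valid
        if not valid:
            assert "fewer than three SNPs" in inst.invalid_reason


def test_full_selection_pipeline_order():
    """p-filter, clumping, F screen and the min-SNP rule compose."""
    cfg = SimConfig(seed=5, m_snps=100, n_blocks=25, n_causal=20,
                    n_causal_med=0, n_exp=50_000, n_out=50_000)
    from mrkit.synth import simulate_pair
    exp, _, _ = simulate_pair(cfg)
    ld, _ = simulate_ld(cfg)
    inst = select_instruments(exp, ld)
    assert inst.valid
    assert np.all(inst.df["f_stat"] >= 10)
    assert np.all(inst.df["pval"] < 1e-5)
    # clump independence within each chromosome window
    d = inst.df.set_index("snp_id")
    for a in d.index:
        for b in d.index:
            if a < b and d.at[a, "chrom"] == d.at[b, "chrom"] and \
                    abs(d.at[a, "pos_bp"] - d.at[b, "pos_bp"]) < 1e7:
                assert ld.get_r2(a, b) < 0.001


def test_ld_reference_roundtrip(tmp_path):
    cfg = SimConfig(seed=7, m_snps=30, n_blocks=10, n_causal=5, n_causal_med=0)
    ld, _ = simulate_ld(cfg)
    write_ld_reference(ld, tmp_path / "pairs.tsv", tmp_path / "snps.tsv")
    ld2 = read_ld_reference(tmp_path / "pairs.tsv", tmp_path / "snps.tsv")
    assert ld2.snp_ids == ld.snp_ids
    assert np.allclose(ld2.r2.toarray(), ld.r2.toarray())
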
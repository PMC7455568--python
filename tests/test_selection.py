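"""Filtering, contrasts, DIF scoring, selection rule, overlap significance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from difsel import (
    common_genes,
    dif_scores,
    export_dif_attributes,
    filter_expressed,
    genewise_scale,
    log2_contrast,
    overlap_pvalue,
    select_week,
)
from difsel.errors import ComputationError
from difsel.selection import ContrastTable, DifTable

from conftest import make_matrix
from oracles import brute_force_select, hypergeom_upper_tail_exact


def contrasts_from(l_wt: dict, l_ko: dict, weeks=(2, 4)) -> ContrastTable:
    """Build a ContrastTable directly from per-gene L values (same both weeks
    unless per-week dicts are given)."""
    def frame(d):
        if isinstance(next(iter(d.values())), dict):
            return pd.DataFrame(d).T[list(weeks)]
        return pd.DataFrame({w: pd.Series(d) for w in weeks})
    return ContrastTable(l_wt=frame(l_wt), l_ko=frame(l_ko), pseudocount=1.0)


class TestFilterExpressed:
    def test_strict_threshold_semantics(self):
        matrix = make_matrix({
            "AllLow": [0.5, 0.9, 0.3, 0.8, 0.1, 0.6, 0.4, 0.2],
            "OneHigh": [0, 0, 0, 0, 0, 0, 0, 1.5],
            "ExactlyOne": [1.0] * 8,
        })
        kept = filter_expressed(matrix).gene_ids
        assert kept == ["OneHigh"]

    def test_empty_universe_is_an_error(self):
        matrix = make_matrix({"G": [0.1] * 8})
        with pytest.raises(ComputationError, match="no expressed genes"):
            filter_expressed(matrix)


class TestLog2Contrast:
    def test_exact_and_pseudocount_arithmetic(self):
        # WT: sham 2, DMM 8 both weeks; KO flat at 2
        matrix = make_matrix({"G": [2, 8, 2, 8, 2, 2, 2, 2]})
        eps0 = log2_contrast(matrix, pseudocount=0)
        assert eps0.l_wt.loc["G", 2] == pytest.approx(2.0)
        assert eps0.l_ko.loc["G", 4] == 0.0
        eps1 = log2_contrast(matrix, pseudocount=1)
        assert eps1.l_wt.loc["G", 2] == pytest.approx(np.log2(3), abs=1e-12)

    def test_zero_tpm_with_zero_pseudocount_names_gene_and_cell(self):
        matrix = make_matrix({"G": [0, 8, 2, 8, 2, 1, 2, 1]})
        with pytest.raises(ComputationError, match=r"G.*WT.*sham.*2"):
            log2_contrast(matrix, pseudocount=0)

    def test_replicated_cells_are_mean_aggregated(self):
        matrix = make_matrix({"G": [2, 8, 2, 8, 2, 2, 2, 2]})
        dup = matrix.values[["WT_sham_w2"]].rename(columns={"WT_sham_w2": "WT_sham_w2b"})
        dup["WT_sham_w2b"] = 6.0  # cell mean becomes (2+6)/2 = 4
        rep = make_matrix({"G": [2, 8, 2, 8, 2, 2, 2, 2]})
        rep.values = pd.concat([rep.values, dup], axis=1)
        rep.meta = pd.concat([
            rep.meta,
            pd.DataFrame({"genotype": ["WT"], "condition": ["sham"], "week": [2]},
                         index=["WT_sham_w2b"]),
        ])
        out = log2_contrast(rep, pseudocount=0)
        assert out.l_wt.loc["G", 2] == pytest.approx(1.0)  # log2(8/4)


class TestDifScores:
    def test_dif_is_ko_minus_wt(self):
        c = contrasts_from({"A": 2.0, "B": 1.0}, {"A": -1.0, "B": 1.0})
        d = dif_scores(c)
        assert d.dif.loc["A", 2] == -3.0
        assert d.dif.loc["B", 4] == 0.0

    def test_lower_quartile_linear_interpolation(self):
        c = contrasts_from(
            {g: 0.0 for g in "ABCD"},
            {"A": -4.0, "B": -2.0, "C": 0.0, "D": 2.0},
        )
        d = dif_scores(c, quantile_rule="linear")
        assert d.q25[2] == pytest.approx(-2.5)

    def test_pooled_scope_shares_one_threshold(self):
        l_ko = {"A": {2: -4.0, 4: 0.0}, "B": {2: -2.0, 4: 2.0}}
        l_wt = {"A": {2: 0.0, 4: 0.0}, "B": {2: 0.0, 4: 0.0}}
        d = dif_scores(contrasts_from(l_wt, l_ko), quartile_scope="pooled")
        assert d.q25[2] == d.q25[4] == pytest.approx(-2.5)

    def test_quartile_lies_within_dif_range(self, rng):
        vals = rng.normal(size=200)
        c = contrasts_from(
            {f"g{i}": 0.0 for i in range(200)},
            {f"g{i}": float(v) for i, v in enumerate(vals)},
        )
        d = dif_scores(c)
        for w in (2, 4):
            assert vals.min() <= d.q25[w] <= vals.max()

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-8, 8, allow_nan=False), min_size=4, max_size=40),
           st.lists(st.floats(-8, 8, allow_nan=False), min_size=4, max_size=40))
    def test_genotype_swap_negates_dif_exactly(self, a, b):
        n = min(len(a), len(b))
        l_wt = {f"g{i}": a[i] for i in range(n)}
        l_ko = {f"g{i}": b[i] for i in range(n)}
        d = dif_scores(contrasts_from(l_wt, l_ko))
        d_sw = dif_scores(contrasts_from(l_ko, l_wt))
        assert (d_sw.dif == -d.dif).all().all()


class TestSelectWeek:
    def test_rule_boundaries_are_strict(self):
        # atQ sits exactly at the quartile boundary: DIF = -1.0 is not < -1.0
        l_wt = {"sel": 1.2, "zeroWT": 0.0, "posKO": 1.0, "atQ": 0.5}
        l_ko = {"sel": -0.8, "zeroWT": -3.0, "posKO": 0.5, "atQ": -0.5}
        c = contrasts_from(l_wt, l_ko)
        d = dif_scores(c)
        d = DifTable(dif=d.dif, q25={2: -1.0, 4: -1.0})
        assert select_week(c, d, 2) == {"sel"}

    def test_matches_brute_force_on_random_universe(self, rng):
        genes = [f"g{i}" for i in range(50)]
        l_wt = {g: float(v) for g, v in zip(genes, rng.normal(0, 2, 50))}
        l_ko = {g: float(v) for g, v in zip(genes, rng.normal(0, 2, 50))}
        c = contrasts_from(l_wt, l_ko)
        d = dif_scores(c)
        expected = brute_force_select(l_wt, l_ko, d.q25[2])
        assert select_week(c, d, 2) == expected

    def test_quartile_bound_on_selection_size(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 120))
            genes = [f"g{i}" for i in range(n)]
            l_wt = {g: float(v) for g, v in zip(genes, rng.normal(1, 1, n))}
            l_ko = {g: float(v) for g, v in zip(genes, rng.normal(-1, 1, n))}
            c = contrasts_from(l_wt, l_ko)
            d = dif_scores(c)
            assert len(select_week(c, d, 2)) <= int(np.ceil(0.25 * n))

    def test_unknown_week_rejected(self):
        c = contrasts_from({"a": 1.0}, {"a": -1.0})
        with pytest.raises(ValueError, match="week"):
            select_week(c, dif_scores(c), 3)


class TestCommonGenes:
    @pytest.mark.parametrize("s2,s4,expected", [
        ({"A", "B", "C"}, {"B", "C", "D"}, {"B", "C"}),
        ({"A"}, {"B"}, set()),
        ({"A", "B"}, {"A", "B", "C"}, {"A", "B"}),
    ])
    def test_intersection(self, s2, s4, expected):
        assert common_genes(s2, s4) == expected


class TestOverlapPvalue:
    def test_hand_enumerated_instance(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert overlap_pvalue(4, 5, 4, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_degenerate_cases_give_one(self):
        assert overlap_pvalue(0, 5, 4, 10) == pytest.approx(1.0)
        assert overlap_pvalue(3, 3, 3, 3) == pytest.approx(1.0)

    def test_monotone_nonincreasing_in_k(self):
        ps = [overlap_pvalue(k, 40, 30, 100) for k in range(0, 31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_matches_exact_enumeration(self, rng):
        for _ in range(100):
            N = int(rng.integers(2, 26))
            n1 = int(rng.integers(1, N + 1))
            n2 = int(rng.integers(1, N + 1))
            lo = max(0, n1 + n2 - N)
            k = int(rng.integers(lo, min(n1, n2) + 1))
            exact = float(hypergeom_upper_tail_exact(k, N, n1, n2))
            assert overlap_pvalue(k, n1, n2, N) == pytest.approx(exact, rel=1e-10)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            overlap_pvalue(6, 5, 4, 10)


class TestGenewiseScale:
    def test_three_sample_row_hand_value(self):
        matrix = make_matrix({"G": [1, 2, 3, 1, 2, 3, 1, 2]})
        sub = matrix.values[["WT_sham_w2", "WT_DMM_w2", "WT_sham_w4"]]
        mu, sd = sub.loc["G"].mean(), sub.loc["G"].std(ddof=1)
        np.testing.assert_allclose(((sub.loc["G"] - mu) / sd).to_numpy(), [-1, 0, 1])

    def test_scaled_rows_have_zero_mean_unit_sd(self, default_study):
        matrix, _ = default_study
        genes = matrix.gene_ids[:40]
        scaled = genewise_scale(matrix, genes)
        np.testing.assert_allclose(scaled.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(scaled.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_constant_row_warns_and_zeroes(self):
        matrix = make_matrix({"Flat": [2.0] * 8, "Var": range(8)})
        with pytest.warns(UserWarning, match="constant"):
            scaled = genewise_scale(matrix, ["Flat", "Var"])
        assert (scaled.loc["Flat"] == 0).all()

    def test_absent_gene_raises_key_error(self, default_study):
        matrix, _ = default_study
        with pytest.raises(KeyError):
            genewise_scale(matrix, ["NotAGene"])


class TestExportDifAttributes:
    def test_per_week_and_mean_policies(self):
        c = contrasts_from({"A": 1.0, "B": 2.0}, {"A": -1.0, "B": 0.0})
        d = dif_scores(c)
        per_week = export_dif_attributes(d, {"A", "B"}, week_policy="per_week")
        assert list(per_week.columns) == ["gene", "DIF_w2", "DIF_w4"]
        assert len(per_week) == 2
        mean = export_dif_attributes(d, {"A"}, week_policy="mean")
        assert mean.loc[0, "DIF"] == pytest.approx(-2.0)

    def test_empty_gene_set_gives_header_only(self):
        c = contrasts_from({"A": 1.0}, {"A": -1.0})
        table = export_dif_attributes(dif_scores(c), set())
        assert len(table) == 0 and "gene" in table.columns
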
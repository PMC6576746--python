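"""Drug-sensitivity statistics: labels, t-tests, fold change, FDR, ORA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import comb

from remap3d import (
    classify_cell_lines,
    fold_change,
    gene_statistics,
    gene_t_test,
    overrepresentation,
    q_values,
    select_genes,
    simulate_expression,
)


class TestClassification:
    @pytest.mark.parametrize(
        "aa,label",
        [
            (5.0, "sensitive"),
            (1.95, "sensitive"),  # boundary inclusive
            (1.3, "resistant"),  # boundary inclusive
            (1.5, "intermediate"),
            (0.0, "resistant"),
        ],
    )
    def test_thresholds(self, aa, label):
        labels = classify_cell_lines({"cell": aa})
        assert labels["cell"] == label

    def test_nonfinite_area_rejected(self):
        with pytest.raises(ValueError):
            classify_cell_lines({"cell": float("nan")})


def _labels(s_cells, r_cells):
    return classify_cell_lines({**{c: 5.0 for c in s_cells}, **{c: 0.5 for c in r_cells}})


class TestGeneTTest:
    def test_worked_example_pooled_t(self):
        expr = pd.DataFrame(
            [[3.0, 4.0, 5.0, 1.0, 2.0, 3.0]],
            index=["g"],
            columns=["s1", "s2", "s3", "r1", "r2", "r3"],
        )
        res = gene_t_test(expr, _labels(["s1", "s2", "s3"], ["r1", "r2", "r3"]))
        assert res.loc["g", "t"] == pytest.approx(2.449, abs=1e-3)
        assert res.loc["g", "p"] == pytest.approx(0.0705, abs=1e-3)

    def test_identical_groups_give_null_result(self):
        expr = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]], index=["g"], columns=["s1", "s2", "r1", "r2"])
        res = gene_t_test(expr, _labels(["s1", "s2"], ["r1", "r2"]))
        assert res.loc["g", "t"] == 0.0
        assert res.loc["g", "p"] == 1.0

    def test_zero_variance_separation_guard(self):
        expr = pd.DataFrame(
            [[2.0, 2.0, 2.0, 0.0, 0.0, 0.0]],
            index=["g"],
            columns=["s1", "s2", "s3", "r1", "r2", "r3"],
        )
        res = gene_t_test(expr, _labels(["s1", "s2", "s3"], ["r1", "r2", "r3"]))
        assert res.loc["g", "t"] == np.inf
        assert res.loc["g", "p"] == 0.0

    def test_undersized_group_named_in_error(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["s1", "r1", "r2"])
        with pytest.raises(ValueError, match="sensitive"):
            gene_t_test(expr, _labels(["s1"], ["r1", "r2"]))

    def test_intermediate_lines_excluded(self):
        labels = classify_cell_lines({"s1": 5.0, "s2": 5.0, "i1": 1.5, "r1": 0.5, "r2": 0.5})
        expr = pd.DataFrame(
            [[1.0, 1.0, 99.0, 1.0, 1.0]], index=["g"], columns=["s1", "s2", "i1", "r1", "r2"]
        )
        res = gene_t_test(expr, labels)
        assert res.loc["g", "t"] == 0.0  # the outlier intermediate line is ignored

    def test_matches_reference_implementation_on_random_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 12))
        cols = [f"s{i}" for i in range(6)] + [f"r{i}" for i in range(6)]
        expr = pd.DataFrame(X, columns=cols, index=[f"g{i}" for i in range(50)])
        res = gene_t_test(expr, _labels(cols[:6], cols[6:]))
        t_ref, p_ref = sps.ttest_ind(X[:, :6], X[:, 6:], axis=1, equal_var=True)
        assert np.allclose(res["t"], t_ref, atol=1e-10)
        assert np.allclose(res["p"], p_ref, atol=1e-10)


class TestFoldChange:
    @pytest.mark.parametrize(
        "es,er,expected", [(4.0, 2.0, 2.0), (2.0, 4.0, -2.0), (3.0, 3.0, 1.0)]
    )
    def test_piecewise_form(self, es, er, expected):
        assert fold_change(es, er) == expected

    def test_nonpositive_denominator_flagged(self):
        with pytest.raises(ZeroDivisionError):
            fold_change(4.0, 0.0)
        with pytest.raises(ZeroDivisionError):
            fold_change(-1.0, 4.0)

    @given(
        es=st.floats(min_value=0.1, max_value=20),
        er=st.floats(min_value=0.1, max_value=20),
    )
    @settings(max_examples=80, deadline=None)
    def test_antisymmetry_away_from_ties(self, es, er):
        if es == er:
            return
        assert fold_change(er, es) == pytest.approx(-fold_change(es, er))


class TestQValues:
    def test_worked_example(self):
        assert q_values([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_test_is_identity(self):
        assert q_values([0.2]) == pytest.approx([0.2])

    def test_ties_share_mean_rank(self):
        q = q_values([0.5, 0.5])
        # mean rank 1.5: q = 0.5/1.5*2 for both
        assert q == pytest.approx([2 / 3, 2 / 3])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_permutation_equivariance(self, ps):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ps))
        base = q_values(ps)
        permuted = q_values([ps[i] for i in perm])
        assert np.allclose(permuted, base[perm])


class TestSelection:
    def test_strict_cut_and_direction_split(self):
        table = pd.DataFrame(
            {
                "q": [1.0e-3, 9e-4, 9e-4],
                "fold_change": [2.0, 2.0, -2.0],
                "flagged": [False, False, False],
            },
            index=["g_at_cut", "g_up", "g_down"],
        )
        sens, resist = select_genes(table)
        assert sens == ["g_up"]  # q exactly at the cut is excluded
        assert resist == ["g_down"]

    def test_empty_input(self):
        table = pd.DataFrame(columns=["q", "fold_change", "flagged"])
        assert select_genes(table) == ([], [])

    def test_planted_differential_expression_recovered(self):
        expr, labels, de = simulate_expression(
            n_genes=300, n_sensitive=15, n_resistant=15, n_de_genes=20, effect_size=3.0, seed=5
        )
        lab = classify_cell_lines(
            {c: (2.5 if labels[c] == "sensitive" else 0.5) for c in expr.columns}
        )
        table = gene_statistics(expr, lab)
        sens, _ = select_genes(table, q_cut=1e-3)
        assert set(sens) == de  # effect size 3 at n=15/group: power ~ 1


class TestOverrepresentation:
    def test_exact_enumeration_example(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        selected = term | {f"g{i}" for i in range(5, 8)}  # n=8, k=5
        res = overrepresentation(selected, {"term": term}, universe)
        expected_p = comb(15, 3, exact=True) / comb(20, 8, exact=True)
        assert res.loc["term", "p"] == pytest.approx(expected_p, rel=1e-12)
        assert res.loc["term", "fold_enrichment"] == pytest.approx((5 / 8) / (5 / 20))

    def test_selection_equal_to_term(self):
        universe = {f"g{i}" for i in range(10)}
        term = {"g0", "g1"}
        res = overrepresentation(term, {"term": term}, universe)
        assert res.loc["term", "fold_enrichment"] == pytest.approx(10 / 2)

    def test_term_outside_universe_skipped(self):
        res = overrepresentation({"a"}, {"empty": {"zzz"}}, {"a", "b"})
        assert len(res) == 0

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation({"x"}, {}, {"a"})

    def test_null_selection_type_one_error(self):
        # random selections: P(p < 0.05) <= 0.05 up to discreteness + noise
        rng = np.random.default_rng(11)
        universe = [f"g{i}" for i in range(60)]
        term = set(universe[:15])
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            sel = set(rng.choice(universe, size=12, replace=False))
            res = overrepresentation(sel, {"t": term}, universe)
            hits += res.loc["t", "p"] < 0.05
        assert hits / n_sim < 0.08  # hypergeometric p is conservative at 0.05
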
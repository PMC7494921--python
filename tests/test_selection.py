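import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tensorfe.io_formats import SampleAnnotation
from tensorfe.selection import (
    bh_adjust,
    chi2_pvalues,
    choose_component,
    diagnose_components,
    score_features,
    select_features,
)
from tensorfe.tdfe_core import TdFactorization

from _oracles import bh_bruteforce, chi2_1_sf


def make_factorization(proj_rows, proj_cols):
    proj_rows = np.asarray(proj_rows, dtype=float)
    proj_cols = np.asarray(proj_cols, dtype=float)
    m, L = proj_rows.shape
    return TdFactorization(
        lambdas=np.arange(L, 0, -1, dtype=float),
        u_rows=np.eye(3, L),
        u_cols=np.eye(3, L),
        feature_ids_rows=["a0", "a1", "a2"],
        feature_ids_cols=["b0", "b1", "b2"],
        proj_rows=proj_rows,
        proj_cols=proj_cols,
        sample_ids=[f"s{j}" for j in range(m)],
    )


ANN4 = SampleAnnotation(
    {"s0": "case", "s1": "case", "s2": "control", "s3": "control"}
)


class TestDiagnoseComponents:
    def test_equal_class_distributions_give_t_p_one(self):
        proj = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        d = diagnose_components(make_factorization(proj, proj + 0.5), ANN4)
        assert d[0].t_p_rows == pytest.approx(1.0)

    def test_identical_projections_have_pcc_one(self):
        proj = np.array([[1.0], [2.0], [3.0], [5.0]])
        d = diagnose_components(make_factorization(proj, proj), ANN4)
        assert d[0].pcc == pytest.approx(1.0)

    def test_orientation_independence(self):
        rng = np.random.default_rng(0)
        pr, pc = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
        d1 = diagnose_components(make_factorization(pr, pc), ANN4)
        d2 = diagnose_components(make_factorization(-pr, pc), ANN4)
        for a, b in zip(d1, d2):
            assert a.t_p_rows == pytest.approx(b.t_p_rows)
            assert abs(a.pcc) == pytest.approx(abs(b.pcc))

    def test_missing_annotation_lists_ids(self):
        proj = np.ones((4, 1))
        ann = SampleAnnotation({"s0": "case", "s1": "control"})
        with pytest.raises(KeyError, match="s2"):
            diagnose_components(make_factorization(proj, proj), ann)

    def test_signal_component_attains_minimum_p(self, td_results):
        diags = {d.l: d for d in td_results._component_diags()}
        chosen = td_results.selected_component()
        best_rows = min(diags.values(), key=lambda d: d.t_p_rows).l
        best_cols = min(diags.values(), key=lambda d: d.t_p_cols).l
        assert best_rows == best_cols == chosen == 2


class TestChooseComponent:
    def mk(self, pr, pc):
        from tensorfe.selection import ComponentDiagnostics

        return [
            ComponentDiagnostics(l + 1, a, b, 0.0, 1.0)
            for l, (a, b) in enumerate(zip(pr, pc))
        ]

    def test_auto_minimizes_worse_layer(self):
        d = self.mk([0.5, 1e-8, 1e-3], [1e-12, 1e-6, 1e-4])
        assert choose_component(d) == 2

    def test_ties_break_to_smaller_l(self):
        d = self.mk([0.1, 0.1], [0.1, 0.1])
        assert choose_component(d) == 1

    def test_manual_passthrough_and_range_check(self):
        d = self.mk([0.5], [0.5])
        assert choose_component(d, "manual", 1) == 1
        with pytest.raises(ValueError, match="outside"):
            choose_component(d, "manual", 2)

    def test_single_component(self):
        assert choose_component(self.mk([0.9], [0.9])) == 1


class TestChi2Pvalues:
    def test_zero_entry_gives_p_one(self):
        u = np.array([0.0, 1.0, -1.0, 2.0])
        p = chi2_pvalues(u, sd_mode="population")
        assert p[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("stat, expected", [(3.841459, 0.05), (1.0, 0.3173105)])
    def test_known_quantiles_of_the_null(self, stat, expected):
        # closed-form upper tail: P[chi2_1 > x] = erfc(sqrt(x/2))
        assert chi2_1_sf(stat) == pytest.approx(expected, abs=5e-7)

    @pytest.mark.parametrize("sd_mode", ["sample", "population"])
    def test_matches_survival_function_oracle(self, rng, sd_mode):
        u = rng.standard_normal(25)
        sigma = u.std(ddof=1 if sd_mode == "sample" else 0)
        p = chi2_pvalues(u, sd_mode=sd_mode)
        expected = [chi2_1_sf((ui / sigma) ** 2) for ui in u]
        np.testing.assert_allclose(p, expected, atol=1e-12)

    def test_monotone_decreasing_in_abs_u(self, rng):
        u = rng.standard_normal(50)
        p = chi2_pvalues(u)
        order = np.argsort(np.abs(u))
        assert (np.diff(p[order]) <= 1e-15).all()

    def test_degenerate_component_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi2_pvalues(np.array([1.0, 1.0, 1.0]))


class TestBhAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate_values(self):
        assert bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)
        np.testing.assert_allclose(bh_adjust(np.ones(5)), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_bruteforce_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=200)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestSelectFeatures:
    def test_thresholding_is_strict(self):
        scores = pd.DataFrame(
            {"id": list("abc"), "layer": "mRNA", "u": 0.0, "chi2": 0.0,
             "p": [0.001, 0.01, 0.5], "p_adj": [0.005, 0.01, 0.5]}
        )
        out = select_features(scores, alpha=0.01)
        assert out["selected"].tolist() == [True, False, False]

    def test_alpha_one_selects_everything_below_one(self):
        scores = pd.DataFrame(
            {"id": list("ab"), "layer": "m", "u": 0.0, "chi2": 0.0,
             "p": [0.3, 1.0], "p_adj": [0.9, 1.0]}
        )
        assert select_features(scores, alpha=1.0)["selected"].tolist() == [True, False]

    def test_constructed_chain_selects_exactly_the_planted_three(self, rng):
        # 3 features carrying nearly all the component weight, 97 small
        u = np.concatenate([np.full(3, 5.0) * np.array([1, -1, 1]),
                            rng.normal(0, 0.1, size=97)])
        table = score_features(u, [f"f{i}" for i in range(100)], "mRNA",
                               alpha=0.01)
        assert set(table.loc[table["selected"], "id"]) == {"f0", "f1", "f2"}

    def test_invariant_to_global_sign_flip(self, rng):
        u = rng.standard_normal(30)
        t1 = score_features(u, [f"f{i}" for i in range(30)], "m")
        t2 = score_features(-u, [f"f{i}" for i in range(30)], "m")
        assert t1["selected"].tolist() == t2["selected"].tolist()
        np.testing.assert_allclose(t1["p"], t2["p"], atol=1e-15)
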
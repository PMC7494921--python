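import numpy as np
import pandas as pd
import pytest

from tensorfe.io_formats import ConfusionTable, ExpressionMatrix, SampleAnnotation
from tensorfe.validation import (
    correlation_sign_counts,
    cross_dataset_confusion,
    fisher_exact,
    pairwise_correlations,
    welch_t_baseline,
)

from _oracles import fisher_twosided_enum, welch_p_scalar


def layer(values, name="mRNA", prefix="f"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        name,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
    )


class TestPairwiseCorrelations:
    def test_self_pair_and_negated_pair(self, rng):
        v = rng.standard_normal(20)
        a = layer(v[None, :], "mRNA", "a")
        b = layer(np.vstack([v, -v]), "miRNA", "b")
        t = pairwise_correlations(a, b)
        assert t.loc[t["id_b"] == "b0", "pcc"].iloc[0] == pytest.approx(1.0)
        assert t.loc[t["id_b"] == "b1", "pcc"].iloc[0] == pytest.approx(-1.0)

    def test_constructed_sign_counts(self, rng):
        """3 mRNA x 2 miRNA: 2 strongly positive pairs, 1 strongly negative,
        3 null pairs, at n = 50 samples."""
        n = 50
        z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
        noise = lambda: 0.05 * rng.standard_normal(n)
        a = layer(np.vstack([z1 + noise(), z2 + noise(),
                             -z1 + noise()]), "mRNA", "a")
        b = layer(np.vstack([z1 + noise(), z2 + noise()]), "miRNA", "b")
        t = pairwise_correlations(a, b, alpha=0.01)
        counts = correlation_sign_counts(t)
        assert counts["n_pairs"] == 6
        assert counts["n_positive"] == 2
        assert counts["n_negative"] == 1

    def test_pvalues_match_pearsonr(self, rng):
        import scipy.stats

        a = layer(rng.standard_normal((3, 15)), "mRNA", "a")
        b = layer(rng.standard_normal((2, 15)), "miRNA", "b")
        t = pairwise_correlations(a, b)
        for _, row in t.iterrows():
            i = int(row["id_a"][1:])
            k = int(row["id_b"][1:])
            r, p = scipy.stats.pearsonr(a.values[i], b.values[k])
            assert row["pcc"] == pytest.approx(r, abs=1e-12)
            assert row["p"] == pytest.approx(p, abs=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        a = layer(rng.standard_normal((2, 12)), "mRNA", "a")
        b = layer(rng.standard_normal((2, 12)), "miRNA", "b")
        t1 = pairwise_correlations(a, b)
        a2 = layer(3.0 * a.values + 7.0, "mRNA", "a")
        t2 = pairwise_correlations(a2, b)
        np.testing.assert_allclose(t1["pcc"], t2["pcc"], atol=1e-12)

    def test_zero_variance_feature_excluded_from_bh(self, rng):
        a = layer(np.vstack([np.ones(10), rng.standard_normal(10)]), "mRNA", "a")
        b = layer(rng.standard_normal((1, 10)), "miRNA", "b")
        t = pairwise_correlations(a, b)
        flat = t[t["id_a"] == "a0"]
        assert flat["p_adj"].isna().all()
        assert not flat["significant"].any()

    def test_too_few_samples_rejected(self, rng):
        a = layer(rng.standard_normal((1, 2)), "mRNA", "a")
        b = layer(rng.standard_normal((1, 2)), "miRNA", "b")
        with pytest.raises(ValueError, match=">= 3 samples"):
            pairwise_correlations(a, b)


class TestWelchTBaseline:
    ann = SampleAnnotation(
        {f"s{j}": ("case" if j < 3 else "control") for j in range(6)}
    )

    def test_identical_class_distributions_give_p_one(self):
        x = layer(np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]))
        t = welch_t_baseline(x, self.ann)
        assert t["t"].iloc[0] == pytest.approx(0.0)
        assert t["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_textbook_welch_oracle(self, rng):
        x = layer(rng.standard_normal((8, 6)))
        t = welch_t_baseline(x, self.ann)
        for i in range(8):
            expected = welch_p_scalar(x.values[i, :3], x.values[i, 3:])
            assert t["p"].iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_top_n_truncation_selects_smallest_raw_p(self, rng):
        x = layer(rng.standard_normal((10, 6)))
        t = welch_t_baseline(x, self.ann, top_n=3)
        assert t["selected"].sum() == 3
        assert set(t.loc[t["selected"], "p"]) == set(t["p"].nsmallest(3))

    def test_planted_features_all_top_ranked(self, default_dataset):
        ds = default_dataset
        t = welch_t_baseline(ds.layer_a, ds.annotation,
                             top_n=len(ds.truth_a))
        sel = set(t.loc[t["selected"], "id"])
        assert len(sel & ds.truth_a) / len(ds.truth_a) >= 0.9

    def test_class_with_too_few_samples_rejected(self):
        ann = SampleAnnotation(
            {f"s{j}": ("case" if j == 0 else "control") for j in range(6)}
        )
        with pytest.raises(ValueError, match=">= 2 samples"):
            welch_t_baseline(layer(np.zeros((1, 6)) + np.arange(6)), ann)


class TestCrossDatasetConfusion:
    def test_published_style_counts(self):
        universe = {f"g{i}" for i in range(17440)}
        ids = sorted(universe)
        sel_a = set(ids[:71])                      # 71 selected in A
        sel_b = set(ids[:11]) | set(ids[71:231])   # 11 shared + 160 B-only
        t = cross_dataset_confusion(sel_a, sel_b, universe)
        assert (t.a, t.b, t.c, t.d) == (17209, 160, 60, 11)

    def test_disjoint_selections(self):
        uni = {f"g{i}" for i in range(10)}
        t = cross_dataset_confusion({"g0", "g1"}, {"g2", "g3"}, uni)
        assert (t.a, t.b, t.c, t.d) == (6, 2, 2, 0)

    def test_everything_selected(self):
        uni = {"x", "y", "z"}
        t = cross_dataset_confusion(uni, uni, uni)
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 3)

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            cross_dataset_confusion({"bad"}, set(), {"g0"})


class TestFisherExact:
    def test_no_association_table(self):
        r = fisher_exact(ConfusionTable(10, 10, 10, 10))
        assert r["odds_ratio_sample"] == pytest.approx(1.0)
        assert r["p_two_sided"] == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_small_margins(self):
        checked = 0
        for a in range(13):
            for b in range(13 - a):
                for c in range(13 - a):
                    for d in range(min(13 - b, 13 - c)):
                        t = ConfusionTable(a, b, c, d)
                        arr = t.to_array()
                        if (arr.sum(axis=0) == 0).any() or \
                           (arr.sum(axis=1) == 0).any():
                            continue
                        r = fisher_exact(t)
                        expected = fisher_twosided_enum(a, b, c, d)
                        assert r["p_two_sided"] == pytest.approx(
                            expected, abs=1e-12
                        ), (a, b, c, d)
                        checked += 1
        assert checked > 1000

    def test_transpose_invariance(self):
        t = ConfusionTable(8, 3, 5, 2)
        tt = ConfusionTable(8, 5, 3, 2)
        assert fisher_exact(t)["p_two_sided"] == pytest.approx(
            fisher_exact(tt)["p_two_sided"], abs=1e-14
        )

    def test_infinite_sample_odds_ratio(self):
        r = fisher_exact(ConfusionTable(5, 0, 3, 2))
        assert np.isinf(r["odds_ratio_sample"])

    def test_degenerate_margin_flagged(self):
        r = fisher_exact(ConfusionTable(0, 0, 3, 2))
        assert r["degenerate"] and r["p_two_sided"] == 1.0
        assert np.isnan(r["odds_ratio_sample"])
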
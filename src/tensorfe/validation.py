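"""Post-selection analyses: pair correlations, supervised baseline, and
cross-dataset concordance.

After the unsupervised selection has produced mRNA and miRNA signatures,
three checks establish whether they mean anything: (i) Pearson correlation of
every selected mRNA x selected miRNA pair across samples (miRNA regulation
should make many pairs strongly correlated, in either direction); (ii) a
supervised per-feature Welch t-test, the conventional alternative the method
is benchmarked against; (iii) a 2x2 confusion table of selection agreement
between two independent datasets over a shared feature universe, tested with
Fisher's exact test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

from .io_formats import ConfusionTable, ExpressionMatrix, SampleAnnotation
from .selection import DEFAULT_ALPHA, bh_adjust

logger = logging.getLogger(__name__)


def pairwise_correlations(
    a_sel: ExpressionMatrix,
    b_sel: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Pearson correlation for every cross-layer pair of selected features.

    BH adjustment runs over the full pair grid jointly.  Pairs involving a
    zero-variance feature have undefined correlation; they are flagged and
    excluded from the adjustment.  Columns: id_a, id_b, pcc, p, p_adj,
    significant, sign.
    """
    if a_sel.sample_ids != b_sel.sample_ids:
        raise ValueError("layers are not aligned on identical ordered samples")
    m = a_sel.n_samples
    if m < 3:
        raise ValueError(f"need >= 3 samples for correlation P-values, got {m}")

    av = a_sel.values - a_sel.values.mean(axis=1, keepdims=True)
    bv = b_sel.values - b_sel.values.mean(axis=1, keepdims=True)
    a_norm = np.sqrt((av ** 2).sum(axis=1))
    b_norm = np.sqrt((bv ** 2).sum(axis=1))
    a_zero, b_zero = a_norm == 0, b_norm == 0
    if a_zero.any() or b_zero.any():
        bad = [a_sel.feature_ids[i] for i in np.flatnonzero(a_zero)] + \
              [b_sel.feature_ids[i] for i in np.flatnonzero(b_zero)]
        logger.warning("pairwise_correlations: zero-variance features excluded "
                       "from BH: %s", bad[:10])

    with np.errstate(invalid="ignore", divide="ignore"):
        r = (av @ bv.T) / np.outer(a_norm, b_norm)
    r = np.clip(r, -1.0, 1.0)
    defined = ~(np.outer(a_zero, np.ones_like(b_zero, dtype=bool))
                | np.outer(np.ones_like(a_zero, dtype=bool), b_zero))

    # two-sided P from the exact null distribution of r (same as pearsonr)
    p = np.full_like(r, np.nan)
    dist = scipy.stats.beta(m / 2 - 1, m / 2 - 1, loc=-1, scale=2)
    p[defined] = 2 * dist.sf(np.abs(r[defined]))
    p = np.clip(p, 0.0, 1.0)

    ia, ib = np.meshgrid(np.arange(a_sel.n_features), np.arange(b_sel.n_features),
                         indexing="ij")
    table = pd.DataFrame(
        {
            "id_a": [a_sel.feature_ids[i] for i in ia.ravel()],
            "id_b": [b_sel.feature_ids[k] for k in ib.ravel()],
            "pcc": r.ravel(),
            "p": p.ravel(),
        }
    )
    table["p_adj"] = np.nan
    ok = table["p"].notna().to_numpy()
    if ok.any():
        table.loc[ok, "p_adj"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    table["sign"] = np.where(table["pcc"] >= 0, "positive", "negative")
    return table


def correlation_sign_counts(pairs: pd.DataFrame) -> dict[str, int]:
    """Significant positively/negatively correlated pair counts."""
    sig = pairs[pairs["significant"]]
    return {
        "n_pairs": len(pairs),
        "n_significant": len(sig),
        "n_positive": int((sig["sign"] == "positive").sum()),
        "n_negative": int((sig["sign"] == "negative").sum()),
    }


def welch_t_baseline(
    x: ExpressionMatrix,
    ann: SampleAnnotation,
    alpha: float = DEFAULT_ALPHA,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Supervised baseline: per-feature two-sided Welch t-test with BH.

    ``selected`` is adjusted P < alpha, or, when ``top_n`` is given, the
    ``top_n`` features with smallest raw P (how a fixed-size signature is
    drawn from a supervised ranking).  Ties on raw P break by input order.
    """
    g1, g2, lab1, lab2 = ann.binary_masks(x.sample_ids)
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError(
            f"need >= 2 samples per class, got {lab1}: {int(g1.sum())}, "
            f"{lab2}: {int(g2.sum())}"
        )
    res = scipy.stats.ttest_ind(
        x.values[:, g1], x.values[:, g2], axis=1, equal_var=False
    )
    p = np.asarray(res.pvalue, dtype=float)
    table = pd.DataFrame(
        {
            "id": x.feature_ids,
            "layer": x.layer_name,
            "t": np.asarray(res.statistic, dtype=float),
            "p": p,
            "p_adj": bh_adjust(p),
        }
    )
    if top_n is None:
        table["selected"] = table["p_adj"] < alpha
    else:
        if top_n < 0:
            raise ValueError("top_n must be >= 0")
        order = np.argsort(p, kind="stable")[:top_n]
        sel = np.zeros(len(table), dtype=bool)
        sel[order] = True
        table["selected"] = sel
    return table


def cross_dataset_confusion(
    sel_a: set[str], sel_b: set[str], universe: set[str]
) -> ConfusionTable:
    """2x2 selection-agreement counts of two datasets over a shared feature
    universe: d = both, c = A only, b = B only, a = neither."""
    sel_a, sel_b, universe = set(sel_a), set(sel_b), set(universe)
    stray = (sel_a | sel_b) - universe
    if stray:
        raise ValueError(
            f"selections outside the feature universe: {sorted(stray)[:10]}"
        )
    d = len(sel_a & sel_b)
    c = len(sel_a - sel_b)
    b = len(sel_b - sel_a)
    a = len(universe) - len(sel_a | sel_b)
    return ConfusionTable(a=a, b=b, c=c, d=d)


def fisher_exact(t: ConfusionTable) -> dict[str, float | bool]:
    """Fisher's exact test of selection agreement.

    Returns the two-sided P (probability-mass criterion: the sum of
    hypergeometric probabilities not exceeding that of the observed table),
    the sample (cross-product) odds ratio a*d / (b*c) — infinite when b*c = 0
    with a*d > 0 — and the conditional maximum-likelihood odds ratio.  A
    degenerate table (a zero row or column margin) carries no evidence:
    P = 1, odds ratios undefined (NaN), and the result is flagged.
    """
    arr = t.to_array()
    degenerate = (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any()
    if degenerate:
        return {
            "p_two_sided": 1.0,
            "odds_ratio_sample": float("nan"),
            "odds_ratio_cmle": float("nan"),
            "degenerate": True,
        }
    p = float(scipy.stats.fisher_exact(arr, alternative="two-sided")[1])
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        or_sample = float("inf") if ad > 0 else float("nan")
    else:
        or_sample = ad / bc
    or_cmle = float(_cmle_odds_ratio(arr, kind="conditional").statistic)
    return {
        "p_two_sided": p,
        "odds_ratio_sample": or_sample,
        "odds_ratio_cmle": or_cmle,
        "degenerate": False,
    }
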
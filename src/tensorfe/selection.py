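"""Component diagnostics and chi-squared feature selection.

The decomposition is unsupervised; class labels enter only afterwards, to
identify which component tracks the phenotype.  For each component the two
sample projections are compared between classes with Welch's t-test, and the
agreement between the layers is quantified by the Pearson correlation of the
two projections.  Features are then scored on the chosen component's feature
vector u: each entry is standardized by the vector's own standard deviation
sigma and

    P = Pr[ chi2_1 > (u / sigma)^2 ]

is the upper-tail probability of a 1-df chi-squared variate (the square of a
standard Gaussian — the implicit null is that component entries of
uninformative features are Gaussian noise).  P-values are Benjamini-Hochberg
adjusted and features with adjusted P strictly below alpha (default 0.01) are
selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_formats import SampleAnnotation
from .tdfe_core import TdFactorization

DEFAULT_ALPHA = 0.01

#: columns of a feature-score table
SCORE_COLUMNS = ["id", "layer", "u", "chi2", "p", "p_adj", "selected"]


@dataclass
class ComponentDiagnostics:
    """Per-component class separation and cross-layer agreement.

    ``l`` is 1-based.  ``t_p_rows``/``t_p_cols`` are two-sided Welch t-test
    P-values comparing the class projections in each layer; ``pcc`` is the
    Pearson correlation between the two layers' projections (its sign depends
    on the arbitrary component orientation; P-values and |pcc| do not).
    """

    l: int
    t_p_rows: float
    t_p_cols: float
    pcc: float
    pcc_p: float


def _welch_p(x: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> float:
    res = scipy.stats.ttest_ind(x[g1], x[g2], equal_var=False)
    return float(res.pvalue)


def diagnose_components(
    f: TdFactorization, ann: SampleAnnotation
) -> list[ComponentDiagnostics]:
    """Welch t-test and inter-layer Pearson correlation for every component."""
    if f.proj_rows is None or f.proj_cols is None or f.sample_ids is None:
        raise ValueError("factorization lacks sample projections; run project_samples")
    g1, g2, lab1, lab2 = ann.binary_masks(f.sample_ids)
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError(
            f"need >= 2 samples per class, got {lab1}: {int(g1.sum())}, "
            f"{lab2}: {int(g2.sum())}"
        )
    out = []
    for l in range(f.n_components):
        pr, pc = f.proj_rows[:, l], f.proj_cols[:, l]
        r, rp = scipy.stats.pearsonr(pr, pc)
        out.append(
            ComponentDiagnostics(
                l=l + 1,
                t_p_rows=_welch_p(pr, g1, g2),
                t_p_cols=_welch_p(pc, g1, g2),
                pcc=float(r),
                pcc_p=float(rp),
            )
        )
    return out


def diagnostics_frame(diags: list[ComponentDiagnostics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "l": [d.l for d in diags],
            "t_p_rows": [d.t_p_rows for d in diags],
            "t_p_cols": [d.t_p_cols for d in diags],
            "pcc": [d.pcc for d in diags],
            "pcc_p": [d.pcc_p for d in diags],
        }
    )


def choose_component(
    diags: list[ComponentDiagnostics],
    strategy: str = "auto",
    manual_l: int | None = None,
) -> int:
    """Pick the component whose projections best separate the classes.

    ``auto`` minimizes ``max(t_p_rows, t_p_cols)`` — the component must
    separate the classes in *both* layers — with ties broken toward smaller
    l.  ``manual`` returns ``manual_l`` after a range check (mirrors choosing
    a component by inspection).
    """
    if not diags:
        raise ValueError("no component diagnostics")
    if strategy == "manual":
        if manual_l is None:
            raise ValueError("manual strategy requires manual_l")
        valid = {d.l for d in diags}
        if manual_l not in valid:
            raise ValueError(f"manual_l={manual_l} outside available components {sorted(valid)}")
        return manual_l
    if strategy != "auto":
        raise ValueError(f"unknown strategy {strategy!r}")
    best = min(diags, key=lambda d: (max(d.t_p_rows, d.t_p_cols), d.l))
    return best.l


def chi2_pvalues(u: np.ndarray, sd_mode: str = "sample") -> np.ndarray:
    """Upper-tail chi-squared (1 df) probability of (u_i / sigma)^2.

    sigma is the standard deviation of the component vector itself;
    ``sd_mode`` picks the ``m-1`` (sample, default) or ``m`` (population)
    denominator.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size < 2:
        raise ValueError("component vector must be 1-D with >= 2 entries")
    if sd_mode not in {"sample", "population"}:
        raise ValueError(f"sd_mode must be 'sample' or 'population', got {sd_mode!r}")
    sigma = u.std(ddof=1 if sd_mode == "sample" else 0)
    if sigma == 0:
        raise ValueError("degenerate component: zero standard deviation")
    return scipy.stats.chi2.sf((u / sigma) ** 2, df=1)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def score_features(
    u: np.ndarray,
    feature_ids: list[str],
    layer: str,
    alpha: float = DEFAULT_ALPHA,
    sd_mode: str = "sample",
) -> pd.DataFrame:
    """Full per-feature scoring chain: chi2 statistic -> raw P -> BH -> flag."""
    u = np.asarray(u, dtype=float)
    sigma = u.std(ddof=1 if sd_mode == "sample" else 0)
    p = chi2_pvalues(u, sd_mode=sd_mode)
    scores = pd.DataFrame(
        {
            "id": feature_ids,
            "layer": layer,
            "u": u,
            "chi2": (u / sigma) ** 2,
            "p": p,
            "p_adj": bh_adjust(p),
        }
    )
    return select_features(scores, alpha)


def select_features(scores: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Set the ``selected`` flag: adjusted P strictly below alpha."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    scores = scores.copy()
    scores["selected"] = scores["p_adj"] < alpha
    return scores[[c for c in SCORE_COLUMNS if c in scores.columns]]
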
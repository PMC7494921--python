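"""PCA-based unsupervised feature extraction — the single-layer baseline.

Each layer is analysed separately.  After per-sample standardization, the PC
scores u (attributed to features) are the eigenvectors of the N x N gram
matrix  sum_j x_ij x_i'j, and the PC loadings v (attributed to samples) are
the projections v_lj = sum_i x_ij u_li.  Computationally the eigenproblem is
solved through the SVD of x itself (x = U S V^T gives eigenvectors U and
eigenvalues S^2) so the gram matrix is never formed for large N.  The
component whose loadings separate the classes is then passed through the same
chi-squared / Benjamini-Hochberg feature-scoring chain as the tensor route;
components are chosen independently per layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .io_formats import ExpressionMatrix, SampleAnnotation
from .selection import DEFAULT_ALPHA, score_features
from .tdfe_core import _fix_signs


@dataclass
class PcaFactorization:
    """Gram-matrix eigendecomposition of one standardized layer.

    ``eigenvalues`` nonincreasing (numerical negatives clamped to 0);
    ``pc_scores`` (N x L) orthonormal feature eigenvectors; ``pc_loadings``
    (M x L) sample projections v = x^T u.
    """

    eigenvalues: np.ndarray
    pc_scores: np.ndarray
    pc_loadings: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    layer_name: str

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def pca_fit(x: ExpressionMatrix, L: int | None = None) -> PcaFactorization:
    """Top-L gram-matrix eigenvectors of a standardized layer, via SVD of x."""
    n, m = x.values.shape
    max_l = min(n, m)
    if L is None:
        L = min(10, max_l)
    if not 1 <= L <= max_l:
        raise ValueError(f"L must be in [1, {max_l}], got {L}")
    u, s, _vt = scipy.linalg.svd(x.values, full_matrices=False)
    u = np.ascontiguousarray(u[:, :L])
    s = s[:L]
    # derive loadings directly from the data, matching v = x^T u exactly
    dummy = np.zeros((1, L))
    _fix_signs(u, dummy)
    loadings = x.values.T @ u
    return PcaFactorization(
        eigenvalues=np.maximum(s ** 2, 0.0),
        pc_scores=u,
        pc_loadings=loadings,
        feature_ids=list(x.feature_ids),
        sample_ids=list(x.sample_ids),
        layer_name=x.layer_name,
    )


def pca_diagnostics(f: PcaFactorization, ann: SampleAnnotation) -> pd.DataFrame:
    """Welch t-test P-value of each component's sample loadings between
    classes (1-based component index)."""
    g1, g2, lab1, lab2 = ann.binary_masks(f.sample_ids)
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError(
            f"need >= 2 samples per class, got {lab1}: {int(g1.sum())}, "
            f"{lab2}: {int(g2.sum())}"
        )
    ps = [
        float(scipy.stats.ttest_ind(f.pc_loadings[g1, l], f.pc_loadings[g2, l],
                                    equal_var=False).pvalue)
        for l in range(f.n_components)
    ]
    return pd.DataFrame({"l": np.arange(1, f.n_components + 1), "t_p": ps})


def pca_select(
    f: PcaFactorization,
    ann: SampleAnnotation,
    alpha: float = DEFAULT_ALPHA,
    sd_mode: str = "sample",
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Choose the class-separating component and score features on it.

    Returns ``(score_table, diagnostics, chosen_l)``; the component is the
    one minimizing the loadings t-test P (ties toward smaller l).
    """
    diags = pca_diagnostics(f, ann)
    chosen = int(diags.loc[diags["t_p"].idxmin(), "l"])
    # idxmin already prefers the first (smallest l) among ties
    scores = score_features(
        f.pc_scores[:, chosen - 1], f.feature_ids, f.layer_name,
        alpha=alpha, sd_mode=sd_mode,
    )
    return scores, diags, chosen
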
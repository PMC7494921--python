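"""The tensor-decomposition feature-extraction engine.

Two layers measured on the same M samples — layer A with N features (mRNA)
and layer B with K features (miRNA) — define an implicit 3-way tensor

    x_ijk = a_ij * b_kj .

A full Tucker/HOSVD of that tensor would need N*M*K memory, which is
prohibitive at transcriptome scale (~5e9 entries for a typical TCGA cohort),
so the tensor is never materialized.  Instead it is collapsed over the sample
mode,

    x_ik = sum_j x_ijk = sum_j a_ij * b_kj = (A B^T)_ik ,

and the N x K collapsed matrix is factorized by SVD,

    x_ik = sum_l lambda_l u_rows[i,l] u_cols[k,l] .

The feature singular vectors are then pushed back onto samples to give one
sample projection per layer and component,

    proj_rows[j,l] = sum_i a_ij u_rows[i,l],
    proj_cols[j,l] = sum_k b_kj u_cols[k,l] ,

which play the role of the missing sample-mode factor: a component whose two
projections separate the phenotype classes carries the shared signal, and its
feature vectors are what downstream selection scores.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .io_formats import ExpressionMatrix

# above this size the dense SVD of the collapsed matrix is replaced by a
# truncated iterative solver
_DENSE_SVD_LIMIT = 2000


@dataclass
class CollapsedMatrix:
    """The sample-collapsed cross-layer matrix x_ik = sum_j a_ij b_kj."""

    values: np.ndarray  # N x K
    feature_ids_rows: list[str]
    feature_ids_cols: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids_rows), len(self.feature_ids_cols)):
            raise ValueError("collapsed matrix shape does not match feature IDs")


@dataclass
class TdFactorization:
    """SVD factors of the collapsed matrix plus per-layer sample projections.

    ``lambdas`` are the nonincreasing singular values; ``u_rows`` (N x L) and
    ``u_cols`` (K x L) have orthonormal columns; ``proj_rows``/``proj_cols``
    (M x L) are filled in by :func:`project_samples`.
    """

    lambdas: np.ndarray
    u_rows: np.ndarray
    u_cols: np.ndarray
    feature_ids_rows: list[str]
    feature_ids_cols: list[str]
    proj_rows: np.ndarray | None = None
    proj_cols: np.ndarray | None = None
    sample_ids: list[str] | None = None

    @property
    def n_components(self) -> int:
        return len(self.lambdas)


def collapse_over_samples(a: ExpressionMatrix, b: ExpressionMatrix) -> CollapsedMatrix:
    """Collapse the implicit tensor over samples: x_ik = sum_j a_ij b_kj.

    Computed as ``A @ B.T``; memory stays proportional to N*K.  Both layers
    must already be aligned on an identical ordered sample set.
    """
    if a.sample_ids != b.sample_ids:
        raise ValueError(
            "layers are not aligned on identical ordered samples; "
            "call align_layers first"
        )
    return CollapsedMatrix(
        values=a.values @ b.values.T,
        feature_ids_rows=list(a.feature_ids),
        feature_ids_cols=list(b.feature_ids),
    )


def _fix_signs(u_rows: np.ndarray, u_cols: np.ndarray) -> None:
    """Orient each component so the largest-|.| entry of u_rows is positive.

    SVD signs are arbitrary; a fixed convention makes runs reproducible.
    Operates in place, flipping u_cols consistently.
    """
    for l in range(u_rows.shape[1]):
        i = int(np.argmax(np.abs(u_rows[:, l])))
        if u_rows[i, l] < 0:
            u_rows[:, l] *= -1.0
            u_cols[:, l] *= -1.0


def factorize(x: CollapsedMatrix, L: int | None = None) -> TdFactorization:
    """Top-L SVD of the collapsed matrix.

    Defaults to ``L = min(10, min(N, K))`` — only low components are ever
    inspected downstream.  Dense LAPACK SVD when ``min(N, K) <= 2000``,
    truncated Lanczos above (with a fixed start vector for determinism).
    """
    n, k = x.values.shape
    max_l = min(n, k)
    if L is None:
        L = min(10, max_l)
    if not 1 <= L <= max_l:
        raise ValueError(f"L must be in [1, {max_l}], got {L}")
    if max_l <= _DENSE_SVD_LIMIT:
        u, s, vt = scipy.linalg.svd(x.values, full_matrices=False)
        u, s, vt = u[:, :L], s[:L], vt[:L]
    else:
        v0 = np.ones(min(x.values.shape))
        u, s, vt = scipy.sparse.linalg.svds(x.values, k=L, v0=v0)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
    u = np.ascontiguousarray(u)
    v = np.ascontiguousarray(vt.T)
    _fix_signs(u, v)
    return TdFactorization(
        lambdas=s,
        u_rows=u,
        u_cols=v,
        feature_ids_rows=list(x.feature_ids_rows),
        feature_ids_cols=list(x.feature_ids_cols),
    )


def project_samples(
    a: ExpressionMatrix, b: ExpressionMatrix, f: TdFactorization
) -> TdFactorization:
    """Project each layer onto its feature singular vectors, giving the M x L
    sample-mode coordinates of every component (one set per layer)."""
    if a.sample_ids != b.sample_ids:
        raise ValueError("layers are not aligned on identical ordered samples")
    if a.n_features != f.u_rows.shape[0] or b.n_features != f.u_cols.shape[0]:
        raise ValueError(
            "factorization dimensions do not match the layers "
            f"({f.u_rows.shape[0]}x{f.u_cols.shape[0]} vs "
            f"{a.n_features}x{b.n_features} features)"
        )
    return replace(
        f,
        proj_rows=a.values.T @ f.u_rows,
        proj_cols=b.values.T @ f.u_cols,
        sample_ids=list(a.sample_ids),
    )
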
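"""Feature filtering and per-sample standardization.

Each sample column j of a layer with N features is normalized so that
sum_i x_ij = 0 and sum_i x_ij^2 = N.  This puts every sample on a common
scale and makes the squared, standardized singular-vector entries used for
feature scoring comparable to a chi-squared null.  The same standardization
is applied before both the tensor and the PCA routes by default (the PCA
route requires it; applying it to the tensor route too keeps the two
comparable), and can be disabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Preprocessing switches.

    log2_offset : float or None
        When set, apply ``log2(x + offset)`` before anything else (useful for
        RNA-seq count-like units; off by default since microarray intensities
        are already log-scale).
    standardize : bool
        Per-sample centering/scaling (mean 0, sum of squares = N).
    drop_nonfinite : bool
        Remove features with any non-finite value.
    drop_zero_variance : bool
        Remove features constant across samples.
    """

    log2_offset: float | None = None
    standardize: bool = True
    drop_nonfinite: bool = True
    drop_zero_variance: bool = True

    def __post_init__(self) -> None:
        if self.log2_offset is not None:
            off = float(self.log2_offset)
            if not np.isfinite(off) or off < 0:
                raise ValueError("log2_offset must be a finite value >= 0")
            self.log2_offset = off


def filter_features(x: ExpressionMatrix, cfg: PreprocessConfig) -> ExpressionMatrix:
    """Drop features with non-finite values and/or zero variance."""
    keep = np.ones(x.n_features, dtype=bool)
    if cfg.drop_nonfinite:
        finite = np.isfinite(x.values).all(axis=1)
        n_bad = int((~finite).sum())
        if n_bad:
            logger.info(
                "filter_features(%s): removing %d features with non-finite values",
                x.layer_name, n_bad,
            )
        keep &= finite
    if cfg.drop_zero_variance:
        with np.errstate(invalid="ignore"):
            var = np.nanvar(x.values, axis=1)
        flat = keep & ~(var > 0)
        n_flat = int(flat.sum())
        if n_flat:
            logger.info(
                "filter_features(%s): removing %d zero-variance features",
                x.layer_name, n_flat,
            )
        keep &= var > 0
    if not keep.any():
        raise ValueError(f"all features of layer {x.layer_name!r} removed by filtering")
    if keep.all():
        return x
    return x.subset_features(keep)


def standardize_per_sample(x: ExpressionMatrix) -> ExpressionMatrix:
    """Center and rescale each sample column to mean 0 and sum of squares N.

    A column that is constant before centering cannot be rescaled; it becomes
    all-zero and is flagged in the log.  Idempotent up to floating-point
    round-off.
    """
    n = x.n_features
    if n < 2:
        raise ValueError("standardization needs at least 2 features")
    v = x.values - x.values.mean(axis=0, keepdims=True)
    ss = (v ** 2).sum(axis=0)
    zero = ss == 0
    if zero.any():
        flagged = [x.sample_ids[j] for j in np.flatnonzero(zero)]
        logger.warning(
            "standardize_per_sample(%s): constant columns set to zero: %s",
            x.layer_name, flagged[:10],
        )
    scale = np.where(zero, 1.0, np.sqrt(n / np.where(zero, 1.0, ss)))
    return ExpressionMatrix(
        layer_name=x.layer_name,
        feature_ids=list(x.feature_ids),
        sample_ids=list(x.sample_ids),
        values=v * scale,
    )


def apply_preprocessing(x: ExpressionMatrix, cfg: PreprocessConfig) -> ExpressionMatrix:
    """log2 transform (optional) -> feature filtering -> standardization."""
    if cfg.log2_offset is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.log2(x.values + cfg.log2_offset)
        x = ExpressionMatrix(x.layer_name, list(x.feature_ids), list(x.sample_ids), vals)
    x = filter_features(x, cfg)
    if cfg.standardize:
        x = standardize_per_sample(x)
    return x
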
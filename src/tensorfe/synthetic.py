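"""Synthetic paired-omics generator with planted class-driven signal.

Emulates the structure the method assumes: two expression layers over the
same samples, two phenotype classes, and a small planted feature subset in
each layer whose mean shifts with the class.  The generative model per layer
is

    x_ij = mu_i + delta * s_i * c_j * [i planted] + eps_ij

with feature baselines mu_i ~ Normal(mu0, baseline_sd^2), random signal signs
s_i in {+1, -1}, class scores c_j = +1 (case) / -1 (control), and iid
Gaussian noise eps_ij ~ Normal(0, noise_sd^2); both layers are generated
independently with the *same* class scores, so the signal is shared across
layers.  With the baseline mean well above 0 (default 5) the leading
component of the decomposition captures baseline magnitudes and the class
signal lands on component 2 — the configuration the method is designed to
detect.  An optional lognormal mode exponentiates the Gaussian field for
positively skewed, strictly positive values.

Defaults are desk-scale: N = 2000 mRNAs, K = 300 miRNAs, 30 cases + 30
controls, 50 + 20 planted features, delta = 2, noise_sd = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ExpressionMatrix, SampleAnnotation

DEFAULT_SEED = 20200916


@dataclass
class SyntheticConfig:
    """Generator parameters (units are arbitrary expression units)."""

    n_features_a: int = 2000
    n_features_b: int = 300
    n_case: int = 30
    n_control: int = 30
    n_signal_a: int = 50
    n_signal_b: int = 20
    effect: float = 2.0        # delta, class-driven half-difference of means
    noise_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    seed: int = DEFAULT_SEED
    distribution: str = "normal"  # or "lognormal"

    def __post_init__(self) -> None:
        for name in ("n_features_a", "n_features_b", "n_case", "n_control"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.n_signal_a <= self.n_features_a:
            raise ValueError("n_signal_a must be in [0, n_features_a]")
        if not 0 <= self.n_signal_b <= self.n_features_b:
            raise ValueError("n_signal_b must be in [0, n_features_b]")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.distribution not in {"normal", "lognormal"}:
            raise ValueError("distribution must be 'normal' or 'lognormal'")


def tcga_like_config(**overrides) -> SyntheticConfig:
    """Preset mirroring the sample imbalance of a typical tumor cohort
    (253 cases vs 71 controls)."""
    base = dict(n_case=253, n_control=71)
    base.update(overrides)
    return SyntheticConfig(**base)


@dataclass
class SyntheticDataset:
    """Paired layers, class labels, and ground-truth planted feature sets."""

    layer_a: ExpressionMatrix
    layer_b: ExpressionMatrix
    annotation: SampleAnnotation
    truth_a: frozenset[str]
    truth_b: frozenset[str]
    config: SyntheticConfig = field(repr=False, default_factory=SyntheticConfig)


def _make_layer(
    rng: np.random.Generator,
    prefix: str,
    layer_name: str,
    n_features: int,
    n_signal: int,
    c: np.ndarray,
    sample_ids: list[str],
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, frozenset[str]]:
    m = len(sample_ids)
    width = max(4, len(str(n_features)))
    ids = [f"{prefix}{i + 1:0{width}d}" for i in range(n_features)]
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_features)
    signal_idx = rng.choice(n_features, size=n_signal, replace=False)
    s = rng.choice([-1.0, 1.0], size=n_signal)
    values = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_features, m))
    values[signal_idx] += cfg.effect * s[:, None] * c[None, :]
    if cfg.distribution == "lognormal":
        values = np.exp(values * np.log(2.0))  # 2**x: shifts become fold changes
    truth = frozenset(ids[i] for i in signal_idx)
    return ExpressionMatrix(layer_name, ids, sample_ids, values), truth


def generate_dataset(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """Draw one dataset; fully reproducible from ``cfg.seed``."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_case + cfg.n_control
    width = max(3, len(str(m)))
    sample_ids = [f"sample{j + 1:0{width}d}" for j in range(m)]
    labels = {
        s: ("case" if j < cfg.n_case else "control")
        for j, s in enumerate(sample_ids)
    }
    c = np.where(np.arange(m) < cfg.n_case, 1.0, -1.0)
    layer_a, truth_a = _make_layer(
        rng, "gene", "mRNA", cfg.n_features_a, cfg.n_signal_a, c, sample_ids, cfg
    )
    layer_b, truth_b = _make_layer(
        rng, "mir", "miRNA", cfg.n_features_b, cfg.n_signal_b, c, sample_ids, cfg
    )
    return SyntheticDataset(
        layer_a=layer_a,
        layer_b=layer_b,
        annotation=SampleAnnotation(labels),
        truth_a=truth_a,
        truth_b=truth_b,
        config=cfg,
    )


def recovery_metrics(selected: set[str], truth: set[str]) -> dict[str, float]:
    """Precision, recall and F1 of a selected feature set against the planted
    truth.  An empty selection has precision 1 when the truth is also empty,
    otherwise 0."""
    selected, truth = set(selected), set(truth)
    tp = len(selected & truth)
    if selected:
        precision = tp / len(selected)
    else:
        precision = 1.0 if not truth else 0.0
    recall = tp / len(truth) if truth else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1}
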
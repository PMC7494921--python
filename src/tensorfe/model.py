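"""Model/Results interface over the functional pipeline.

``TensorFE`` holds the two aligned, preprocessed layers plus the optional
class annotation; ``fit()`` performs the collapse + SVD and returns a
``TensorFEResults`` carrying the factorization, the per-component diagnostics
and the feature-selection methods.  ``PCAFE`` does the same for a single
layer through the PCA route.  Both Results objects expose a ``summary()``
text table in the spirit of statsmodels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import pca_fe, preprocess, selection, tdfe_core
from .io_formats import ExpressionMatrix, SampleAnnotation, align_layers
from .selection import DEFAULT_ALPHA


class TensorFE:
    """Tensor-decomposition feature extraction for two paired layers.

    Parameters
    ----------
    layer_a, layer_b : ExpressionMatrix
        The two omics layers (e.g. mRNA and miRNA); they are aligned on
        their shared samples and preprocessed at construction.
    annotation : SampleAnnotation, optional
        Binary class labels; required for diagnostics and selection.
    config : PreprocessConfig, optional
        Preprocessing switches (default: drop degenerate features and
        standardize each sample column).
    """

    def __init__(
        self,
        layer_a: ExpressionMatrix,
        layer_b: ExpressionMatrix,
        annotation: SampleAnnotation | None = None,
        config: preprocess.PreprocessConfig | None = None,
    ):
        self.config = config or preprocess.PreprocessConfig()
        a, b = align_layers(layer_a, layer_b)
        self.layer_a = preprocess.apply_preprocessing(a, self.config)
        self.layer_b = preprocess.apply_preprocessing(b, self.config)
        self.annotation = annotation

    @classmethod
    def from_dataframes(
        cls,
        frame_a: pd.DataFrame,
        frame_b: pd.DataFrame,
        annotation: SampleAnnotation | dict[str, str] | None = None,
        **kwargs,
    ) -> "TensorFE":
        """Build from two features-by-samples DataFrames."""
        if isinstance(annotation, dict):
            annotation = SampleAnnotation(annotation)
        return cls(
            ExpressionMatrix.from_frame(frame_a, "mRNA"),
            ExpressionMatrix.from_frame(frame_b, "miRNA"),
            annotation,
            **kwargs,
        )

    def fit(self, L: int | None = None) -> "TensorFEResults":
        """Collapse over samples, factorize, and project; returns Results."""
        collapsed = tdfe_core.collapse_over_samples(self.layer_a, self.layer_b)
        fact = tdfe_core.factorize(collapsed, L)
        fact = tdfe_core.project_samples(self.layer_a, self.layer_b, fact)
        return TensorFEResults(self, fact)


class TensorFEResults:
    """Fitted factorization with diagnostics and feature selection."""

    def __init__(self, model: TensorFE, factorization: tdfe_core.TdFactorization):
        self.model = model
        self.factorization = factorization
        self._diags: list[selection.ComponentDiagnostics] | None = None

    @property
    def lambdas(self) -> np.ndarray:
        return self.factorization.lambdas

    def diagnostics(self) -> pd.DataFrame:
        """Per-component Welch t-test P-values and cross-layer PCC."""
        return selection.diagnostics_frame(self._component_diags())

    def _component_diags(self) -> list[selection.ComponentDiagnostics]:
        if self._diags is None:
            if self.model.annotation is None:
                raise ValueError("diagnostics require a sample annotation")
            self._diags = selection.diagnose_components(
                self.factorization, self.model.annotation
            )
        return self._diags

    def selected_component(
        self, strategy: str = "auto", manual_l: int | None = None
    ) -> int:
        return selection.choose_component(self._component_diags(), strategy, manual_l)

    def feature_scores(
        self,
        component: int | str = "auto",
        alpha: float = DEFAULT_ALPHA,
        sd_mode: str = "sample",
    ) -> pd.DataFrame:
        """Chi-squared/BH score table for both layers on one component.

        ``component`` is a 1-based index or ``"auto"``.
        """
        if component == "auto":
            l = self.selected_component()
        else:
            l = selection.choose_component(
                self._component_diags(), "manual", int(component)
            )
        f = self.factorization
        rows = selection.score_features(
            f.u_rows[:, l - 1], f.feature_ids_rows, self.model.layer_a.layer_name,
            alpha=alpha, sd_mode=sd_mode,
        )
        cols = selection.score_features(
            f.u_cols[:, l - 1], f.feature_ids_cols, self.model.layer_b.layer_name,
            alpha=alpha, sd_mode=sd_mode,
        )
        return pd.concat([rows, cols], ignore_index=True)

    def selected_ids(self, layer: str, **kwargs) -> set[str]:
        scores = self.feature_scores(**kwargs)
        sel = scores[(scores["layer"] == layer) & scores["selected"]]
        return set(sel["id"])

    def projections_frame(self) -> pd.DataFrame:
        """Sample projections of both layers, long format."""
        f = self.factorization
        frames = []
        for tag, proj in (("rows", f.proj_rows), ("cols", f.proj_cols)):
            layer = (self.model.layer_a if tag == "rows" else self.model.layer_b)
            df = pd.DataFrame(
                proj,
                index=pd.Index(f.sample_ids, name="sample_id"),
                columns=[f"l{l + 1}" for l in range(f.n_components)],
            )
            df.insert(0, "layer", layer.layer_name)
            frames.append(df.reset_index())
        return pd.concat(frames, ignore_index=True)

    def summary(self, alpha: float = DEFAULT_ALPHA) -> str:
        """Human-readable fit summary."""
        f = self.factorization
        lines = [
            "Tensor-decomposition feature extraction",
            "=" * 55,
            f"layers: {self.model.layer_a.layer_name} "
            f"({f.u_rows.shape[0]} features) x "
            f"{self.model.layer_b.layer_name} ({f.u_cols.shape[0]} features), "
            f"{len(f.sample_ids or [])} samples",
            f"components: {f.n_components}",
            "",
            "  l     lambda   t_p(A)      t_p(B)      PCC",
        ]
        diags = None
        if self.model.annotation is not None:
            diags = {d.l: d for d in self._component_diags()}
        for l in range(f.n_components):
            lam = f.lambdas[l]
            if diags:
                d = diags[l + 1]
                lines.append(
                    f"  {l + 1:<3d} {lam:10.4g} {d.t_p_rows:<11.3g} "
                    f"{d.t_p_cols:<11.3g} {d.pcc:+.3f}"
                )
            else:
                lines.append(f"  {l + 1:<3d} {lam:10.4g}")
        if diags:
            chosen = self.selected_component()
            scores = self.feature_scores(component=chosen, alpha=alpha)
            n_a = int(scores[(scores["layer"] == self.model.layer_a.layer_name)
                             & scores["selected"]].shape[0])
            n_b = int(scores[(scores["layer"] == self.model.layer_b.layer_name)
                             & scores["selected"]].shape[0])
            lines += [
                "",
                f"chosen component (auto): l = {chosen}",
                f"selected at BH-adjusted P < {alpha}: "
                f"{n_a} {self.model.layer_a.layer_name}, "
                f"{n_b} {self.model.layer_b.layer_name}",
            ]
        return "\n".join(lines)

    def plot_projections(self, component: int | None = None, ax=None):
        """Scatter of layer-A vs layer-B sample projections for one
        component, colored by class when annotated."""
        import matplotlib.pyplot as plt

        f = self.factorization
        l = component or (
            self.selected_component() if self.model.annotation else 1
        )
        if ax is None:
            _fig, ax = plt.subplots()
        x = f.proj_cols[:, l - 1]
        y = f.proj_rows[:, l - 1]
        if self.model.annotation is not None:
            g1, g2, lab1, lab2 = self.model.annotation.binary_masks(f.sample_ids)
            ax.scatter(x[g1], y[g1], facecolors="none", edgecolors="black",
                       label=lab1)
            ax.scatter(x[g2], y[g2], facecolors="none", edgecolors="red",
                       label=lab2)
            ax.legend()
        else:
            ax.scatter(x, y, facecolors="none", edgecolors="black")
        ax.set_xlabel(f"{self.model.layer_b.layer_name} projection l={l}")
        ax.set_ylabel(f"{self.model.layer_a.layer_name} projection l={l}")
        return ax


class PCAFE:
    """PCA-based feature extraction for a single layer (baseline)."""

    def __init__(
        self,
        layer: ExpressionMatrix,
        annotation: SampleAnnotation | None = None,
        config: preprocess.PreprocessConfig | None = None,
    ):
        self.config = config or preprocess.PreprocessConfig()
        if not self.config.standardize:
            raise ValueError("the PCA route requires per-sample standardization")
        self.layer = preprocess.apply_preprocessing(layer, self.config)
        self.annotation = annotation

    def fit(self, L: int | None = None) -> "PCAFEResults":
        return PCAFEResults(self, pca_fe.pca_fit(self.layer, L))


class PCAFEResults:
    def __init__(self, model: PCAFE, factorization: pca_fe.PcaFactorization):
        self.model = model
        self.factorization = factorization

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.factorization.eigenvalues

    def diagnostics(self) -> pd.DataFrame:
        if self.model.annotation is None:
            raise ValueError("diagnostics require a sample annotation")
        return pca_fe.pca_diagnostics(self.factorization, self.model.annotation)

    def feature_scores(
        self, alpha: float = DEFAULT_ALPHA, sd_mode: str = "sample"
    ) -> tuple[pd.DataFrame, int]:
        """Score table and auto-chosen component for this layer."""
        if self.model.annotation is None:
            raise ValueError("feature scoring requires a sample annotation")
        scores, _diags, chosen = pca_fe.pca_select(
            self.factorization, self.model.annotation, alpha=alpha, sd_mode=sd_mode
        )
        return scores, chosen

    def selected_ids(self, **kwargs) -> set[str]:
        scores, _ = self.feature_scores(**kwargs)
        return set(scores.loc[scores["selected"], "id"])

    def summary(self, alpha: float = DEFAULT_ALPHA) -> str:
        f = self.factorization
        lines = [
            f"PCA feature extraction — layer {f.layer_name}",
            "=" * 55,
            f"{len(f.feature_ids)} features, {len(f.sample_ids)} samples, "
            f"{f.n_components} components",
            "",
            "  l     eigenvalue  t_p",
        ]
        diags = None
        if self.model.annotation is not None:
            diags = self.diagnostics().set_index("l")["t_p"]
        for l in range(f.n_components):
            if diags is not None:
                lines.append(
                    f"  {l + 1:<3d} {f.eigenvalues[l]:11.4g} {diags[l + 1]:.3g}"
                )
            else:
                lines.append(f"  {l + 1:<3d} {f.eigenvalues[l]:11.4g}")
        if self.model.annotation is not None:
            scores, chosen = self.feature_scores(alpha=alpha)
            lines += [
                "",
                f"chosen component: l = {chosen}",
                f"selected at BH-adjusted P < {alpha}: "
                f"{int(scores['selected'].sum())}",
            ]
        return "\n".join(lines)
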
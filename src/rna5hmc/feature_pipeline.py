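"""Hybrid feature fusion and PCA-based feature selection.

The hybrid feature vector is the ordered concatenation of all seven
encoder outputs (k-mer, RC-k-mer, PseDNC, PseTNC, TAC, TCC, DCC); with the
default encoder configuration it has exactly 174 columns. Dimensionality
is then reduced by unsupervised principal component analysis, keeping the
top 75 components by default.

PCA is fitted on the training partition only. Fitting on pooled
train+test data leaks test information into cross-validated performance
estimates; a ``pooled`` escape hatch exists in the evaluation driver for
comparison, but fold-wise fitting is the default. Features are
mean-centered but not variance-scaled before PCA (covariance PCA);
``standardize=True`` switches to correlation PCA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .encoders import EncoderConfig, encode_sequence
from .sequence_io import LabeledDataset

__all__ = [
    "FeatureMatrix",
    "PcaModel",
    "encode_dataset",
    "encode_hybrid",
    "fit_pca",
    "transform_pca",
    "inverse_transform_pca",
]


@dataclass
class FeatureMatrix:
    """Sequences x features matrix with ordered ids and feature names."""

    ids: list[str]
    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.feature_names)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.feature_names)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def rows(self, indices) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            [self.ids[i] for i in idx], self.feature_names, self.values[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.ids, columns=list(self.feature_names)
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            [str(i) for i in df.index],
            tuple(df.columns),
            df.to_numpy(dtype=float),
        )


def encode_dataset(
    data: LabeledDataset,
    cfg: EncoderConfig | None = None,
    only: str | None = None,
) -> FeatureMatrix:
    """Encode every sequence of a dataset with one encoder (``only``) or
    the full hybrid concatenation. Per-sequence encoder failures are
    re-raised with the sequence id attached."""
    cfg = cfg or EncoderConfig()
    rows, names = [], None
    for seq in data.sequences:
        try:
            fv = encode_sequence(seq, cfg, only=only)
        except ValueError as e:
            raise ValueError(f"encoding failed for sequence {seq.id!r}: {e}") from e
        if names is None:
            names = fv.names
        rows.append(fv.values)
    return FeatureMatrix(data.ids, names, np.vstack(rows))


def encode_hybrid(data: LabeledDataset, cfg: EncoderConfig | None = None) -> FeatureMatrix:
    """The full 174-column hybrid feature matrix (default configuration)."""
    return encode_dataset(data, cfg, only=None)


@dataclass
class PcaModel:
    """Fitted PCA basis: column means, orthonormal components (rows) and
    their explained variances, plus the input feature schema.

    Component signs follow a deterministic convention — the
    largest-magnitude loading of each component is positive — so that
    serialized models are comparable across runs.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    n_components: int
    feature_names: tuple[str, ...]
    scale: np.ndarray | None = None

    def save(self, prefix: str | Path) -> None:
        """Serialize to ``<prefix>.json`` (schema) + ``<prefix>.npz`` (arrays)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "n_components": self.n_components,
            "feature_names": list(self.feature_names),
            "standardized": self.scale is not None,
        }
        Path(f"{prefix}.json").write_text(json.dumps(meta, indent=2))
        arrays = {
            "mean": self.mean,
            "components": self.components,
            "explained_variance": self.explained_variance,
        }
        if self.scale is not None:
            arrays["scale"] = self.scale
        np.savez(f"{prefix}.npz", **arrays)

    @classmethod
    def load(cls, prefix: str | Path) -> "PcaModel":
        meta = json.loads(Path(f"{prefix}.json").read_text())
        arrays = np.load(f"{prefix}.npz")
        return cls(
            mean=arrays["mean"],
            components=arrays["components"],
            explained_variance=arrays["explained_variance"],
            n_components=meta["n_components"],
            feature_names=tuple(meta["feature_names"]),
            scale=arrays["scale"] if "scale" in arrays else None,
        )


def fit_pca(
    train: FeatureMatrix,
    n_components: int | float = 75,
    standardize: bool = False,
) -> PcaModel:
    """Fit centered PCA on training rows only.

    ``n_components`` is either an integer component count or a fraction in
    (0, 1) interpreted as the minimum variance to retain. Components are
    sign-fixed so the largest-magnitude loading of each is positive.
    """
    n_rows, n_cols = train.shape
    if n_rows < 2:
        raise ValueError("PCA requires at least 2 training rows")
    if isinstance(n_components, float) and not 0 < n_components < 1:
        raise ValueError("fractional n_components must be in (0, 1)")
    if isinstance(n_components, (int, np.integer)):
        bound = min(n_rows - 1, n_cols)
        if not 1 <= n_components <= bound:
            raise ValueError(
                f"n_components={n_components} must be in [1, {bound}] "
                f"(min(rows-1, columns) for a {n_rows}x{n_cols} matrix)"
            )
    X = train.values
    scale = None
    if standardize:
        scale = X.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        X = (X - X.mean(axis=0)) / scale
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    # deterministic sign: flip so each component's largest |loading| is positive
    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] = -components[i]
    mean = train.values.mean(axis=0)
    return PcaModel(
        mean=mean,
        components=components,
        explained_variance=pca.explained_variance_.copy(),
        n_components=components.shape[0],
        feature_names=train.feature_names,
        scale=scale,
    )


def _check_schema(model: PcaModel, m: FeatureMatrix) -> None:
    if m.feature_names != model.feature_names:
        diff = set(m.feature_names) ^ set(model.feature_names)
        raise ValueError(
            f"feature schema mismatch; symmetric difference: {sorted(diff)[:10]}"
            + ("..." if len(diff) > 10 else "")
        )


def transform_pca(model: PcaModel, m: FeatureMatrix) -> FeatureMatrix:
    """Project a matrix with the same feature schema onto the fitted
    components. Output columns are named pc1..pcN; row order is preserved."""
    _check_schema(model, m)
    X = m.values - model.mean
    if model.scale is not None:
        X = X / model.scale
    scores = X @ model.components.T
    names = tuple(f"pc{i + 1}" for i in range(model.n_components))
    return FeatureMatrix(list(m.ids), names, scores)


def inverse_transform_pca(model: PcaModel, scores: FeatureMatrix) -> FeatureMatrix:
    """Map component scores back to the original feature space (lossy for
    n_components < rank)."""
    X = scores.values @ model.components
    if model.scale is not None:
        X = X * model.scale
    return FeatureMatrix(list(scores.ids), model.feature_names, X + model.mean)
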
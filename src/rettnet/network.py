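"""Network loadings (PCA over coherence features) and covariance
architecture matrices.

The 28 pairwise coherence features of every subject x timepoint row are
stacked into one table and decomposed by principal component analysis
fitted once on all rows, so component scores ("network loadings") share a
common basis across groups and timepoints and can be compared between
design cells.  Features are centred but not variance-standardised: all are
coherences on a common [0, 1] scale, and leaving the scale intact preserves
the covariance interpretation of the architecture matrices.

Follows the statsmodels convention: ``NetworkPCA(table).fit()`` returns a
results object carrying loadings, scores, explained variances and a
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .exceptions import DegenerateInputError
from .montage import PAIR_LABELS

META_COLUMNS = ["subject_id", "group", "design_group", "timepoint",
                "responder"]


class FeatureTable:
    """One row per subject x timepoint: 28 coherence features plus metadata.

    Wraps a DataFrame whose metadata columns are (a subset of)
    ``META_COLUMNS`` and whose feature columns default to the canonical
    pair labels.  All feature values must be finite and in [0, 1].
    """

    def __init__(self, df: pd.DataFrame,
                 feature_columns: list[str] | None = None) -> None:
        self.df = df.reset_index(drop=True)
        if feature_columns is None:
            feature_columns = [c for c in PAIR_LABELS if c in df.columns]
        if not feature_columns:
            raise DegenerateInputError("no feature columns found")
        missing = [c for c in feature_columns if c not in df.columns]
        if missing:
            raise DegenerateInputError(f"missing feature columns {missing}")
        self.feature_columns = list(feature_columns)
        vals = self.features
        if not np.all(np.isfinite(vals)):
            raise DegenerateInputError("non-finite feature values")
        if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise DegenerateInputError("coherence features must lie in [0, 1]")

    @property
    def features(self) -> np.ndarray:
        return self.df[self.feature_columns].to_numpy(dtype=float)

    @property
    def meta(self) -> pd.DataFrame:
        cols = [c for c in META_COLUMNS if c in self.df.columns]
        return self.df[cols]

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def rows(self, **criteria) -> "FeatureTable":
        """Subset by metadata equality, e.g. rows(group="treated",
        timepoint="baseline")."""
        mask = pd.Series(True, index=self.df.index)
        for col, val in criteria.items():
            if val is not None:
                mask &= self.df[col] == val
        return FeatureTable(self.df[mask], self.feature_columns)


@dataclass
class NetworkPCAResults:
    """Fitted network-loading decomposition.

    loadings: (n_components, n_features) orthonormal rows, sign-fixed so
        each row's largest-magnitude element is positive.
    scores: (n_rows, n_components) projections of the centred features.
    explained_variance: sample (ddof=1) variance along each component;
        sums to the total feature variance.
    n_retained: smallest k whose cumulative explained variance ratio
        reaches the retention threshold.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean_: np.ndarray
    n_retained: int
    feature_names: list[str]
    meta: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def retained_scores(self) -> pd.DataFrame:
        """Scores of the retained components, with metadata columns."""
        cols = {f"PC{k + 1}": self.scores[:, k]
                for k in range(self.n_retained)}
        out = pd.DataFrame(cols)
        if self.meta is not None:
            out = pd.concat([self.meta.reset_index(drop=True), out], axis=1)
        return out

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        """Reconstruct (centred) features from the first k components."""
        k = self.n_components if k is None else k
        return self.scores[:, :k] @ self.loadings[:k] + self.mean_

    def summary(self) -> str:
        lines = ["Network PCA", "=" * 11,
                 f"rows: {self.scores.shape[0]}  "
                 f"features: {len(self.feature_names)}  "
                 f"retained: {self.n_retained}"]
        cum = np.cumsum(self.explained_variance_ratio)
        for k in range(min(self.n_components, 10)):
            lines.append(
                f"PC{k + 1}: var {self.explained_variance[k]:.5f}  "
                f"ratio {self.explained_variance_ratio[k]:.3f}  "
                f"cumulative {cum[k]:.3f}")
        return "\n".join(lines)


class NetworkPCA:
    """PCA model over a coherence feature table (fit once on all rows)."""

    def __init__(self, table: FeatureTable,
                 retention: float = 0.9) -> None:
        if table.n_rows < 2:
            raise DegenerateInputError("PCA needs at least 2 rows")
        if not 0 < retention <= 1:
            raise DegenerateInputError("retention threshold must be in (0, 1]")
        self.table = table
        self.retention = retention

    def fit(self) -> NetworkPCAResults:
        x = self.table.features
        pca = PCA(svd_solver="full")
        scores = pca.fit_transform(x)
        loadings = pca.components_
        # sign convention: largest-magnitude element of each loading positive
        flip = np.sign(loadings[np.arange(loadings.shape[0]),
                                np.argmax(np.abs(loadings), axis=1)])
        flip[flip == 0] = 1.0
        loadings = loadings * flip[:, None]
        scores = scores * flip[None, :]
        ratio = pca.explained_variance_ratio_
        cum = np.cumsum(ratio)
        n_retained = int(np.searchsorted(cum, self.retention - 1e-12) + 1)
        n_retained = min(n_retained, loadings.shape[0])
        return NetworkPCAResults(
            loadings=loadings,
            scores=scores,
            explained_variance=pca.explained_variance_,
            explained_variance_ratio=ratio,
            mean_=pca.mean_,
            n_retained=n_retained,
            feature_names=list(self.table.feature_columns),
            meta=self.table.meta.copy(),
        )


def fit_network_pca(table: FeatureTable,
                    retention: float = 0.9) -> NetworkPCAResults:
    """Functional shorthand for ``NetworkPCA(table, retention).fit()``."""
    return NetworkPCA(table, retention).fit()


@dataclass
class ArchitectureMatrix:
    """Covariance (or correlation) of coherence features within one
    group x timepoint cell; symmetric positive semi-definite."""

    matrix: np.ndarray
    feature_names: list[str]
    cell: dict[str, str]
    n_rows: int
    kind: str = "covariance"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.feature_names,
                            columns=self.feature_names)


def architecture(table: FeatureTable, kind: str = "covariance",
                 **cell) -> ArchitectureMatrix:
    """Sample covariance of the feature rows in one design cell, e.g.
    ``architecture(ft, group="treated", timepoint="baseline")``."""
    sub = table.rows(**cell)
    if sub.n_rows < 2:
        raise DegenerateInputError(
            f"cell {cell} has {sub.n_rows} row(s); covariance needs >= 2")
    x = sub.features
    if kind == "covariance":
        mat = np.cov(x, rowvar=False, ddof=1)
    elif kind == "correlation":
        sd = x.std(axis=0, ddof=1)
        safe = np.where(sd > 0, sd, 1.0)
        mat = np.cov(x, rowvar=False, ddof=1) / np.outer(safe, safe)
        np.fill_diagonal(mat, np.where(sd > 0, 1.0, 0.0))
    else:
        raise ValueError(f"unknown architecture kind {kind!r}")
    mat = np.atleast_2d(mat)
    return ArchitectureMatrix(matrix=mat,
                              feature_names=list(sub.feature_columns),
                              cell={k: v for k, v in cell.items()},
                              n_rows=sub.n_rows, kind=kind)
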
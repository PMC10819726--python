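"""Correlation-matrix PCA with a weighted comprehensive evaluation score.

The feature table is z-scored column-wise, the correlation matrix of the
standardized data is eigendecomposed, and components are retained until
their cumulative contribution rate (share of total variance) reaches a
threshold, 85% by default.  Each retained component i then receives the
weight w_i = C_i / delta_k — its contribution rate divided by the
cumulative contribution of the k retained components — and the weighted
sum of a sample's component scores is its *comprehensive evaluation
score*, a single scalar summarizing the clip's position in feature
space.  That scalar is used downstream as an extra classifier input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import ValidationError

__all__ = [
    "FeatureMatrix",
    "PCAModel",
    "ScoredSamples",
    "zscore",
    "correlation_matrix",
    "eigendecompose",
    "contribution_rates",
    "select_components",
    "loadings",
    "pc_scores",
    "comprehensive_score",
    "fit_transform",
]


@dataclass
class FeatureMatrix:
    """n_samples x n_features numeric matrix with per-row labels."""

    X: np.ndarray
    labels: np.ndarray | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] < 2:
            raise ValidationError("feature matrix must be 2-D with at least 2 samples")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("feature matrix contains missing/non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.X.shape[0]:
                raise ValidationError("labels length must match the number of rows")
        if self.feature_names is not None and len(self.feature_names) != self.X.shape[1]:
            raise ValidationError("feature_names length must match the number of columns")


@dataclass
class ScoredSamples:
    """Component scores F (n x k) and the comprehensive score per sample."""

    F: np.ndarray
    f_comprehensive: np.ndarray
    labels: np.ndarray | None = None


@dataclass
class PCAModel:
    """Fitted standardization constants and correlation eigenstructure."""

    means: np.ndarray
    stds: np.ndarray
    R: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns are unit-norm eigenvectors
    contributions: np.ndarray
    cumulative: np.ndarray
    k: int
    weights: np.ndarray
    loadings: np.ndarray
    threshold: float
    feature_names: list[str] | None = None

    def transform(self, X: np.ndarray, labels=None) -> ScoredSamples:
        """Score new rows using the stored training-fit statistics."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.means):
            raise ValidationError(
                f"expected {len(self.means)} features, got {X.shape[1]}"
            )
        Z = (X - self.means) / self.stds
        F = pc_scores(Z, self.eigenvectors, self.k)
        return ScoredSamples(
            F=F,
            f_comprehensive=comprehensive_score(F, self.contributions, self.k),
            labels=None if labels is None else np.asarray(labels),
        )

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "contributions": self.contributions.tolist(),
            "cumulative": self.cumulative.tolist(),
            "k": int(self.k),
            "weights": self.weights.tolist(),
            "threshold": self.threshold,
            "feature_names": self.feature_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        eigenvectors = np.asarray(d["eigenvectors"], dtype=float)
        eigenvalues = np.asarray(d["eigenvalues"], dtype=float)
        return cls(
            means=np.asarray(d["means"], dtype=float),
            stds=np.asarray(d["stds"], dtype=float),
            R=np.empty((0, 0)),
            eigenvalues=eigenvalues,
            eigenvectors=eigenvectors,
            contributions=np.asarray(d["contributions"], dtype=float),
            cumulative=np.asarray(d["cumulative"], dtype=float),
            k=int(d["k"]),
            weights=np.asarray(d["weights"], dtype=float),
            loadings=loadings(eigenvectors, eigenvalues),
            threshold=float(d["threshold"]),
            feature_names=d.get("feature_names"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def zscore(X: np.ndarray, feature_names=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize columns: Z = (x - mean) / sd with the n-1 sample sd."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(stds == 0)
    if bad.size:
        names = (
            [feature_names[j] for j in bad] if feature_names is not None else bad.tolist()
        )
        raise ValidationError(f"zero-variance feature column(s): {names}")
    return (X - means) / stds, means, stds


def correlation_matrix(Z: np.ndarray) -> np.ndarray:
    """Correlation matrix of standardized data: R = Z'Z / (n - 1)."""
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 samples for a correlation matrix")
    R = (Z.T @ Z) / (n - 1)
    return np.clip((R + R.T) / 2.0, -1.0, 1.0)


def eigendecompose(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and unit-norm eigenvector columns of R.

    The sign of each eigenvector is fixed so its largest-magnitude entry
    is positive, making scores reproducible across numeric backends.
    """
    R = np.asarray(R, dtype=float)
    if R.shape[0] != R.shape[1] or np.abs(R - R.T).max() > 1e-8:
        raise ValidationError("correlation matrix must be symmetric")
    values, vectors = np.linalg.eigh(R)
    order = np.argsort(values)[::-1]
    values, vectors = values[order], vectors[:, order]
    for i in range(vectors.shape[1]):
        j = np.argmax(np.abs(vectors[:, i]))
        if vectors[j, i] < 0:
            vectors[:, i] = -vectors[:, i]
    return values, vectors


def contribution_rates(eigenvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Contribution rates C_i = lambda_i / sum(lambda) and their cumsum."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    total = eigenvalues.sum()
    if total <= 0:
        raise ValidationError("eigenvalues sum to zero: no variance to attribute")
    C = eigenvalues / total
    return C, np.cumsum(C)


def select_components(cumulative: np.ndarray, threshold: float = 0.85) -> int:
    """Smallest k whose cumulative contribution rate reaches the threshold."""
    cumulative = np.asarray(cumulative, dtype=float)
    hits = np.flatnonzero(cumulative >= threshold)
    return int(hits[0]) + 1 if hits.size else len(cumulative)


def loadings(
    eigenvectors: np.ndarray, eigenvalues: np.ndarray, convention: str = "sqrt"
) -> np.ndarray:
    """Component loadings.

    ``sqrt`` (default): a_i * sqrt(lambda_i), the correlation between each
    feature and component, so column i's squared entries sum to lambda_i.
    ``raw``: a_i * lambda_i.  Loadings are descriptive only; neither
    convention affects scores or classification.
    """
    eigenvalues = np.maximum(np.asarray(eigenvalues, dtype=float), 0.0)
    if convention == "sqrt":
        return eigenvectors * np.sqrt(eigenvalues)
    if convention == "raw":
        return eigenvectors * eigenvalues
    raise ValidationError("loading convention must be 'sqrt' or 'raw'")


def pc_scores(Z: np.ndarray, eigenvectors: np.ndarray, k: int) -> np.ndarray:
    """Project standardized rows onto the first k eigenvectors: F = Z A_k."""
    return np.asarray(Z, dtype=float) @ eigenvectors[:, :k]


def comprehensive_score(F: np.ndarray, contributions: np.ndarray, k: int) -> np.ndarray:
    """Weighted sum of component scores with w_i = C_i / delta_k."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if F.shape[1] != k:
        raise ValidationError(f"score matrix must have k={k} columns")
    w = component_weights(contributions, k)
    return F @ w


def component_weights(contributions: np.ndarray, k: int) -> np.ndarray:
    contributions = np.asarray(contributions, dtype=float)
    delta_k = contributions[:k].sum()
    return contributions[:k] / delta_k


def fit_transform(
    data: FeatureMatrix, threshold: float = 0.85
) -> tuple[PCAModel, ScoredSamples]:
    """Fit the PCA model on a feature matrix and score its own rows."""
    Z, means, stds = zscore(data.X, data.feature_names)
    R = correlation_matrix(Z)
    eigenvalues, eigenvectors = eigendecompose(R)
    C, cumulative = contribution_rates(eigenvalues)
    k = select_components(cumulative, threshold)
    model = PCAModel(
        means=means,
        stds=stds,
        R=R,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        contributions=C,
        cumulative=cumulative,
        k=k,
        weights=component_weights(C, k),
        loadings=loadings(eigenvectors, eigenvalues),
        threshold=threshold,
        feature_names=data.feature_names,
    )
    F = pc_scores(Z, eigenvectors, k)
    scored = ScoredSamples(
        F=F,
        f_comprehensive=comprehensive_score(F, C, k),
        labels=data.labels,
    )
    return model, scored


def scored_to_frame(scored: ScoredSamples, ids=None) -> pd.DataFrame:
    """Scored-sample table ``id,label,F1..Fk,Fcomprehensive``."""
    k = scored.F.shape[1]
    df = pd.DataFrame(scored.F, columns=[f"F{i+1}" for i in range(k)])
    df.insert(0, "label", scored.labels if scored.labels is not None else None)
    df.insert(0, "id", ids if ids is not None else np.arange(len(df)))
    df["Fcomprehensive"] = scored.f_comprehensive
    return df
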
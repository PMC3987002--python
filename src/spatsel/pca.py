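"""Correlation-matrix PCA of exposure variables.

Chemicals are measured on wildly different scales (µg/kg vs µg/L, metals vs
solvents), so components are extracted from the sample *correlation* matrix
— equivalently, PCA of the column-standardized exposure matrix. Components
are retained until they explain at least 80% of total variance; per-component
signed loadings above a display cutoff summarise which chemicals drive each
score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CorrelationPCA",
    "PCAResult",
    "LoadingReport",
    "correlation_pca",
    "retain_components",
    "loading_report",
]


@dataclass
class PCAResult:
    """Eigenstructure of the exposure correlation matrix.

    eigenvalues sum to the number of variables; loadings columns are the
    (sign-pinned) orthonormal eigenvectors; scores are the standardized data
    projected on them.
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # chemicals x components
    scores: pd.DataFrame  # participants x components
    variance_fractions: np.ndarray


@dataclass
class LoadingReport:
    """Per retained component, the chemicals with |loading| >= cutoff and signs."""

    components: list[list[tuple[str, str]]]  # [(chemical, '+'|'-'), ...] per comp
    cutoff: float

    def to_text(self) -> str:
        lines = []
        for i, comp in enumerate(self.components, start=1):
            body = ", ".join(f"{name}({sign})" for name, sign in comp) or "(none)"
            lines.append(f"{i}: {body}")
        return "\n".join(lines)


class CorrelationPCA(BaseEstimator, TransformerMixin):
    """PCA on the sample correlation matrix of an exposure table.

    Parameters
    ----------
    threshold : cumulative variance fraction components must reach; the
        smallest such count is stored as ``n_components_retained_``.

    Attributes
    ----------
    eigenvalues_ : nonincreasing eigenvalues (they sum to n_features).
    loadings_ : (n_features, n_features) eigenvector matrix; each column is
        flipped so its largest-magnitude entry is negative, pinning the
        otherwise arbitrary eigenvector sign.
    variance_fractions_ : eigenvalues / n_features.
    n_components_retained_ : smallest k with cumulative fraction >= threshold.
    """

    def __init__(self, threshold: float = 0.80):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("need at least 2 rows and 2 columns for correlation PCA")
        vals = X.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("exposure matrix contains non-finite entries; "
                             "drop or impute upstream")
        std = vals.std(axis=0, ddof=1)
        # tolerance: a column of identical values accumulates ~1e-16 noise
        tiny = 1e-12 * np.maximum(1.0, np.abs(vals.mean(axis=0)))
        constant = [str(c) for c, s, t in zip(X.columns, std, tiny) if s <= t]
        if constant:
            raise ValueError(f"constant column(s) not allowed in correlation PCA: {constant}")
        corr = np.corrcoef(vals, rowvar=False)
        w, v = np.linalg.eigh(corr)
        order = np.argsort(w)[::-1]
        w = np.clip(w[order], 0.0, None)
        v = v[:, order]
        # pin signs: largest-|.| element of each eigenvector made negative
        for j in range(v.shape[1]):
            i = np.argmax(np.abs(v[:, j]))
            if v[i, j] > 0:
                v[:, j] = -v[:, j]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.mean_ = vals.mean(axis=0)
        self.scale_ = std
        self.eigenvalues_ = w
        self.loadings_ = v
        self.variance_fractions_ = w / w.sum()
        cum = np.cumsum(self.variance_fractions_)
        self.n_components_retained_ = int(np.searchsorted(cum, self.threshold - 1e-12) + 1)
        return self

    def transform(self, X) -> np.ndarray:
        """Scores: standardized X projected on the eigenvectors."""
        X = pd.DataFrame(X)
        z = (X.to_numpy(dtype=float) - self.mean_) / self.scale_
        return z @ self.loadings_

    def result(self, X) -> PCAResult:
        """Package the fit plus scores of X as a :class:`PCAResult`."""
        comp_names = [f"PC{j + 1}" for j in range(len(self.eigenvalues_))]
        scores = pd.DataFrame(
            self.transform(X), index=pd.DataFrame(X).index, columns=comp_names
        )
        loadings = pd.DataFrame(
            self.loadings_, index=self.feature_names_in_, columns=comp_names
        )
        return PCAResult(
            eigenvalues=self.eigenvalues_.copy(),
            loadings=loadings,
            scores=scores,
            variance_fractions=self.variance_fractions_.copy(),
        )


def correlation_pca(X) -> PCAResult:
    """Fit :class:`CorrelationPCA` on X and return its :class:`PCAResult`."""
    est = CorrelationPCA()
    est.fit(X)
    return est.result(X)


def retain_components(r: PCAResult, threshold: float = 0.80) -> tuple[int, pd.DataFrame]:
    """Smallest k whose cumulative variance fraction reaches the threshold,
    plus the first k score columns."""
    cum = np.cumsum(r.variance_fractions)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, r.scores.shape[1])
    return k, r.scores.iloc[:, :k]


def loading_report(r: PCAResult, k: int, cutoff: float = 0.30) -> LoadingReport:
    """Signed-loading summary of the first k components.

    Chemicals whose |loading| falls below the cutoff "didn't load" and are
    omitted.
    """
    if k > r.loadings.shape[1]:
        raise ValueError(f"k={k} exceeds the {r.loadings.shape[1]} available components")
    comps = []
    for j in range(k):
        col = r.loadings.iloc[:, j]
        entries = [
            (str(name), "+" if val > 0 else "-")
            for name, val in col.items()
            if abs(val) >= cutoff
        ]
        comps.append(entries)
    return LoadingReport(components=comps, cutoff=cutoff)
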
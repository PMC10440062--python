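"""Ordination of Procrustes shape data: PCA and between-group PCA with
leave-one-out cross-validated classification.

Between-group PCA (bgPCA) takes as its axes the principal components of
the group mean shapes and projects individuals onto them. Unlike
canonical variate analysis it does not rescale by the within-group
covariance, so it does not exaggerate group separation; with g groups
there are at most g - 1 axes.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EIG_RTOL = 1e-10


@dataclasses.dataclass
class PCAResult:
    scores: np.ndarray              # (N, p)
    components: np.ndarray          # (p, d) orthonormal rows
    eigenvalues: np.ndarray         # descending
    variance_fractions: np.ndarray
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.mean[None] + self.scores @ self.components


def pca(X: np.ndarray) -> PCAResult:
    """Principal component analysis of mean-centred rows.

    Components with eigenvalue below ``1e-10 x`` the largest are
    dropped (numerically null shape dimensions).
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pca needs an (N >= 2) x d matrix")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (X.shape[0] - 1)
    keep = eig > _EIG_RTOL * (eig[0] if eig.size else 0.0)
    U, s, Vt, eig = U[:, keep], s[keep], Vt[keep], eig[keep]
    total = eig.sum()
    fractions = eig / total if total > 0 else eig
    return PCAResult(
        scores=U * s,
        components=Vt,
        eigenvalues=eig,
        variance_fractions=fractions,
        mean=mean,
    )


# ----------------------------------------------------------------------

@dataclasses.dataclass
class BetweenGroupPCAResults:
    """Fitted between-group PCA: axes, scores and cross-validation."""

    labels: list
    group_means: np.ndarray         # (g, d), label order
    axes: np.ndarray                # (n_axes, d) orthonormal rows
    scores: np.ndarray              # (N, n_axes)
    groups: np.ndarray
    degenerate: bool
    cv_table: pd.DataFrame | None = None
    cv_accuracy: float | None = None

    @property
    def n_axes(self) -> int:
        return self.axes.shape[0]

    def summary(self) -> str:
        lines = [
            f"Between-group PCA: {len(self.labels)} groups, {self.n_axes} axis/axes",
        ]
        if self.cv_accuracy is not None:
            lines.append(f"Leave-one-out classification accuracy: {self.cv_accuracy:.3f}")
            lines.append(str(self.cv_table))
        return "\n".join(lines)


class BetweenGroupPCA:
    """Between-group PCA model over a shape matrix and group labels."""

    def __init__(self, X: np.ndarray, groups):
        X = np.asarray(X, float)
        groups = np.asarray(groups)
        if X.shape[0] != groups.shape[0]:
            raise ValueError("X and groups must have the same number of rows")
        labels, counts = np.unique(groups, return_counts=True)
        if labels.size < 2:
            raise ValueError("between-group PCA needs at least two groups")
        if np.any(counts == 0):
            raise ValueError("every group needs at least one member")
        self.X = X
        self.groups = groups
        self.labels = list(labels)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, shape_columns, group_column: str):
        return cls(data.loc[:, list(shape_columns)].to_numpy(float), data[group_column].to_numpy())

    def fit(self, cv: bool = True) -> BetweenGroupPCAResults:
        means = np.stack([self.X[self.groups == g].mean(axis=0) for g in self.labels])
        grand = means.mean(axis=0)
        axes, degenerate = _mean_axes(means, grand)
        if degenerate:
            logger.warning("between-group PCA: group means coincide; no axes retained")
        scores = (self.X - grand) @ axes.T
        result = BetweenGroupPCAResults(
            labels=self.labels,
            group_means=means,
            axes=axes,
            scores=scores,
            groups=self.groups,
            degenerate=degenerate,
        )
        if cv and not degenerate:
            result.cv_table, result.cv_accuracy = loo_classify(self.X, self.groups)
        return result


def _mean_axes(means: np.ndarray, grand: np.ndarray):
    B = means - grand
    U, s, Vt = np.linalg.svd(B, full_matrices=False)
    if s.size == 0 or s[0] <= 0 or not np.any(s > 1e-12 * s[0]):
        return np.empty((0, means.shape[1])), True
    keep = s > 1e-12 * s[0]
    return Vt[keep], False


def loo_classify(X: np.ndarray, groups):
    """Leave-one-out cross-validated bgPCA classification.

    Each specimen is held out; group means and between-group axes are
    re-estimated from the remainder; the held-out specimen is assigned
    to the group whose projected mean is nearest in score space (ties
    go to the first label in sorted order).

    Returns a (true x predicted) confusion DataFrame and the accuracy.
    """
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if np.any(counts < 2):
        small = labels[counts < 2]
        raise ValueError(f"leave-one-out needs every group size >= 2; too small: {list(small)}")
    label_index = {g: j for j, g in enumerate(labels)}
    sums = np.stack([X[groups == g].sum(axis=0) for g in labels])
    table = np.zeros((labels.size, labels.size), dtype=int)
    for i in range(X.shape[0]):
        gi = label_index[groups[i]]
        means = sums / counts[:, None]
        means[gi] = (sums[gi] - X[i]) / (counts[gi] - 1)
        grand = means.mean(axis=0)
        axes, degenerate = _mean_axes(means, grand)
        if degenerate:
            predicted = 0   # indistinguishable means: first label
        else:
            zi = (X[i] - grand) @ axes.T
            zm = (means - grand) @ axes.T
            predicted = int(np.argmin(((zm - zi) ** 2).sum(axis=1)))
        table[gi, predicted] += 1
    cv_table = pd.DataFrame(table, index=labels, columns=labels)
    cv_table.index.name = "true"
    cv_table.columns.name = "predicted"
    accuracy = float(np.trace(table) / X.shape[0])
    return cv_table, accuracy


def between_group_pca(X: np.ndarray, groups, cv: bool = True) -> BetweenGroupPCAResults:
    """Convenience wrapper: ``BetweenGroupPCA(X, groups).fit(cv=cv)``."""
    return BetweenGroupPCA(X, groups).fit(cv=cv)
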
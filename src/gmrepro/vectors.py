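"""Paired multivariate comparisons of mean shapes: repeated-measures
Hotelling's T², angles between shape-change vectors, inter-operator
difference vectors and bootstrapped group distances.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy import special, stats

_EIG_RTOL = 1e-10


@dataclasses.dataclass
class RepeatedMeasuresResult:
    """Paired Hotelling T² between two sets of matched multivariate scores."""

    euclidean_distance: float
    T2: float
    F: float
    df1: int
    df2: int
    p: float

    def summary(self) -> str:
        return (
            f"Repeated-measures Hotelling T2={self.T2:.4f}, "
            f"F({self.df1}, {self.df2})={self.F:.4f}, p={self.p:.4g}, "
            f"Euclidean distance between means={self.euclidean_distance:.6g}"
        )


def repeated_measures_t2(set_a: np.ndarray, set_b: np.ndarray) -> RepeatedMeasuresResult:
    """Test whether two sets of paired observations share a mean.

    Rows must be paired by specimen. The paired differences are reduced
    to the dimensions in which they actually vary (eigenvalues of the
    difference covariance above ``1e-10 x`` the largest — at most N - 1
    dimensions), then ``T² = N d̄' S⁻¹ d̄`` with
    ``F = T² (N - p) / (p (N - 1)) ~ F(p, N - p)``.
    """
    A = np.asarray(set_a, float)
    B = np.asarray(set_b, float)
    if A.shape != B.shape:
        raise ValueError(f"paired sets must match in shape: {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least three paired rows")
    d = A - B
    scale = max(float(np.abs(A).max()), float(np.abs(B).max()), 1e-300)
    if float(np.abs(d).max()) <= 1e-9 * scale:
        # numerically identical paired sets
        return RepeatedMeasuresResult(0.0, 0.0, 0.0, 0, n - 1, 1.0)
    dbar = d.mean(axis=0)
    distance = float(np.linalg.norm(A.mean(axis=0) - B.mean(axis=0)))
    dc = d - dbar
    U, s, Vt = np.linalg.svd(dc, full_matrices=False)
    eig = s ** 2 / (n - 1)
    if eig.size == 0 or eig[0] <= 0:
        return RepeatedMeasuresResult(distance, 0.0, 0.0, 0, n - 1, 1.0)
    keep = eig > _EIG_RTOL * eig[0]
    eig = eig[keep]
    V = Vt[keep]
    p = int(eig.size)
    if n - p < 1:
        raise ValueError(
            f"difference covariance rank {p} leaves no error degrees of freedom at "
            f"N={n}; reduce the scores to fewer principal components"
        )
    z = V @ dbar
    T2 = float(n * np.sum(z ** 2 / eig))
    F = T2 * (n - p) / (p * (n - 1))
    pval = float(stats.f.sf(F, p, n - p))
    return RepeatedMeasuresResult(distance, T2, float(F), p, n - p, pval)


# ----------------------------------------------------------------------

@dataclasses.dataclass
class AngleTestResult:
    """Angle between two direction vectors with its null probability.

    ``p_value`` is the probability that two uniformly random directions
    in p dimensions subtend an angle at most as large as the one
    observed; small values mean the vectors are more aligned than
    chance.
    """

    angle_deg: float
    dims: int
    p_value: float

    def summary(self) -> str:
        return f"angle {self.angle_deg:.2f} deg in {self.dims} dims, p={self.p_value:.3g}"


def angle_test(v1: np.ndarray, v2: np.ndarray) -> AngleTestResult:
    """Angle between two shape-change vectors and its uniform-null p-value.

    Under the null the cosine follows the projection of a uniform
    direction on the (p-1)-sphere, with density proportional to
    ``sin^(p-2)(theta)``; the CDF is evaluated with the regularised
    incomplete beta function, so orthogonal vectors give exactly 0.5.
    """
    v1 = np.asarray(v1, float).ravel()
    v2 = np.asarray(v2, float).ravel()
    if v1.shape != v2.shape:
        raise ValueError("vectors must have the same dimension")
    p = v1.size
    if p < 2:
        raise ValueError("angle test needs vectors of dimension >= 2")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero vector has no direction")
    cos = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cos)))
    s2 = max(1.0 - cos ** 2, 0.0)
    half = 0.5 * float(special.betainc((p - 1) / 2.0, 0.5, s2))
    p_value = half if cos >= 0 else 1.0 - half
    return AngleTestResult(angle_deg=angle, dims=p, p_value=p_value)


def operator_difference_vector(aligned_a: np.ndarray, aligned_b: np.ndarray) -> np.ndarray:
    """Mean per-specimen difference of superimposed coordinates.

    Rows must be paired by specimen; by linearity this equals the
    difference of the two mean shapes.
    """
    A = np.asarray(aligned_a, float)
    B = np.asarray(aligned_b, float)
    if A.shape != B.shape:
        raise ValueError(f"paired sets must match in shape: {A.shape} vs {B.shape}")
    return (A - B).mean(axis=0)


# ----------------------------------------------------------------------

@dataclasses.dataclass
class BootstrapDistanceResult:
    """Bootstrap distribution of the distance between two group mean shapes."""

    mean_distance: float
    median_distance: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    seed: int | None

    def summary(self) -> str:
        return (
            f"bootstrap distance: mean={self.mean_distance:.6g}, "
            f"median={self.median_distance:.6g}, "
            f"95% CI=({self.ci_lower:.6g}, {self.ci_upper:.6g}), "
            f"n_boot={self.n_boot}"
        )


def bootstrap_group_distance(shape: np.ndarray, groups, n_boot: int = 1000,
                             seed: int | None = None, ci: float = 0.95) -> BootstrapDistanceResult:
    """Bootstrap estimate of the Euclidean distance between the mean
    shapes of two groups (resampling with replacement within each group,
    sizes preserved)."""
    X = np.asarray(shape, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"exactly two groups required, found {labels.size}")
    a = X[groups == labels[0]]
    b = X[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two members")
    rng = np.random.default_rng(seed)
    dists = np.empty(n_boot)
    for i in range(n_boot):
        ma = a[rng.integers(0, len(a), len(a))].mean(axis=0)
        mb = b[rng.integers(0, len(b), len(b))].mean(axis=0)
        dists[i] = np.linalg.norm(ma - mb)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(dists, [alpha, 1.0 - alpha])
    return BootstrapDistanceResult(
        mean_distance=float(dists.mean()),
        median_distance=float(np.median(dists)),
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_boot=n_boot,
        seed=seed,
    )
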
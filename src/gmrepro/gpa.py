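"""Procrustes geometry: centroid size, pairwise fits, generalised
Procrustes analysis with sliding semi-landmarks, unbending, outliers.

Conventions
-----------
Partial Procrustes superimposition: every configuration is centred and
scaled to unit centroid size, then rotated (rotation only, no
reflection — all specimens are photographed from the same side) onto
the evolving consensus. Semi-landmarks slide along the chord between
their neighbouring landmarks of the *current specimen* by the scalar
minimising distance to the consensus. Centroid sizes are retained in
the original units for allometric analyses.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .base import LandmarkScheme, ShapeDataset

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# elementary geometry

def centroid_size(points: np.ndarray) -> float:
    """Root summed squared distances of landmarks to their centroid."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need a (k >= 2) x 2 configuration")
    c = pts - pts.mean(axis=0)
    size = float(np.sqrt((c ** 2).sum()))
    if size == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return size


def centroid_sizes(coords: np.ndarray) -> np.ndarray:
    """Vectorised centroid size for an (N, k, 2) block."""
    c = coords - coords.mean(axis=1, keepdims=True)
    s = np.sqrt((c ** 2).sum(axis=(1, 2)))
    if np.any(s == 0.0):
        raise ValueError("degenerate configuration: all landmarks coincide")
    return s


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared coordinate differences of superimposed shapes."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"landmark count mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))


def _rotation_angle(moving_c: np.ndarray, ref_c: np.ndarray) -> float:
    """Least-squares rotation angle (radians) of a centred configuration
    onto a centred reference; determinant +1 by construction."""
    dot = float((moving_c * ref_c).sum())
    cross = float((moving_c[:, 0] * ref_c[:, 1] - moving_c[:, 1] * ref_c[:, 0]).sum())
    return float(np.arctan2(cross, dot))


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclasses.dataclass(frozen=True)
class PairFit:
    """Least-squares similarity alignment of one configuration onto another."""

    angle: float              # rotation in radians (counter-clockwise)
    scale: float
    translation: np.ndarray   # applied after rotation and scaling
    residual: float           # partial Procrustes distance of unit-size forms

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(self.angle))

    @property
    def rotation(self) -> np.ndarray:
        return _rot(self.angle)


def fit_pair(moving: np.ndarray, reference: np.ndarray) -> PairFit:
    """Optimal similarity transform mapping ``moving`` onto ``reference``.

    The transform is ``x -> scale * R x + translation`` minimising the
    summed squared distance to the reference; reflections are not
    allowed. The residual is the root summed squared difference between
    the centred, unit-centroid-size forms after rotation.
    """
    moving = np.asarray(moving, float)
    reference = np.asarray(reference, float)
    if moving.shape != reference.shape:
        raise ValueError(f"landmark count mismatch: {moving.shape} vs {reference.shape}")
    cm = moving.mean(axis=0)
    cr = reference.mean(axis=0)
    X = moving - cm
    Y = reference - cr
    sx = centroid_size(moving)
    sy = centroid_size(reference)
    theta = _rotation_angle(X, Y)
    R = _rot(theta)
    RX = X @ R.T
    beta = float((Y * RX).sum() / (X ** 2).sum())
    translation = cr - beta * (R @ cm)
    residual = float(np.sqrt(((Y / sy - RX / sx) ** 2).sum()))
    return PairFit(angle=theta, scale=beta, translation=translation, residual=residual)


# ----------------------------------------------------------------------
# sliding semi-landmarks

def slide_semilandmarks(
    config: np.ndarray, reference: np.ndarray, scheme: LandmarkScheme
) -> np.ndarray:
    """Slide semi-landmarks along their tangent towards the reference.

    The tangent of each semi-landmark is the unit chord from its
    previous to its next neighbour in the *current* configuration; the
    landmark is moved along it by the least-squares projection of its
    offset from the reference (the minimum Procrustes distance
    criterion). Fixed landmarks are untouched.
    """
    out = np.array(config, dtype=float)
    semi0 = scheme.semi0
    if semi0.size == 0:
        return out
    prev0, next0 = scheme.prev0, scheme.next0
    tang = out[next0] - out[prev0]
    norms = np.sqrt((tang ** 2).sum(axis=1))
    ok = norms > 1e-12
    if not np.all(ok):
        logger.warning(
            "zero-length sliding tangent at semi-landmark(s) %s; left unmoved",
            list((semi0[~ok] + 1)),
        )
    u = np.zeros_like(tang)
    u[ok] = tang[ok] / norms[ok, None]
    shift = ((reference[semi0] - out[semi0]) * u).sum(axis=1)
    out[semi0] += shift[:, None] * u
    return out


def _slide_block(coords: np.ndarray, reference: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Vectorised sliding of an (N, k, 2) block against one reference."""
    semi0 = scheme.semi0
    if semi0.size == 0:
        return coords
    prev0, next0 = scheme.prev0, scheme.next0
    out = coords.copy()
    tang = out[:, next0] - out[:, prev0]
    norms = np.sqrt((tang ** 2).sum(axis=2))
    ok = norms > 1e-12
    u = np.zeros_like(tang)
    u[ok] = tang[ok] / norms[ok][:, None]
    shift = ((reference[semi0][None] - out[:, semi0]) * u).sum(axis=2)
    out[:, semi0] += shift[..., None] * u
    return out


# ----------------------------------------------------------------------
# unbending

def unbend(dataset: ShapeDataset, degree: int = 2) -> ShapeDataset:
    """Remove body-arching by straightening a polynomial through the
    scheme's unbend landmarks.

    Per configuration: rotate so the chord through the first and last
    unbend landmarks is horizontal, fit ``y = polynomial(x)`` of the
    given degree through the unbend landmarks by least squares, subtract
    the fitted curve (the chord itself is the zero line in the rotated
    frame), then rotate back. Unbend landmarks become collinear up to
    the fit residual; a configuration whose unbend landmarks already lie
    on a line is returned unchanged up to rounding.
    """
    idx = dataset.scheme.unbend0
    if idx.size < degree + 1:
        raise ValueError(
            f"unbending of degree {degree} needs at least {degree + 1} reference "
            f"landmarks, scheme has {idx.size}"
        )
    out = np.empty_like(dataset.coords)
    for i in range(dataset.n):
        p = dataset.coords[i]
        a, b = p[idx[0]], p[idx[-1]]
        chord = b - a
        L = float(np.hypot(*chord))
        if L < 1e-12 * centroid_size(p):
            raise ValueError(f"degenerate unbend chord in row {i}: endpoints coincide")
        theta = float(np.arctan2(chord[1], chord[0]))
        R = _rot(-theta)
        q = (p - a) @ R.T
        xs = q[idx, 0] / L      # normalised abscissa for conditioning
        ys = q[idx, 1]
        if np.ptp(xs) < 1e-9:
            raise ValueError(f"degenerate unbend reference span in row {i}")
        with warnings.catch_warnings():
            warnings.simplefilter("error", np.exceptions.RankWarning)
            try:
                coef = np.polyfit(xs, ys, degree)
            except np.exceptions.RankWarning:
                raise ValueError(
                    f"unbend reference landmarks in row {i} cannot support a degree-"
                    f"{degree} fit"
                ) from None
        corrected = q.copy()
        corrected[:, 1] = q[:, 1] - np.polyval(coef, q[:, 0] / L)
        out[i] = corrected @ _rot(theta).T + a
    return ShapeDataset(out, dataset.factors, dataset.scheme)


# ----------------------------------------------------------------------
# generalised Procrustes analysis

@dataclasses.dataclass
class GPAResult:
    """Superimposed coordinates and diagnostics from a GPA fit.

    ``aligned`` is (N, k, 2) in the canonical consensus frame; the
    consensus has unit centroid size and the mean of the aligned
    configurations equals the consensus. Centroid sizes are in the
    original input units.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    n_iterations: int
    final_change: float
    converged: bool
    factors: pd.DataFrame
    scheme: LandmarkScheme

    @property
    def log_centroid_sizes(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.aligned.reshape(self.n, -1)

    def distances_to_consensus(self) -> np.ndarray:
        d = self.aligned - self.consensus[None]
        return np.sqrt((d ** 2).sum(axis=(1, 2)))

    def flag_outliers(self, k_iqr: float = 1.5) -> "OutlierReport":
        return flag_outliers(self, k_iqr=k_iqr)

    def to_frame(self) -> pd.DataFrame:
        """Aligned coordinates in long format (one landmark per row)."""
        n, k = self.aligned.shape[:2]
        rep = self.factors.loc[self.factors.index.repeat(k)].reset_index(drop=True)
        rep["landmark"] = np.tile(np.arange(1, k + 1), n)
        rep["x"] = self.aligned[:, :, 0].ravel()
        rep["y"] = self.aligned[:, :, 1].ravel()
        rep["centroid_size"] = np.repeat(self.centroid_sizes, k)
        return rep

    def summary(self) -> str:
        return (
            f"GPA: N={self.n}, k={self.aligned.shape[1]}, "
            f"iterations={self.n_iterations}, final change={self.final_change:.3e}, "
            f"converged={self.converged}"
        )


@dataclasses.dataclass
class OutlierReport:
    """Procrustes distances to consensus with an IQR flagging rule."""

    distances: np.ndarray   # in dataset row order
    flagged: np.ndarray     # row indices, sorted by decreasing distance
    rule: str
    factors: pd.DataFrame

    @property
    def table(self) -> pd.DataFrame:
        order = np.argsort(-self.distances)
        t = self.factors.iloc[order].copy()
        t["distance"] = self.distances[order]
        t["flagged"] = np.isin(order, self.flagged)
        return t.reset_index(drop=True)


def flag_outliers(result: GPAResult, k_iqr: float = 1.5) -> OutlierReport:
    """Flag configurations whose distance to the consensus exceeds
    Q3 + k_iqr * IQR of the distance distribution."""
    d = result.distances_to_consensus()
    q1, q3 = np.percentile(d, [25, 75])
    threshold = q3 + k_iqr * (q3 - q1)
    flagged = np.flatnonzero(d > threshold)
    flagged = flagged[np.argsort(-d[flagged])]
    return OutlierReport(
        distances=d,
        flagged=flagged,
        rule=f"distance > Q3 + {k_iqr} * IQR (threshold {threshold:.6g})",
        factors=result.factors,
    )


class GeneralizedProcrustes:
    """Generalised Procrustes superimposition model.

    Parameters
    ----------
    dataset
        Landmark configurations to superimpose; the scheme's excluded
        landmarks must already have been dropped (``ShapeDataset.drop_excluded``).
    slide
        Slide semi-landmarks against the evolving consensus each
        iteration (minimum Procrustes distance criterion).
    slide_iterations
        Number of leading GPA iterations in which sliding is applied.
        Chord-based minimum-distance sliding has a nearly neutral
        direction (all semi-landmarks migrating together along the
        outline) so iterating it to full convergence is ill-posed;
        like the standard toolchains, a small fixed number of sliding
        passes is used, after which semi-landmark positions are frozen
        and the rotation/averaging iteration converges normally.
    tol, max_iter
        Convergence tolerance on the root summed squared change of the
        consensus between iterations, and the iteration cap.
    """

    def __init__(self, dataset: ShapeDataset, slide: bool = True,
                 tol: float = 1e-10, max_iter: int = 100,
                 slide_iterations: int = 5):
        if dataset.n < 2:
            raise ValueError("GPA needs at least two configurations")
        if dataset.scheme.excluded:
            raise ValueError("drop excluded landmarks before GPA (ShapeDataset.drop_excluded)")
        self.dataset = dataset
        self.slide = slide
        self.tol = tol
        self.max_iter = max_iter
        self.slide_iterations = slide_iterations

    def fit(self) -> GPAResult:
        ds = self.dataset
        sizes = centroid_sizes(ds.coords)
        work = ds.coords - ds.coords.mean(axis=1, keepdims=True)
        work = work / sizes[:, None, None]

        consensus = work[0].copy()
        consensus /= centroid_size(consensus)
        n_iter = 0
        change = np.inf
        scale_factor = 1.0
        for n_iter in range(1, self.max_iter + 1):
            work = self._rotate_onto(work, consensus)
            if self.slide and ds.scheme.semi0.size and n_iter <= self.slide_iterations:
                work = _slide_block(work, consensus, ds.scheme)
                work = work - work.mean(axis=1, keepdims=True)
                work = work / centroid_sizes(work)[:, None, None]
                work = self._rotate_onto(work, consensus)
            mean = work.mean(axis=0)
            mean -= mean.mean(axis=0)
            scale_factor = centroid_size(mean)
            new_consensus = mean / scale_factor
            change = procrustes_distance(new_consensus, consensus)
            consensus = new_consensus
            if change < self.tol:
                break
        converged = change < self.tol
        if not converged:
            logger.warning(
                "GPA did not converge in %d iterations (last change %.3e)",
                self.max_iter, change,
            )
        # common rescale so that mean(aligned) == consensus exactly while
        # the consensus keeps unit centroid size
        aligned = work / scale_factor
        consensus = work.mean(axis=0) / scale_factor
        consensus -= consensus.mean(axis=0)
        aligned, consensus = _canonical_orientation(aligned, consensus)
        return GPAResult(
            aligned=aligned,
            consensus=consensus,
            centroid_sizes=sizes,
            n_iterations=n_iter,
            final_change=float(change),
            converged=bool(converged),
            factors=ds.factors,
            scheme=ds.scheme,
        )

    @staticmethod
    def _rotate_onto(work: np.ndarray, consensus: np.ndarray) -> np.ndarray:
        dot = (work * consensus[None]).sum(axis=(1, 2))
        cross = (work[:, :, 0] * consensus[None, :, 1]
                 - work[:, :, 1] * consensus[None, :, 0]).sum(axis=1)
        theta = np.arctan2(cross, dot)
        c, s = np.cos(theta), np.sin(theta)
        x, y = work[:, :, 0], work[:, :, 1]
        return np.stack(
            [c[:, None] * x - s[:, None] * y, s[:, None] * x + c[:, None] * y], axis=2
        )


def _canonical_orientation(aligned: np.ndarray, consensus: np.ndarray):
    """Rotate the whole superimposition to a deterministic frame.

    The consensus principal axis is placed along x, with the sign fixed
    so that the landmark farthest from the centroid has negative x.
    This makes GPA output invariant to arbitrary similarity transforms
    of the input (the frame no longer depends on the orientation of the
    first configuration).
    """
    cov = consensus.T @ consensus
    theta = 0.5 * np.arctan2(2.0 * cov[0, 1], cov[0, 0] - cov[1, 1])
    R = _rot(-theta)
    consensus = consensus @ R.T
    aligned = aligned @ R.T
    far = int(np.argmax((consensus ** 2).sum(axis=1)))
    if consensus[far, 0] > 0:
        consensus = -consensus
        aligned = -aligned
    return aligned, consensus


def gpa(dataset: ShapeDataset, slide: bool = True, tol: float = 1e-10,
        max_iter: int = 100, slide_iterations: int = 5) -> GPAResult:
    """Convenience wrapper: ``GeneralizedProcrustes(dataset, ...).fit()``."""
    return GeneralizedProcrustes(
        dataset, slide=slide, tol=tol, max_iter=max_iter,
        slide_iterations=slide_iterations,
    ).fit()
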
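"""Generalized Procrustes analysis, shape PCA and allometric regression.

Configurations are (p,3) arrays of corresponding points (landmarks,
semilandmarks, or full vertex sets). GPA removes translation, scale
(configurations are fixed at unit centroid size — partial Procrustes)
and rotation (proper rotations only; biological surfaces are chiral, so
reflections are never allowed). Allometry is the multivariate linear
regression of the superimposed coordinates on ln centroid size;
regressing coordinates directly is equivalent, in exact arithmetic, to
regressing the full set of PC scores and back-transforming.

No tangent-space projection is applied before PCA or regression: the
shape differences studied here are small, and the choice is recorded in
output metadata by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import centroid_size

__all__ = ["AlignedSample", "ShapePCA", "AllometricModel", "gpa",
           "procrustes_distance", "optimal_rotation", "shape_pca",
           "fit_allometry", "predict_shape_at_size"]


def _center_scale(x: np.ndarray) -> tuple[np.ndarray, float]:
    x = np.asarray(x, dtype=float)
    cs = centroid_size(x)
    return (x - x.mean(axis=0)) / cs, cs


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ‖a − b R‖_F (apply as ``b @ R``)."""
    u, _, vt = np.linalg.svd(b.T @ a)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.ones(a.shape[1])
    s[-1] = d
    return (u * s) @ vt


@dataclass(frozen=True)
class AlignedSample:
    """GPA output: unit-size superimposed configurations plus size metadata."""

    aligned: np.ndarray         # (n, p, 3), dimensionless
    mean_shape: np.ndarray      # (p, 3), centroid size 1
    centroid_sizes: np.ndarray  # (n,), original units
    iterations: int

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def p(self) -> int:
        return self.aligned.shape[1]


def gpa(configs: np.ndarray | list[np.ndarray], tol: float = 1e-10,
        max_iters: int = 100) -> AlignedSample:
    """Generalized Procrustes superimposition.

    Each configuration is centered, scaled to unit centroid size and
    iteratively rotated to the running mean until the mean stabilises.
    """
    arr = np.asarray(configs, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("configs must be (n, p, 3) with consistent p")
    n, p, _ = arr.shape
    if n < 2 or p < 3:
        raise ValueError("GPA needs >= 2 configurations of >= 3 points")

    sizes = np.empty(n)
    aligned = np.empty_like(arr)
    for i in range(n):
        aligned[i], sizes[i] = _center_scale(arr[i])

    mean = aligned[0].copy()
    iters = 0
    for iters in range(1, max_iters + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ optimal_rotation(mean, aligned[i])
        new_mean = aligned.mean(axis=0)
        new_mean = (new_mean - new_mean.mean(axis=0)) / centroid_size(new_mean)
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    return AlignedSample(aligned, mean, sizes, iters)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance: ‖â − b̂R‖ after centering, unit-size
    scaling and optimal proper rotation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations must have the same shape")
    ah, _ = _center_scale(a)
    bh, _ = _center_scale(b)
    return float(np.linalg.norm(ah - bh @ optimal_rotation(ah, bh)))


@dataclass(frozen=True)
class ShapePCA:
    scores: np.ndarray              # (n, n_components)
    components: np.ndarray          # (n_components, 3p), orthonormal rows
    variance_fractions: np.ndarray  # sums to 1
    center: np.ndarray              # (3p,) mean of the flattened sample


def shape_pca(sample: AlignedSample) -> ShapePCA:
    """PCA of the row-vectorised aligned coordinates.

    Components are ordered by descending variance; the sign of each is
    fixed so its largest-magnitude loading is positive, making score
    plots reproducible across methods and densities.
    """
    if sample.n < 3:
        raise ValueError("shape PCA needs at least 3 specimens")
    X = sample.aligned.reshape(sample.n, -1)
    center = X.mean(axis=0)
    Xc = X - center
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    ncomp = min(sample.n - 1, vt.shape[0])
    s, vt = s[:ncomp], vt[:ncomp]
    # deterministic sign convention
    flips = np.sign(vt[np.arange(ncomp), np.argmax(np.abs(vt), axis=1)])
    flips[flips == 0] = 1.0
    vt = vt * flips[:, None]
    scores = Xc @ vt.T
    var = s**2
    total = var.sum()
    fractions = var / total if total > 0 else np.full(ncomp, 1.0 / ncomp)
    return ShapePCA(scores, vt, fractions, center)


@dataclass(frozen=True)
class AllometricModel:
    """Linear shape-on-lnCS model: shape(s) = mean + (lnCS − lnCS_mean)·V."""

    mean_shape: np.ndarray   # (p,3) — the regression's fitted value at lnCS_mean
    slope_field: np.ndarray  # (p,3) displacement per unit lnCS
    lncs_mean: float
    lncs_min: float
    lncs_max: float


def fit_allometry(sample: AlignedSample) -> AllometricModel:
    """Regress superimposed coordinates on ln centroid size."""
    if sample.n < 3:
        raise ValueError("allometric regression needs at least 3 specimens")
    lncs = np.log(sample.centroid_sizes)
    if np.ptp(lncs) < 1e-12 * max(1.0, np.abs(lncs).max()):
        raise ValueError("centroid sizes are (numerically) all equal: "
                         "lnCS is constant")
    x = lncs - lncs.mean()
    Y = sample.aligned.reshape(sample.n, -1)
    slope = (x @ (Y - Y.mean(axis=0))) / (x @ x)
    return AllometricModel(
        mean_shape=Y.mean(axis=0).reshape(sample.p, 3),
        slope_field=slope.reshape(sample.p, 3),
        lncs_mean=float(lncs.mean()),
        lncs_min=float(lncs.min()),
        lncs_max=float(lncs.max()),
    )


def predict_shape_at_size(model: AllometricModel, lncs: float) -> np.ndarray:
    """Predicted shape at a given ln centroid size (extrapolation allowed)."""
    return model.mean_shape + (lncs - model.lncs_mean) * model.slope_field
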
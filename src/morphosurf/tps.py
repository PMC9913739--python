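"""3D thin-plate-spline interpolation, warping and bending energy.

A "triplet" of splines — one per coordinate — interpolates n source
control points onto n targets:

    f(x) = c + B x + Σᵢ wᵢ U(‖x − sᵢ‖),      U(r) = r

subject to the side conditions Σ wᵢ = 0 and Σ wᵢ sᵢᵀ = 0, so the kernel
part is orthogonal to affine maps. With kernel U(r)=r the quadratic form
wᵀKw is nonpositive on the side-condition subspace (r is conditionally
negative definite in 3D; the biharmonic Green function is −r/(8π)), so
the bending energy is reported as −trace(WᵀKW) ≥ 0, which is zero exactly
for affine maps. Only ratios and orderings of the energy are used
downstream, so the 8π normalisation constant is omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["TPSWarp", "tps_fit", "tps_apply", "bending_energy_between",
           "bending_energy_matrix", "TPSSingularError"]


class TPSSingularError(ValueError):
    """TPS system is singular (duplicate or coplanar source points)."""


@dataclass(frozen=True)
class TPSWarp:
    """A fitted 3D thin-plate-spline map."""

    source_points: np.ndarray     # (n,3)
    nonaffine_weights: np.ndarray  # (n,3)
    affine_matrix: np.ndarray     # (3,3); applied as x @ B
    affine_translation: np.ndarray  # (3,)
    regularization: float
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return tps_apply(self, points)


def _kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """U(r)=r kernel matrix between point sets (na,3) and (nb,3)."""
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.einsum("ijd,ijd->ij", diff, diff))


def _check_sources(source: np.ndarray) -> None:
    n = source.shape[0]
    if n < 5:
        raise ValueError(f"TPS needs at least 5 control points, got {n}")
    from .mesh import centroid_size
    cs = centroid_size(source)
    d = _kernel(source, source)
    iu = np.triu_indices(n, k=1)
    dup = d[iu] < 1e-9 * cs
    if dup.any():
        i = int(np.argmax(dup))
        r, c = iu[0][i], iu[1][i]
        raise TPSSingularError(
            f"duplicate source points {r} and {c} (distance {d[r, c]:.3e})")
    # coplanarity: rank of centered sources < 3
    sv = np.linalg.svd(source - source.mean(axis=0), compute_uv=False)
    if sv[2] < 1e-10 * max(sv[0], 1e-300):
        raise TPSSingularError("source points are (near-)coplanar: TPS affine "
                               "part is rank-deficient")


def _assemble(source: np.ndarray, lam: float):
    # The smoothing term is *subtracted*: U(r)=r is conditionally negative
    # definite, so K restricted to the side-condition subspace is negative
    # definite and K − λI moves its eigenvalues away from zero (adding λ
    # would cross a singularity at finite λ).
    n = source.shape[0]
    K = _kernel(source, source) - lam * np.eye(n)
    P = np.hstack([np.ones((n, 1)), source])
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    return L, K


def tps_fit(source: np.ndarray, target: np.ndarray, lam: float = 0.0) -> TPSWarp:
    """Fit the TPS triplet mapping ``source`` onto ``target``.

    ``lam`` >= 0 smooths the fit (λ=0 gives exact interpolation; larger
    λ trades residual at the controls for lower bending energy).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError("source and target must both be (n,3)")
    if lam < 0:
        raise ValueError("regularization must be nonnegative")
    _check_sources(source)

    n = source.shape[0]
    L, K = _assemble(source, lam)
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = target
    try:
        sol = scipy.linalg.solve(L, rhs)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise TPSSingularError(str(exc)) from exc
    W = sol[:n]
    c = sol[n]
    B = sol[n + 1:]
    energy = max(0.0, -float(np.einsum("id,ij,jd->", W, K + lam * np.eye(n), W)))
    return TPSWarp(source, W, B, c, float(lam), energy)


def tps_apply(warp: TPSWarp, points: np.ndarray) -> np.ndarray:
    """Evaluate the warp at m points: affine part + kernel part."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    U = _kernel(pts, warp.source_points)
    out = warp.affine_translation + pts @ warp.affine_matrix + U @ warp.nonaffine_weights
    return out if np.asarray(points).ndim == 2 else out[0]


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """The p×p positive-semidefinite form Bₑ with BE(Y) = trace(Yᵀ Bₑ Y).

    Bₑ is minus the upper-left p×p block of the inverse of the full TPS
    system matrix built on ``reference`` (sign flipped because U(r)=r is
    conditionally negative definite). Its null space is spanned by
    [1 | reference], so affine images of the reference have zero energy.
    """
    reference = np.asarray(reference, dtype=float)
    _check_sources(reference)
    p = reference.shape[0]
    L, _ = _assemble(reference, 0.0)
    Linv = scipy.linalg.inv(L)
    Be = -Linv[:p, :p]
    return 0.5 * (Be + Be.T)


def bending_energy_between(reference: np.ndarray, target: np.ndarray) -> float:
    """Bending energy of the TPS mapping reference -> target (λ=0)."""
    target = np.asarray(target, dtype=float)
    Be = bending_energy_matrix(reference)
    return max(0.0, float(np.einsum("id,ij,jd->", target, Be, target)))
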
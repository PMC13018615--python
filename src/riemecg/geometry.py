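"""Affine-invariant Riemannian geometry on symmetric positive-definite matrices.

The n x n inter-lead covariance of a 12-lead ECG is a point on the SPD
manifold.  Under the affine-invariant Riemannian metric (AIRM) the distance

    d(A, B) = || logm(A^{-1/2} B A^{-1/2}) ||_F = sqrt(sum_k log^2 lambda_k),

with lambda_k the generalised eigenvalues of (A, B), is invariant under
congruence C -> P C P^T by any invertible P — covariances measured in any
non-degenerate re-referencing of the leads are equidistant.  This module
provides the metric, the log/exp maps, geodesics, the weighted Frechet
(Karcher) mean, and the tangent-space vectorisation used to hand SPD
features to Euclidean learners.

All functions operate on plain ``numpy`` arrays; helpers validate SPD-ness
and raise :class:`SPDError` naming the offending eigenvalue rather than
silently repairing inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "SPDError",
    "DimensionMismatchError",
    "FrechetConfig",
    "check_spd",
    "riemannian_distance",
    "log_map",
    "exp_map",
    "tangent_project",
    "tangent_lift",
    "upper_vec",
    "upper_unvec",
    "geodesic",
    "frechet_mean",
]

#: relative eigenvalue floor (fraction of the largest eigenvalue) below which
#: an input is rejected as numerically singular.  Repair (shrinkage) belongs
#: to covariance estimation, not to the geometry layer.
EIG_FLOOR = 1e-12

_SYM_TOL = 1e-10


class SPDError(ValueError):
    """Input is not symmetric positive-definite (to tolerance)."""


class DimensionMismatchError(SPDError):
    """Operands live on SPD manifolds of different dimension."""


def _as_square(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise SPDError(f"{name} must be a square matrix, got shape {m.shape}")
    return m


def check_spd(m: np.ndarray, *, name: str = "matrix", sym_tol: float = _SYM_TOL) -> np.ndarray:
    """Validate symmetry and positive-definiteness; return the symmetrised copy.

    Symmetry is checked relative to the matrix norm; eigenvalues must all
    exceed ``EIG_FLOOR`` times the largest one.
    """
    m = _as_square(m, name)
    scale = max(1.0, float(np.linalg.norm(m)))
    asym = float(np.linalg.norm(m - m.T))
    if asym > sym_tol * scale:
        raise SPDError(f"{name} is not symmetric: ||M - M^T|| = {asym:.3e} (relative tol {sym_tol})")
    m = 0.5 * (m + m.T)
    w = np.linalg.eigvalsh(m)
    floor = EIG_FLOOR * max(w[-1], 0.0)
    if w[0] <= floor:
        raise SPDError(
            f"{name} is not positive-definite: smallest eigenvalue {w[0]:.6e} "
            f"(floor {floor:.3e}); consider shrinkage at the estimation stage"
        )
    return m


def _check_pair(a: np.ndarray, b: np.ndarray, na: str, nb: str) -> tuple[np.ndarray, np.ndarray]:
    a = check_spd(a, name=na)
    b = check_spd(b, name=nb)
    if a.shape != b.shape:
        raise DimensionMismatchError(f"{na} is {a.shape[0]}x{a.shape[0]} but {nb} is {b.shape[0]}x{b.shape[0]}")
    return a, b


def _sym(m: np.ndarray) -> np.ndarray:
    # suppress floating-point asymmetry drift after matrix functions
    return 0.5 * (m + m.T)


def _eigh_checked(m: np.ndarray, name: str) -> tuple[np.ndarray, np.ndarray]:
    w, v = np.linalg.eigh(m)
    floor = EIG_FLOOR * max(w[-1], 0.0)
    if w[0] <= floor:
        raise SPDError(
            f"{name}: eigenvalue {w[0]:.6e} at or below clipping floor {floor:.3e}; input rejected"
        )
    return w, v


def _matrix_power_spd(m: np.ndarray, p: float, name: str = "matrix") -> np.ndarray:
    w, v = _eigh_checked(m, name)
    return _sym((v * w**p) @ v.T)


def sqrtm_spd(m: np.ndarray) -> np.ndarray:
    """Principal square root of an SPD matrix (eigendecomposition route)."""
    return _matrix_power_spd(m, 0.5)


def invsqrtm_spd(m: np.ndarray) -> np.ndarray:
    """Inverse principal square root of an SPD matrix."""
    return _matrix_power_spd(m, -0.5)


def logm_spd(m: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix; result is symmetric."""
    w, v = _eigh_checked(m, "logm input")
    return _sym((v * np.log(w)) @ v.T)


def expm_sym(s: np.ndarray, *, sym_tol: float = _SYM_TOL) -> np.ndarray:
    """Matrix exponential of a symmetric matrix; result is SPD."""
    s = _as_square(s, "expm input")
    scale = max(1.0, float(np.linalg.norm(s)))
    if float(np.linalg.norm(s - s.T)) > sym_tol * scale:
        raise SPDError("expm input is not symmetric to tolerance")
    s = _sym(s)
    w, v = np.linalg.eigh(s)
    return _sym((v * np.exp(w)) @ v.T)


def riemannian_distance(a: np.ndarray, b: np.ndarray) -> float:
    """AIRM geodesic distance ``sqrt(sum_k log^2 lambda_k(a^{-1} b))``."""
    a, b = _check_pair(a, b, "a", "b")
    # generalised eigenvalues of (b, a) are the eigenvalues of a^{-1} b
    lam = scipy.linalg.eigvalsh(b, a)
    lam = np.clip(lam, EIG_FLOOR, None)
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def log_map(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Riemannian logarithm of ``x`` at base point ``ref``.

    Returns the symmetric matrix ``ref^{1/2} logm(ref^{-1/2} x ref^{-1/2}) ref^{1/2}``;
    the zero matrix iff ``x == ref``.
    """
    x, ref = _check_pair(x, ref, "x", "ref")
    r = sqrtm_spd(ref)
    ir = invsqrtm_spd(ref)
    return _sym(r @ logm_spd(_sym(ir @ x @ ir)) @ r)


def exp_map(v: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Riemannian exponential of tangent matrix ``v`` at base point ``ref``."""
    ref = check_spd(ref, name="ref")
    v = _as_square(v, "v")
    if v.shape != ref.shape:
        raise DimensionMismatchError(f"tangent matrix is {v.shape} but ref is {ref.shape}")
    scale = max(1.0, float(np.linalg.norm(v)))
    if float(np.linalg.norm(v - v.T)) > _SYM_TOL * scale:
        raise SPDError("tangent matrix is not symmetric to tolerance")
    r = sqrtm_spd(ref)
    ir = invsqrtm_spd(ref)
    return _sym(r @ expm_sym(_sym(ir @ v @ ir)) @ r)


def upper_vec(s: np.ndarray) -> np.ndarray:
    """Vectorise a symmetric matrix: upper triangle, off-diagonal scaled by sqrt(2).

    The scaling makes the Euclidean norm of the vector equal the Frobenius
    norm of the matrix, so tangent-vector norms equal Riemannian distances.
    """
    s = _as_square(s, "symmetric matrix")
    n = s.shape[0]
    iu = np.triu_indices(n)
    v = s[iu].copy()
    v[iu[0] != iu[1]] *= np.sqrt(2.0)
    return v


def upper_unvec(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`upper_vec`."""
    v = np.asarray(v, dtype=float).ravel()
    n = int(round((np.sqrt(8 * v.size + 1) - 1) / 2))
    if n * (n + 1) // 2 != v.size:
        raise ValueError(f"vector length {v.size} is not n(n+1)/2 for any integer n")
    s = np.zeros((n, n))
    iu = np.triu_indices(n)
    w = v.copy()
    w[iu[0] != iu[1]] /= np.sqrt(2.0)
    s[iu] = w
    s = s + s.T - np.diag(np.diag(s))
    return s


def tangent_project(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Project ``x`` to the tangent space at ``ref`` and vectorise.

    Computes ``S = ref^{-1/2} Log_ref(x) ref^{-1/2}`` (the whitened tangent
    chart) and returns its upper triangle as a length n(n+1)/2 vector with
    sqrt(2)-scaled off-diagonals, so ``||v||_2 == riemannian_distance(x, ref)``.
    """
    x, ref = _check_pair(x, ref, "x", "ref")
    ir = invsqrtm_spd(ref)
    s = logm_spd(_sym(ir @ x @ ir))
    return upper_vec(s)


def tangent_lift(v: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`tangent_project`: vector back to an SPD matrix."""
    ref = check_spd(ref, name="ref")
    s = upper_unvec(v)
    if s.shape != ref.shape:
        raise DimensionMismatchError(
            f"vector of length {np.asarray(v).size} implies dim {s.shape[0]}, ref is {ref.shape[0]}"
        )
    r = sqrtm_spd(ref)
    return _sym(r @ expm_sym(s) @ r)


def geodesic(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Point at parameter ``t`` on the AIRM geodesic from ``a`` to ``b``.

    ``a^{1/2} (a^{-1/2} b a^{-1/2})^t a^{1/2}``; endpoints are ``a`` (t=0)
    and ``b`` (t=1), and ``d(a, geodesic(a,b,t)) = t * d(a,b)``.
    """
    a, b = _check_pair(a, b, "a", "b")
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"geodesic parameter t={t} outside [0, 1]; extrapolation not supported")
    r = sqrtm_spd(a)
    ir = invsqrtm_spd(a)
    mid = _matrix_power_spd(_sym(ir @ b @ ir), t, "whitened geodesic operand")
    return _sym(r @ mid @ r)


@dataclass(frozen=True)
class FrechetConfig:
    """Stopping rule for the Karcher fixed-point iteration."""

    tol: float = 1e-8
    max_iter: int = 100
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 < self.step <= 1.0:
            raise ValueError("step must be in (0, 1]")


def _batched_whitened_log(mats: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Whitened logs ``logm(c^{-1/2} M_i c^{-1/2})`` for a stack of SPD matrices."""
    ic = invsqrtm_spd(c)
    w_all = np.einsum("ij,njk,kl->nil", ic, mats, ic)
    w_all = 0.5 * (w_all + np.swapaxes(w_all, 1, 2))
    lam, vec = np.linalg.eigh(w_all)
    if np.any(lam <= 0):
        idx = int(np.argmin(lam.min(axis=1)))
        raise SPDError(
            f"matrix {idx} lost positive-definiteness when whitened "
            f"(eigenvalue {lam.min():.3e})"
        )
    logs = np.einsum("nij,nj,nkj->nik", vec, np.log(lam), vec)
    return 0.5 * (logs + np.swapaxes(logs, 1, 2))


def frechet_mean(
    mats,
    weights=None,
    config: FrechetConfig | None = None,
    *,
    return_info: bool = False,
):
    """Weighted Frechet (Karcher) mean of SPD matrices under the AIRM.

    Minimises ``sum_i w_i d(C, C_i)^2`` by the fixed-point iteration
    ``C <- Exp_C(step * sum_i w_i Log_C(C_i))``, initialised at the
    log-Euclidean mean ``expm(sum_i w_i logm(C_i))``.  Non-convergence at
    ``max_iter`` is reported as a warning, not an exception.

    Parameters
    ----------
    mats
        Sequence of SPD matrices of a common dimension (at least one).
    weights
        Nonnegative weights; normalised to sum to 1.  Uniform if None.
    config
        Solver tolerances; see :class:`FrechetConfig`.
    return_info
        If True, also return ``{"converged": bool, "n_iter": int, "grad_norm": float}``.
    """
    if config is None:
        config = FrechetConfig()
    mats = [check_spd(m, name=f"matrix {i}") for i, m in enumerate(mats)]
    if len(mats) == 0:
        raise ValueError("frechet_mean of an empty list is undefined")
    n = mats[0].shape[0]
    for i, m in enumerate(mats):
        if m.shape[0] != n:
            raise DimensionMismatchError(f"matrix {i} is {m.shape[0]}x{m.shape[0]}, expected {n}x{n}")
    if weights is None:
        w = np.full(len(mats), 1.0 / len(mats))
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.size != len(mats):
            raise ValueError(f"{w.size} weights for {len(mats)} matrices")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        tot = float(w.sum())
        if tot <= 0:
            raise ValueError("weights sum to zero")
        w = w / tot

    stack = np.stack(mats)
    # log-Euclidean initialisation
    logs = np.stack([logm_spd(m) for m in mats])
    c = expm_sym(np.einsum("n,nij->ij", w, logs))

    converged = False
    grad_norm = np.inf
    it = 0
    for it in range(1, config.max_iter + 1):
        wl = _batched_whitened_log(stack, c)
        grad = np.einsum("n,nij->ij", w, wl)  # tangent update in the whitened chart
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm < config.tol:
            converged = True
            break
        r = sqrtm_spd(c)
        c = _sym(r @ expm_sym(config.step * grad) @ r)
    if not converged:
        warnings.warn(
            f"Karcher flow did not converge in {config.max_iter} iterations "
            f"(gradient norm {grad_norm:.3e} >= tol {config.tol:.1e})",
            RuntimeWarning,
            stacklevel=2,
        )
    if return_info:
        return c, {"converged": converged, "n_iter": it, "grad_norm": grad_norm}
    return c
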
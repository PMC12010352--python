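"""Shared dense linear-algebra helpers: jittered inversion and PSD projection."""

from __future__ import annotations

import numpy as np
import scipy.linalg


class NumericalError(RuntimeError):
    """Raised when a matrix stays numerically singular after the jitter budget."""


# Jitter schedule: start at 1e-10 * trace/m, escalate x10 up to 1e-6 * trace/m.
_JITTER_START = 1e-10
_JITTER_MAX = 1e-6


def _jitter_levels(mat: np.ndarray):
    scale = float(np.trace(mat)) / max(mat.shape[0], 1)
    if scale <= 0 or not np.isfinite(scale):
        scale = 1.0
    level = _JITTER_START
    yield 0.0
    while level <= _JITTER_MAX * (1 + 1e-12):
        yield level * scale
        level *= 10.0


def sym(mat: np.ndarray) -> np.ndarray:
    """Symmetrize: (S + S^T)/2."""
    return 0.5 * (mat + mat.T)


def cho_solve_spd(mat: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve mat @ x = rhs for symmetric positive-definite ``mat``.

    Adds escalating diagonal jitter when the Cholesky factorization fails;
    raises :class:`NumericalError` once the jitter budget is exhausted.
    """
    mat = sym(np.asarray(mat, dtype=float))
    rhs = np.asarray(rhs, dtype=float)
    m = mat.shape[0]
    for eps in _jitter_levels(mat):
        try:
            c, low = scipy.linalg.cho_factor(mat + eps * np.eye(m), lower=True)
            return scipy.linalg.cho_solve((c, low), rhs)
        except np.linalg.LinAlgError:
            continue
    raise NumericalError(
        f"matrix of shape {mat.shape} not positive definite within jitter budget "
        f"(trace={np.trace(mat):.3e})"
    )


def spd_inverse(mat: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric positive-definite matrix via jittered Cholesky."""
    return cho_solve_spd(mat, np.eye(mat.shape[0]))


def slogdet_spd(mat: np.ndarray) -> float:
    """log|mat| for SPD ``mat``; jittered like :func:`cho_solve_spd`."""
    mat = sym(np.asarray(mat, dtype=float))
    m = mat.shape[0]
    for eps in _jitter_levels(mat):
        try:
            c = np.linalg.cholesky(mat + eps * np.eye(m))
            return 2.0 * float(np.sum(np.log(np.diag(c))))
        except np.linalg.LinAlgError:
            continue
    raise NumericalError("log-determinant of a non-PD matrix")


def psd_project(mat: np.ndarray) -> np.ndarray:
    """Nearest (in Frobenius sense) PSD matrix: clip negative eigenvalues at 0."""
    mat = sym(np.asarray(mat, dtype=float))
    w, v = np.linalg.eigh(mat)
    if w[0] >= 0:
        return mat
    return sym((v * np.clip(w, 0.0, None)) @ v.T)


def check_symmetric(mat: np.ndarray, tol: float = 1e-8, name: str = "matrix") -> None:
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got shape {mat.shape}")
    denom = max(float(np.abs(mat).max()), 1e-300)
    if float(np.abs(mat - mat.T).max()) / denom > tol:
        raise ValueError(f"{name} is not symmetric within tolerance {tol}")
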
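"""Reference inverse solvers: sLORETA, LCMV beamformer, and minimum-current (L1).

All three consume the same :class:`~snchamp.model_core.LeadField` /
:class:`~snchamp.model_core.SensorDataset` pair and return
``(power_map, xbar)`` with ``power_map`` the per-voxel mean squared estimate,
directly consumable by the metrics module.  They are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._linalg import cho_solve_spd, sym
from .model_core import LeadField, SensorDataset

__all__ = ["BaselineOptions", "sloreta_solve", "lcmv_solve", "mce_solve"]


@dataclass(frozen=True)
class BaselineOptions:
    """Hyperparameters shared by the baseline solvers.

    ``regularization`` scales with the mean eigenvalue of the matrix being
    regularized (the sensor Gram for sLORETA, the data covariance for LCMV),
    keeping it portable across data scales.  ``mce_penalty`` is the absolute
    L1 weight; ``None`` selects ``0.1 * max|L^T y|`` over the record.
    """

    regularization: float = 0.05
    mce_penalty: float | None = None
    mce_max_iter: int = 2000
    mce_tol: float = 1e-10

    def __post_init__(self):
        if self.regularization < 0:
            raise ValueError("regularization must be nonnegative")
        if self.mce_penalty is not None and self.mce_penalty < 0:
            raise ValueError("mce_penalty must be nonnegative")
        if self.mce_max_iter < 1 or self.mce_tol <= 0:
            raise ValueError("invalid MCE iteration settings")


def _power(xbar: np.ndarray) -> np.ndarray:
    return np.mean(xbar**2, axis=1)


def sloreta_solve(
    data: SensorDataset, leadfield: LeadField, opts: BaselineOptions | None = None
):
    """Standardized minimum-norm estimate.

    Minimum-norm kernel ``W = L^T (L L^T + eps I)^-1`` with
    ``eps = regularization * mean_eigenvalue(L L^T)``; each voxel estimate is
    divided by the square root of the resolution-matrix diagonal ``(W L)_ii``,
    which gives zero localization bias for a noiseless single source.
    """
    opts = opts or BaselineOptions()
    L = leadfield.gain
    gram = L @ L.T
    eps = opts.regularization * float(np.trace(gram)) / leadfield.m
    W = cho_solve_spd(gram + eps * np.eye(leadfield.m), L).T  # n x m
    res_diag = np.sum(W * L.T, axis=1)  # (W L)_ii
    if np.any(res_diag <= 0):
        raise ValueError("resolution-matrix diagonal not positive; increase eps")
    xbar = (W @ data.y) / np.sqrt(res_diag)[:, None]
    return _power(xbar), xbar


def lcmv_solve(
    data: SensorDataset, leadfield: LeadField, opts: BaselineOptions | None = None
):
    """Unit-gain minimum-variance beamformer.

    ``w_i = C^-1 l_i / (l_i^T C^-1 l_i)`` with the regularized data covariance
    ``C = (1/K) Y Y^T + eps I``; ``power_map_i = w_i^T C w_i``.
    """
    opts = opts or BaselineOptions()
    L, Y = leadfield.gain, data.y
    m, K = data.m, data.K
    C0 = (Y @ Y.T) / K
    reg = opts.regularization
    if K < m and reg == 0:
        warnings.warn(
            "rank-deficient data covariance (K < m); forcing regularization",
            RuntimeWarning,
            stacklevel=2,
        )
        reg = 0.05
    eps = reg * float(np.trace(C0)) / m
    C = sym(C0 + eps * np.eye(m))
    CinvL = cho_solve_spd(C, L)
    denom = np.sum(L * CinvL, axis=0)  # l_i^T C^-1 l_i
    if np.any(denom <= 0):
        raise ValueError("beamformer denominator not positive")
    W = CinvL / denom  # columns are w_i
    xbar = W.T @ Y
    power = np.sum(W * (C @ W), axis=0)  # w_i^T C w_i
    return power, xbar


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def mce_solve(
    data: SensorDataset, leadfield: LeadField, opts: BaselineOptions | None = None
):
    """Minimum-current estimate: ``min_x 0.5 ||y - L x||^2 + lam ||x||_1``.

    Solved for all time samples simultaneously by FISTA with a fixed step
    ``1/||L||_2^2``; a non-converged run warns and returns the best iterate.
    """
    opts = opts or BaselineOptions()
    L, Y = leadfield.gain, data.y
    n, K = leadfield.n, data.K
    lam = opts.mce_penalty
    corr = L.T @ Y
    if lam is None:
        lam = 0.1 * float(np.abs(corr).max())
    if lam == 0:
        raise ValueError("mce_penalty must be positive (lam > 0)")
    if float(np.abs(corr).max()) <= lam:
        return np.zeros(n), np.zeros((n, K))  # below the L1 null threshold

    step = 1.0 / float(np.linalg.norm(L, 2) ** 2)
    X = np.zeros((n, K))
    Z = X.copy()
    t = 1.0
    converged = False
    scale = max(float(np.linalg.norm(Y)), 1e-300)
    for _ in range(opts.mce_max_iter):
        grad = L.T @ (L @ Z - Y)
        X_new = _soft_threshold(Z - step * grad, step * lam)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Z = X_new + ((t - 1.0) / t_new) * (X_new - X)
        change = float(np.linalg.norm(X_new - X)) / scale
        X, t = X_new, t_new
        if change < opts.mce_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCE did not reach tol={opts.mce_tol} in {opts.mce_max_iter} "
            "iterations; returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return _power(X), X
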
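"""Linear-Gaussian machinery of the sparse-Bayesian source model.

The generative model is ``y_k = L x_k + z_k`` with independent zero-mean
Gaussian sources of per-voxel variance ``v_i`` and additive sensor noise with
covariance ``Sigma_n``.  This module provides the model covariance, the source
posterior, the (negative log-evidence) cost, and the convex-bounding
fixed-point update of the source variances.

Conventions
-----------
- The noise model stores the noise *covariance* ``Sigma_n``; the precision is
  derived from it on demand.
- Source variances ``v`` parametrize everything; the source precision matrix
  is never formed for pruned voxels (``v_i == 0``).
- The variance update defaults to the square-root fixed point
  ``v_i = sqrt(mean_k xbar_ik^2 / g_i)`` with ``g_i = l_i^T Sigma_y^-1 l_i``,
  which is the stationary point of the convex bound in the variance
  parametrization and is cost-monotone.  ``as_printed`` (no square root) is
  retained as a switch for fidelity experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._linalg import (
    NumericalError,
    check_symmetric,
    cho_solve_spd,
    slogdet_spd,
    spd_inverse,
    sym,
)

__all__ = [
    "LeadField",
    "SensorDataset",
    "NoiseModel",
    "ChampagneState",
    "compute_model_covariance",
    "compute_posterior_sources",
    "champagne_cost",
    "update_source_variances",
    "NumericalError",
]

#: voxels with variance below this fraction of the max are clamped to 0 (hard
#: ARD pruning) on every sweep.
PRUNE_REL_TOL = 1e-12


@dataclass(frozen=True)
class LeadField:
    """Gain matrix mapping unit voxel sources to sensors, plus voxel geometry.

    Parameters
    ----------
    gain
        ``(m, n)`` array; column ``i`` is the sensor topography of a unit
        source at voxel ``i``.
    voxel_coords
        ``(n, 3)`` voxel positions in mm.
    normalized
        If True, every column of ``gain`` must have unit Euclidean norm.
    """

    gain: np.ndarray
    voxel_coords: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        gain = np.atleast_2d(np.asarray(self.gain, dtype=float))
        coords = np.asarray(self.voxel_coords, dtype=float)
        if gain.ndim != 2 or gain.shape[0] < 1 or gain.shape[1] < 1:
            raise ValueError(f"gain must be a 2-D m x n matrix, got {gain.shape}")
        if coords.shape != (gain.shape[1], 3):
            raise ValueError(
                f"voxel_coords must be ({gain.shape[1]}, 3), got {coords.shape}"
            )
        if not np.all(np.isfinite(gain)):
            raise ValueError("gain contains non-finite entries")
        if self.normalized:
            norms = np.linalg.norm(gain, axis=0)
            if np.any(norms == 0):
                raise ValueError("normalized lead-field has an all-zero column")
            if np.max(np.abs(norms - 1.0)) > 1e-12:
                raise ValueError("normalized flag set but columns are not unit-norm")
        object.__setattr__(self, "gain", gain)
        object.__setattr__(self, "voxel_coords", coords)

    @property
    def m(self) -> int:
        return self.gain.shape[0]

    @property
    def n(self) -> int:
        return self.gain.shape[1]

    def normalized_copy(self) -> "LeadField":
        """Return a copy with unit-norm columns (zero columns rejected)."""
        norms = np.linalg.norm(self.gain, axis=0)
        if np.any(norms == 0):
            raise ValueError("cannot normalize a lead-field with all-zero columns")
        return LeadField(self.gain / norms, self.voxel_coords, normalized=True)


@dataclass(frozen=True)
class SensorDataset:
    """Sensor time series: ``(m, K)`` measurements sampled at ``fs`` Hz."""

    y: np.ndarray
    fs: float
    times: np.ndarray | None = None

    def __post_init__(self):
        y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if y.shape[1] < 1:
            raise ValueError("need at least one time sample")
        if not np.all(np.isfinite(y)):
            raise ValueError("sensor data contains non-finite entries")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        times = self.times
        if times is None:
            times = np.arange(y.shape[1]) / float(self.fs)
        else:
            times = np.asarray(times, dtype=float)
            if times.shape != (y.shape[1],):
                raise ValueError("times must have one entry per sample")
            dt = np.diff(times)
            if times.size > 1 and (
                np.any(dt <= 0) or np.max(np.abs(dt - 1.0 / self.fs)) > 1e-9 / self.fs
            ):
                raise ValueError("times must increase in steps of 1/fs")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "times", times)

    @property
    def m(self) -> int:
        return self.y.shape[0]

    @property
    def K(self) -> int:
        return self.y.shape[1]


@dataclass(frozen=True)
class NoiseModel:
    """Sensor-noise covariance with its (lazily computed) precision.

    ``kind`` is one of ``{"fixed-diagonal", "learned-diagonal", "structured"}``.
    """

    covariance: np.ndarray
    kind: str = "fixed-diagonal"

    def __post_init__(self):
        cov = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        check_symmetric(cov, tol=1e-8, name="noise covariance")
        cov = sym(cov)
        w = np.linalg.eigvalsh(cov)
        if w[0] < -1e-10 * max(np.trace(cov), 1e-300):
            raise ValueError("noise covariance has significantly negative eigenvalues")
        if self.kind not in {"fixed-diagonal", "learned-diagonal", "structured"}:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        object.__setattr__(self, "covariance", cov)

    @property
    def m(self) -> int:
        return self.covariance.shape[0]

    @property
    def precision(self) -> np.ndarray:
        """Inverse covariance, computed with diagonal jitter when needed."""
        return spd_inverse(self.covariance)


@dataclass
class ChampagneState:
    """Mutable solver state: variances, posterior means, model covariance, cost."""

    source_variances: np.ndarray
    xbar: np.ndarray | None = None
    Sigma_y: np.ndarray | None = None
    gamma_diag_terms: np.ndarray | None = None
    cost_trace: list[float] = field(default_factory=list)


def _check_dims(leadfield: LeadField, v: np.ndarray, noise: NoiseModel) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if v.shape[0] != leadfield.n:
        raise ValueError(f"v has length {v.shape[0]}, expected n={leadfield.n}")
    if noise.m != leadfield.m:
        raise ValueError(
            f"noise covariance is {noise.m}x{noise.m}, lead-field has m={leadfield.m}"
        )
    if not np.all(np.isfinite(v)):
        raise ValueError("source variances contain non-finite entries")
    if np.any(v < 0):
        raise ValueError("source variances must be nonnegative")
    return v


def compute_model_covariance(
    leadfield: LeadField, v: np.ndarray, noise: NoiseModel
) -> np.ndarray:
    """Model data covariance ``Sigma_y = Sigma_n + L diag(v) L^T`` (symmetrized)."""
    v = _check_dims(leadfield, v, noise)
    L = leadfield.gain
    active = v > 0
    if not np.any(active):
        return sym(noise.covariance.copy())
    La = L[:, active]
    return sym(noise.covariance + (La * v[active]) @ La.T)


def compute_posterior_sources(
    data: SensorDataset,
    leadfield: LeadField,
    v: np.ndarray,
    noise: NoiseModel,
    Sigma_y: np.ndarray | None = None,
    return_precision: bool = False,
):
    """Posterior mean of the sources, ``xbar_k = diag(v) L^T Sigma_y^-1 y_k``.

    With ``return_precision=True`` also returns the posterior precision
    ``Gamma = diag(1/v) + L^T Lambda L`` restricted to active voxels
    (``v_i > 0``); pruned voxels carry zero posterior mean and are excluded.

    Returns
    -------
    xbar : (n, K) ndarray
    info : dict with keys ``active`` (bool mask) and, on request,
        ``posterior_precision`` ((n_active, n_active)).
    """
    v = _check_dims(leadfield, v, noise)
    if data.m != leadfield.m:
        raise ValueError("data and lead-field sensor counts differ")
    L = leadfield.gain
    if Sigma_y is None:
        Sigma_y = compute_model_covariance(leadfield, v, noise)
    xbar = np.zeros((leadfield.n, data.K))
    active = v > 0
    if np.any(active):
        # diag(v) L^T Sigma_y^-1 Y, active rows only
        xbar[active] = v[active, None] * (L[:, active].T @ cho_solve_spd(Sigma_y, data.y))
    info: dict = {"active": active}
    if return_precision:
        La = L[:, active]
        Lam = noise.precision
        info["posterior_precision"] = sym(np.diag(1.0 / v[active]) + La.T @ Lam @ La)
    return xbar, info


def champagne_cost(data: SensorDataset, Sigma_y: np.ndarray) -> float:
    """Negative log-evidence cost ``log|Sigma_y| + mean_k y_k^T Sigma_y^-1 y_k``.

    Up to the affine constant ``m log(2 pi)`` this is ``-2/K`` times the joint
    Gaussian log-likelihood of the ``K`` columns; it is *minimized*.
    """
    check_symmetric(Sigma_y, name="Sigma_y")
    quad = float(np.sum(data.y * cho_solve_spd(Sigma_y, data.y))) / data.K
    return slogdet_spd(Sigma_y) + quad


def update_source_variances(
    xbar: np.ndarray,
    leadfield: LeadField,
    Sigma_y: np.ndarray,
    variance_update: str = "sqrt",
    prune: bool = True,
):
    """Convex-bounding fixed-point update of the per-voxel source variances.

    ``g_i = l_i^T Sigma_y^-1 l_i``;
    ``sqrt`` mode (default): ``v_i = sqrt(mean_k xbar_ik^2 / g_i)``;
    ``as_printed`` mode: ``v_i = mean_k xbar_ik^2 / g_i``.

    Voxels whose updated variance falls below ``PRUNE_REL_TOL * max(v)`` are
    clamped to exactly 0 when ``prune`` is set.

    Returns
    -------
    v : (n,) nonnegative ndarray
    g : (n,) ndarray of the quadratic terms ``g_i``
    """
    if variance_update not in {"sqrt", "as_printed"}:
        raise ValueError(f"unknown variance_update {variance_update!r}")
    xbar = np.asarray(xbar, dtype=float)
    L = leadfield.gain
    K = xbar.shape[1]
    g = np.sum(L * cho_solve_spd(Sigma_y, L), axis=0)
    zero_cols = g <= 0
    if np.any(zero_cols):
        col_norms = np.linalg.norm(L, axis=0)
        bad = zero_cols & (col_norms > 0)
        if np.any(bad):
            raise NumericalError(
                "nonpositive quadratic term g_i for a nonzero lead-field column; "
                "Sigma_y is not positive definite"
            )
        warnings.warn(
            f"{int(np.sum(zero_cols))} zero lead-field column(s); variances set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    power = np.mean(xbar**2, axis=1) if K else np.zeros(L.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(zero_cols, 0.0, power / np.where(zero_cols, 1.0, g))
    v = np.sqrt(ratio) if variance_update == "sqrt" else ratio
    if prune and v.size and v.max() > 0:
        v[v < PRUNE_REL_TOL * v.max()] = 0.0
    return v, g
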
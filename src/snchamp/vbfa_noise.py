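"""Variational Bayesian factor analysis (VBFA) of sensor-space residuals.

Models a residual matrix ``Z`` (m sensors x K samples) as ``z_k = A u_k + e``
with standard-normal factors ``u_k``, ARD priors on the columns of the mixing
matrix ``A`` (precisions ``alpha``), and diagonal modeling-noise precision
``Omega``.  The fitted state yields a structured (low-rank + diagonal) noise
covariance for the source solver.

With ``q = 0`` the machinery reduces exactly to per-sensor residual variance
learning, which is the package's diagonal noise-learning mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._linalg import psd_project, spd_inverse, sym
from .model_core import NoiseModel

__all__ = [
    "ResidualSet",
    "VBFAState",
    "vbfa_e_step",
    "vbfa_m_step",
    "vbfa_fit",
    "vbfa_init",
    "noise_covariance",
    "auto_factor_count",
]


@dataclass(frozen=True)
class ResidualSet:
    """Residuals ``z = y - L xbar`` at one outer iteration of the solver.

    ``scatter_correction`` optionally carries the posterior source-uncertainty
    term ``K L Gamma^-1 L^T`` so that ``R_zz`` is the *expected* residual
    scatter under the source posterior rather than the scatter of the point
    residuals alone.  Without it, ``R_zz`` is exactly ``sum_k z_k z_k^T``.
    The correction keeps the alternating noise update away from its degenerate
    zero fixed point: the point residuals are posterior-shrunk copies of the
    noise, and feeding their scatter straight back in contracts the noise
    covariance to zero.
    """

    z: np.ndarray
    iteration: int = 0
    scatter_correction: np.ndarray | None = None

    def __post_init__(self):
        z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if not np.all(np.isfinite(z)):
            raise ValueError("residuals contain non-finite entries")
        object.__setattr__(self, "z", z)
        if self.scatter_correction is not None:
            corr = sym(np.asarray(self.scatter_correction, dtype=float))
            if corr.shape != (z.shape[0], z.shape[0]):
                raise ValueError("scatter_correction must be m x m")
            object.__setattr__(self, "scatter_correction", corr)

    @property
    def m(self) -> int:
        return self.z.shape[0]

    @property
    def K(self) -> int:
        return self.z.shape[1]

    @property
    def R_zz(self) -> np.ndarray:
        """Residual scatter ``sum_k z_k z_k^T`` (+ posterior correction if set)."""
        scatter = self.z @ self.z.T
        if self.scatter_correction is not None:
            scatter = sym(scatter + self.scatter_correction)
        return scatter


@dataclass
class VBFAState:
    """Parameters, factor moments and hyperparameters of the VBFA model.

    ``Omega_inv`` holds the per-sensor modeling-noise *variances* (the diagonal
    of the inverse of the precision matrix Omega); ``Sigma_u`` is the posterior
    *precision* of the factors.
    """

    A: np.ndarray
    Omega_inv: np.ndarray
    alpha: np.ndarray
    Psi: np.ndarray
    ubar: np.ndarray | None = None
    Sigma_u: np.ndarray | None = None
    R_uu: np.ndarray | None = None
    R_zu: np.ndarray | None = None
    R_zz: np.ndarray | None = None
    K: int = 0
    converged: bool = False
    n_iter: int = 0
    trace: list[float] = field(default_factory=list)
    n_clip_warnings: int = 0

    @property
    def q(self) -> int:
        return self.A.shape[1]

    @property
    def m(self) -> int:
        return self.A.shape[0]


def _omega_floor(R_zz: np.ndarray, K: int) -> float:
    floor = 1e-12 * float(np.mean(np.diag(R_zz))) / max(K, 1)
    return max(floor, 1e-30)


def vbfa_init(residuals: ResidualSet, q: int, seed: int | None = 0) -> VBFAState:
    """Deterministic (per seed) initialization.

    ``A`` starts at the top-``q`` eigenvectors of ``R_zz/K`` scaled by the
    square roots of their eigenvalues, plus small seeded Gaussian jitter;
    ``Omega_inv`` at the per-sensor sample variances; ``alpha = 1``; ``Psi = I``.
    """
    m, K = residuals.m, residuals.K
    if q > m:
        raise ValueError(f"factor count q={q} exceeds sensor count m={m}")
    if q < 0:
        raise ValueError("factor count must be nonnegative")
    R_zz = residuals.R_zz
    sample_cov = R_zz / max(K, 1)
    floor = _omega_floor(R_zz, K)
    Omega_inv = np.maximum(np.diag(sample_cov).copy(), floor)
    if q == 0:
        A = np.zeros((m, 0))
    else:
        w, vec = np.linalg.eigh(sym(sample_cov))
        order = np.argsort(w)[::-1][:q]
        A = vec[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
        rng = np.random.default_rng(seed)
        scale = np.sqrt(max(float(np.mean(np.diag(sample_cov))), floor))
        A = A + 1e-3 * scale * rng.standard_normal((m, q))
    return VBFAState(
        A=A,
        Omega_inv=Omega_inv,
        alpha=np.ones(q),
        Psi=np.eye(q),
        R_zz=R_zz,
        K=K,
    )


def vbfa_e_step(residuals: ResidualSet, state: VBFAState) -> VBFAState:
    """Update the factor posterior moments given current ``A``, ``Omega``, ``Psi``.

    ``Sigma_u = A^T Omega A + m Psi^-1 + I`` (posterior factor precision);
    ``ubar_k = Sigma_u^-1 A^T Omega z_k``;
    ``R_uu = sum_k ubar_k ubar_k^T + K Sigma_u^-1``;
    ``R_zu = sum_k z_k ubar_k^T``.
    """
    m, K = residuals.m, residuals.K
    A, Omega_inv = state.A, state.Omega_inv
    q = A.shape[1]
    if q == 0:
        state.ubar = np.zeros((0, K))
        state.Sigma_u = np.zeros((0, 0))
        state.R_uu = np.zeros((0, 0))
        state.R_zu = np.zeros((m, 0))
        state.R_zz = residuals.R_zz
        return state
    AtOmega = A.T / Omega_inv  # A^T Omega, Omega diagonal
    Sigma_u = sym(AtOmega @ A + m * spd_inverse(state.Psi) + np.eye(q))
    Sigma_u_inv = spd_inverse(Sigma_u)
    W = Sigma_u_inv @ AtOmega  # ubar_k = W z_k
    R_zz = residuals.R_zz
    state.Sigma_u = Sigma_u
    state.ubar = W @ residuals.z
    # via the scatter matrix these equal sum_k ubar ubar^T + K Sigma_u^-1 and
    # sum_k z_k ubar_k^T when no posterior correction is attached
    state.R_uu = sym(W @ R_zz @ W.T + K * Sigma_u_inv)
    state.R_zu = R_zz @ W.T
    state.R_zz = R_zz
    return state


def vbfa_m_step(residuals: ResidualSet, state: VBFAState) -> VBFAState:
    """Update ``A``, ``Psi``, ``alpha``, ``Omega_inv`` from the factor moments.

    ``A = R_zu (R_uu + diag(alpha))^-1``; ``Psi = R_uu + diag(alpha)``;
    ``alpha^-1 = diag[(1/m) A^T Omega A + Psi^-1]``;
    ``Omega_inv = diag[(1/K)(R_zz - A R_uz)]`` (diagonal extraction; floored,
    negative entries clipped with a counted warning).
    """
    m, K = residuals.m, residuals.K
    q = state.q
    R_zz = state.R_zz if state.R_zz is not None else residuals.R_zz
    floor = _omega_floor(R_zz, K)
    if q == 0:
        state.Omega_inv = np.maximum(np.diag(R_zz) / max(K, 1), floor)
        state.R_zz = R_zz
        return state
    Psi = sym(state.R_uu + np.diag(state.alpha))
    A = np.linalg.solve(Psi, state.R_zu.T).T  # R_zu (R_uu + alpha)^-1
    Psi_inv = spd_inverse(Psi)
    AtOmegaA = (A.T / state.Omega_inv) @ A
    alpha_inv = np.diag(AtOmegaA) / m + np.diag(Psi_inv)
    omega_diag = (np.diag(R_zz) - np.sum(A * state.R_zu, axis=1)) / max(K, 1)
    n_neg = int(np.sum(omega_diag < floor))
    if np.any(omega_diag < 0):
        warnings.warn(
            "negative modeling-noise variance clipped to floor",
            RuntimeWarning,
            stacklevel=2,
        )
    state.n_clip_warnings += n_neg if np.any(omega_diag < 0) else 0
    state.A = A
    state.Psi = Psi
    state.alpha = 1.0 / np.maximum(alpha_inv, 1e-300)
    state.Omega_inv = np.maximum(omega_diag, floor)
    return state


def vbfa_fit(
    residuals: ResidualSet,
    q: int,
    max_iter: int = 50,
    tol: float = 1e-6,
    seed: int | None = 0,
    init: VBFAState | None = None,
) -> VBFAState:
    """Alternate e-step/m-step until the parameters stop moving.

    Convergence surrogate: relative Frobenius change of the stacked parameter
    block ``[A | Omega_inv]`` below ``tol``.  ``init`` allows warm-starting
    from a previous state (its moments are refreshed against ``residuals``).
    """
    if q > residuals.m:
        raise ValueError(f"factor count q={q} exceeds sensor count m={residuals.m}")
    state = vbfa_init(residuals, q, seed=seed) if init is None else init
    if state.q != q:
        raise ValueError("warm-start state has a different factor count")
    state.R_zz = residuals.R_zz
    state.K = residuals.K

    def _params(s: VBFAState) -> np.ndarray:
        return np.concatenate([s.A.ravel(), s.Omega_inv])

    prev = _params(state)
    state.trace = []
    state.converged = False
    for it in range(1, max_iter + 1):
        vbfa_e_step(residuals, state)
        vbfa_m_step(residuals, state)
        cur = _params(state)
        denom = max(float(np.linalg.norm(cur)), 1e-300)
        change = float(np.linalg.norm(cur - prev)) / denom
        state.trace.append(change)
        state.n_iter = it
        prev = cur
        if change < tol:
            state.converged = True
            break
    # leave moments consistent with the final parameters
    vbfa_e_step(residuals, state)
    return state


def noise_covariance(state: VBFAState, mode: str = "fa_model") -> NoiseModel:
    """Structured noise covariance implied by a fitted VBFA state.

    ``fa_model`` (default): ``Sigma_n = (1/K) A R_uu A^T + diag(Omega_inv)``,
    the marginal covariance of the factor model.  ``as_printed``:
    ``Sigma_n = (1/K) A R_uu A^T + (1/K) diag(Omega_inv) tr(R_uu Psi^-1)``.
    The result is symmetrized and projected onto the PSD cone.
    """
    if mode not in {"fa_model", "as_printed"}:
        raise ValueError(f"unknown noise covariance mode {mode!r}")
    K = max(state.K, 1)
    m = state.m
    if state.q == 0:
        low_rank = np.zeros((m, m))
    else:
        if state.R_uu is None:
            raise ValueError("state has no factor moments; run at least one e-step")
        low_rank = (state.A @ state.R_uu @ state.A.T) / K
    if mode == "fa_model":
        diag_term = np.diag(state.Omega_inv)
    else:
        if state.q == 0:
            diag_term = np.diag(state.Omega_inv) * 0.0
        else:
            trace_term = float(np.trace(state.R_uu @ spd_inverse(state.Psi)))
            diag_term = np.diag(state.Omega_inv) * (trace_term / K)
    cov = psd_project(sym(low_rank + diag_term))
    kind = "learned-diagonal" if state.q == 0 else "structured"
    return NoiseModel(covariance=cov, kind=kind)


def auto_factor_count(residuals: ResidualSet, cap: int | None = None) -> int:
    """Heuristic factor count: eigenvalues of ``R_zz/K`` above twice the median.

    Deterministic and cheap; ARD prunes any excess.  Capped at ``m - 1``.
    """
    m, K = residuals.m, residuals.K
    w = np.linalg.eigvalsh(sym(residuals.R_zz / max(K, 1)))
    med = float(np.median(w))
    q = int(np.sum(w > 2.0 * med))
    limit = m - 1 if cap is None else min(cap, m - 1)
    return int(np.clip(q, 0, max(limit, 0)))
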
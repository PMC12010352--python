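"""Outer alternating solver: sources <-> source variances <-> structured noise.

One outer iteration performs, in order:

1. posterior source means from the current variances and noise covariance,
2. the convex-bounding variance update,
3. a noise-covariance refresh from the residuals ``y - L xbar`` — either a
   VBFA fit (``structured``), per-sensor variances (``diagonal-learned``,
   identical to a VBFA with zero factors), or nothing (``fixed``).

The loop stops when the relative change of the evidence cost falls below
``outer_tol`` or after ``max_outer_iter`` sweeps.  Everything is deterministic
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._linalg import NumericalError, cho_solve_spd
from .model_core import (
    ChampagneState,
    LeadField,
    NoiseModel,
    SensorDataset,
    champagne_cost,
    compute_model_covariance,
    compute_posterior_sources,
    update_source_variances,
)
from .vbfa_noise import (
    ResidualSet,
    VBFAState,
    auto_factor_count,
    noise_covariance,
    vbfa_fit,
)

__all__ = ["SNCOptions", "SNCResult", "snc_fit", "reconstruct_power_map"]

_NOISE_KINDS = {"fixed", "diagonal-learned", "structured"}


@dataclass(frozen=True)
class SNCOptions:
    """Knobs of the alternating solver; defaults follow the reference protocol."""

    max_outer_iter: int = 100
    outer_tol: float = 1e-6
    q: int | str = "auto"
    noise_kind: str = "structured"
    noise_update_every: int = 1
    #: sweeps of plain variance updates before the first noise refresh; gives
    #: the source pruning time to leave a residual with genuine noise
    #: structure (an immediate refresh sees an almost noise-free residual)
    noise_burn_in: int = 10
    seed: int = 0
    variance_update: str = "sqrt"
    noise_cov_mode: str = "fa_model"
    initial_noise_scale: float = 0.1
    vbfa_max_iter: int = 50
    vbfa_tol: float = 1e-6
    warm_start: bool = True

    def __post_init__(self):
        if self.max_outer_iter < 1:
            raise ValueError("max_outer_iter must be >= 1")
        if self.outer_tol <= 0 or self.vbfa_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.noise_kind not in _NOISE_KINDS:
            raise ValueError(f"noise_kind must be one of {sorted(_NOISE_KINDS)}")
        if self.noise_update_every < 1:
            raise ValueError("noise_update_every must be >= 1")
        if self.noise_burn_in < 0:
            raise ValueError("noise_burn_in must be >= 0")
        if not (self.q == "auto" or (isinstance(self.q, int) and self.q >= 0)):
            raise ValueError("q must be 'auto' or a nonnegative integer")
        if self.initial_noise_scale <= 0:
            raise ValueError("initial_noise_scale must be positive")


@dataclass
class SNCResult:
    """Reconstruction output: variances, time courses, noise model, diagnostics."""

    source_variances: np.ndarray
    xbar: np.ndarray
    power_map: np.ndarray
    noise: NoiseModel
    cost_trace: list[float]
    n_iter: int
    converged: bool
    residual_norms: list[float] = field(default_factory=list)
    vbfa: VBFAState | None = None
    options: SNCOptions | None = None


class DivergenceError(NumericalError):
    """Cost increased for several consecutive sweeps; diagnostic state attached."""

    def __init__(self, message: str, state: ChampagneState):
        super().__init__(message)
        self.state = state


def _learn_noise(
    residuals: ResidualSet, q: int, opts: SNCOptions, warm: VBFAState | None
) -> tuple[NoiseModel, VBFAState]:
    init = warm if (opts.warm_start and warm is not None and warm.q == q) else None
    state = vbfa_fit(
        residuals,
        q=q,
        max_iter=opts.vbfa_max_iter,
        tol=opts.vbfa_tol,
        seed=opts.seed,
        init=init,
    )
    return noise_covariance(state, mode=opts.noise_cov_mode), state


def snc_fit(
    data: SensorDataset,
    leadfield: LeadField,
    opts: SNCOptions | None = None,
    noise0: NoiseModel | None = None,
) -> SNCResult:
    """Run the alternating source/variance/noise loop to convergence.

    Parameters
    ----------
    noise0
        Optional initial (and, for ``noise_kind='fixed'``, permanent) noise
        model.  Defaults to a scaled identity,
        ``initial_noise_scale * mean(y**2) * I``.
    """
    opts = opts or SNCOptions()
    if data.m != leadfield.m:
        raise ValueError("data and lead-field sensor counts differ")
    lf = leadfield if leadfield.normalized else leadfield.normalized_copy()
    m, n, K = lf.m, lf.n, data.K

    if noise0 is None:
        floor = float(np.mean(data.y**2))
        if floor <= 0:
            floor = 1.0
        noise = NoiseModel(opts.initial_noise_scale * floor * np.eye(m))
    else:
        noise = noise0

    v = np.ones(n)
    q = opts.q
    if opts.noise_kind == "diagonal-learned":
        q = 0
    cost_trace: list[float] = []
    residual_norms: list[float] = []
    vbfa_state: VBFAState | None = None
    xbar = np.zeros((n, K))
    converged = False
    n_bad = 0
    state = ChampagneState(source_variances=v, cost_trace=cost_trace)

    for it in range(1, opts.max_outer_iter + 1):
        Sigma_y = compute_model_covariance(lf, v, noise)
        xbar, _ = compute_posterior_sources(data, lf, v, noise, Sigma_y=Sigma_y)
        v, _ = update_source_variances(
            xbar, lf, Sigma_y, variance_update=opts.variance_update
        )

        learn_noise = (
            opts.noise_kind != "fixed"
            and it > opts.noise_burn_in
            and (it - opts.noise_burn_in) % opts.noise_update_every == 0
        )
        if learn_noise:
            # expected residual scatter under the source posterior adds
            # K * L Gamma^-1 L^T = K * (C - C Sigma_y^-1 C) with C = Sigma_y - Sigma_n
            C = Sigma_y - noise.covariance
            correction = K * (C - C @ cho_solve_spd(Sigma_y, C))
            residuals = ResidualSet(
                data.y - lf.gain @ xbar,
                iteration=it,
                scatter_correction=correction,
            )
            residual_norms.append(float(np.linalg.norm(residuals.z)))
            if q == "auto":
                q = auto_factor_count(residuals)
            noise, vbfa_state = _learn_noise(residuals, q, opts, vbfa_state)

        cost = champagne_cost(data, compute_model_covariance(lf, v, noise))
        cost_trace.append(cost)
        state.source_variances, state.xbar, state.Sigma_y = v, xbar, Sigma_y

        if len(cost_trace) > 1:
            prev = cost_trace[-2]
            rel = (cost - prev) / max(abs(prev), 1e-300)
            if rel > 1e-3:
                n_bad += 1
                if n_bad >= 5:
                    raise DivergenceError(
                        f"cost increased for {n_bad} consecutive sweeps "
                        f"(last {prev:.6g} -> {cost:.6g})",
                        state,
                    )
            else:
                n_bad = 0
            if abs(rel) < opts.outer_tol:
                converged = True
                break

    # final posterior consistent with the last variances and noise model
    Sigma_y = compute_model_covariance(lf, v, noise)
    xbar, _ = compute_posterior_sources(data, lf, v, noise, Sigma_y=Sigma_y)
    result = SNCResult(
        source_variances=v,
        xbar=xbar,
        power_map=np.mean(xbar**2, axis=1),
        noise=noise,
        cost_trace=cost_trace,
        n_iter=len(cost_trace),
        converged=converged,
        residual_norms=residual_norms,
        vbfa=vbfa_state,
        options=opts,
    )
    return result


def reconstruct_power_map(result: SNCResult) -> np.ndarray:
    """Per-voxel mean squared reconstructed time course, ``(1/K) sum_k xbar_ik^2``."""
    return np.mean(np.asarray(result.xbar, dtype=float) ** 2, axis=1)
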
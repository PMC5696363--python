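"""Hierarchical Bayesian Elitist Lasso via a pairwise-MRF decomposition.

The mixed-norm prior ``exp(-alpha * sum_t ||J_t||_1^2)`` is not separable
across generators, but conditioning each amplitude on the summed absolute
values of the others (``delta_it = sum_{j != i} |J_jt|``) yields a
Normal x Laplace conditional that admits the same truncated-Gamma scale
mixture as the elastic net, with truncation limit ``alpha * delta^2``.
A single global ``alpha`` couples every time point; ``delta`` is not
optimized (the objective is non-differentiable there) but refreshed from
the current posterior mean once per sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import optimize

from . import _updates as upd
from .core import (
    EEGRecording,
    LeadField,
    PriorVariance,
    SpatioTemporalSource,
    gaussian_posterior,
    type2_objective,
)
from .enet import FitResult, _init_common

__all__ = [
    "ELASSOConfig",
    "ELASSOHyperState",
    "elasso_effective_variance",
    "update_delta",
    "winv_apply",
    "elasso_gamma_objective",
    "elasso_alpha_objective",
    "elasso_update_hyperparameters",
    "elasso_hyper_neglogprior",
    "elasso_fit",
]


@dataclass
class ELASSOConfig:
    max_iter: int = 30
    tol: float = 3e-3
    seed: int = 0
    lam_bar_floor: float = 1e-6
    descent_tol: float = 1e-8
    # One noise variance for the whole record.  With per-time beta_t the
    # quadratic column penalty alpha * ||J_t||_1^2 makes it cheaper to
    # absorb strong columns into beta_t than to represent them, which
    # flattens the activation profile; a shared beta cannot do that.
    shared_beta: bool = True

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.lam_bar_floor <= 0 or self.lam_bar_floor >= 1:
            raise ValueError("lam_bar_floor must lie in (0, 1)")


@dataclass
class ELASSOHyperState:
    """Hyperparameters: gamma, delta are S x T; alpha is one global scalar."""

    gamma: np.ndarray
    delta: np.ndarray
    alpha: float
    beta: np.ndarray

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.alpha = float(self.alpha)
        if self.alpha <= 0 or np.any(self.beta <= 0) or np.any(self.delta < 0):
            raise ValueError("alpha, beta must be positive and delta nonnegative")
        if np.any(self.gamma <= self.alpha * self.delta ** 2):
            raise ValueError("support violation: gamma must exceed alpha * delta^2")

    def copy(self) -> "ELASSOHyperState":
        return ELASSOHyperState(self.gamma.copy(), self.delta.copy(),
                                self.alpha, self.beta.copy())


def elasso_effective_variance(gamma, delta, alpha: float,
                              floor: float = 1e-6) -> PriorVariance:
    """Effective prior variance ``lam = (1 - alpha delta^2 / gamma) / (2 alpha)``."""
    gamma = np.asarray(gamma, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    limit = alpha * delta ** 2
    if np.any(gamma <= limit):
        raise ValueError("support violation: gamma must exceed alpha * delta^2")
    raw = np.where(limit == 0, 1.0, 1.0 - limit / np.where(gamma > 0, gamma, 1.0))
    lam_bar = upd.clip_lam_bar(raw, floor)
    return PriorVariance(lam=lam_bar / (2.0 * alpha), lam_bar=lam_bar)


def update_delta(mu: np.ndarray) -> np.ndarray:
    """Cross-component couplings ``delta_it = sum_{j != i} |mu_jt|``.

    Computed as the column L1 norm minus the own term, O(S T) total.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    a = np.abs(mu)
    return a.sum(axis=0, keepdims=True) - a


def winv_apply(delta_col: np.ndarray) -> np.ndarray:
    """Apply ``W^{-1}`` with ``W = ones - I``: ``(sum delta)/(S-1) - delta``."""
    delta_col = np.asarray(delta_col, dtype=float)
    n = delta_col.shape[0]
    if n < 2:
        raise ValueError("W = ones - I is singular for S = 1")
    return delta_col.sum() / (n - 1) - delta_col


# ---------------------------------------------------------------------------
# Coordinate objectives
# ---------------------------------------------------------------------------

def elasso_gamma_objective(gamma, m: float, alpha: float, delta: float):
    """Type-II terms depending on one ``gamma`` (support ``gamma > alpha delta^2``)."""
    gamma = np.asarray(gamma, dtype=float)
    limit = alpha * delta ** 2
    lam_bar = np.ones_like(gamma) if limit == 0 else 1.0 - limit / gamma
    lam = lam_bar / (2.0 * alpha)
    out = np.where(
        lam > 0,
        0.5 * np.log(np.where(lam > 0, lam, 1.0)) + m / (2.0 * np.where(lam > 0, lam, 1.0)),
        np.inf,
    )
    return out + 0.5 * np.log(gamma) + gamma


def elasso_alpha_objective(alpha, gamma: np.ndarray, delta: np.ndarray,
                           m: np.ndarray, winv_l1_sq: np.ndarray,
                           floor: float = 1e-6):
    """Type-II terms depending on the single global sparsity level ``alpha``.

    Pools every time point: the per-coordinate variance terms, every
    truncation normalizer ``log Gamma_bar(alpha delta^2)``, the
    ``-(S T / 2) log alpha`` normalizer of the coupling prior and the
    ``alpha * ||W^{-1} delta_t||_1^2`` penalties.  Like the elastic-net
    ``k`` objective, it is evaluated along the continuous path
    ``gamma_eff = max(gamma, alpha delta^2 / (1 - floor))``, which keeps it
    finite for every positive ``alpha`` while never letting gammas shrink
    (the joint minimization over shrinking gammas is unbounded below).
    Broadcasts over a vector of ``alpha`` values.
    """
    alpha = np.asarray(alpha, dtype=float)
    scalar = alpha.ndim == 0
    av = np.atleast_1d(alpha)
    n_gen, n_times = gamma.shape
    g = gamma.ravel()
    d2 = (delta ** 2).ravel()
    mv = np.asarray(m, dtype=float).ravel()
    wsum = float(np.sum(winv_l1_sq))

    out = np.empty(av.shape[0])
    for idx, a in enumerate(av):
        limit = a * d2
        g_eff = np.maximum(g, limit / (1.0 - floor))
        lam_bar = 1.0 - limit / g_eff                   # in [floor, 1]
        out[idx] = (
            float(np.sum(0.5 * np.log(lam_bar / (2.0 * a)) + a * mv / lam_bar
                         + 0.5 * np.log(g_eff) + g_eff
                         + upd.log_upper_gamma_half(limit)))
            - 0.5 * n_gen * n_times * np.log(a) + a * wsum)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Updates
# ---------------------------------------------------------------------------

def _gamma_update_matrix(m: np.ndarray, alpha: float, delta: np.ndarray,
                         gamma_cur: np.ndarray, floor: float) -> np.ndarray:
    """Argmin of each gamma at fixed (alpha, delta); coordinates with
    ``delta == 0`` are skipped (their variance factor ignores gamma)."""
    limit = alpha * delta ** 2
    active = limit > 0
    gamma = gamma_cur.copy()
    if not active.any():
        return gamma
    u = upd.gamma_stationary_excess(alpha, m[active], limit[active])
    g = limit[active] + u
    raw = u / g
    g = np.where(raw < floor, limit[active] / (1.0 - floor), g)
    gamma[active] = g
    return gamma


def _alpha_update(state: ELASSOHyperState, m: np.ndarray,
                  winv_l1_sq: np.ndarray, config: ELASSOConfig) -> float:
    lo = max(upd.HYPER_MIN, state.alpha * 1e-6)
    hi = min(upd.HYPER_MAX, state.alpha * 1e6)

    def fun(a):
        return elasso_alpha_objective(a, state.gamma, state.delta, m,
                                      winv_l1_sq, floor=config.lam_bar_floor)

    cur = float(np.clip(state.alpha, lo, hi))
    best_x, best_f = upd.refine_candidates(fun, lo, hi, cur, n_grid=192)
    f_cur = float(fun(cur))
    if best_f > f_cur + config.descent_tol * (1.0 + abs(f_cur)):
        raise RuntimeError("alpha update increased its coordinate objective")
    return best_x if best_f < f_cur else cur


def elasso_update_hyperparameters(state: ELASSOHyperState, posteriors,
                                  V, K, config: ELASSOConfig) -> ELASSOHyperState:
    """One sweep: delta (refresh, not minimized), gamma, the global alpha,
    gamma again (support re-projection after alpha moved), then beta."""
    new = state.copy()
    n_times = new.beta.shape[0]
    if len(posteriors) != n_times:
        raise ValueError("one posterior per time point is required")
    mu = np.column_stack([p.mu for p in posteriors])
    m = np.column_stack([p.mu ** 2 + p.sigma_diag for p in posteriors])
    if not np.all(np.isfinite(m)):
        raise FloatingPointError("non-finite posterior moments")
    floor = config.lam_bar_floor

    new.delta = update_delta(mu)
    new.gamma = _gamma_update_matrix(m, new.alpha, new.delta, new.gamma, floor)
    winv_l1_sq = np.array([
        float(np.sum(np.abs(winv_apply(new.delta[:, t]))) ** 2)
        for t in range(n_times)])
    new.alpha = _alpha_update(new, m, winv_l1_sq, config)
    new.gamma = _gamma_update_matrix(m, new.alpha, new.delta, new.gamma, floor)
    for t in range(n_times):
        post = posteriors[t]
        new.beta[t] = upd.beta_update(float(post.residual @ post.residual)
                                      + post.trace_ksk, post.residual.shape[0])
    if config.shared_beta:
        # exact joint update: sum_t (rss_t + tr_t) / (N T) = mean of per-t argmins
        new.beta[:] = float(np.mean(new.beta))
    return new


def elasso_hyper_neglogprior(state: ELASSOHyperState) -> float:
    """Negative log prior of the ELASSO hyperparameters (constants dropped)."""
    limit = state.alpha * state.delta ** 2
    trunc = upd.log_upper_gamma_half(limit)
    n_gen, n_times = state.gamma.shape
    winv_l1_sq = sum(
        float(np.sum(np.abs(winv_apply(state.delta[:, t]))) ** 2)
        for t in range(n_times)) if n_gen >= 2 else 0.0
    return float(np.sum(trunc)
                 + 0.5 * np.sum(np.log(state.gamma)) + np.sum(state.gamma)
                 - 0.5 * n_gen * n_times * np.log(state.alpha)
                 + state.alpha * winv_l1_sq)


def elasso_fit(V, K, config: ELASSOConfig | None = None) -> FitResult:
    """Run the ELASSO empirical-Bayes solver; one joint run over the S x T
    map, since the single ``alpha`` couples all time points."""
    config = config or ELASSOConfig()
    Vmat, Kmat, n_sensors, n_times, beta0, scale = _init_common(V, K)
    n_gen = Kmat.shape[1]
    alpha = float(np.clip(1.0 / (2.0 * max(float(np.mean(scale)), 1e-300)),
                          upd.HYPER_MIN, upd.HYPER_MAX))
    beta_init = np.full(n_times, float(np.mean(beta0))) if config.shared_beta \
        else beta0.copy()
    state = ELASSOHyperState(gamma=np.ones((n_gen, n_times)),
                             delta=np.zeros((n_gen, n_times)),
                             alpha=alpha, beta=beta_init)

    # Warm-up half-sweep: the couplings start at delta = 0, which makes the
    # very first objective value incomparable with every later one (the
    # pairwise terms are switched off).  One posterior pass plus one sweep
    # turns them on before the trajectory is recorded.
    lams0 = [elasso_effective_variance(state.gamma[:, t], state.delta[:, t],
                                       state.alpha, config.lam_bar_floor)
             for t in range(n_times)]
    posts0 = [gaussian_posterior(Kmat, Vmat[:, t], lams0[t], state.beta[t])
              for t in range(n_times)]
    state = elasso_update_hyperparameters(state, posts0, Vmat, Kmat, config)

    objective_traj: List[float] = []
    hyper_traj = [state.copy()]
    posteriors = None
    converged = False
    n_iter = 0
    for it in range(config.max_iter):
        lams = [elasso_effective_variance(state.gamma[:, t], state.delta[:, t],
                                          state.alpha, config.lam_bar_floor)
                for t in range(n_times)]
        posteriors = [gaussian_posterior(Kmat, Vmat[:, t], lams[t], state.beta[t])
                      for t in range(n_times)]
        obj = type2_objective(posteriors, lams,
                              elasso_hyper_neglogprior(state), state.beta)
        if objective_traj:
            prev = objective_traj[-1]
            if obj > prev + config.descent_tol * (1.0 + abs(prev)):
                raise RuntimeError(
                    f"type-II objective increased: {prev} -> {obj} at iteration {it}")
        objective_traj.append(obj)
        n_iter = it + 1
        if len(objective_traj) >= 2 and \
                abs(objective_traj[-1] - objective_traj[-2]) <= config.tol * (1.0 + abs(objective_traj[-2])):
            converged = True
            break
        state = elasso_update_hyperparameters(state, posteriors, Vmat, Kmat, config)
        hyper_traj.append(state.copy())

    if not converged:
        lams = [elasso_effective_variance(state.gamma[:, t], state.delta[:, t],
                                          state.alpha, config.lam_bar_floor)
                for t in range(n_times)]
        posteriors = [gaussian_posterior(Kmat, Vmat[:, t], lams[t], state.beta[t])
                      for t in range(n_times)]
    estimate = SpatioTemporalSource(np.column_stack([p.mu for p in posteriors]))
    return FitResult(estimate=estimate, hyper_trajectory=hyper_traj,
                     objective_trajectory=objective_traj, n_iter=n_iter,
                     converged=converged, posteriors=posteriors)
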
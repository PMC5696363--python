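"""Internals shared by the two empirical-Bayes solvers."""

from __future__ import annotations

import numpy as np
from scipy import optimize, special

# Floors used to keep boundary coordinates representable in floating point.
GAMMA_EXCESS_FLOOR = 1e-10   # minimal gamma - truncation_limit for active coords
PRUNED_REL_EXCESS = 1e-12    # gamma = limit * (1 + this) marks a pruned coord
LOG_FLOOR = 1e-10            # floor inside log terms of monitoring objectives
HYPER_MIN, HYPER_MAX = 1e-12, 1e12


def log_upper_gamma_half(x):
    """``log( Gamma(1/2, x) / Gamma(1/2) )`` = ``log erfc(sqrt(x))``.

    Evaluated through the scaled complementary error function so it stays
    finite for arbitrarily large truncation limits.
    """
    x = np.asarray(x, dtype=float)
    return np.log(special.erfcx(np.sqrt(x))) - x


def clip_lam_bar(raw: np.ndarray, floor: float) -> np.ndarray:
    """Clip the dimensionless variance factor to ``[floor, 1]``.

    Values below ``floor / 2`` (the truncation-limit regime) map to an
    exact zero so the coordinate is pruned rather than floored.
    """
    raw = np.asarray(raw, dtype=float)
    return np.where(raw < floor / 2, 0.0, np.clip(raw, floor, 1.0))


def gamma_stationary_excess(scale: float | np.ndarray, m: np.ndarray, limit: np.ndarray) -> np.ndarray:
    """Positive root of ``u^2 + u/2 - scale * m * limit = 0``.

    This is the stationary point, in ``u = gamma - limit``, of the
    per-coordinate objective ``log(u)/2 + scale*m*limit/u + u``.
    """
    c = np.asarray(scale * np.asarray(m) * np.asarray(limit), dtype=float)
    u = 0.5 * (-0.5 + np.sqrt(0.25 + 4.0 * c))
    return np.maximum(u, GAMMA_EXCESS_FLOOR * (1.0 + np.asarray(limit)))


def beta_update(rss_plus_trace: float, n_sensors: int) -> float:
    """Closed-form noise-variance update ``(||r||^2 + tr(K Sigma K')) / N``."""
    return float(np.clip(rss_plus_trace / n_sensors, HYPER_MIN, HYPER_MAX))


def beta_objective(beta, rss_plus_trace: float, n_sensors: int):
    """Coordinate restriction of the objective in the noise variance."""
    beta = np.asarray(beta, dtype=float)
    return 0.5 * (n_sensors * np.log(beta) + rss_plus_trace / beta)


def refine_candidates(fun, lo: float, hi: float, current: float,
                      n_grid: int = 256):
    """Log-grid scan of a vectorized 1-D function plus local refinement.

    The current point is inserted into the candidate set (objectives can be
    sharply curved right next to it), and the bracket around the grid
    argmin is polished with bounded Brent.  Returns ``(x, f(x))`` of the
    best point seen.
    """
    grid = np.geomspace(lo, hi, n_grid)
    if lo <= current <= hi:
        grid = np.unique(np.concatenate([grid, [current]]))
    vals = np.asarray(fun(grid), dtype=float)
    vals = np.where(np.isfinite(vals), vals, np.inf)
    i = int(np.argmin(vals))
    best_x, best_f = float(grid[i]), float(vals[i])
    lo_b, hi_b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    if hi_b > lo_b:
        res = optimize.minimize_scalar(lambda x: float(fun(x)),
                                       bounds=(lo_b, hi_b), method="bounded")
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = float(res.x), float(res.fun)
    return best_x, best_f


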
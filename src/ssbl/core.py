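"""Shared data types, the Gaussian posterior, and the type-II objective.

Everything downstream (the two sparse Bayesian solvers, the LORETA
baseline, the simulator and the metric battery) works in terms of the
types defined here.  Conventions: all indices are 0-based, time is always
the second axis of an ``S x T`` or ``N x T`` matrix, and zero prior
variances are carried as exact zeros so that sparsity is representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "SourceSpace",
    "LeadField",
    "EEGRecording",
    "SpatioTemporalSource",
    "PriorVariance",
    "GaussianPosterior",
    "graph_laplacian",
    "gaussian_posterior",
    "type2_objective",
]


def _as_finite_array(x, name: str, dtype=float) -> np.ndarray:
    arr = np.asarray(x, dtype=dtype)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass
class SourceSpace:
    """Generator geometry: positions (mm), boolean adjacency and Laplacian."""

    positions: np.ndarray          # (S, 3) mm
    adjacency: np.ndarray          # (S, S) bool, symmetric, empty diagonal
    laplacian: np.ndarray | None = None  # (S, S) combinatorial Laplacian

    def __post_init__(self):
        self.positions = _as_finite_array(self.positions, "positions")
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape[0] != adj.shape[1] or adj.shape[0] != self.positions.shape[0]:
            raise ValueError("adjacency shape inconsistent with positions")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj)):
            raise ValueError("adjacency diagonal must be empty")
        self.adjacency = adj
        if self.laplacian is None:
            self.laplacian = graph_laplacian(self)

    @property
    def n_generators(self) -> int:
        return self.positions.shape[0]


@dataclass
class LeadField:
    """The forward operator: an ``N x S`` gain matrix plus metadata."""

    K: np.ndarray
    sensor_labels: Sequence[str] | None = None
    generator_index: SourceSpace | None = None

    def __post_init__(self):
        self.K = _as_finite_array(self.K, "lead field K")
        if self.K.ndim != 2:
            raise ValueError("lead field K must be a 2-D matrix")
        if self.sensor_labels is None:
            self.sensor_labels = [f"E{i:03d}" for i in range(self.K.shape[0])]

    @property
    def n_sensors(self) -> int:
        return self.K.shape[0]

    @property
    def n_generators(self) -> int:
        return self.K.shape[1]


@dataclass
class EEGRecording:
    """An ``N x T`` scalp potential matrix with timing metadata."""

    V: np.ndarray
    fs: float = 1.0
    t0: float = 0.0

    def __post_init__(self):
        self.V = _as_finite_array(self.V, "V")
        if self.V.ndim == 1:
            self.V = self.V[:, None]
        if self.V.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_sensors(self) -> int:
        return self.V.shape[0]

    @property
    def n_times(self) -> int:
        return self.V.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_times) / self.fs


@dataclass
class SpatioTemporalSource:
    """An ``S x T`` current-density matrix (truth or estimate)."""

    J: np.ndarray
    generator_index: SourceSpace | None = None

    def __post_init__(self):
        self.J = _as_finite_array(self.J, "J")
        if self.J.ndim == 1:
            self.J = self.J[:, None]


@dataclass
class PriorVariance:
    """Effective per-generator prior variance for a single time point.

    ``lam`` is the variance itself, ``lam_bar`` the dimensionless factor
    in ``[0, 1]`` it derives from (``lam = lam_bar / (2 * scale)``).
    """

    lam: np.ndarray
    lam_bar: np.ndarray

    def __post_init__(self):
        self.lam = _as_finite_array(self.lam, "lam")
        self.lam_bar = _as_finite_array(self.lam_bar, "lam_bar")
        if np.any(self.lam < 0):
            raise ValueError("lam must be nonnegative")
        if np.any((self.lam_bar < 0) | (self.lam_bar > 1)):
            raise ValueError("lam_bar must lie in [0, 1]")


@dataclass
class GaussianPosterior:
    """Per-time-point Gaussian posterior of the sources.

    ``sigma_logdet`` is the log pseudo-determinant of the posterior
    covariance restricted to the support of positive prior variance.
    ``trace_ksk`` caches ``tr(K Sigma K^T)`` and ``trace_ratio`` caches
    ``tr(Sigma diag(lam)^+)``; both are needed by the EM-style
    hyperparameter updates.
    """

    mu: np.ndarray
    sigma_diag: np.ndarray
    sigma_logdet: float
    residual: np.ndarray
    trace_ksk: float = 0.0
    trace_ratio: float = 0.0
    support: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def graph_laplacian(space) -> np.ndarray:
    """Combinatorial graph Laplacian ``L = Deg - A`` of a source space.

    Accepts a :class:`SourceSpace` or a raw boolean adjacency matrix.
    Isolated generators yield zero rows; an asymmetric adjacency is an
    error.
    """
    adj = space.adjacency if hasattr(space, "adjacency") else np.asarray(space)
    adj = adj.astype(float)
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    deg = adj.sum(axis=1)
    return np.diag(deg) - adj


def gaussian_posterior(K, v, lam, beta: float) -> GaussianPosterior:
    """Posterior of the sources for one time point under a Gaussian model.

    Computes ``mu = D K^T (K D K^T + beta I)^{-1} v`` and the diagonal and
    log-determinant of ``Sigma = D - D K^T (K D K^T + beta I)^{-1} K D``
    with ``D = diag(lam)``, through the ``N x N`` system only (cost
    ``O(N^2 S)``).  Coordinates with ``lam == 0`` are pinned exactly at
    zero; the log-determinant is the pseudo-determinant over the positive
    support.
    """
    Kmat = K.K if isinstance(K, LeadField) else np.asarray(K, dtype=float)
    v = _as_finite_array(v, "v").ravel()
    lam_arr = lam.lam if isinstance(lam, PriorVariance) else np.asarray(lam, dtype=float)
    lam_arr = _as_finite_array(lam_arr, "lam").ravel()
    if not np.isfinite(beta) or beta <= 0:
        raise ValueError("beta must be a positive finite scalar")
    if np.any(lam_arr < 0):
        raise ValueError("prior variances must be nonnegative")
    n_sensors, n_gen = Kmat.shape
    if v.shape[0] != n_sensors or lam_arr.shape[0] != n_gen:
        raise ValueError("inconsistent shapes for K, v, lam")

    support = lam_arr > 0
    Kd = Kmat * lam_arr  # K @ diag(lam), columnwise scaling
    M = Kd @ Kmat.T
    M[np.diag_indices_from(M)] += beta
    try:
        cho = linalg.cho_factor(M, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:  # pragma: no cover - beta > 0 keeps M SPD
        raise linalg.LinAlgError(f"singular N x N system in posterior: {exc}") from exc

    mu = lam_arr * (Kmat.T @ linalg.cho_solve(cho, v, check_finite=False))
    Z = linalg.cho_solve(cho, Kd, check_finite=False)  # M^{-1} K D
    # (D K^T M^{-1} K D)_ii = lam_i * K[:, i] . Z[:, i]
    sigma_diag = lam_arr - lam_arr * np.einsum("ns,ns->s", Kmat, Z)
    tiny = np.finfo(float).tiny
    sigma_diag = np.where(support, np.maximum(sigma_diag, tiny), 0.0)

    sign, logdet_m = np.linalg.slogdet(M)
    if sign <= 0:  # pragma: no cover
        raise linalg.LinAlgError("K D K^T + beta I is not positive definite")
    sigma_logdet = float(np.sum(np.log(lam_arr[support])) + n_sensors * np.log(beta) - logdet_m)

    Minv_trace = float(np.trace(linalg.cho_solve(cho, np.eye(n_sensors), check_finite=False)))
    trace_ksk = beta * (n_sensors - beta * Minv_trace)
    # tr(Sigma D^+) = sum over support of sigma_ii / lam_i
    trace_ratio = float(np.sum(sigma_diag[support] / lam_arr[support]))

    residual = v - Kmat @ mu
    return GaussianPosterior(
        mu=mu,
        sigma_diag=sigma_diag,
        sigma_logdet=sigma_logdet,
        residual=residual,
        trace_ksk=float(trace_ksk),
        trace_ratio=trace_ratio,
        support=support,
    )


def type2_objective(posteriors, lam, hyper_neglogprior: float, beta) -> float:
    """Negative log-posterior of the hyperparameters (constants dropped).

    ``L = 1/2 * sum_t { N log beta_t + ||v_t - K mu_t||^2 / beta_t
    + sum_i log lam_it + mu_t' diag(lam_t)^{-1} mu_t - logdet Sigma_t }
    + hyper_neglogprior`` with log and division terms restricted to the
    positive support of the prior variance.
    """
    if np.isscalar(beta):
        beta = [float(beta)]
    if isinstance(lam, PriorVariance):
        lam = [lam]
    if isinstance(posteriors, GaussianPosterior):
        posteriors = [posteriors]
    if not (len(posteriors) == len(lam) == len(beta)):
        raise ValueError("posteriors, lam and beta must have matching lengths")
    total = 0.0
    for post, lam_t, beta_t in zip(posteriors, lam, beta):
        lam_arr = lam_t.lam if isinstance(lam_t, PriorVariance) else np.asarray(lam_t, float)
        if lam_arr.shape != post.mu.shape:
            raise ValueError("lam and posterior mean dimensions do not match")
        supp = lam_arr > 0
        n_sensors = post.residual.shape[0]
        rss = float(post.residual @ post.residual)
        quad = float(np.sum(post.mu[supp] ** 2 / lam_arr[supp]))
        logs = float(np.sum(np.log(lam_arr[supp])))
        total += 0.5 * (
            n_sensors * np.log(beta_t) + rss / beta_t + logs + quad - post.sigma_logdet
        )
    return float(total + hyper_neglogprior)
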
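"""Source-localization quality measures and benchmark rank statistics.

All measures are computed from non-thresholded estimates; only the truth
is binarized (for the ROC-based measures).  EMD and DLE are reported in
millimetres, AUC and F1 as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from scipy.stats import ranksums
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "QualityReport",
    "emd",
    "dle",
    "roc_auc",
    "f1_optimal",
    "sparsity_level",
    "activation_curve",
    "rank_summaries",
]

_EXACT_LP_MAX = 1000
_CLUSTER_POINTS = 500


@dataclass
class QualityReport:
    """Per-trial measure arrays (one entry per evaluated cell)."""

    method: str
    trial: int
    emd: np.ndarray = None
    dle: np.ndarray = None
    auc: np.ndarray = None
    f1: np.ndarray = None
    sparsity: np.ndarray = None
    activation: np.ndarray = None

    def measure(self, name: str) -> np.ndarray:
        return np.atleast_1d(np.asarray(getattr(self, name), dtype=float))


def _normalized_mass(j: np.ndarray, name: str) -> np.ndarray:
    a = np.abs(np.asarray(j, dtype=float).ravel())
    total = a.sum()
    if total == 0:
        raise ValueError(f"{name} is identically zero; its mass distribution is undefined")
    return a / total


def _aggregate(mass: np.ndarray, pos: np.ndarray, n_points: int):
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=n_points, n_init=3, random_state=0).fit(pos)
    agg = np.zeros(n_points)
    np.add.at(agg, km.labels_, mass)
    return agg, km.cluster_centers_


def emd(j_true, j_est, positions) -> float:
    """Earth Mover's Distance (mm) between the normalized absolute maps.

    Solves the transportation linear program exactly (Euclidean ground
    metric) for up to 1000 generators; larger spaces are first aggregated
    onto a 500-point clustering.
    """
    positions = np.asarray(positions, dtype=float)
    a = _normalized_mass(j_true, "j_true")
    b = _normalized_mass(j_est, "j_est")
    pa, pb = positions, positions
    if positions.shape[0] > _EXACT_LP_MAX:
        a, pa = _aggregate(a, positions, _CLUSTER_POINTS)
        b, pb = _aggregate(b, positions, _CLUSTER_POINTS)
    ia, ib = np.flatnonzero(a), np.flatnonzero(b)
    wa, wb = a[ia], b[ib]
    cost = np.linalg.norm(pa[ia][:, None, :] - pb[ib][None, :, :], axis=2)
    na, nb = wa.size, wb.size
    # row-sum and column-sum equality constraints on the transport plan
    row_idx = np.repeat(np.arange(na), nb)
    col_idx = np.tile(np.arange(nb), na) + na
    var = np.arange(na * nb)
    A_eq = sparse.coo_matrix(
        (np.ones(2 * na * nb),
         (np.concatenate([row_idx, col_idx]), np.concatenate([var, var]))),
        shape=(na + nb, na * nb)).tocsr()[:-1]   # last constraint is redundant
    b_eq = np.concatenate([wa, wb])[:-1]
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None),
                  method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def _graph_local_maxima(scores: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Indices where |score| is positive and no neighbor exceeds it."""
    neigh_max = np.where(adjacency, scores[None, :], -np.inf).max(axis=1)
    return np.flatnonzero((scores > 0) & (scores >= neigh_max))


def dle(j_true, j_est, positions, patch_centers, adjacency,
        symmetric: bool = False) -> float:
    """Dipole localization error (mm).

    Mean over simulated patch centers of the distance to the nearest
    graph-local maximum of ``|j_est|``; a flat nonzero estimate falls back
    to its global maximum, an all-zero estimate is an error.  With
    ``symmetric=True`` the average of both directions is returned.
    """
    positions = np.asarray(positions, dtype=float)
    scores = np.abs(np.asarray(j_est, dtype=float).ravel())
    if scores.max() == 0:
        raise ValueError("all-zero estimate has no localization maxima")
    peaks = _graph_local_maxima(scores, np.asarray(adjacency, dtype=bool))
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(scores))])
    centers = np.atleast_1d(np.asarray(patch_centers, dtype=int))
    d_matrix = np.linalg.norm(positions[centers][:, None, :]
                              - positions[peaks][None, :, :], axis=2)
    forward = float(d_matrix.min(axis=1).mean())
    if not symmetric:
        return forward
    backward = float(d_matrix.min(axis=0).mean())
    return 0.5 * (forward + backward)


def roc_auc(j_true, j_est) -> float:
    """ROC area under the curve (percent): scores ``|j_est|`` against the
    binarized truth support, mid-rank (trapezoidal) tie handling."""
    labels = np.asarray(j_true, dtype=float).ravel() != 0
    if labels.all() or not labels.any():
        raise ValueError("truth must contain both active and inactive generators")
    return float(roc_auc_score(labels, np.abs(np.asarray(j_est, float).ravel())) * 100.0)


def f1_optimal(j_true, j_est, mean: str = "harmonic"):
    """F1 (percent) at the ROC operating point maximizing Youden's J.

    Returns ``(f1, threshold, recall, precision)``.  ``mean`` selects the
    harmonic (standard) or geometric combination of precision and recall.
    """
    labels = np.asarray(j_true, dtype=float).ravel() != 0
    if labels.all() or not labels.any():
        raise ValueError("truth must contain both active and inactive generators")
    scores = np.abs(np.asarray(j_est, dtype=float).ravel())
    fpr, tpr, thresholds = roc_curve(labels, scores)
    idx = int(np.argmax(tpr - fpr))
    threshold = float(thresholds[idx])
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    recall = tp / int(labels.sum())
    precision = tp / int(pred.sum()) if pred.any() else 0.0
    if precision + recall == 0:
        f1 = 0.0
    elif mean == "harmonic":
        f1 = 2.0 * precision * recall / (precision + recall)
    elif mean == "geometric":
        f1 = float(np.sqrt(precision * recall))
    else:
        raise ValueError(f"unknown mean {mean!r}")
    return 100.0 * f1, threshold, recall, precision


def sparsity_level(J) -> np.ndarray:
    """``1 - ||J_t||_1 / max_tau ||J_tau||_1`` per time point, in [0, 1]."""
    act = activation_curve(J)
    peak = act.max()
    if peak == 0:
        raise ValueError("all-zero source matrix has no sparsity profile")
    return 1.0 - act / peak


def activation_curve(J) -> np.ndarray:
    """Column L1 norms ``||J_t||_1`` (the per-time activation level)."""
    Jm = J.J if hasattr(J, "J") else np.atleast_2d(np.asarray(J, dtype=float))
    return np.abs(Jm).sum(axis=0)


_LOWER_BETTER = {"emd": True, "dle": True, "auc": False, "f1": False}


def rank_summaries(reports: dict, measures=("emd", "dle", "auc", "f1"),
                   p_threshold: float = 0.05):
    """Typical-trial selection and pairwise significant-win percentages.

    ``reports`` maps method name to a list of :class:`QualityReport` (same
    trial count and cell layout everywhere).  The typical trial of a method
    sits at the median position of the sum-of-ranks ordering over all
    measures; the win table counts, per ordered method pair and measure,
    the percentage of cells where the first method is significantly better
    by a two-sided Wilcoxon rank-sum test across trials.
    """
    methods = list(reports)
    typical = {}
    for method in methods:
        trials = reports[method]
        if len(trials) < 1:
            raise ValueError("need at least one trial per method")
        scores = np.zeros(len(trials))
        for meas in measures:
            vals = np.array([r.measure(meas).mean() for r in trials])
            order = vals if _LOWER_BETTER[meas] else -vals
            scores += np.argsort(np.argsort(order)) + 1
        ordering = np.argsort(scores, kind="stable")
        typical[method] = trials[ordering[(len(trials) - 1) // 2]].trial

    if len(methods) < 2:
        raise ValueError("pairwise table needs at least two methods")
    n_trials = len(reports[methods[0]])
    if n_trials < 2:
        return typical, None  # a single trial supports no rank test
    table = {meas: {} for meas in measures}
    for meas in measures:
        lower = _LOWER_BETTER[meas]
        stacked = {m: np.stack([r.measure(meas) for r in reports[m]])
                   for m in methods}          # (trials, cells)
        n_cells = stacked[methods[0]].shape[1]
        for m_a in methods:
            for m_b in methods:
                if m_a == m_b:
                    continue
                wins = 0
                for c in range(n_cells):
                    x, y = stacked[m_a][:, c], stacked[m_b][:, c]
                    stat, p = ranksums(x, y)
                    better = x.mean() < y.mean() if lower else x.mean() > y.mean()
                    if p < p_threshold and better:
                        wins += 1
                table[meas][(m_a, m_b)] = 100.0 * wins / n_cells
    return typical, table
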
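"""Recovery metrics for simulation studies: partition ARI, tree ARI, loading RMSE.

The tree ARI compares two full merge hierarchies level by level: the adjusted
Rand index of the Q-group partitions, plus one ARI per merge level comparing
the two-block split induced by each hierarchy's i-th merge, summed and
rescaled by Q so that 1 means perfect recovery of the whole dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .hierarchy import Hierarchy
from .model import UFAParams, loading_matrix

__all__ = [
    "RecoveryReport",
    "adjusted_rand",
    "tree_ari",
    "loading_rmse",
    "recovery_report",
]


@dataclass(frozen=True)
class RecoveryReport:
    """Agreement between a planted and an estimated hierarchy."""

    ari_q: float
    tree_ari: float
    rmse: float
    perfect_partition: bool
    perfect_tree: bool

    def to_dict(self) -> dict:
        return {
            "ari_q": self.ari_q,
            "tree_ari": self.tree_ari,
            "rmse": self.rmse,
            "perfect_partition": self.perfect_partition,
            "perfect_tree": self.perfect_tree,
        }


def adjusted_rand(p1, p2) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings."""
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("partitions must label the same elements")
    return float(adjusted_rand_score(p1, p2))


def _merge_split(h: Hierarchy, level: int) -> tuple[np.ndarray, np.ndarray]:
    """Variable masks of the two sides joined by merge ``level`` (1-based)."""
    q = h.n_groups
    a, b = h.merges[level - 1]
    mask = np.zeros((2, h.n_vars), dtype=bool)
    for side, node in enumerate((a, b)):
        groups = h.group_sets(node)
        mask[side] = np.isin(h.assignment, list(groups))
    return mask[0], mask[1]


def tree_ari(true: Hierarchy, est: Hierarchy, clamp: bool = True,
             merge_domain: str = "intersection") -> float:
    """Dendrogram-recovery score in [0, 1].

    ``(ARI of the Q-group partitions + sum over merge levels of the ARI
    between the two-block splits induced by the i-th merges) / Q``.  Each
    merge-level ARI is computed over the variables covered by both merges
    (``merge_domain='intersection'``, 0 if fewer than two shared variables)
    or over all J variables with uncovered ones as a third block
    (``merge_domain='all'``).  Negative totals are clamped to 0 by default.
    """
    if true.n_vars != est.n_vars or true.n_groups != est.n_groups:
        raise ValueError("hierarchies must share J and Q")
    q = true.n_groups
    total = adjusted_rand(true.assignment, est.assignment)
    for level in range(1, q):
        t_a, t_b = _merge_split(true, level)
        e_a, e_b = _merge_split(est, level)
        if merge_domain == "intersection":
            domain = (t_a | t_b) & (e_a | e_b)
            if domain.sum() < 2:
                continue
            lab_t = t_b[domain].astype(int)
            lab_e = e_b[domain].astype(int)
        elif merge_domain == "all":
            lab_t = np.where(t_a, 0, np.where(t_b, 1, 2))
            lab_e = np.where(e_a, 0, np.where(e_b, 1, 2))
        else:
            raise ValueError(f"unknown merge_domain {merge_domain!r}")
        total += adjusted_rand(lab_t, lab_e)
    score = total / q
    return float(max(score, 0.0)) if clamp else float(score)


def loading_rmse(true_loadings: np.ndarray, est_loadings: np.ndarray,
                 n_groups: int | None = None) -> float:
    """Permutation-matched RMSE between two J x (2Q-1) loading matrices.

    The loading matrix is unique only up to relabeling, so columns are
    optimally matched (rectangular assignment on column-wise squared
    differences) separately within the first Q group columns and within the
    last Q-1 merge columns before the elementwise RMSE over all entries.
    """
    a = np.asarray(true_loadings, dtype=float)
    b = np.asarray(est_loadings, dtype=float)
    if a.shape != b.shape:
        raise ValueError("loading matrices must have the same shape")
    n_cols = a.shape[1]
    if n_groups is None:
        if n_cols % 2 == 0:
            raise ValueError("cannot infer Q from an even column count")
        n_groups = (n_cols + 1) // 2
    sse = 0.0
    for lo, hi in ((0, n_groups), (n_groups, n_cols)):
        if hi <= lo:
            continue
        block_a, block_b = a[:, lo:hi], b[:, lo:hi]
        cost = ((block_a[:, :, None] - block_b[:, None, :]) ** 2).sum(axis=0)
        rows, cols = linear_sum_assignment(cost)
        sse += cost[rows, cols].sum()
    return float(np.sqrt(sse / a.size))


def recovery_report(truth: UFAParams, estimate: UFAParams) -> RecoveryReport:
    """Score an estimated parameter set against the planted one."""
    ari_q = adjusted_rand(truth.hierarchy.assignment, estimate.hierarchy.assignment)
    t_ari = tree_ari(truth.hierarchy, estimate.hierarchy)
    rmse = loading_rmse(loading_matrix(truth), loading_matrix(estimate),
                        truth.hierarchy.n_groups)
    return RecoveryReport(
        ari_q=ari_q,
        tree_ari=t_ari,
        rmse=rmse,
        perfect_partition=bool(ari_q >= 1.0 - 1e-12),
        perfect_tree=bool(t_ari >= 1.0 - 1e-12),
    )
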
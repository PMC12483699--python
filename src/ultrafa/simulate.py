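"""Synthetic correlation matrices with planted ultrametric structure.

The generator plants a hierarchy (random equal-probability partition of J
variables into Q non-empty groups, then Q-1 uniformly random pairwise
agglomerations), draws node correlation levels top-down — a root level
uniform on [0.10, 0.30] plus a uniform [0.05, 0.20] increment per node, with
within levels capped so no communality exceeds 0.9 — and composes the implied
correlation matrix, which is ultrametric by construction.  Observation noise
is a symmetrized elementwise-uniform perturbation of the off-diagonal entries
followed, when needed, by the diagonal-shift (Cailliez) positive
semi-definite repair and rescaling back to unit diagonal.

Error-level presets: low 0.05, medium 0.15, high 0.30 (half-width of the
uniform perturbation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hierarchy import CorrelationMatrix, Hierarchy, UltrametricValues, as_array
from .model import UFAParams, implied_correlation

__all__ = [
    "ERROR_LEVELS",
    "Scenario",
    "generate_structure",
    "generate_sigma",
    "perturb",
    "sample_observations",
    "psd_repair",
    "run_scenarios",
    "summarize_scenarios",
]

#: preset half-widths of the uniform perturbation
ERROR_LEVELS = {"low": 0.05, "medium": 0.15, "high": 0.30}

#: level-generation defaults
ROOT_LEVEL_RANGE = (0.10, 0.30)
INCREMENT_RANGE = (0.05, 0.20)
MAX_COMMUNALITY = 0.9


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid."""

    j_vars: int
    q_groups: int
    error: float | str = "low"
    n_replicates: int = 20
    seed: int = 0
    n_obs: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.error, str):
            if self.error not in ERROR_LEVELS:
                raise ValueError(f"unknown error level {self.error!r}")
        elif self.error < 0:
            raise ValueError("the error half-width must be non-negative")
        if not 2 <= self.q_groups <= self.j_vars:
            raise ValueError("need 2 <= Q <= J")

    @property
    def epsilon(self) -> float:
        return ERROR_LEVELS[self.error] if isinstance(self.error, str) else float(self.error)

    @property
    def label(self) -> str:
        err = self.error if isinstance(self.error, str) else f"{self.error:g}"
        return f"J{self.j_vars}_Q{self.q_groups}_{err}"


def _random_partition(j_n: int, q: int, rng: np.random.Generator) -> np.ndarray:
    for _ in range(1000):
        idx = rng.integers(0, q, size=j_n)
        if np.unique(idx).size == q:
            return idx
    idx = np.concatenate([np.arange(q), rng.integers(0, q, size=j_n - q)])
    return idx[rng.permutation(j_n)]


def generate_structure(j_vars: int, q_groups: int,
                       rng: np.random.Generator | int | None = None) -> UFAParams:
    """Draw a planted hierarchy with valid ultrametric levels.

    Groups come from an equal-probability multinomial conditioned on being
    non-empty; the merge tree agglomerates uniformly random pairs of active
    nodes; levels grow top-down by uniform increments so they are
    non-increasing up every root path by construction.
    """
    import warnings

    rng = np.random.default_rng(rng)
    if j_vars < 2 * q_groups:
        warnings.warn(
            f"J={j_vars} < 2Q={2 * q_groups}: singleton groups become likely",
            stacklevel=2,
        )
    idx = _random_partition(j_vars, q_groups, rng)
    # random binary tree: agglomerate uniformly random pairs of active nodes
    active = list(range(1, q_groups + 1))
    merges = []
    for i in range(1, q_groups):
        a, b = rng.choice(len(active), size=2, replace=False)
        pair = tuple(sorted((active[a], active[b])))
        merges.append(pair)
        active = [n for n in active if n not in pair]
        active.append(q_groups + i)
    h = Hierarchy(idx + 1, tuple(merges))
    # top-down levels: root uniform, one uniform increment per non-root node
    parent = h.parent_array()
    by_node = np.zeros(h.n_nodes)
    by_node[h.root - 1] = rng.uniform(*ROOT_LEVEL_RANGE)
    for node in range(h.n_nodes - 1, 0, -1):
        if parent[node] != 0:
            by_node[node - 1] = by_node[parent[node] - 1] + rng.uniform(*INCREMENT_RANGE)
    # cap communalities by proportional rescaling: clipping would create level
    # ties (zero increments) that make the planted tree unidentifiable
    max_within = by_node[:q_groups].max()
    if max_within > MAX_COMMUNALITY:
        by_node *= MAX_COMMUNALITY / max_within
    # a singleton group has no within pairs, so its level is unidentifiable;
    # pin it to the parent's level (zero increment) as the estimator does
    sizes = np.bincount(idx, minlength=q_groups)
    for g in np.nonzero(sizes == 1)[0]:
        by_node[g] = by_node[parent[g + 1] - 1]
    # canonical merge order (descending level): agglomerative estimators emit
    # merges from the most to the least correlated pair, and the tree-recovery
    # score pairs merge levels by index
    h, by_node = _canonical_merge_order(h, by_node)
    values = UltrametricValues(by_node[:q_groups], by_node[q_groups:])
    return UFAParams.from_levels(h, values)


def _canonical_merge_order(h: Hierarchy, by_node: np.ndarray
                           ) -> tuple[Hierarchy, np.ndarray]:
    """Reorder merges by descending level (stable), remapping node ids."""
    q = h.n_groups
    merge_levels = by_node[q:]
    order = sorted(range(q - 1), key=lambda i: (-merge_levels[i], i))
    node_map = {g: g for g in range(1, q + 1)}
    for new_pos, old_i in enumerate(order, start=1):
        node_map[q + old_i + 1] = q + new_pos
    new_merges = tuple(
        tuple(sorted((node_map[a], node_map[b])))
        for a, b in (h.merges[i] for i in order)
    )
    new_by_node = by_node.copy()
    for old, new in node_map.items():
        new_by_node[new - 1] = by_node[old - 1]
    return Hierarchy(h.assignment, new_merges), new_by_node


def generate_sigma(params: UFAParams) -> CorrelationMatrix:
    """Implied correlation matrix of the planted structure (ultrametric)."""
    return implied_correlation(params)


def psd_repair(r: CorrelationMatrix | np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Diagonal-shift repair: add |smallest eigenvalue| to the diagonal when
    the matrix is not positive semi-definite, then rescale to unit diagonal."""
    values = np.array(as_array(r), dtype=float)
    lam_min = np.linalg.eigvalsh(0.5 * (values + values.T))[0]
    if lam_min < ridge:
        shift = abs(lam_min) + ridge
        values = values + shift * np.eye(values.shape[0])
        values = values / (1.0 + shift)
        np.fill_diagonal(values, 1.0)
    return values


def perturb(sigma: CorrelationMatrix | np.ndarray, epsilon: float,
            rng: np.random.Generator | int | None = None,
            one_sided: bool = False) -> CorrelationMatrix:
    """Add symmetrized elementwise-uniform noise and repair definiteness.

    The error matrix is uniform on ``[-eps, eps]`` (or ``[0, eps]`` with
    ``one_sided``), symmetrized as ``(E + E') / 2`` with a zero diagonal;
    perturbed entries are clipped to [0, 1] and the diagonal-shift repair is
    applied if the result is not positive semi-definite.  ``epsilon = 0``
    returns the input unchanged.
    """
    values = as_array(sigma)
    if epsilon < 0:
        raise ValueError("the error half-width must be non-negative")
    if epsilon == 0:
        return CorrelationMatrix(values.copy())
    rng = np.random.default_rng(rng)
    lo = 0.0 if one_sided else -epsilon
    e = rng.uniform(lo, epsilon, size=values.shape)
    e = 0.5 * (e + e.T)
    np.fill_diagonal(e, 0.0)
    out = np.clip(values + e, 0.0, 1.0)
    np.fill_diagonal(out, 1.0)
    out = psd_repair(out)
    return CorrelationMatrix(out)


def sample_observations(sigma: CorrelationMatrix | np.ndarray, n: int,
                        rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Draw n multivariate-normal rows with mean zero and covariance sigma."""
    rng = np.random.default_rng(rng)
    values = as_array(sigma)
    labels = sigma.labels if isinstance(sigma, CorrelationMatrix) else [
        f"V{j + 1}" for j in range(values.shape[0])
    ]
    data = rng.multivariate_normal(np.zeros(values.shape[0]), values, size=n,
                                   method="eigh")
    return pd.DataFrame(data, columns=list(labels))


def replicate_rng(master_seed: int, *indices: int) -> np.random.Generator:
    """Counter-based child generator: any replicate is re-runnable in isolation."""
    return np.random.default_rng([master_seed, *indices])


def run_scenarios(scenarios, fit_config=None, master_seed: int = 0,
                  from_observations: bool = False) -> pd.DataFrame:
    """Run the full generate-perturb-fit-score protocol over a scenario grid.

    Returns one row per scenario x replicate with the recovery metrics
    (partition ARI, tree ARI, loading RMSE), fit quality (F, AGFI when n is
    known) and iteration counts.
    """
    from .estimator import FitConfig, fit  # deferred: estimator imports this module
    from .metrics import recovery_report
    from .model import fit_indices, implied_correlation, loading_matrix

    rows = []
    for scen in scenarios:
        for rep in range(scen.n_replicates):
            rng = replicate_rng(master_seed, scen.seed, rep)
            truth = generate_structure(scen.j_vars, scen.q_groups, rng)
            sigma = generate_sigma(truth)
            observed = perturb(sigma, scen.epsilon, rng)
            n_obs = scen.n_obs
            if from_observations and n_obs:
                data = sample_observations(observed, n_obs, rng)
                observed = CorrelationMatrix(np.corrcoef(data.values, rowvar=False))
            # the diagonal-shift repair can leave an exactly singular matrix;
            # a tiny ridge keeps the ML discrepancy defined
            if np.linalg.eigvalsh(observed.values)[0] < 1e-10:
                observed = CorrelationMatrix(psd_repair(observed.values, ridge=1e-8))
            cfg = fit_config or FitConfig(q=scen.q_groups)
            cfg = type(cfg)(**{**cfg.__dict__, "q": scen.q_groups,
                               "seed": int(rng.integers(2 ** 31))})
            res = fit(observed, cfg)
            report = recovery_report(truth, res.params)
            n_for_agfi = n_obs or 100
            ind = fit_indices(implied_correlation(res.params), observed,
                              n_for_agfi, scen.q_groups)
            rows.append({
                "scenario": scen.label,
                "J": scen.j_vars,
                "Q": scen.q_groups,
                "epsilon": scen.epsilon,
                "replicate": rep,
                "ari_q": report.ari_q,
                "tree_ari": report.tree_ari,
                "rmse": report.rmse,
                "perfect_partition": report.perfect_partition,
                "perfect_tree": report.perfect_tree,
                "agfi": ind.agfi,
                "F": res.discrepancy,
                "iterations": res.n_iterations,
            })
    return pd.DataFrame(rows)


def summarize_scenarios(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate replicate-level results to per-scenario means and %-perfect."""
    grouped = results.groupby(["scenario", "J", "Q", "epsilon"], sort=False)
    out = grouped.agg(
        pct_perfect_partition=("perfect_partition", lambda s: 100.0 * s.mean()),
        pct_perfect_tree=("perfect_tree", lambda s: 100.0 * s.mean()),
        mean_ari_q=("ari_q", "mean"),
        mean_tree_ari=("tree_ari", "mean"),
        mean_agfi=("agfi", "mean"),
        mean_rmse=("rmse", "mean"),
        mean_iterations=("iterations", "mean"),
    )
    return out.reset_index()
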
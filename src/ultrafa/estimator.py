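"""Cycling block coordinate-descent ML estimation of the ultrametric factor model.

Given a sample correlation matrix R and a number of first-order factors Q, the
estimator alternates:

1.1  reassign each variable to the group that minimizes the ML discrepancy,
     with correlation levels fully re-estimated for every candidate move;
1.2  rebuild the merge tree by greedy agglomeration of the two clusters with
     the largest average-linkage between correlation;
2    re-estimate the node levels as mean within-/cross-block sample
     correlations, projected onto the monotone (ultrametric) cone by upward
     clipping;
3    close the diagonal with uniquenesses ``psi_j = 1 - communality_j``.

Every block update is accepted only if it does not increase the discrepancy,
so traces are non-increasing by construction.  Multistart over random initial
partitions mitigates local minima of this combinatorial problem.

The parsimonious disjoint variant (PDFA) pins all merge-node increments at
zero, giving a block-diagonal implied matrix; it is both a standalone fit and
the seed of the constrained variant, which freezes the PDFA partition and
within levels and only estimates the hierarchy above them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg

from .hierarchy import (
    CorrelationMatrix,
    Hierarchy,
    UltrametricValues,
    as_array,
    check_correlation,
)
from .model import (
    PSI_FLOOR,
    FitIndices,
    UFAParams,
    cronbach_alpha,
    fit_indices,
    implied_correlation,
    n_parameters,
    n_parameters_pdfa,
)
from .simulate import psd_repair

__all__ = [
    "FitConfig",
    "FitResult",
    "SelectionResult",
    "initialize",
    "update_assignment",
    "update_hierarchy",
    "update_loadings",
    "update_psi",
    "fit",
    "fit_pdfa",
    "select_q",
]


@dataclass(frozen=True)
class FitConfig:
    """Settings of one estimation run."""

    q: int
    n_starts: int = 50
    max_iter: int = 100
    tol: float = 1e-6
    seed: int | None = None
    constrained: bool = False
    n: int | None = None
    strict: bool = False
    df_convention: str = "full"
    refine: bool = True
    exact_assignment: bool = True
    allow_negative: bool = False

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be at least 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class FitResult:
    """Converged parameters plus optimization and diagnostic traces."""

    params: UFAParams
    discrepancy: float
    trace: tuple[float, ...]
    n_iterations: int
    converged: bool
    best_start: int
    start_discrepancies: tuple[float, ...]
    indices: FitIndices | None
    diagnostics: dict

    @property
    def hierarchy(self) -> Hierarchy:
        return self.params.hierarchy

    def levels(self) -> UltrametricValues:
        return self.params.levels()


@dataclass(frozen=True)
class SelectionResult:
    """Model-selection table over a range of Q."""

    table: pd.DataFrame
    best: dict
    chosen_q: int
    criterion: str


# ---------------------------------------------------------------------------
# internal machinery


class _Tree:
    """Precomputed structure of a fixed merge sequence over Q groups."""

    def __init__(self, merges: tuple[tuple[int, int], ...], q: int):
        self.q = q
        self.merges = tuple(merges)
        parent = np.zeros(2 * q, dtype=int)
        for i, (a, b) in enumerate(self.merges, start=1):
            parent[a] = parent[b] = q + i
        self.parent = parent
        below: dict[int, list[int]] = {g: [g - 1] for g in range(1, q + 1)}
        self.sides: list[tuple[list[int], list[int]]] = []
        for i, (a, b) in enumerate(self.merges, start=1):
            below[q + i] = below[a] + below[b]
            self.sides.append((below[a], below[b]))
        lca = np.zeros((q, q), dtype=int)
        np.fill_diagonal(lca, np.arange(q))
        for i, (ga, gb) in enumerate(self.sides):
            for x in ga:
                for y in gb:
                    lca[x, y] = lca[y, x] = q + i
        self.lca0 = lca  # 0-based node index of the lowest common node


def _evaluate(r: np.ndarray, idx: np.ndarray, tree: _Tree, r_logdet: float,
              pdfa: bool = False,
              fixed_within: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Level estimation + monotone projection + discrepancy for one structure.

    Returns ``(levels_by_node, sigma, F)``.  Levels are mean within-block and
    cross-block entries of ``r``; merge levels are clipped from above at the
    minimum of their children's levels so the result is ultrametric; within
    levels are capped at ``1 - PSI_FLOOR`` so uniquenesses stay positive.
    Singleton groups inherit their parent's level (zero increment).
    """
    q = tree.q
    j_n = r.shape[0]
    onehot = np.zeros((j_n, q))
    onehot[np.arange(j_n), idx] = 1.0
    sizes = onehot.sum(axis=0)
    block = onehot.T @ r @ onehot
    levels = np.zeros(2 * q - 1)
    nontrivial = sizes > 1
    diag = np.diag(block)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw_within = np.where(
            nontrivial, (diag - sizes) / np.maximum(sizes * (sizes - 1), 1), 0.0
        )
    if fixed_within is not None:
        raw_within = fixed_within
        nontrivial = nontrivial | True
    levels[:q] = np.clip(raw_within, 0.0, 1.0 - PSI_FLOOR)
    if pdfa:
        for g in np.nonzero(~nontrivial)[0]:
            levels[g] = 0.0
    else:
        for i, (ga, gb) in enumerate(tree.sides):
            na, nb = sizes[ga].sum(), sizes[gb].sum()
            lv = block[np.ix_(ga, gb)].sum() / (na * nb)
            lv = max(lv, 0.0)
            a, b = tree.merges[i]
            for c in (a, b):
                c0 = c - 1
                if c <= q and not nontrivial[c0]:
                    continue  # singleton group imposes no cap
                lv = min(lv, levels[c0])
            levels[q + i] = lv
        for g in np.nonzero(~nontrivial)[0]:
            levels[g] = levels[tree.parent[g + 1] - 1]
    sigma = levels[tree.lca0[idx][:, idx]]
    np.fill_diagonal(sigma, 1.0)
    try:
        c_s = scipy.linalg.cho_factor(sigma, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError:
        return levels, sigma, np.inf
    logdet_s = 2.0 * np.sum(np.log(np.diag(c_s[0])))
    trace = np.trace(scipy.linalg.cho_solve(c_s, r, check_finite=False))
    f = float(logdet_s + trace - r_logdet - j_n)
    return levels, sigma, f


def _greedy_merges(r: np.ndarray, idx: np.ndarray, q: int
                   ) -> tuple[tuple[int, int], ...]:
    """Agglomerate the Q groups by repeatedly merging the pair of active
    clusters with the largest average-linkage between correlation (mean of
    the sample correlations over all cross-cluster variable pairs); ties go
    to the smallest pair of node ids."""
    j_n = r.shape[0]
    onehot = np.zeros((j_n, q))
    onehot[np.arange(j_n), idx] = 1.0
    sizes = {g: float(onehot[:, g - 1].sum()) for g in range(1, q + 1)}
    block = onehot.T @ r @ onehot
    active = list(range(1, q + 1))
    cross = {(a, b): block[a - 1, b - 1] for a in active for b in active if a < b}
    merges: list[tuple[int, int]] = []
    for i in range(1, q):
        best_pair, best_val = None, -np.inf
        for a in active:
            for b in active:
                if a >= b:
                    continue
                val = cross[(a, b)] / (sizes[a] * sizes[b])
                if val > best_val + 1e-15:
                    best_pair, best_val = (a, b), val
        a, b = best_pair
        new = q + i
        merges.append((a, b))
        active = [n for n in active if n not in (a, b)]
        sizes[new] = sizes[a] + sizes[b]
        for c in active:
            cross[tuple(sorted((c, new)))] = (
                cross[tuple(sorted((c, a)))] + cross[tuple(sorted((c, b)))]
            )
        active.append(new)
    return tuple(merges)


def _random_partition(j_n: int, q: int, rng: np.random.Generator) -> np.ndarray:
    """Equal-probability multinomial assignment conditioned on no empty group."""
    for _ in range(1000):
        idx = rng.integers(0, q, size=j_n)
        if np.unique(idx).size == q:
            return idx
    # J barely above Q: guarantee coverage, then fill at random
    idx = np.concatenate([np.arange(q), rng.integers(0, q, size=j_n - q)])
    return idx[rng.permutation(j_n)]


def _sweep(r: np.ndarray, idx: np.ndarray, tree: _Tree, r_logdet: float,
           f_cur: float, pdfa: bool = False,
           fixed_levels: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """One row-by-row reassignment pass; returns the new assignment and F.

    By default every candidate move is scored with the fully re-estimated
    model; passing ``fixed_levels`` switches to the cheap approximate mode
    that holds levels (hence loadings and uniquenesses) fixed during the
    sweep.
    """
    q = tree.q
    idx = idx.copy()
    counts = np.bincount(idx, minlength=q)
    for j in range(r.shape[0]):
        g0 = idx[j]
        if counts[g0] == 1:
            continue  # the move would empty a group
        costs = np.empty(q)
        for g in range(q):
            idx[j] = g
            if fixed_levels is None:
                costs[g] = _evaluate(r, idx, tree, r_logdet, pdfa=pdfa)[2]
            else:
                costs[g] = _sigma_discrepancy(r, idx, tree, fixed_levels,
                                              r_logdet)
        best = int(np.argmin(costs))  # ties resolve to the lowest group index
        if costs[best] > f_cur:
            best = g0  # guard: never accept an increase
        idx[j] = best
        if best != g0:
            counts[g0] -= 1
            counts[best] += 1
            f_cur = costs[best]
    if fixed_levels is not None:
        # report the fully re-estimated discrepancy of the final assignment
        f_cur = _evaluate(r, idx, tree, r_logdet, pdfa=pdfa)[2]
    return idx, f_cur


def _sigma_discrepancy(r: np.ndarray, idx: np.ndarray, tree: _Tree,
                       levels: np.ndarray, r_logdet: float) -> float:
    sigma = levels[tree.lca0[idx][:, idx]]
    np.fill_diagonal(sigma, 1.0)
    try:
        c_s = scipy.linalg.cho_factor(sigma, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError:
        return np.inf
    logdet_s = 2.0 * np.sum(np.log(np.diag(c_s[0])))
    trace = np.trace(scipy.linalg.cho_solve(c_s, r, check_finite=False))
    return float(logdet_s + trace - r_logdet - r.shape[0])


def _params_from_state(idx: np.ndarray, tree: _Tree, levels: np.ndarray
                       ) -> UFAParams:
    h = Hierarchy(idx + 1, tree.merges)
    values = UltrametricValues(levels[: tree.q], levels[tree.q:])
    return UFAParams.from_levels(h, values)


def _state_from_params(p: UFAParams) -> tuple[np.ndarray, _Tree]:
    return p.hierarchy.assignment - 1, _Tree(p.hierarchy.merges, p.hierarchy.n_groups)


def _r_logdet(r: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise np.linalg.LinAlgError("sample correlation matrix is singular")
    return float(logdet)


# ---------------------------------------------------------------------------
# public step operations


def initialize(r: CorrelationMatrix | np.ndarray, q: int,
               rng: np.random.Generator | int | None = None,
               assignment: np.ndarray | None = None) -> UFAParams:
    """Random starting point: multinomial partition, greedy merge tree,
    mean-correlation levels, uniquenesses as one minus communality.

    ``assignment`` (1-based labels) can be forced instead of drawn.
    """
    values = as_array(r)
    j_n = values.shape[0]
    if not 2 <= q <= j_n:
        raise ValueError(f"need 2 <= Q <= J, got Q={q}, J={j_n}")
    if assignment is None:
        rng = np.random.default_rng(rng)
        idx = _random_partition(j_n, q, rng)
    else:
        idx = np.asarray(assignment, dtype=int) - 1
    merges = _greedy_merges(values, idx, q)
    tree = _Tree(merges, q)
    levels, _, _ = _evaluate(values, idx, tree, _r_logdet(values))
    return _params_from_state(idx, tree, levels)


def update_assignment(params: UFAParams, r: CorrelationMatrix | np.ndarray,
                      pdfa: bool = False, exact: bool = True) -> UFAParams:
    """Step 1.1: reassign each variable to the discrepancy-minimizing group.

    Levels, increments and uniquenesses are fully re-estimated for every
    candidate move (``exact=False`` holds them fixed during the sweep, the
    cheap approximate mode); moves that would empty a group are skipped and
    ties break to the lowest group index.  The returned state never has a
    larger discrepancy than the input.
    """
    values = as_array(r)
    idx, tree = _state_from_params(params)
    r_logdet = _r_logdet(values)
    levels, _, f_cur = _evaluate(values, idx, tree, r_logdet, pdfa=pdfa)
    idx2, f_new = _sweep(values, idx, tree, r_logdet, f_cur, pdfa=pdfa,
                         fixed_levels=None if exact else levels)
    if f_new > f_cur:  # approximate sweep may overshoot; keep the old state
        idx2 = idx
    levels, _, _ = _evaluate(values, idx2, tree, r_logdet, pdfa=pdfa)
    return _params_from_state(idx2, tree, levels)


def update_hierarchy(params: UFAParams, r: CorrelationMatrix | np.ndarray
                     ) -> UFAParams:
    """Step 1.2: rebuild the merge tree by greedy max-correlation agglomeration."""
    values = as_array(r)
    idx, _ = _state_from_params(params)
    q = params.hierarchy.n_groups
    merges = _greedy_merges(values, idx, q)
    tree = _Tree(merges, q)
    levels, _, _ = _evaluate(values, idx, tree, _r_logdet(values))
    return _params_from_state(idx, tree, levels)


def update_loadings(params: UFAParams, r: CorrelationMatrix | np.ndarray,
                    pdfa: bool = False) -> UFAParams:
    """Steps 2.1-2.2: re-estimate node levels from block means and project
    them onto the ultrametric cone (upward clipping)."""
    values = as_array(r)
    idx, tree = _state_from_params(params)
    levels, _, _ = _evaluate(values, idx, tree, _r_logdet(values), pdfa=pdfa)
    return _params_from_state(idx, tree, levels)


def update_psi(params: UFAParams) -> UFAParams:
    """Step 3: uniquenesses as one minus the communality, floored at
    ``PSI_FLOOR`` with a Heywood warning when flooring occurs."""
    comm = params.communalities()
    psi = 1.0 - comm
    if np.any(psi < PSI_FLOOR):
        warnings.warn(
            "Heywood case: some communalities reach 1; uniquenesses floored",
            stacklevel=2,
        )
        psi = np.maximum(psi, PSI_FLOOR)
    return UFAParams(params.hierarchy, params.increments, psi)


# ---------------------------------------------------------------------------
# full fits


def _descend(r: np.ndarray, idx: np.ndarray, tree: _Tree, f: float,
             cfg: FitConfig, r_logdet: float, pdfa: bool = False,
             fixed_within: np.ndarray | None = None,
             assignment_free: bool = True
             ) -> tuple[np.ndarray, _Tree, float, list[float], bool]:
    """Alternate the block updates until the discrepancy decrease falls below
    ``cfg.tol``; every block update is guarded against increases."""
    trace = [f]
    converged = False
    for _ in range(cfg.max_iter):
        f_prev = f
        if assignment_free:
            fixed_levels = None
            if not cfg.exact_assignment:
                fixed_levels = _evaluate(r, idx, tree, r_logdet, pdfa=pdfa,
                                         fixed_within=fixed_within)[0]
            idx2, f2 = _sweep(r, idx, tree, r_logdet, f, pdfa=pdfa,
                              fixed_levels=fixed_levels)
            if f2 <= f:
                idx, f = idx2, f2
        if not pdfa:
            merges2 = _greedy_merges(r, idx, q := tree.q)
            if merges2 != tree.merges:
                tree2 = _Tree(merges2, q)
                _, _, f3 = _evaluate(r, idx, tree2, r_logdet,
                                     fixed_within=fixed_within)
                if f3 <= f:
                    tree, f = tree2, f3
        _, _, f4 = _evaluate(r, idx, tree, r_logdet, pdfa=pdfa,
                             fixed_within=fixed_within)
        if f4 <= f:
            f = f4
        trace.append(f)
        if f_prev - f < cfg.tol:
            converged = True
            break
    return idx, tree, f, trace, converged


def _fit_one_start(r: np.ndarray, q: int, cfg: FitConfig,
                   rng: np.random.Generator, r_logdet: float,
                   pdfa: bool = False,
                   fixed_idx: np.ndarray | None = None,
                   fixed_within: np.ndarray | None = None
                   ) -> tuple[np.ndarray, _Tree, np.ndarray, float, list[float], bool]:
    assignment_free = fixed_idx is None
    idx = _random_partition(r.shape[0], q, rng) if assignment_free else fixed_idx.copy()
    tree = _Tree(_greedy_merges(r, idx, q), q)
    _, _, f = _evaluate(r, idx, tree, r_logdet, pdfa=pdfa,
                        fixed_within=fixed_within)
    idx, tree, f, trace, converged = _descend(
        r, idx, tree, f, cfg, r_logdet, pdfa=pdfa, fixed_within=fixed_within,
        assignment_free=assignment_free,
    )
    levels, _, f = _evaluate(r, idx, tree, r_logdet, pdfa=pdfa,
                             fixed_within=fixed_within)
    return idx, tree, levels, f, trace, converged


def _two_split(r: np.ndarray, members: np.ndarray) -> np.ndarray | None:
    """Bisect a variable set by similarity to its least-correlated pair."""
    if members.size < 2:
        return None
    sub = r[np.ix_(members, members)]
    i, j = np.unravel_index(np.argmin(sub), sub.shape)
    labels = (sub[:, j] > sub[:, i]).astype(int)
    if labels.min() == labels.max():
        return None
    return labels


def _split_merge_refine(r: np.ndarray, idx: np.ndarray, tree: _Tree, f: float,
                        cfg: FitConfig, r_logdet: float, pdfa: bool = False,
                        max_rounds: int = 10, n_descents: int = 8
                        ) -> tuple[np.ndarray, _Tree, float, list[float]]:
    """Split-merge escape moves for the fixed-Q partition descent.

    The row-by-row sweep can never empty a group, so solutions that need a
    group dissolved (for instance a planted singleton absorbed elsewhere)
    are unreachable local minima.  Each proposal merges two groups into one
    and refills the freed label with one half of a bisected group, then
    re-runs the guarded descent; a proposal is accepted only if it lowers
    the discrepancy, so traces remain monotone.
    """
    q = tree.q
    trace: list[float] = []
    for _ in range(max_rounds):
        groups = [np.nonzero(idx == g)[0] for g in range(q)]
        proposals = []
        for a, b in itertools.combinations(range(q), 2):
            for c in range(q):
                if c == b or (c != a and len(groups[c]) < 2):
                    continue
                idx2 = idx.copy()
                idx2[groups[b]] = a
                members = (
                    np.nonzero(idx2 == a)[0] if c == a else groups[c]
                )
                labels = _two_split(r, members)
                if labels is None:
                    continue
                idx2[members[labels == 1]] = b
                tree2 = _Tree(_greedy_merges(r, idx2, q), q)
                _, _, f2 = _evaluate(r, idx2, tree2, r_logdet, pdfa=pdfa)
                proposals.append((f2, idx2, tree2))
        proposals.sort(key=lambda t: t[0])
        best = None
        for f2, idx2, tree2 in proposals[:n_descents]:
            idx3, tree3, f3, _, _ = _descend(r, idx2, tree2, f2, cfg,
                                             r_logdet, pdfa=pdfa)
            if f3 < f - 1e-10 and (best is None or f3 < best[0]):
                best = (f3, idx3, tree3)
        if best is None:
            break
        f, idx, tree = best
        trace.append(f)
    return idx, tree, f, trace


def _diagnostics(params: UFAParams) -> dict:
    h = params.hierarchy
    levels = params.levels()
    sizes = np.bincount(h.assignment, minlength=h.n_groups + 1)[1:]
    alphas = {}
    spectra = {}
    for g in range(1, h.n_groups + 1):
        if sizes[g - 1] >= 2:
            alphas[g] = cronbach_alpha(int(sizes[g - 1]), float(levels.within[g - 1]))
            spectra[g] = [
                float(x)
                for x in np.concatenate(
                    [[1.0 + (sizes[g - 1] - 1) * levels.within[g - 1]],
                     np.full(sizes[g - 1] - 1, 1.0 - levels.within[g - 1])]
                )
            ]
    heywood = bool(np.any(params.psi <= PSI_FLOOR + 1e-12))
    return {
        "group_sizes": [int(s) for s in sizes],
        "cronbach_alpha": alphas,
        "block_spectra": spectra,
        "heywood": heywood,
        "singleton_groups": [int(g) for g in np.nonzero(sizes == 1)[0] + 1],
    }


def _prepare_input(r: CorrelationMatrix | np.ndarray, strict: bool,
                   allow_negative: bool = False) -> np.ndarray:
    values = as_array(r)
    problems = check_correlation(values, require_nonnegative=False)
    psd_issue = "matrix is not positive semi-definite" in problems
    structural = [p for p in problems if "positive semi-definite" not in p]
    if structural:
        raise ValueError("invalid correlation matrix: " + "; ".join(structural))
    if np.any(values < -1e-8):
        if not allow_negative:
            raise ValueError(
                "negative correlations present; the ultrametric model assumes "
                "non-negative correlations (override with allow_negative)"
            )
        warnings.warn(
            "fitting despite negative correlations; the ultrametric model "
            "assumes non-negative correlations", stacklevel=3,
        )
    if psd_issue or np.linalg.eigvalsh(0.5 * (values + values.T))[0] < 1e-10:
        if strict:
            raise ValueError("correlation matrix is not positive definite")
        warnings.warn(
            "correlation matrix is not positive definite; applying the "
            "diagonal-shift repair", stacklevel=3,
        )
        values = psd_repair(values, ridge=1e-8)
    return values


def fit(r: CorrelationMatrix | np.ndarray, config: FitConfig) -> FitResult:
    """Multistart coordinate-descent fit of the ultrametric factor model.

    Runs ``config.n_starts`` optimizations from random partitions and keeps
    the solution with the smallest discrepancy.  Deterministic given
    ``config.seed``: start ``s`` uses the generator seeded with
    ``(seed, s)``, so any single start is re-runnable in isolation.
    """
    values = _prepare_input(r, config.strict, config.allow_negative)
    if config.constrained:
        return _fit_constrained(values, config)
    return _fit_multistart(values, config, pdfa=False)


def fit_pdfa(r: CorrelationMatrix | np.ndarray, config: FitConfig) -> FitResult:
    """Fit the parsimonious disjoint special case (all merge increments zero)."""
    values = _prepare_input(r, config.strict, config.allow_negative)
    return _fit_multistart(values, config, pdfa=True)


def _fit_multistart(values: np.ndarray, config: FitConfig, pdfa: bool,
                    fixed_idx: np.ndarray | None = None,
                    fixed_within: np.ndarray | None = None) -> FitResult:
    q = config.q
    j_n = values.shape[0]
    if not 2 <= q <= j_n:
        raise ValueError(f"need 2 <= Q <= J, got Q={q}, J={j_n}")
    r_logdet = _r_logdet(values)
    n_starts = 1 if fixed_idx is not None else config.n_starts
    best = None
    start_fs = []
    for s in range(n_starts):
        rng = np.random.default_rng(
            [config.seed, s] if config.seed is not None else None
        )
        out = _fit_one_start(values, q, config, rng, r_logdet, pdfa=pdfa,
                             fixed_idx=fixed_idx, fixed_within=fixed_within)
        start_fs.append(out[3])
        if best is None or out[3] < best[1][3]:
            best = (s, out)
    s_best, (idx, tree, levels, f, trace, converged) = best
    if config.refine and fixed_idx is None and fixed_within is None:
        idx, tree, f, extra = _split_merge_refine(
            values, idx, tree, f, config, r_logdet, pdfa=pdfa
        )
        trace = list(trace) + extra
        levels, _, f = _evaluate(values, idx, tree, r_logdet, pdfa=pdfa)
    params = _params_from_state(idx, tree, levels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = update_psi(params)
    indices = None
    if config.n is not None:
        sigma = implied_correlation(params)
        npar = n_parameters_pdfa(q) if pdfa else n_parameters(q)
        indices = fit_indices(sigma, values, config.n, q,
                              df_convention=config.df_convention, npar=npar)
    return FitResult(
        params=params,
        discrepancy=f,
        trace=tuple(trace),
        n_iterations=len(trace) - 1,
        converged=converged,
        best_start=s_best,
        start_discrepancies=tuple(start_fs),
        indices=indices,
        diagnostics=_diagnostics(params),
    )


def _fit_constrained(values: np.ndarray, config: FitConfig) -> FitResult:
    """Constrained variant: freeze the converged PDFA partition and within
    levels, then estimate only the hierarchy and its between levels."""
    pdfa_res = _fit_multistart(values, config, pdfa=True)
    idx = pdfa_res.params.hierarchy.assignment - 1
    fixed_within = pdfa_res.params.levels().within
    res = _fit_multistart(values, config, pdfa=False, fixed_idx=idx,
                          fixed_within=fixed_within)
    diag = dict(res.diagnostics)
    diag["pdfa_discrepancy"] = pdfa_res.discrepancy
    return replace(res, diagnostics=diag)


def select_q(r: CorrelationMatrix | np.ndarray, q_range, config: FitConfig,
             criterion: str = "bic") -> SelectionResult:
    """Fit the model for every Q in ``q_range`` and tabulate F, AIC, BIC, AGFI.

    The chosen Q minimizes AIC or BIC, or maximizes AGFI, per ``criterion``
    (default BIC); the optima of all three criteria are always reported.
    """
    if config.n is None:
        raise ValueError("model selection needs the number of observations n")
    values = as_array(r)
    j_n = values.shape[0]
    rows = []
    for q in q_range:
        if not 2 <= q <= j_n:
            raise ValueError(f"Q range must stay within [2, {j_n}], got {q}")
        res = fit(values, replace(config, q=q))
        ind = res.indices
        rows.append({"Q": q, "F": res.discrepancy, "npar": ind.npar, "df": ind.df,
                     "AIC": ind.aic, "BIC": ind.bic, "GFI": ind.gfi,
                     "AGFI": ind.agfi})
    table = pd.DataFrame(rows)
    best = {
        "aic": int(table.loc[table["AIC"].idxmin(), "Q"]),
        "bic": int(table.loc[table["BIC"].idxmin(), "Q"]),
        "agfi": int(table.loc[table["AGFI"].idxmax(), "Q"]),
    }
    if criterion not in best:
        raise ValueError(f"unknown selection criterion {criterion!r}")
    return SelectionResult(table=table, best=best, chosen_q=best[criterion],
                           criterion=criterion)
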
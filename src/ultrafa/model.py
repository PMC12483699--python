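"""The ultrametric factor model: parameters, implied correlation, discrepancy, fit indices.

The model decomposes a J x J correlation matrix as ``Sigma = Lambda Lambda' + Psi``
where the loading matrix ``Lambda`` is constrained by a hierarchy of variable
groups: every internal node ``m`` of the dendrogram (Q group nodes plus Q-1
merge nodes) contributes a non-negative variance increment ``b2[m]`` shared by
all variables below it.  The off-diagonal implied correlation of two variables
is the sum of increments over their common nodes, i.e. the cumulative level of
their lowest common ancestor, which makes ``Sigma`` ultrametric by
construction.  Uniquenesses close the diagonal to one:
``psi_j = 1 - sum of increments on j's root path``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .hierarchy import (
    CorrelationMatrix,
    Hierarchy,
    UltrametricValues,
    as_array,
    membership_matrix,
)

__all__ = [
    "UFAParams",
    "FitIndices",
    "loading_matrix",
    "implied_correlation",
    "discrepancy",
    "n_parameters",
    "n_parameters_pdfa",
    "degrees_of_freedom",
    "fit_indices",
    "cronbach_alpha",
    "block_spectrum",
    "is_unidimensional",
]

#: uniquenesses below this trigger a Heywood warning and are floored
PSI_FLOOR = 1e-4


@dataclass(frozen=True)
class UFAParams:
    """Full parameter set: hierarchy, per-node variance increments, uniquenesses.

    ``increments[m-1]`` is the non-negative variance ``b2`` contributed by node
    ``m``; the cumulative level of a node is the sum of increments from the
    node up to the root.  For every variable the path-sum of increments plus
    its uniqueness equals one.
    """

    hierarchy: Hierarchy
    increments: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        inc = np.asarray(self.increments, dtype=float)
        psi = np.asarray(self.psi, dtype=float)
        object.__setattr__(self, "increments", inc)
        object.__setattr__(self, "psi", psi)
        h = self.hierarchy
        if inc.shape != (h.n_nodes,):
            raise ValueError(f"expected {h.n_nodes} increments, got {inc.shape}")
        if psi.shape != (h.n_vars,):
            raise ValueError(f"expected {h.n_vars} uniquenesses, got {psi.shape}")
        if np.any(inc < -1e-12):
            raise ValueError("variance increments must be non-negative")
        if np.any(psi <= 0):
            raise ValueError("uniquenesses must be positive")
        comm = self.communalities()
        # slack of 2*PSI_FLOOR admits Heywood-floored uniquenesses
        if not np.allclose(comm + psi, 1.0, atol=2 * PSI_FLOOR):
            raise ValueError("increments path-sum + psi must equal 1 for every variable")

    def levels(self) -> UltrametricValues:
        """Cumulative level (path-sum of increments up to the root) per node."""
        h = self.hierarchy
        parent = h.parent_array()
        by_node = np.array(self.increments, dtype=float)
        # accumulate top-down: nodes are created in merge order, so the parent
        # of any node has a larger id, and a reverse sweep suffices
        for node in range(h.n_nodes - 1, 0, -1):
            if parent[node] != 0:
                by_node[node - 1] += by_node[parent[node] - 1]
        q = h.n_groups
        return UltrametricValues(by_node[:q], by_node[q:])

    def communalities(self) -> np.ndarray:
        levels = self.levels()
        return levels.within[self.hierarchy.assignment - 1]

    @classmethod
    def from_levels(cls, h: Hierarchy, values: UltrametricValues) -> "UFAParams":
        """Convert node levels back to increments; inverse of :meth:`levels`."""
        by_node = values.by_node()
        parent = h.parent_array()
        inc = np.array(by_node, dtype=float)
        for node in range(1, h.n_nodes):
            inc[node - 1] -= by_node[parent[node] - 1]
        inc = np.maximum(inc, 0.0)
        psi = 1.0 - values.within[h.assignment - 1]
        return cls(h, inc, psi)

    def canonical(self) -> "UFAParams":
        """Label-sorted representative (groups relabelled by first occurrence)."""
        h2 = self.hierarchy.relabel_canonical()
        # increments follow the node relabelling
        old_levels = self.levels().by_node()
        q = self.hierarchy.n_groups
        order: dict[int, int] = {}
        for lab in self.hierarchy.assignment:
            if lab not in order:
                order[int(lab)] = len(order) + 1
        new_by_node = np.array(old_levels)
        for old, new in order.items():
            new_by_node[new - 1] = old_levels[old - 1]
        values = UltrametricValues(new_by_node[:q], new_by_node[q:])
        return UFAParams.from_levels(h2, values)

    def to_dict(self) -> dict:
        levels = self.levels()
        return {
            **self.hierarchy.to_dict(),
            "within": [float(x) for x in levels.within],
            "between": [float(x) for x in levels.between],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UFAParams":
        h = Hierarchy.from_dict(d)
        values = UltrametricValues(np.asarray(d["within"]), np.asarray(d["between"]))
        return cls.from_levels(h, values)


@dataclass(frozen=True)
class FitIndices:
    """Discrepancy-based fit summary for one fitted model."""

    discrepancy: float
    aic: float
    bic: float
    gfi: float
    agfi: float
    npar: int
    df: int
    n: int


def loading_matrix(p: UFAParams) -> np.ndarray:
    """J x (2Q-1) loading matrix: entry (j, m) = sqrt(b2[m]) iff j lies below node m."""
    v = membership_matrix(p.hierarchy)
    return v * np.sqrt(np.maximum(p.increments, 0.0))


def implied_correlation(p: UFAParams) -> CorrelationMatrix:
    """Model-implied correlation matrix ``Lambda Lambda' + Psi`` (unit diagonal)."""
    h = p.hierarchy
    by_node = p.levels().by_node()
    lca = h.lca_table()
    idx = h.assignment - 1
    r = by_node[lca[np.ix_(idx, idx)] - 1]
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r)


def discrepancy(sigma: CorrelationMatrix | np.ndarray,
                r: CorrelationMatrix | np.ndarray) -> float:
    """ML discrepancy ``F = log|Sigma| + tr(Sigma^-1 R) - log|R| - J``.

    Non-negative, zero iff the matrices coincide; both must be positive
    definite.
    """
    s = as_array(sigma)
    x = as_array(r)
    j_n = s.shape[0]
    try:
        c_s = scipy.linalg.cho_factor(s, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"implied matrix is not positive definite "
            f"(condition number {np.linalg.cond(s):.3g})"
        ) from exc
    sign_r, logdet_r = np.linalg.slogdet(x)
    if sign_r <= 0:
        raise np.linalg.LinAlgError(
            f"sample matrix is not positive definite "
            f"(condition number {np.linalg.cond(x):.3g})"
        )
    logdet_s = 2.0 * np.sum(np.log(np.diag(c_s[0])))
    trace = np.trace(scipy.linalg.cho_solve(c_s, x, check_finite=False))
    return float(logdet_s + trace - logdet_r - j_n)


def n_parameters(q: int) -> int:
    """Effective parameter count of the hierarchical model: ``3Q - 1``.

    One loading per group, one per merge node (Q-1), one uniqueness per group;
    independent of the number of variables.
    """
    return 3 * q - 1


def n_parameters_pdfa(q: int) -> int:
    """Parameter count of the parsimonious disjoint model (no hierarchy): ``2Q``."""
    return 2 * q


def degrees_of_freedom(j_n: int, q: int, convention: str = "full") -> int:
    """Model degrees of freedom.

    ``convention='full'`` counts all J(J+1)/2 distinct moments of a symmetric
    matrix (the standard ML factor-analysis count); ``'offdiag'`` counts only
    the J(J-1)/2 off-diagonal correlations.
    """
    if not 2 <= q <= j_n:
        raise ValueError(f"need 2 <= Q <= J, got Q={q}, J={j_n}")
    if convention == "full":
        moments = j_n * (j_n + 1) // 2
    elif convention == "offdiag":
        moments = j_n * (j_n - 1) // 2
    else:
        raise ValueError(f"unknown df convention {convention!r}")
    return moments - n_parameters(q)


def fit_indices(sigma: CorrelationMatrix | np.ndarray,
                r: CorrelationMatrix | np.ndarray,
                n: int, q: int, df_convention: str = "full",
                npar: int | None = None) -> FitIndices:
    """AIC, BIC, GFI and AGFI for a fitted implied matrix.

    ``AIC = n F + 2 npar`` and ``BIC = n F + npar log n`` on the discrepancy
    scale (additive constants cancel in model comparison);
    ``GFI = 1 - tr[(Sigma^-1 S - I)^2] / tr[(Sigma^-1 S)^2]`` and AGFI
    penalizes GFI by the ratio of moments to degrees of freedom.
    """
    if n < 2:
        raise ValueError("fit indices need the number of observations n >= 2")
    s = as_array(sigma)
    x = as_array(r)
    j_n = s.shape[0]
    f = discrepancy(s, x)
    if npar is None:
        npar = n_parameters(q)
    moments = j_n * (j_n + 1) // 2 if df_convention == "full" else j_n * (j_n - 1) // 2
    df = moments - npar
    w = np.linalg.solve(s, x)
    gfi = 1.0 - np.trace((w - np.eye(j_n)) @ (w - np.eye(j_n))) / np.trace(w @ w)
    if df > 0:
        agfi = 1.0 - (j_n * (j_n + 1) / (2.0 * df)) * (1.0 - gfi)
    else:
        agfi = float("nan")
    return FitIndices(
        discrepancy=f,
        aic=float(n * f + 2 * npar),
        bic=float(n * f + npar * np.log(n)),
        gfi=float(gfi),
        agfi=float(agfi),
        npar=int(npar),
        df=int(df),
        n=int(n),
    )


def cronbach_alpha(group_size: int, level: float) -> float:
    """Standardized Cronbach's alpha of an equicorrelated block.

    ``alpha = (J_q rho) / (1 + (J_q - 1) rho)``: the internal-consistency
    reliability of a group of ``group_size`` variables with common
    correlation ``level``.
    """
    if group_size < 2:
        raise ValueError("alpha requires a group of at least two variables")
    if not 0.0 <= level <= 1.0:
        raise ValueError("the correlation level must lie in [0, 1]")
    return float(group_size * level / (1.0 + (group_size - 1) * level))


def block_spectrum(group_size: int, level: float) -> np.ndarray:
    """Eigenvalues of the J_q x J_q equicorrelation block, descending.

    The largest eigenvalue is ``1 + (J_q - 1) rho``; the remaining
    ``J_q - 1`` all equal ``1 - rho``.  A block is unidimensional when only
    the leading eigenvalue exceeds one.
    """
    if group_size < 1:
        raise ValueError("group size must be positive")
    if not 0.0 <= level < 1.0:
        raise ValueError("the correlation level must lie in [0, 1)")
    rest = np.full(group_size - 1, 1.0 - level)
    return np.concatenate([[1.0 + (group_size - 1) * level], rest])


def is_unidimensional(group_size: int, level: float) -> bool:
    """True when the equicorrelation block has a single eigenvalue above one."""
    spectrum = block_spectrum(group_size, level)
    return bool(spectrum[0] > 1.0 and (group_size == 1 or spectrum[1] < 1.0))
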
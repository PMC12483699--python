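"""Hierarchies of variable groups and the ultrametric correlation matrices they generate.

A hierarchy is a partition of J observed variables into Q disjoint groups
together with an ordered sequence of Q-1 binary merges of those groups; it is
the combinatorial skeleton of a dendrogram whose leaves are the variables.
Attaching one correlation level to every internal node (a within level per
group, a between level per merge) yields an ultrametric correlation matrix:
within-group entries take the group's level and cross-group entries take the
level of the lowest merge node containing both groups.

Node numbering convention: groups are nodes ``1..Q``; merge ``i`` (1-based)
creates node ``Q+i``; the root is node ``2Q-1``.  Variables are 0-based
internally and 1-based in all serialized output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Hierarchy",
    "UltrametricValues",
    "CorrelationMatrix",
    "check_correlation",
    "check_ultrametric",
    "membership_matrix",
    "compose_ultrametric",
    "extract_levels",
    "to_newick",
]

#: two level values closer than this are treated as equal
LEVEL_TOL = 1e-8


@dataclass(frozen=True)
class CorrelationMatrix:
    """A labelled square correlation matrix."""

    values: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"correlation matrix must be square, got shape {values.shape}")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"V{j + 1}" for j in range(values.shape[0]))
            )
        elif len(self.labels) != values.shape[0]:
            raise ValueError("number of labels does not match matrix order")


def as_array(r: "CorrelationMatrix | np.ndarray") -> np.ndarray:
    """Accept either a bare array or a :class:`CorrelationMatrix`."""
    if isinstance(r, CorrelationMatrix):
        return r.values
    return np.asarray(r, dtype=float)


@dataclass(frozen=True, eq=False)
class Hierarchy:
    """Partition of J variables into Q groups plus Q-1 ordered binary merges.

    Parameters
    ----------
    assignment
        Length-J vector of group labels in ``1..Q``; every label occurs.
    merges
        Q-1 pairs of node identifiers.  Merge ``i`` consumes two previously
        available nodes and creates node ``Q+i``; after the last merge a
        single root remains.
    """

    assignment: np.ndarray
    merges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        assignment = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", assignment)
        merges = tuple((int(a), int(b)) for a, b in self.merges)
        object.__setattr__(self, "merges", merges)
        q = len(merges) + 1
        if assignment.ndim != 1 or assignment.size < q:
            raise ValueError("assignment must be a 1-d vector with at least Q entries")
        if q < 2:
            raise ValueError("a hierarchy needs at least two groups")
        present = np.unique(assignment)
        if present[0] < 1 or present[-1] > q or present.size != q:
            raise ValueError(
                f"assignment labels must cover 1..{q} with no empty group, got {present}"
            )
        # merges must consume every node except the root exactly once
        available = set(range(1, q + 1))
        for i, (a, b) in enumerate(merges, start=1):
            if a == b or a not in available or b not in available:
                raise ValueError(f"merge {i} = ({a}, {b}) references unavailable nodes")
            available -= {a, b}
            available.add(q + i)
        if available != {2 * q - 1}:
            raise ValueError("merges do not reduce to a single root")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Hierarchy)
            and np.array_equal(self.assignment, other.assignment)
            and self.merges == other.merges
        )

    def __hash__(self) -> int:
        return hash((tuple(int(g) for g in self.assignment), self.merges))

    # -- basic structure -------------------------------------------------

    @property
    def n_vars(self) -> int:
        return int(self.assignment.size)

    @property
    def n_groups(self) -> int:
        return len(self.merges) + 1

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_groups - 1

    @property
    def root(self) -> int:
        return self.n_nodes

    def parent_array(self) -> np.ndarray:
        """1-indexed parent node ids; ``parent[root] = 0``; index 0 unused."""
        q = self.n_groups
        parent = np.zeros(2 * q, dtype=int)
        for i, (a, b) in enumerate(self.merges, start=1):
            parent[a] = parent[b] = q + i
        return parent

    def children(self, node: int) -> tuple[int, int]:
        q = self.n_groups
        if node <= q:
            raise ValueError(f"node {node} is a group, not a merge node")
        return self.merges[node - q - 1]

    def path_to_root(self, node: int) -> list[int]:
        """Node ids from ``node`` (inclusive) up to the root."""
        parent = self.parent_array()
        path = [node]
        while parent[path[-1]] != 0:
            path.append(int(parent[path[-1]]))
        return path

    def group_sets(self, node: int) -> frozenset[int]:
        """Group labels (1..Q) lying below ``node``."""
        q = self.n_groups
        if node <= q:
            return frozenset({node})
        a, b = self.children(node)
        return self.group_sets(a) | self.group_sets(b)

    def lca_table(self) -> np.ndarray:
        """Q x Q table of the lowest common node of two groups (0-indexed rows/cols).

        The diagonal holds the group node itself.
        """
        q = self.n_groups
        table = np.zeros((q, q), dtype=int)
        np.fill_diagonal(table, np.arange(1, q + 1))
        for i, _ in enumerate(self.merges, start=1):
            node = q + i
            groups = sorted(self.group_sets(node))
            a, b = self.children(node)
            ga, gb = self.group_sets(a), self.group_sets(b)
            for x in ga:
                for y in gb:
                    table[x - 1, y - 1] = table[y - 1, x - 1] = node
        return table

    def relabel_canonical(self) -> "Hierarchy":
        """Relabel groups by first occurrence along the variable order.

        Two hierarchies identical up to a permutation of group labels map to
        the same canonical representative.
        """
        order: dict[int, int] = {}
        for lab in self.assignment:
            if lab not in order:
                order[int(lab)] = len(order) + 1
        new_assignment = np.array([order[int(g)] for g in self.assignment])
        q = self.n_groups
        node_map = {q + i: q + i for i in range(1, q)}
        node_map.update({old: new for old, new in order.items()})
        new_merges = tuple(
            tuple(sorted((node_map[a], node_map[b]))) for a, b in self.merges
        )
        return Hierarchy(new_assignment, new_merges)

    def to_dict(self) -> dict:
        return {
            "assignment": [int(g) for g in self.assignment],
            "merges": [list(m) for m in self.merges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hierarchy":
        return cls(np.asarray(d["assignment"], dtype=int),
                   tuple(tuple(m) for m in d["merges"]))


@dataclass(frozen=True)
class UltrametricValues:
    """Correlation levels attached to the nodes of a :class:`Hierarchy`.

    ``within[q-1]`` is the common correlation inside group ``q``;
    ``between[i-1]`` is the correlation level of merge node ``Q+i``.
    Validity requires the levels to be non-increasing up every root path.
    """

    within: np.ndarray
    between: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "within", np.asarray(self.within, dtype=float))
        object.__setattr__(self, "between", np.asarray(self.between, dtype=float))

    @property
    def n_groups(self) -> int:
        return int(self.within.size)

    def by_node(self) -> np.ndarray:
        """Level of node ``m`` at index ``m-1`` (length 2Q-1)."""
        return np.concatenate([self.within, self.between])

    def validate(self, h: Hierarchy, strict_global: bool = False,
                 tol: float = LEVEL_TOL) -> list[str]:
        """Return the list of violated ordering conditions (empty if valid).

        By default each group's within level must dominate the between levels
        on its own root path only; ``strict_global`` additionally requires
        every within level to dominate every between level.
        """
        problems: list[str] = []
        if self.within.size != h.n_groups or self.between.size != h.n_groups - 1:
            return [f"expected {h.n_groups} within and {h.n_groups - 1} between levels"]
        for arr, name in ((self.within, "within"), (self.between, "between")):
            if np.any(arr < -tol) or np.any(arr > 1 + tol):
                problems.append(f"{name} levels outside [0, 1]")
        levels = self.by_node()
        for q in range(1, h.n_groups + 1):
            path = h.path_to_root(q)
            for child, par in zip(path, path[1:]):
                if levels[child - 1] < levels[par - 1] - tol:
                    problems.append(
                        f"level of node {child} ({levels[child - 1]:.6f}) below its "
                        f"parent node {par} ({levels[par - 1]:.6f})"
                    )
        if strict_global and self.between.size:
            if np.min(self.within) < np.max(self.between) - tol:
                problems.append("global ordering: min within < max between")
        # de-duplicate while keeping order
        return list(dict.fromkeys(problems))


# ---------------------------------------------------------------------------
# validation of correlation matrices


def check_correlation(r: "CorrelationMatrix | np.ndarray",
                      require_nonnegative: bool = True,
                      tol: float = 1e-8) -> list[str]:
    """Validate a candidate correlation matrix.

    Checks symmetry, unit diagonal, (optionally) non-negative entries, and
    positive semi-definiteness (smallest eigenvalue >= ``-tol``).  Returns a
    list of human-readable violations, empty when the matrix passes.
    """
    values = as_array(r)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {values.shape}")
    problems = []
    if not np.allclose(values, values.T, atol=tol):
        problems.append("matrix is not symmetric")
    if not np.allclose(np.diag(values), 1.0, atol=tol):
        problems.append("diagonal entries differ from 1")
    if np.any(np.abs(values) > 1 + tol):
        problems.append("entries outside [-1, 1]")
    if require_nonnegative and np.any(values < -tol):
        problems.append("negative entries present (non-negativity required)")
    sym = 0.5 * (values + values.T)
    if np.linalg.eigvalsh(sym)[0] < -tol:
        problems.append("matrix is not positive semi-definite")
    return problems


def check_ultrametric(r: "CorrelationMatrix | np.ndarray", tol: float = LEVEL_TOL
                      ) -> tuple[bool, tuple[int, int, int] | None]:
    """Test the similarity-ultrametric condition on every triplet.

    A matrix is ultrametric in the similarity sense when, for every triplet
    of indices, the minimum of the three pairwise values is attained at least
    twice (within ``tol``).  Returns ``(True, None)`` or ``(False, (j, l, p))``
    with the first violating triplet in 0-based index order.
    """
    values = as_array(r)
    j_n = values.shape[0]
    for j in range(j_n):
        for l in range(j + 1, j_n):
            for p in range(l + 1, j_n):
                x, y, z = values[j, l], values[j, p], values[l, p]
                m = min(x, y, z)
                if sum(v <= m + tol for v in (x, y, z)) < 2:
                    return False, (j, l, p)
    return True, None


# ---------------------------------------------------------------------------
# construction


def membership_matrix(h: Hierarchy) -> np.ndarray:
    """Binary J x (2Q-1) membership matrix.

    Column ``m-1`` indicates the variables below node ``m``: the first Q
    columns one-hot encode the partition, a merge column is the elementwise
    sum of its children's columns, and the last column is all ones.
    """
    q = h.n_groups
    v = np.zeros((h.n_vars, 2 * q - 1), dtype=int)
    v[np.arange(h.n_vars), h.assignment - 1] = 1
    for i, (a, b) in enumerate(h.merges, start=1):
        v[:, q + i - 1] = v[:, a - 1] + v[:, b - 1]
    return v


def compose_ultrametric(h: Hierarchy, values: UltrametricValues,
                        labels: Sequence[str] | None = None,
                        strict_global: bool = False) -> CorrelationMatrix:
    """Build the ultrametric correlation matrix generated by a hierarchy.

    Entry (j, l) equals the within level of their common group, or the level
    of the lowest merge node containing both groups.  Raises ``ValueError``
    naming the violated ordering when ``values`` is not valid for ``h``.
    """
    problems = values.validate(h, strict_global=strict_global)
    if problems:
        raise ValueError("invalid ultrametric levels: " + "; ".join(problems))
    by_node = values.by_node()
    lca = h.lca_table()
    idx = h.assignment - 1
    r = by_node[lca[np.ix_(idx, idx)] - 1]
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, tuple(labels) if labels else ())


def extract_levels(r: "CorrelationMatrix | np.ndarray", h: Hierarchy) -> UltrametricValues:
    """Mean within-block / cross-block entries of ``r`` under hierarchy ``h``.

    Exactly inverts :func:`compose_ultrametric` when ``r`` is generated by
    ``h``; on arbitrary matrices it is the natural level estimator.  A
    singleton group has no within pairs; its within level is set to the
    level of its parent merge node (zero increment).
    """
    values = as_array(r)
    q = h.n_groups
    idx = h.assignment - 1
    onehot = np.zeros((h.n_vars, q))
    onehot[np.arange(h.n_vars), idx] = 1.0
    sizes = onehot.sum(axis=0)
    block_sums = onehot.T @ values @ onehot
    within = np.zeros(q)
    nontrivial = sizes > 1
    within[nontrivial] = (np.diag(block_sums)[nontrivial] - sizes[nontrivial]) / (
        sizes[nontrivial] * (sizes[nontrivial] - 1)
    )
    between = np.zeros(q - 1)
    for i, _ in enumerate(h.merges, start=1):
        a, b = h.children(q + i)
        ga = [g - 1 for g in h.group_sets(a)]
        gb = [g - 1 for g in h.group_sets(b)]
        cross = block_sums[np.ix_(ga, gb)].sum()
        n_pairs = sizes[ga].sum() * sizes[gb].sum()
        between[i - 1] = cross / n_pairs
    # singleton groups inherit their parent's level
    parent = h.parent_array()
    by_node = np.concatenate([within, between])
    for g in np.nonzero(~nontrivial)[0]:
        within[g] = by_node[parent[g + 1] - 1]
    return UltrametricValues(within, between)


# ---------------------------------------------------------------------------
# Newick export


def to_newick(h: Hierarchy, values: UltrametricValues,
              labels: Sequence[str] | None = None) -> str:
    """Render the hierarchy as a Newick dendrogram string.

    Node height is ``1 - level``; leaves sit at height 0, so the tree is
    ultrametric (all leaves equidistant from the root).  Singleton group
    nodes, which are unary, are collapsed into their leaf edge.
    """
    problems = values.validate(h)
    if problems:
        raise ValueError("invalid ultrametric levels: " + "; ".join(problems))
    if labels is None:
        labels = [f"V{j + 1}" for j in range(h.n_vars)]
    by_node = values.by_node()
    q = h.n_groups

    def height(node: int) -> float:
        return 1.0 - by_node[node - 1]

    def render(node: int, parent_height: float) -> str:
        if node <= q:
            members = np.nonzero(h.assignment == node)[0]
            if members.size == 1:
                # collapse the unary singleton-group node
                return f"{labels[members[0]]}:{parent_height:.10g}"
            leaf_h = height(node)
            inner = ",".join(f"{labels[j]}:{leaf_h:.10g}" for j in members)
            return f"({inner}):{parent_height - leaf_h:.10g}"
        a, b = h.children(node)
        node_h = height(node)
        inner = ",".join(render(c, node_h) for c in (a, b))
        if parent_height is None:
            return f"({inner})"
        return f"({inner}):{parent_height - node_h:.10g}"

    root = h.root
    root_h = height(root)
    inner = ",".join(render(c, root_h) for c in h.children(root))
    return f"({inner});"
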
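"""Exhaustive enumeration of hierarchies for small problems.

Enumerates every partition of J variables into exactly Q non-empty groups and
every binary merge sequence over the groups, evaluates the same
level-estimation objective the coordinate-descent estimator uses, and returns
the global minimum.  Feasible only at toy scale (the partition count is the
Stirling number S(J, Q)); it exists to certify that the heuristic search
reaches the global optimum on small inputs.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .estimator import _evaluate, _r_logdet, _Tree, _params_from_state
from .hierarchy import CorrelationMatrix, as_array
from .model import UFAParams

__all__ = ["iter_partitions", "iter_merge_sequences", "brute_force_fit"]


def iter_partitions(j_n: int, q: int) -> Iterator[np.ndarray]:
    """All partitions of ``j_n`` items into exactly ``q`` non-empty blocks.

    Yields 0-based restricted-growth label vectors (block labels appear in
    first-occurrence order), so each set partition appears exactly once.
    """
    labels = np.zeros(j_n, dtype=int)

    def rec(pos: int, used: int) -> Iterator[np.ndarray]:
        if pos == j_n:
            if used == q:
                yield labels.copy()
            return
        if used + (j_n - pos) < q:
            return  # cannot reach q blocks any more
        for lab in range(min(used + 1, q)):
            labels[pos] = lab
            yield from rec(pos + 1, max(used, lab + 1))

    yield from rec(0, 0)


def iter_merge_sequences(q: int) -> Iterator[tuple[tuple[int, int], ...]]:
    """All ordered sequences of Q-1 binary merges over nodes 1..Q."""

    def rec(active: tuple[int, ...], step: int) -> Iterator[tuple]:
        if len(active) == 1:
            yield ()
            return
        new = q + step
        items = sorted(active)
        for i in range(len(items)):
            for k in range(i + 1, len(items)):
                pair = (items[i], items[k])
                rest = tuple(n for n in active if n not in pair) + (new,)
                for tail in rec(rest, step + 1):
                    yield (pair,) + tail

    yield from rec(tuple(range(1, q + 1)), 1)


def brute_force_fit(r: CorrelationMatrix | np.ndarray, q: int
                    ) -> tuple[float, UFAParams]:
    """Global minimum of the estimation objective over all hierarchies."""
    values = as_array(r)
    r_logdet = _r_logdet(values)
    trees = [_Tree(m, q) for m in iter_merge_sequences(q)]
    best_f = np.inf
    best = None
    for idx in iter_partitions(values.shape[0], q):
        for tree in trees:
            levels, _, f = _evaluate(values, idx, tree, r_logdet)
            if f < best_f:
                best_f = f
                best = (idx.copy(), tree, levels.copy())
    idx, tree, levels = best
    return float(best_f), _params_from_state(idx, tree, levels)
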
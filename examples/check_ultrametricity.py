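"""Compose an ultrametric correlation matrix and validate the defining conditions.

Builds the matrix generated by two variable groups with one merge, verifies
the correlation-matrix conditions and the triplet (ultrametricity) condition,
then shows a matrix that fails it.
"""

import numpy as np

from ultrafa import (
    Hierarchy,
    UltrametricValues,
    check_correlation,
    check_ultrametric,
    compose_ultrametric,
)

hierarchy = Hierarchy(assignment=[1, 1, 2, 2], merges=[(1, 2)])
levels = UltrametricValues(within=[0.7, 0.6], between=[0.3])
r = compose_ultrametric(hierarchy, levels)

print("composed matrix:")
print(np.round(r.values, 2))
print("correlation-matrix violations:", check_correlation(r) or "none")
ok, _ = check_ultrametric(r)
print("ultrametric (every triplet's minimum attained twice):", ok)

bad = np.array([[1.0, 0.8, 0.5], [0.8, 1.0, 0.3], [0.5, 0.3, 1.0]])
ok, triplet = check_ultrametric(bad)
print(f"\nmatrix with off-diagonals (0.8, 0.5, 0.3) ultrametric: {ok}; "
      f"violating triplet (0-based): {triplet}")
# (0.8, 0.5, 0.3): the minimum 0.3 appears once, so no dendrogram can
# generate these similarities.
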
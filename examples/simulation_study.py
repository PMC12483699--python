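"""A scaled-down structure-recovery study over noise levels.

For each scenario, planted ultrametric matrices are perturbed and refitted;
the table reports how often the variable partition and the full merge tree
are recovered exactly, plus the mean matched-loading RMSE.
"""

from ultrafa import FitConfig, Scenario, run_scenarios, summarize_scenarios

grid = [
    Scenario(12, 3, "low", n_replicates=5),
    Scenario(12, 3, "medium", n_replicates=5),
    Scenario(12, 3, "high", n_replicates=5),
]
results = run_scenarios(grid, FitConfig(q=3, n_starts=10), master_seed=0)
summary = summarize_scenarios(results)

cols = ["scenario", "pct_perfect_partition", "pct_perfect_tree",
        "mean_tree_ari", "mean_rmse", "mean_iterations"]
print(summary[cols].to_string(index=False, float_format=lambda x: f"{x:.2f}"))
# recovery degrades from near-perfect at the low error level (0.05) to poor
# at the high level (0.30), where noise masks the planted hierarchy.
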
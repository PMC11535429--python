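"""Permutation test for a binary promoter/flank feature.

A hit table with a planted 15-percentage-point difference between UHP and
type-0 genes is tested with label permutations; the Bonferroni step
excludes features whose observed statistic is indistinguishable from its
permutation mean.
"""

from psicoupling import (
    bonferroni_with_exclusion,
    permutation_enrichment,
    simulate_feature_table,
)

hits, class_of = simulate_feature_table(
    n_items=1000, planted_delta=[0.15, 0.0], base_rate=0.25,
    n_features=2, seed=5,
)
res = permutation_enrichment(hits, class_of, n_permutations=20_000, seed=6)
adj = bonferroni_with_exclusion(res)
cols = ["feature", "prop_A", "prop_B", "delta", "p_empirical", "excluded",
        "p_bonferroni"]
print(adj[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
# f0 carries the planted effect: its hit proportion is ~15 points higher
# in UHP genes and the empirical p is 0 (no permutation reached the
# observed difference).  f1 is null: its small observed difference is pure
# sampling noise and its p stays far from significance.  A feature whose
# observed statistic sits within 0.5 points (or 5%) of its permutation
# mean would be excluded from the Bonferroni denominator entirely.
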
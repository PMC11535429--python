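"""Permutation-based enrichment of binary features between exon classes.

The statistic for a feature is the difference in hit proportion between
two classes in percentage points,

    delta = 100 * (prop_A - prop_B).

Class labels are shuffled without replacement (class sizes preserved) and
the one-sided empirical p-value is the fraction of permutations whose
statistic strictly exceeds the observed one; one shared set of shuffles
serves all features.  Bonferroni correction is applied after excluding
features whose observed statistic sits too close to its permutation mean
(an effect-size screen), with the multiplier equal to the number of tests
that survive the screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["permutation_enrichment", "bonferroni_with_exclusion"]


def permutation_enrichment(
    hits: pd.DataFrame,
    class_of: pd.Series,
    class_pair: tuple[str, str] = ("UHP", "TYPE0"),
    n_permutations: int = 1_000_000,
    seed: int = 0,
    chunk_size: int = 20_000,
) -> pd.DataFrame:
    """Empirical enrichment p-values for every feature column.

    ``hits`` is an item x feature 0/1 table; ``class_of`` assigns a class
    to every item.  Only items of the two classes in ``class_pair``
    participate.  Returns one row per feature with the observed
    proportions, delta (percentage points), the permutation mean of the
    statistic, and the empirical p-value.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    cls_a, cls_b = class_pair
    # canonical item order: results do not depend on input row order
    hits = hits.sort_index(kind="stable")
    class_of = class_of.reindex(hits.index)
    mask = class_of.isin(class_pair).to_numpy()
    h = hits.to_numpy(dtype=float)[mask]
    labels = class_of.to_numpy()[mask]
    n_a = int((labels == cls_a).sum())
    n_b = int((labels == cls_b).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError(f"both classes of {class_pair} must be non-empty")

    is_a = labels == cls_a
    total = h.sum(axis=0)
    sum_a = h[is_a].sum(axis=0)
    prop_a = sum_a / n_a
    prop_b = (total - sum_a) / n_b
    delta = 100.0 * (prop_a - prop_b)

    rng = np.random.default_rng(seed)
    n_items = n_a + n_b
    exceed = np.zeros(h.shape[1], dtype=np.int64)
    delta_sum = np.zeros(h.shape[1])
    done = 0
    while done < n_permutations:
        m = min(chunk_size, n_permutations - done)
        u = rng.random((m, n_items))
        # rank < n_a marks the items assigned to class A in this shuffle
        assign_a = np.argsort(np.argsort(u, axis=1), axis=1) < n_a
        perm_sum_a = assign_a @ h
        perm_delta = 100.0 * (
            perm_sum_a / n_a - (total[None, :] - perm_sum_a) / n_b
        )
        exceed += (perm_delta > delta[None, :]).sum(axis=0)
        delta_sum += perm_delta.sum(axis=0)
        done += m

    return pd.DataFrame(
        {
            "feature": hits.columns,
            "class_A": cls_a,
            "class_B": cls_b,
            "prop_A": 100.0 * prop_a,
            "prop_B": 100.0 * prop_b,
            "delta": delta,
            "delta_null_mean": delta_sum / n_permutations,
            "p_empirical": exceed / n_permutations,
            "n_permutations": n_permutations,
        }
    )


def bonferroni_with_exclusion(
    results: pd.DataFrame,
    abs_floor: float = 0.5,
    rel_floor: float = 0.05,
) -> pd.DataFrame:
    """Bonferroni correction after an effect-size exclusion screen.

    A test is excluded when the distance between its observed statistic
    and the permutation mean is below ``abs_floor`` percentage points, or
    below ``rel_floor`` of the observed statistic's magnitude (tests with
    a zero statistic are excluded outright).  Remaining p-values are
    multiplied by the number of surviving tests, capped at 1.
    """
    out = results.copy()
    gap = (out["delta_null_mean"] - out["delta"]).abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = gap / out["delta"].abs()
    excluded = (gap < abs_floor) | (rel < rel_floor) | (out["delta"] == 0)
    m = int((~excluded).sum())
    out["excluded"] = excluded
    out["n_tests_after_exclusion"] = m
    out["p_bonferroni"] = np.where(
        excluded, np.nan, np.minimum(1.0, out["p_empirical"] * m)
    )
    return out
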
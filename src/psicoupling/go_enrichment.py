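"""Hypergeometric overrepresentation of isoform-level GO annotations.

Given an isoform -> GO-term map, a universe of isoforms (those for which
any cassette event was detected) and a target set (e.g. isoforms that
include a UHP exon in at least one tissue), each term is tested with the
upper-tail hypergeometric probability

    p = P(X >= k),  X ~ Hypergeom(N, K, n),

where N is the universe size, K the universe isoforms annotated to the
term, n the target size and k the annotated target isoforms.  Terms with
fewer than ``min_annotated`` target isoforms are not tested, and
Bonferroni correction runs over the tested terms only.  Passing gene sets
instead of isoform sets turns the same operation into a plain gene-set
overlap test.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Set

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["go_overrepresentation", "read_go_map", "uhp_isoforms"]


def go_overrepresentation(
    annotations: Mapping[str, Set[str]],
    universe: Set[str],
    target: Set[str],
    min_annotated: int = 5,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test per GO term.

    ``annotations`` maps isoform id -> set of term ids; isoforms outside
    ``universe`` are ignored.  ``target`` must be a subset of the
    universe.  Coverage is k/K, the proportion of a term's annotated
    isoforms that are in the target set.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set(target) <= set(universe):
        raise ValueError("target isoforms must be a subset of the universe")

    by_term: dict[str, set[str]] = {}
    for iso, terms in annotations.items():
        if iso not in universe:
            continue
        for term in terms:
            by_term.setdefault(term, set()).add(iso)

    n_universe = len(universe)
    n_target = len(target)
    rows = []
    for term in sorted(by_term):
        annotated = by_term[term]
        big_k = len(annotated)
        k = len(annotated & target)
        if k < min_annotated:
            continue
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_target))
        rows.append(
            {
                "term": term,
                "coverage": k / big_k,
                "k": k,
                "K": big_k,
                "n": n_target,
                "N": n_universe,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "coverage", "k", "K", "n", "N", "p"]
    )
    if not out.empty:
        out["p_adj"] = np.minimum(1.0, out["p"] * len(out))
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (isoform, term), one pair per line; '#' comments."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            iso, term = line.split("\t")[:2]
            mapping.setdefault(iso, set()).add(term)
    return mapping


def uhp_isoforms(events, classifications: pd.DataFrame, label: str = "UHP") -> set[str]:
    """Isoforms in the including set of >= 1 event carrying ``label`` in
    >= 1 tissue."""
    tagged = set(
        classifications.loc[classifications["label"] == label, "event_id"]
    )
    out: set[str] = set()
    for ev in events:
        if ev.event_id in tagged:
            out |= set(ev.including_transcripts)
    return out
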
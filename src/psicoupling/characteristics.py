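"""Descriptive comparison of type-0, UHP and DHP exon classes.

For each feature (exons per gene, transcripts per gene, inclusion
proportion, flanking-intron lengths, exon length) the per-class values are
collected and the three class pairs are compared with a two-sided
Mann-Whitney U test.  Genes containing events of several classes
contribute to each of those classes.  Transcript-biotype composition is
reported as fractions over the including transcripts of each class.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_models import CassetteEvent, GeneModel

__all__ = ["compare_classes", "mann_whitney_two_sided", "biotype_fractions"]

CLASSES = ("TYPE0", "UHP", "DHP")
_PAIRS = (("TYPE0", "UHP"), ("TYPE0", "DHP"), ("UHP", "DHP"))


def mann_whitney_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact when min(n, m) <= 8: scipy's exact distribution for tie-free
    data, full enumeration of label assignments when ties are present and
    the pooled size permits it.  Otherwise the normal approximation with
    tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    small = min(x.size, y.size) <= 8
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if small and not has_ties:
        return float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
    if small and has_ties and pooled.size <= 12:
        return _exact_with_ties(x, y)
    return float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        ).pvalue
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    # midrank-based U of the first sample
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2)


def _exact_with_ties(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all C(n+m, n) label assignments."""
    n = x.size
    pooled = np.concatenate([x, y])
    u_obs = _u_statistic(x, y)
    us = []
    idx = np.arange(pooled.size)
    for comb in itertools.combinations(idx, n):
        sel = np.zeros(pooled.size, dtype=bool)
        sel[list(comb)] = True
        us.append(_u_statistic(pooled[sel], pooled[~sel]))
    us = np.asarray(us)
    eps = 1e-9
    p_ge = float((us >= u_obs - eps).mean())
    p_le = float((us <= u_obs + eps).mean())
    return min(1.0, 2.0 * min(p_ge, p_le))


def _event_class(classifications: pd.DataFrame) -> pd.Series:
    def consensus(labels: pd.Series) -> str:
        for lab in ("UHP", "DHP", "TYPE0"):
            if (labels == lab).any():
                return lab
        return "UNCLASSIFIED"

    return classifications.groupby("event_id")["label"].agg(consensus)


def _interval_length(iv: tuple[int, int] | None) -> float:
    return np.nan if iv is None else iv[1] - iv[0] + 1


def compare_classes(
    events: Sequence[CassetteEvent],
    classifications: pd.DataFrame,
    gene_models: Iterable[GeneModel],
) -> pd.DataFrame:
    """Per-feature class medians and pairwise Mann-Whitney p-values.

    Returns one row per feature with columns ``median_TYPE0``,
    ``median_UHP``, ``median_DHP`` and ``p_TYPE0_vs_UHP`` etc.  Biotype
    fractions are available via :func:`biotype_fractions`.
    """
    label_of = _event_class(classifications)
    genes = {g.gene_id: g for g in gene_models}

    per_class_values: dict[str, dict[str, list[float]]] = {
        feat: {c: [] for c in CLASSES}
        for feat in (
            "exons_per_gene",
            "transcripts_per_gene",
            "inclusion_proportion",
            "upstream_intron_length",
            "downstream_intron_length",
            "exon_length",
        )
    }

    genes_of_class: dict[str, set[str]] = {c: set() for c in CLASSES}
    for ev in events:
        label = label_of.get(ev.event_id, "UNCLASSIFIED")
        if label not in CLASSES:
            continue
        vals = per_class_values
        n_inc = len(ev.including_transcripts)
        n_exc = len(ev.excluding_transcripts)
        vals["inclusion_proportion"][label].append(n_inc / (n_inc + n_exc))
        vals["exon_length"][label].append(ev.exon_length)
        up = _interval_length(ev.upstream_intron)
        down = _interval_length(ev.downstream_intron)
        if not np.isnan(up):
            vals["upstream_intron_length"][label].append(up)
        if not np.isnan(down):
            vals["downstream_intron_length"][label].append(down)
        genes_of_class[label].add(ev.gene_id)

    # genes that contain events of several classes are counted for each
    for label, gene_ids in genes_of_class.items():
        for gid in gene_ids:
            gene = genes[gid]
            n_exons = len({x for t in gene.transcripts for x in t.exons})
            per_class_values["exons_per_gene"][label].append(n_exons)
            per_class_values["transcripts_per_gene"][label].append(
                len(gene.transcripts)
            )

    rows = []
    for feat, by_class in per_class_values.items():
        row: dict[str, object] = {"feature": feat}
        for c in CLASSES:
            v = by_class[c]
            row[f"median_{c}"] = float(np.median(v)) if v else np.nan
            row[f"n_{c}"] = len(v)
        for a, b in _PAIRS:
            key = f"p_{a}_vs_{b}"
            if by_class[a] and by_class[b]:
                row[key] = mann_whitney_two_sided(by_class[a], by_class[b])
            else:
                warnings.warn(
                    f"empty class in comparison {a} vs {b} for {feat}",
                    stacklevel=2,
                )
                row[key] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def biotype_fractions(
    events: Sequence[CassetteEvent],
    classifications: pd.DataFrame,
    gene_models: Iterable[GeneModel],
) -> pd.DataFrame:
    """Fraction of each transcript biotype among including transcripts,
    per exon class; fractions sum to 1 within a class."""
    label_of = _event_class(classifications)
    biotype_of = {
        t.transcript_id: t.biotype
        for g in gene_models
        for t in g.transcripts
    }
    counts: dict[str, dict[str, int]] = {c: {} for c in CLASSES}
    for ev in events:
        label = label_of.get(ev.event_id, "UNCLASSIFIED")
        if label not in CLASSES:
            continue
        for tid in ev.including_transcripts:
            bt = biotype_of[tid]
            counts[label][bt] = counts[label].get(bt, 0) + 1
    rows = []
    for c in CLASSES:
        total = sum(counts[c].values())
        for bt, n in sorted(counts[c].items()):
            rows.append(
                {
                    "class": c,
                    "biotype": bt,
                    "count": n,
                    "fraction": n / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["class", "biotype", "count", "fraction"])
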
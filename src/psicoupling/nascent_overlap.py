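"""Overlap of nascent-RNA reads (or ChIP peaks) with class-labelled introns.

Intervals are BED-style 0-based half-open.  A read counts for an intron
when they overlap by at least one base pair, and each (read, intron) pair
counts once — the semantics of a default ``bedtools intersect``.  Per-class
totals are normalised by intron base pairs, the class x read-count
contingency is tested against an expectation proportional to intron
length, and a label-permutation null (class labels shuffled across
introns) bounds the largest rate difference expected by chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "count_overlaps",
    "label_permutation_null",
    "OverlapSummary",
    "PermutationNull",
    "read_bed",
]

Interval = tuple[str, int, int]
LabelledInterval = tuple[str, int, int, str]


def _per_intron_counts(
    introns: Sequence[LabelledInterval], reads: Sequence[Interval]
) -> np.ndarray:
    """Number of overlapping reads for each intron (sorted sweep)."""
    counts = np.zeros(len(introns), dtype=np.int64)
    reads_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in reads:
        if start < 0 or start >= end:
            raise ValueError(f"bad read interval ({chrom}, {start}, {end})")
        reads_by_chrom.setdefault(chrom, []).append((start, end))

    sorted_reads: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    for chrom, ivs in reads_by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e in ivs], dtype=np.int64)
        max_len = int((ends - starts).max())
        sorted_reads[chrom] = (starts, ends, max_len)

    for i, (chrom, istart, iend, _label) in enumerate(introns):
        # zero-length introns are tolerated; they can overlap nothing
        if istart < 0 or istart > iend:
            raise ValueError(f"bad intron interval ({chrom}, {istart}, {iend})")
        if chrom not in sorted_reads:
            continue
        starts, ends, max_len = sorted_reads[chrom]
        # candidate reads: start in [istart - max_len + 1, iend)
        lo = np.searchsorted(starts, istart - max_len + 1, side="left")
        hi = np.searchsorted(starts, iend, side="left")
        if hi > lo:
            counts[i] = int((ends[lo:hi] > istart).sum())
    return counts


@dataclass
class OverlapSummary:
    per_class: pd.DataFrame      # class, n_introns, total_bp, reads, per_bp_rate
    per_intron: pd.DataFrame     # chrom, start, end, class, reads
    chi2_p: float


def count_overlaps(
    introns: Sequence[LabelledInterval], reads: Sequence[Interval]
) -> OverlapSummary:
    """Per-class overlapping-read totals, per-bp rates and a chi-squared
    test of the read counts against intron-length-proportional expectation.

    Classes whose introns carry zero base pairs are skipped with a
    warning; results do not depend on input ordering.
    """
    import warnings

    counts = _per_intron_counts(introns, reads)
    labels = np.array([iv[3] for iv in introns])
    lengths = np.array([iv[2] - iv[1] for iv in introns], dtype=np.int64)

    rows = []
    for cls in sorted(set(labels)):
        sel = labels == cls
        bp = int(lengths[sel].sum())
        if bp == 0:
            warnings.warn(f"class {cls!r} has zero intron bp; skipped", stacklevel=2)
            continue
        n_reads = int(counts[sel].sum())
        rows.append(
            {
                "class": cls,
                "n_introns": int(sel.sum()),
                "total_bp": bp,
                "reads": n_reads,
                "per_bp_rate": n_reads / bp,
            }
        )
    per_class = pd.DataFrame(
        rows, columns=["class", "n_introns", "total_bp", "reads", "per_bp_rate"]
    )

    chi2_p = float("nan")
    if len(per_class) >= 2 and per_class["reads"].sum() > 0:
        obs = per_class["reads"].to_numpy(dtype=float)
        expected = (
            per_class["total_bp"].to_numpy(dtype=float)
            / per_class["total_bp"].sum()
            * obs.sum()
        )
        chi2_p = float(stats.chisquare(obs, f_exp=expected).pvalue)

    per_intron = pd.DataFrame(
        [
            {"chrom": c, "start": s, "end": e, "class": lab, "reads": int(n)}
            for (c, s, e, lab), n in zip(introns, counts)
        ],
        columns=["chrom", "start", "end", "class", "reads"],
    )
    return OverlapSummary(per_class=per_class, per_intron=per_intron, chi2_p=chi2_p)


@dataclass
class PermutationNull:
    observed_max_delta: float
    null_max_deltas: np.ndarray
    n_exceeding: int
    p_empirical: float


def label_permutation_null(
    introns: Sequence[LabelledInterval],
    reads: Sequence[Interval],
    n_permutations: int = 1000,
    seed: int = 0,
    ref_class: str = "TYPE0",
) -> PermutationNull:
    """Null distribution of the largest per-bp rate difference.

    Class labels are shuffled across introns (sizes preserved); each
    permutation records max_c |rate(ref) - rate(c)| over the other
    classes.  The empirical p is the fraction of permutations reaching
    the observed statistic.
    """
    labels = np.array([iv[3] for iv in introns])
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 intron classes")
    if ref_class not in classes:
        raise ValueError(f"reference class {ref_class!r} not present")
    counts = _per_intron_counts(introns, reads).astype(float)
    lengths = np.array([iv[2] - iv[1] for iv in introns], dtype=float)
    code_of = {c: i for i, c in enumerate(classes)}
    codes = np.array([code_of[lab] for lab in labels])
    ref = code_of[ref_class]

    def max_delta(perm_codes: np.ndarray) -> float:
        reads_per = np.bincount(perm_codes, weights=counts, minlength=len(classes))
        bp_per = np.bincount(perm_codes, weights=lengths, minlength=len(classes))
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = reads_per / bp_per
        others = [i for i in range(len(classes)) if i != ref]
        return float(np.nanmax(np.abs(rates[ref] - rates[others])))

    observed = max_delta(codes)
    rng = np.random.default_rng(seed)
    null = np.array(
        [max_delta(rng.permutation(codes)) for _ in range(n_permutations)]
    )
    n_exceed = int((null >= observed).sum())
    return PermutationNull(
        observed_max_delta=observed,
        null_max_deltas=null,
        n_exceeding=n_exceed,
        p_empirical=n_exceed / n_permutations,
    )


def read_bed(path) -> list[tuple]:
    """BED3 or BED4+ records; column 4 (when present) is kept as label."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if len(parts) >= 4:
                records.append((chrom, start, end, parts[3]))
            else:
                records.append((chrom, start, end))
    return records
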
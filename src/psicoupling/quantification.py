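"""Per-sample percent-spliced-in and expression-variability filters.

psi of a cassette event in a sample is the fraction of the gene's signal
carried by transcripts that include the event's exons,

    psi = inc / (inc + exc),

where inc and exc are the summed abundances of the including and excluding
transcript sets.  Total gene expression Y is the sum over *all* transcripts
of the gene.  When inc + exc = 0 the sample carries no splicing
information and psi is missing.

Events enter the coupling analysis only if, within a tissue, they are
expressed in at least half the samples (inclusion signal >= 1), show a mean
inclusion signal of at least 20, and the gene's expression spans at least a
two-fold ratio between its 95th and 5th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gene_models import CassetteEvent

__all__ = [
    "PsiExpressionTable",
    "compute_psi",
    "apply_variability_filters",
    "read_abundance",
    "read_metadata",
]


@dataclass
class PsiExpressionTable:
    """Per-event psi and per-gene expression, events/genes x samples."""

    psi: pd.DataFrame
    inc: pd.DataFrame
    exc: pd.DataFrame
    gene_expression: pd.DataFrame
    event_gene: pd.Series  # event_id -> gene_id

    @property
    def samples(self) -> pd.Index:
        return self.psi.columns

    def gene_expression_for_events(self) -> pd.DataFrame:
        """Gene expression rows aligned to the event index."""
        y = self.gene_expression.loc[self.event_gene.to_numpy()]
        y.index = self.psi.index
        return y


def compute_psi(
    events: Sequence[CassetteEvent],
    matrix: pd.DataFrame,
    gene_of_transcript: pd.Series | None = None,
) -> PsiExpressionTable:
    """psi per (event, sample) and total expression Y per (gene, sample).

    ``matrix`` is transcripts x samples.  Gene totals are computed from
    ``gene_of_transcript`` when given (transcript_id -> gene_id for every
    matrix row); otherwise from the transcripts referenced by the events.
    Missing transcripts raise a ``KeyError`` listing the offending ids.
    """
    missing = sorted(
        {
            t
            for ev in events
            for t in ev.including_transcripts | ev.excluding_transcripts
            if t not in matrix.index
        }
    )
    if missing:
        raise KeyError(f"transcripts absent from abundance matrix: {missing}")

    values = matrix.to_numpy(dtype=float)
    row_of = {t: i for i, t in enumerate(matrix.index)}
    n_events, n_samples = len(events), matrix.shape[1]
    inc = np.zeros((n_events, n_samples))
    exc = np.zeros((n_events, n_samples))
    for i, ev in enumerate(events):
        inc[i] = values[[row_of[t] for t in sorted(ev.including_transcripts)]].sum(
            axis=0
        )
        exc[i] = values[[row_of[t] for t in sorted(ev.excluding_transcripts)]].sum(
            axis=0
        )
    denom = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(denom > 0, inc / np.where(denom > 0, denom, 1.0), np.nan)

    event_ids = [ev.event_id for ev in events]
    event_gene = pd.Series(
        {ev.event_id: ev.gene_id for ev in events}, name="gene_id"
    ).loc[event_ids]

    if gene_of_transcript is None:
        pairs = {
            t: ev.gene_id
            for ev in events
            for t in ev.including_transcripts | ev.excluding_transcripts
        }
        gene_of_transcript = pd.Series(pairs)
    grouped = matrix.groupby(
        gene_of_transcript.reindex(matrix.index)
    ).sum()
    grouped = grouped.loc[sorted(set(event_gene))]

    cols = matrix.columns
    return PsiExpressionTable(
        psi=pd.DataFrame(psi, index=event_ids, columns=cols),
        inc=pd.DataFrame(inc, index=event_ids, columns=cols),
        exc=pd.DataFrame(exc, index=event_ids, columns=cols),
        gene_expression=grouped,
        event_gene=event_gene,
    )


def percentile_ratio_95_5(values: np.ndarray) -> float:
    """95th over 5th percentile (linear-interpolation percentiles).

    A zero 5th percentile with a positive 95th yields +inf; an all-zero
    vector yields nan (no expression at all, treated as failing).
    """
    p5, p95 = np.percentile(values, [5.0, 95.0])
    if p5 > 0:
        return float(p95 / p5)
    if p95 > 0:
        return float("inf")
    return float("nan")


def apply_variability_filters(
    table: PsiExpressionTable,
    metadata: pd.DataFrame,
    min_mean: float = 20.0,
    min_ratio: float = 2.0,
    min_expressed_fraction: float = 0.5,
    expressed_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-(event, tissue) expression filters; long-format report.

    Columns: event_id, tissue, expressed_fraction, mean_level, ratio_95_5,
    passed.  ``expressed_fraction`` and ``mean_level`` are computed on the
    event's inclusion signal; the 95/5 percentile ratio on the gene's
    total expression within the tissue.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata else metadata
    tissues = meta.loc[table.samples, "tissue"]
    rows = []
    y_events = table.gene_expression_for_events()
    for tissue, cols in tissues.groupby(tissues).groups.items():
        cols = list(cols)
        if len(cols) == 0:
            raise ValueError(f"tissue {tissue!r} has no samples")
        inc = table.inc[cols].to_numpy()
        y = y_events[cols].to_numpy()
        expressed = (inc >= expressed_threshold).mean(axis=1)
        mean_level = inc.mean(axis=1)
        ratio = np.array([percentile_ratio_95_5(row) for row in y])
        with np.errstate(invalid="ignore"):
            passed = (
                (expressed >= min_expressed_fraction)
                & (mean_level >= min_mean)
                & (ratio >= min_ratio)
            )
        for i, event_id in enumerate(table.psi.index):
            rows.append(
                {
                    "event_id": event_id,
                    "tissue": tissue,
                    "expressed_fraction": expressed[i],
                    "mean_level": mean_level[i],
                    "ratio_95_5": ratio[i],
                    "passed": bool(passed[i]),
                }
            )
    return pd.DataFrame(rows)


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a transcripts x samples matrix from TSV or GCT 1.2.

    A GCT file is recognised by its ``#1.2`` first line; its Description
    column is dropped.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must carry columns {sorted(required)}")
    return meta
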
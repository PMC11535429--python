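"""Synthetic datasets with planted expression-splicing coupling.

Every gene carries exactly one cassette event.  For each sample the event's
inclusion fraction psi is drawn from a Beta distribution and total gene
expression follows the linear coupling model

    Y = b0 + s * b1 * psi + eps,   s = +1 (UHP), -1 (DHP), 0 (type 0),

with eps Gaussian and Y kept positive by truncation.  The expression is
then allocated to the gene's transcripts so that recomputing psi from the
transcript abundances returns the drawn value exactly: including
transcripts share Y*psi equally, excluding transcripts share Y*(1-psi).

For DHP events the intercept is raised by b1 (the gene downregulates from
a higher baseline), so expression stays positive over the whole psi range
instead of being censored at psi near 1.

The default scenario is the one used throughout the test-bench: 100 UHP,
100 DHP and 300 type-0 events observed in 3 tissues of 300 samples each,
with a coupling-to-noise ratio b1/noise_sd of 5 and a bimodal Beta(1/2,1/2)
psi distribution (cassette exons in real tissues are predominantly near
fully included or fully skipped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_models import CassetteEvent, GeneModel, TranscriptModel, find_cassette_events

__all__ = [
    "SimScenario",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_feature_table",
    "simulate_interval_reads",
    "write_gtf",
    "write_gct",
    "write_bed",
]

LABELS = ("UHP", "DHP", "TYPE0")
_SIGN = {"UHP": 1.0, "DHP": -1.0, "TYPE0": 0.0}


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for one simulated dataset."""

    n_uhp: int = 100
    n_dhp: int = 100
    n_type0: int = 300
    transcripts_per_gene: tuple[int, int] = (2, 4)
    tissues: tuple[str, ...] = ("spleen", "thyroid", "liver")
    n_samples_per_tissue: int = 300
    n_donors: int = 30
    beta0: float = 60.0
    beta1_magnitude: float = 100.0
    noise_sd: float = 20.0
    psi_beta: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta1_magnitude <= 0:
            raise ValueError("beta1_magnitude must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        a, b = self.psi_beta
        if a <= 0 or b <= 0:
            raise ValueError("psi_beta parameters must be > 0")
        lo, hi = self.transcripts_per_gene
        if lo < 2 or hi < lo:
            raise ValueError("transcripts_per_gene must be a range with min >= 2")

    @property
    def n_genes(self) -> int:
        return self.n_uhp + self.n_dhp + self.n_type0

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_tissue * len(self.tissues)

    def planted_labels(self) -> list[str]:
        return (
            ["UHP"] * self.n_uhp + ["DHP"] * self.n_dhp + ["TYPE0"] * self.n_type0
        )


@dataclass
class SimulatedDataset:
    genes: list[GeneModel]
    events: list[CassetteEvent]
    abundance: pd.DataFrame          # transcripts x samples
    metadata: pd.DataFrame           # sample_id, tissue, donor
    truth: pd.DataFrame              # event_id, gene_id, label, beta0, beta1
    psi_true: pd.DataFrame           # events x samples, the drawn psi


_BIOTYPES = (
    "protein_coding",
    "protein_coding",
    "protein_coding",
    "retained_intron",
    "nonsense_mediated_decay",
    "lncRNA",
)


def _build_gene(
    idx: int, label: str, n_tx: int, rng: np.random.Generator
) -> GeneModel:
    """One gene with a single cassette exon shared by its including set."""
    base = 1_000_000 * (idx + 1)
    len_a = int(rng.integers(80, 300))
    len_b = int(rng.integers(60, 300))
    len_c = int(rng.integers(80, 300))
    intron_up = int(rng.integers(200, 2000))
    intron_down = int(rng.integers(200, 2000))
    a = (base, base + len_a - 1)
    b = (a[1] + intron_up + 1, a[1] + intron_up + len_b)
    c = (b[1] + intron_down + 1, b[1] + intron_down + len_c)
    strand = "+" if rng.random() < 0.5 else "-"
    n_inc = max(1, n_tx // 2)
    gene_id = f"g{idx:04d}"
    transcripts = []
    for j in range(n_tx):
        exons = (a, b, c) if j < n_inc else (a, c)
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.t{j + 1}",
                biotype=_BIOTYPES[int(rng.integers(0, len(_BIOTYPES)))],
                exons=exons,
            )
        )
    return GeneModel(
        gene_id=gene_id, chrom="chrS", strand=strand, transcripts=tuple(transcripts)
    )


def _truncated_normal(
    mu: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Draws from Normal(mu, sd) conditioned on being > 0, elementwise."""
    if sd == 0:
        if np.any(mu < 0):
            warnings.warn(
                "noise-free expression would be negative; clamping at 0",
                stacklevel=3,
            )
        return np.maximum(mu, 0.0)
    u = rng.random(mu.shape)
    lo = stats.norm.cdf(0.0, loc=mu, scale=sd)
    return stats.norm.ppf(lo + u * (1.0 - lo), loc=mu, scale=sd)


def simulate_dataset(scn: SimScenario) -> SimulatedDataset:
    """Generate gene models, a transcript-abundance matrix, sample metadata
    and a planted-truth table, reproducibly from ``scn.seed``."""
    rng = np.random.default_rng(scn.seed)
    labels = scn.planted_labels()
    lo, hi = scn.transcripts_per_gene

    genes, events = [], []
    for i, label in enumerate(labels):
        n_tx = int(rng.integers(lo, hi + 1))
        gene = _build_gene(i, label, n_tx, rng)
        genes.append(gene)
        evs = find_cassette_events(gene)
        assert len(evs) == 1, "simulated gene must yield exactly one event"
        events.append(evs[0])

    n_samples = scn.n_samples
    sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    tissue = np.repeat(list(scn.tissues), scn.n_samples_per_tissue)
    donor = np.array(
        [f"d{i % scn.n_donors:03d}" for i in range(n_samples)]
    )
    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "tissue": tissue, "donor": donor}
    )

    a, b = scn.psi_beta
    psi = rng.beta(a, b, size=(len(genes), n_samples))

    truth_rows = []
    tx_rows: dict[str, np.ndarray] = {}
    for i, (gene, event, label) in enumerate(zip(genes, events, labels)):
        s = _SIGN[label]
        b0 = scn.beta0 + (scn.beta1_magnitude if label == "DHP" else 0.0)
        mu = b0 + s * scn.beta1_magnitude * psi[i]
        y = _truncated_normal(mu, scn.noise_sd, rng)
        inc_ids = sorted(event.including_transcripts)
        exc_ids = sorted(event.excluding_transcripts)
        inc_total = y * psi[i]
        exc_total = y * (1.0 - psi[i])
        for tid in inc_ids:
            tx_rows[tid] = inc_total / len(inc_ids)
        for tid in exc_ids:
            tx_rows[tid] = exc_total / len(exc_ids)
        truth_rows.append(
            {
                "event_id": event.event_id,
                "gene_id": gene.gene_id,
                "label": label,
                "beta0": b0,
                "beta1": s * scn.beta1_magnitude,
            }
        )

    abundance = pd.DataFrame.from_dict(
        tx_rows, orient="index", columns=sample_ids
    )
    truth = pd.DataFrame(truth_rows)
    psi_true = pd.DataFrame(
        psi, index=[e.event_id for e in events], columns=sample_ids
    )
    return SimulatedDataset(
        genes=genes,
        events=events,
        abundance=abundance,
        metadata=metadata,
        truth=truth,
        psi_true=psi_true,
    )


def simulate_feature_table(
    n_items: int,
    planted_delta: float | Sequence[float] = 0.0,
    base_rate: float = 0.3,
    n_features: int = 1,
    classes: tuple[str, str] = ("UHP", "TYPE0"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Binary feature-hit table with a planted hit-rate difference.

    ``n_items`` items per class; class ``classes[0]`` has hit rate
    ``base_rate + planted_delta`` (per feature), class ``classes[1]`` has
    ``base_rate``.  Returns (hits, class_of).
    """
    deltas = np.broadcast_to(
        np.asarray(planted_delta, dtype=float), (n_features,)
    )
    if base_rate < 0 or np.any(base_rate + deltas > 1) or np.any(
        base_rate + deltas < 0
    ):
        raise ValueError("hit rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if n_items == 0:
        hits = pd.DataFrame(
            np.empty((0, n_features), dtype=int),
            columns=[f"f{j}" for j in range(n_features)],
        )
        return hits, pd.Series([], dtype=object, name="class")
    rate_a = base_rate + deltas
    hits_a = rng.random((n_items, n_features)) < rate_a
    hits_b = rng.random((n_items, n_features)) < base_rate
    hits = pd.DataFrame(
        np.vstack([hits_a, hits_b]).astype(int),
        index=[f"item{i:05d}" for i in range(2 * n_items)],
        columns=[f"f{j}" for j in range(n_features)],
    )
    class_of = pd.Series(
        [classes[0]] * n_items + [classes[1]] * n_items,
        index=hits.index,
        name="class",
    )
    return hits, class_of


def simulate_interval_reads(
    introns_by_type: Mapping[str, Sequence[tuple[str, int, int]]],
    density_per_bp_by_type: Mapping[str, float],
    seed: int = 0,
) -> list[tuple[str, int, int]]:
    """Unit-length reads placed uniformly in introns, Poisson counts.

    Introns are BED-style 0-based half-open.  The read count of each
    intron is Poisson(density * length) with the density of its type.
    """
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, int, int]] = []
    for itype in sorted(introns_by_type):
        density = density_per_bp_by_type[itype]
        if density < 0:
            raise ValueError(f"negative density for type {itype!r}")
        for chrom, start, end in introns_by_type[itype]:
            length = end - start
            count = int(rng.poisson(density * length))
            if count == 0:
                continue
            positions = rng.integers(start, end, size=count)
            reads.extend((chrom, int(p), int(p) + 1) for p in positions)
    return reads


# ---------------------------------------------------------------------------
# plain-text writers


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for s, e in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}"; '
                        f'transcript_biotype "{tx.biotype}";'
                    )
                    fh.write(
                        f"{gene.chrom}\tsim\texon\t{s}\t{e}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )


def write_gct(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a transcripts x samples matrix in GCT 1.2 layout."""
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.columns) + "\n")
        for tid, row in matrix.iterrows():
            vals = "\t".join(format(v, ".10g") for v in row.to_numpy())
            fh.write(f"{tid}\tna\t{vals}\n")


def write_bed(
    records: Sequence[tuple], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")
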
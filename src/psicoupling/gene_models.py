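"""Gene models and cassette-exon event derivation.

Transcript structures are read from GTF (1-based, inclusive coordinates).
A *cassette event* groups the exons of a gene whose inclusion pattern over
the gene's transcripts is identical: if several exons are perfectly
correlated with respect to transcript structure they are collapsed into a
single event, so the downstream statistics are computed only once per
distinguishable splicing choice.  Exons that overlap an exon of a
transcript that "excludes" them (alternative 5'/3' boundary variants,
retained-intron fragments) are not cassette exons and are never emitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "CassetteEvent",
    "parse_gtf",
    "find_cassette_events",
    "flanking_introns",
    "events_to_frame",
    "introns_to_bed",
    "GtfParseError",
]


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message carries the line number."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: ordered exons plus a biotype label.

    Exons are (start, end) 1-based inclusive intervals sorted by genomic
    start and non-overlapping within the transcript.
    """

    transcript_id: str
    biotype: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.exons) < 1:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for s, e in self.exons:
            if s > e:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon start {s} > end {e}"
                )
        srt = tuple(sorted(self.exons))
        if srt != self.exons:
            object.__setattr__(self, "exons", srt)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def transcript_ids(self) -> tuple[str, ...]:
        return tuple(t.transcript_id for t in self.transcripts)


@dataclass(frozen=True)
class CassetteEvent:
    """A collapsed set of perfectly correlated alternatively included exons.

    ``including_transcripts`` and ``excluding_transcripts`` partition the
    gene's transcripts.  Flanking introns are in transcriptional (strand
    aware) orientation; on the minus strand the upstream intron lies at
    higher genomic coordinates than the exon.
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    exon_keys: tuple[tuple[int, int], ...]
    including_transcripts: frozenset[str]
    excluding_transcripts: frozenset[str]
    upstream_intron: tuple[int, int] | None = None
    downstream_intron: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.including_transcripts & self.excluding_transcripts:
            raise ValueError(f"event {self.event_id}: transcript sets overlap")
        if not self.including_transcripts or not self.excluding_transcripts:
            raise ValueError(f"event {self.event_id}: empty transcript set")

    @property
    def representative_exon(self) -> tuple[int, int]:
        """First exon of the collapsed set in transcriptional order."""
        exons = sorted(self.exon_keys)
        return exons[0] if self.strand == "+" else exons[-1]

    @property
    def exon_length(self) -> int:
        s, e = self.representative_exon
        return e - s + 1


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gtf(
    path: str | Path, gene_whitelist: set[str] | None = None
) -> list[GeneModel]:
    """Parse exon features of a GTF file into :class:`GeneModel` objects.

    Accepts the GENCODE/Ensembl dialect; the biotype is read from
    ``transcript_biotype`` or ``transcript_type`` (missing -> ``"unknown"``).
    Duplicate exon rows for a transcript are deduplicated.  A malformed
    line raises :class:`GtfParseError` naming the line number.
    """
    # gene -> transcript -> exon set; insertion order preserved
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfParseError(
                    f"line {lineno}: non-integer coordinates {start!r}/{end!r}"
                ) from exc
            if strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
            attr = _parse_attributes(attrs)
            gene_id = attr.get("gene_id")
            if gene_id is None:
                raise GtfParseError(f"line {lineno}: exon without gene_id")
            tx_id = attr.get("transcript_id")
            if tx_id is None:
                raise GtfParseError(f"line {lineno}: exon without transcript_id")
            if gene_whitelist is not None and gene_id not in gene_whitelist:
                continue
            biotype = attr.get("transcript_biotype") or attr.get(
                "transcript_type", "unknown"
            )
            g = genes.setdefault(
                gene_id, {"chrom": chrom, "strand": strand, "tx": {}}
            )
            tx = g["tx"].setdefault(tx_id, {"biotype": biotype, "exons": set()})
            tx["exons"].add((start_i, end_i))

    models = []
    for gene_id, g in genes.items():
        transcripts = tuple(
            TranscriptModel(
                transcript_id=tx_id,
                biotype=tx["biotype"],
                exons=tuple(sorted(tx["exons"])),
            )
            for tx_id, tx in g["tx"].items()
        )
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=g["chrom"],
                strand=g["strand"],
                transcripts=transcripts,
            )
        )
    return models


def _is_cassette(
    exon: tuple[int, int], excluding: Iterable[TranscriptModel]
) -> bool:
    """True when no excluding transcript has an exon overlapping ``exon``.

    An overlap means the exon is an alternative-boundary variant of an exon
    present in the other transcripts, not a skipped cassette.
    """
    s, e = exon
    for tx in excluding:
        for ts, te in tx.exons:
            if ts <= e and s <= te:
                return False
    return True


def find_cassette_events(gene: GeneModel) -> list[CassetteEvent]:
    """Derive collapsed cassette events from a gene's transcript structures.

    Exons are grouped by their inclusion pattern (the exact set of
    transcripts containing them); each maximal group with a non-trivial
    pattern becomes one event, provided every exon of the group passes the
    cassette test against the excluding transcripts.  Output order and
    event ids are deterministic (sorted by the group's first exon).
    """
    if len(gene.transcripts) < 2:
        return []
    tx_by_id = {t.transcript_id: t for t in gene.transcripts}
    all_ids = frozenset(tx_by_id)

    pattern: dict[tuple[int, int], frozenset[str]] = {}
    for tx in gene.transcripts:
        for exon in tx.exons:
            pattern.setdefault(exon, frozenset())
    for tx in gene.transcripts:
        for exon in tx.exons:
            pattern[exon] = pattern[exon] | {tx.transcript_id}

    groups: dict[frozenset[str], list[tuple[int, int]]] = {}
    for exon, incl in pattern.items():
        if incl == all_ids:
            continue
        groups.setdefault(incl, []).append(exon)

    events = []
    for incl, exons in groups.items():
        excl = all_ids - incl
        excluding_models = [tx_by_id[i] for i in sorted(excl)]
        kept = [x for x in sorted(exons) if _is_cassette(x, excluding_models)]
        if not kept:
            continue
        events.append((tuple(kept), incl, excl))

    events.sort(key=lambda t: t[0][0])
    out = []
    for i, (exons, incl, excl) in enumerate(events, start=1):
        ev = CassetteEvent(
            event_id=f"{gene.gene_id}:EV{i:03d}",
            gene_id=gene.gene_id,
            chrom=gene.chrom,
            strand=gene.strand,
            exon_keys=exons,
            including_transcripts=frozenset(incl),
            excluding_transcripts=frozenset(excl),
        )
        up, down = flanking_introns(ev, gene)
        out.append(
            CassetteEvent(
                event_id=ev.event_id,
                gene_id=ev.gene_id,
                chrom=ev.chrom,
                strand=ev.strand,
                exon_keys=ev.exon_keys,
                including_transcripts=ev.including_transcripts,
                excluding_transcripts=ev.excluding_transcripts,
                upstream_intron=up,
                downstream_intron=down,
            )
        )
    return out


def _modal_interval(
    intervals: Sequence[tuple[int, int]]
) -> tuple[int, int] | None:
    """Most frequent interval; ties broken by length, then coordinates."""
    if not intervals:
        return None
    counts: dict[tuple[int, int], int] = {}
    for iv in intervals:
        counts[iv] = counts.get(iv, 0) + 1
    return max(counts, key=lambda iv: (counts[iv], iv[1] - iv[0], iv))


def flanking_introns(
    event: CassetteEvent, gene: GeneModel
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """Flanking introns of the event's representative exon, strand aware.

    The intron on each side is computed per including transcript as the gap
    to the adjacent exon; when transcripts disagree the modal intron is
    taken (ties -> the longest).  A transcript-terminal exon contributes no
    intron on its missing side.
    """
    rep = event.representative_exon
    tx_by_id = {t.transcript_id: t for t in gene.transcripts}
    left: list[tuple[int, int]] = []   # genomically left of the exon
    right: list[tuple[int, int]] = []
    for tx_id in event.including_transcripts:
        tx = tx_by_id[tx_id]
        if rep not in tx.exons:
            continue
        idx = tx.exons.index(rep)
        if idx > 0:
            prev = tx.exons[idx - 1]
            left.append((prev[1] + 1, rep[0] - 1))
        if idx < len(tx.exons) - 1:
            nxt = tx.exons[idx + 1]
            right.append((rep[1] + 1, nxt[0] - 1))
    lmode, rmode = _modal_interval(left), _modal_interval(right)
    if gene.strand == "+":
        return lmode, rmode
    return rmode, lmode


def events_to_frame(events: Iterable[CassetteEvent]):
    """Events as a tidy table (one row per event)."""
    import pandas as pd

    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.event_id,
                "gene_id": ev.gene_id,
                "chrom": ev.chrom,
                "strand": ev.strand,
                "exons": ";".join(f"{s}-{e}" for s, e in ev.exon_keys),
                "exon_length": ev.exon_length,
                "including_transcripts": ",".join(
                    sorted(ev.including_transcripts)
                ),
                "excluding_transcripts": ",".join(
                    sorted(ev.excluding_transcripts)
                ),
                "upstream_intron": _fmt_interval(ev.upstream_intron),
                "downstream_intron": _fmt_interval(ev.downstream_intron),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "gene_id",
            "chrom",
            "strand",
            "exons",
            "exon_length",
            "including_transcripts",
            "excluding_transcripts",
            "upstream_intron",
            "downstream_intron",
        ],
    )


def _fmt_interval(iv: tuple[int, int] | None) -> str:
    return "" if iv is None else f"{iv[0]}-{iv[1]}"


def introns_to_bed(
    events: Iterable[CassetteEvent], side: str = "downstream"
) -> list[tuple[str, int, int, str]]:
    """Flanking introns as BED4 records (0-based half-open).

    ``side`` is ``"upstream"`` or ``"downstream"`` in transcriptional
    orientation; events without the requested intron are skipped.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError(f"side must be upstream/downstream, got {side!r}")
    records = []
    for ev in events:
        iv = ev.upstream_intron if side == "upstream" else ev.downstream_intron
        if iv is None:
            continue
        records.append((ev.chrom, iv[0] - 1, iv[1], ev.event_id))
    return records
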
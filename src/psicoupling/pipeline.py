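"""End-to-end orchestration: from GTF + abundance matrix to all reports.

Stages (events -> psi -> classify -> consistency -> characteristics ->
feature enrichment -> GO -> nascent overlap) compose the library modules;
optional inputs that are absent simply disable their stage.  Every output
is a TSV under the chosen directory and a manifest records the
configuration hash and per-stage row counts, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .characteristics import biotype_fractions, compare_classes
from .classification import (
    classify_events,
    cross_tissue_consistency,
    donor_level_reclassification,
)
from .feature_enrichment import bonferroni_with_exclusion, permutation_enrichment
from .gene_models import events_to_frame, find_cassette_events, introns_to_bed, parse_gtf
from .go_enrichment import go_overrepresentation, read_go_map, uhp_isoforms
from .nascent_overlap import count_overlaps, label_permutation_null, read_bed
from .quantification import (
    apply_variability_filters,
    compute_psi,
    read_abundance,
    read_metadata,
)

log = logging.getLogger("psicoupling")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    gtf: str
    matrix: str
    metadata: str
    out_dir: str = "psicoupling_out"
    hit_table: str | None = None
    class_map: str | None = None
    go_map: str | None = None
    reads_bed: str | None = None
    min_mean: float = 20.0
    min_ratio: float = 2.0
    min_expressed_fraction: float = 0.5
    alpha: float = 0.05
    type0_floor: float = 0.5
    min_r2: float = 0.5
    min_samples_per_donor: int = 20
    n_permutations: int = 10_000
    n_label_permutations: int = 1000
    min_annotated: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest["outputs"][path.name] = len(df)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all applicable stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "outputs": {},
    }

    for name in ("gtf", "matrix", "metadata"):
        path = getattr(config, name)
        if not Path(path).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {path}")

    genes = parse_gtf(config.gtf)
    events = [ev for g in genes for ev in find_cassette_events(g)]
    log.info("events: %d genes -> %d cassette events", len(genes), len(events))
    _write(events_to_frame(events), out / "events.tsv", manifest)

    matrix = read_abundance(config.matrix)
    metadata = read_metadata(config.metadata)
    events_q = [
        ev for ev in events
        if (ev.including_transcripts | ev.excluding_transcripts) <= set(matrix.index)
    ]
    if len(events_q) < len(events):
        log.warning(
            "dropping %d events with transcripts absent from the matrix",
            len(events) - len(events_q),
        )
    table = compute_psi(events_q, matrix)
    psi_out = table.psi.reset_index(names="event_id")
    _write(psi_out, out / "psi.tsv", manifest)

    filters = apply_variability_filters(
        table,
        metadata,
        min_mean=config.min_mean,
        min_ratio=config.min_ratio,
        min_expressed_fraction=config.min_expressed_fraction,
    )
    _write(filters, out / "filters.tsv", manifest)

    cls = classify_events(
        table,
        filters,
        metadata,
        alpha=config.alpha,
        type0_floor=config.type0_floor,
        min_r2=config.min_r2,
        min_ratio=config.min_ratio,
    )
    for tissue, grp in cls.groupby("tissue"):
        log.info(
            "tissue %s: %d fitted, %s",
            tissue,
            int((grp["reason"] == "fitted").sum()),
            grp["label"].value_counts().to_dict(),
        )
    _write(cls, out / "classifications.tsv", manifest)

    consistency = cross_tissue_consistency(cls)
    _write(consistency, out / "consistency.tsv", manifest)

    if "donor" in metadata.columns:
        donor = donor_level_reclassification(
            table,
            metadata,
            cls,
            min_samples_per_donor=config.min_samples_per_donor,
            alpha=config.alpha,
            type0_floor=config.type0_floor,
            min_r2=config.min_r2,
            min_ratio=config.min_ratio,
        )
        _write(donor.report, out / "donor_classifications.tsv", manifest)
        manifest["donor_agreement_fraction"] = donor.agreement_fraction

    _write(
        compare_classes(events_q, cls, genes), out / "characteristics.tsv", manifest
    )
    _write(
        biotype_fractions(events_q, cls, genes),
        out / "biotype_fractions.tsv",
        manifest,
    )

    if config.hit_table and config.class_map:
        hits = pd.read_csv(config.hit_table, sep="\t", index_col=0)
        class_of = pd.read_csv(
            config.class_map, sep="\t", index_col=0
        ).iloc[:, 0]
        enr = permutation_enrichment(
            hits,
            class_of,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        _write(
            bonferroni_with_exclusion(enr), out / "feature_enrichment.tsv", manifest
        )

    if config.go_map:
        annotations = read_go_map(config.go_map)
        universe = {
            t
            for ev in events_q
            for t in ev.including_transcripts | ev.excluding_transcripts
        }
        target = uhp_isoforms(events_q, cls)
        if target:
            go = go_overrepresentation(
                annotations, universe, target, min_annotated=config.min_annotated
            )
            _write(go, out / "go_enrichment.tsv", manifest)
        else:
            log.warning("no UHP isoforms; GO stage skipped")

    if config.reads_bed:
        reads = [r[:3] for r in read_bed(config.reads_bed)]
        label_of = dict(
            cls[cls["label"].isin(["UHP", "DHP", "TYPE0"])]
            .groupby("event_id")["label"]
            .first()
        )
        introns = []
        for ev in events_q:
            lab = label_of.get(ev.event_id)
            if lab is None or ev.downstream_intron is None:
                continue
            s, e = ev.downstream_intron
            introns.append((ev.chrom, s - 1, e, lab))
        if introns:
            summary = count_overlaps(introns, reads)
            _write(summary.per_class, out / "overlap_summary.tsv", manifest)
            manifest["overlap_chi2_p"] = summary.chi2_p
            if len({iv[3] for iv in introns}) >= 2:
                null = label_permutation_null(
                    introns,
                    reads,
                    n_permutations=config.n_label_permutations,
                    seed=config.seed,
                )
                pd.DataFrame(
                    {"max_delta": null.null_max_deltas}
                ).to_csv(out / "overlap_permutations.tsv", sep="\t", index=False)
                manifest["overlap_observed_max_delta"] = null.observed_max_delta
                manifest["overlap_p_empirical"] = null.p_empirical

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
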
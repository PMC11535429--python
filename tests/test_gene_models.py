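import itertools

import numpy as np
import pytest

from psicoupling.gene_models import (
    GtfParseError,
    find_cassette_events,
    flanking_introns,
    introns_to_bed,
    parse_gtf,
)

from conftest import A, B, C, D, E, make_gene

GTF_LINE = '{chrom}\tsrc\texon\t{s}\t{e}\t.\t{strand}\t.\tgene_id "{g}"; transcript_id "{t}"; transcript_biotype "protein_coding";\n'


def write_gtf(path, rows):
    with open(path, "w") as fh:
        for chrom, s, e, strand, g, t in rows:
            fh.write(GTF_LINE.format(chrom=chrom, s=s, e=e, strand=strand, g=g, t=t))


class TestParseGtf:
    def test_toy_gtf_two_transcripts(self, tmp_path):
        p = tmp_path / "toy.gtf"
        rows = [
            ("chr1", *iv, "+", "g1", "t1") for iv in [A, B, C]
        ] + [("chr1", *iv, "+", "g1", "t2") for iv in [A, C]]
        write_gtf(p, rows)
        genes = parse_gtf(p)
        assert len(genes) == 1
        (gene,) = genes
        assert len(gene.transcripts) == 2
        by_id = {t.transcript_id: t for t in gene.transcripts}
        assert by_id["t1"].exons == (A, B, C)
        assert by_id["t2"].exons == (A, C)

    def test_duplicate_exon_rows_deduplicated(self, tmp_path):
        p = tmp_path / "dup.gtf"
        write_gtf(p, [("chr1", *A, "+", "g1", "t1")] * 3)
        (gene,) = parse_gtf(p)
        assert gene.transcripts[0].exons == (A,)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.gtf"
        p.write_text("")
        assert parse_gtf(p) == []

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        write_gtf(p, [("chr1", *A, "+", "g1", "t1")])
        with open(p, "a") as fh:
            fh.write("only three\tfields\there\n")
        with pytest.raises(GtfParseError, match="line 2"):
            parse_gtf(p)

    def test_exon_without_transcript_id(self, tmp_path):
        p = tmp_path / "notid.gtf"
        p.write_text('chr1\tsrc\texon\t1\t10\t.\t+\t.\tgene_id "g1";\n')
        with pytest.raises(GtfParseError, match="transcript_id"):
            parse_gtf(p)

    def test_gene_whitelist(self, tmp_path):
        p = tmp_path / "two.gtf"
        write_gtf(
            p,
            [("chr1", *A, "+", "g1", "t1"), ("chr1", *A, "+", "g2", "t1g2")],
        )
        genes = parse_gtf(p, gene_whitelist={"g2"})
        assert [g.gene_id for g in genes] == ["g2"]


class TestFindCassetteEvents:
    def test_simple_cassette(self, simple_gene):
        (ev,) = find_cassette_events(simple_gene)
        assert ev.exon_keys == (B,)
        assert ev.including_transcripts == frozenset({"t1"})
        assert ev.excluding_transcripts == frozenset({"t2"})

    def test_perfectly_correlated_exons_collapse(self, collapse_gene):
        (ev,) = find_cassette_events(collapse_gene)
        assert ev.exon_keys == (B, D)

    def test_identical_transcripts_yield_nothing(self):
        gene = make_gene("g", "+", {"t1": [A, B, C], "t2": [A, B, C]})
        assert find_cassette_events(gene) == []

    def test_single_transcript_gene(self):
        gene = make_gene("g", "+", {"t1": [A, B, C]})
        assert find_cassette_events(gene) == []

    def test_alternative_boundary_exon_not_emitted(self):
        # t2's middle exon shares B's locus with a shifted 5' boundary:
        # neither variant is a skipped cassette.
        gene = make_gene("g", "+", {"t1": [A, B, C], "t2": [A, (320, 400), C]})
        assert find_cassette_events(gene) == []

    def test_transcript_order_invariance(self):
        tx = {"t1": [A, B, C, D, E], "t2": [A, C, E], "t3": [A, B, C, E]}
        reference = None
        for order in itertools.permutations(tx):
            gene = make_gene("g", "+", {k: tx[k] for k in order})
            got = [
                (ev.exon_keys, ev.including_transcripts, ev.excluding_transcripts)
                for ev in find_cassette_events(gene)
            ]
            if reference is None:
                reference = got
            assert got == reference

    def test_partition_and_pattern_round_trip(self, rng):
        """On random toy genes every alternatively included cassette exon
        lands in exactly one event, and the event's transcript sets
        reproduce the exon-by-transcript inclusion matrix."""
        slots = [(100 + 200 * i, 200 + 200 * i) for i in range(8)]
        for _ in range(25):
            n_tx = int(rng.integers(2, 5))
            tx_exons = {}
            for j in range(n_tx):
                picks = [s for s in slots if rng.random() < 0.6]
                if not picks:
                    picks = [slots[0]]
                tx_exons[f"t{j}"] = picks
            gene = make_gene("g", "+", tx_exons)
            events = find_cassette_events(gene)
            all_ids = set(tx_exons)
            seen = set()
            for ev in events:
                assert ev.including_transcripts | ev.excluding_transcripts == all_ids
                for exon in ev.exon_keys:
                    assert exon not in seen
                    seen.add(exon)
                    containing = {
                        t for t, exons in tx_exons.items() if exon in exons
                    }
                    assert containing == set(ev.including_transcripts)


class TestFlankingIntrons:
    def test_plus_strand_coordinates(self):
        gene = make_gene("g", "+", {"t1": [A, B, C], "t2": [A, C]})
        (ev,) = find_cassette_events(gene)
        assert ev.upstream_intron == (201, 299)
        assert ev.downstream_intron == (401, 499)

    def test_minus_strand_swaps_sides(self):
        gene = make_gene("g", "-", {"t1": [A, B, C], "t2": [A, C]})
        (ev,) = find_cassette_events(gene)
        assert ev.upstream_intron == (401, 499)
        assert ev.downstream_intron == (201, 299)

    def test_terminal_exon_has_one_absent_side(self):
        # E is t1's last exon; on the + strand nothing lies downstream
        gene = make_gene("g", "+", {"t1": [A, C, E], "t2": [A, C]})
        (ev,) = find_cassette_events(gene)
        assert ev.exon_keys == (E,)
        assert ev.upstream_intron == (601, 899)
        assert ev.downstream_intron is None

    def test_modal_intron_among_including_transcripts(self):
        # two including transcripts reach B from A, one from a nearer exon:
        # the modal upstream intron wins
        gene = make_gene(
            "g",
            "+",
            {
                "t1": [A, B, C],
                "t2": [A, B, C],
                "t3": [(250, 280), B, C],
                "t4": [A, C],
            },
        )
        events = find_cassette_events(gene)
        ev_b = next(ev for ev in events if B in ev.exon_keys)
        up, down = flanking_introns(ev_b, gene)
        assert up == (201, 299)
        assert down == (401, 499)


def test_introns_to_bed_is_zero_based_half_open(simple_gene):
    events = find_cassette_events(simple_gene)
    (rec,) = introns_to_bed(events, side="downstream")
    chrom, start, end, name = rec
    assert (start, end) == (400, 499)  # 1-based [401, 499] inclusive
    assert name == events[0].event_id
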
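"""Derive cassette events, with collapsing, from a small GTF.

The toy gene reproduces the classic collapsing case: transcripts
A-B-C-D-E and A-C-E differ by exons B and D, which are perfectly
correlated across transcripts and therefore form a single event.
"""

import tempfile
from pathlib import Path

from psicoupling import find_cassette_events, parse_gtf

LINE = '{c}\tx\texon\t{s}\t{e}\t.\t+\t.\tgene_id "g1"; transcript_id "{t}"; transcript_biotype "protein_coding";\n'

exons = {"A": (100, 200), "B": (300, 400), "C": (500, 600),
         "D": (700, 800), "E": (900, 1000)}
rows = [LINE.format(c="chr1", s=exons[k][0], e=exons[k][1], t="t1")
        for k in "ABCDE"]
rows += [LINE.format(c="chr1", s=exons[k][0], e=exons[k][1], t="t2")
         for k in "ACE"]

with tempfile.TemporaryDirectory() as tmp:
    gtf = Path(tmp) / "toy.gtf"
    gtf.write_text("".join(rows))
    (gene,) = parse_gtf(gtf)
    events = find_cassette_events(gene)

for ev in events:
    print(f"event {ev.event_id}")
    print(f"  collapsed exons:   {ev.exon_keys}")
    print(f"  including:         {sorted(ev.including_transcripts)}")
    print(f"  excluding:         {sorted(ev.excluding_transcripts)}")
    print(f"  upstream intron:   {ev.upstream_intron}")
    print(f"  downstream intron: {ev.downstream_intron}")
# One event is printed: exons B and D share the inclusion pattern {t1},
# so their statistics will be computed once and applied to both.
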
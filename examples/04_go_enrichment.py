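"""Isoform-level GO overrepresentation with the hypergeometric test.

The universe holds 60 isoforms; 15 of them contain a UHP exon.  Term
GO:COUPLED annotates mostly UHP isoforms, term GO:BACKGROUND annotates a
random slice of the universe.
"""

from psicoupling import go_overrepresentation

universe = {f"iso{i:02d}" for i in range(60)}
uhp = {f"iso{i:02d}" for i in range(15)}

annotations = {}
for i in range(12):                     # 10 UHP + 2 background isoforms
    annotations.setdefault(f"iso{i:02d}" if i < 10 else f"iso{i + 30}", set()).add(
        "GO:COUPLED"
    )
for i in range(0, 60, 4):
    annotations.setdefault(f"iso{i:02d}", set()).add("GO:BACKGROUND")

out = go_overrepresentation(annotations, universe, uhp, min_annotated=3)
print(out.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
# GO:COUPLED: 10 of its 12 annotated isoforms are UHP (coverage 0.83),
# far above the 25% UHP share of the universe -> tiny p.  GO:BACKGROUND
# tracks the universe composition and is not significant.
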
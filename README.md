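# psicoupling

Detection and characterization of coupling between gene expression and
alternative splicing from transcript-level RNA-seq abundances.

Many cassette exons are included or skipped independently of how strongly
their gene is transcribed, but for a sizeable minority the inclusion
fraction tracks total gene expression — a signature of co-transcriptional
regulation (e.g. RNA-polymerase elongation speed modulating the splicing
"window of opportunity"). `psicoupling` classifies cassette exons into:

* **UHP** ("upregulated–high ψ"): higher inclusion predicts higher gene
  expression,
* **DHP** ("downregulated–high ψ"): higher inclusion predicts lower gene
  expression,
* **type 0**: variably expressed, but with no expression–splicing
  association,

and then characterizes the classes: descriptive statistics with
Mann-Whitney tests, permutation-based enrichment of binary promoter/flank
features, isoform-level GO overrepresentation, nascent-read overlap with
flanking introns, and marker-gene correlation.

## The model

For cassette exon *e* of gene *g*, the percent spliced in per sample is

```
ψ(e) = IT_inc(e) / (IT_inc(e) + IT_excl(e))
```

where `IT_inc`/`IT_excl` are the summed abundances of the transcripts that
include/exclude the exon. Total gene expression `Y(g)` is the sum over all
transcripts of the gene. Per tissue, an ordinary least-squares line

```
Y(g) ~ β0 + β1 · ψ(e)
```

is fitted for every exon that passes expression-variability filters
(expressed in ≥ half the samples, mean inclusion signal ≥ 20, 95th/5th
expression-percentile ratio ≥ 2). The two-sided t-test p-value on β1 is
Benjamini–Hochberg-corrected within each tissue. An exon is UHP/DHP when
the adjusted p ≤ 0.05, R² ≥ 0.5 and the percentile-ratio condition holds
(sign of β1 decides the direction), and type 0 when the adjusted p ≥ 0.5
while the variability conditions still hold.

Exon sets that are perfectly correlated with respect to transcript
structure (e.g. transcripts A-B-C-D-E vs A-C-E) are collapsed into a
single event before testing.

## Worked example

```python
import pandas as pd
import psicoupling as pc

scn = pc.SimScenario(n_uhp=20, n_dhp=20, n_type0=40,
                     n_samples_per_tissue=100, seed=1)
sim = pc.simulate_dataset(scn)
table = pc.compute_psi(sim.events, sim.abundance)
filters = pc.apply_variability_filters(table, sim.metadata)
cls = pc.classify_events(table, filters, sim.metadata)
merged = cls.merge(sim.truth[["event_id", "label"]]
                   .rename(columns={"label": "truth"}), on="event_id")
print(pd.crosstab(merged["truth"], merged["label"]))
```

prints (80 events × 3 tissues = 240 event–tissue classifications):

```
label  DHP  TYPE0  UHP  UNCLASSIFIED
truth
DHP     60      0    0             0
TYPE0    0     70    0            50
UHP      0      0   60             0
```

Every planted coupled exon is recovered with the correct direction in
every tissue, and no planted type-0 exon is ever called coupled. Type-0
events split between the TYPE0 label (adjusted p ≥ 0.5, clear absence of
coupling) and UNCLASSIFIED (adjusted p between 0.05 and 0.5 — evidence
inconclusive either way, which the pipeline never converts into a coupled
call). The `examples/` directory has one short script per capability
(event derivation from GTF, feature enrichment, GO overrepresentation,
nascent-read overlap, Poisson-mixture sample splitting).

A thin CLI wraps the same library:

```
psicoupling simulate --out-dir sim --seed 1
psicoupling run config.yaml        # events → ψ → classify → reports
psicoupling demo                   # one-shot synthetic end-to-end run
```

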
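# Methods

## Cassette events from gene models

Transcript structures are read from GTF (GENCODE/Ensembl attribute
dialect; 1-based inclusive coordinates internally, converted to 0-based
half-open only on BED export). Within a gene, every exon interval is
assigned its *inclusion pattern* — the exact set of transcripts containing
it. Exons whose pattern is neither empty nor the full transcript set are
candidate alternative exons; exons sharing a pattern are collapsed into
one event, so statistics are computed once per distinguishable splicing
choice. Exon identity is the exact (start, end) interval: two exons
differing by one base pair are distinct.

A candidate is only a *cassette* exon if no excluding transcript carries
an exon overlapping its interval; overlapping variants (alternative 5'/3'
boundaries, retained-intron fragments) are never emitted, and no other
event classes are modeled. Alternative first/last exons that are cleanly
absent from the excluding transcripts are kept; their flanking intron on
the missing side is reported absent.

Flanking introns are transcriptional (strand-aware): the upstream intron
of a minus-strand exon lies at higher genomic coordinates. Each including
transcript proposes the gap to its adjacent exon; when transcripts
disagree, the modal intron is used, ties broken by the longer intron and
then by coordinates. This rule is a package choice — computing introns
from a canonical transcript instead would be equally defensible — and the
representative exon of a collapsed event (used for exon length and
flanking introns) is the first exon of the set in transcriptional order.

## ψ and expression

ψ is the ratio of summed including-transcript abundances to the summed
abundances of both sets. The inputs are continuous abundances (TPM-like);
a literal count of transcript *models* would be constant across samples
and could not enter a per-sample regression, so the summed-abundance
reading is the only coherent one. When both sums are zero the sample
carries no splicing information and ψ is missing; such samples are
dropped pairwise per event. Gene expression Y is the sum over all
transcripts assigned to the gene, including transcripts not involved in
any event.

Filters per (event, tissue), all thresholds configurable:

| filter | default | applied to |
|---|---|---|
| expressed fraction ≥ | 0.5 | inclusion signal ≥ 1 |
| mean level ≥ | 20 | inclusion signal |
| 95th/5th percentile ratio ≥ | 2.0 | gene expression Y |

Percentiles use linear interpolation between order statistics (the numpy
default), fixed for reproducibility. A zero 5th percentile with positive
95th yields an infinite ratio (passes); an all-zero expression vector
fails. The expressed/mean filters act on the event's own inclusion
signal because they gate the exon, not the gene.

## Classification

Per event and tissue, OLS of Y on ψ; the p-value is the two-sided t-test
on β1. Benjamini–Hochberg runs within each tissue over the events
actually fitted there (not over all annotated exons); ties follow the
standard step-up convention. Labels:

* UHP: β1 > 0, adjusted p ≤ 0.05, R² ≥ 0.5, percentile ratio ≥ 2;
* DHP: β1 < 0, same thresholds;
* TYPE0: adjusted p ≥ 0.5 with the ratio and expression filters passing;
* UNCLASSIFIED: everything else — filter failures, < 3 usable samples,
  constant ψ, or adjusted p between 0.05 and 0.5. Inconclusive events are
  deliberately never counted as coupled or as type 0.

The R² ≥ 0.5 gate is applied uniformly in every grouping (tissues and
donors) and is exposed as a parameter. Classification itself is fully
deterministic.

Donor-level reclassification reruns the identical filter+classify
machinery with the donor as the grouping variable, restricted to donors
with ≥ 20 samples, and reports the fraction of donor-level UHP/DHP calls
whose direction matches the tissue-level call for the same event.
Cross-tissue consistency flags any event called UHP in one tissue and
DHP in another.

The slope analysis regresses per-event |β1| (averaged over the tissues
where the event is coupled) on the gene's mean expression. Marker
correlation reports the Pearson r between each event's ψ and a chosen
marker gene's expression (e.g. a proliferation marker), with r missing
when either side is constant.

Sample stratification by mutation count uses a two-component Poisson
mixture fitted by EM: means initialized at the 25th/75th percentiles of
the counts, equal starting weights, log-likelihood convergence tolerance
1e-8, at most 1000 iterations. The split point is the smallest integer
count whose posterior probability of the high-mean component exceeds 0.5.
If the components merge (|λ₁ − λ₂| < 1e-6) a warning is raised and the
threshold is placed past the largest observed count. The EM is written
in-package; no installed library offers a Poisson mixture.

## Class characteristics

Features compared across classes: exons per gene, transcripts per gene,
inclusion proportion (|including| / (|including| + |excluding|) per
event), upstream/downstream intron length, exon length. Genes containing
events of several classes contribute to each class. Pairwise two-sided
Mann-Whitney U tests are exact when min(n, m) ≤ 8 — scipy's exact
distribution for tie-free data, full enumeration of label assignments
when ties are present and the pooled size is ≤ 12 — and otherwise use the
normal approximation with tie and continuity correction. The two-sided
exact p is twice the smaller tail, capped at 1. Biotype composition is
reported as fractions over including transcripts per class and sums to 1
within each class.

## Feature enrichment

The statistic for a binary feature is Δ = 100·(prop_A − prop_B), the
difference in hit proportions between two classes in percentage points.
Class labels are shuffled without replacement (class sizes preserved);
one shared sequence of shuffles serves all features, and items are
canonically ordered by identifier first so results do not depend on input
row order. The empirical p is the fraction of permutations whose Δ′
strictly exceeds the observed Δ; ties do not count against the observed
statistic, and no add-one smoothing is applied by default. Because the
statistic is discrete, P(p ≤ α) can slightly exceed α for small item
counts — the strict-greater convention trades a little anti-conservatism
at the atom boundaries for the plain proportion definition.

The Bonferroni step first excludes tests whose observed statistic is
within 0.5 percentage points, or within 5 % of |Δ|, of the statistic's
*permutation mean* — an effect-size screen separating real displacement
from noise around the null. Reading the screen's reference point as the
permutation mean of Δ′ is a documented package choice (the screen could
also be read per-permutation); both floors are parameters. Surviving
p-values are multiplied by the number of surviving tests, capped at 1.
The default permutation count is 1,000,000, configurable down for
desk-scale runs.

## GO overrepresentation

Isoform→term annotations are taken as given (no GO-graph propagation).
With universe size N, K universe isoforms annotated to a term, a target
set of n isoforms (those in the including set of ≥ 1 UHP event in ≥ 1
tissue) and k annotated target isoforms, the p-value is the upper tail
P(X ≥ k) of Hypergeom(N, K, n). Terms with k < 5 are not tested;
Bonferroni runs over tested terms. Coverage is k/K. Passing gene sets
instead of isoform sets yields a plain gene-overlap test.

## Nascent-read overlap

Intervals are BED-style 0-based half-open. A read counts for an intron at
≥ 1 bp of overlap, once per overlapping intron (the semantics of a
default, unstranded `bedtools intersect`); a strand-aware mode is not
provided because the default comparison is unstranded. Counting uses a
sorted sweep with a maximum-read-length window; per-class totals are
reported both raw and per intron base pair. The class × read-count
contingency is tested by chi-squared against expectation proportional to
intron bp. The label-permutation null shuffles class labels across
introns (sizes preserved) and records, per permutation, the largest
absolute per-bp rate difference between the type-0 class and any other
class; the empirical p is the fraction of permutations reaching the
observed value.

## Synthetic data generator

The generator is the test bench's ground truth. Each gene carries exactly
one cassette event: including transcripts share exons A-B-C, excluding
transcripts share A-C; with more than two transcripts the sets collapse
to a single event exactly as in real multi-transcript genes. Exon and
intron lengths are drawn per gene (exon 60–300 bp, introns 0.2–2 kb),
strands are random, and biotypes are sampled with protein-coding
predominating.

Per sample, ψ ~ Beta(1/2, 1/2) — bimodal, reflecting that real cassette
exons are mostly near fully included or fully skipped — and expression
follows Y = β0 + s·β1·ψ + ε with s = +1/−1/0 for UHP/DHP/type-0. Defaults:
β0 = 60, β1 = 100, noise sd = 20 (coupling-to-noise ratio 5), 3 tissues ×
300 samples, donors assigned round-robin so each of 30 donors holds 30
samples across tissues. For DHP events the intercept is raised by β1
(downregulation operates from a higher baseline), keeping expression
positive over the whole ψ range instead of censoring it near ψ = 1. Noise
is drawn from a normal conditioned on Y > 0 (inverse-CDF truncation),
which at ≥ 3σ separation from zero is numerically indistinguishable from
the unconditioned normal but guarantees every sample carries a
recoverable ψ; with zero noise, negative means are clamped at 0 with a
warning. Y·ψ is split equally among including transcripts and Y·(1−ψ)
among excluding transcripts, so recomputing ψ from the matrix returns the
drawn value to machine precision — the round-trip the test suite asserts
at 1e-12.

What the generator does *not* emulate: count noise and length bias of
real RNA-seq quantification, correlated expression across genes, shared
splicing programs across events, unbalanced donor designs, and genes with
several interacting events. Recovery results on this bench therefore
demonstrate correctness of the estimation machinery under the stated
model, not power on real tissue data.

Feature tables are Bernoulli hits with a planted between-class rate
difference; interval read sets place Poisson(density × length) unit reads
uniformly within each intron.

## Problem sizes and runtime

The default recovery scenario (500 events, 900 samples, 1500 tissue-level
plus ~15,000 donor-level regressions) runs in ~10 s on one core. Oracle
comparisons use exhaustive enumeration at small sizes (Mann-Whitney
n+m ≤ 10; hypergeometric N ≤ 12; permutation test on 8 items against all
70 label assignments with 10⁵ random permutations). The null-calibration
checks use 200 events × 300 samples and 200 null features × 2000
permutations; the overlap check uses ~10⁴ reads over 67 kb of introns.

## Known limitations

* Event discovery handles cassette exons only; intron retention,
  alternative splice sites and alternative promoters are out of scope.
* The ψ definition requires transcript-resolved abundances; the package
  does not quantify transcripts from reads.
* Whether the expression filters should run on TPM or raw counts is left
  to the caller: thresholds are parameters, and the classification is
  scale-invariant apart from the mean-level filter.
* GO annotations are tested as provided; without propagation, enrichment
  of specific terms does not imply enrichment of their ancestors.
* The permutation-mean reading of the enrichment exclusion screen is one
  of several possible operationalizations.
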
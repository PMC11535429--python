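"""Nascent-read density in downstream introns per exon class.

Reads are simulated at twice the per-bp density in UHP introns compared
to type-0 introns; the per-class rates, the chi-squared test and a
1000-fold label-permutation null all flag the difference.
"""

from psicoupling import (
    count_overlaps,
    label_permutation_null,
    simulate_interval_reads,
)

introns_by_type = {
    "UHP": [("chr1", i * 2000, i * 2000 + 1000) for i in range(30)],
    "TYPE0": [("chr2", i * 2000, i * 2000 + 1000) for i in range(30)],
}
reads = simulate_interval_reads(
    introns_by_type, {"UHP": 0.2, "TYPE0": 0.1}, seed=11
)
introns = [
    (c, s, e, lab) for lab, ivs in introns_by_type.items() for c, s, e in ivs
]
summary = count_overlaps(introns, reads)
print(summary.per_class.to_string(index=False))
print(f"chi-squared p: {summary.chi2_p:.3g}")

null = label_permutation_null(introns, reads, n_permutations=1000, seed=12)
print(
    f"observed max rate difference: {null.observed_max_delta:.4f} reads/bp; "
    f"permutations exceeding it: {null.n_exceeding}/1000"
)
# The UHP per-bp rate is ~2x the type-0 rate and none of the 1000 label
# shuffles reaches the observed difference: the planted density contrast
# is detected.
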
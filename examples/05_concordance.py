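"""Asymmetric concordance between two callsets of the same cohort.

Compares a fine-grained callset against a coarse one under the 1-bp and
50%-overlap criteria, demonstrating why each comparison must be run in
both directions.
"""

from cnvburden import GenomicInterval, concordance_matrix, matrix_to_frame

# a "fine" callset of small events and a "coarse" one of wide events
fine = [GenomicInterval("chr1", s, s + 800) for s in range(0, 50_000, 2_500)]
coarse = [GenomicInterval("chr1", s, s + 9_000) for s in range(0, 50_000, 12_500)]

results = concordance_matrix([("fine", fine), ("coarse", coarse)],
                             criteria=("1bp", 0.5))
frame = matrix_to_frame(results)
print(frame.round(3))

# Under 1 bp almost every fine event touches some coarse event, and vice
# versa. Under 50% overlap the comparison is directional: each fine event
# inside a coarse one is fully covered (high recall in the "fine" column),
# but a 9-kb coarse event is barely covered by the 800-bp fine events that
# intersect it, so the "coarse" column drops - the same asymmetry seen
# when benchmarking a dense callset against a sparse external resource.
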
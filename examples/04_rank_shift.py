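"""Compare covariation between two groups with the rank-shift statistic.

Raw MI scores are not directly comparable across alignments, but within-
group percentile ranks are.  This example plants one coupled pair in group
A only, computes covariation for both groups over the same column set, and
shows that the pair tops the |rank shift| selection with a positive shift
(stronger in the first group).
"""

from psrkit import covariation_analysis, rank_shift
from psrkit.synthetic import (
    SyntheticSpec,
    coupled_pair,
    generate_alignment,
    landmark_map_for,
    make_two_group_fixture,
)

spec_a = SyntheticSpec(n_sequences=500, n_columns=60, seed=11,
                       coupled_blocks=(coupled_pair(12, 42, 0.9),),
                       group_label="group_A")
spec_b = SyntheticSpec(n_sequences=500, n_columns=60, seed=12,
                       group_label="group_B")
fixture = make_two_group_fixture(spec_a, spec_b)

cov_a = covariation_analysis(fixture.receiver, fixture.landmark_map)
cov_b = covariation_analysis(fixture.psr, fixture.landmark_map)

shifts = rank_shift(cov_a, cov_b, top_fraction=0.02)
print(f"pairs significant in at least one group: {len(shifts.all_significant)}")
print("top |rank shift| selection:")
for _, row in shifts.table.iterrows():
    print(f"  {int(row['pos_i']):>3} - {int(row['pos_j']):<3}  "
          f"rank A={row['rank_receiver']:6.2f}  rank B={row['rank_psr']:6.2f}  "
          f"shift={row['shift']:+7.2f}  significant in: {row['significant_in']}")

# A positive shift means the interaction ranks higher in group A than in
# group B: the planted pair (reference positions 13-43) is significant only
# in A and shows a near-maximal positive shift.
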
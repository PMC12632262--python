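"""Mutual information, average-product correction, significance, ranks,
and the between-group rank-shift comparison."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psrkit import (
    column_mi,
    covariation_analysis,
    product_correction,
    rank_pairs,
    rank_shift,
    significance,
)
from psrkit.align_io import AMINO_ACIDS
from psrkit.covariation import (
    DegenerateScoreDistribution,
    mi_matrix,
    top_fraction_indices,
)
from psrkit.synthetic import (
    SyntheticSpec,
    coupled_pair,
    generate_alignment,
    landmark_map_for,
    make_two_group_fixture,
)


# ---------------------------------------------------------------------------
# Independent oracle: plain double sum over the observed joint table, in
# pure Python, with optional pairwise deletion and uniform pseudocount.

def brute_force_mi(col_i, col_j, pseudocount=0.0, drop_gaps=True):
    pairs = list(zip(col_i, col_j))
    if drop_gaps:
        pairs = [(a, b) for a, b in pairs if a != "-" and b != "-"]
    letters = sorted(AMINO_ACIDS)
    joint = {}
    for a, b in pairs:
        joint[(a, b)] = joint.get((a, b), 0.0) + 1.0
    if pseudocount:
        for a in letters:
            for b in letters:
                joint[(a, b)] = joint.get((a, b), 0.0) + pseudocount
    total = sum(joint.values())
    pa, pb = {}, {}
    for (a, b), c in joint.items():
        pa[a] = pa.get(a, 0.0) + c / total
        pb[b] = pb.get(b, 0.0) + c / total
    mi = 0.0
    for (a, b), c in joint.items():
        p = c / total
        if p > 0:
            mi += p * math.log2(p / (pa[a] * pb[b]))
    return mi


def brute_force_entropy(col):
    vals = [a for a in col if a != "-"]
    counts = {}
    for a in vals:
        counts[a] = counts.get(a, 0) + 1
    n = len(vals)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def random_columns(rng, n_rows, alphabet=AMINO_ACIDS, gap_prob=0.0):
    letters = list(alphabet)
    cols = []
    for _ in range(2):
        col = rng.choice(letters, size=n_rows)
        if gap_prob:
            col[rng.random(n_rows) < gap_prob] = "-"
        cols.append("".join(col))
    return cols


class TestColumnMI:
    def test_constant_columns_have_zero_mi(self):
        assert column_mi("AAAA", "AAAA") == 0.0

    def test_perfect_two_letter_coupling_is_one_bit(self):
        assert column_mi("AAGG", "CCWW") == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_on_random_columns(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 21))
            a, b = random_columns(rng, n, alphabet="ACDEG", gap_prob=0.1)
            try:
                got = column_mi(a, b)
            except ValueError:
                continue  # insufficient coverage after pairwise deletion
            assert got == pytest.approx(brute_force_mi(a, b), abs=1e-12)

    def test_matches_bruteforce_with_pseudocount(self, rng):
        for _ in range(20):
            a, b = random_columns(rng, 10, alphabet="ACD")
            assert column_mi(a, b, pseudocount=0.5) == pytest.approx(
                brute_force_mi(a, b, pseudocount=0.5), abs=1e-12
            )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from("ACDEG-"), st.sampled_from("ACDEG-")
            ),
            min_size=6,
            max_size=20,
        )
    )
    def test_bruteforce_equivalence_property(self, data):
        a = "".join(x for x, _ in data)
        b = "".join(y for _, y in data)
        usable = sum(1 for x, y in data if x != "-" and y != "-")
        if usable < 2:
            with pytest.raises(ValueError, match="insufficient coverage"):
                column_mi(a, b)
        else:
            assert column_mi(a, b) == pytest.approx(
                brute_force_mi(a, b), abs=1e-12
            )

    def test_entropy_bound(self, rng):
        for _ in range(50):
            a, b = random_columns(rng, 15, alphabet="ACDEFG")
            mi = column_mi(a, b)
            assert mi <= min(brute_force_entropy(a), brute_force_entropy(b)) + 1e-12
            assert mi >= 0.0

    def test_gap_rows_dropped_pairwise(self):
        # MI over ungapped rows only: gapped rows must not contribute
        a, b = "AAGG--", "CCWWAA"
        assert column_mi(a, b) == pytest.approx(column_mi("AAGG", "CCWW"), abs=1e-15)

    def test_insufficient_coverage(self):
        with pytest.raises(ValueError, match="insufficient coverage"):
            column_mi("A---", "C-CC")


class TestProductCorrection:
    def test_constant_offdiagonal_corrects_to_zero(self):
        for p, c in [(4, 1.0), (10, 0.37), (25, 5.0)]:
            m = np.full((p, p), c)
            np.fill_diagonal(m, 0.0)
            corrected = product_correction(m)
            assert np.allclose(corrected, 0.0, atol=1e-12)

    def test_all_zero_matrix_corrects_to_zero(self):
        corrected = product_correction(np.zeros((6, 6)))
        assert np.allclose(corrected, 0.0)

    def test_four_by_four_matches_hand_computation(self):
        # off-diagonal row means (2, 10/3, 4, 14/3), overall mean 3.5;
        # APC(i,j) = mean_i * mean_j / 3.5, hand-evaluated below
        m = np.array(
            [
                [0.0, 1.0, 2.0, 3.0],
                [1.0, 0.0, 4.0, 5.0],
                [2.0, 4.0, 0.0, 6.0],
                [3.0, 5.0, 6.0, 0.0],
            ]
        )
        corrected = product_correction(m)
        expected = {
            (0, 1): 1.0 - (2.0 * (10.0 / 3.0)) / 3.5,
            (0, 2): 2.0 - (2.0 * 4.0) / 3.5,
            (0, 3): 3.0 - (2.0 * (14.0 / 3.0)) / 3.5,
            (1, 2): 4.0 - ((10.0 / 3.0) * 4.0) / 3.5,
            (1, 3): 5.0 - ((10.0 / 3.0) * (14.0 / 3.0)) / 3.5,
            (2, 3): 6.0 - (4.0 * (14.0 / 3.0)) / 3.5,
        }
        for (i, j), val in expected.items():
            assert corrected[i, j] == pytest.approx(val, abs=1e-12)
            assert corrected[j, i] == pytest.approx(val, abs=1e-12)

    def test_symmetry_preserved(self, rng):
        m = rng.random((8, 8))
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        corrected = product_correction(m)
        assert np.allclose(corrected, corrected.T)


class TestSignificance:
    def test_degenerate_distribution_warns_and_selects_nothing(self):
        m = np.full((5, 5), 2.0)
        np.fill_diagonal(m, 0.0)
        with pytest.warns(DegenerateScoreDistribution):
            _, sig = significance(product_correction(m))
        assert not sig.any()

    def test_single_outlier_is_the_only_significant_pair(self, rng):
        p = 46  # 1035 off-diagonal pairs
        m = rng.normal(0.0, 1e-3, size=(p, p))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        m[3, 17] = m[17, 3] = 1.0
        z, sig = significance(m, threshold=6.5)
        assert sig[3, 17] and sig[17, 3]
        assert sig.sum() == 2  # symmetric mask, one pair
        assert z[3, 17] > 6.5


class TestRankPairs:
    def test_three_distinct_scores(self):
        m = np.array(
            [[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]]
        )
        pct = rank_pairs(m)
        assert pct[0, 1] == pytest.approx(100 / 3)
        assert pct[0, 2] == pytest.approx(200 / 3)
        assert pct[1, 2] == pytest.approx(100.0)

    def test_all_ties_share_one_rank(self):
        m = np.full((4, 4), 2.0)
        np.fill_diagonal(m, 0.0)
        pct = rank_pairs(m)
        off = pct[np.triu_indices(4, k=1)]
        assert np.allclose(off, off[0])

    def test_monotone_transform_of_scores(self, rng):
        m = rng.random((10, 10))
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        pct = rank_pairs(m)
        iu, ju = np.triu_indices(10, k=1)
        order = np.argsort(m[iu, ju])
        assert (np.diff(pct[iu, ju][order]) >= 0).all()

    def test_top_one_percent_of_4950_pairs_selects_50(self, rng):
        scores = rng.permutation(4950).astype(float)
        assert len(top_fraction_indices(scores, 0.01)) == 50

    def test_boundary_ties_all_included(self):
        scores = np.array([5.0, 4.0, 4.0, 1.0, 0.0] + [0.0] * 95)
        sel = top_fraction_indices(scores, 0.02)  # ceil(2) = 2, tie at 4.0
        assert set(sel) == {0, 1, 2}


class TestPipeline:
    def test_planted_pair_is_significant_and_top_ranked(self):
        spec = SyntheticSpec(
            n_sequences=500,
            n_columns=60,
            seed=5,
            coupled_blocks=(coupled_pair(20, 44, 0.9),),
        )
        aln, _ = generate_alignment(spec)
        cov = covariation_analysis(aln, landmark_map_for(spec))
        i = list(cov.columns).index(21)  # reference number of column 20
        j = list(cov.columns).index(45)
        assert cov.significant[i, j]
        assert cov.percentile_rank[i, j] >= 99.0
        assert cov.raw_mi[i, j] >= 0.0

    def test_matrices_symmetric_and_mi_nonnegative(self, rng):
        spec = SyntheticSpec(n_sequences=80, n_columns=15, seed=9, gap_rate=0.05)
        aln, _ = generate_alignment(spec)
        cov = covariation_analysis(aln, landmark_map_for(spec))
        for mat in (cov.raw_mi, cov.corrected_mi, cov.zscores, cov.percentile_rank):
            assert np.allclose(mat, mat.T, equal_nan=True)
        off = cov.raw_mi[np.triu_indices(cov.n_positions, k=1)]
        assert np.nanmin(off) >= 0.0

    def test_high_gap_columns_excluded(self):
        spec = SyntheticSpec(
            n_sequences=100, n_columns=20, seed=3, gap_rate={4: 0.8}
        )
        aln, _ = generate_alignment(spec)
        cov = covariation_analysis(aln, landmark_map_for(spec), max_gap_fraction=0.5)
        assert 5 not in cov.columns  # reference number of column 4


class TestRankShift:
    def _two_groups(self, seed_a=100, seed_b=200, plant_in_a=True):
        blocks_a = (coupled_pair(10, 30, 0.9),) if plant_in_a else ()
        spec_a = SyntheticSpec(
            n_sequences=500, n_columns=60, seed=seed_a,
            coupled_blocks=blocks_a, group_label="A",
        )
        spec_b = SyntheticSpec(
            n_sequences=500, n_columns=60, seed=seed_b, group_label="B",
        )
        fx = make_two_group_fixture(spec_a, spec_b)
        cov_a = covariation_analysis(fx.receiver, fx.landmark_map)
        cov_b = covariation_analysis(fx.psr, fx.landmark_map)
        return cov_a, cov_b

    def test_identical_inputs_give_empty_selection(self):
        cov, _ = self._two_groups(plant_in_a=False)
        table = rank_shift(cov, cov, top_fraction=0.02)
        assert (table.all_significant["shift"] == 0).all()
        assert len(table.table) == 0

    def test_swap_negates_shifts(self):
        cov_a, cov_b = self._two_groups()
        ab = rank_shift(cov_a, cov_b)
        ba = rank_shift(cov_b, cov_a)
        merged = ab.all_significant.merge(
            ba.all_significant, on=["pos_i", "pos_j"], suffixes=("_ab", "_ba")
        )
        assert len(merged) == len(ab.all_significant)
        assert np.allclose(merged["shift_ab"], -merged["shift_ba"])

    def test_group_specific_pair_selected_with_positive_shift(self):
        cov_a, cov_b = self._two_groups()
        table = rank_shift(cov_a, cov_b, top_fraction=0.02).table
        hit = table[(table.pos_i == 11) & (table.pos_j == 31)]
        assert len(hit) == 1
        assert hit["shift"].iloc[0] > 0
        assert "receiver" in hit["significant_in"].iloc[0]

    def test_mismatched_columns_rejected(self):
        spec_a = SyntheticSpec(n_sequences=50, n_columns=30, seed=1)
        spec_b = SyntheticSpec(n_sequences=50, n_columns=30, seed=2, gap_rate={3: 0.9})
        aln_a, _ = generate_alignment(spec_a)
        aln_b, _ = generate_alignment(spec_b)
        cov_a = covariation_analysis(aln_a, landmark_map_for(spec_a))
        cov_b = covariation_analysis(aln_b, landmark_map_for(spec_b))
        with pytest.raises(ValueError, match="alignments not comparable"):
            rank_shift(cov_a, cov_b)
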
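"""Synthetic generator: determinism, planted structure, and spec I/O."""

import json

import numpy as np
import pytest
from scipy.stats import binom

from psrkit import (
    column_mi,
    covariation_analysis,
    partition_set,
    rank_shift,
)
from psrkit.synthetic import (
    CoupledBlockSpec,
    LandmarkSiteSpec,
    SyntheticSpec,
    coupled_pair,
    generate_alignment,
    landmark_map_for,
    make_two_group_fixture,
    psr_like_spec,
    receiver_like_spec,
    spec_from_yaml,
    spec_to_yaml,
    write_fixture,
)


def full_landmark_sites(p=1.0, d_substitute=None):
    classes = {"DD1": "DE", "DD2": "DE", "D": "D", "T": "ST", "K": "K"}
    cols = {"DD1": 5, "DD2": 6, "D": 26, "T": 40, "K": 50}
    rates = p if isinstance(p, dict) else {k: p for k in classes}
    return {
        name: LandmarkSiteSpec(
            column=cols[name],
            conserved=frozenset(classes[name]),
            p_conserved=rates[name],
            substitute=d_substitute if name == "D" else None,
        )
        for name in classes
    }


class TestDeterminism:
    def test_same_spec_same_seed_byte_identical(self):
        spec = SyntheticSpec(
            n_sequences=40, n_columns=30, seed=13,
            coupled_blocks=(coupled_pair(3, 9, 0.5),), gap_rate=0.05,
        )
        a1, t1 = generate_alignment(spec)
        a2, t2 = generate_alignment(spec)
        assert a1.sequences == a2.sequences
        assert t1.missing_landmarks == t2.missing_landmarks

    def test_different_seed_differs(self):
        spec = SyntheticSpec(n_sequences=40, n_columns=30, seed=13)
        a1, _ = generate_alignment(spec)
        a2, _ = generate_alignment(spec, seed=14)
        assert a1.sequences != a2.sequences


class TestValidation:
    def test_coupling_letters_must_be_amino_acids(self):
        with pytest.raises(ValueError, match="alphabet"):
            CoupledBlockSpec((1, 2), 0.5, (("A", "X"), ("V", "A")))

    def test_coupled_columns_must_avoid_landmarks(self):
        with pytest.raises(ValueError, match="landmark"):
            SyntheticSpec(
                n_sequences=10, n_columns=60,
                landmark_sites=full_landmark_sites(),
                coupled_blocks=(coupled_pair(26, 30, 0.5),),
            )

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            SyntheticSpec(n_sequences=10, n_columns=20, gap_rate=1.5)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            LandmarkSiteSpec(0, frozenset("D"), 1.2)

    def test_substitute_must_not_overlap_conserved(self):
        with pytest.raises(ValueError, match="overlaps"):
            LandmarkSiteSpec(0, frozenset("ST"), 0.5, substitute=frozenset("TA"))


class TestPlantedClassification:
    def test_full_conservation_yields_all_receivers(self):
        spec = SyntheticSpec(
            n_sequences=200, n_columns=60, seed=3,
            landmark_sites=full_landmark_sites(1.0),
        )
        aln, truth = generate_alignment(spec)
        receivers, psrs, calls = partition_set(aln, landmark_map_for(spec))
        assert psrs.n_sequences == 0
        assert truth.n_receiver == 200
        assert [c.call for c in calls] == list(truth.calls)

    def test_zero_d_conservation_with_glu_yields_all_alrs(self):
        sites = full_landmark_sites(1.0, d_substitute=frozenset("E"))
        sites["D"] = LandmarkSiteSpec(
            26, frozenset("D"), 0.0, substitute=frozenset("E")
        )
        spec = SyntheticSpec(
            n_sequences=100, n_columns=60, seed=4, landmark_sites=sites
        )
        aln, truth = generate_alignment(spec)
        _, psrs, calls = partition_set(aln, landmark_map_for(spec))
        assert psrs.n_sequences == 100
        assert all(c.is_alr for c in calls)
        assert truth.n_alr == 100
        # the hallmark substitution: every D column residue is Glu
        d_col = 26
        assert all(res[d_col] == "E" for _, res in aln.sequences)

    def test_truth_record_matches_classifier_exactly(self):
        spec = SyntheticSpec(
            n_sequences=500, n_columns=60, seed=5,
            landmark_sites=full_landmark_sites(0.9), gap_rate=0.01,
        )
        aln, truth = generate_alignment(spec)
        _, _, calls = partition_set(aln, landmark_map_for(spec))
        assert [c.call for c in calls] == list(truth.calls)
        assert [c.missing_landmarks for c in calls] == list(truth.missing_landmarks)


class TestBackgroundConvergence:
    def test_empirical_composition_tracks_background(self):
        # n = 5000 draws per column: spot-check planted frequencies against
        # the central 99% binomial interval
        spec = SyntheticSpec(
            n_sequences=5000, n_columns=10, seed=6,
            background={2: {"W": 0.5, "C": 0.25}},
        )
        aln, _ = generate_alignment(spec)
        codes = aln.to_codes()
        from psrkit.align_io import AMINO_ACIDS

        n = spec.n_sequences
        for col, aa, p in [(2, "W", 0.5), (2, "C", 0.25), (0, "A", 0.05)]:
            freq = (codes[:, col] == AMINO_ACIDS.index(aa)).mean()
            lo = binom.ppf(0.005, n, p) / n
            hi = binom.ppf(0.995, n, p) / n
            assert lo <= freq <= hi, (col, aa, freq)


class TestPlantedCoupling:
    def test_mi_monotone_in_coupling_strength(self):
        # n is large enough that the sparse-table MI bias (which shrinks as
        # the uncoupled mixture component grows) cannot mask the coupling
        mis = []
        for k, coupling in enumerate([0.2, 0.5, 0.9]):
            spec = SyntheticSpec(
                n_sequences=5000, n_columns=12, seed=30 + k,
                coupled_blocks=(coupled_pair(4, 9, coupling),),
            )
            aln, _ = generate_alignment(spec)
            codes = aln.to_codes()
            mis.append(column_mi(codes[:, 4], codes[:, 9]))
        assert mis[0] < mis[1] < mis[2]

    def test_planted_pair_beats_uncoupled_background(self):
        spec = SyntheticSpec(
            n_sequences=500, n_columns=20, seed=1,
            coupled_blocks=(coupled_pair(3, 12, 0.9),),
        )
        aln, _ = generate_alignment(spec)
        codes = aln.to_codes()
        planted = column_mi(codes[:, 3], codes[:, 12])
        background = [
            column_mi(codes[:, i], codes[:, j])
            for i in range(10)
            for j in range(i + 1, 10)
            if (i, j) != (3, 12) and 3 not in (i, j) and 12 not in (i, j)
        ]
        assert planted > np.percentile(background, 95)


class TestTwoGroupFixture:
    def test_mismatched_widths_rejected(self):
        a = SyntheticSpec(n_sequences=10, n_columns=30)
        b = SyntheticSpec(n_sequences=10, n_columns=40)
        with pytest.raises(ValueError, match="equal n_columns"):
            make_two_group_fixture(a, b)

    def test_identical_specs_show_no_rank_shift_signal(self):
        spec = SyntheticSpec(n_sequences=300, n_columns=40, seed=17, group_label="G")
        fx = make_two_group_fixture(spec, spec)
        cov_a = covariation_analysis(fx.receiver, fx.landmark_map)
        cov_b = covariation_analysis(fx.psr, fx.landmark_map)
        table = rank_shift(cov_a, cov_b, top_fraction=0.02)
        assert len(table.table) == 0  # identical groups: all shifts zero


class TestPresets:
    def test_receiver_preset_is_fully_conserved(self):
        spec = receiver_like_spec(n_sequences=300, seed=42)
        aln, truth = generate_alignment(spec)
        assert truth.n_receiver == 300
        _, psrs, _ = partition_set(aln, landmark_map_for(spec))
        assert psrs.n_sequences == 0

    def test_psr_preset_marginals(self):
        # planted landmark retention: D 65%, T 70%, K 65%, DD2 20%
        n = 4000
        spec = psr_like_spec(n_sequences=n, seed=43)
        aln, truth = generate_alignment(spec)
        d_ok = sum("D" not in m for m in truth.missing_landmarks) / n
        for got, planted in [
            (d_ok, 0.65),
            (sum("T" not in m for m in truth.missing_landmarks) / n, 0.70),
            (sum("DD2" not in m for m in truth.missing_landmarks) / n, 0.20),
        ]:
            lo = binom.ppf(0.005, n, planted) / n
            hi = binom.ppf(0.995, n, planted) / n
            assert lo <= got <= hi


class TestSpecIO:
    def test_yaml_round_trip(self, tmp_path):
        spec = SyntheticSpec(
            n_sequences=25, n_columns=60, seed=9, group_label="rt",
            background={7: {"A": 0.4}},
            landmark_sites=full_landmark_sites(0.8, frozenset("E")),
            coupled_blocks=(coupled_pair(10, 20, 0.6),),
            gap_rate=0.02,
        )
        path = tmp_path / "spec.yaml"
        spec_to_yaml(spec, path)
        back = spec_from_yaml(path)
        a1, _ = generate_alignment(spec)
        a2, _ = generate_alignment(back)
        assert a1.sequences == a2.sequences

    def test_write_fixture_emits_fasta_and_truth(self, tmp_path):
        spec = SyntheticSpec(n_sequences=8, n_columns=20, seed=2, group_label="fx")
        fasta, truth_path = write_fixture(spec, tmp_path)
        from psrkit import read_alignment

        aln = read_alignment(fasta, group_label="fx")
        assert aln.n_sequences == 8
        payload = json.loads(truth_path.read_text())
        assert payload["calls"] == ["receiver"] * 8  # no landmarks planted
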
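"""Randomization protocols: targeting semantics, nesting, motif masking."""

import numpy as np
import pytest

from clmprobe.perturbation import (
    PerturbationPlan,
    ResidueFrequencies,
    control_variants,
    cumulative_position_sets,
    cumulative_variants,
    mask_motif,
    mask_random_control,
    motif_positions,
    randomize_positions,
    residue_frequencies,
)

G_ONLY = ResidueFrequencies({"G": 1.0})


class TestResidueFrequencies:
    def test_two_sequence_corpus(self):
        freqs = residue_frequencies(["AA", "CC"]).frequencies
        assert freqs == {"A": 0.5, "C": 0.5}

    def test_single_sequence_uniform(self):
        freqs = residue_frequencies(["ACDE"]).frequencies
        assert all(v == 0.25 for v in freqs.values())

    def test_sums_to_one_on_any_corpus(self):
        rng = np.random.default_rng(0)
        corpus = [
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=30))
            for _ in range(5)
        ]
        total = sum(residue_frequencies(corpus).frequencies.values())
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            ResidueFrequencies({"A": 0.6, "C": 0.6})


class TestRandomizePositions:
    def test_empty_position_set_is_identity(self):
        seq = "ACDEFGHIKL"
        rng = np.random.default_rng(0)
        assert randomize_positions(seq, [], G_ONLY, rng) == seq

    def test_untargeted_suffix_unchanged(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        rng = np.random.default_rng(0)
        out = randomize_positions(seq, range(15), G_ONLY, rng)
        assert out[15:] == seq[15:]
        assert out[:15] == "G" * 15

    def test_degenerate_frequencies_force_outcome(self):
        rng = np.random.default_rng(1)
        out = randomize_positions("ACDE", [0, 2], G_ONLY, rng)
        assert out == "GCGE"

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            randomize_positions("ACDE", [4], G_ONLY, np.random.default_rng(0))


class TestCumulative:
    def test_n_to_c_third_step_targets_first_45(self):
        sets = cumulative_position_sets(100, "n_to_c")
        assert sets[2] == frozenset(range(45))

    def test_variant_count_is_ceil_l_over_segment(self):
        sets = cumulative_position_sets(100, "n_to_c")
        assert len(sets) == 7  # ceil(100/15)
        assert sets[-1] == frozenset(range(100))

    def test_c_to_n_first_step_targets_last_15(self):
        sets = cumulative_position_sets(100, "c_to_n")
        assert sets[0] == frozenset(range(85, 100))

    def test_targeted_sets_nested(self):
        for direction in ("n_to_c", "c_to_n"):
            sets = cumulative_position_sets(64, direction)
            for a, b in zip(sets, sets[1:]):
                assert a < b

    def test_variants_extend_earlier_randomization(self):
        """Variant k keeps variant k-1's drawn residues and only redraws the
        newly targeted segment."""
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        freqs = residue_frequencies([seq])
        variants = cumulative_variants(seq, "n_to_c", freqs, seed=0)
        for k, (a, b) in enumerate(zip(variants, variants[1:]), start=1):
            span = 15 * k
            assert b[:span] == a[:span]  # earlier draws kept verbatim
            assert b[min(15 * (k + 1), len(seq)):] == seq[min(15 * (k + 1), len(seq)):]
        assert len(variants) == 3
        full_g = cumulative_variants(seq, "n_to_c", G_ONLY, seed=0)
        assert full_g[-1] == "G" * len(seq)


class TestControls:
    def test_full_count_targets_all_positions(self):
        seq = "ACDEFGHIKL"
        out = control_variants(seq, [len(seq)], G_ONLY, seed=0)[0]
        assert out == "G" * len(seq)

    def test_exactly_commanded_cardinality(self):
        # sequence has no G, frequencies force G: diffs == targeted count
        seq = "ACDEFHIKLMNPQRSTVWY" * 3
        out = control_variants(seq, [15], G_ONLY, seed=1)[0]
        diffs = sum(a != b for a, b in zip(seq, out))
        assert diffs == 15

    def test_same_seed_reproducible_fresh_sets_per_step(self):
        seq = "ACDEFHIKLMNPQRSTVWY" * 3
        a = control_variants(seq, [10, 10], G_ONLY, seed=5)
        b = control_variants(seq, [10, 10], G_ONLY, seed=5)
        assert a == b
        positions_step1 = {i for i, (x, y) in enumerate(zip(seq, a[0])) if x != y}
        positions_step2 = {i for i, (x, y) in enumerate(zip(seq, a[1])) if x != y}
        assert positions_step1 != positions_step2  # fresh draws, not cumulative

    def test_count_beyond_length_rejected(self):
        with pytest.raises(ValueError):
            control_variants("ACDE", [5], G_ONLY, seed=0)


class TestMotifMasking:
    def test_family_signature_range_in_alanine_mode(self):
        """A 1-based inclusive 140-156 window yields 17 consecutive alanines."""
        seq = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(200))
        out = mask_motif(seq, [(140, 156)], "alanine")
        assert out[139:156] == "A" * 17
        assert out[:139] == seq[:139] and out[156:] == seq[156:]

    def test_split_atp_site_ranges_modify_ten_positions(self):
        """Ranges [32-40, 55] cover 9 + 1 = 10 positions."""
        assert len(motif_positions([(32, 40), (55, 55)], 100)) == 10
        seq = "C" * 100
        out = mask_motif(seq, [(32, 40), (55, 55)], "alanine")
        assert sum(a != b for a, b in zip(seq, out)) == 10

    def test_poly_alanine_motif_unchanged_by_alanine_mode(self):
        seq = "CCCC" + "A" * 6 + "CCCC"
        assert mask_motif(seq, [(5, 10)], "alanine") == seq

    def test_randomize_mode_targets_only_motif(self):
        seq = "C" * 30
        out = mask_motif(seq, [(11, 15)], "randomize", G_ONLY, seed=0)
        assert out[:10] == "C" * 10 and out[15:] == "C" * 15
        assert out[10:15] == "G" * 5

    def test_overlapping_ranges_merged_with_warning(self):
        with pytest.warns(UserWarning):
            positions = motif_positions([(5, 10), (8, 12)], 30)
        assert positions == list(range(4, 12))

    def test_control_modifies_same_number_of_positions(self):
        seq = "C" * 60
        out = mask_random_control(seq, 17, "alanine", seed=3)
        assert sum(a != b for a, b in zip(seq, out)) == 17

    def test_range_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            mask_motif("ACDE", [(2, 9)], "alanine")


def test_plan_validation():
    with pytest.raises(ValueError):
        PerturbationPlan(kind="unknown_kind")
    with pytest.raises(ValueError):
        PerturbationPlan(kind="motif_alanine", repeats=0)
    with pytest.raises(ValueError):
        PerturbationPlan(kind="cumulative_n_to_c", segment=0)
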
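"""Generator invariants: MT calibration, determinism, validity, ground truth."""

from collections import Counter

import pytest

from clmprobe.chem import canonical_nonisomeric, is_valid_smiles, murcko_core
from clmprobe.universe import (
    SyntheticUniverse,
    UniverseConfig,
    UniverseCapacityError,
    generate_universe,
    read_fasta_sequences,
    validate_universe,
)

SMALL = UniverseConfig(
    n_families=3,
    sequences_per_family=4,
    sequence_length=48,
    n_series_per_family=3,
    analogs_per_series=20,
    compounds_per_sequence=8,
    seed=11,
)


@pytest.fixture(scope="module")
def small_universe():
    return generate_universe(SMALL)


def brute_force_mt_stats(pairs):
    """Independent count of MT fraction and mean multiplicity from a pair list."""
    per_compound = Counter()
    for seq_id, cpd_id in pairs:
        per_compound[cpd_id] += 1  # pairs are unique, so count = multiplicity
    mults = list(per_compound.values())
    mt = [m for m in mults if m >= 2]
    return len(mt) / len(mults), (sum(mt) / len(mt) if mt else float("nan"))


def test_no_mt_compounds_when_fraction_zero():
    cfg = UniverseConfig(
        n_families=2,
        sequences_per_family=3,
        sequence_length=40,
        n_series_per_family=2,
        analogs_per_series=25,
        compounds_per_sequence=8,
        mt_fraction=0.0,
        seed=5,
    )
    universe = generate_universe(cfg)
    counts = Counter(c for _, c in universe.pairs)
    assert all(v == 1 for v in counts.values())


def test_mt_statistics_match_corpus_calibration():
    """Default universe reproduces the corpus-level MT shape: ~29% MT
    compounds with ~2.91 sequences per MT compound."""
    universe = generate_universe(UniverseConfig())
    fraction, mean_mult = brute_force_mt_stats(universe.pairs)
    assert 0.26 <= fraction <= 0.32
    assert 2.6 <= mean_mult <= 3.2


def test_mt_statistics_tighten_with_universe_size():
    """Empirical MT statistics converge to the configured values as the
    universe grows (tolerance roughly halves with 4x the pairs)."""
    small = UniverseConfig(
        n_families=2,
        sequences_per_family=5,
        sequence_length=40,
        n_series_per_family=3,
        analogs_per_series=25,
        compounds_per_sequence=10,
        seed=3,
    )
    big = UniverseConfig(
        n_families=4,
        sequences_per_family=10,
        sequence_length=40,
        n_series_per_family=5,
        analogs_per_series=30,
        compounds_per_sequence=20,
        seed=3,
    )
    f_small, m_small = brute_force_mt_stats(generate_universe(small).pairs)
    f_big, m_big = brute_force_mt_stats(generate_universe(big).pairs)
    assert abs(f_small - 0.29) <= 0.08
    assert abs(m_small - 2.91) <= 0.6
    assert abs(f_big - 0.29) <= 0.04
    assert abs(m_big - 2.91) <= 0.3


def test_same_seed_is_byte_identical_different_seed_differs(small_universe):
    again = generate_universe(SMALL)
    assert again.sequences_to_fasta() == small_universe.sequences_to_fasta()
    assert again.pairs_to_tsv().equals(small_universe.pairs_to_tsv())
    other = generate_universe(UniverseConfig(**{**SMALL.__dict__, "seed": 12}))
    assert other.sequences_to_fasta() != small_universe.sequences_to_fasta()


def test_generated_universe_has_no_violations(small_universe):
    assert validate_universe(small_universe) == []


def test_compounds_are_canonical_and_valid(small_universe):
    for rec in small_universe.compounds.values():
        assert is_valid_smiles(rec.smiles)
        assert canonical_nonisomeric(rec.smiles) == rec.smiles


def test_series_members_share_ground_truth_scaffold(small_universe):
    for rec in small_universe.compounds.values():
        assert murcko_core(rec.smiles) == small_universe.series_scaffolds[rec.series]


def test_cross_family_scaffolds_disjoint(small_universe):
    by_family: dict[str, set[str]] = {}
    for series, scaffold in small_universe.series_scaffolds.items():
        by_family.setdefault(series.split(".")[0], set()).add(scaffold)
    families = list(by_family)
    for i, a in enumerate(families):
        for b in families[i + 1 :]:
            assert not (by_family[a] & by_family[b])


def test_validator_flags_dangling_reference(small_universe):
    broken = SyntheticUniverse(
        sequences=small_universe.sequences,
        compounds={
            k: v
            for k, v in small_universe.compounds.items()
            if k != small_universe.pairs[0][1]
        },
        pairs=small_universe.pairs,
        series_scaffolds=small_universe.series_scaffolds,
        config=small_universe.config,
    )
    violations = validate_universe(broken)
    dangling = [v for v in violations if v.kind == "dangling_compound"]
    # the removed compound may participate in several pairs
    assert len(dangling) >= 1
    assert all(small_universe.pairs[0][1] in v.message for v in dangling[:1])


def test_validator_flags_corrupted_smiles(small_universe):
    import dataclasses

    cid = next(iter(small_universe.compounds))
    corrupted = dict(small_universe.compounds)
    corrupted[cid] = dataclasses.replace(corrupted[cid], smiles="c1ccccc1((")
    broken = SyntheticUniverse(
        sequences=small_universe.sequences,
        compounds=corrupted,
        pairs=small_universe.pairs,
        series_scaffolds=small_universe.series_scaffolds,
        config=small_universe.config,
    )
    violations = [v for v in validate_universe(broken) if v.kind == "invalid_smiles"]
    assert len(violations) == 1
    assert cid in violations[0].message


def test_capacity_error_when_scaffold_grammar_exhausted():
    with pytest.raises(UniverseCapacityError):
        generate_universe(
            UniverseConfig(
                n_families=1,
                sequences_per_family=2,
                sequence_length=40,
                n_series_per_family=500,
                analogs_per_series=2,
                compounds_per_sequence=2,
                seed=0,
            )
        )


def test_capacity_error_when_substituent_grammar_exhausted(monkeypatch):
    import numpy as np

    from clmprobe import universe as universe_mod

    monkeypatch.setattr(universe_mod, "_SUBSTITUENTS", ("F", "Cl"))
    with pytest.raises(UniverseCapacityError):
        universe_mod.sample_analogs("C1CCCCC1", 500, np.random.default_rng(0))


def test_motif_range_outside_sequence_rejected():
    with pytest.raises(ValueError):
        UniverseConfig(
            sequence_length=30, motif_spec=(("F0", (25, 40), "A" * 16),)
        )


def test_motifs_written_verbatim(small_universe):
    cfg = UniverseConfig(
        n_families=2,
        sequences_per_family=3,
        sequence_length=50,
        n_series_per_family=2,
        analogs_per_series=20,
        compounds_per_sequence=6,
        motif_spec=(("F0", (5, 10), "WWWYYY"), ("F1", (11, 14), "HHHH")),
        seed=2,
    )
    universe = generate_universe(cfg)
    for rec in universe.sequences.values():
        if rec.family == "F0":
            assert rec.residues[4:10] == "WWWYYY"
        else:
            assert rec.residues[10:14] == "HHHH"


def test_fasta_round_trip(tmp_path, small_universe):
    path = tmp_path / "seqs.fasta"
    small_universe.sequences_to_fasta(path)
    back = read_fasta_sequences(path)
    assert back == small_universe.sequences
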
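"""Split disjointness, family packing optimality, MT dilution semantics."""

import itertools

import pandas as pd
import pytest

from clmprobe.datasets import PairDataset, SequenceRecord
from clmprobe.partitioning import (
    DilutionSchedule,
    SplitPlan,
    _choose_family_subset,
    dilute_mt,
    dilution_series,
    split_by_family,
    split_by_sequence,
)
from clmprobe.universe import UniverseConfig, generate_universe


def make_dataset(pair_tuples, families=None):
    families = families or {}
    seq_ids = sorted({s for s, _ in pair_tuples})
    sequences = {
        s: SequenceRecord(s, "ACDEFGHIKL", families.get(s, "FX")) for s in seq_ids
    }
    df = pd.DataFrame(pair_tuples, columns=["sequence_id", "smiles"])
    return PairDataset(df, sequences)


@pytest.fixture(scope="module")
def universe_dataset():
    return generate_universe(
        UniverseConfig(
            n_families=4,
            sequences_per_family=5,
            sequence_length=48,
            n_series_per_family=3,
            analogs_per_series=25,
            compounds_per_sequence=10,
            seed=7,
        )
    ).to_pair_dataset()


class TestSequenceSplit:
    def test_seventy_thirty_on_ten_sequences(self):
        ds = make_dataset([(f"S{i}", f"CCO{'C' * i}") for i in range(10)])
        train, test = split_by_sequence(ds, SplitPlan(seed=0))
        assert len(train.sequence_ids) == 7
        assert len(test.sequence_ids) == 3

    def test_sides_disjoint_and_pairs_preserved(self, universe_dataset):
        train, test = split_by_sequence(universe_dataset, SplitPlan(seed=1))
        assert not (set(train.sequence_ids) & set(test.sequence_ids))
        assert train.n_pairs + test.n_pairs == universe_dataset.n_pairs

    def test_mt_compound_can_straddle_the_split(self):
        # compound X pairs with s1 and s2; whatever the assignment, some split
        # seed places them on opposite sides
        ds = make_dataset([("s1", "X"), ("s2", "X"), ("s3", "CCN")])
        straddled = False
        for seed in range(10):
            train, test = split_by_sequence(ds, SplitPlan(seed=seed))
            if "X" in train.compounds and "X" in test.compounds:
                straddled = True
        assert straddled

    def test_too_few_sequences_error(self):
        ds = make_dataset([("s1", "CCO")])
        with pytest.raises(ValueError):
            split_by_sequence(ds, SplitPlan())

    def test_deterministic_given_seed(self, universe_dataset):
        a = split_by_sequence(universe_dataset, SplitPlan(seed=5))
        b = split_by_sequence(universe_dataset, SplitPlan(seed=5))
        assert a[0].sequence_ids == b[0].sequence_ids


class TestFamilySplit:
    def test_two_equal_families_split_one_each(self):
        pairs = [(f"a{i}", f"C{'C' * i}O") for i in range(4)] + [
            (f"b{i}", f"N{'C' * i}O") for i in range(4)
        ]
        fams = {f"a{i}": "FA" for i in range(4)} | {f"b{i}": "FB" for i in range(4)}
        train, test = split_by_family(make_dataset(pairs, fams), SplitPlan(scheme="family"))
        assert len(train.families) == 1 and len(test.families) == 1
        assert train.families != test.families

    def test_packing_matches_exhaustive_on_known_instance(self):
        """Pair counts 50,20,15,10,5 at 70%: optimum is exactly 70 pairs."""
        counts = {"F0": 50, "F1": 20, "F2": 15, "F3": 10, "F4": 5}
        chosen = _choose_family_subset(counts, 0.7 * 100)
        assert sum(counts[f] for f in chosen) == 70
        assert chosen == {"F0", "F1"}  # tie-break: fewer train families

    @pytest.mark.parametrize("seed", range(5))
    def test_packing_matches_exhaustive_search(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        counts = {f"F{i}": int(rng.integers(1, 60)) for i in range(n)}
        target = 0.7 * sum(counts.values())
        chosen = _choose_family_subset(counts, target)
        best = min(
            (
                abs(sum(counts[f] for f in combo) - target)
                for r in range(1, n)
                for combo in itertools.combinations(sorted(counts), r)
            ),
        )
        assert abs(sum(counts[f] for f in chosen) - target) == pytest.approx(best)

    def test_family_labels_disjoint(self, universe_dataset):
        train, test = split_by_family(
            universe_dataset, SplitPlan(scheme="family", seed=0)
        )
        assert not (set(train.families) & set(test.families))

    def test_single_family_error(self):
        ds = make_dataset([("s1", "CCO"), ("s2", "CCN")], {"s1": "FA", "s2": "FA"})
        with pytest.raises(ValueError):
            split_by_family(ds, SplitPlan(scheme="family"))


class TestDilution:
    def test_retain_one_is_identity(self, universe_dataset):
        out = dilute_mt(universe_dataset, 1.0, seed=0)
        assert out.n_pairs == universe_dataset.n_pairs

    def test_three_target_compound_keeps_exactly_one_pair(self):
        ds = make_dataset([("s1", "X"), ("s2", "X"), ("s3", "X"), ("s1", "CCN")])
        out = dilute_mt(ds, 0.0, seed=0)
        assert int(out.multiplicity()["X"]) == 1
        assert out.n_pairs == 2  # one X pair + the untouched single-target pair

    def test_exact_conversion_count(self):
        # 100 MT compounds (2 pairs each) + 10 single-target
        pairs = []
        for i in range(100):
            pairs += [(f"s{i % 7}", f"MT{i}"), (f"s{(i + 1) % 7}", f"MT{i}")]
        pairs += [(f"s{i % 7}", f"ST{i}") for i in range(10)]
        ds = make_dataset(pairs)
        out = dilute_mt(ds, 0.25, seed=3)
        mult = out.multiplicity()
        converted = sum(1 for c in ds.mt_compounds() if mult[c] == 1)
        assert converted == 75

    def test_single_target_pairs_never_removed(self, universe_dataset):
        st = {
            c for c, m in universe_dataset.multiplicity().items() if m == 1
        }
        out = dilute_mt(universe_dataset, 0.0, seed=0)
        assert st <= out.compounds

    def test_conversion_sets_nested_across_levels(self, universe_dataset):
        schedule = DilutionSchedule(seed=4)
        series = dilution_series(universe_dataset, schedule)
        converted_sets = []
        for retain, ds in series:
            mult = ds.multiplicity()
            converted_sets.append(
                {c for c in universe_dataset.mt_compounds() if mult[c] == 1}
            )
        for smaller, larger in zip(converted_sets, converted_sets[1:]):
            assert smaller <= larger

    def test_retain_zero_all_single_target(self, universe_dataset):
        out = dilute_mt(universe_dataset, 0.0, seed=0)
        assert (out.multiplicity() == 1).all()

    def test_retain_zero_then_split_gives_disjoint_compounds(self, universe_dataset):
        out = dilute_mt(universe_dataset, 0.0, seed=0)
        train, test = split_by_sequence(out, SplitPlan(seed=0))
        assert not (train.compounds & test.compounds)


def test_schedule_validation():
    with pytest.raises(ValueError):
        DilutionSchedule(retain_levels=(0.75, 0.5))
    with pytest.raises(ValueError):
        DilutionSchedule(retain_levels=(1.0, 0.5, 0.5))
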
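"""Sampling-based reproduction, core, similarity and memorization metrics.

For each test sequence, output strings are sampled from a fitted model
(multinomial, temperature 1 by default), invalid strings are discarded (but
counted — validity is a health metric), and the valid remainder is
canonicalized. The headline quantity is n_uq_repro: the number of *distinct*
test compounds of that sequence exactly reproduced among the samples; the
same count on Murcko cores measures reproduction of close structural
analogs. Memorization statistics relate reproduced compounds back to the
training pairs: the fraction seen verbatim during training, and the mean
Tanimoto similarity to the nearest training neighbor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem import (
    SmilesParseError,
    canonical_nonisomeric,
    murcko_core,
    morgan_tanimoto,  # noqa: F401  (re-exported as part of the module surface)
    nearest_neighbor_similarities,
)
from .datasets import PairDataset
from .model import SequenceToCompoundTransformer

DEFAULT_N_SAMPLES = 2500
EXTENDED_N_SAMPLES = 5000
MIN_AVAILABLE_COMPOUNDS = 20  # per-sequence inclusion rule: "> 20 available"


@dataclass
class SampleSet:
    """Raw and valid-canonical output strings sampled for one sequence."""

    sequence_id: str
    raw: list[str]
    temperature: float
    seed: int
    valid: list[str] = field(init=False)

    def __post_init__(self):
        valid = []
        for s in self.raw:
            try:
                valid.append(canonical_nonisomeric(s))
            except SmilesParseError:
                continue
        self.valid = valid

    @property
    def n(self) -> int:
        return len(self.raw)

    @property
    def validity_rate(self) -> float:
        return len(self.valid) / self.n if self.n else 0.0

    def unique_valid(self) -> set[str]:
        return set(self.valid)

    def to_text(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.raw) + "\n")


def sample(
    model: SequenceToCompoundTransformer,
    sequence: str,
    n: int = DEFAULT_N_SAMPLES,
    temperature: float = 1.0,
    seed: int = 0,
    sequence_id: str = "",
) -> SampleSet:
    """Sample ``n`` output strings for one sequence (seed-reproducible)."""
    raw = model.sample_strings(sequence, n, temperature=temperature, seed=seed)
    return SampleSet(sequence_id or sequence[:12], raw, temperature, seed)


def count_reproduced(samples: SampleSet, test_compounds: set[str]) -> int:
    """Distinct members of ``test_compounds`` present among valid samples."""
    return len(samples.unique_valid() & set(test_compounds))


def extract_cores(compounds: set[str] | list[str]) -> dict[str, str]:
    """Map each compound to its core (Murcko scaffold; acyclic → itself).

    Unparseable entries are skipped. All members of one analog series map to
    the same core by construction of the synthetic universe.
    """
    cores: dict[str, str] = {}
    for smiles in compounds:
        try:
            cores[smiles] = murcko_core(smiles)
        except SmilesParseError:
            continue
    return cores


def count_reproduced_cores(samples: SampleSet, test_compounds: set[str]) -> int:
    """Distinct test cores matched by cores of the valid samples."""
    test_cores = set(extract_cores(test_compounds).values())
    sample_cores = set(extract_cores(samples.unique_valid()).values())
    return len(sample_cores & test_cores)


def memorization_analysis(
    reproduced: set[str] | list[str], training_compounds: set[str] | list[str]
) -> tuple[float | None, float | None]:
    """(fraction of reproduced compounds seen in training, mean NN Tanimoto).

    Identity is canonical-string equality; the nearest neighbor is taken
    over all training compounds by Morgan/Tanimoto. Both values are ``None``
    when no compounds were reproduced.
    """
    reproduced = sorted(set(reproduced))
    training = set(training_compounds)
    if not reproduced:
        return None, None
    seen = sum(1 for c in reproduced if c in training)
    fraction = seen / len(reproduced)
    sims = nearest_neighbor_similarities(reproduced, sorted(training))
    return fraction, sum(sims) / len(sims)


@dataclass
class ReproductionReport:
    """Per-sequence reproduction counts plus corpus-level memorization stats."""

    per_sequence: pd.DataFrame  # sequence_id, n_available, n_samples,
    #                             validity_rate, n_uq_repro_compounds,
    #                             n_uq_repro_cores
    memorization_fraction: float | None
    mean_nn_tanimoto: float | None
    reproduced_compounds: set[str]

    @property
    def total_compounds(self) -> int:
        return int(self.per_sequence["n_uq_repro_compounds"].sum())

    @property
    def total_cores(self) -> int:
        return int(self.per_sequence["n_uq_repro_cores"].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.per_sequence.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "n_sequences": len(self.per_sequence),
            "total_uq_repro_compounds": self.total_compounds,
            "total_uq_repro_cores": self.total_cores,
            "mean_uq_repro_compounds": float(
                self.per_sequence["n_uq_repro_compounds"].mean()
            )
            if len(self.per_sequence)
            else 0.0,
            "memorization_fraction": self.memorization_fraction,
            "mean_nn_tanimoto": self.mean_nn_tanimoto,
        }

    def summary_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def evaluate_reproduction(
    model: SequenceToCompoundTransformer,
    test: PairDataset,
    train: PairDataset,
    n_samples: int = DEFAULT_N_SAMPLES,
    temperature: float = 1.0,
    seed: int = 0,
    min_available: int = MIN_AVAILABLE_COMPOUNDS,
    sequence_ids: list[str] | None = None,
    with_memorization: bool = True,
) -> ReproductionReport:
    """Sample for every eligible test sequence and assemble the report.

    Eligible sequences have strictly more than ``min_available`` associated
    test compounds, unless an explicit ``sequence_ids`` list is given.
    """
    if sequence_ids is None:
        sequence_ids = [
            s
            for s in test.sequence_ids
            if len(test.compounds_of(s)) > min_available
        ]
    rows = []
    all_reproduced: set[str] = set()
    for i, sid in enumerate(sequence_ids):
        ss = sample(
            model,
            test.sequences[sid].residues,
            n=n_samples,
            temperature=temperature,
            seed=seed + i,
            sequence_id=sid,
        )
        test_compounds = test.compounds_of(sid)
        reproduced = ss.unique_valid() & test_compounds
        all_reproduced |= reproduced
        rows.append(
            {
                "sequence_id": sid,
                "n_available": len(test_compounds),
                "n_samples": n_samples,
                "validity_rate": ss.validity_rate,
                "n_uq_repro_compounds": len(reproduced),
                "n_uq_repro_cores": count_reproduced_cores(ss, test_compounds),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "sequence_id",
            "n_available",
            "n_samples",
            "validity_rate",
            "n_uq_repro_compounds",
            "n_uq_repro_cores",
        ],
    )
    fraction, nn_sim = (None, None)
    if with_memorization and all_reproduced:
        fraction, nn_sim = memorization_analysis(all_reproduced, train.compounds)
    return ReproductionReport(frame, fraction, nn_sim, all_reproduced)


def largest_test_sequences(test: PairDataset, k: int) -> list[str]:
    """The k test sequences with the most available compounds (stable order)."""
    ranked = sorted(
        test.sequence_ids, key=lambda s: (-len(test.compounds_of(s)), s)
    )
    return ranked[:k]
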
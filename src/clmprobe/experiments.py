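"""End-to-end control experiments composed from the package's pieces.

Each function wires one of the harness's headline experiments: training on
a chosen partition, sampling for test sequences, and computing reproduction
and memorization metrics, or running perturbation protocols against a
trained model. These are the entry points used by the acceptance script and
the integration tests; they work at desk scale on synthetic universes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import PairDataset
from .evaluation import (
    ReproductionReport,
    evaluate_reproduction,
    largest_test_sequences,
)
from .model import SequenceToCompoundTransformer, fit_on_dataset
from .partitioning import SplitPlan, dilute_mt, split_by_family, split_by_sequence
from .perturbation import (
    PerturbationPlan,
    ResidueFrequencies,
    residue_frequencies,
    run_experiment,
)
from .stats import StatTestResult, mann_whitney_u

# Desk-scale training configuration: smallest transformer that reliably
# memorizes the synthetic corpora within minutes on one CPU. Dropout is off:
# at a few hundred training pairs, memorization is the phenomenon under
# study, and regularization only slows its onset.
DESK_MODEL_KWARGS = dict(
    d_model=64,
    n_heads=4,
    n_encoder_layers=2,
    n_decoder_layers=2,
    d_ff=128,
    dropout=0.0,
    batch_size=32,
    epochs=60,
    base_lr=1e-4,
    max_lr=1e-3,
    cycle_epochs=4,
    dtype="float32",
)


def train_on_split(
    dataset: PairDataset,
    scheme: str = "sequence",
    retain_mt: float = 1.0,
    seed: int = 0,
    **model_overrides,
) -> tuple[SequenceToCompoundTransformer, PairDataset, PairDataset]:
    """Optionally dilute MT compounds, split 70/30, and train on the train side.

    Dilution is applied to the full dataset *before* partitioning so that a
    converted compound's single surviving pair lands on exactly one side.
    """
    if retain_mt < 1.0:
        dataset = dilute_mt(dataset, retain_mt, seed=seed)
    plan = SplitPlan(scheme=scheme, seed=seed)
    split = split_by_sequence if scheme == "sequence" else split_by_family
    train, test = split(dataset, plan)
    kwargs = {**DESK_MODEL_KWARGS, **model_overrides, "random_state": seed}
    model = fit_on_dataset(train, **kwargs)
    return model, train, test


@dataclass
class PartitionComparison:
    """Reproduction under sequence- vs family-based partitioning."""

    sequence_report: ReproductionReport
    family_report: ReproductionReport

    def totals(self) -> dict:
        return {
            "sequence_split_compounds": self.sequence_report.total_compounds,
            "sequence_split_cores": self.sequence_report.total_cores,
            "family_split_compounds": self.family_report.total_compounds,
            "family_split_cores": self.family_report.total_cores,
        }


def partition_comparison(
    dataset: PairDataset,
    seed: int = 0,
    n_samples: int = 1000,
    n_sequences: int = 5,
    **model_overrides,
) -> PartitionComparison:
    """Train sequence- and family-split models and compare reproduction.

    Evaluation covers the ``n_sequences`` test sequences with the most
    available compounds on each side.
    """
    reports = {}
    for scheme in ("sequence", "family"):
        model, train, test = train_on_split(
            dataset, scheme=scheme, seed=seed, **model_overrides
        )
        sids = largest_test_sequences(test, n_sequences)
        reports[scheme] = evaluate_reproduction(
            model, test, train, n_samples=n_samples, seed=seed, sequence_ids=sids
        )
    return PartitionComparison(reports["sequence"], reports["family"])


def dilution_experiment(
    dataset: PairDataset,
    retain: float,
    seed: int = 0,
    n_samples: int = 2500,
    n_sequences: int = 5,
    **model_overrides,
) -> tuple[ReproductionReport, SequenceToCompoundTransformer, PairDataset, PairDataset]:
    """Reproduction after diluting MT compounds to the given retain level."""
    model, train, test = train_on_split(
        dataset, scheme="sequence", retain_mt=retain, seed=seed, **model_overrides
    )
    sids = largest_test_sequences(test, n_sequences)
    report = evaluate_reproduction(
        model, test, train, n_samples=n_samples, seed=seed, sequence_ids=sids
    )
    return report, model, train, test


def randomization_study(
    model: SequenceToCompoundTransformer,
    test: PairDataset,
    train: PairDataset,
    sequence_ids: list[str],
    repeats: int = 5,
    n_samples: int = 400,
    segment: int = 15,
    seed: int = 0,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Cumulative N→C / C→N randomization plus positional controls.

    Returns per sequence a mapping kind → summarized curve (mean, sd per
    step), with residue frequencies taken from the full corpus (train +
    test sequences).
    """
    freqs = _corpus_frequencies(train, test)
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for sid in sequence_ids:
        out[sid] = {}
        for kind in (
            "cumulative_n_to_c",
            "cumulative_c_to_n",
            "cumulative_random_control",
        ):
            plan = PerturbationPlan(
                kind=kind,
                segment=segment,
                repeats=repeats,
                seed=seed,
                n_samples=n_samples,
            )
            curve = run_experiment(model, test, sid, plan, freqs)
            out[sid][kind] = curve.summarize()
    return out


def best_reproducing_sequences(
    model: SequenceToCompoundTransformer,
    test: PairDataset,
    k: int,
    n_samples: int = 500,
    seed: int = 0,
    candidates: int = 8,
) -> list[str]:
    """The k test sequences with the highest baseline reproduction counts.

    Perturbation experiments are only informative on sequences for which
    the unperturbed model reproduces something; this screens the largest
    ``candidates`` test sequences with a quick sampling pass.
    """
    screened = largest_test_sequences(test, candidates)
    report = evaluate_reproduction(
        model, test, None, n_samples=n_samples, seed=seed,
        sequence_ids=screened, with_memorization=False,
    )
    ranked = report.per_sequence.sort_values(
        ["n_uq_repro_compounds", "sequence_id"], ascending=[False, True]
    )
    return ranked["sequence_id"].head(k).tolist()


def band_overlap_fraction(curves: list[pd.DataFrame], n_sd: float = 2.0) -> float:
    """Fraction of steps at which all curves' mean ± n_sd bands overlap.

    Bands with undefined sd are treated as width zero at that step.
    """
    los, his = [], []
    for c in curves:
        sd = c["sd"].fillna(0.0).to_numpy()
        los.append(c["mean"].to_numpy() - n_sd * sd)
        his.append(c["mean"].to_numpy() + n_sd * sd)
    lo = np.max(np.vstack(los), axis=0)
    hi = np.min(np.vstack(his), axis=0)
    return float((lo <= hi).mean())


@dataclass
class MaskingInstance:
    sequence_id: str
    mode: str  # "randomize" | "alanine"
    masked_counts: list[int]
    control_counts: list[int]
    test: StatTestResult = field(init=False)

    def __post_init__(self):
        self.test = mann_whitney_u(self.masked_counts, self.control_counts)


def motif_masking_study(
    model: SequenceToCompoundTransformer,
    test: PairDataset,
    train: PairDataset,
    sequence_ids: list[str],
    modes: tuple[str, ...] = ("randomize", "alanine"),
    repeats: int = 10,
    n_samples: int = 400,
    seed: int = 0,
) -> list[MaskingInstance]:
    """Masked-vs-control comparison for each (sequence, mode) instance.

    Each instance runs ``repeats`` independent prediction trials for the
    masked sequence and for a random control modifying the same number of
    residues, and tests the two count distributions with a two-sided
    Mann-Whitney U test.
    """
    freqs = _corpus_frequencies(train, test)
    instances = []
    for i, sid in enumerate(sequence_ids):
        for j, mode in enumerate(modes):
            base = seed + 100_000 * (2 * i + j)
            masked_kind = f"motif_{mode}"
            control_kind = f"motif_random_control_{mode}"
            masked = run_experiment(
                model,
                test,
                sid,
                PerturbationPlan(
                    kind=masked_kind, repeats=repeats, seed=base, n_samples=n_samples
                ),
                freqs,
            )
            control = run_experiment(
                model,
                test,
                sid,
                PerturbationPlan(
                    kind=control_kind,
                    repeats=repeats,
                    seed=base + 50_000,
                    n_samples=n_samples,
                ),
                freqs,
            )
            instances.append(
                MaskingInstance(
                    sid,
                    mode,
                    masked["n_uq_repro"].tolist(),
                    control["n_uq_repro"].tolist(),
                )
            )
    return instances


def _corpus_frequencies(train: PairDataset, test: PairDataset) -> ResidueFrequencies:
    seqs = [r.residues for r in train.sequences.values()]
    seqs += [r.residues for r in test.sequences.values()]
    return residue_frequencies(seqs)
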
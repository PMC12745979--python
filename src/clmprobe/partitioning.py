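"""Train/test partitioning and multi-target compound dilution.

Two 70/30 partition schemes are provided. Sequence-based partitioning
randomly assigns whole sequences (with all their pairs) to sides, so an MT
compound can appear on both sides through different sequences — the leakage
channel under study. Family-based partitioning assigns whole protein
families, removing that channel together with most sequence similarity.

MT dilution converts a fraction of MT compounds into single-target compounds
by deleting all but one of their pairs; at ``retain=0`` every compound has
multiplicity one, so after a sequence split the train and test compound sets
are disjoint. Conversion sets are nested across retain levels for a fixed
seed, making dilution series monotone in expectation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import PairDataset


@dataclass(frozen=True)
class SplitPlan:
    scheme: str = "sequence"  # "sequence" | "family"
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("sequence", "family"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class DilutionSchedule:
    """Ordered retain levels, starting at 1.0 and strictly decreasing."""

    retain_levels: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25, 0.0)
    seed: int = 0

    def __post_init__(self):
        levels = self.retain_levels
        if not levels or levels[0] != 1.0:
            raise ValueError("schedule must start at retain=1.0")
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise ValueError("retain levels must be strictly decreasing")
        if any(not 0.0 <= x <= 1.0 for x in levels):
            raise ValueError("retain levels must lie in [0, 1]")


def _manifest(plan: SplitPlan, train: PairDataset, test: PairDataset) -> dict:
    overlap = train.compounds & test.compounds
    return {
        "scheme": plan.scheme,
        "seed": plan.seed,
        "train_fraction": plan.train_fraction,
        "train": train.summary(),
        "test": test.summary(),
        "mt_compound_overlap": len(overlap),
    }


def split_by_sequence(
    dataset: PairDataset, plan: SplitPlan
) -> tuple[PairDataset, PairDataset]:
    """Randomly divide whole sequences (with their pairs) 70/30."""
    if plan.scheme != "sequence":
        raise ValueError("plan.scheme must be 'sequence'")
    seq_ids = dataset.sequence_ids
    if len(seq_ids) < 2:
        raise ValueError("need at least 2 sequences to split")
    rng = np.random.default_rng(plan.seed)
    order = [seq_ids[i] for i in rng.permutation(len(seq_ids))]
    n_train = round(plan.train_fraction * len(seq_ids))
    n_train = min(max(n_train, 1), len(seq_ids) - 1)
    train_ids, test_ids = order[:n_train], order[n_train:]
    train = dataset.subset_sequences(train_ids)
    test = dataset.subset_sequences(test_ids)
    manifest = _manifest(plan, train, test)
    train.provenance.update({"split": manifest, "side": "train"})
    test.provenance.update({"split": manifest, "side": "test"})
    return train, test


def _choose_family_subset(
    counts: dict[str, int], target: float
) -> set[str]:
    """Pick the family subset whose pair count is closest to ``target``.

    Exact search (all subsets) for up to 20 families, with ties broken by
    fewer train families, then lexicographically; greedy descent beyond.
    Proper subsets only: neither side may be empty.
    """
    families = sorted(counts)
    if len(families) <= 20:
        best: tuple[float, int, tuple[str, ...]] | None = None
        for r in range(1, len(families)):
            for combo in itertools.combinations(families, r):
                total = sum(counts[f] for f in combo)
                key = (abs(total - target), r, combo)
                if best is None or key < best:
                    best = key
        assert best is not None
        return set(best[2])
    chosen: set[str] = set()
    total = 0
    for fam in sorted(families, key=lambda f: -counts[f]):
        if len(chosen) == len(families) - 1:
            break
        if abs(total + counts[fam] - target) < abs(total - target) or not chosen:
            chosen.add(fam)
            total += counts[fam]
    return chosen


def split_by_family(
    dataset: PairDataset, plan: SplitPlan
) -> tuple[PairDataset, PairDataset]:
    """Divide whole protein families, targeting 70% of pairs in train."""
    families = dataset.families
    if len(families) < 2:
        raise ValueError("need at least 2 families for a family split")
    counts = {
        fam: int(
            sum(
                dataset.pairs["sequence_id"].map(
                    lambda s: dataset.sequences[s].family == fam
                )
            )
        )
        for fam in families
    }
    train_families = _choose_family_subset(
        counts, plan.train_fraction * dataset.n_pairs
    )
    train_ids = [
        s for s in dataset.sequence_ids if dataset.sequences[s].family in train_families
    ]
    test_ids = [s for s in dataset.sequence_ids if s not in set(train_ids)]
    train = dataset.subset_sequences(train_ids)
    test = dataset.subset_sequences(test_ids)
    manifest = _manifest(plan, train, test)
    manifest["train_families"] = sorted(train_families)
    train.provenance.update({"split": manifest, "side": "train"})
    test.provenance.update({"split": manifest, "side": "test"})
    return train, test


def dilute_mt(dataset: PairDataset, retain: float, seed: int = 0) -> PairDataset:
    """Convert a fraction (1 - retain) of MT compounds to single-target.

    For each converted compound one pair is kept uniformly at random and the
    others removed. For a fixed seed the converted sets are *nested* across
    retain levels (the compounds converted at retain=0.75 are a subset of
    those converted at 0.5, and so on), because the conversion order and each
    compound's kept pair are derived from the seed alone.
    """
    if not 0.0 <= retain <= 1.0:
        raise ValueError("retain must be in [0, 1]")
    mt = sorted(dataset.mt_compounds())
    rng = np.random.default_rng(seed)
    order = [mt[i] for i in rng.permutation(len(mt))]
    # kept-pair choice drawn for every MT compound so the stream consumed is
    # independent of the retain level — this is what makes levels nested
    kept_draw = {c: rng.random() for c in order}
    n_convert = round((1.0 - retain) * len(mt))
    converted = set(order[:n_convert])

    keep_rows = []
    for smiles, group in dataset.pairs.groupby("smiles", sort=True):
        if smiles in converted:
            rows = group.sort_values("sequence_id")
            keep_rows.append(rows.iloc[int(kept_draw[smiles] * len(rows))])
        else:
            keep_rows.extend(row for _, row in group.iterrows())
    pairs = pd.DataFrame(keep_rows).reset_index(drop=True)
    out = PairDataset(pairs, dict(dataset.sequences), dict(dataset.provenance))
    out.provenance["dilution"] = {
        "retain": retain,
        "seed": seed,
        "n_mt_before": len(mt),
        "n_converted": n_convert,
    }
    return out


def dilution_series(
    dataset: PairDataset, schedule: DilutionSchedule
) -> list[tuple[float, PairDataset]]:
    """Datasets for every retain level of the schedule (nested conversions)."""
    return [
        (retain, dilute_mt(dataset, retain, schedule.seed))
        for retain in schedule.retain_levels
    ]


def write_split_manifest(path: str | Path, dataset: PairDataset) -> None:
    Path(path).write_text(json.dumps(dataset.provenance.get("split", {}), indent=2))
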
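"""Record-level curation of ChEMBL-style activity tables.

Filters retain only direct-binding measurements at the highest assay
confidence (score 9), compounds up to 1,000 Da, targets up to 1,000 residues,
and records not excluded by external anti-target/interference/aggregator
filters (supplied as a boolean flag). Per (compound, target) group, all
records are dropped when repeated measurements disagree by more than an
order of magnitude. Surviving records are collapsed into unique
sequence-compound pairs on canonical nonisomeric SMILES.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .chem import SmilesParseError, canonical_nonisomeric, molecular_weight
from .datasets import PairDataset, SequenceRecord

logger = logging.getLogger(__name__)

MAX_MOLECULAR_WEIGHT = 1000.0  # Da
MAX_SEQUENCE_LENGTH = 1000  # residues
REQUIRED_CONFIDENCE = 9


@dataclass(frozen=True)
class ActivityRecord:
    """One assay measurement linking a compound to a target sequence."""

    compound_smiles: str
    target_id: str
    activity_value: float | None  # nM
    confidence_score: int
    direct_binding: bool = True
    excluded_by_public_filters: bool = False

    def __post_init__(self):
        if self.activity_value is not None and self.activity_value <= 0:
            raise ValueError("activity_value must be positive (nM)")
        if not 0 <= self.confidence_score <= 9:
            raise ValueError("confidence_score must be in [0, 9]")


def _same_order_ratio(values: list[float]) -> bool:
    """True iff max/min <= 10 (scale-free 'same order of magnitude')."""
    return max(values) / min(values) <= 10.0


def _same_order_log_bin(values: list[float]) -> bool:
    """True iff all values share the same floor(log10) bin."""
    return len({math.floor(math.log10(v)) for v in values}) == 1


def filter_records(
    records: list[ActivityRecord],
    sequences: dict[str, SequenceRecord] | dict[str, str],
    order_rule: str = "ratio",
) -> list[ActivityRecord]:
    """Apply the record-level curation filters; idempotent.

    ``order_rule`` selects how "same order of magnitude" is judged for
    repeated (compound, target) measurements: ``"ratio"`` (max/min <= 10,
    default) or ``"log_bin"`` (identical floor-log10 bins).
    """
    same_order = {"ratio": _same_order_ratio, "log_bin": _same_order_log_bin}[order_rule]

    def seq_length(target_id: str) -> int | None:
        rec = sequences.get(target_id)
        if rec is None:
            return None
        return len(rec.residues if isinstance(rec, SequenceRecord) else rec)

    kept: list[ActivityRecord] = []
    for rec in records:
        length = seq_length(rec.target_id)
        if length is None:
            logger.warning("dropping record for unknown target %s", rec.target_id)
            continue
        if length > MAX_SEQUENCE_LENGTH:
            continue
        if rec.confidence_score != REQUIRED_CONFIDENCE:
            continue
        if not rec.direct_binding or rec.excluded_by_public_filters:
            continue
        try:
            if molecular_weight(rec.compound_smiles) > MAX_MOLECULAR_WEIGHT:
                continue
        except SmilesParseError:
            logger.warning("dropping unparseable SMILES %r", rec.compound_smiles)
            continue
        kept.append(rec)

    # Order-of-magnitude consistency per (compound, target) group.
    groups: dict[tuple[str, str], list[float]] = {}
    for rec in kept:
        if rec.activity_value is not None:
            groups.setdefault((rec.compound_smiles, rec.target_id), []).append(
                rec.activity_value
            )
    inconsistent = {
        key for key, vals in groups.items() if len(vals) >= 2 and not same_order(vals)
    }
    return [
        rec
        for rec in kept
        if (rec.compound_smiles, rec.target_id) not in inconsistent
    ]


def build_pairs(
    records: list[ActivityRecord],
    sequences: dict[str, SequenceRecord],
) -> PairDataset:
    """Collapse filtered records into a deduplicated PairDataset.

    SMILES are canonicalized to nonisomeric form, so stereoisomer records of
    the same compound/target merge into one pair; per-compound multiplicity
    (distinct targets) is exposed by the dataset.
    """
    seen: set[tuple[str, str]] = set()
    rows = []
    for rec in records:
        smiles = canonical_nonisomeric(rec.compound_smiles)
        key = (rec.target_id, smiles)
        if key not in seen:
            seen.add(key)
            rows.append(key)
    df = pd.DataFrame(rows, columns=["sequence_id", "smiles"])
    used = set(df["sequence_id"]) if len(df) else set()
    return PairDataset(
        df,
        {sid: sequences[sid] for sid in used},
        {"source": "curation", "n_input_records": len(records)},
    )


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "compound_smiles",
    "target_id",
    "activity_value_nm",
    "confidence_score",
    "direct_binding",
    "excluded_by_public_filters",
]


def read_activity_tsv(path: str | Path) -> list[ActivityRecord]:
    """Read an activity table (see TSV_COLUMNS) into ActivityRecords."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"activity TSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        value = getattr(row, "activity_value_nm")
        records.append(
            ActivityRecord(
                compound_smiles=row.compound_smiles,
                target_id=row.target_id,
                activity_value=None if pd.isna(value) else float(value),
                confidence_score=int(row.confidence_score),
                direct_binding=bool(row.direct_binding),
                excluded_by_public_filters=bool(row.excluded_by_public_filters),
            )
        )
    return records
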
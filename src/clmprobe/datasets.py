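"""Deduplicated sequence-compound pair datasets with multi-target annotation.

A :class:`PairDataset` is the unit everything downstream consumes: a table of
unique (sequence id, canonical SMILES) pairs plus per-sequence metadata
(residue string, protein family label, optional motif ranges). A compound
paired with two or more distinct sequences is a multi-target (MT) compound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with its family label and motif coordinates.

    ``motif_ranges`` are 1-based inclusive residue intervals, the convention
    used by sequence-signature databases.
    """

    sequence_id: str
    residues: str
    family: str
    motif_ranges: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        for start, end in self.motif_ranges:
            if not (1 <= start <= end <= len(self.residues)):
                raise ValueError(
                    f"motif range {start}-{end} outside sequence "
                    f"{self.sequence_id} of length {len(self.residues)}"
                )


@dataclass
class PairDataset:
    """Unique sequence-compound pairs plus sequence metadata.

    ``pairs`` has columns ``sequence_id`` and ``smiles`` (canonical
    nonisomeric). Duplicate pairs are rejected at construction.
    """

    pairs: pd.DataFrame
    sequences: dict[str, SequenceRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pairs = self.pairs.reset_index(drop=True)[["sequence_id", "smiles"]]
        if self.pairs.duplicated().any():
            raise ValueError("duplicate (sequence, compound) pairs")
        unknown = set(self.pairs["sequence_id"]) - set(self.sequences)
        if unknown:
            raise ValueError(f"pairs reference unknown sequences: {sorted(unknown)[:5]}")

    # ---- basic accessors -------------------------------------------------

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def sequence_ids(self) -> list[str]:
        return sorted(set(self.pairs["sequence_id"]))

    @property
    def compounds(self) -> set[str]:
        return set(self.pairs["smiles"])

    @property
    def families(self) -> list[str]:
        return sorted({self.sequences[s].family for s in self.sequence_ids})

    def compounds_of(self, sequence_id: str) -> set[str]:
        return set(self.pairs.loc[self.pairs["sequence_id"] == sequence_id, "smiles"])

    # ---- multi-target structure -----------------------------------------

    def multiplicity(self) -> pd.Series:
        """Distinct-sequence count per unique compound."""
        return self.pairs.groupby("smiles")["sequence_id"].nunique()

    def mt_compounds(self) -> set[str]:
        mult = self.multiplicity()
        return set(mult.index[mult >= 2])

    def mt_fraction(self) -> float:
        mult = self.multiplicity()
        return float((mult >= 2).mean())

    def mean_mt_multiplicity(self) -> float:
        """Mean number of sequences per MT compound (NaN if none)."""
        mult = self.multiplicity()
        mt = mult[mult >= 2]
        return float(mt.mean()) if len(mt) else float("nan")

    def summary(self) -> dict:
        mult = self.multiplicity()
        return {
            "n_pairs": self.n_pairs,
            "n_unique_compounds": int(mult.size),
            "n_sequences": len(self.sequence_ids),
            "n_families": len(self.families),
            "mt_fraction": self.mt_fraction(),
            "mean_mt_multiplicity": self.mean_mt_multiplicity(),
            "mean_multiplicity": float(mult.mean()) if mult.size else float("nan"),
        }

    # ---- derived datasets ------------------------------------------------

    def subset_sequences(self, sequence_ids, provenance: dict | None = None) -> "PairDataset":
        keep = set(sequence_ids)
        sub = self.pairs[self.pairs["sequence_id"].isin(keep)]
        seqs = {s: self.sequences[s] for s in self.sequences if s in keep}
        return PairDataset(sub.copy(), seqs, provenance or dict(self.provenance))

    # ---- I/O -------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        mult = self.multiplicity()
        out = self.pairs.copy()
        out["multiplicity"] = out["smiles"].map(mult)
        out.to_csv(path, sep="\t", index=False)

    def summary_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))
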
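"""Synthetic sequence-compound universes with known ground truth.

The generator emulates the *shape* of a curated bioactivity corpus — protein
families of similar sequences, analog series of compounds sharing a scaffold,
and a controllable multi-target (MT) structure in the pair list — so that
data-leakage and memorization effects of sequence-conditioned compound
generators can be probed against known ground truth, without any database
download.

Construction guarantees:

* families are point-mutated copies of a family ancestor over the 20-letter
  amino-acid alphabet, with a family-specific motif written verbatim into a
  fixed window of every member;
* compounds are substituted ring scaffolds (halogen/alkyl/... substituents
  attached to ring carbons), so every SMILES is valid, canonical and carries
  a known core equal to its series scaffold;
* scaffold sets of different families are disjoint, which is what makes the
  family-holdout phenomenon testable;
* MT compounds are extra assignments of one compound to additional sequences
  of the owning family, with multiplicities drawn from a shifted geometric
  distribution tuned to the configured mean.

With ``motif_coupled=True`` all families share one global ancestor and the
only family-discriminative positions are the motif window — a positive
control in which masking the motif *must* destroy family identity.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import canonical_nonisomeric, is_valid_smiles, murcko_core
from .datasets import PairDataset, SequenceRecord
from .encoding import IUPAC_AMINO_ACIDS

AMINO_ACIDS = IUPAC_AMINO_ACIDS

# Ring systems used as series scaffolds (all carbons carry at least one H).
_RINGS = (
    "c1ccccc1",        # benzene
    "c1ccncc1",        # pyridine
    "c1cncnc1",        # pyrimidine
    "c1ccoc1",         # furan
    "c1ccsc1",         # thiophene
    "c1cc[nH]c1",      # pyrrole
    "C1CCCCC1",        # cyclohexane
    "C1CCNCC1",        # piperidine
    "C1CCOCC1",        # tetrahydropyran
    "c1ccc2ccccc2c1",  # naphthalene
)

# Substituents attached to ring carbons by a single bond (first atom binds).
# Composite linker x terminal fragments give ~40 distinct groups, so the
# combinatorial space per scaffold (two to three substitution sites) runs to
# ~10^4-10^5 analogs — sparse enough that a held-out analog cannot be
# guessed, emulating the sparsity of real analog series in chemical space.
_TERMINALS = (
    "F", "Cl", "Br", "I", "C", "O", "N", "OC", "C#N", "C(F)(F)F",
    "N(C)C", "C(C)C", "CO", "NC",
)
_LINKERS = ("", "C", "CC")
_SUBSTITUENTS = tuple(
    dict.fromkeys(linker + terminal for linker in _LINKERS for terminal in _TERMINALS)
)


class UniverseCapacityError(ValueError):
    """The substituent grammar cannot produce the demanded number of analogs."""


@dataclass(frozen=True)
class UniverseConfig:
    """Parameters of a synthetic sequence-compound universe.

    Defaults give ~40 sequences in 4 families and ~800 pairs, with the MT
    structure calibrated to the corpus-level statistics of curated
    bioactivity data (29% MT compounds, mean 2.91 sequences per MT compound).
    """

    n_families: int = 4
    sequences_per_family: int = 10
    sequence_length: int = 60
    within_family_identity: float = 0.90
    motif_spec: tuple[tuple[str, tuple[int, int], str], ...] | None = None
    n_series_per_family: int = 5
    analogs_per_series: int = 28
    mt_fraction: float = 0.29
    mt_mean_multiplicity: float = 2.91
    compounds_per_sequence: int = 20
    motif_coupled: bool = False
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_families": self.n_families,
            "sequences_per_family": self.sequences_per_family,
            "sequence_length": self.sequence_length,
            "n_series_per_family": self.n_series_per_family,
            "analogs_per_series": self.analogs_per_series,
            "compounds_per_sequence": self.compounds_per_sequence,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.sequence_length > 1000:
            raise ValueError("sequence_length capped at 1,000 residues")
        if not 0.0 <= self.within_family_identity <= 1.0:
            raise ValueError("within_family_identity must be in [0, 1]")
        if not 0.0 <= self.mt_fraction <= 1.0:
            raise ValueError("mt_fraction must be in [0, 1]")
        if self.mt_fraction > 0 and self.mt_mean_multiplicity < 2.0:
            raise ValueError("mt_mean_multiplicity must be >= 2 when MT compounds exist")
        if self.motif_spec is not None:
            for family, (start, end), motif in self.motif_spec:
                if not (1 <= start <= end <= self.sequence_length):
                    raise ValueError(
                        f"motif range {start}-{end} for family {family} exceeds "
                        f"sequence length {self.sequence_length}"
                    )
                if len(motif) != end - start + 1:
                    raise ValueError(
                        f"motif string length {len(motif)} != range span "
                        f"{end - start + 1} for family {family}"
                    )


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str
    series: str
    family: str


@dataclass(frozen=True)
class Violation:
    kind: str
    message: str


@dataclass
class SyntheticUniverse:
    """A generated universe: sequences, compounds, pairs, and ground truth."""

    sequences: dict[str, SequenceRecord]
    compounds: dict[str, CompoundRecord]
    pairs: list[tuple[str, str]]
    series_scaffolds: dict[str, str]
    config: UniverseConfig

    def to_pair_dataset(self) -> PairDataset:
        df = pd.DataFrame(
            {
                "sequence_id": [s for s, _ in self.pairs],
                "smiles": [self.compounds[c].smiles for _, c in self.pairs],
            }
        )
        return PairDataset(
            df, dict(self.sequences), {"source": "synthetic", "config": asdict(self.config)}
        )

    # ---- serialization ---------------------------------------------------

    def sequences_to_fasta(self, path: str | Path | None = None) -> str:
        """FASTA with family and motif ranges as key=value description tokens."""
        buf = io.StringIO()
        for sid in sorted(self.sequences):
            rec = self.sequences[sid]
            motifs = ";".join(f"{a}-{b}" for a, b in rec.motif_ranges)
            buf.write(f">{sid} family={rec.family} motifs={motifs}\n{rec.residues}\n")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    def pairs_to_tsv(self, path: str | Path | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                (i, s, c, self.compounds[c].smiles)
                for i, (s, c) in enumerate(self.pairs)
            ],
            columns=["pair_id", "sequence_id", "compound_id", "smiles"],
        )
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df

    def config_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self.config), indent=2))


def read_fasta_sequences(path: str | Path) -> dict[str, SequenceRecord]:
    """Read sequences written by :meth:`SyntheticUniverse.sequences_to_fasta`."""
    from Bio import SeqIO

    out: dict[str, SequenceRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
        )
        motifs = tuple(
            tuple(int(x) for x in rng.split("-"))
            for rng in fields.get("motifs", "").split(";")
            if rng
        )
        out[rec.id] = SequenceRecord(
            rec.id, str(rec.seq), fields.get("family", ""), motifs
        )
    return out


# ---------------------------------------------------------------------------
# compound grammar
# ---------------------------------------------------------------------------


def _attach(mol: Chem.Mol, atom_idx: int, fragment_smiles: str) -> Chem.Mol:
    """Attach a fragment (binding via its first atom) to ``atom_idx`` by a single bond."""
    frag = Chem.MolFromSmiles(fragment_smiles)
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(atom_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def _substitution_sites(mol: Chem.Mol) -> list[int]:
    """Ring carbons with at least one hydrogen, in atom order."""
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1 and a.IsInRing()
    ]


def _scaffolds_from_rings(rings: tuple[str, ...], n: int) -> list[str]:
    """``n`` distinct canonical scaffolds built from the given ring systems.

    Single rings first, then two-ring scaffolds joined directly or through
    short alkyl linkers.
    """
    out: list[str] = []
    seen: set[str] = set()

    def push(smiles: str) -> None:
        can = canonical_nonisomeric(smiles)
        if can not in seen:
            seen.add(can)
            out.append(can)

    for ring in rings:
        push(ring)
    for linker in ("", "C", "CC"):
        for i, ring_a in enumerate(rings):
            for ring_b in rings[i:]:
                if len(out) >= n:
                    return out[:n]
                mol = Chem.MolFromSmiles(ring_a)
                site = _substitution_sites(mol)[0]
                push(Chem.MolToSmiles(_attach(mol, site, linker + ring_b)))
    if len(out) < n:
        raise UniverseCapacityError(
            f"scaffold grammar exhausted at {len(out)} scaffolds, {n} demanded"
        )
    return out[:n]


def build_family_scaffolds(n_families: int, n_per_family: int) -> list[list[str]]:
    """Per-family scaffold lists over *disjoint ring systems*.

    The ring pool is partitioned round-robin across families and each
    family's scaffolds (single rings and within-family two-ring systems)
    are built only from its own rings. A family held out of training
    therefore withholds entire chemotypes — its ring systems never occur on
    the training side — mirroring how family-based partitioning of real
    corpora removes whole regions of chemical space.
    """
    if n_families > len(_RINGS):
        raise UniverseCapacityError(
            f"at most {len(_RINGS)} families supported (one ring system each)"
        )
    ring_sets: list[list[str]] = [[] for _ in range(n_families)]
    for i, ring in enumerate(_RINGS):
        ring_sets[i % n_families].append(ring)
    return [
        _scaffolds_from_rings(tuple(rings), n_per_family) for rings in ring_sets
    ]


def sample_analogs(
    scaffold: str, n: int, rng: np.random.Generator
) -> list[str]:
    """``n`` distinct analogs of a scaffold, sampled sparsely from its space.

    Each analog carries two or three substituents at random ring-carbon
    sites. Sampling a *sparse random subset* of the (large) substitution
    space — rather than a dense enumeration prefix — mirrors real analog
    series, where the analogs present in a corpus are a tiny fraction of the
    chemically accessible series, so an exact unseen analog cannot be
    guessed by pattern completion. Every analog's Murcko core equals the
    scaffold.
    """
    base = Chem.MolFromSmiles(scaffold)
    sites = _substitution_sites(base)
    analogs: list[str] = []
    seen: set[str] = set()
    stagnation, max_stagnation = 0, 2000  # draws without a new analog
    while stagnation < max_stagnation:
        k = min(int(rng.choice([2, 3], p=[0.6, 0.4])), len(sites))
        chosen_sites = sorted(rng.choice(len(sites), size=k, replace=False))
        mol = base
        for s in chosen_sites:
            sub = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
            mol = _attach(mol, sites[s], sub)
        can = canonical_nonisomeric(Chem.MolToSmiles(mol))
        if can in seen:
            stagnation += 1
            continue
        stagnation = 0
        seen.add(can)
        analogs.append(can)
        if len(analogs) >= n:
            return analogs
    raise UniverseCapacityError(
        f"substituent grammar yielded only {len(analogs)} distinct analogs of "
        f"{scaffold!r} ({n} demanded); space exhausted"
    )


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, ancestor: str, n_mutations: int) -> str:
    """Point-substitute ``n_mutations`` distinct positions, never to the same residue."""
    seq = list(ancestor)
    positions = rng.choice(len(seq), size=n_mutations, replace=False)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != seq[pos]]
        seq[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def _default_motif_spec(
    config: UniverseConfig, rng: np.random.Generator
) -> tuple[tuple[str, tuple[int, int], str], ...]:
    """One motif window per family: same window, family-distinct strings.

    In motif-coupled universes the window is wider (15 residues): there the
    motif is the *only* family-discriminative signal, and the positive
    control requires a signal strong enough for the model to learn at desk
    scale. The motif should stay a small fraction of the sequence, as real
    family signatures are, so that random-position controls rarely corrupt
    it; coupled universes are therefore best generated with longer
    sequences (see the methods note).
    """
    length = min(15 if config.motif_coupled else 12, config.sequence_length)
    start = min(config.sequence_length - length + 1, config.sequence_length // 3 + 1)
    spec = []
    seen: set[str] = set()
    for f in range(config.n_families):
        motif = _random_sequence(rng, length)
        while motif in seen:
            motif = _random_sequence(rng, length)
        seen.add(motif)
        spec.append((f"F{f}", (start, start + length - 1), motif))
    return tuple(spec)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def generate_universe(config: UniverseConfig) -> SyntheticUniverse:
    """Generate a universe deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    families = [f"F{f}" for f in range(config.n_families)]

    motif_spec = (
        config.motif_spec
        if config.motif_spec is not None
        else _default_motif_spec(config, rng)
    )
    motifs_by_family: dict[str, list[tuple[tuple[int, int], str]]] = {
        fam: [] for fam in families
    }
    for fam, rng_pair, motif in motif_spec:
        if fam not in motifs_by_family:
            raise ValueError(f"motif_spec references unknown family {fam}")
        motifs_by_family[fam].append((tuple(rng_pair), motif))

    # --- sequences: mutated ancestors + verbatim motifs -------------------
    # Each member is mutated at half the divergence budget so that *pairwise*
    # identity within a family matches within_family_identity in expectation.
    n_mut = round((1.0 - config.within_family_identity) / 2.0 * config.sequence_length)
    global_ancestor = _random_sequence(rng, config.sequence_length)
    sequences: dict[str, SequenceRecord] = {}
    for fam in families:
        ancestor = (
            global_ancestor
            if config.motif_coupled
            else _random_sequence(rng, config.sequence_length)
        )
        for i in range(config.sequences_per_family):
            residues = list(_mutate(rng, ancestor, n_mut))
            for (start, end), motif in motifs_by_family[fam]:
                residues[start - 1 : end] = list(motif)
            sid = f"{fam}S{i:02d}"
            sequences[sid] = SequenceRecord(
                sid,
                "".join(residues),
                fam,
                tuple(r for r, _ in motifs_by_family[fam]),
            )

    # --- compounds: family-owned analog series -----------------------------
    scaffolds_by_family = build_family_scaffolds(
        config.n_families, config.n_series_per_family
    )
    compounds: dict[str, CompoundRecord] = {}
    series_scaffolds: dict[str, str] = {}
    family_pools: dict[str, list[str]] = {fam: [] for fam in families}
    cpd_counter = 0
    for fi, fam in enumerate(families):
        for k in range(config.n_series_per_family):
            series = f"{fam}.s{k}"
            scaffold = scaffolds_by_family[fi][k]
            series_scaffolds[series] = scaffold
            for smiles in sample_analogs(scaffold, config.analogs_per_series, rng):
                cid = f"CPD{cpd_counter:05d}"
                cpd_counter += 1
                compounds[cid] = CompoundRecord(cid, smiles, series, fam)
                family_pools[fam].append(cid)

    # --- pair list with MT structure ---------------------------------------
    mean_multiplicity = (
        config.mt_fraction * config.mt_mean_multiplicity + (1.0 - config.mt_fraction)
    )
    pairs: list[tuple[str, str]] = []
    used_compounds: dict[str, CompoundRecord] = {}
    for fam in families:
        seq_ids = [f"{fam}S{i:02d}" for i in range(config.sequences_per_family)]
        target_pairs = config.sequences_per_family * config.compounds_per_sequence
        n_unique = max(1, round(target_pairs / mean_multiplicity))
        pool = family_pools[fam]
        if n_unique > len(pool):
            raise UniverseCapacityError(
                f"family {fam} demands {n_unique} unique compounds but the "
                f"series grammar provides {len(pool)}"
            )
        chosen = [pool[j] for j in rng.permutation(len(pool))[:n_unique]]
        n_mt = round(config.mt_fraction * n_unique)
        multiplicities = np.ones(n_unique, dtype=int)
        if n_mt > 0:
            p = 1.0 / (config.mt_mean_multiplicity - 1.0)
            draws = 1 + rng.geometric(p, size=n_mt)
            multiplicities[:n_mt] = np.minimum(draws, len(seq_ids))
        load = {s: 0 for s in seq_ids}
        for cid, mult in zip(chosen, multiplicities):
            ranked = sorted(seq_ids, key=lambda s: (load[s], rng.random()))
            for s in ranked[: int(mult)]:
                pairs.append((s, cid))
                load[s] += 1
            used_compounds[cid] = compounds[cid]

    universe = SyntheticUniverse(
        sequences=sequences,
        compounds=used_compounds,
        pairs=pairs,
        series_scaffolds=series_scaffolds,
        config=config,
    )
    return universe


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_IDENTITY_TOLERANCE = 0.05


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / max(len(a), len(b))


def validate_universe(universe: SyntheticUniverse) -> list[Violation]:
    """Check universe invariants; empty list iff all hold."""
    violations: list[Violation] = []

    seen_pairs = set()
    for sid, cid in universe.pairs:
        if sid not in universe.sequences:
            violations.append(
                Violation("dangling_sequence", f"pair references missing sequence {sid}")
            )
        if cid not in universe.compounds:
            violations.append(
                Violation("dangling_compound", f"pair references missing compound {cid}")
            )
        if (sid, cid) in seen_pairs:
            violations.append(Violation("duplicate_pair", f"duplicate pair ({sid}, {cid})"))
        seen_pairs.add((sid, cid))

    for cid, rec in universe.compounds.items():
        if not is_valid_smiles(rec.smiles):
            violations.append(Violation("invalid_smiles", f"{cid}: {rec.smiles!r}"))
        elif canonical_nonisomeric(rec.smiles) != rec.smiles:
            violations.append(Violation("non_canonical", f"{cid}: {rec.smiles!r}"))
        elif rec.series in universe.series_scaffolds:
            core = murcko_core(rec.smiles)
            if core != universe.series_scaffolds[rec.series]:
                violations.append(
                    Violation("core_mismatch", f"{cid}: core {core!r} != series scaffold")
                )

    motif_lookup: dict[str, list[tuple[tuple[int, int], str]]] = {}
    spec = universe.config.motif_spec
    if spec is None:
        # reconstruct expected motif strings from any member (majority-free:
        # verbatim write means all members agree unless corrupted)
        pass
    else:
        for fam, rng_pair, motif in spec:
            motif_lookup.setdefault(fam, []).append((tuple(rng_pair), motif))

    by_family: dict[str, list[SequenceRecord]] = {}
    for rec in universe.sequences.values():
        by_family.setdefault(rec.family, []).append(rec)
    for fam, members in by_family.items():
        for (start, end) in {r for m in members for r in m.motif_ranges}:
            windows = {m.residues[start - 1 : end] for m in members}
            if len(windows) != 1:
                violations.append(
                    Violation(
                        "motif_mismatch",
                        f"family {fam} members disagree in motif window {start}-{end}",
                    )
                )
        expected = motif_lookup.get(fam, [])
        for (start, end), motif in expected:
            for m in members:
                if m.residues[start - 1 : end] != motif:
                    violations.append(
                        Violation(
                            "motif_mismatch",
                            f"{m.sequence_id} motif window {start}-{end} != spec",
                        )
                    )
        threshold = universe.config.within_family_identity - _IDENTITY_TOLERANCE
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if _identity(a.residues, b.residues) < threshold:
                    violations.append(
                        Violation(
                            "family_identity",
                            f"{a.sequence_id} vs {b.sequence_id} below "
                            f"{threshold:.2f} identity",
                        )
                    )

    if not universe.config.motif_coupled:
        fam_scaffolds: dict[str, set[str]] = {}
        for series, scaffold in universe.series_scaffolds.items():
            fam_scaffolds.setdefault(series.split(".")[0], set()).add(scaffold)
        fams = sorted(fam_scaffolds)
        for i, fa in enumerate(fams):
            for fb in fams[i + 1 :]:
                overlap = fam_scaffolds[fa] & fam_scaffolds[fb]
                if overlap:
                    violations.append(
                        Violation(
                            "scaffold_overlap",
                            f"families {fa}/{fb} share scaffolds {sorted(overlap)}",
                        )
                    )

    return violations
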
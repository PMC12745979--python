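"""RDKit-backed chemistry primitives shared across the package.

All compound identity in this package is defined on canonical *nonisomeric*
SMILES: stereochemistry and isotope labels are stripped before
canonicalization, so ``C[C@H](N)O`` and ``CC(N)O`` denote the same compound.
"""

from __future__ import annotations

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.DataStructs import BulkTanimotoSimilarity, TanimotoSimilarity

RDLogger.DisableLog("rdApp.*")

MORGAN_RADIUS = 2
MORGAN_NBITS = 2048

_morgan = rdFingerprintGenerator.GetMorganGenerator(
    radius=MORGAN_RADIUS, fpSize=MORGAN_NBITS
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse ``smiles``, raising :class:`SmilesParseError` on failure."""
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def is_valid_smiles(smiles: str) -> bool:
    return bool(smiles) and Chem.MolFromSmiles(smiles) is not None


def canonical_nonisomeric(smiles: str) -> str:
    """Canonical SMILES with stereochemistry and isotopes removed."""
    mol = mol_from_smiles(smiles)
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    return Chem.MolToSmiles(mol, isomericSmiles=False)


def molecular_weight(smiles: str) -> float:
    """Average molecular weight in Da, implicit hydrogens included."""
    return Descriptors.MolWt(mol_from_smiles(smiles))


def murcko_core(smiles: str) -> str:
    """Scaffold (ring systems + linkers, side chains removed) as canonical SMILES.

    Acyclic molecules have an empty Murcko scaffold; by convention the
    molecule itself is returned as its own core so that every compound
    maps to a non-empty core.
    """
    mol = mol_from_smiles(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return canonical_nonisomeric(smiles)
    Chem.RemoveStereochemistry(scaffold)
    return Chem.MolToSmiles(scaffold, isomericSmiles=False)


def morgan_fingerprint(smiles: str):
    """2,048-bit binary Morgan fingerprint, radius 2."""
    return _morgan.GetFingerprint(mol_from_smiles(smiles))


def morgan_tanimoto(a: str, b: str) -> float:
    """Tanimoto similarity of two molecules on hashed circular fingerprints."""
    return float(TanimotoSimilarity(morgan_fingerprint(a), morgan_fingerprint(b)))


def nearest_neighbor_similarities(
    queries: list[str], reference: list[str]
) -> list[float]:
    """For each query SMILES, max Tanimoto similarity over ``reference``."""
    if not reference:
        raise ValueError("reference set is empty")
    ref_fps = [morgan_fingerprint(s) for s in reference]
    out = []
    for q in queries:
        sims = BulkTanimotoSimilarity(morgan_fingerprint(q), ref_fps)
        out.append(float(max(sims)))
    return out
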
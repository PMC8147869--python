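"""Structure handling: SMILES canonicalization, hashed circular fingerprints
and Tanimoto similarity."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from promsets.errors import ContractError, SmilesParseError

RDLogger.DisableLog("rdApp.*")

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary substructure fingerprint (set-bit indices)."""

    bits: frozenset[int]
    n_bits: int
    radius: int

    def __post_init__(self) -> None:
        if self.n_bits <= 0 or self.n_bits & (self.n_bits - 1):
            raise ValueError(f"n_bits must be a power of two, got {self.n_bits}")
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ValueError("bit index out of range")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def canonicalize_smiles(smiles: str) -> str:
    """Canonical aromatic SMILES with stereochemistry stripped.

    Idempotent; stereoisomers map to the same string. Raises
    :class:`SmilesParseError` on unparsable input.
    """
    mol = _mol_from_smiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol, isomericSmiles=False)


@lru_cache(maxsize=8)
def _generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def fingerprint(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> Fingerprint:
    """Hashed circular fingerprint of the canonical structure.

    Deterministic for a given input and parameters; two SMILES spellings of
    the same molecule yield identical fingerprints.
    """
    mol = _mol_from_smiles(canonicalize_smiles(smiles))
    fp = _generator(radius, n_bits).GetFingerprint(mol)
    return Fingerprint(bits=frozenset(fp.GetOnBits()), n_bits=n_bits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b| over set bits."""
    if a.n_bits != b.n_bits:
        raise ContractError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        raise ContractError("tanimoto undefined for two empty fingerprints")
    return len(a.bits & b.bits) / union


def fingerprint_map(
    smiles_by_cid: dict[str, str],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> dict[str, Fingerprint]:
    """Fingerprints for a compound-id → SMILES mapping."""
    return {cid: fingerprint(s, radius=radius, n_bits=n_bits) for cid, s in smiles_by_cid.items()}
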
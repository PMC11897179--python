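"""SMILES handling, Morgan fingerprints, and maximum Tanimoto similarity (MTS).

The unit of similarity throughout the package is the binary Morgan
(ECFP-style) fingerprint, radius 2 folded to 2048 bits by default.  A
prediction model's applicability domain (AD) is defined by the maximum
Tanimoto similarity of a query against the model's training fingerprints:
``max_tanimoto`` is that reliability score ``s``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger("reliamol")

RDLogger.DisableLog("rdApp.*")  # rdkit parse noise; invalid SMILES are reported via exceptions

DEFAULT_RADIUS = 2
DEFAULT_NBITS = 2048


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class DimensionMismatchError(ValueError):
    """Raised when fingerprints of different dimension are compared."""


class EmptyReferenceSetError(ValueError):
    """Raised when MTS is requested against an empty reference set."""


@dataclass(frozen=True)
class Molecule:
    """A molecule identified by its toolkit-canonical SMILES."""

    smiles: str
    n_heavy_atoms: int

    def __post_init__(self) -> None:
        if self.n_heavy_atoms < 1:
            raise ValueError("molecule must have at least one heavy atom")


@dataclass(frozen=True)
class Fingerprint:
    """Sparse binary fingerprint: the set of on-bit indices.

    The similarity contract is defined on bit *sets*; any packed
    representation is an implementation detail of the producers.
    """

    bits: frozenset[int]
    nbits: int = DEFAULT_NBITS
    radius: int = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if any(b < 0 or b >= self.nbits for b in self.bits):
            raise ValueError("bit index out of range")

    @property
    def n_on(self) -> int:
        return len(self.bits)


@dataclass
class ReferenceSet:
    """Ordered collection of fingerprints, e.g. a model's training set."""

    fingerprints: list[Fingerprint]
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.source_ids:
            self.source_ids = [str(i) for i in range(len(self.fingerprints))]
        if len(self.source_ids) != len(self.fingerprints):
            raise ValueError("source_ids must parallel fingerprints")
        dims = {(fp.radius, fp.nbits) for fp in self.fingerprints}
        if len(dims) > 1:
            raise DimensionMismatchError(f"mixed fingerprint dimensions: {dims}")

    def __len__(self) -> int:
        return len(self.fingerprints)


def canonicalize(smiles: str) -> Molecule:
    """Parse a SMILES string and return a canonical :class:`Molecule`.

    Canonicalization is idempotent: feeding the canonical SMILES back
    returns the same string.  Raises :class:`InvalidSmilesError` on
    unparseable input.
    """
    if not smiles or not smiles.strip():
        raise InvalidSmilesError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {smiles!r}")
    return Molecule(smiles=Chem.MolToSmiles(mol), n_heavy_atoms=mol.GetNumHeavyAtoms())


def is_valid_smiles(smiles: str) -> bool:
    try:
        canonicalize(smiles)
        return True
    except InvalidSmilesError:
        return False


def morgan_fingerprint(
    mol: Molecule | str,
    radius: int = DEFAULT_RADIUS,
    nbits: int = DEFAULT_NBITS,
) -> Fingerprint:
    """Binary Morgan fingerprint of a molecule (default radius 2, 2048 bits)."""
    smiles = mol.smiles if isinstance(mol, Molecule) else canonicalize(mol).smiles
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:  # pragma: no cover - canonical SMILES always reparse
        raise InvalidSmilesError(smiles)
    gen = _fp_generator(radius, nbits)
    on_bits = gen.GetFingerprint(rdmol).GetOnBits()
    return Fingerprint(bits=frozenset(on_bits), nbits=nbits, radius=radius)


_GENERATORS: dict[tuple[int, int], object] = {}


def _fp_generator(radius: int, nbits: int):
    key = (radius, nbits)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits
        )
    return _GENERATORS[key]


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity |a∩b| / |a∪b| between two fingerprints.

    Two empty fingerprints have similarity 0.0: featureless inputs never
    signal similarity.
    """
    if a.nbits != b.nbits:
        raise DimensionMismatchError(f"nbits mismatch: {a.nbits} vs {b.nbits}")
    if not a.bits and not b.bits:
        return 0.0
    inter = len(a.bits & b.bits)
    union = len(a.bits) + len(b.bits) - inter
    return inter / union


def max_tanimoto(query: Fingerprint, refs: ReferenceSet) -> float:
    """Maximum Tanimoto similarity of ``query`` against a reference set.

    This is the reliability score ``s`` of a prediction: the closer the
    query sits to the training data, the closer ``s`` is to 1.
    """
    if len(refs) == 0:
        raise EmptyReferenceSetError("reference set is empty")
    return max(tanimoto(query, r) for r in refs.fingerprints)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_smiles_file(path: str | Path) -> list[tuple[str, Molecule]]:
    """Read a .smi file (one SMILES per line, optional whitespace-separated id).

    Invalid rows are logged and skipped; the skip count is reported once.
    """
    records: list[tuple[str, Molecule]] = []
    skipped = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        ident = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
        try:
            records.append((ident, canonicalize(smiles)))
        except InvalidSmilesError:
            logger.warning("skipping invalid SMILES at %s:%d: %r", path, lineno, smiles)
            skipped += 1
    if skipped:
        logger.info("read %d molecules from %s (%d invalid rows skipped)", len(records), path, skipped)
    return records


def read_smiles_csv(
    path: str | Path, smiles_column: str = "smiles", value_column: str | None = None
) -> list[tuple[str, Molecule, float | None]]:
    """Read molecules (and optionally a numeric value column) from CSV."""
    records: list[tuple[str, Molecule, float | None]] = []
    skipped = 0
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or smiles_column not in reader.fieldnames:
            raise ValueError(f"CSV {path} lacks a {smiles_column!r} column")
        for i, row in enumerate(reader):
            try:
                mol = canonicalize(row[smiles_column])
                value = float(row[value_column]) if value_column else None
            except (InvalidSmilesError, ValueError, TypeError):
                logger.warning("skipping invalid row %d in %s", i, path)
                skipped += 1
                continue
            ident = row.get("id", str(i))
            records.append((ident, mol, value))
    if skipped:
        logger.info("read %d rows from %s (%d skipped)", len(records), path, skipped)
    return records


def write_smiles_csv(path: str | Path, records: Iterable[tuple[str, Molecule]]) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["id", "canonical_smiles"])
        for ident, mol in records:
            writer.writerow([ident, mol.smiles])


def reference_set_from_molecules(
    molecules: Sequence[Molecule],
    ids: Sequence[str] | None = None,
    radius: int = DEFAULT_RADIUS,
    nbits: int = DEFAULT_NBITS,
) -> ReferenceSet:
    fps = [morgan_fingerprint(m, radius=radius, nbits=nbits) for m in molecules]
    return ReferenceSet(fingerprints=fps, source_ids=list(ids) if ids else [])
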
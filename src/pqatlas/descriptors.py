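"""Molecular representations: MQN count vectors, ECFP4 fingerprints, property panel.

Molecules enter the pipeline as SMILES lines. Every downstream stage works on
one of three representations computed here:

* the 42-dimensional MQN (molecular quantum numbers) count vector — integer
  counts of atom types, bond types, polar groups and topological features —
  which is the embedding that gets product-quantized and clustered;
* the ECFP4 circular substructure fingerprint (radius 2, folded), compared by
  Tanimoto similarity, used for the per-cluster secondary maps;
* a nine-descriptor physicochemical panel (MW, HAC, rings, RBC, HBD, HBA,
  TPSA, FCsp3, aromatic atom count) used for cluster-dispersion diagnostics
  and for colouring map nodes.

All values come from RDKit and are pure functions of the canonical SMILES, so
permuting the input never changes a per-molecule value.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator, rdMolDescriptors

logger = logging.getLogger(__name__)

# silence per-molecule parse warnings; invalid records are counted instead
RDLogger.DisableLog("rdApp.error")

MQN_DIM = 42
PANEL_COLUMNS = (
    "MW",
    "HAC",
    "rings",
    "RBC",
    "HBD",
    "HBA",
    "TPSA",
    "FCsp3",
    "aromatic_atoms",
)


@dataclass(frozen=True)
class MoleculeRecord:
    """One parsed input line.

    ``id`` is the stable integer index within the dataset, ``smiles`` the
    canonical SMILES when ``valid`` (the raw token otherwise), ``name`` an
    optional identifier column carried through as metadata.
    """

    id: int
    smiles: str
    valid: bool
    name: str | None = None


@dataclass(frozen=True)
class DescriptorPanel:
    MW: float
    HAC: int
    rings: int
    RBC: int
    HBD: int
    HBA: int
    TPSA: float
    FCsp3: float
    aromatic_atoms: int

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, c) for c in PANEL_COLUMNS)


def parse_smiles(line: str, id: int = 0) -> MoleculeRecord:
    """Parse one SMILES line into a :class:`MoleculeRecord`.

    Never raises on bad input: an unparseable token yields ``valid=False``.
    Accepts both a bare SMILES and a ``SMILES<TAB>name`` dialect; the name is
    preserved as metadata. Canonical SMILES is stored for valid records, so
    ``"C1CC1"`` and ``"C1CC1 "`` produce identical records.
    """
    token = line.strip()
    name: str | None = None
    if "\t" in token:
        token, name = token.split("\t", 1)
        name = name.strip() or None
    elif " " in token:
        token, name = token.split(None, 1)
        name = name.strip() or None
    mol = Chem.MolFromSmiles(token) if token else None
    if mol is None:
        return MoleculeRecord(id=id, smiles=token, valid=False, name=name)
    return MoleculeRecord(id=id, smiles=Chem.MolToSmiles(mol), valid=True, name=name)


def read_smiles(path: str | Path, start_id: int = 0) -> Iterator[MoleculeRecord]:
    """Stream molecule records from a SMILES line file (plain or gzip).

    One molecule per line; blank lines are skipped; invalid lines are yielded
    with ``valid=False`` so callers can count skips.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    idx = start_id
    with opener(path, "rt") as handle:
        for line in handle:
            if not line.strip():
                continue
            yield parse_smiles(line, id=idx)
            idx += 1


@lru_cache(maxsize=8)
def _morgan_generator(n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)


def _require_valid(record: MoleculeRecord) -> Chem.Mol:
    if not record.valid:
        raise ValueError(f"molecule {record.id} ({record.smiles!r}) is not a valid structure")
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:  # pragma: no cover - canonical SMILES always reparses
        raise ValueError(f"canonical SMILES failed to reparse: {record.smiles!r}")
    return mol


def compute_mqn(record: MoleculeRecord) -> np.ndarray:
    """42 MQN counts for a valid record (non-negative integers)."""
    mol = _require_valid(record)
    return np.asarray(rdMolDescriptors.MQNs_(mol), dtype=np.int64)


def compute_ecfp4(record: MoleculeRecord, n_bits: int = 2048) -> np.ndarray:
    """Radius-2 circular (ECFP4) fingerprint folded to ``n_bits`` booleans."""
    if n_bits <= 0 or (n_bits & (n_bits - 1)) != 0:
        raise ValueError(f"n_bits must be a power of two, got {n_bits}")
    mol = _require_valid(record)
    gen = _morgan_generator(n_bits)
    arr = np.zeros(n_bits, dtype=bool)
    arr[list(gen.GetFingerprint(mol).GetOnBits())] = True
    return arr


def compute_panel(record: MoleculeRecord) -> DescriptorPanel:
    """The nine-descriptor physicochemical panel for dispersion diagnostics."""
    mol = _require_valid(record)
    return DescriptorPanel(
        MW=float(Descriptors.MolWt(mol)),
        HAC=int(mol.GetNumHeavyAtoms()),
        rings=int(rdMolDescriptors.CalcNumRings(mol)),
        RBC=int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        HBD=int(rdMolDescriptors.CalcNumHBD(mol)),
        HBA=int(rdMolDescriptors.CalcNumHBA(mol)),
        TPSA=float(rdMolDescriptors.CalcTPSA(mol)),
        FCsp3=float(rdMolDescriptors.CalcFractionCSP3(mol)),
        aromatic_atoms=sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()),
    )


def mqn_matrix(records: Iterable[MoleculeRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack MQN vectors for all valid records.

    Returns ``(ids, X)`` where ``X`` has shape ``(n_valid, 42)``. Invalid
    records are skipped with a logged count rather than aborting the stream.
    """
    ids: list[int] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for rec in records:
        if not rec.valid:
            skipped += 1
            continue
        ids.append(rec.id)
        rows.append(compute_mqn(rec))
    if skipped:
        logger.info("mqn_matrix: skipped %d invalid molecules", skipped)
    X = np.vstack(rows) if rows else np.empty((0, MQN_DIM), dtype=np.int64)
    return np.asarray(ids, dtype=np.int64), X


def ecfp_matrix(
    records: Iterable[MoleculeRecord], n_bits: int = 2048
) -> tuple[np.ndarray, np.ndarray]:
    """Stack ECFP4 fingerprints for all valid records (bool matrix)."""
    ids: list[int] = []
    rows: list[np.ndarray] = []
    for rec in records:
        if not rec.valid:
            continue
        ids.append(rec.id)
        rows.append(compute_ecfp4(rec, n_bits=n_bits))
    X = np.vstack(rows) if rows else np.empty((0, n_bits), dtype=bool)
    return np.asarray(ids, dtype=np.int64), X


def panel_frame(records: Sequence[MoleculeRecord]):
    """Panel descriptors for valid records as a pandas DataFrame indexed by id."""
    import pandas as pd

    data = {c: [] for c in PANEL_COLUMNS}
    ids = []
    for rec in records:
        if not rec.valid:
            continue
        panel = compute_panel(rec)
        ids.append(rec.id)
        for c in PANEL_COLUMNS:
            data[c].append(getattr(panel, c))
    return pd.DataFrame(data, index=pd.Index(ids, name="id"))


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| between two binary fingerprints.

    Two empty fingerprints have similarity 1 by convention (identical sets).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
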
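"""Compound library ingest, fingerprints, descriptors and sharding.

Compounds are carried through the pipeline as :class:`CompoundRecord` objects
holding a canonical SMILES, a 1024-bit Morgan fingerprint (radius 2) stored as
a dense ``uint8`` 0/1 vector, and the three descriptors the downstream stages
need: molecular mass ``m`` (Da), the rotatable-bond count ``n_rotor`` and the
calculated octanol/water partition coefficient cLogP.

Supported input formats are ``.smi`` (whitespace-separated SMILES + id), CSV
with ``id,smiles[,...]`` columns, and SDF (V2000).  Unparseable structures are
skipped and counted in a rejection ledger rather than aborting the run.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

DEFAULT_FP_BITS = 1024
DEFAULT_FP_RADIUS = 2

#: Strict rotatable-bond SMARTS: a non-ring single bond between two non-terminal
#: heavy atoms, excluding amide C-N bonds.  This is RDKit's "strict" definition
#: (Lipinski.NumRotatableBonds with BondRotIntLigand strictness); n-hexane
#: counts 3 rotatable bonds under it.
ROTATABLE_BOND_SMARTS = (
    "[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]"
)


class LibraryError(ValueError):
    """Raised for malformed libraries (duplicate ids, unknown formats...)."""


@dataclass
class CompoundRecord:
    """One library member.

    ``smiles`` is canonicalized on ingest so duplicate detection is
    structure-based; the raw input string is preserved in ``raw_smiles``.
    """

    id: str
    smiles: str
    raw_smiles: str = ""
    fingerprint: np.ndarray | None = None
    mol_mass: float | None = None
    n_rotor: int | None = None
    clogp: float | None = None
    heavy_atoms: int | None = None
    source: str = ""
    flagged: bool = False
    flag_reason: str = ""

    def __post_init__(self) -> None:
        if not self.raw_smiles:
            self.raw_smiles = self.smiles


@dataclass
class RejectionLedger:
    """Counts and reasons for rows skipped on ingest."""

    n_read: int = 0
    n_accepted: int = 0
    rejected: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def reject(self, identifier: str, reason: str) -> None:
        self.rejected.append((identifier, reason))


@dataclass
class LibraryShard:
    shard_index: int
    records: list[CompoundRecord]
    batch_size: int


# ---------------------------------------------------------------------------
# fingerprints and similarity
# ---------------------------------------------------------------------------

def compute_fingerprint(
    smiles: str, radius: int = DEFAULT_FP_RADIUS, n_bits: int = DEFAULT_FP_BITS
) -> np.ndarray:
    """Morgan fingerprint of ``smiles`` as a dense uint8 0/1 vector.

    Deterministic: the same SMILES always yields the same vector.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise LibraryError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two 0/1 bit vectors.

    Two all-zero vectors are defined to be identical (similarity 1.0).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise LibraryError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(np.logical_and(a, b)))
    union = int(np.count_nonzero(np.logical_or(a, b)))
    if union == 0:
        return 1.0
    return inter / union


def tanimoto_matrix(fps: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto between rows of ``fps`` (n,b) and ``refs`` (m,b).

    Vectorized over both axes; empty-vs-empty pairs score 1.0 as in
    :func:`tanimoto`.
    """
    fps = np.asarray(fps, dtype=np.float32)
    refs = np.asarray(refs, dtype=np.float32)
    inter = fps @ refs.T
    pops_a = fps.sum(axis=1, keepdims=True)
    pops_b = refs.sum(axis=1, keepdims=True).T
    union = pops_a + pops_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

class RDKitDescriptorProvider:
    """Default descriptor provider backed by the chemistry toolkit.

    Supplies molecular mass, strict rotatable-bond count and Crippen cLogP.
    """

    def __call__(self, smiles: str) -> dict:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise LibraryError(f"unparseable SMILES: {smiles!r}")
        return {
            "mol_mass": float(Descriptors.MolWt(mol)),
            "n_rotor": int(Lipinski.NumRotatableBonds(mol)),
            "clogp": float(Crippen.MolLogP(mol)),
            "heavy_atoms": int(mol.GetNumHeavyAtoms()),
        }


def compute_descriptors(
    record: CompoundRecord, provider=None
) -> CompoundRecord:
    """Populate ``mol_mass``, ``n_rotor``, ``clogp`` (idempotent).

    Provider failures flag the record instead of dropping it.
    """
    if provider is None:
        provider = RDKitDescriptorProvider()
    try:
        desc = provider(record.smiles)
    except Exception as exc:  # provider contract: flag, never drop
        return replace(record, flagged=True, flag_reason=str(exc))
    return replace(
        record,
        mol_mass=desc["mol_mass"],
        n_rotor=desc["n_rotor"],
        clogp=desc["clogp"],
        heavy_atoms=desc.get("heavy_atoms"),
    )


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

def _canonicalize(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _iter_smi(path: str) -> Iterator[tuple[str, str]]:
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"mol{i}"
            yield cid, smiles


def _iter_csv(path: str) -> Iterator[tuple[str, str]]:
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns or "smiles" not in df.columns:
        raise LibraryError(f"CSV {path} must have 'id' and 'smiles' columns")
    for row in df.itertuples(index=False):
        yield str(row.id), str(row.smiles)


def _iter_sdf(path: str) -> Iterator[tuple[str, str]]:
    supplier = Chem.SDMolSupplier(path, sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            yield f"sdf_record_{i}", "<unparseable>"
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        yield cid, Chem.MolToSmiles(mol)


def read_compound_table(
    path: str,
    format: str | None = None,
    fp_bits: int = DEFAULT_FP_BITS,
    fp_radius: int = DEFAULT_FP_RADIUS,
    compute_fps: bool = True,
    descriptors: bool = True,
    source: str = "",
) -> tuple[list[CompoundRecord], RejectionLedger]:
    """Read a compound table (.smi, .csv or .sdf) into records.

    Invalid structures are skipped and recorded in the returned
    :class:`RejectionLedger`; duplicate ids raise :class:`LibraryError`.
    An empty file yields an empty record list (not an error).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").lower()
    if format == "smi":
        rows: Iterable[tuple[str, str]] = _iter_smi(path)
    elif format == "csv":
        rows = _iter_csv(path)
    elif format == "sdf":
        rows = _iter_sdf(path)
    else:
        raise LibraryError(f"unknown format: {format!r}")

    ledger = RejectionLedger()
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    provider = RDKitDescriptorProvider() if descriptors else None
    for cid, smiles in rows:
        ledger.n_read += 1
        canonical = _canonicalize(smiles)
        if canonical is None:
            ledger.reject(cid, f"unparseable SMILES: {smiles!r}")
            continue
        if cid in seen:
            raise LibraryError(f"duplicate compound id: {cid!r}")
        seen.add(cid)
        rec = CompoundRecord(id=cid, smiles=canonical, raw_smiles=smiles, source=source)
        if compute_fps:
            rec.fingerprint = compute_fingerprint(canonical, fp_radius, fp_bits)
        if descriptors:
            rec = compute_descriptors(rec, provider)
        records.append(rec)
        ledger.n_accepted += 1
    return records, ledger


def fingerprint_to_hex(fp: np.ndarray) -> str:
    return np.packbits(np.asarray(fp, dtype=np.uint8)).tobytes().hex()


def fingerprint_from_hex(s: str, n_bits: int = DEFAULT_FP_BITS) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(s), dtype=np.uint8)
    return np.unpackbits(raw)[:n_bits].astype(np.uint8)


def write_library(records: Sequence[CompoundRecord], path: str) -> None:
    """Write records as a compact CSV (fingerprints hex-packed)."""
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "fingerprint": [
                fingerprint_to_hex(r.fingerprint) if r.fingerprint is not None else ""
                for r in records
            ],
            "mol_mass": [r.mol_mass for r in records],
            "n_rotor": [r.n_rotor for r in records],
            "clogp": [r.clogp for r in records],
            "heavy_atoms": [r.heavy_atoms for r in records],
            "source": [r.source for r in records],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_library(path: str, n_bits: int = DEFAULT_FP_BITS) -> list[CompoundRecord]:
    """Read a library written by :func:`write_library`."""
    df = pd.read_csv(
        path, dtype={"id": str}, keep_default_na=False, float_precision="round_trip"
    )
    records = []
    for row in df.itertuples(index=False):
        fp = fingerprint_from_hex(row.fingerprint, n_bits) if row.fingerprint else None
        records.append(
            CompoundRecord(
                id=str(row.id),
                smiles=row.smiles,
                fingerprint=fp,
                mol_mass=float(row.mol_mass) if row.mol_mass != "" else None,
                n_rotor=int(float(row.n_rotor)) if row.n_rotor != "" else None,
                clogp=float(row.clogp) if row.clogp != "" else None,
                heavy_atoms=int(float(row.heavy_atoms)) if row.heavy_atoms != "" else None,
                source=str(row.source),
            )
        )
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise LibraryError("duplicate compound ids in library file")
    return records


# ---------------------------------------------------------------------------
# sharding
# ---------------------------------------------------------------------------

def shard_batches(
    records: Sequence[CompoundRecord], batch_size: int
) -> list[LibraryShard]:
    """Split records into order-preserving shards of ``batch_size``.

    Every shard except possibly the last has exactly ``batch_size`` records;
    concatenating shards in index order reproduces the input order.
    """
    if batch_size < 1:
        raise LibraryError(f"batch_size must be >= 1, got {batch_size}")
    shards = []
    for i, start in enumerate(range(0, len(records), batch_size)):
        shards.append(
            LibraryShard(
                shard_index=i,
                records=list(records[start : start + batch_size]),
                batch_size=batch_size,
            )
        )
    return shards
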
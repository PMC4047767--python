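"""Reading/writing molecule sets and converting LD50 doses to the modeling scale.

Activities are modeled as -log10(mol/kg): larger values mean higher toxicity.
Supported structure inputs are SMILES files (``.smi``, one ``SMILES<TAB>id``
per line), SD files, and CSV/TSV tables with an ``id,smiles[,activity]`` or
``id,smiles,ld50_mg_per_kg,mw`` header.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")


class MolIOError(ValueError):
    """Raised for unreadable inputs, duplicate ids, or empty compound sets."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A single identified structure with optional activity.

    ``structure`` is stored as a canonical SMILES so that identical molecules
    produce identical features regardless of the input SMILES dialect.
    ``activity`` is on the -log10(mol/kg) scale.
    """

    id: str
    structure: str
    activity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.activity is not None and not math.isfinite(self.activity):
            raise MolIOError(f"non-finite activity for record {self.id!r}")

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.structure)
        if mol is None:  # pragma: no cover - structure was canonicalized on ingest
            raise MolIOError(f"stored structure for {self.id!r} no longer parses")
        return mol


@dataclass
class CompoundSet:
    """An ordered collection of molecule records acting as reference or query set."""

    records: list[MoleculeRecord]
    role: str = "reference"
    failures: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ("reference", "query"):
            raise MolIOError(f"unknown role {self.role!r}")
        if self.role == "reference" and not self.records:
            raise MolIOError("reference compound set must be non-empty")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise MolIOError(f"duplicate compound id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    @property
    def activities(self) -> list[Optional[float]]:
        return [rec.activity for rec in self.records]

    def activity_array(self):
        import numpy as np

        vals = [rec.activity for rec in self.records]
        if any(v is None for v in vals):
            missing = [r.id for r in self.records if r.activity is None]
            raise MolIOError(f"records without activity: {missing[:5]}")
        return np.asarray(vals, dtype=float)


def canonical_smiles(smiles: str) -> Optional[str]:
    """Canonical SMILES for ``smiles``, or None if it does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def convert_ld50(dose_mg_per_kg: float, mol_weight_g_per_mol: float) -> float:
    """Convert an LD50 dose in mg/kg to -log10(mol/kg).

    The dose is divided by 1000 * MW (mg -> g -> mol) before taking the
    negative decadic logarithm, so the result is strictly decreasing in dose
    and increasing in molecular weight.
    """
    if not (dose_mg_per_kg > 0):
        raise MolIOError(f"dose must be positive, got {dose_mg_per_kg}")
    if not (mol_weight_g_per_mol > 0):
        raise MolIOError(f"molecular weight must be positive, got {mol_weight_g_per_mol}")
    mol_per_kg = dose_mg_per_kg / (1000.0 * mol_weight_g_per_mol)
    return -math.log10(mol_per_kg)


def _read_activity_csv(path: Path) -> dict[str, float]:
    """Read an id-keyed activity table; converts mg/kg + MW rows when present."""
    out: dict[str, float] = {}
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        dialect = csv.Sniffer().sniff(sample, delimiters=",\t")
        reader = csv.DictReader(fh, dialect=dialect)
        fields = [f.strip().lower() for f in reader.fieldnames or []]
        if "id" not in fields:
            raise MolIOError(f"{path}: activity table needs an 'id' column")
        for row in reader:
            row = {k.strip().lower(): v for k, v in row.items() if k is not None}
            cid = row["id"].strip()
            if "activity" in row and row["activity"] not in (None, ""):
                out[cid] = float(row["activity"])
            elif "ld50_mg_per_kg" in row and "mw" in row:
                out[cid] = convert_ld50(float(row["ld50_mg_per_kg"]), float(row["mw"]))
            else:
                raise MolIOError(
                    f"{path}: row {cid!r} has neither 'activity' nor "
                    "'ld50_mg_per_kg'+'mw' columns"
                )
    return out


def _parse_smi(path: Path) -> tuple[list[tuple[str, str]], list[str]]:
    entries: list[tuple[str, str]] = []
    failures: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            canon = canonical_smiles(smiles)
            if canon is None:
                failures.append(f"{path.name}:{lineno}: unparseable SMILES {smiles!r}")
                continue
            entries.append((cid, canon))
    return entries, failures


def _parse_csv(path: Path) -> tuple[list[tuple[str, str, Optional[float]]], list[str]]:
    entries: list[tuple[str, str, Optional[float]]] = []
    failures: list[str] = []
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        dialect = csv.Sniffer().sniff(sample, delimiters=",\t")
        reader = csv.DictReader(fh, dialect=dialect)
        fields = [f.strip().lower() for f in reader.fieldnames or []]
        if "id" not in fields or "smiles" not in fields:
            raise MolIOError(f"{path}: need 'id' and 'smiles' columns, got {fields}")
        for lineno, row in enumerate(reader, 2):
            row = {k.strip().lower(): v for k, v in row.items() if k is not None}
            cid = row["id"].strip()
            canon = canonical_smiles(row["smiles"].strip())
            if canon is None:
                failures.append(
                    f"{path.name}:{lineno}: unparseable SMILES {row['smiles']!r}"
                )
                continue
            activity: Optional[float] = None
            if row.get("activity") not in (None, ""):
                activity = float(row["activity"])
            elif row.get("ld50_mg_per_kg") not in (None, "") and row.get("mw") not in (None, ""):
                activity = convert_ld50(float(row["ld50_mg_per_kg"]), float(row["mw"]))
            entries.append((cid, canon, activity))
    return entries, failures


def _parse_sdf(path: Path) -> tuple[list[tuple[str, str, Optional[float]]], list[str]]:
    entries: list[tuple[str, str, Optional[float]]] = []
    failures: list[str] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            failures.append(f"{path.name}: record {i + 1} unparseable")
            continue
        if mol.HasProp("id"):
            cid = mol.GetProp("id")
        elif mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            cid = mol.GetProp("_Name").strip()
        else:
            cid = f"mol{i + 1}"
        activity = float(mol.GetProp("activity")) if mol.HasProp("activity") else None
        entries.append((cid, Chem.MolToSmiles(mol), activity))
    return entries, failures


def read_compound_set(
    structures_path: str | Path,
    activities_path: Optional[str | Path] = None,
    fmt: Optional[str] = None,
    role: str = "reference",
) -> CompoundSet:
    """Read a compound set from a SMILES, SDF, or CSV/TSV file.

    Unparseable structures are collected in ``CompoundSet.failures`` rather
    than silently dropped; an input yielding zero parseable molecules raises.
    An optional side table of activities (CSV keyed by id) can be attached.
    """
    path = Path(structures_path)
    if not path.exists():
        raise MolIOError(f"no such file: {path}")
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"smi": "smi", "smiles": "smi", "sdf": "sdf", "csv": "csv", "tsv": "csv"}.get(
            suffix
        )
        if fmt is None:
            raise MolIOError(f"cannot infer format from {path.name!r}; pass fmt=")

    if fmt == "smi":
        raw, failures = _parse_smi(path)
        entries = [(cid, smiles, None) for cid, smiles in raw]
    elif fmt == "csv":
        entries, failures = _parse_csv(path)
    elif fmt == "sdf":
        entries, failures = _parse_sdf(path)
    else:
        raise MolIOError(f"unknown format {fmt!r}")

    if not entries:
        raise MolIOError(f"{path}: no parseable molecules (failures: {failures[:3]})")

    activity_map: dict[str, float] = {}
    if activities_path is not None:
        activity_map = _read_activity_csv(Path(activities_path))

    records = []
    for cid, smiles, activity in entries:
        if cid in activity_map:
            activity = activity_map[cid]
        records.append(MoleculeRecord(id=cid, structure=smiles, activity=activity))
    return CompoundSet(records=records, role=role, failures=failures)


def write_compound_set(cset: CompoundSet, path: str | Path, fmt: Optional[str] = None) -> None:
    """Write a compound set as ``.smi`` or CSV (id,smiles,activity)."""
    path = Path(path)
    if fmt is None:
        fmt = "smi" if path.suffix.lower() in (".smi", ".smiles") else "csv"
    if fmt == "smi":
        with open(path, "w") as fh:
            for rec in cset:
                fh.write(f"{rec.structure}\t{rec.id}\n")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "smiles", "activity"])
            for rec in cset:
                writer.writerow(
                    [rec.id, rec.structure, "" if rec.activity is None else repr(rec.activity)]
                )
    else:
        raise MolIOError(f"unknown format {fmt!r}")
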
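"""Compound-list curation for Pgp classification datasets.

Reads labeled SMILES tables, canonicalizes every structure to a uniform
representation, and enforces the curation rules: unparseable structures,
compounds heavier than a molecular-weight limit (default 1000 Da), exact
duplicates (same canonical SMILES and label) and overlapping compounds
(same canonical SMILES under two distinct labels) are removed, each with a
logged reason, and a per-label census is reported.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

LABELS = ("inhibitor", "non_inhibitor", "substrate", "non_substrate")

REMOVAL_REASONS = ("unparseable", "overweight", "duplicate", "overlapping")


class SmilesError(ValueError):
    """Raised for a SMILES string that does not parse to a molecule."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, SMILES, Pgp class label, provenance tag."""

    id: str
    smiles: str
    label: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(
                f"label {self.label!r} not one of {LABELS}")


@dataclass
class CuratedDataset:
    """Curation outcome: kept records, removal log and per-label census."""

    records: list[MoleculeRecord]
    removed: list[tuple[MoleculeRecord, str]]
    census: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.census:
            self.census = census(self.records)


def canonicalize_smiles(smiles: str) -> str:
    """Canonical SMILES of a molecule (deterministic, idempotent).

    Two SMILES of the same molecule map to the same output; malformed
    input raises :class:`SmilesError` rather than returning silently.
    """
    if not smiles or not smiles.strip():
        raise SmilesError(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(smiles)
    return Chem.MolToSmiles(mol)


def molecular_weight(smiles: str) -> float:
    """Average-atomic-mass molecular weight (Da), implicit H included."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(smiles)
    return Descriptors.MolWt(mol)


def curate(records: list[MoleculeRecord], mw_limit: float = 1000.0) -> CuratedDataset:
    """Apply the curation rules in order:

    1. unparseable SMILES removed;
    2. molecular weight > ``mw_limit`` Da removed;
    3. duplicates (same canonical SMILES + label) removed, first
       occurrence in input order kept;
    4. overlapping compounds (one canonical SMILES under two distinct
       labels) removed from every class.

    Salts / multi-fragment SMILES are kept verbatim but flagged in the log.
    """
    if not records:
        raise ValueError("no input records")
    removed: list[tuple[MoleculeRecord, str]] = []

    canonical: list[tuple[MoleculeRecord, str]] = []
    for rec in records:
        try:
            can = canonicalize_smiles(rec.smiles)
        except SmilesError:
            removed.append((rec, "unparseable"))
            continue
        if "." in can:
            log.info("multi-fragment SMILES kept verbatim: %s (%s)", rec.id, can)
        canonical.append((rec, can))

    surviving: list[tuple[MoleculeRecord, str]] = []
    for rec, can in canonical:
        if molecular_weight(can) > mw_limit:
            removed.append((rec, "overweight"))
        else:
            surviving.append((rec, can))

    seen: set[tuple[str, str]] = set()
    deduped: list[tuple[MoleculeRecord, str]] = []
    for rec, can in surviving:
        key = (can, rec.label)
        if key in seen:
            removed.append((rec, "duplicate"))
        else:
            seen.add(key)
            deduped.append((rec, can))

    labels_per_smiles: dict[str, set[str]] = {}
    for rec, can in deduped:
        labels_per_smiles.setdefault(can, set()).add(rec.label)
    kept: list[MoleculeRecord] = []
    for rec, can in deduped:
        if len(labels_per_smiles[can]) > 1:
            removed.append((rec, "overlapping"))
        else:
            kept.append(MoleculeRecord(id=rec.id, smiles=can,
                                       label=rec.label, source=rec.source))

    cen = census(kept)
    if cen["total"] == 0:
        warnings.warn("curation removed every record", stacklevel=2)
        cen["empty"] = True
    return CuratedDataset(records=kept, removed=removed, census=cen)


def census(records: list[MoleculeRecord]) -> dict:
    """Per-label counts plus total; counts always sum to total."""
    counts = Counter(r.label for r in records)
    out = {label: counts.get(label, 0) for label in LABELS}
    out["total"] = len(records)
    return out


# ---- I/O ----------------------------------------------------------------

def read_records(path: str | Path, label: str | None = None,
                 source: str | None = None) -> list[MoleculeRecord]:
    """Read compounds from a delimited table or a .smi file.

    CSV/TSV files need header columns ``smiles,label[,id]``; ``.smi``
    files hold ``SMILES<whitespace>id`` per line and require the
    ``label`` argument.
    """
    path = Path(path)
    src = source or path.name
    records: list[MoleculeRecord] = []
    if path.suffix.lower() == ".smi":
        if label is None:
            raise ValueError(".smi input requires an explicit label")
        for i, line in enumerate(path.read_text().splitlines()):
            if not line.strip():
                continue
            parts = line.split()
            rid = parts[1] if len(parts) > 1 else f"{path.stem}_{i}"
            records.append(MoleculeRecord(id=rid, smiles=parts[0],
                                          label=label, source=src))
        return records
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None or "smiles" not in reader.fieldnames:
            raise ValueError(f"{path}: missing 'smiles' header column")
        for i, row in enumerate(reader):
            records.append(MoleculeRecord(
                id=row.get("id") or f"{path.stem}_{i}",
                smiles=row["smiles"],
                label=row.get("label") or label or "",
                source=src))
    return records


def write_curated(dataset: CuratedDataset, out_dir: str | Path,
                  prefix: str = "curated") -> dict[str, Path]:
    """Write curated CSV, removal-log CSV and census JSON; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curated_path = out_dir / f"{prefix}.csv"
    with curated_path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "label", "source"])
        for r in dataset.records:
            w.writerow([r.id, r.smiles, r.label, r.source])
    removed_path = out_dir / f"{prefix}_removed.csv"
    with removed_path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "label", "reason"])
        for r, reason in dataset.removed:
            w.writerow([r.id, r.smiles, r.label, reason])
    census_path = out_dir / f"{prefix}_census.json"
    census_path.write_text(json.dumps(dataset.census, indent=2) + "\n")
    return {"curated": curated_path, "removed": removed_path,
            "census": census_path}
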
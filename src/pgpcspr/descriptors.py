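"""Interpretable molecular descriptors for CSPR modelling.

Seven 2-D descriptors are computed from the parsed structure:

==========  =============================================================
MW          molecular weight, Da (average atomic masses, implicit H)
RBN         rotatable bond count: single acyclic bonds between two
            non-terminal heavy atoms, amide C-N excluded
nCIC        number of rings: cyclomatic number of the heavy-atom graph
nHDon       H-bond donors: hydrogen atoms bonded to N or O
nHAcc       H-bond acceptors: count of N, O and F atoms
ALogP       Ghose-Crippen/Wildman octanol-water partition coefficient
TPSA        Ertl topological polar surface area, A^2
==========  =============================================================

Six quantum chemical descriptors (mean absolute partial charge Qm, total
energy, dipole moment, HOMO, LUMO and the HOMO-LUMO gap) come from an
external electronic-structure calculation and are ingest-only: they are
merged from a CSV and validated (gap = LUMO - HOMO), never computed here.
An optional Gasteiger-charge surrogate for Qm can be emitted for synthetic
exercises; it is always flagged as a surrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors as RDDescriptors, rdMolDescriptors
from rdkit.Chem.rdPartialCharges import ComputeGasteigerCharges

from .curation import CuratedDataset, SmilesError

log = logging.getLogger(__name__)

DESCRIPTOR_COLUMNS = ("MW", "RBN", "nCIC", "nHDon", "nHAcc", "ALogP", "TPSA")
QUANTUM_COLUMNS = ("Qm", "energy", "dipole", "HOMO", "LUMO", "gap")

GAP_TOL_EV = 1e-3


@dataclass(frozen=True)
class DescriptorVector:
    """The seven 2-D descriptors of one compound (quantum block optional)."""

    MW: float
    RBN: int
    nCIC: int
    nHDon: int
    nHAcc: int
    ALogP: float
    TPSA: float
    quantum: dict | None = None

    def as_dict(self) -> dict:
        out = {c: getattr(self, c) for c in DESCRIPTOR_COLUMNS}
        if self.quantum is not None:
            out.update(self.quantum)
        return out


@dataclass
class FeatureTable:
    """Row-aligned descriptor matrix with class labels.

    The canonical in-memory container handed between pipeline stages:
    a numeric DataFrame (one row per compound, ordered descriptor
    columns) plus a parallel label array.
    """

    X: pd.DataFrame
    labels: np.ndarray
    ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not self.ids:
            self.ids = list(self.X.index)
        if len(self.labels) != len(self.X):
            raise ValueError("labels and rows misaligned")
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        if len(set(self.X.columns)) != len(self.X.columns):
            raise ValueError("duplicate column names")

    @property
    def columns(self) -> list:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, mask) -> "FeatureTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return FeatureTable(X=self.X.iloc[idx].copy(),
                            labels=self.labels[idx],
                            ids=[self.ids[i] for i in idx])

    def to_csv(self, path: str | Path) -> None:
        df = self.X.copy()
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        ids = df.pop("id").tolist() if "id" in df else None
        labels = df.pop("label").to_numpy()
        return cls(X=df, labels=labels, ids=ids or [])


def rotatable_bond_count(mol) -> int:
    """Rotatable bonds: single acyclic bonds between two non-terminal
    heavy atoms, with amide C-N bonds excluded.

    Implemented directly (RDKit's strict variant additionally excludes
    esters, which this convention does not).
    """
    count = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetDegree() < 2 or b.GetDegree() < 2:
            continue
        if _is_amide_cn(a, b) or _is_amide_cn(b, a):
            continue
        count += 1
    return count


def _is_amide_cn(c, n) -> bool:
    if c.GetAtomicNum() != 6 or n.GetAtomicNum() != 7:
        return False
    return any(b.GetBondType() == Chem.BondType.DOUBLE
               and b.GetOtherAtom(c).GetAtomicNum() == 8
               for b in c.GetBonds())


def compute_2d_descriptors(mol_or_smiles) -> DescriptorVector:
    """Compute the seven 2-D descriptors of a molecule.

    Accepts an RDKit Mol or a SMILES string; raises on structures with
    no heavy atoms.
    """
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise SmilesError(mol_or_smiles)
        # recompute from the canonical form: additive descriptors are
        # summed in atom order, so equivalent SMILES must map to one
        # atom ordering to give bit-identical values
        mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    else:
        mol = mol_or_smiles
    if mol.GetNumHeavyAtoms() == 0:
        raise ValueError("structure has no heavy atoms")
    n_hdon = sum(a.GetTotalNumHs() for a in mol.GetAtoms()
                 if a.GetAtomicNum() in (7, 8))
    n_hacc = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8, 9))
    return DescriptorVector(
        MW=float(RDDescriptors.MolWt(mol)),
        RBN=rotatable_bond_count(mol),
        nCIC=int(rdMolDescriptors.CalcNumRings(mol)),
        nHDon=int(n_hdon),
        nHAcc=int(n_hacc),
        ALogP=float(Crippen.MolLogP(mol)),
        TPSA=float(RDDescriptors.TPSA(mol)),
    )


def surrogate_qm(mol_or_smiles) -> dict:
    """Mean absolute Gasteiger partial charge as a stand-in Qm.

    This is an empirical charge-equalization surrogate for the
    quantum-chemical mean absolute charge; it is always returned with
    ``surrogate=True`` so downstream reports can flag it.
    """
    mol = (Chem.MolFromSmiles(mol_or_smiles)
           if isinstance(mol_or_smiles, str) else mol_or_smiles)
    mol = Chem.AddHs(mol)
    ComputeGasteigerCharges(mol)
    charges = [abs(a.GetDoubleProp("_GasteigerCharge")) for a in mol.GetAtoms()]
    return {"Qm": float(np.mean(charges)), "surrogate": True}


def build_feature_table(dataset: CuratedDataset) -> FeatureTable:
    """One descriptor row per curated record; failures dropped and logged."""
    if not dataset.records:
        raise ValueError("empty curated dataset")
    rows, labels, ids = [], [], []
    for rec in dataset.records:
        try:
            vec = compute_2d_descriptors(rec.smiles)
        except (SmilesError, ValueError) as exc:
            log.warning("descriptor failure for %s: %s", rec.id, exc)
            continue
        rows.append([getattr(vec, c) for c in DESCRIPTOR_COLUMNS])
        labels.append(rec.label)
        ids.append(rec.id)
    if not rows:
        raise ValueError("descriptor computation failed for every record")
    X = pd.DataFrame(rows, columns=list(DESCRIPTOR_COLUMNS))
    return FeatureTable(X=X, labels=np.asarray(labels), ids=ids)


def attach_quantum_block(table: FeatureTable, quantum_file: str | Path) -> FeatureTable:
    """Merge precomputed quantum descriptors into a feature table by id.

    The file needs columns ``id,Qm,energy,dipole,HOMO,LUMO[,gap]``.  A
    missing gap column is filled as LUMO - HOMO; a present one is
    validated against LUMO - HOMO to within 1e-3 eV.
    """
    q = pd.read_csv(quantum_file)
    required = {"id", "Qm", "energy", "dipole", "HOMO", "LUMO"}
    missing_cols = required - set(q.columns)
    if missing_cols:
        raise ValueError(f"quantum file missing columns: {sorted(missing_cols)}")
    q = q.set_index("id")
    missing_ids = [i for i in table.ids if i not in q.index]
    if missing_ids:
        raise KeyError(f"ids missing from quantum file: {missing_ids}")
    q = q.loc[table.ids]
    computed_gap = q["LUMO"] - q["HOMO"]
    if "gap" in q.columns:
        bad = (q["gap"] - computed_gap).abs() > GAP_TOL_EV
        if bad.any():
            raise ValueError(
                f"gap inconsistent with LUMO - HOMO for ids: "
                f"{list(q.index[bad])}")
    else:
        q["gap"] = computed_gap
    X = table.X.copy()
    for col in QUANTUM_COLUMNS:
        X[col] = q[col].to_numpy()
    return FeatureTable(X=X, labels=table.labels.copy(), ids=list(table.ids))
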
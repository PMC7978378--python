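"""Molecule ingestion, standardization, properties and dataset splitting.

Reads SMILES / CSV / SDF libraries into :class:`MoleculeRecord` objects,
computes the four decoy-matching properties (MW, HBA, HBD, logP), applies
Lipinski's rule of five with the standard one-violation allowance, and
produces stratified, seeded train/test/validation splits.

Property definitions follow the simple Lipinski-style counts: HBD is the
number of N-H and O-H hydrogens, HBA is the number of N and O atoms, and
logP is the Crippen atom-contribution estimate. Multi-fragment inputs (salts)
are reduced to their largest fragment before any downstream use.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski

RDLogger.DisableLog("rdApp.*")  # parse failures are reported structurally

__all__ = [
    "MoleculeRecord",
    "PropertyVector",
    "DatasetSplit",
    "ParseFailure",
    "read_molecules",
    "write_sdf",
    "standardize",
    "compute_properties",
    "lipinski_pass",
    "split_dataset",
]


@dataclass(frozen=True)
class PropertyVector:
    """MW (Da), H-bond acceptor/donor counts, Crippen logP."""

    mw: float
    hba: int
    hbd: int
    logp: float

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("molecular weight must be > 0")
        if self.hba < 0 or self.hbd < 0:
            raise ValueError("H-bond counts must be >= 0")


@dataclass
class MoleculeRecord:
    """One identified compound: canonical SMILES plus optional 3D/label data.

    ``conformer`` is a list of (atom_index, x, y, z) heavy-atom coordinates
    in Angstroms, aligned with the canonical atom order of ``mol``.
    """

    id: str
    smiles: str
    mol: Chem.Mol = None
    conformer: Optional[list] = None
    props: Optional[PropertyVector] = None
    label: Optional[str] = None  # "active" | "inactive" | None

    @classmethod
    def from_smiles(cls, mol_id: str, smiles: str,
                    label: Optional[str] = None) -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for {mol_id!r}: {smiles!r}")
        mol = standardize(mol)
        return cls(id=mol_id, smiles=Chem.MolToSmiles(mol), mol=mol, label=label)

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()


@dataclass(frozen=True)
class ParseFailure:
    """A reported (never silently dropped) unparseable library entry."""

    line: int
    text: str
    reason: str


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/test/validation id sets from a stratified split."""

    train: frozenset
    test: frozenset
    validation: frozenset
    seed: int
    ratio: tuple

    def __post_init__(self) -> None:
        sets = (self.train, self.test, self.validation)
        total = sum(len(s) for s in sets)
        if len(self.train | self.test | self.validation) != total:
            raise ValueError("split sets must be pairwise disjoint")


def standardize(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest fragment (by heavy atoms) of a multi-fragment input.

    A deterministic surrogate for full structure preparation: counterions and
    minor fragments are stripped; protonation and tautomer state are used as
    drawn.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda f: (f.GetNumHeavyAtoms(),
                                        Descriptors.MolWt(f)))
    return mol


def _read_smiles_lines(path: Path):
    records, failures = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol_{lineno}"
            try:
                records.append(MoleculeRecord.from_smiles(mol_id, smiles))
            except ValueError:
                failures.append(ParseFailure(lineno, line, "unparseable SMILES"))
    return records, failures


def _read_csv(path: Path, smiles_column: str, id_column: Optional[str],
              label_column: Optional[str]):
    records, failures = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or smiles_column not in reader.fieldnames:
            raise ValueError(
                f"CSV {path} has no column named {smiles_column!r}")
        for lineno, row in enumerate(reader, start=2):  # header is line 1
            smiles = (row.get(smiles_column) or "").strip()
            if not smiles:
                failures.append(ParseFailure(lineno, str(row), "empty SMILES"))
                continue
            mol_id = (row.get(id_column) or f"mol_{lineno}") if id_column \
                else row.get("id", f"mol_{lineno}")
            label = row.get(label_column) if label_column else None
            try:
                records.append(MoleculeRecord.from_smiles(mol_id, smiles, label))
            except ValueError:
                failures.append(ParseFailure(lineno, smiles, "unparseable SMILES"))
    return records, failures


def _read_sdf(path: Path):
    records, failures = [], []
    suppl = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
    for idx, mol in enumerate(suppl):
        if mol is None:
            failures.append(ParseFailure(idx + 1, f"SDF entry {idx + 1}",
                                         "unparseable SDF record"))
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and \
            mol.GetProp("_Name") else f"mol_{idx + 1}"
        conformer = None
        if mol.GetNumConformers() > 0:
            # capture coordinates in the *canonical* atom order used after
            # SMILES round-tripping, so read/write round-trips are stable
            conf = mol.GetConformer()
            order = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
            inv = sorted(range(len(order)), key=lambda i: order[i])
            conformer = []
            for new_idx, old_idx in enumerate(inv):
                p = conf.GetAtomPosition(old_idx)
                conformer.append((new_idx, p.x, p.y, p.z))
        std = standardize(mol)
        rec = MoleculeRecord(id=mol_id, smiles=Chem.MolToSmiles(std), mol=std,
                             conformer=conformer)
        records.append(rec)
    return records, failures


def read_molecules(path, format: str = "smiles", *,
                   smiles_column: str = "smiles",
                   id_column: Optional[str] = "id",
                   label_column: Optional[str] = None,
                   ) -> tuple[list, list]:
    """Read a molecule library; returns (records, parse_failures).

    Unparseable entries are returned as :class:`ParseFailure` with their
    line numbers, never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "smiles":
        return _read_smiles_lines(path)
    if format == "csv":
        return _read_csv(path, smiles_column, id_column, label_column)
    if format == "sdf":
        return _read_sdf(path)
    raise ValueError(f"unknown format {format!r}")


def write_sdf(records: Sequence[MoleculeRecord], path) -> None:
    """Write records as V2000 SDF; conformers are embedded when present."""
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.Mol(rec.mol)
            mol.SetProp("_Name", rec.id)
            if rec.conformer is not None:
                conf = Chem.Conformer(mol.GetNumAtoms())
                for atom_idx, x, y, z in rec.conformer:
                    conf.SetAtomPosition(int(atom_idx), (float(x), float(y), float(z)))
                mol.RemoveAllConformers()
                mol.AddConformer(conf, assignId=True)
            writer.write(mol)
    finally:
        writer.close()


def compute_properties(mol: MoleculeRecord | Chem.Mol) -> PropertyVector:
    """MW, HBA (N+O count), HBD (N-H + O-H hydrogens), Crippen logP.

    Deterministic and invariant to input atom ordering.
    """
    m = mol.mol if isinstance(mol, MoleculeRecord) else mol
    if m is None:
        raise ValueError("molecule did not parse")
    return PropertyVector(
        mw=Descriptors.MolWt(m),
        hba=Lipinski.NOCount(m),
        hbd=Lipinski.NHOHCount(m),
        logp=Crippen.MolLogP(m),
    )


def lipinski_pass(props: PropertyVector) -> bool:
    """Rule of five with inclusive boundaries and one violation allowed."""
    violations = sum([
        props.mw > 500.0,
        props.logp > 5.0,
        props.hbd > 5,
        props.hba > 10,
    ])
    return violations <= 1


def _apportion(n: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items over weights."""
    total = float(sum(weights))
    quotas = [n * w / total for w in weights]
    counts = [math.floor(q) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    short = n - sum(counts)
    # assign leftovers by descending remainder, ties to the earlier set
    order = sorted(range(len(weights)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def split_dataset(records: Sequence[MoleculeRecord],
                  ratio: Sequence[float] = (7, 2, 1),
                  seed: int = 0) -> DatasetSplit:
    """Stratified, seeded train/test/validation split.

    Each labelled class is shuffled independently with the seed and
    apportioned by the largest-remainder rule, so per-set class proportions
    differ from the global ratio by less than one member.
    """
    if len(ratio) != 3 or any(w < 0 for w in ratio) or sum(ratio) == 0:
        raise ValueError("ratio must be three non-negative weights, not all zero")
    by_class: dict[str, list[str]] = {}
    for rec in records:
        by_class.setdefault(rec.label or "unlabeled", []).append(rec.id)
    if not by_class:
        raise ValueError("no records to split")

    rng = np.random.default_rng(seed)
    buckets = ([], [], [])
    for cls in sorted(by_class):
        ids = sorted(by_class[cls])
        rng.shuffle(ids)
        counts = _apportion(len(ids), ratio)
        start = 0
        for b, c in zip(buckets, counts):
            b.extend(ids[start:start + c])
            start += c
    return DatasetSplit(train=frozenset(buckets[0]), test=frozenset(buckets[1]),
                        validation=frozenset(buckets[2]), seed=seed,
                        ratio=tuple(ratio))
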
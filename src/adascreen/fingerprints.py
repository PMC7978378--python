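"""Circular fingerprints, Tanimoto similarity, clustering and novelty.

Three schemes are supported: binary ECFP4 (radius-2 Morgan hashed to a fixed
bit length), a count-folded Morgan variant of the same radius, and the 166
MACCS structural keys. Tanimoto values are never compared across schemes;
for count vectors the Tanimoto generalizes to sum(min)/sum(max).

Also builds the atom-feature/adjacency graphs consumed by the neural
fingerprint model, runs Butina sphere-exclusion diversity clustering, and
computes the per-scheme maximum-Tc novelty statistic for candidate hits
against a reference set of known actives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .chemstore import MoleculeRecord

__all__ = [
    "BitFingerprint",
    "MolGraph",
    "ClusterAssignment",
    "ecfp4",
    "morgan_counts",
    "maccs",
    "fingerprint",
    "tanimoto",
    "novelty_assessment",
    "cluster_compounds",
    "mol_graph",
    "fp_to_hex",
    "hex_to_fp",
    "ELEMENTS",
    "ATOM_FEATURE_DIM",
]

SCHEMES = ("ecfp4", "morgan", "maccs")


@dataclass(frozen=True)
class BitFingerprint:
    """A fixed-length fingerprint vector tagged with its scheme.

    ``bits`` is a uint32 vector: 0/1 for binary schemes (ecfp4, maccs),
    non-negative counts for the count-folded morgan scheme.
    """

    bits: np.ndarray
    nbits: int
    scheme: str

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.bits.shape != (self.nbits,):
            raise ValueError("bits length must equal nbits")

    @property
    def popcount(self) -> int:
        return int(np.count_nonzero(self.bits))


def _as_mol(mol) -> Chem.Mol:
    if isinstance(mol, MoleculeRecord):
        return mol.mol
    if isinstance(mol, Chem.Mol):
        return mol
    m = Chem.MolFromSmiles(mol)
    if m is None:
        raise ValueError(f"unparseable SMILES {mol!r}")
    return m


def ecfp4(mol, nbits: int = 2048) -> BitFingerprint:
    """Binary radius-2 circular fingerprint hashed onto ``nbits`` bits."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=nbits)
    bv = gen.GetFingerprint(_as_mol(mol))
    arr = np.zeros(nbits, dtype=np.uint32)
    arr[list(bv.GetOnBits())] = 1
    return BitFingerprint(bits=arr, nbits=nbits, scheme="ecfp4")


def morgan_counts(mol, nbits: int = 2048) -> BitFingerprint:
    """Count-folded radius-2 Morgan fingerprint."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=nbits)
    cv = gen.GetCountFingerprint(_as_mol(mol))
    arr = np.zeros(nbits, dtype=np.uint32)
    for idx, count in cv.GetNonzeroElements().items():
        arr[idx] = count
    return BitFingerprint(bits=arr, nbits=nbits, scheme="morgan")


def maccs(mol) -> BitFingerprint:
    """166-key MACCS structural fingerprint (bit 0 of RDKit's 167 unused)."""
    bv = MACCSkeys.GenMACCSKeys(_as_mol(mol))
    arr = np.zeros(167, dtype=np.uint32)
    arr[list(bv.GetOnBits())] = 1
    return BitFingerprint(bits=arr[1:], nbits=166, scheme="maccs")


def fingerprint(mol, scheme: str, nbits: int = 2048) -> BitFingerprint:
    """Dispatch to the named fingerprint scheme."""
    if scheme == "ecfp4":
        return ecfp4(mol, nbits)
    if scheme == "morgan":
        return morgan_counts(mol, nbits)
    if scheme == "maccs":
        return maccs(mol)
    raise ValueError(f"unknown scheme {scheme!r}")


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """|a AND b| / |a OR b| (sum-min / sum-max for count vectors).

    Defined as 0 when both vectors are empty, keeping novelty conservative.
    """
    if a.scheme != b.scheme:
        raise ValueError(f"scheme mismatch: {a.scheme} vs {b.scheme}")
    if a.nbits != b.nbits:
        raise ValueError("fingerprint length mismatch")
    inter = float(np.minimum(a.bits, b.bits).sum())
    union = float(np.maximum(a.bits, b.bits).sum())
    if union == 0:
        return 0.0
    return inter / union


def novelty_assessment(query, references: Sequence,
                       schemes: Sequence[str] = SCHEMES,
                       nbits: int = 2048) -> dict[str, float]:
    """Per-scheme maximum Tanimoto of a query against known references.

    A value near 0 in every scheme indicates a structurally novel hit.
    """
    if not references:
        raise ValueError("reference set must be non-empty")
    out = {}
    for scheme in schemes:
        qfp = fingerprint(query, scheme, nbits)
        out[scheme] = max(
            tanimoto(qfp, fingerprint(ref, scheme, nbits)) for ref in references
        )
    return out


@dataclass(frozen=True)
class ClusterAssignment:
    """Butina clustering output: cluster id per molecule, one representative
    (the sphere centroid) per cluster, and the Tc threshold used."""

    cluster_ids: tuple
    representatives: dict
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def cluster_compounds(fps: Sequence[BitFingerprint],
                      threshold: float) -> ClusterAssignment:
    """Sphere-exclusion (Butina) clustering at a Tanimoto threshold.

    Neighbors are pairs with Tc >= threshold. Centroids are picked by
    descending unassigned-neighbor count, ties broken by input order; each
    centroid claims its unassigned neighbors as one cluster.
    """
    if not fps:
        raise ValueError("need at least one fingerprint")
    n = len(fps)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = tanimoto(fps[i], fps[j])
    neighbors = [set(np.nonzero(sim[i] >= threshold)[0]) - {i} for i in range(n)]

    assigned = [-1] * n
    representatives: dict[int, int] = {}
    cluster = 0
    while True:
        best, best_count = -1, -1
        for i in range(n):
            if assigned[i] >= 0:
                continue
            count = sum(1 for j in neighbors[i] if assigned[j] < 0)
            if count > best_count:  # strict > keeps earliest on ties
                best, best_count = i, count
        if best < 0:
            break
        assigned[best] = cluster
        representatives[cluster] = best
        for j in neighbors[best]:
            if assigned[j] < 0:
                assigned[j] = cluster
        cluster += 1
    return ClusterAssignment(cluster_ids=tuple(assigned),
                             representatives=representatives,
                             threshold=threshold)


# ---------------------------------------------------------------------------
# Molecule graphs for the neural fingerprint
# ---------------------------------------------------------------------------

ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
MAX_DEGREE = 5
MAX_H = 4
#: element one-hot (incl. "other") + degree one-hot + H-count one-hot + aromatic
ATOM_FEATURE_DIM = (len(ELEMENTS) + 1) + (MAX_DEGREE + 1) + (MAX_H + 1) + 1


@dataclass
class MolGraph:
    """Atom-feature matrix plus symmetric neighbor lists for one molecule."""

    atom_features: np.ndarray  # (n_atoms, ATOM_FEATURE_DIM)
    neighbors: list  # list of sorted atom-index lists
    bond_features: Optional[np.ndarray] = None

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    def adjacency(self) -> np.ndarray:
        adj = np.zeros((self.n_atoms, self.n_atoms))
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                adj[i, j] = 1.0
        return adj


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    vec = np.zeros(ATOM_FEATURE_DIM)
    sym = atom.GetSymbol()
    idx = ELEMENTS.index(sym) if sym in ELEMENTS else len(ELEMENTS)
    vec[idx] = 1.0
    off = len(ELEMENTS) + 1
    vec[off + min(atom.GetDegree(), MAX_DEGREE)] = 1.0
    off += MAX_DEGREE + 1
    vec[off + min(atom.GetTotalNumHs(), MAX_H)] = 1.0
    vec[-1] = 1.0 if atom.GetIsAromatic() else 0.0
    return vec


_BOND_TYPES = (Chem.BondType.SINGLE, Chem.BondType.DOUBLE,
               Chem.BondType.TRIPLE, Chem.BondType.AROMATIC)


def mol_graph(mol) -> MolGraph:
    """Build the heavy-atom graph with the standard atom feature set."""
    m = _as_mol(mol)
    if m.GetNumHeavyAtoms() == 0:
        raise ValueError("empty molecule graph")
    feats = np.stack([_atom_features(a) for a in m.GetAtoms()])
    neighbors = [[] for _ in range(m.GetNumAtoms())]
    n_bonds = m.GetNumBonds()
    bond_feats = np.zeros((n_bonds, len(_BOND_TYPES)))
    for b_idx, bond in enumerate(m.GetBonds()):
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        neighbors[i].append(j)
        neighbors[j].append(i)
        if bond.GetBondType() in _BOND_TYPES:
            bond_feats[b_idx, _BOND_TYPES.index(bond.GetBondType())] = 1.0
    return MolGraph(atom_features=feats,
                    neighbors=[sorted(nb) for nb in neighbors],
                    bond_features=bond_feats)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def fp_to_hex(fp: BitFingerprint) -> str:
    """Hex string of a binary fingerprint (count schemes not supported)."""
    if fp.scheme == "morgan":
        raise ValueError("count fingerprints have no hex form")
    packed = np.packbits(fp.bits.astype(np.uint8))
    return packed.tobytes().hex()


def hex_to_fp(hexstr: str, nbits: int, scheme: str) -> BitFingerprint:
    raw = np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8)
    bits = np.unpackbits(raw)[:nbits].astype(np.uint32)
    return BitFingerprint(bits=bits, nbits=nbits, scheme=scheme)


def similarity_matrix(fps: Sequence[BitFingerprint],
                      ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Dense pairwise Tanimoto matrix as a labelled DataFrame."""
    n = len(fps)
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = tanimoto(fps[i], fps[j])
    return pd.DataFrame(mat, index=ids, columns=ids)
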
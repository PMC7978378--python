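"""3D pharmacophore feature perception and partial hypothesis matching.

A hypothesis is a user-supplied list of typed sites (acceptor A, donor D,
aromatic ring R, hydrophobe H) at 3D positions with per-site tolerance radii,
plus a minimum number of sites a molecule must satisfy (partial matching,
e.g. "4 of 5"). A molecule matches when some type-consistent injective
assignment of its perceived features to a subset of >= min_match sites
admits a rigid (rotation + translation) superposition placing every matched
feature within its site's tolerance.

Feature perception uses documented SMARTS patterns (listed in
:data:`DEFAULT_FEATURE_SMARTS`): acceptors are N/O with an available lone
pair excluding amide-type nitrogens, donors are N-H/O-H heavy atoms,
aromatic-ring features sit at ring centroids, and hydrophobes at centroids
of connected aliphatic-carbon patches. Conformers are embedded with seeded
ETKDG when a record carries no 3D coordinates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

from .chemstore import MoleculeRecord

__all__ = [
    "DEFAULT_FEATURE_SMARTS",
    "FeatureDefs",
    "Feature",
    "Hypothesis",
    "MatchResult",
    "perceive_features",
    "match_hypothesis",
    "screen_by_hypothesis",
    "embed_conformers",
    "kabsch",
    "load_hypothesis",
    "save_hypothesis",
]

#: Auditable feature definitions. Atom-placed types list SMARTS whose first
#: matched atom carries the feature; centroid types aggregate matched atoms.
DEFAULT_FEATURE_SMARTS = {
    "A": [  # H-bond acceptor: N/O with a lone pair, amide-type N excluded
        "[O;X2;v2]",                                # ether / hydroxyl oxygen
        "[O;X1]",                                   # carbonyl-type oxygen
        "[N;X3;v3;!$([N][C,S,P]=[O,S,N]);!$([N]a)]",  # sp3 amine, not amide/anilide
        "[n;X2;+0]",                                # pyridine-type aromatic N
        "[N;X2;v3;!$([N]=[O])]",                    # imine / azo nitrogen
    ],
    "D": [  # H-bond donor heavy atom
        "[N;!H0]", "[n;!H0]", "[O;!H0]",
    ],
}

#: Hydrophobe atoms: aliphatic carbons not bonded or doubly bonded to
#: heteroatoms; connected patches are merged into one centroid feature.
HYDROPHOBE_SMARTS = "[C;!$(C=[O,N,S]);!$(C#N);!$(C[O,N,S,P,F,Cl,Br,I])]"

FEATURE_TYPES = ("A", "D", "R", "H")


@dataclass(frozen=True)
class FeatureDefs:
    """Substructure patterns per feature type plus placement rules."""

    smarts: dict = field(default_factory=lambda: DEFAULT_FEATURE_SMARTS)
    hydrophobe_smarts: str = HYDROPHOBE_SMARTS

    def compiled(self) -> dict:
        out = {}
        for ftype, patterns in self.smarts.items():
            out[ftype] = []
            for p in patterns:
                q = Chem.MolFromSmarts(p)
                if q is None:
                    raise ValueError(f"invalid SMARTS for {ftype}: {p!r}")
                out[ftype].append(q)
        return out


@dataclass(frozen=True)
class Feature:
    """A perceived pharmacophore feature at a 3D position (Angstroms)."""

    type: str
    position: tuple

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError("feature position must be finite")


@dataclass(frozen=True)
class Hypothesis:
    """Typed sites with tolerances and the partial-match requirement."""

    sites: tuple  # of (type, (x, y, z), tolerance)
    min_match: int

    def __post_init__(self) -> None:
        if self.min_match > len(self.sites):
            raise ValueError("min_match cannot exceed the number of sites")
        if any(s[2] < 0 for s in self.sites):
            raise ValueError("tolerances must be >= 0")


@dataclass(frozen=True)
class MatchResult:
    """An accepted partial match: site-feature pairs, the rigid transform
    aligning features onto sites, and the fit rmsd."""

    pairs: tuple  # of (site_index, feature_index)
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    @property
    def matched_count(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Feature perception
# ---------------------------------------------------------------------------

def _conformer_positions(record: MoleculeRecord) -> np.ndarray:
    if record.conformer is None:
        raise ValueError(f"{record.id}: no 3D conformer present")
    pos = np.zeros((record.mol.GetNumHeavyAtoms(), 3))
    for atom_idx, x, y, z in record.conformer:
        pos[int(atom_idx)] = (x, y, z)
    return pos


def perceive_features(record: MoleculeRecord,
                      defs: FeatureDefs = FeatureDefs()) -> list:
    """Deterministic typed feature list from a molecule's 3D conformer.

    An atom may carry several types (e.g. a hydroxyl O is both A and D),
    but each (type, atom) pair yields at most one feature.
    """
    mol = record.mol
    pos = _conformer_positions(record)
    features: list[Feature] = []

    compiled = defs.compiled()
    for ftype in ("A", "D"):
        hit_atoms = set()
        for q in compiled.get(ftype, []):
            for match in mol.GetSubstructMatches(q):
                hit_atoms.add(match[0])
        for a in sorted(hit_atoms):
            features.append(Feature(ftype, tuple(pos[a])))

    # aromatic rings at centroids
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in ring):
            centroid = pos[list(ring)].mean(axis=0)
            features.append(Feature("R", tuple(centroid)))

    # hydrophobic patches: connected components of qualifying carbons
    q = Chem.MolFromSmarts(defs.hydrophobe_smarts)
    hydro = sorted({m[0] for m in mol.GetSubstructMatches(q)})
    seen: set[int] = set()
    for start in hydro:
        if start in seen:
            continue
        patch, stack = [], [start]
        while stack:
            a = stack.pop()
            if a in seen or a not in hydro:
                continue
            seen.add(a)
            patch.append(a)
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                stack.append(nb.GetIdx())
        centroid = pos[sorted(patch)].mean(axis=0)
        features.append(Feature("H", tuple(centroid)))
    return features


def embed_conformers(record: MoleculeRecord, n_conformers: int = 10,
                     seed: int = 0) -> list:
    """Seeded ETKDG conformers as heavy-atom coordinate lists."""
    mol = Chem.AddHs(Chem.Mol(record.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    params.numThreads = 1
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers, params=params)
    if len(ids) == 0:
        raise ValueError(f"{record.id}: conformer embedding failed")
    mol_noH = Chem.RemoveHs(mol)
    out = []
    for cid in ids:
        conf = mol_noH.GetConformer(cid)
        out.append([(i, *conf.GetAtomPosition(i))
                    for i in range(mol_noH.GetNumHeavyAtoms())])
    return out


# ---------------------------------------------------------------------------
# Rigid superposition and matching
# ---------------------------------------------------------------------------

def kabsch(moving: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``moving`` onto ``target``.

    Returns (rotation 3x3, translation 3, rmsd). Proper rotation enforced
    via the SVD determinant correction.
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    mc, tc = moving.mean(axis=0), target.mean(axis=0)
    A = (moving - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    moved = moving @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def _assignments(site_indices, features, sites):
    """Injective, type-consistent feature choices for the given sites."""
    candidates = []
    for si in site_indices:
        stype = sites[si][0]
        cand = [fi for fi, f in enumerate(features) if f.type == stype]
        if not cand:
            return
        candidates.append(cand)
    for combo in itertools.product(*candidates):
        if len(set(combo)) == len(combo):
            yield combo


def match_hypothesis(features: Sequence[Feature],
                     hyp: Hypothesis) -> Optional[MatchResult]:
    """Best partial match of perceived features against the hypothesis.

    Exhaustively searches site subsets (largest first) and injective
    type-consistent assignments; a candidate is accepted when, after its
    least-squares rigid alignment, every matched feature lies within its
    site's tolerance. Among accepted candidates the one with the most sites
    wins, ties broken by lowest rmsd. Returns None when nothing matches.
    """
    n_sites = len(hyp.sites)
    best: Optional[MatchResult] = None
    for k in range(n_sites, hyp.min_match - 1, -1):
        for site_subset in itertools.combinations(range(n_sites), k):
            site_pos = np.array([hyp.sites[i][1] for i in site_subset])
            for combo in _assignments(site_subset, features, hyp.sites):
                feat_pos = np.array([features[fi].position for fi in combo])
                R, t, rmsd = kabsch(feat_pos, site_pos)
                moved = feat_pos @ R.T + t
                dists = np.linalg.norm(moved - site_pos, axis=1)
                tols = np.array([hyp.sites[i][2] for i in site_subset])
                if np.all(dists <= tols + 1e-9):
                    if best is None or rmsd < best.rmsd - 1e-12:
                        best = MatchResult(
                            pairs=tuple(zip(site_subset, combo)),
                            rotation=R, translation=t, rmsd=rmsd)
        if best is not None:
            return best  # larger subsets always beat smaller ones
    return None


def screen_by_hypothesis(library: Sequence[MoleculeRecord], hyp: Hypothesis,
                         conformers_per_mol: int = 10, seed: int = 0,
                         defs: FeatureDefs = FeatureDefs()) -> list:
    """Pharmacophore filter: a molecule passes if any conformer matches.

    Returns (record, MatchResult) pairs for passing molecules; the fit score
    orders by matched_count then by -rmsd (lexicographic).
    """
    passes = []
    for rec in library:
        conformer_sets = ([rec.conformer] if rec.conformer is not None
                          else None)
        if conformer_sets is None:
            try:
                conformer_sets = embed_conformers(rec, conformers_per_mol, seed)
            except ValueError:
                continue
        best: Optional[MatchResult] = None
        for conformer in conformer_sets:
            trial = MoleculeRecord(id=rec.id, smiles=rec.smiles, mol=rec.mol,
                                   conformer=conformer, label=rec.label)
            result = match_hypothesis(perceive_features(trial, defs), hyp)
            if result is not None and (
                    best is None
                    or (result.matched_count, -result.rmsd)
                    > (best.matched_count, -best.rmsd)):
                best = result
        if best is not None:
            passes.append((rec, best))
    passes.sort(key=lambda p: (-p[1].matched_count, p[1].rmsd, p[0].id))
    return passes


# ---------------------------------------------------------------------------
# Hypothesis IO
# ---------------------------------------------------------------------------

def load_hypothesis(path) -> Hypothesis:
    """Read a hypothesis from YAML: sites [{type, x, y, z, tolerance}],
    min_match."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    sites = tuple(
        (s["type"], (float(s["x"]), float(s["y"]), float(s["z"])),
         float(s.get("tolerance", 2.0)))
        for s in data["sites"])
    return Hypothesis(sites=sites, min_match=int(data["min_match"]))


def save_hypothesis(hyp: Hypothesis, path) -> None:
    data = {
        "sites": [
            {"type": t, "x": float(p[0]), "y": float(p[1]), "z": float(p[2]),
             "tolerance": float(tol)}
            for t, p, tol in hyp.sites],
        "min_match": hyp.min_match,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
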
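"""The multistage screening funnel and its synthetic study fixtures.

Stage order mirrors the discovery campaign: (1) the dual-model gate keeps
compounds predicted active by BOTH the dense-fingerprint classifier and the
graph-fingerprint classifier; (2) a 3D pharmacophore hypothesis removes
compounds matching fewer than ``min_match`` sites; (3) an external-score
stage ranks survivors by user-provided score columns (e.g. docking scores
from outside software) and keeps configured top fractions sequentially;
(4) an optional manual include-list models the final visual-inspection cut.
Scores for stage 3 are never computed internally - docking is deliberately
a pluggable external input.

Every stage logs input and output counts into a :class:`FunnelReport`;
candidate ids only ever shrink from stage to stage.

The module also houses the synthetic data generators used throughout the
test suite: a two-class SMILES library (a decorated xanthine-like scaffold
family vs diverse acyclic amine/ether backgrounds - structurally separable
by construction) and ranked-list fixtures with prescribed active placements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

from .chemstore import MoleculeRecord
from .fingerprints import mol_graph
from .neuralmodels import ModelParams, intersect_filters, predict_filter
from .pharmacophore import Hypothesis, screen_by_hypothesis
from .screenmetrics import RankedList

__all__ = [
    "StageConfig",
    "FunnelReport",
    "run_cascade",
    "generate_synthetic_library",
    "generate_ranked_fixture",
    "load_stage_config",
]


@dataclass
class StageConfig:
    """Ordered stage descriptions for one funnel run.

    Each stage is a dict with a ``kind`` key:

    * ``dual_model``: {kind, dnn: ModelParams, nfp: ModelParams,
      threshold: float, fingerprints: {id: bitvector}, graphs: {id: MolGraph}}
    * ``pharmacophore``: {kind, hypothesis: Hypothesis, conformers_per_mol,
      seed}
    * ``external_scores``: {kind, scores: DataFrame with id + score columns,
      retained_fractions: [float, ...], ascending: bool}
    * ``include_list``: {kind, ids: set}
    """

    stages: list

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("at least one stage is required")
        for st in self.stages:
            if "kind" not in st:
                raise ValueError("every stage needs a 'kind'")
            for frac in st.get("retained_fractions", []):
                if not (0 < frac <= 1):
                    raise ValueError("retained fractions must be in (0, 1]")


@dataclass
class FunnelReport:
    """Per-stage attrition counts plus the surviving candidates."""

    stages: list = field(default_factory=list)  # (name, n_in, n_out)
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def counts(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_in", "n_out"])


def _stage_dual_model(records, stage) -> tuple[set, dict]:
    ids = [r.id for r in records]
    fps = np.array([stage["fingerprints"][r.id] for r in records],
                   dtype=float) if records else np.zeros((0, 1))
    graphs = [stage["graphs"][r.id] for r in records]
    threshold = stage.get("threshold", 0.5)
    if records:
        pass_dnn, dnn_scores = predict_filter(stage["dnn"], ids, fps, threshold)
        pass_nfp, nfp_scores = predict_filter(stage["nfp"], ids, graphs,
                                              threshold)
        surviving = intersect_filters(pass_dnn, pass_nfp)
        scores = {i: {"p_dnn": float(d), "p_nfp": float(n)}
                  for i, d, n in zip(ids, dnn_scores["p_active"],
                                     nfp_scores["p_active"])}
    else:
        surviving, scores = set(), {}
    return surviving, scores


def _stage_pharmacophore(records, stage) -> tuple[set, dict]:
    passes = screen_by_hypothesis(
        records, stage["hypothesis"],
        conformers_per_mol=stage.get("conformers_per_mol", 10),
        seed=stage.get("seed", 0))
    scores = {rec.id: {"matched_count": res.matched_count, "rmsd": res.rmsd}
              for rec, res in passes}
    return {rec.id for rec, _ in passes}, scores


def _stage_external_scores(records, stage) -> tuple[set, dict]:
    df = stage["scores"]
    if "id" not in df.columns:
        raise ValueError("external score table needs an 'id' column")
    score_cols = [c for c in df.columns if c != "id"]
    fractions = stage.get("retained_fractions", [1.0] * len(score_cols))
    ascending = stage.get("ascending", False)

    current = [r.id for r in records]
    lookup = df.set_index("id")
    missing = [i for i in current if i not in lookup.index]
    # ids without external scores are reported and treated as non-passing
    current = [i for i in current if i in lookup.index]
    scores: dict = {i: {"missing_external_score": True} for i in missing}

    for col, frac in zip(score_cols, fractions):
        ranked = sorted(current, key=lambda i: (
            lookup.loc[i, col] if ascending else -lookup.loc[i, col], i))
        keep = math.ceil(frac * len(ranked))
        current = ranked[:keep]
        for i in current:
            scores.setdefault(i, {})[col] = float(lookup.loc[i, col])
    return set(current), scores


def run_cascade(library: Sequence[MoleculeRecord],
                config: StageConfig) -> FunnelReport:
    """Run the funnel over a library; every stage only removes compounds."""
    report = FunnelReport()
    current = list(library)
    all_scores: dict[str, dict] = {r.id: {} for r in current}

    handlers = {
        "dual_model": _stage_dual_model,
        "pharmacophore": _stage_pharmacophore,
        "external_scores": _stage_external_scores,
        "include_list": lambda recs, st: (
            {r.id for r in recs} & set(st["ids"]), {}),
    }
    for stage in config.stages:
        kind = stage["kind"]
        if kind not in handlers:
            raise ValueError(f"unknown stage kind {kind!r}")
        n_in = len(current)
        surviving, scores = handlers[kind](current, stage)
        for i, s in scores.items():
            all_scores.setdefault(i, {}).update(s)
        current = [r for r in current if r.id in surviving]
        report.stages.append((stage.get("name", kind), n_in, len(current)))

    rows = []
    for rec in current:
        row = {"id": rec.id}
        row.update(all_scores.get(rec.id, {}))
        rows.append(row)
    report.candidates = pd.DataFrame(rows)
    return report


def load_stage_config(path, artifacts: Optional[dict] = None) -> StageConfig:
    """Load a YAML funnel config; ``artifacts`` resolves named model and
    hypothesis objects referenced by the file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    artifacts = artifacts or {}
    stages = []
    for st in raw["stages"]:
        stage = dict(st)
        for key in ("dnn", "nfp", "hypothesis", "fingerprints", "graphs"):
            if key in stage and isinstance(stage[key], str):
                stage[key] = artifacts[stage[key]]
        if stage.get("kind") == "external_scores" and \
                isinstance(stage.get("scores"), str):
            stage["scores"] = pd.read_csv(stage["scores"])
        stages.append(stage)
    return StageConfig(stages=stages)


# ---------------------------------------------------------------------------
# Synthetic study fixtures
# ---------------------------------------------------------------------------

#: N-substituents decorating the xanthine-like positive scaffold.
_DECORATIONS = ("C", "CC", "CCC", "CCCC", "CC(C)C", "CCO", "CC(C)", "CCCCC")
#: Chain atoms for the acyclic background family.
_CHAIN_ATOMS = ("C", "C", "C", "C", "O", "N")


def _positive_smiles(rng: np.random.Generator) -> str:
    r1, r2, r3 = (rng.choice(_DECORATIONS) for _ in range(3))
    # decorated xanthine core (caffeine-like), substituents on the three N
    return f"{r1}n1cnc2c1c(=O)n({r2})c(=O)n2{r3}"


def _background_smiles(rng: np.random.Generator) -> str:
    length = int(rng.integers(5, 12))
    parts = ["C"]
    prev_hetero = False
    for _ in range(length):
        atom = str(rng.choice(_CHAIN_ATOMS))
        if prev_hetero and atom in ("O", "N"):
            atom = "C"  # avoid adjacent heteroatoms for blandness
        parts.append(atom)
        prev_hetero = atom in ("O", "N")
        if atom == "C" and rng.random() < 0.3:
            parts.append("(C)")
    return "".join(parts)


def generate_synthetic_library(seed: int, n_positive_like: int = 150,
                               n_background: int = 150
                               ) -> tuple[list, pd.DataFrame]:
    """Two structurally separable SMILES families with ground-truth labels.

    Positives share a decorated fused bicyclic xanthine-like scaffold
    (echoing classical adenosine-receptor antagonist chemotypes); the
    background is diverse acyclic amine/ether chains. Deterministic under
    the seed; requested counts honored exactly.
    """
    if n_positive_like < 1 or n_background < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    records, rows = [], []

    def emit(generator, n, label, prefix):
        seen = set()
        attempts = 0
        while len(seen) < n:
            attempts += 1
            if attempts > 100 * n + 1000:
                raise RuntimeError("could not generate enough unique molecules")
            smi = generator(rng)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            canon = Chem.MolToSmiles(mol)
            if canon in seen:
                continue
            seen.add(canon)
            mol_id = f"{prefix}{len(seen):04d}"
            records.append(MoleculeRecord(id=mol_id, smiles=canon, mol=mol,
                                          label=label))
            rows.append({"id": mol_id, "smiles": canon, "label": label})

    emit(_positive_smiles, n_positive_like, "active", "act_")
    emit(_background_smiles, n_background, "inactive", "bg_")
    return records, pd.DataFrame(rows)


def generate_ranked_fixture(N: int, n_actives: int,
                            placement) -> RankedList:
    """Deterministic ranked list with actives at prescribed positions.

    ``placement`` is "top", "bottom", "interleaved", or an explicit sequence
    of 1-based ranks; with an explicit sequence any remaining actives are
    left unranked (they implicitly occupy the bottom of the universe).
    Scores descend linearly with rank.
    """
    if n_actives > N:
        raise ValueError("n_actives cannot exceed N")
    unranked = 0
    if placement == "top":
        active_ranks = set(range(1, n_actives + 1))
    elif placement == "bottom":
        active_ranks = set(range(N - n_actives + 1, N + 1))
    elif placement == "interleaved":
        step = N / n_actives
        active_ranks = {min(N, 1 + round(i * step)) for i in range(n_actives)}
        # rounding collisions pushed to the next free rank
        while len(active_ranks) < n_actives:
            for r in range(1, N + 1):
                if r not in active_ranks:
                    active_ranks.add(r)
                    break
    else:
        ranks = sorted(int(r) for r in placement)
        if any(r < 1 or r > N for r in ranks) or len(set(ranks)) != len(ranks):
            raise ValueError("invalid placement ranks")
        if len(ranks) > n_actives:
            raise ValueError("more placement ranks than actives")
        unranked = n_actives - len(ranks)
        active_ranks = set(ranks)
        n_entries = N - unranked
        if any(r > n_entries for r in ranks):
            raise ValueError("explicit ranks collide with the unranked tail")
        entries = [(f"cmpd_{r:05d}", float(N - r), r in active_ranks)
                   for r in range(1, n_entries + 1)]
        return RankedList(entries=entries, unranked_actives=unranked)

    entries = [(f"cmpd_{r:05d}", float(N - r), r in active_ranks)
               for r in range(1, N + 1)]
    return RankedList(entries=entries, unranked_actives=0)
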
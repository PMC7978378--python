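"""Property-matched, topology-dissimilar decoy selection.

Implements the six DecoyFinder-style criteria: a candidate decoy must
(1) have Tanimoto < 0.75 to every active, be within (2) +-2 H-bond
acceptors, (3) +-1 H-bond donors, (4) +-25 Da molecular weight and
(5) +-1 logP of at least one active (per-active matching), and
(6) have Tanimoto < 0.9 to every already-accepted decoy. Tanimoto values
use binary ECFP4/2048 throughout. The scan is greedy in pool order; seeded
shuffling of the pool is the only sanctioned randomness. Every examined
candidate is logged with its accepting active or rejecting criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chemstore import MoleculeRecord, compute_properties
from .fingerprints import ecfp4, tanimoto

__all__ = ["DecoyCriteria", "select_decoys", "verify_decoys"]


@dataclass(frozen=True)
class DecoyCriteria:
    """Thresholds for the six selection criteria."""

    max_tc_to_actives: float = 0.75
    hba_window: int = 2
    hbd_window: int = 1
    mw_window: float = 25.0
    logp_window: float = 1.0
    max_tc_between_decoys: float = 0.9

    def __post_init__(self) -> None:
        for w in (self.hba_window, self.hbd_window, self.mw_window,
                  self.logp_window):
            if w < 0:
                raise ValueError("property windows must be >= 0")
        for t in (self.max_tc_to_actives, self.max_tc_between_decoys):
            if not (0 < t <= 1):
                raise ValueError("Tc thresholds must be in (0, 1]")


def _props_match(cand_props, act_props, criteria: DecoyCriteria) -> bool:
    """Inclusive property windows against one active."""
    return (abs(cand_props.hba - act_props.hba) <= criteria.hba_window
            and abs(cand_props.hbd - act_props.hbd) <= criteria.hbd_window
            and abs(cand_props.mw - act_props.mw) <= criteria.mw_window
            and abs(cand_props.logp - act_props.logp) <= criteria.logp_window)


def select_decoys(actives: Sequence[MoleculeRecord],
                  pool: Sequence[MoleculeRecord],
                  criteria: DecoyCriteria = DecoyCriteria(),
                  per_active: int = 36,
                  seed: Optional[int] = None,
                  nbits: int = 2048) -> tuple[list, pd.DataFrame]:
    """Greedy decoy selection; returns (decoys, audit table).

    The audit table has one row per examined candidate with columns
    candidate_id, matched_active, status, failed_criterion. A candidate is
    assigned to the first active (in input order) whose property windows it
    satisfies and that still has capacity.
    """
    if not actives or not pool:
        raise ValueError("actives and pool must be non-empty")
    if per_active < 1:
        raise ValueError("per_active must be >= 1")
    active_ids = {a.id for a in actives}
    if any(p.id in active_ids for p in pool):
        raise ValueError("pool and actives must be disjoint by id")

    pool = list(pool)
    if seed is not None:
        rng = np.random.default_rng(seed)
        rng.shuffle(pool)

    act_props = [compute_properties(a) for a in actives]
    act_fps = [ecfp4(a, nbits) for a in actives]

    accepted: list[MoleculeRecord] = []
    accepted_fps = []
    capacity = {a.id: per_active for a in actives}
    audit_rows = []

    for cand in pool:
        cand_props = compute_properties(cand)
        cand_fp = ecfp4(cand, nbits)
        row = {"candidate_id": cand.id, "matched_active": None,
               "status": "rejected", "failed_criterion": None}

        # criterion 1: topological dissimilarity from every active
        max_tc_act = max(tanimoto(cand_fp, afp) for afp in act_fps)
        if max_tc_act >= criteria.max_tc_to_actives:
            row["failed_criterion"] = "tc_to_actives"
            audit_rows.append(row)
            continue

        # criteria 2-5: property windows against some active with capacity
        matched = None
        any_window_match = False
        for act, props in zip(actives, act_props):
            if _props_match(cand_props, props, criteria):
                any_window_match = True
                if capacity[act.id] > 0:
                    matched = act
                    break
        if matched is None:
            row["failed_criterion"] = ("property_windows" if not any_window_match
                                       else "per_active_quota")
            audit_rows.append(row)
            continue

        # criterion 6: dissimilarity from previously accepted decoys
        if accepted_fps and max(tanimoto(cand_fp, dfp)
                                for dfp in accepted_fps) >= \
                criteria.max_tc_between_decoys:
            row["failed_criterion"] = "tc_between_decoys"
            audit_rows.append(row)
            continue

        capacity[matched.id] -= 1
        accepted.append(cand)
        accepted_fps.append(cand_fp)
        row.update(matched_active=matched.id, status="accepted")
        audit_rows.append(row)

    audit = pd.DataFrame(audit_rows, columns=[
        "candidate_id", "matched_active", "status", "failed_criterion"])
    return accepted, audit


def verify_decoys(decoys: Sequence[MoleculeRecord],
                  actives: Sequence[MoleculeRecord],
                  criteria: DecoyCriteria = DecoyCriteria(),
                  nbits: int = 2048) -> bool:
    """Independently re-check all six criteria on a returned decoy set.

    Used as a self-audit invariant: every accepted decoy must satisfy the
    Tc-to-actives bound, match the property windows of at least one active,
    and keep pairwise decoy Tc below the between-decoy bound.
    """
    act_props = [compute_properties(a) for a in actives]
    act_fps = [ecfp4(a, nbits) for a in actives]
    dec_fps = [ecfp4(d, nbits) for d in decoys]
    for i, dec in enumerate(decoys):
        props = compute_properties(dec)
        if max(tanimoto(dec_fps[i], afp) for afp in act_fps) >= \
                criteria.max_tc_to_actives:
            return False
        if not any(_props_match(props, ap, criteria) for ap in act_props):
            return False
        for j in range(i):
            if tanimoto(dec_fps[i], dec_fps[j]) >= \
                    criteria.max_tc_between_decoys:
                return False
    return True
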
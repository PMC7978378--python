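"""Classification and early-recognition metrics for virtual screening.

Covers the six classifier statistics (sensitivity, specificity, positive and
negative predictive accuracy, Matthews correlation coefficient, ROC AUC), the
ranked-list "early recognition" metrics used to validate screening models
(enrichment factor at a fraction, BEDROC, area under the accumulation curve),
and the Cheng-Prusoff conversion from a competition IC50 to a binding
constant Ki.

Ranked lists may carry *unranked* actives: compounds known to be active that
the screening model failed to score at all (e.g. pharmacophore non-matchers).
By default these are treated as occupying the very bottom ranks of the
evaluation universe, which is the conservative choice for every metric here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "RankedList",
    "EnrichmentParams",
    "AssayConstants",
    "DPCPX",
    "ZM241385",
    "confusion_metrics",
    "roc_auc",
    "enrichment_factor",
    "bedroc",
    "auac",
    "cheng_prusoff",
    "p_transform",
    "read_ranked_csv",
    "write_ranked_csv",
]


# ---------------------------------------------------------------------------
# Confusion-matrix statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of true/false positives and negatives for a 2-class screen."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_actives(self) -> int:
        return self.tp + self.fn

    @property
    def n_inactives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricSet:
    """SE/SP/Q+/Q-/MCC (and optionally AUC) for one classifier.

    A metric whose defining denominator is zero is reported as None
    ("undefined") rather than silently coerced to 0.
    """

    se: Optional[float]
    sp: Optional[float]
    q_plus: Optional[float]
    q_minus: Optional[float]
    mcc: Optional[float]
    auc: Optional[float] = None

    def rounded(self, ndigits: int = 3) -> "MetricSet":
        rd = lambda v: None if v is None else round(v, ndigits)
        return MetricSet(rd(self.se), rd(self.sp), rd(self.q_plus),
                         rd(self.q_minus), rd(self.mcc), rd(self.auc))


def confusion_metrics(cc: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, predictive accuracies and MCC from counts.

    SE = TP/(TP+FN); SP = TN/(TN+FP); Q+ = TP/(TP+FP); Q- = TN/(TN+FN);
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP)).

    Intermediate arithmetic is exact (integer/Fraction); the square root is
    the only floating step.
    """
    tp, fp, tn, fn = cc.tp, cc.fp, cc.tn, cc.fn

    def ratio(num: int, den: int) -> Optional[float]:
        return None if den == 0 else float(Fraction(num, den))

    se = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    q_plus = ratio(tp, tp + fp)
    q_minus = ratio(tn, tn + fn)

    denom_sq = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = None if denom_sq == 0 else (tp * tn - fn * fp) / math.sqrt(denom_sq)
    return MetricSet(se=se, sp=sp, q_plus=q_plus, q_minus=q_minus, mcc=mcc)


# ---------------------------------------------------------------------------
# Ranked lists
# ---------------------------------------------------------------------------

@dataclass
class RankedList:
    """A score-descending screen output over a fixed evaluation universe.

    ``entries`` are the scored compounds; ``unranked_actives`` counts actives
    the screen produced no score for. The universe size is
    ``N = len(entries) + unranked_actives`` and the active total ``n`` counts
    ranked and unranked actives alike.

    Ties in score are broken pessimistically for the actives (an active never
    ranks above an equally-scored inactive), so tied metrics are lower bounds.
    """

    entries: list = field(default_factory=list)  # (id, score, is_active)
    unranked_actives: int = 0

    def __post_init__(self) -> None:
        if self.unranked_actives < 0:
            raise ValueError("unranked_actives must be >= 0")
        # sort descending by score; among ties inactives come first
        self.entries = sorted(
            self.entries, key=lambda e: (-float(e[1]), bool(e[2]))
        )

    @property
    def n_total(self) -> int:
        return len(self.entries) + self.unranked_actives

    @property
    def n_actives(self) -> int:
        return sum(1 for e in self.entries if e[2]) + self.unranked_actives

    def active_ranks(self, include_unranked: bool = True) -> list[int]:
        """1-based ranks of actives; unranked actives get the bottom ranks."""
        ranks = [i + 1 for i, e in enumerate(self.entries) if e[2]]
        if include_unranked:
            base = len(self.entries)
            ranks += list(range(base + 1, base + 1 + self.unranked_actives))
        return ranks

    def scores_and_labels(self) -> tuple[np.ndarray, np.ndarray]:
        scores = np.array([float(e[1]) for e in self.entries])
        labels = np.array([bool(e[2]) for e in self.entries])
        return scores, labels


@dataclass(frozen=True)
class EnrichmentParams:
    """Fraction for EF (e.g. 0.01 for EF1%) and alpha for BEDROC."""

    fraction: float = 0.01
    alpha: float = 160.9

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


def roc_auc(ranked: RankedList) -> float:
    """ROC AUC as the tie-corrected pairwise concordance statistic.

    Equals P(score_active > score_inactive) + 0.5 * P(equal). Unranked
    actives are treated as scoring below every ranked entry, contributing 0
    concordance against each inactive.
    """
    scores, labels = ranked.scores_and_labels()
    n_act = ranked.n_actives
    n_inact = ranked.n_total - n_act
    if n_act == 0 or n_inact == 0:
        raise ValueError("roc_auc needs at least one active and one inactive")

    act_scores = scores[labels]
    inact_scores = scores[~labels]
    # rank-sum formulation with midranks handles ties exactly
    if act_scores.size and inact_scores.size:
        from scipy.stats import rankdata

        allscores = np.concatenate([act_scores, inact_scores])
        r = rankdata(allscores)  # ascending midranks
        rank_sum = r[: act_scores.size].sum()
        concordant = rank_sum - act_scores.size * (act_scores.size + 1) / 2.0
    else:
        concordant = 0.0
    # unranked actives add 0 concordant pairs
    return float(concordant) / (n_act * n_inact)


def enrichment_factor(ranked: RankedList, params: EnrichmentParams) -> float:
    """Enrichment factor at the given fraction of the universe.

    The top bin holds ceil(fraction * N) entries; EF is the active rate in
    that bin divided by the global active rate n/N.
    """
    N = ranked.n_total
    n = ranked.n_actives
    if n == 0:
        raise ValueError("enrichment factor undefined with zero actives")
    bin_size = math.ceil(params.fraction * N)
    if bin_size < 1:
        raise ValueError("fraction * N must round to at least one entry")
    hits = sum(1 for e in ranked.entries[:bin_size] if e[2])
    return (hits / bin_size) / (n / N)


def bedroc(ranked: RankedList, params: EnrichmentParams,
           unranked: str = "bottom") -> float:
    """Boltzmann-enhanced discrimination of ROC (Truchon-Bayly).

    RIE is the mean Boltzmann weight e^{-alpha * r_i / N} over actives,
    normalized by its random expectation; BEDROC rescales RIE onto [0, 1]
    with the full hyperbolic min/max normalization.

    ``unranked`` selects how actives without a score enter: "bottom" (the
    default) assigns them the worst ranks; "exclude" drops them from the
    universe altogether.
    """
    if params.alpha <= 0:
        raise ValueError("alpha must be > 0")
    if unranked == "bottom":
        ranks = ranked.active_ranks(include_unranked=True)
        N = ranked.n_total
    elif unranked == "exclude":
        ranks = ranked.active_ranks(include_unranked=False)
        N = len(ranked.entries)
    else:
        raise ValueError("unranked must be 'bottom' or 'exclude'")
    n = len(ranks)
    if n == 0:
        raise ValueError("bedroc undefined with zero actives")
    if N <= n:
        raise ValueError("bedroc needs at least one inactive in the universe")

    a = params.alpha
    ra = n / N
    s = sum(math.exp(-a * r / N) for r in ranks)
    rand = ra * (1 - math.exp(-a)) / (math.exp(a / N) - 1)
    rie = s / rand
    return (
        rie * ra * math.sinh(a / 2) / (math.cosh(a / 2) - math.cosh(a / 2 - a * ra))
        + 1.0 / (1 - math.exp(a * (1 - ra)))
    )


def auac(ranked: RankedList) -> float:
    """Area under the accumulation curve, trapezoidal over ranks.

    The curve plots cumulative fraction of actives found vs fraction of the
    universe screened; unranked actives accumulate only in the final bottom
    ranks.
    """
    N = ranked.n_total
    n = ranked.n_actives
    if N == 0:
        raise ValueError("auac undefined on an empty list")
    if n == 0:
        raise ValueError("auac undefined with zero actives")
    found = np.zeros(N + 1)
    active_at = np.zeros(N + 1)
    for r in ranked.active_ranks(include_unranked=True):
        active_at[r] = 1
    found = np.cumsum(active_at) / n
    x = np.arange(N + 1) / N
    return float(np.trapezoid(found, x))


# ---------------------------------------------------------------------------
# Assay math
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayConstants:
    """Radioligand concentration [C*] and dissociation constant Kd*, in nM."""

    radioligand_conc: float
    radioligand_kd: float

    def __post_init__(self) -> None:
        if self.radioligand_conc < 0:
            raise ValueError("radioligand concentration must be >= 0")
        if self.radioligand_kd <= 0:
            raise ValueError("radioligand Kd must be > 0")


#: [3H]DPCPX conditions for the A1 receptor competition assay.
DPCPX = AssayConstants(radioligand_conc=2.5, radioligand_kd=2.1)
#: [3H]ZM241385 conditions for the A2A receptor competition assay.
ZM241385 = AssayConstants(radioligand_conc=0.5, radioligand_kd=2.06)


def cheng_prusoff(ic50: float, constants: AssayConstants) -> float:
    """Ki = IC50 / (1 + [C*]/Kd*), all concentrations in nM.

    In the limit [C*] -> 0 (no competing radioligand) Ki equals IC50.
    """
    if ic50 <= 0:
        raise ValueError("IC50 must be > 0")
    return ic50 / (1.0 + constants.radioligand_conc / constants.radioligand_kd)


def p_transform(x_nM: float) -> float:
    """Negative log10 of a concentration given in nM (pKi/pIC50 scale)."""
    if x_nM <= 0:
        raise ValueError("concentration must be > 0")
    return -math.log10(x_nM * 1e-9)


# ---------------------------------------------------------------------------
# Ranked-list IO
# ---------------------------------------------------------------------------

def read_ranked_csv(path, unranked_actives: int = 0) -> RankedList:
    """Read a ranked list from CSV with columns id, score, is_active."""
    df = pd.read_csv(path)
    for col in ("id", "score", "is_active"):
        if col not in df.columns:
            raise ValueError(f"ranked CSV missing column {col!r}")
    entries = [
        (str(r.id), float(r.score), bool(r.is_active))
        for r in df.itertuples(index=False)
    ]
    return RankedList(entries=entries, unranked_actives=unranked_actives)


def write_ranked_csv(ranked: RankedList, path) -> None:
    df = pd.DataFrame(ranked.entries, columns=["id", "score", "is_active"])
    df.to_csv(path, index=False)
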
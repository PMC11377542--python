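"""Screening-evaluation statistics: EF, ROC enrichment, AUC, success rates.

All metrics operate on a :class:`RankedList` of (label, score, id) entries.
The ``direction`` flag normalizes affinity-style rankings (lower dG is
better) into a common internal order; ties in score are broken by compound id
so top-X% membership is deterministic, while AUC uses midranks for ties as a
proper rank statistic.

Conventions, fixed and documented because the field uses several:

* top-X% window size is ``ceil(x/100 * n)`` compounds;
* ROC enrichment takes the true-positive rate at the ranking position where
  the false-positive rate first reaches X% — counted in whole decoys, no
  interpolation — divided by ``x/100``;
* screening-power success at top-X% means the best binder's rank is within
  ``ceil(x/100 * n)`` for that target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score


class MetricsError(ValueError):
    pass


@dataclass
class RankedList:
    """(label, score, id) triples plus the score direction."""

    labels: np.ndarray
    scores: np.ndarray
    ids: list[str] = field(default_factory=list)
    direction: str = "lower_is_better"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(int).ravel()
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        if self.labels.shape != self.scores.shape:
            raise MetricsError("labels and scores length mismatch")
        if not self.ids:
            self.ids = [f"c{i}" for i in range(len(self.labels))]
        if len(self.ids) != len(self.labels):
            raise MetricsError("ids length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise MetricsError("ids must be unique")
        if self.direction not in ("lower_is_better", "higher_is_better"):
            raise MetricsError(f"unknown direction {self.direction!r}")

    def __len__(self) -> int:
        return int(len(self.labels))

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    @property
    def n_decoys(self) -> int:
        return int(len(self) - self.labels.sum())

    def goodness(self) -> np.ndarray:
        """Scores mapped so larger = better regardless of direction."""
        return -self.scores if self.direction == "lower_is_better" else self.scores

    def rank_order(self) -> np.ndarray:
        """Indices best-first, ties broken by id."""
        ids = np.asarray(self.ids)
        return np.lexsort((ids, -self.goodness()))


def roc_auc(ranked: RankedList) -> float:
    """Rank-based AUC (midrank tie handling).

    Equals the probability that a uniformly random active outranks a
    uniformly random decoy, counting ties as half.
    """
    if ranked.n_actives == 0 or ranked.n_decoys == 0:
        raise MetricsError("AUC needs both classes")
    return float(roc_auc_score(ranked.labels, ranked.goodness()))


def enrichment_factor(ranked: RankedList, x_percent: float) -> float:
    """EF at X%: active rate in the top ceil(x% n) over the overall active rate."""
    if not 0 < x_percent <= 100:
        raise MetricsError("x_percent must be in (0, 100]")
    if ranked.n_actives == 0:
        raise MetricsError("EF needs at least one active")
    n = len(ranked)
    k = math.ceil(x_percent / 100.0 * n)
    top = ranked.rank_order()[:k]
    hits = int(ranked.labels[top].sum())
    return (hits / ranked.n_actives) / (x_percent / 100.0)


def roc_enrichment(ranked: RankedList, fpr_percent: float) -> float:
    """TPR at the first whole-decoy crossing of X% FPR, divided by x/100."""
    if ranked.n_actives == 0 or ranked.n_decoys == 0:
        raise MetricsError("ROC enrichment needs both classes")
    if not 0 < fpr_percent < 100:
        raise MetricsError("fpr_percent must be in (0, 100)")
    k_decoys = math.ceil(fpr_percent / 100.0 * ranked.n_decoys)
    order = ranked.rank_order()
    decoys_seen = 0
    actives_seen = 0
    for idx in order:
        if ranked.labels[idx] == 1:
            actives_seen += 1
        else:
            decoys_seen += 1
            if decoys_seen >= k_decoys:
                break
    tpr = actives_seen / ranked.n_actives
    return tpr / (fpr_percent / 100.0)


def screening_success_rate(
    per_target_best_binder_rank: Sequence[tuple[int, int]], top_percent: float
) -> float:
    """Percent of targets whose best binder ranks within the top X%."""
    if not per_target_best_binder_rank:
        raise MetricsError("empty input")
    hits = 0
    for rank, n_candidates in per_target_best_binder_rank:
        if not 1 <= rank <= n_candidates:
            raise MetricsError(f"rank {rank} outside [1, {n_candidates}]")
        if rank <= math.ceil(top_percent / 100.0 * n_candidates):
            hits += 1
    return 100.0 * hits / len(per_target_best_binder_rank)


def docking_success(
    poses: Sequence[tuple[float, float]], rmsd_cutoff: float = 2.0
) -> bool:
    """True iff the best-scored pose (ties: lowest rmsd) is within the cutoff."""
    if not poses:
        raise MetricsError("empty pose list")
    best = min(poses, key=lambda sr: (sr[0], sr[1]))
    return best[1] <= rmsd_cutoff


# ---------------------------------------------------------------------------
# campaign arithmetic
# ---------------------------------------------------------------------------

def hit_rate(n_hits: int, n_tested: int) -> float:
    """Experimental hit rate in percent (hits / compounds tested)."""
    if n_tested < 1 or n_hits < 0 or n_hits > n_tested:
        raise MetricsError("invalid hit counts")
    return 100.0 * n_hits / n_tested


def rank_percentile(rank: int, n_total: int) -> float:
    """Rank expressed as a percentile of the library, in percent."""
    if not 1 <= rank <= n_total:
        raise MetricsError("rank outside library")
    return 100.0 * rank / n_total
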
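"""Post-screen hit selection: property filters, clustering, novelty, ledger.

After the docking campaign, the ranked candidate sheet is triaged before any
compound is considered for synthesis:

* **property filters** drop poses that look like false positives — too
  lipophilic (cLogP > 3.5), buried unsatisfied hydrogen bonds at the
  interface (Nunsats > 1), or torsion-geometry outliers
  (N_unusual_torsion > 1);
* **similarity clustering** (leader / sphere-exclusion at Tanimoto 0.6)
  removes redundancy, keeping one representative per chemotype — either the
  best-affinity member or the smallest (fewest heavy atoms, for building
  centroid libraries);
* a **novelty filter** removes anything within Tanimoto 0.33 of known
  actives.

Both campaign orderings are expressible (filter-then-cluster or
cluster-then-filter).  Every stage records (n_in, n_removed, n_out) and the
removed ids with reasons in a :class:`TriageLedger`, which checks its own
conservation: counts chain exactly from stage to stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .library import CompoundRecord, tanimoto
from .oracle import PoseProperties


class TriageError(ValueError):
    pass


@dataclass
class HitRecord:
    """One ranked candidate: compound + dock outcome, as triage sees it."""

    record: CompoundRecord
    dG: float
    pose: PoseProperties

    @property
    def id(self) -> str:
        return self.record.id


@dataclass
class FilterRules:
    max_clogp: float = 3.5
    max_unsats: int = 1
    max_unusual_torsion: int | None = 1
    order: tuple[str, ...] = ("clogp", "unsats")

    KNOWN_STAGES = ("clogp", "unsats", "unusual_torsion")

    def __post_init__(self) -> None:
        if not self.order:
            raise TriageError("stage order must be non-empty")
        for stage in self.order:
            if stage not in self.KNOWN_STAGES:
                raise TriageError(f"unknown filter stage {stage!r}")


@dataclass
class LedgerStage:
    stage: str
    n_in: int
    n_removed: int
    n_out: int
    removed: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class TriageLedger:
    stages: list[LedgerStage] = field(default_factory=list)

    def add(self, stage: str, n_in: int, removed: list[tuple[str, str]]) -> None:
        entry = LedgerStage(
            stage=stage, n_in=n_in, n_removed=len(removed),
            n_out=n_in - len(removed), removed=removed,
        )
        if self.stages and self.stages[-1].n_out != n_in:
            raise TriageError(
                f"ledger chain broken: stage {stage!r} n_in={n_in} but previous "
                f"n_out={self.stages[-1].n_out}"
            )
        self.stages.append(entry)

    def stage_named(self, name: str) -> LedgerStage:
        for s in self.stages:
            if s.stage == name:
                return s
        raise KeyError(name)

    @property
    def n_in(self) -> int:
        return self.stages[0].n_in if self.stages else 0

    @property
    def n_out(self) -> int:
        return self.stages[-1].n_out if self.stages else 0


def _stage_failure(hit: HitRecord, stage: str, rules: FilterRules) -> str | None:
    """Reason string if ``hit`` fails ``stage``, else None; missing data flags."""
    if stage == "clogp":
        if hit.record.clogp is None:
            return "missing cLogP"
        if hit.record.clogp > rules.max_clogp:
            return f"cLogP {hit.record.clogp:.2f} > {rules.max_clogp}"
    elif stage == "unsats":
        if hit.pose.n_unsats > rules.max_unsats:
            return f"Nunsats {hit.pose.n_unsats} > {rules.max_unsats}"
    elif stage == "unusual_torsion":
        if rules.max_unusual_torsion is not None and (
            hit.pose.n_unusual_torsion > rules.max_unusual_torsion
        ):
            return (
                f"N_unusual_torsion {hit.pose.n_unusual_torsion} > "
                f"{rules.max_unusual_torsion}"
            )
    return None


def apply_filters(
    hits: Sequence[HitRecord],
    rules: FilterRules | None = None,
    ledger: TriageLedger | None = None,
) -> tuple[list[HitRecord], TriageLedger]:
    """Apply filter stages sequentially; each record is removed at the first
    stage it fails.  Per-record predicates, so survivors are independent of
    input order."""
    if rules is None:
        rules = FilterRules()
    if ledger is None:
        ledger = TriageLedger()
    current = list(hits)
    for stage in rules.order:
        removed: list[tuple[str, str]] = []
        survivors: list[HitRecord] = []
        for hit in current:
            reason = _stage_failure(hit, stage, rules)
            if reason is None:
                survivors.append(hit)
            else:
                removed.append((hit.id, reason))
        ledger.add(stage, len(current), removed)
        current = survivors
    return current, ledger


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    leader: HitRecord
    members: list[HitRecord]


def cluster_compounds(
    hits: Sequence[HitRecord], similarity_cutoff: float = 0.6
) -> list[Cluster]:
    """Deterministic leader (sphere-exclusion) clustering.

    Records are visited best-dG-first (ties by id); each joins the first
    existing cluster whose *leader* is at least ``similarity_cutoff`` similar,
    else founds a new cluster.  The visit order makes the result independent
    of input permutation.
    """
    ordered = sorted(hits, key=lambda h: (h.dG, h.id))
    clusters: list[Cluster] = []
    for hit in ordered:
        placed = False
        for cluster in clusters:
            if tanimoto(hit.record.fingerprint, cluster.leader.record.fingerprint) >= (
                similarity_cutoff
            ):
                cluster.members.append(hit)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(leader=hit, members=[hit]))
    return clusters


def _heavy_atoms(hit: HitRecord) -> int:
    ha = hit.record.heavy_atoms
    if ha is not None:
        return ha
    # fall back to a mass-based proxy when atom counts are unavailable
    return int(round((hit.record.mol_mass or 0.0) / 13.0))


def pick_representative(cluster: Cluster, policy: str = "best_affinity") -> HitRecord:
    """Cluster representative under the given policy.

    ``best_affinity``: minimum dG (ties: fewer heavy atoms, then id);
    ``smallest``: fewest heavy atoms (ties: lower mass, then id).
    """
    if not cluster.members:
        raise TriageError("empty cluster")
    if policy == "best_affinity":
        return min(cluster.members, key=lambda h: (h.dG, _heavy_atoms(h), h.id))
    if policy == "smallest":
        return min(
            cluster.members, key=lambda h: (_heavy_atoms(h), h.record.mol_mass or math.inf, h.id)
        )
    raise TriageError(f"unknown representative policy {policy!r}")


def novelty_filter(
    hits: Sequence[HitRecord],
    known_actives: Sequence[np.ndarray],
    max_similarity: float = 0.33,
    ledger: TriageLedger | None = None,
) -> tuple[list[HitRecord], TriageLedger]:
    """Keep records whose max Tanimoto to any known active is < cutoff.

    An empty known-actives set passes everything.
    """
    if ledger is None:
        ledger = TriageLedger()
    removed: list[tuple[str, str]] = []
    survivors: list[HitRecord] = []
    for hit in hits:
        max_sim = max(
            (tanimoto(hit.record.fingerprint, ka) for ka in known_actives), default=0.0
        )
        if max_sim < max_similarity:
            survivors.append(hit)
        else:
            removed.append((hit.id, f"similarity {max_sim:.3f} >= {max_similarity}"))
    ledger.add("novelty", len(hits), removed)
    return survivors, ledger
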
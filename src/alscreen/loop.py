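"""The active-learning screening loop: dock -> label -> train -> select.

One campaign iterates a cheap docking mode over a growing subset of the
library, guided by the surrogate classifier:

1. iteration 1 docks random, disjoint training and testing samples;
2. affinities are ranked as ``dG = dH + dS`` (entropy penalty, simple mode by
   default so no per-compound sampling is needed at scale);
3. a dG cutoff at the iteration's scheduled top-N% of the *testing* set turns
   affinities into binder labels; the surrogate is (re)trained with early
   stopping against the fixed testing set;
4. the surrogate scores every never-docked compound; the next batch is the
   greedy top ``n_select_top`` by predicted probability plus
   ``n_select_random`` uniform draws from the remainder;
5. the loop stops at ``max_iterations`` or when the running best dG stops
   improving; the top-ranked compounds are then re-docked in the
   high-precision mode and the refreshed dG replaces the express value for
   the final ranking.

Counts are config-scaled: the production-scale profile (0.5 M / 1 M / 0.25 M
+ 0.25 M, ten iterations, 50 k rescore) is preserved as ``paper_profile``;
the default desk profile runs the same loop at thousands of compounds.
Every random choice derives from the campaign seed, and oracle noise is keyed
per compound, so a campaign replays bit-for-bit from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .entropy import EntropyParams, binding_free_energy, total_entropy
from .library import CompoundRecord, shard_batches
from .oracle import DockRequest, DockResult, DockingOracle, dock_batch
from .surrogate import (
    LabeledSet,
    SurrogateConfig,
    SurrogateModel,
    TrainingReport,
    assign_labels,
    compute_cutoff,
    predict_library,
    schedule_percent,
    train_surrogate,
)


class ScreenError(ValueError):
    pass


@dataclass
class ScreenConfig:
    """Campaign-level counts, schedule and convergence settings."""

    n_train_init: int = 5_000
    n_test_init: int = 10_000
    n_select_top: int = 2_500
    n_select_random: int = 2_500
    max_iterations: int = 10
    schedule_points: int = 10
    schedule_start: float = 10.0
    schedule_end: float = 0.01
    rescore_top_k: int = 500
    batch_size_express: int = 50
    batch_size_high_precision: int = 5
    convergence_tolerance: float = 0.1
    convergence_patience: int = 2
    top_percentile: float = 0.1
    seed: int = 0
    entropy: EntropyParams = field(default_factory=lambda: EntropyParams(mode="simple"))
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)

    def __post_init__(self) -> None:
        for name in (
            "n_train_init", "n_test_init", "n_select_top", "n_select_random",
            "rescore_top_k",
        ):
            if getattr(self, name) <= 0:
                raise ScreenError(f"{name} must be positive")
        if self.max_iterations < 1:
            raise ScreenError("max_iterations must be >= 1")


def paper_profile(**overrides) -> ScreenConfig:
    """Production-scale counts (0.5 M / 1 M / 0.25 M + 0.25 M, 50 k rescore)."""
    cfg = dict(
        n_train_init=500_000, n_test_init=1_000_000,
        n_select_top=250_000, n_select_random=250_000,
        max_iterations=10, rescore_top_k=50_000,
    )
    cfg.update(overrides)
    return ScreenConfig(**cfg)


def compact_profile(seed: int = 0, **overrides) -> ScreenConfig:
    """Small desk campaign used for end-to-end properties on ~50 k libraries.

    Sized so that four iterations dock 6000 compounds: an ideal selector can
    then concentrate planted binders well above the base rate, keeping
    enrichment properties informative (with larger per-iteration budgets the
    docked set would swamp the 500 planted binders arithmetically).
    """
    cfg = dict(
        n_train_init=1_000, n_test_init=2_000,
        n_select_top=500, n_select_random=500,
        max_iterations=10, rescore_top_k=200,
        seed=seed,
        surrogate=SurrogateConfig(
            hidden_sizes=(256, 256), max_epochs=12, patience=3, batch_size=256,
            learning_rate=3e-4, seed=seed,
        ),
    )
    cfg.update(overrides)
    return ScreenConfig(**cfg)


@dataclass
class IterationState:
    """Cumulative ledger of a campaign."""

    iteration: int = 0
    docked: dict[str, DockResult] = field(default_factory=dict)
    dG: dict[str, float] = field(default_factory=dict)
    dS: dict[str, float] = field(default_factory=dict)
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)
    cutoff_history: list[tuple[float, float]] = field(default_factory=list)
    top_percentile_dG: list[float] = field(default_factory=list)
    best_dG_history: list[float] = field(default_factory=list)
    selection_history: list[list[str]] = field(default_factory=list)
    truncated: bool = False
    model: SurrogateModel | None = None
    report: TrainingReport | None = None
    model_hashes: list[str] = field(default_factory=list)

    @property
    def n_docked(self) -> int:
        return len(self.docked)

    def best_dG(self) -> float:
        return min(self.dG.values())


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _dock_ids(
    ids: Sequence[str],
    by_id: dict[str, CompoundRecord],
    oracle: DockingOracle,
    mode: str,
    batch_size: int,
    receptor_id: str = "target",
) -> list[DockResult]:
    records = [by_id[i] for i in ids]
    results: list[DockResult] = []
    for shard in shard_batches(records, batch_size):
        results.extend(dock_batch(DockRequest(receptor_id, mode, shard), oracle))
    return results

def _absorb_results(
    state: IterationState, results: Sequence[DockResult],
    by_id: dict[str, CompoundRecord], config: ScreenConfig,
) -> None:
    for res in results:
        state.docked[res.compound_id] = res
        if res.ok:
            ds = total_entropy(by_id[res.compound_id], params=config.entropy)
            state.dS[res.compound_id] = ds
            state.dG[res.compound_id] = binding_free_energy(res.dH, ds)


def _record_summaries(
    state: IterationState, config: ScreenConfig, n_library: int
) -> None:
    # top-percentile window is sized by the library being screened, so the
    # summary is the running k-th-best docked dG and can only improve
    dgs = np.sort(np.fromiter(state.dG.values(), dtype=float))
    k = max(1, int(np.ceil(config.top_percentile / 100.0 * n_library)))
    state.top_percentile_dG.append(float(dgs[min(k, len(dgs)) - 1]))
    best = float(dgs[0])
    if state.best_dG_history:
        best = min(best, state.best_dG_history[-1])
    state.best_dG_history.append(best)


def _labeled_sets(
    state: IterationState, by_id: dict[str, CompoundRecord], percent: float
) -> tuple[LabeledSet, LabeledSet, float]:
    test_dgs = np.array([state.dG[i] for i in state.test_ids])
    cutoff = compute_cutoff(test_dgs, percent)
    train_fps = np.stack([by_id[i].fingerprint for i in state.train_ids])
    train_dgs = np.array([state.dG[i] for i in state.train_ids])
    train = LabeledSet(train_fps, assign_labels(train_dgs, cutoff), dG=train_dgs, role="train")
    test_fps = np.stack([by_id[i].fingerprint for i in state.test_ids])
    test = LabeledSet(test_fps, assign_labels(test_dgs, cutoff), dG=test_dgs, role="test")
    return train, test, float(cutoff)


def _model_hash(model: SurrogateModel) -> str:
    h = hashlib.sha256()
    for key, arr in sorted(model.state_dict().items()):
        h.update(key.encode())
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def _train_iteration(
    state: IterationState, by_id: dict[str, CompoundRecord], config: ScreenConfig
) -> None:
    percent = schedule_percent(
        min(state.iteration, config.schedule_points),
        config.schedule_points, config.schedule_start, config.schedule_end,
    )
    train, test, cutoff = _labeled_sets(state, by_id, percent)
    if len(np.unique(train.labels)) < 2:
        # degenerate labelling (all one class): keep the previous model
        state.cutoff_history.append((percent, cutoff))
        return
    surrogate_cfg = SurrogateConfig(**{
        **asdict(config.surrogate), "seed": config.surrogate.seed + state.iteration,
    })
    state.model, state.report = train_surrogate(train, test, surrogate_cfg)
    state.model_hashes.append(_model_hash(state.model))
    state.cutoff_history.append((percent, cutoff))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def init_screen(
    library: Sequence[CompoundRecord], oracle: DockingOracle, config: ScreenConfig
) -> IterationState:
    """Iteration 1: dock disjoint random train/test samples and train."""
    n_needed = config.n_train_init + config.n_test_init
    if len(library) < n_needed:
        raise ScreenError(f"library of {len(library)} smaller than {n_needed}")
    by_id = {r.id: r for r in library}
    ids = sorted(by_id)
    rng = np.random.default_rng(config.seed)
    sample = rng.choice(len(ids), size=n_needed, replace=False)
    train_ids = [ids[i] for i in sample[: config.n_train_init]]
    test_ids = [ids[i] for i in sample[config.n_train_init :]]

    state = IterationState(iteration=1, train_ids=train_ids, test_ids=test_ids)
    results = _dock_ids(
        train_ids + test_ids, by_id, oracle, "express", config.batch_size_express
    )
    _absorb_results(state, results, by_id, config)
    _record_summaries(state, config, len(library))
    _train_iteration(state, by_id, config)
    return state


def select_next_batch(
    model: SurrogateModel,
    library: Sequence[CompoundRecord],
    state: IterationState,
    config: ScreenConfig,
) -> list[str]:
    """Greedy top-probability picks plus uniform random exploration.

    Both parts draw only from never-docked compounds, the random part also
    excludes the greedy picks; probability ties break by compound id.  If
    fewer undocked compounds remain than requested, all are returned and the
    truncation is flagged on the state.
    """
    undocked = [r for r in library if r.id not in state.docked]
    n_want = config.n_select_top + config.n_select_random
    if not undocked:
        return []
    if len(undocked) <= n_want:
        state.truncated = True
        return [r.id for r in undocked]
    fps = np.stack([r.fingerprint for r in undocked])
    probs = predict_library(model, fps)
    ids = np.array([r.id for r in undocked])
    order = np.lexsort((ids, -probs))
    greedy = [str(x) for x in ids[order[: config.n_select_top]]]
    rest = ids[order[config.n_select_top :]]
    rng = np.random.default_rng((config.seed, state.iteration))
    random_part = rng.choice(rest, size=config.n_select_random, replace=False)
    return greedy + [str(x) for x in random_part]


def run_iteration(
    state: IterationState,
    library: Sequence[CompoundRecord],
    oracle: DockingOracle,
    config: ScreenConfig,
) -> IterationState:
    """One active-learning round: select, dock, augment, retrain, summarize."""
    if state.model is None:
        raise ScreenError("run_iteration requires a trained model from a previous round")
    by_id = {r.id: r for r in library}
    selection = select_next_batch(state.model, library, state, config)
    state.iteration += 1
    state.selection_history.append(selection)
    if selection:
        results = _dock_ids(selection, by_id, oracle, "express", config.batch_size_express)
        _absorb_results(state, results, by_id, config)
        state.train_ids.extend([i for i in selection if i not in set(state.test_ids)])
    _record_summaries(state, config, len(library))
    _train_iteration(state, by_id, config)
    return state


def check_convergence(state: IterationState, config: ScreenConfig) -> bool:
    """True at max_iterations, or when the best dG has stalled for
    ``convergence_patience`` consecutive iterations."""
    if state.iteration >= config.max_iterations:
        return True
    hist = state.best_dG_history
    patience = config.convergence_patience
    if len(hist) < patience + 1:
        return False
    recent = hist[-(patience + 1) :]
    improvements = [recent[i] - recent[i + 1] for i in range(patience)]
    return all(imp < config.convergence_tolerance for imp in improvements)


def rescore_top(
    state: IterationState,
    library: Sequence[CompoundRecord],
    oracle_high_precision: DockingOracle,
    k: int,
    config: ScreenConfig,
) -> pd.DataFrame:
    """Re-dock the current top-k by dG in high-precision mode; the refreshed
    dG replaces the express value in the final ranking."""
    if k == 0:
        return pd.DataFrame(columns=["rank", "compound_id", "dH", "dS", "dG"])
    if k > state.n_docked:
        raise ScreenError(f"k={k} exceeds docked count {state.n_docked}")
    by_id = {r.id: r for r in library}
    top_ids = sorted(state.dG, key=lambda i: (state.dG[i], i))[:k]
    results = _dock_ids(
        top_ids, by_id, oracle_high_precision, "high_precision",
        config.batch_size_high_precision,
    )
    rows = []
    for res in results:
        if not res.ok:
            continue
        ds = state.dS[res.compound_id]
        dg = binding_free_energy(res.dH, ds)
        state.docked[res.compound_id] = res
        state.dG[res.compound_id] = dg
        rows.append({"compound_id": res.compound_id, "dH": res.dH, "dS": ds, "dG": dg})
    df = pd.DataFrame(rows).sort_values(["dG", "compound_id"]).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


# ---------------------------------------------------------------------------
# campaigns and manifests
# ---------------------------------------------------------------------------

@dataclass
class CampaignResult:
    state: IterationState
    final_ranking: pd.DataFrame
    manifest: dict


def campaign_manifest(config: ScreenConfig, state: IterationState) -> dict:
    """Everything needed to replay a campaign (plus audit info)."""
    cfg = asdict(config)
    return {
        "config": cfg,
        "iterations_run": state.iteration,
        "n_docked": state.n_docked,
        "cutoff_history": state.cutoff_history,
        "selection_sizes": [len(s) for s in state.selection_history],
        "model_hashes": state.model_hashes,
        "best_dG_history": state.best_dG_history,
        "top_percentile_dG": state.top_percentile_dG,
    }


def config_from_manifest(manifest: dict) -> ScreenConfig:
    cfg = dict(manifest["config"])
    cfg["entropy"] = EntropyParams(**cfg["entropy"])
    sur = dict(cfg["surrogate"])
    sur["hidden_sizes"] = tuple(sur["hidden_sizes"])
    cfg["surrogate"] = SurrogateConfig(**sur)
    return ScreenConfig(**cfg)


def run_campaign(
    library: Sequence[CompoundRecord],
    oracle: DockingOracle,
    config: ScreenConfig,
    oracle_high_precision: DockingOracle | None = None,
    rescore: bool = True,
    max_iterations: int | None = None,
) -> CampaignResult:
    """Run a full campaign: init, iterate to convergence, high-precision rescore."""
    state = init_screen(library, oracle, config)
    limit = max_iterations if max_iterations is not None else config.max_iterations
    while state.iteration < limit and not check_convergence(state, config):
        run_iteration(state, library, oracle, config)
    if rescore:
        hp_oracle = oracle_high_precision or oracle
        k = min(config.rescore_top_k, state.n_docked)
        ranking = rescore_top(state, library, hp_oracle, k, config)
    else:
        top_ids = sorted(state.dG, key=lambda i: (state.dG[i], i))
        ranking = pd.DataFrame(
            {
                "rank": np.arange(1, len(top_ids) + 1),
                "compound_id": top_ids,
                "dH": [state.docked[i].dH for i in top_ids],
                "dS": [state.dS[i] for i in top_ids],
                "dG": [state.dG[i] for i in top_ids],
            }
        )
    return CampaignResult(
        state=state, final_ranking=ranking, manifest=campaign_manifest(config, state)
    )


def run_from_manifest(
    library: Sequence[CompoundRecord],
    oracle: DockingOracle,
    manifest: dict,
    oracle_high_precision: DockingOracle | None = None,
) -> CampaignResult:
    """Replay a campaign from its manifest; selections and rankings are
    reproduced bit-for-bit given the same library and oracle."""
    config = config_from_manifest(manifest)
    return run_campaign(
        library, oracle, config,
        oracle_high_precision=oracle_high_precision,
        max_iterations=manifest["iterations_run"],
    )


def save_manifest(manifest: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)


def load_manifest(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
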
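"""Synthetic compound libraries with planted binder clusters.

A desk-scale stand-in for an ultra-large make-on-demand library: tens of
thousands of fingerprint records instead of billions of purchasable
structures.  Binders are generated as controlled perturbations of a few
cluster reference fingerprints (the "planted pharmacophores"), so their
within-cluster Tanimoto similarity is held near a target value while
background compounds are independent sparse random vectors.  Together with
the similarity-based synthetic docking oracle this yields a known ground
truth: which compounds are binders and what their noise-free enthalpy is.

Descriptors are drawn from distributions typical of drug-like, make-on-demand
chemistry: mass ~ N(350, 60) Da, rotatable bonds ~ Poisson(5), cLogP ~
N(2.5, 1.2).  Everything is reproducible from (spec, seed).

Also here: the filter fixture reproducing a published-style triage ledger
(1000 candidates, 93 solubility failures, 754 buried-unsat failures, 153
survivors) and a two-Gaussian ranked benchmark whose AUC has the closed form
Phi(separation / sqrt(2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .library import CompoundRecord, tanimoto_matrix
from .oracle import PoseProperties


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticLibrarySpec:
    n_compounds: int = 50_000
    n_binder_clusters: int = 10
    binder_fraction: float = 0.01
    fp_bits: int = 1024
    bit_density: float = 0.05
    within_cluster_similarity: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bit_density < 1:
            raise SyntheticError("bit_density must be in (0, 1)")
        if not 0 < self.binder_fraction < 1:
            raise SyntheticError("binder_fraction must be in (0, 1)")
        if self.binder_fraction * self.n_compounds < self.n_binder_clusters:
            raise SyntheticError("fewer planted binders than clusters")
        if not 0 < self.within_cluster_similarity < 1:
            raise SyntheticError(
                "within_cluster_similarity must be in (0, 1); 1.0 is infeasible "
                "with nonzero perturbation"
            )


@dataclass
class GroundTruth:
    is_binder: dict[str, bool]
    true_dH: dict[str, float] = field(default_factory=dict)
    cluster_of: dict[str, int] = field(default_factory=dict)
    reference_fps: np.ndarray | None = None

    @property
    def binder_ids(self) -> set[str]:
        return {cid for cid, b in self.is_binder.items() if b}


def _perturbed_fingerprint(
    ref_bits: np.ndarray,
    target_similarity: float,
    n_bits: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Perturb a reference so the expected Tanimoto to it is ~``target_similarity``.

    For two k-bit sets with intersection i, T = i / (2k - i); solving for i at
    T = s gives i = 2ks/(1+s).  We keep i reference bits and turn on k - i
    fresh bits, preserving the popcount.
    """
    on = np.flatnonzero(ref_bits)
    k = len(on)
    keep = int(round(2 * k * target_similarity / (1 + target_similarity)))
    keep = min(max(keep, 0), k)
    kept = rng.choice(on, size=keep, replace=False)
    fp = np.zeros(n_bits, dtype=np.uint8)
    fp[kept] = 1
    off = np.flatnonzero(ref_bits == 0)
    fresh = rng.choice(off, size=k - keep, replace=False)
    fp[fresh] = 1
    return fp


def generate_library(
    spec: SyntheticLibrarySpec,
) -> tuple[list[CompoundRecord], GroundTruth]:
    """Generate records plus ground truth (binder flags, noise-free dH).

    ``true_dH`` is the similarity landscape -depth * max-similarity with the
    default oracle depth of 12 kcal/mol; oracles built from
    ``ground_truth.reference_fps`` see exactly this landscape.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    n_binders = int(round(spec.binder_fraction * n))
    n_bg = n - n_binders

    refs = (rng.random((spec.n_binder_clusters, spec.fp_bits)) < spec.bit_density).astype(
        np.uint8
    )
    # guard against an all-zero reference at extreme densities
    for r in range(spec.n_binder_clusters):
        if refs[r].sum() == 0:
            refs[r, rng.integers(spec.fp_bits)] = 1

    fps = np.zeros((n, spec.fp_bits), dtype=np.uint8)
    cluster_of: dict[str, int] = {}
    is_binder: dict[str, bool] = {}

    binder_cluster = rng.integers(spec.n_binder_clusters, size=n_binders)
    for i in range(n_binders):
        fps[i] = _perturbed_fingerprint(
            refs[binder_cluster[i]], spec.within_cluster_similarity, spec.fp_bits, rng
        )
    fps[n_binders:] = (rng.random((n_bg, spec.fp_bits)) < spec.bit_density).astype(np.uint8)

    masses = np.clip(rng.normal(350.0, 60.0, size=n), 100.0, None)
    rotors = rng.poisson(5.0, size=n)
    clogps = rng.normal(2.5, 1.2, size=n)
    heavies = np.clip(rng.normal(25, 5, size=n).round().astype(int), 8, None)

    width = len(str(n - 1))
    order = rng.permutation(n)  # shuffle so binders are not id-contiguous
    records: list[CompoundRecord] = []
    for pos, src in enumerate(order):
        cid = f"S{pos:0{width}d}"
        records.append(
            CompoundRecord(
                id=cid,
                smiles="",
                fingerprint=fps[src],
                mol_mass=float(masses[src]),
                n_rotor=int(rotors[src]),
                clogp=float(clogps[src]),
                heavy_atoms=int(heavies[src]),
                source="synthetic",
            )
        )
        binder = src < n_binders
        is_binder[cid] = bool(binder)
        if binder:
            cluster_of[cid] = int(binder_cluster[src])

    sims = tanimoto_matrix(np.stack([r.fingerprint for r in records]), refs)
    true_dh = {rec.id: float(-12.0 * s) for rec, s in zip(records, sims.max(axis=1))}
    return records, GroundTruth(
        is_binder=is_binder, true_dH=true_dh, cluster_of=cluster_of, reference_fps=refs
    )


# ---------------------------------------------------------------------------
# filter fixture
# ---------------------------------------------------------------------------

def generate_filter_fixture(
    n: int = 1000,
    fail_solubility: int = 93,
    fail_unsats: int = 754,
    seed: int = 0,
) -> list[tuple[CompoundRecord, PoseProperties]]:
    """Candidate sheet with disjoint planted filter failures.

    ``fail_solubility`` records get cLogP > 3.5, a disjoint ``fail_unsats``
    records get more than one buried unsatisfied hydrogen bond, and the rest
    pass both; the order is a seeded shuffle.
    """
    if fail_solubility + fail_unsats > n:
        raise SyntheticError("failure counts exceed fixture size")
    rng = np.random.default_rng(seed)
    roles = (
        ["clogp"] * fail_solubility
        + ["unsats"] * fail_unsats
        + ["pass"] * (n - fail_solubility - fail_unsats)
    )
    rng.shuffle(roles)
    out = []
    width = len(str(n - 1))
    for i, role in enumerate(roles):
        clogp = float(rng.uniform(3.6, 6.0)) if role == "clogp" else float(rng.uniform(-1.0, 3.4))
        n_unsats = int(rng.integers(2, 5)) if role == "unsats" else int(rng.integers(0, 2))
        rec = CompoundRecord(
            id=f"F{i:0{width}d}",
            smiles="",
            clogp=clogp,
            mol_mass=float(rng.uniform(200, 500)),
            n_rotor=int(rng.integers(0, 10)),
            heavy_atoms=int(rng.integers(15, 40)),
            source="filter-fixture",
        )
        pose = PoseProperties(n_unsats=n_unsats, n_unusual_torsion=int(rng.integers(0, 2)))
        out.append((rec, pose))
    return out


# ---------------------------------------------------------------------------
# ranked benchmark with closed-form AUC
# ---------------------------------------------------------------------------

def generate_benchmark_set(
    n_actives: int, n_decoys: int, separation: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two-Gaussian ranked benchmark: (labels, scores), lower score = better.

    Active scores ~ N(-separation, 1), decoys ~ N(0, 1); the population AUC
    is Phi(separation / sqrt(2)).
    """
    if n_actives < 1 or n_decoys < 1:
        raise SyntheticError("need at least one active and one decoy")
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.ones(n_actives, dtype=int), np.zeros(n_decoys, dtype=int)])
    scores = np.concatenate(
        [rng.normal(-separation, 1.0, n_actives), rng.normal(0.0, 1.0, n_decoys)]
    )
    return labels, scores
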
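"""Ligand conformational entropy and entropy-corrected affinity ranking.

Binding a flexible ligand freezes its rigid-body degrees of freedom and its
rotatable torsions; the resulting entropic penalty is what lets two ligands
with similar interaction enthalpy be ranked differently.  The model here has
two modes:

* **default** — ``dS = w_rb * ln(m) + w_torsion * dS_torsion`` where the
  torsional term is estimated from the unbound-state torsion distribution:
  ``dS_torsion = R*T * sum_i sum_j (-p_ij ln p_ij)`` with ``p_ij`` the
  probability of torsion ``i`` falling in 60-degree bin ``j``, sampled from a
  ligand-only Metropolis Monte Carlo chain.  The bound-state torsional entropy
  is assumed negligible, and torsions are treated as independent.  Fitted
  weights: ``(w_rb, w_torsion) = (2.0, 1.0)``.
* **simple** — ``dS = 0.4 * n_rotor``: no sampling, just the rotatable-bond
  count.  The fitted mass weight is exactly zero in this mode, so molecular
  weight does not contribute.

Entropies are in kcal/mol (R in kcal/mol/K) so they combine directly with the
docking oracle's enthalpy: ``dG = dH + dS``, lower is better.  The scale is
arbitrary; only rankings matter.  Receptor entropy is not modelled.

Natural logarithms are used throughout; since only rankings and fitted weights
matter, the base is a pure convention, but it must be consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.98720e-3

DEFAULT_TEMPERATURE = 300.0
DEFAULT_BIN_WIDTH = 60.0

#: Fitted (w_rb, w_torsion) weights per mode.
DEFAULT_MODE_WEIGHTS = {"default": (2.0, 1.0), "simple": (0.0, 0.4)}

#: The 9-pair coarse grid searched when calibrating default-mode weights.
DEFAULT_WEIGHT_GRID = [
    (0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0),
    (0.0, 2.0), (2.0, 0.0), (2.0, 1.0), (1.0, 2.0), (2.0, 2.0),
]


class EntropyError(ValueError):
    pass


@dataclass
class EntropyParams:
    """Weights, temperature and binning for the entropy model."""

    mode: str = "default"
    w_rb: float | None = None
    w_torsion: float | None = None
    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = GAS_CONSTANT_KCAL
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        if self.mode not in DEFAULT_MODE_WEIGHTS:
            raise EntropyError(f"unknown entropy mode: {self.mode!r}")
        if self.temperature <= 0:
            raise EntropyError("temperature must be positive")
        if 360.0 % self.bin_width != 0:
            raise EntropyError("bin_width must divide 360 evenly")
        defaults = DEFAULT_MODE_WEIGHTS[self.mode]
        if self.w_rb is None:
            self.w_rb = defaults[0]
        if self.w_torsion is None:
            self.w_torsion = defaults[1]

    @property
    def n_bins(self) -> int:
        return int(round(360.0 / self.bin_width))

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass
class TorsionSamples:
    """Sampled dihedral values per rotatable torsion, wrapped to [0, 360)."""

    angles: list[np.ndarray]
    stride: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        self.angles = [np.asarray(a, dtype=float) for a in self.angles]
        if self.angles:
            n = len(self.angles[0])
            if n < 1 or any(len(a) != n for a in self.angles):
                raise EntropyError("all torsion sample lists must have equal length >= 1")
            for a in self.angles:
                if np.any((a < 0) | (a >= 360.0)):
                    raise EntropyError("angles must lie in [0, 360)")

    @property
    def n_torsions(self) -> int:
        return len(self.angles)


# ---------------------------------------------------------------------------
# entropy terms
# ---------------------------------------------------------------------------

def torsion_entropy(samples: TorsionSamples, params: EntropyParams) -> float:
    """Torsional entropy R*T * sum_ij (-p_ij ln p_ij) from binned samples.

    Probabilities come from a fixed histogram with ``params.bin_width`` bins;
    empty bins contribute zero (the p ln p -> 0 limit).  Non-negative and
    additive over torsions.
    """
    if samples.n_torsions == 0 or len(samples.angles[0]) == 0:
        raise EntropyError("empty torsion samples")
    edges = np.arange(0.0, 360.0 + params.bin_width, params.bin_width)
    total = 0.0
    for angles in samples.angles:
        counts, _ = np.histogram(angles, bins=edges)
        p = counts / counts.sum()
        nz = p[p > 0]
        total += float(-(nz * np.log(nz)).sum())
    return params.rt * total


def rigid_body_entropy(mol_mass: float, params: EntropyParams) -> float:
    """Rigid-body entropy term w_rb * ln(m); mass in daltons."""
    if mol_mass <= 0:
        raise EntropyError("mol_mass must be positive")
    return params.w_rb * math.log(mol_mass)


def simple_entropy(n_rotor: int, w_torsion: float = 0.4) -> float:
    """Simple entropy: w_torsion * n_rotor (fitted w_torsion = 0.4)."""
    if n_rotor < 0:
        raise EntropyError("n_rotor must be non-negative")
    return w_torsion * n_rotor


def total_entropy(
    record,
    samples: TorsionSamples | None = None,
    params: EntropyParams | None = None,
) -> float:
    """Total entropy penalty dS for a compound under the configured mode.

    default mode: ``w_rb * ln(m) + w_torsion * dS_torsion`` (samples required);
    simple mode: ``w_torsion * n_rotor`` (0.4 per rotatable bond).
    """
    if params is None:
        params = EntropyParams(mode="simple")
    if params.mode == "simple":
        if record.n_rotor is None:
            raise EntropyError(f"record {record.id}: n_rotor required in simple mode")
        return simple_entropy(record.n_rotor, params.w_torsion)
    if samples is None:
        raise EntropyError(f"record {record.id}: torsion samples required in default mode")
    if record.mol_mass is None:
        raise EntropyError(f"record {record.id}: mol_mass required in default mode")
    return rigid_body_entropy(record.mol_mass, params) + params.w_torsion * torsion_entropy(
        samples, params
    )


def binding_free_energy(dH: float, dS: float) -> float:
    """Ranking score dG = dH + dS (temperature folded into dS); lower is better."""
    if not (math.isfinite(dH) and math.isfinite(dS)):
        raise EntropyError("non-finite input to binding_free_energy")
    return dH + dS


# ---------------------------------------------------------------------------
# Monte Carlo torsion sampling
# ---------------------------------------------------------------------------

def cosine_series_potential(
    amplitudes: Sequence[float] = (1.0,), periodicities: Sequence[int] = (3,)
) -> Callable[[np.ndarray], float]:
    """Toy torsional potential: sum_k A_k * (1 + cos(n_k * theta)) per torsion.

    Stands in for a physics force field's intra-ligand torsional energy when
    exercising the sampler; kcal/mol, minima at the staggered positions for
    the default 3-fold term.
    """

    def energy(angles_deg: np.ndarray) -> float:
        theta = np.radians(np.asarray(angles_deg, dtype=float))
        e = 0.0
        for amp, per in zip(amplitudes, periodicities):
            e += float(np.sum(amp * (1.0 + np.cos(per * theta))))
        return e

    return energy


def mc_torsion_sampler(
    energy_fn: Callable[[np.ndarray], float],
    n_torsions: int,
    total_steps: int = 300_000,
    stride: int = 3000,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
    max_perturbation: float = 30.0,
) -> TorsionSamples:
    """Metropolis chain over ligand torsion angles; samples every ``stride`` steps.

    Proposal: uniform perturbation of one randomly chosen torsion by up to
    +/- ``max_perturbation`` degrees.  No burn-in is discarded; the default
    300,000 steps with stride 3000 yield 100 samples per torsion.
    Deterministic for a fixed seed.
    """
    if total_steps < stride:
        raise EntropyError("total_steps must be >= stride")
    if n_torsions < 1:
        raise EntropyError("n_torsions must be >= 1")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (GAS_CONSTANT_KCAL * temperature)
    angles = rng.uniform(0.0, 360.0, size=n_torsions)
    energy = energy_fn(angles)
    if not math.isfinite(energy) and energy != math.inf:
        raise EntropyError("non-finite energy from energy_fn at initial state")
    samples: list[list[float]] = [[] for _ in range(n_torsions)]
    for step in range(1, total_steps + 1):
        idx = rng.integers(n_torsions)
        delta = rng.uniform(-max_perturbation, max_perturbation)
        proposal = angles.copy()
        proposal[idx] = (proposal[idx] + delta) % 360.0
        e_new = energy_fn(proposal)
        if math.isnan(e_new):
            raise EntropyError("NaN energy from energy_fn")
        if e_new <= energy or rng.random() < math.exp(-beta * (e_new - energy)):
            angles = proposal
            energy = e_new
        if step % stride == 0:
            for i in range(n_torsions):
                samples[i].append(angles[i])
    return TorsionSamples(
        angles=[np.asarray(s) for s in samples], stride=stride, seed=seed
    )


# ---------------------------------------------------------------------------
# weight calibration
# ---------------------------------------------------------------------------

def calibrate_entropy_weights(
    candidates: Sequence[tuple[float, float]],
    objective: Callable[[float, float], float],
) -> tuple[float, float]:
    """Grid-search argmax of ``objective`` over candidate (w1, w2) pairs.

    Ties break to the lexicographically smallest pair, so the result is
    deterministic regardless of candidate ordering.
    """
    if not candidates:
        raise EntropyError("empty candidate set")
    best: tuple[float, float] | None = None
    best_val = -math.inf
    for w1, w2 in sorted(candidates):
        val = objective(w1, w2)
        if math.isfinite(val) and val > best_val:
            best_val = val
            best = (w1, w2)
    if best is None:
        raise EntropyError("objective non-finite on all candidates")
    return best


def weight_grid(stop: float = 3.0, step: float = 0.1) -> list[tuple[float, float]]:
    """Fine calibration grid: all (w1, w2) in [0, stop] x [0, stop] at ``step``."""
    vals = np.round(np.arange(0.0, stop + step / 2, step), 10)
    return [(float(a), float(b)) for a in vals for b in vals]
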
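# Methods

This note documents the models implemented in `alscreen`, the defaults and
why they were chosen, what the synthetic data does and does not emulate, and
the numerical conventions that matter for reproducing results.

## Entropy model

Binding a ligand freezes rigid-body degrees of freedom and rotatable
torsions; the resulting penalty ΔS is added to the oracle's enthalpy
estimate to form the ranking score ΔG = ΔH + ΔS. Temperature is folded into
ΔS so the two terms combine directly; the absolute scale is arbitrary and
only rankings are meaningful. Receptor entropy is deliberately not modelled.

**Default mode** — ΔS = w₁·ln m + w₂·ΔS_torsion with

ΔS_torsion = RT · Σᵢ Σⱼ (−pᵢⱼ ln pᵢⱼ),

where pᵢⱼ is the occupancy of 60° bin j by rotatable torsion i in the
*unbound* state (bound-state torsional entropy assumed negligible, torsions
assumed independent). Weights default to (2.0, 1.0), the optimum of a coarse
grid search over the nine pairs {0,1,2}² (exposed as
`DEFAULT_WEIGHT_GRID` together with `calibrate_entropy_weights`, which
breaks ties to the lexicographically smallest pair).

**Simple mode** — ΔS = 0.4·n_rotor. The mass weight is exactly zero in this
mode (molecular weight does not contribute); the 0.4 kcal/mol per rotatable
bond is the optimum of a finer 0.0–3.0 step-0.1 grid (`weight_grid`). This
is the default during screening, where per-compound Monte-Carlo sampling
would dominate the cost of an oracle call.

Numerical conventions:

- natural logarithms throughout (both the histogram entropy and ln m); the
  base is a convention — it rescales entropies uniformly and the fitted
  weights absorb it — but it must be consistent;
- R = 1.98720×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 300 K, so entropies are in
  kcal/mol and combine with ΔH without unit juggling;
- empty histogram bins contribute zero (the p ln p → 0 limit);
- bin width must divide 360° evenly (default 60°, six bins per torsion).

**Monte-Carlo sampler.** Torsion distributions come from a Metropolis chain
over the torsion-angle vector: proposal = uniform ±30° perturbation of one
randomly chosen torsion, acceptance by the standard criterion at 300 K,
samples recorded every 3000 steps, default 300,000 total steps (100 samples
per torsion), no burn-in discarded. The torsion energy function is
pluggable, because a physics force field is outside this package's scope; a
cosine-series toy potential (`cosine_series_potential`) ships for testing.
With six bins and 100 samples the plug-in entropy estimator has a downward
bias of roughly (B−1)/2N ≈ 2.5% — inside the 5% tolerance used by the
flat-potential convergence test, which checks recovery of the uniform
closed form RT·ln 6 ≈ 1.068 kcal/mol per torsion.

## Docking oracle contract

The screening loop sees docking only as a batch contract: a shard of
compounds in, one result per compound out, order preserved, failures flagged
per compound rather than dropped, whole-shard retries on engine crashes.
Two run modes exist as metadata: `express` for the cheap initial screen and
`high_precision` for final re-ranking.

The shipped `SyntheticOracle` makes the loop testable at desk scale with a
known ground truth: `dH(c) = −depth · maxᵣ T(fp_c, fp_r) + ε` over a set of
planted reference fingerprints, with ε ~ N(0, σ) and σ per mode (default
1.0 kcal/mol express, 0.25 high-precision — the high-precision mode is the
same landscape measured more accurately). Noise and pose properties
(buried-unsat and torsion-outlier counts, drawn from categorical
distributions) are keyed by hashing (seed, compound id), **not** by global
RNG state: results are a pure function of the compound, so sharding layout,
call order and retries never change them, and campaigns replay exactly.

## Surrogate classifier

Input: 1024-bit Morgan fingerprints (radius 2). Architecture: two dense
hidden layers of 3000 nodes, each followed by batch normalization and
dropout 0.5, then a linear unit and a sigmoid — the output is the
probability of being a binder. The implementation is a compact, fully
seeded numpy network (Glorot-uniform init, ReLU hidden activations, Adam,
minibatch 1024, learning rate 10⁻⁴). Cross-entropy on the *testing* set is
computed every epoch; training stops when it fails to improve for 5 epochs
(max 100) and the best-epoch weights are restored. Because late iterations
have very sparse positive labels, the loss uses inverse-frequency class
weights. Inference uses batch-norm running statistics, so predictions are
independent of chunk size; everything runs on CPU.

Hidden activation, optimizer, learning rate, batch size and patience are
free design choices here (documented defaults above); ReLU was chosen as
the standard default for dense classifiers of this shape.

## Labels, schedule and selection

- Cutoff percentile: ten log-spaced points from 10% down to 0.01%
  (iteration 2 = 4.64%); consecutive values differ by the constant factor
  10^(−1/3).
- Cutoff value: the k-th smallest testing-set dG with k = ⌈p/100·n⌉ — the
  quantile convention is a package choice; ties at the cutoff are binders
  (label rule is dG ≤ cutoff).
- Selection: greedy top `n_select_top` by predicted probability over
  never-docked compounds (ties broken by compound id), plus
  `n_select_random` uniform draws from the remaining never-docked compounds
  excluding the greedy set. If fewer compounds remain than requested, all
  are taken and the truncation is flagged.
- The testing set is fixed at iteration 1 and reused throughout; newly
  docked compounds augment only the training set.
- Convergence: stop at `max_iterations`, or when the running best dG
  improves by less than 0.1 kcal/mol for 2 consecutive iterations — the
  published stopping criterion is narrative ("no new global minima"), so an
  operational default had to be fixed here.
- Rescoring: the top-k by dG are re-docked in high-precision mode and the
  refreshed dG *replaces* the express value (replacement rather than
  averaging is a package choice).
- The per-iteration "top 0.1-percentile dG" summary sizes its window by the
  library being screened (k = ⌈0.001·n_library⌉ docked compounds), making it
  a running k-th-best statistic that is non-increasing by construction.

## Campaign profiles

| profile | train/test init | per-iteration | rescore | intent |
|---|---|---|---|---|
| `paper_profile` | 500,000 / 1,000,000 | 250,000 + 250,000 | 50,000 | production-scale counts, for real engines |
| `ScreenConfig()` (desk) | 5,000 / 10,000 | 2,500 + 2,500 | 500 | desk-scale default |
| `compact_profile` | 1,000 / 2,000 | 500 + 500 | 200 | end-to-end properties on ~50 k libraries |

The compact profile exists because enrichment properties need headroom: on
a 50,000-compound library with 1% planted binders (500 binders), a
campaign that docks 30,000 compounds caps the docked-binder fraction at
1.67× the base rate *even with a perfect selector* — the docked set simply
outnumbers the binders. Four compact iterations dock 6,000 compounds, so a
perfect selector could reach 8.3× and a measured ≥ 5× enrichment is an
informative outcome rather than an arithmetic impossibility. The compact
surrogate uses 256-node hidden layers and 12 epochs; at 3,000 training
points the full 3000-node architecture adds cost but no measurable ranking
benefit.

## Triage

- Property filters run in a configurable stage order; a record is removed at
  the first stage it fails, and records missing a required property are
  removed with an explicit "missing" reason rather than silently passed.
  Defaults: cLogP > 3.5, Nunsats > 1, optionally N_unusual_torsion > 1.
- Clustering is a deterministic leader (sphere-exclusion) pass: visit
  best-dG-first (ties by id), join the first cluster whose *leader* is ≥ 0.6
  Tanimoto similar, else found a new cluster. The published campaigns do not
  name their clustering algorithm, so cluster counts from real libraries are
  not expected to be reproduced; leader clustering was chosen because
  representatives are defined by affinity and the pass is order-independent
  given the visit rule.
- Representatives: `best_affinity` = minimum dG (ties: fewer heavy atoms,
  then id); `smallest` = fewest heavy atoms (ties: lower mass, then id) —
  "smallest" is interpreted as heavy-atom count.
- Novelty: keep compounds whose maximum Tanimoto to any known active is
  < 0.33; an empty known-actives set passes everything.
- Both orderings (filter→cluster and cluster→filter) are supported; the
  ledger chains its counts and raises if a stage's input does not equal the
  previous stage's output.
- Manual inspection steps (pose examination, medicinal-chemistry vetoes) are
  out of scope; the pipeline ends at a ranked, filtered candidate sheet.

## Metrics

Conventions are fixed because the field uses several: top-X% windows hold
⌈x/100·n⌉ compounds; ROC enrichment is the TPR at the ranking position where
the FPR first reaches X% counted in whole decoys (no interpolation), divided
by x/100; AUC uses midranks for ties; top-X% membership ties are broken by
compound id; a direction flag maps lower-is-better scores into the internal
order. Docking success means the best-*scored* pose (ties: lowest RMSD) is
within 2.0 Å of native. All metrics are cross-checked in the tests against
naive exhaustive reference implementations.

## Synthetic libraries

`generate_library` emulates an ultra-large make-on-demand library at
reduced scale. Binders are perturbations of cluster reference fingerprints
constructed to hit a target Tanimoto to their reference (default 0.7,
popcount-preserving: for k-bit sets the intersection is set to
⌈2ks/(1+s)⌉); background compounds are independent sparse random vectors
(bit density 0.05, matching the ~50 set bits of a 1024-bit drug-like
fingerprint). Descriptors are drawn from drug-like distributions: mass ~
N(350, 60) Da clipped at 100, n_rotor ~ Poisson(5), cLogP ~ N(2.5, 1.2).
Default conditions for the end-to-end property: 50,000 compounds, 10 binder
clusters, 1% binders, oracle depth 12 kcal/mol, express noise 1 kcal/mol.

What this emulates: a similarity-structured affinity landscape where actives
form chemotype clusters and an ML surrogate over fingerprints can
generalize from docked examples — the property that makes active learning
work. What it does not emulate: real chemistry (valence, synthesizability),
descriptor–structure correlations (mass and rotors are independent of the
fingerprint), docking-score pathologies (size bias, charge artifacts), or
pose geometry. Passing the end-to-end tests therefore demonstrates that the
*loop* concentrates a plantable signal under honest noise, not that any
particular docking engine would enrich on a particular target.

`generate_filter_fixture` builds a 1000-compound candidate sheet with
disjoint planted failure sets (93 lipophilicity, 754 buried-unsat), matching
the arithmetic of a sequential filter ledger; `generate_benchmark_set` draws
active scores from N(−sep, 1) and decoys from N(0, 1), whose population AUC
is Φ(sep/√2) — the closed form used to validate the AUC implementation.

## Known limitations

- The entropy model treats torsions as independent and ignores receptor
  entropy; correlated torsions will be over-counted.
- The rigid-body term uses ln m in default mode; the functional dependence
  on mass is an approximation adopted as-is.
- The surrogate is a plain feed-forward network without uncertainty
  estimates; acquisition is purely greedy plus uniform exploration.
- Leader clustering depends on the leader set; it is deterministic and
  order-independent under the visit rule but is not a globally optimal
  clustering.
- Scale: everything here is desk-sized. The production-scale profile
  preserves the published counts but has only been exercised at reduced
  scale in this package's tests.
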
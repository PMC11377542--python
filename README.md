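# alscreen

Desk-scale active-learning virtual screening: entropy-corrected affinity
ranking, a surrogate-guided dock/label/train/select loop over a pluggable
docking oracle, post-screen triage, and the standard screening metrics.

## The problem

Structure-based virtual screening ranks a chemical library against a protein
target so that the handful of compounds worth synthesizing and assaying rise
to the top. Make-on-demand libraries now hold billions of purchasable
molecules, while physics-based docking costs minutes per compound — docking
everything is out of the question. Two ideas make the campaign tractable:

1. **Entropy-corrected ranking.** Docking engines estimate an interaction
   enthalpy ΔH, but ranking different ligands against the same target also
   needs the entropic penalty of freezing the ligand on binding. The ranking
   score is ΔG = ΔH + ΔS (temperature folded into ΔS; the scale is arbitrary,
   only the order matters), with

   - *default* mode: ΔS = w₁·ln m + w₂·RT·Σᵢⱼ(−pᵢⱼ ln pᵢⱼ), where m is the
     molecular mass, and pᵢⱼ is the probability of rotatable torsion *i*
     occupying 60° bin *j* in the unbound state, estimated from a ligand-only
     Metropolis Monte-Carlo chain (fitted weights w₁ = 2.0, w₂ = 1.0);
   - *simple* mode: ΔS = 0.4·n_rotor — just the rotatable-bond count, used
     during high-throughput screening where per-compound sampling would
     dominate the cost.

2. **Active learning.** A cheap surrogate classifier (1024-bit Morgan
   fingerprints → two 3000-node hidden layers with batch-norm and dropout →
   sigmoid binder probability) is trained on the compounds docked so far,
   with binary labels set by a dG cutoff at the iteration's top-N% of a fixed
   testing set (N follows a ten-point log-spaced schedule from 10% down to
   0.01%). Each iteration the surrogate scores the whole library and the next
   docking batch is the greedy top picks plus an equal number of random
   exploration picks. After convergence the top-ranked compounds are
   re-docked in a slower, lower-noise high-precision mode.

Candidates are then triaged: property filters (cLogP > 3.5, buried
unsatisfied H-bonds > 1, torsion outliers > 1 are discarded), leader
clustering at Tanimoto 0.6 with best-affinity or smallest-member
representatives, and a novelty filter at Tanimoto 0.33 against known
actives — every stage audited in a conservation-checked ledger.

The docking engine itself is out of scope by design: it enters only through
a batch oracle contract (`DockRequest → [DockResult]`). The shipped
`SyntheticOracle` plants reference pharmacophores in fingerprint space and
scores `dH = −depth · max-similarity + noise`, deterministically keyed per
compound, so the whole loop runs on a laptop with a known ground truth.

## Worked example

```bash
# generate a 4,000-compound synthetic library with 1% planted binders
alscreen simulate --n 4000 --seed 3 --out synth.csv
# run a compact campaign against the synthetic oracle
alscreen screen --library synth.csv --out run1/ --seed 3 --iterations 3
```

prints

```
wrote 4000 compounds to synth.csv (truth: synth.truth.json)
3 iterations, 4000 docked, best dG -10.73 kcal/mol
```

and `run1/ranked.csv` begins

```
rank,compound_id,dH,dS,dG
1,S0444,-11.93418025970459,1.2000000000000002,-10.73418025970459
2,S0217,-12.033025741577148,1.6,-10.433025741577149
```

Compound S0444 docks at ΔH ≈ −11.9 kcal/mol; its three rotatable bonds cost
0.4 kcal/mol each under simple entropy, giving the ranking score
ΔG ≈ −10.7 kcal/mol. `run1/manifest.json` records seeds, counts, cutoffs and
model checksums — re-running from it reproduces every selection bit-for-bit.

The same pipeline is available as a library (`alscreen.generate_library`,
`alscreen.run_campaign`, `alscreen.apply_filters`,
`alscreen.enrichment_factor`, ...) — see `docs/methods.md` for the model
details and design choices.

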
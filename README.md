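# reliamol

Reliability-aware multi-objective de novo molecular design.

## The problem

Generative molecular design guided by QSAR-style property predictors is
vulnerable to **reward hacking**: the generator drifts into regions of
chemical space where the predictors extrapolate, and optimizes predictions
that are no longer trustworthy.  The classic guard is the **applicability
domain (AD)** — trust a prediction only when the query molecule is similar
enough to the model's training data.  With several objectives this becomes a
balancing act: each property model has its own training set and hence its
own AD, and demanding high reliability for every property can leave no
region of chemical space where all ADs overlap.  How strict to be for each
property cannot be decided before running the design.

`reliamol` implements a closed-loop answer.  Reliability is the **maximum
Tanimoto similarity (MTS)** `s_i` between a designed molecule's Morgan
fingerprint (radius 2, 2048 bits) and the i-th model's training
fingerprints.  A per-property **reliability level** ρ_i defines the AD, and
the design reward is gated on it:

```
Reward = (Π v_i^{w_i})^{1/Σw_i}   if s_i ≥ ρ_i for all i     (the Dscore)
       = 0                         otherwise
```

where `v_i` is a Gaussian-shaped desirability of the predicted property and
`w_i` its weight.  Molecules are generated by Monte Carlo tree search over
SMILES tokens (UCT selection, pluggable n-gram token policy).  The outer
loop then tunes the vector ρ itself by maximizing the **Degree of
Simultaneous Satisfaction**

```
DSS(ρ) = (Π_i Scaler_i(ρ_i))^{1/n} × Reward_top X%
```

over a discrete grid with Gaussian-process Bayesian optimization (expected
improvement), after a short random initialization.  `Scaler_i` is a Gaussian
rising to 1 at ρ_i = 1 whose width σ encodes property priority (σ = 0.15
tight / 0.25 normal / 0.35 loose); `Reward_top X%` is the mean of the top
10% of a design run's rewards.  High DSS therefore means *simultaneously*
reliable and well-optimized designs.

## Who this is for

Computational chemists running multi-objective generative design with
data-driven scoring functions, and methods researchers who need a fully
deterministic, enumerable testbed for AD-gated reward schemes: the package
ships a synthetic benchmark (binary fingerprint clouds with controllable
overlap, deterministic property oracles, finite candidate pools) on which
every stage — including the full Bayesian-optimization loop — can be checked
against brute force.

## Worked example

A three-property synthetic benchmark with partially overlapping training
clouds; reliability levels are searched on a 10×10×10 grid with 10 random
plus 30 BO evaluations:

```python
import numpy as np
from reliamol import SearchSpace, make_benchmark, run_episode

bench = make_benchmark(k=3, separation=0.7, seed=0)
context = bench.context(seed=0)
space = SearchSpace(grids=[np.round(np.linspace(0.1, 0.9, 10), 6)] * 3)
history = run_episode(space, context, n_random=10, n_bo=30, seed=0)
best = history.best()
print(f"best DSS          : {best.dss:.4f}")
print(f"best rho          : {[round(r, 2) for r in best.rho]}")
print(f"molecules in AD   : {best.n_in_ad}/{best.n_records}")
print(f"top-10% reward    : {best.top_reward:.4f}")
```

Output:

```
best DSS          : 0.0154
best rho          : [0.28, 0.28, 0.28]
molecules in AD   : 17/40
top-10% reward    : 0.9998
```

The search settles on moderate reliability levels (ρ ≈ 0.28 per property):
strict enough that 17 of the 40 pool candidates fall inside all three ADs,
loose enough that the AD overlap is not empty.  The top-10% reward ≈ 1.0
says those in-AD candidates also satisfy all three desirability targets;
the DSS value itself is small because the Scalers penalize ρ far below 1 —
exactly the trade-off the objective is designed to expose.  Pushing all
ρ to 0.9 on this benchmark gates every candidate and drives the DSS to 0.

For SMILES-based workflows, the `reliamol` command-line tool wraps the same
pipeline: `reliamol train` fits per-property LightGBM models from
(smiles, value) CSVs, `reliamol design` runs MCTS at fixed ρ, `reliamol
optimize` runs full episodes, `reliamol benchmark` is the synthetic
end-to-end demo, and `reliamol filter` applies a rule-of-five filter plus
k-means representative selection to a design log.  All accept `--seed` and
write CSV/JSON logs.

## Layout

| Module | Contents |
| --- | --- |
| `reliamol.chem` | SMILES canonicalization, Morgan fingerprints, Tanimoto and MTS |
| `reliamol.models` | per-property regressors whose training fingerprints define the AD |
| `reliamol.rewards` | desirability, Dscore, AD-gated reward |
| `reliamol.generator` | n-gram token policy, MCTS design runs, pool generator |
| `reliamol.optimizer` | Scaler, DSS, GP/EI reliability search, brute-force oracle |
| `reliamol.benchmark` | synthetic benchmarks, cross-dataset filtering, rule-of-five, k-means selection |
| `reliamol.config` / `reliamol.cli` | YAML run configuration and the command-line tool |

See `docs/methods.md` for the model details, parameter choices, and known
limitations.
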
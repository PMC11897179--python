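# Methods

This note documents the models and procedures implemented in `reliamol`,
the parameter choices that matter, what the synthetic benchmark does and
does not emulate, and the numerical conventions used throughout.

## Reliability as maximum Tanimoto similarity

Every prediction carries a reliability score `s ∈ [0, 1]`: the maximum
Tanimoto similarity between the query's binary Morgan fingerprint (radius
2, 2048 bits by default) and the fingerprints of the model's training
records.  The applicability domain (AD) of a model at reliability level ρ
is the set of molecules with `s ≥ ρ`.  This is a deliberately simple,
distance-based AD; it assumes structural similarity tracks prediction
accuracy, which activity cliffs can violate.  The AD interface is a
pluggable component of `PropertyModel` (any `Fingerprint → float` score
would do), but only the MTS definition is implemented.

Conventions: fingerprints are sparse sets of on-bit indices; Tanimoto of
two empty bit sets is defined as 0.0 (featureless inputs never count as
similar); comparison across different bit dimensions is an error.  AD
membership uses the inclusive `s ≥ ρ`; a `strict` flag switches to `s > ρ`
for users who want open-boundary semantics.

## Property models

The default regressor is LightGBM on dense 0/1 fingerprint vectors
(200 trees, 31 leaves, learning rate 0.1, deterministic single-threaded
fitting), with 5-fold cross-validated R²/MAE reporting.  Hyperparameter
search is intentionally omitted — model quality is orthogonal to the
framework and fixed sensible defaults keep runs reproducible.  A
constant-target dataset degenerates to a constant predictor with a warning.
Models persist as text only: LightGBM's native model string, the training
fingerprints as a CSV of set-bit indices (so the AD reference set
round-trips bit-exactly), and a metadata JSON.

Predictions and reliabilities are memoized per fingerprint.  This matters
for the outer search: with a fixed candidate pool, re-evaluating a new ρ
vector costs only the gating comparison, not a re-computation of `s`.

## Reward: desirability, Dscore, gate

Raw predictions map to desirabilities `v ∈ [0, 1]` through Gaussian-shaped
modifiers: `gaussian` (peak at μ, width σ_v), `max_gaussian` (saturates at
1 for values ≥ μ — "at least this much"), `min_gaussian` (the mirror).
The multi-objective score is the weighted geometric mean
`Dscore = (Π v_i^{w_i})^{1/Σw_i}`; `v^0` is taken as 1 so zero-weight
properties never gate the product, and zero total weight is an error.  The
design reward is the Dscore when the molecule is inside every property's
AD and 0 otherwise; the per-property `s`, raw predictions, and `v` are
returned even for gated molecules so run logs remain fully diagnosable.

## Molecule generator

SMILES strings are built token by token with Monte Carlo tree search.
Tokenization keeps two-character elements (Cl, Br), bracket atoms, and
`%nn` ring closures as single tokens; the maximum length is 80 tokens.
Node selection uses UCT, `W/n + C·sqrt(2 ln N / n)`, with unvisited
children scoring +∞; C defaults to 1.0 (standard UCT semantics: larger C
explores more).  Expansion proposes the tokens with positive policy mass in
the node's context; simulation completes the prefix by sampling the policy;
the reward is backpropagated along the selected path.  Invalid completions
(unparseable SMILES or length cutoff) receive reward 0 and are
backpropagated like any other simulation, which keeps visit accounting
simple; they are flagged separately from valid-but-gated molecules.
Duplicate SMILES are recorded each time they are generated but scored once
through a canonical-SMILES cache.

The token policy is a maximum-likelihood n-gram model (default order 3)
with backoff to the longest seen shorter context, down to the unigram
distribution.  It is a stand-in interface for heavier sequence models: a
corpus-scale recurrent network would slot in behind the same
`TokenPolicy`-like surface without touching the search.  An n-gram policy
trained on a small corpus generates mostly short, corpus-like molecules;
conclusions about chemical-space coverage should not be drawn from it.

`PoolGenerator` is the second engine: it evaluates a fixed candidate pool
in order, once each.  It exists so that every downstream quantity — the
DSS landscape in particular — can be enumerated exactly and compared
against brute force.

## The reliability search

The DSS objective is

    DSS(ρ) = (Π_i Scaler_i(ρ_i))^{1/n} × Reward_top X%

with `Scaler(ρ) = exp(−(ρ−center)²/2σ²)` below the center (default 1.0)
and 1.0 at or above it — strictly increasing in ρ, harsher for smaller σ.
The σ patterns 0.15 / 0.25 / 0.35 (tight / normal / loose) encode property
prioritization.  `Reward_top X%` is the mean of the `ceil(X·n)` largest
rewards of the run, X = 0.10 by default, computed over all generated
records including invalid ones (a `valid_only` flag restricts the pool).
A run in which every molecule is gated has all rewards 0 and hence DSS 0;
no special-casing is needed.

The search space is a per-property discrete grid, by default the literal
enumeration from 0.1 to 0.9 in steps of 0.01 (81 values per property).
After `n_random = 10` seeded evaluations without replacement, `n_bo = 30`
steps are proposed by maximizing expected improvement (ξ = 0) under a
Gaussian-process surrogate: inputs are the ρ vectors scaled to [0, 1] per
axis, kernel is a constant times an anisotropic RBF with length scales
fitted in [10⁻², 10²], `alpha = 1e-6`, outputs normalized.  Length-scale
bounds are deliberate: hitting them on flat landscapes is expected and the
fit warning is suppressed.  Already-evaluated grid points are excluded from
the acquisition argmax; grids above 20 000 points are subsampled (seeded)
before scoring.  Episodes default to 40 evaluations and 5 independent
episodes per scenario.  `brute_force_landscape` enumerates the exact DSS
at every grid point (refusing more than 10⁵ points) and is the oracle the
BO loop is tested against.

## Synthetic benchmark

`make_benchmark(k, separation, n_per_cloud, d, seed)` builds k training
clouds of binary vectors in a d-bit space (d ≥ 64, default 256).  Each
cloud center has d/8 bits, of which a `1 − separation` fraction is shared
across all centers; members copy their center with 20% bit-flip noise.
Property oracles are deterministic: value = 10 × Tanimoto to the cloud
center.  The candidate pool mixes bridge candidates (bits drawn from every
center — the AD-overlap region), cloud-like candidates, and junk far from
all training data, 40 candidates by default with 20 bridges.  Larger
separation provably lowers cross-cloud MTS, which reproduces the
qualitative trade-off: at `separation = 1.0`, uniformly high ρ gates the
whole pool (DSS exactly 0) while moderate ρ keeps the bridges in play.

`make_planted_benchmark` is the fully analytic variant: all properties
share one single-fingerprint reference set and the pool contains one
candidate at similarity exactly 0.7 whose desirability saturates, so the
DSS argmax on any grid is the largest grid value ≤ 0.7 on every axis —
a closed-form target for the brute-force and BO tests.

What the benchmark does *not* emulate: real chemistry.  Vectors are not
fingerprints of actual molecules, oracles have no activity cliffs, noise
is unstructured, and pools are tiny.  Passing tests on it demonstrates the
correctness and internal consistency of the machinery (gating, DSS, BO)
under known geometry — not predictive performance on real assay data.

## Dataset utilities and post-processing

`remove_cross_similar` drops a molecule from a training dataset when its
MTS against the union of the *other* datasets' molecules exceeds a
threshold (default 0.5).  Each molecule is compared against the original,
pre-removal unions, making the result independent of dataset order.
`lipinski_filter` applies the rule of five (MW ≤ 500, cLogP ≤ 5, H-bond
donors ≤ 5, acceptors ≤ 10) via RDKit descriptors.  `select_representatives`
clusters a run's unique valid molecules with seeded k-means (k = 20
default) on fingerprints and keeps the highest-reward molecule per
cluster, breaking ties by canonical-SMILES order for determinism.

## Problem sizes

Default study conditions used by the test suite and the acceptance script:
3 properties; benchmark pools of 40 candidates with 40-molecule clouds;
episodes of 10 random + 30 BO evaluations; 5 episodes per scenario;
reliability grids of 27 points for brute-force comparisons and 1000 points
for BO-vs-random comparisons; MCTS budgets of 500 iterations on a
20-string toy language.  These sizes keep every stage exactly enumerable
or cheaply repeatable while exercising the full code path; the same
functions scale to the 81³-point default grid and 10⁴-molecule budgets a
production run would use.

## Known limitations

- MTS-based ADs inherit the similarity-implies-accuracy assumption;
  activity cliffs break it.  Alternative AD definitions plug in at
  `PropertyModel.reliability` but are not implemented.
- The n-gram policy is a weak generator by design; it validates the search
  machinery, not chemical novelty.
- The GP surrogate treats the DSS as noiseless (`alpha = 1e-6`); with a
  stochastic generator and small budgets, repeated evaluations at one ρ
  can differ more than that.  Episodes use a fixed per-episode generator
  seed, which makes the objective deterministic within an episode.
- Scalarization is the Dscore only; weighted sums and Pareto fronts are
  out of scope.
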
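"""Reliability-level search: DSS objective and Bayesian optimization.

The outer loop of the framework adjusts one reliability level ρ_i per
property.  Each candidate vector ρ is evaluated by running the generator
with the AD-gated reward and scoring the run with the Degree of
Simultaneous Satisfaction:

    DSS(ρ) = (Π_i Scaler_i(ρ_i))^{1/n} × Reward_top X%

Scaler_i rescales ρ_i to [0, 1] — a Gaussian rising to 1 at ``center``
(default 1.0) whose width σ encodes how strongly low reliability for
property i is penalized (small σ = strict = high priority).  Reward_top X%
is the mean of the top X fraction of the run's rewards (default the top
10%).  The DSS is maximized over a discrete grid of ρ vectors with a
Gaussian-process surrogate and expected-improvement acquisition, seeded by
a short random phase; a brute-force enumerator provides the exact landscape
on small grids for validation.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from .generator import DesignRun
from .models import PropertyModel
from .rewards import DesirabilitySpec, RewardSpec
from .generator import reward_fn_from_spec


class EmptyRewardsError(ValueError):
    pass


class ExhaustedSpaceError(RuntimeError):
    pass


class CombinatorialExplosionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Scaler and DSS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalerConfig:
    """Strictness of the reliability-level scaling for one property.

    ``sigma``: width of the Gaussian penalty (0.15 tight / 0.25 normal /
    0.35 loose are the conventional patterns).  ``center``: the ρ value that
    scores 1.0 (default 1.0; every ρ at or above it is fully desirable).
    """

    sigma: float = 0.25
    center: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 < self.center <= 1):
            raise ValueError("center must be in (0, 1]")


def reliability_scaler(rho: float, cfg: ScalerConfig) -> float:
    """Rescale a reliability level ρ to [0, 1].

    Gaussian in ρ below ``center`` (strictly increasing there), saturated at
    1.0 at and above ``center``.  Smaller σ penalizes the same ρ harder.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must be in [0, 1]")
    if rho >= cfg.center:
        return 1.0
    return math.exp(-((rho - cfg.center) ** 2) / (2.0 * cfg.sigma**2))


def top_fraction_mean(rewards: Sequence[float], X: float = 0.10) -> float:
    """Mean of the ceil(X·n) largest rewards."""
    rewards = np.asarray(rewards, dtype=float)
    if rewards.size == 0:
        raise EmptyRewardsError("rewards must be non-empty")
    if not (0.0 < X <= 1.0):
        raise ValueError("top fraction must be in (0, 1]")
    k = math.ceil(X * rewards.size)
    top = np.sort(rewards)[-k:]
    return float(top.mean())


@dataclass
class DSSConfig:
    """Parameters of the DSS objective: per-property Scalers and top-X%."""

    scalers: list[ScalerConfig]
    top_fraction: float = 0.10
    valid_only: bool = False  # restrict the top-X% pool to valid molecules

    def scaler_for(self, i: int) -> ScalerConfig:
        return self.scalers[i] if len(self.scalers) > 1 else self.scalers[0]


def dss(rho: Sequence[float], run: DesignRun, cfg: DSSConfig) -> float:
    """DSS score of a design run at reliability levels ρ."""
    rho = np.asarray(rho, dtype=float)
    n = rho.size
    scaled = [reliability_scaler(rho[i], cfg.scaler_for(i)) for i in range(n)]
    if any(s == 0.0 for s in scaled):
        return 0.0
    geo = math.exp(sum(math.log(s) for s in scaled) / n)
    rewards = [r.reward for r in run.records if r.valid] if cfg.valid_only else [r.reward for r in run.records]
    if not rewards:
        return 0.0
    return geo * top_fraction_mean(rewards, cfg.top_fraction)


# ---------------------------------------------------------------------------
# Search space and evaluation context
# ---------------------------------------------------------------------------

@dataclass
class SearchSpace:
    """Per-property discrete grids of candidate reliability levels."""

    grids: list[np.ndarray]

    def __post_init__(self) -> None:
        self.grids = [np.asarray(g, dtype=float) for g in self.grids]
        for g in self.grids:
            if g.size == 0:
                raise ValueError("each grid must be non-empty")
            if np.any(np.diff(g) <= 0):
                raise ValueError("grids must be strictly increasing")
            if g.min() < 0 or g.max() > 1:
                raise ValueError("reliability levels must lie in [0, 1]")

    @classmethod
    def from_range(cls, n_properties: int, lo: float = 0.1, hi: float = 0.9, step: float = 0.01) -> "SearchSpace":
        grid = np.round(np.arange(lo, hi + step / 2, step), 10)
        return cls(grids=[grid.copy() for _ in range(n_properties)])

    @property
    def n_properties(self) -> int:
        return len(self.grids)

    @property
    def n_points(self) -> int:
        return int(np.prod([g.size for g in self.grids]))

    def enumerate(self):
        for combo in itertools.product(*self.grids):
            yield np.asarray(combo)

    def point(self, flat_index: int) -> np.ndarray:
        sizes = [g.size for g in self.grids]
        idx = np.unravel_index(flat_index, sizes)
        return np.asarray([g[i] for g, i in zip(self.grids, idx)])

    def normalize(self, rho: np.ndarray) -> np.ndarray:
        """Scale a ρ vector to [0, 1] per axis (GP surrogate input)."""
        out = np.empty_like(rho, dtype=float)
        for i, g in enumerate(self.grids):
            span = g.max() - g.min()
            out[i] = (rho[i] - g.min()) / span if span > 0 else 0.5
        return out


@dataclass
class DesignContext:
    """Everything fixed across the reliability search: models, desirability
    specs, weights, the generator, DSS config, and the per-run budget."""

    models: list[PropertyModel]
    desirabilities: list[DesirabilitySpec]
    weights: np.ndarray
    generator: object  # MCTSGenerator or PoolGenerator
    dss_config: DSSConfig
    budget: int = 10_000
    seed: int = 0
    strict_gate: bool = False

    @property
    def n_properties(self) -> int:
        return len(self.models)


def evaluate_levels(rho: Sequence[float], context: DesignContext) -> tuple[float, DesignRun]:
    """Design molecules at reliability levels ρ and score the run with DSS.

    This is the black-box objective of the reliability search.
    """
    rho = np.asarray(rho, dtype=float)
    spec = RewardSpec(
        models=context.models,
        desirabilities=context.desirabilities,
        weights=context.weights,
        rho=rho,
        strict=context.strict_gate,
    )
    run = context.generator.design(reward_fn_from_spec(spec), context.budget, seed=context.seed)
    return dss(rho, run, context.dss_config), run


# ---------------------------------------------------------------------------
# Exploration history
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExplorationRecord:
    step: int
    step_type: str  # "random" | "bo"
    rho: tuple[float, ...]
    dss: float
    top_reward: float
    n_in_ad: int
    n_records: int


@dataclass
class ExplorationHistory:
    """One episode of the reliability search."""

    records: list[ExplorationRecord] = field(default_factory=list)
    seed: int = 0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def rho_matrix(self) -> np.ndarray:
        return np.asarray([r.rho for r in self.records], dtype=float)

    @property
    def dss_values(self) -> np.ndarray:
        return np.asarray([r.dss for r in self.records], dtype=float)

    def best(self) -> ExplorationRecord:
        return max(self.records, key=lambda r: r.dss)

    def best_so_far(self) -> np.ndarray:
        """Running maximum of DSS (non-decreasing by construction)."""
        return np.maximum.accumulate(self.dss_values)

    def evaluated_points(self) -> set[tuple[float, ...]]:
        return {r.rho for r in self.records}

    def to_csv(self, path: str | Path) -> None:
        n = len(self.records[0].rho) if self.records else 0
        lines = ["step,type," + ",".join(f"rho_{i}" for i in range(n)) + ",dss,top_reward,n_in_ad,n_records"]
        for r in self.records:
            rho = ",".join(f"{x:.6f}" for x in r.rho)
            lines.append(f"{r.step},{r.step_type},{rho},{r.dss:.12g},{r.top_reward:.12g},{r.n_in_ad},{r.n_records}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = 0) -> "ExplorationHistory":
        lines = Path(path).read_text().strip().splitlines()
        n = sum(col.startswith("rho_") for col in lines[0].split(","))
        records = []
        for line in lines[1:]:
            parts = line.split(",")
            records.append(
                ExplorationRecord(
                    step=int(parts[0]),
                    step_type=parts[1],
                    rho=tuple(float(x) for x in parts[2 : 2 + n]),
                    dss=float(parts[2 + n]),
                    top_reward=float(parts[3 + n]),
                    n_in_ad=int(parts[4 + n]),
                    n_records=int(parts[5 + n]),
                )
            )
        return cls(records=records, seed=seed)

    def summary_json(self, path: str | Path) -> None:
        best = self.best()
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "n_steps": len(self.records),
                    "best_step": best.step,
                    "best_rho": list(best.rho),
                    "best_dss": best.dss,
                    "best_top_reward": best.top_reward,
                },
                indent=2,
            )
        )


# ---------------------------------------------------------------------------
# Gaussian-process surrogate and expected improvement
# ---------------------------------------------------------------------------

def fit_surrogate(X: np.ndarray, y: np.ndarray, seed: int = 0) -> GaussianProcessRegressor:
    """Fit the GP surrogate (RBF kernel, fitted length scales) on (ρ, DSS)."""
    n_dim = X.shape[1]
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
        length_scale=np.full(n_dim, 0.5), length_scale_bounds=(1e-2, 1e2)
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        alpha=1e-6,
        normalize_y=True,
        n_restarts_optimizer=2,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # length scales are deliberately bounded; hitting a bound on flat or
        # near-deterministic landscapes is expected, not an error
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X, y)
    return gp


def expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float, xi: float = 0.0) -> np.ndarray:
    """Closed-form EI of a Gaussian posterior over the incumbent best."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    imp = mu - best - xi
    ei = np.zeros_like(mu)
    pos = sigma > 0
    z = imp[pos] / sigma[pos]
    ei[pos] = imp[pos] * norm.cdf(z) + sigma[pos] * norm.pdf(z)
    return ei


MAX_ACQUISITION_CANDIDATES = 20_000


def suggest_next(
    history: ExplorationHistory,
    space: SearchSpace,
    seed: int = 0,
    xi: float = 0.0,
) -> np.ndarray:
    """Propose the unevaluated grid point maximizing expected improvement.

    A GP surrogate is fitted to the (ρ, DSS) pairs in ``history`` (inputs
    scaled to [0,1] per axis); already-evaluated points are excluded from the
    acquisition argmax.  When the grid is too large to score exhaustively, a
    seeded subsample of candidates is scored instead.
    """
    if len(history) == 0:
        raise ValueError("history must contain at least one record")
    evaluated = history.evaluated_points()
    rng = np.random.default_rng(seed)
    if space.n_points <= MAX_ACQUISITION_CANDIDATES:
        candidates = [rho for rho in space.enumerate() if tuple(rho) not in evaluated]
    else:
        flat = rng.choice(space.n_points, size=MAX_ACQUISITION_CANDIDATES, replace=False)
        candidates = [space.point(i) for i in sorted(flat)]
        candidates = [rho for rho in candidates if tuple(rho) not in evaluated]
    if not candidates:
        raise ExhaustedSpaceError("all grid points have been evaluated")

    X = np.vstack([space.normalize(np.asarray(rho)) for rho in history.rho_matrix])
    y = history.dss_values
    gp = fit_surrogate(X, y, seed=seed)
    Xc = np.vstack([space.normalize(rho) for rho in candidates])
    mu, sigma = gp.predict(Xc, return_std=True)
    ei = expected_improvement(mu, sigma, best=float(y.max()), xi=xi)
    return np.asarray(candidates[int(np.argmax(ei))])


# ---------------------------------------------------------------------------
# Episodes and the brute-force oracle
# ---------------------------------------------------------------------------

def run_episode(
    space: SearchSpace,
    context: DesignContext,
    n_random: int = 10,
    n_bo: int = 30,
    seed: int = 0,
) -> ExplorationHistory:
    """One reliability-search episode: ``n_random`` seeded random evaluations
    (without replacement) followed by ``n_bo`` BO-guided evaluations."""
    if space.n_points < n_random + n_bo:
        raise ValueError("search space smaller than the episode length")
    rng = np.random.default_rng(seed)
    step_seeds = np.random.SeedSequence(seed).generate_state(n_bo + 1) % (2**31)
    history = ExplorationHistory(seed=seed)

    flat_indices = rng.choice(space.n_points, size=n_random, replace=False)
    for step, flat in enumerate(flat_indices):
        rho = space.point(int(flat))
        _record(history, step, "random", rho, context)

    for b in range(n_bo):
        rho = suggest_next(history, space, seed=int(step_seeds[b]))
        _record(history, n_random + b, "bo", rho, context)

    return history


def _record(history: ExplorationHistory, step: int, step_type: str, rho: np.ndarray, context: DesignContext) -> None:
    score, run = evaluate_levels(rho, context)
    rewards = run.rewards
    history.records.append(
        ExplorationRecord(
            step=step,
            step_type=step_type,
            rho=tuple(float(x) for x in rho),
            dss=score,
            top_reward=top_fraction_mean(rewards, context.dss_config.top_fraction) if rewards.size else 0.0,
            n_in_ad=run.n_in_ad,
            n_records=len(run.records),
        )
    )


def brute_force_landscape(
    space: SearchSpace,
    context: DesignContext,
    limit: int = 100_000,
) -> dict[tuple[float, ...], float]:
    """Exact DSS at every grid point (test oracle; refuses huge grids)."""
    if space.n_points > limit:
        raise CombinatorialExplosionError(
            f"{space.n_points} grid points exceed the enumeration limit {limit}"
        )
    landscape = {}
    for rho in space.enumerate():
        score, _ = evaluate_levels(rho, context)
        landscape[tuple(float(x) for x in rho)] = score
    return landscape
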
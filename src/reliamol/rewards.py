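"""Desirability scaling, the Dscore, and the AD-gated reward.

The multi-objective reward of a designed molecule is the Dscore — the
weighted geometric mean of per-property desirabilities v_i —

    Dscore = (Π v_i^{w_i})^{1 / Σ w_i}

but it is paid out only inside the overlap of the applicability domains:
the reward is the Dscore if the reliability s_i (maximum Tanimoto similarity
to the i-th model's training data) meets the reliability level ρ_i for every
property, and 0 otherwise.  Gating the reward this way is what prevents the
generator from hacking the predictors in regions where they extrapolate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import Fingerprint, Molecule, morgan_fingerprint
from .models import PropertyModel


class ZeroTotalWeightError(ValueError):
    pass


VALID_SHAPES = ("gaussian", "max_gaussian", "min_gaussian")


@dataclass(frozen=True)
class DesirabilitySpec:
    """Gaussian-shaped desirability modifier mapping a property to [0, 1].

    ``gaussian`` peaks at ``mu`` and decays symmetrically; ``max_gaussian``
    saturates at 1 for values at or above ``mu`` (reward "at least mu");
    ``min_gaussian`` saturates at 1 for values at or below ``mu``.
    ``sigma_v`` is the decay width in property units.
    """

    shape: str = "gaussian"
    mu: float = 0.0
    sigma_v: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in VALID_SHAPES:
            raise ValueError(f"shape must be one of {VALID_SHAPES}, got {self.shape!r}")
        if self.sigma_v <= 0:
            raise ValueError("sigma_v must be positive")


def desirability(x: float, spec: DesirabilitySpec) -> float:
    """Evaluate the desirability v ∈ [0, 1] of a raw property value."""
    g = math.exp(-((x - spec.mu) ** 2) / (2.0 * spec.sigma_v**2))
    if spec.shape == "gaussian":
        return g
    if spec.shape == "max_gaussian":
        return 1.0 if x >= spec.mu else g
    return 1.0 if x <= spec.mu else g  # min_gaussian


def dscore(v: Sequence[float], w: Sequence[float]) -> float:
    """Weighted geometric mean (Π v_i^{w_i})^{1/Σw_i} of desirabilities.

    Zero-weight properties never gate: v_i^0 is taken as 1 even at v_i = 0.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != w.shape:
        raise ValueError("v and w must have equal length")
    total = w.sum()
    if total <= 0:
        raise ZeroTotalWeightError("at least one weight must be positive")
    active = w > 0
    if np.any(v[active] == 0.0):
        return 0.0
    return float(np.exp(np.sum(w[active] * np.log(v[active])) / total))


@dataclass
class RewardSpec:
    """Everything needed to score one molecule: models, desirabilities,
    weights, and the reliability vector ρ currently under evaluation."""

    models: list[PropertyModel]
    desirabilities: list[DesirabilitySpec]
    weights: np.ndarray
    rho: np.ndarray
    strict: bool = False  # use s_i > ρ_i instead of the default inclusive s_i ≥ ρ_i

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        n = len(self.models)
        if not (len(self.desirabilities) == len(self.weights) == len(self.rho) == n):
            raise ValueError("models, desirabilities, weights and rho must have equal length")
        if n == 0:
            raise ValueError("at least one property is required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if self.weights.sum() <= 0:
            raise ZeroTotalWeightError("at least one weight must be positive")

    @property
    def n_properties(self) -> int:
        return len(self.models)


@dataclass(frozen=True)
class RewardResult:
    """Full diagnostic tuple for one scored molecule (kept even when gated)."""

    reward: float
    s: tuple[float, ...]
    predictions: tuple[float, ...]
    v: tuple[float, ...]
    in_ad: bool = False


def gated_reward(mol: Molecule | Fingerprint, spec: RewardSpec) -> RewardResult:
    """Score a molecule with the AD-gated Dscore.

    Returns the reward together with the per-property reliabilities s,
    raw predictions, and desirabilities v, so that gated-to-zero molecules
    remain fully diagnosable in run logs.
    """
    if isinstance(mol, Molecule):
        fp = morgan_fingerprint(mol, radius=spec.models[0].radius, nbits=spec.models[0].nbits)
    else:
        fp = mol
    s = tuple(m.reliability(fp) for m in spec.models)
    preds = tuple(m.predict(fp) for m in spec.models)
    v = tuple(desirability(p, d) for p, d in zip(preds, spec.desirabilities))
    if spec.strict:
        inside = all(si > ri for si, ri in zip(s, spec.rho))
    else:
        inside = all(si >= ri for si, ri in zip(s, spec.rho))
    reward = dscore(v, spec.weights) if inside else 0.0
    return RewardResult(reward=reward, s=s, predictions=preds, v=v, in_ad=inside)
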
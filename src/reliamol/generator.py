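"""Candidate generation: MCTS over SMILES strings, plus a pool generator.

The search engine builds SMILES token by token with Monte Carlo tree search.
Each tree node holds one token; a path from the root is a SMILES prefix.
One iteration runs the classic four steps — selection (UCT score), expansion
(children proposed by a token policy), simulation (the policy completes the
prefix into a full SMILES, which is scored by the reward function), and
backpropagation (the reward is added along the selected path).

The token policy is pluggable.  The default is a maximum-likelihood n-gram
model with backoff, trained on a SMILES corpus; a recurrent network trained
on a large corpus could be dropped in behind the same interface.

For oracle tests and enumerable benchmarks a deterministic
:class:`PoolGenerator` evaluates a fixed candidate pool instead of searching.
"""

from __future__ import annotations

import csv
import math
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .chem import Fingerprint, InvalidSmilesError, Molecule, canonicalize
from .rewards import RewardResult, RewardSpec, gated_reward

BOS = "^"
EOS = "$"

DEFAULT_MAX_TOKENS = 80
DEFAULT_UCB_C = 1.0

# Two-character element symbols (Cl, Br), bracket atoms and %nn ring-bond
# labels must stay single tokens.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOSPFIbcnosp]|[HKWUVYufwky]|"
    r"[0-9]|\(|\)|=|#|-|\+|/|\\|\.|@|:|~|\*|\$)"
)


class EmptyCorpusError(ValueError):
    pass


class EmptyPoolError(ValueError):
    pass


class TokenizationError(ValueError):
    pass


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into atom/bond/control tokens."""
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise TokenizationError(f"cannot tokenize {smiles!r}")
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    return "".join(t for t in tokens if t not in (BOS, EOS))


# ---------------------------------------------------------------------------
# Token policy: n-gram with backoff
# ---------------------------------------------------------------------------

class TokenPolicy:
    """Maximum-likelihood n-gram token model with backoff.

    ``order`` is the context length: the conditional distribution of the next
    token given the last ``order`` tokens.  Contexts never seen in training
    back off to the longest seen suffix, down to the unconditional unigram
    distribution, so every context has positive mass on at least one token.
    """

    def __init__(self, order: int = 3):
        if order < 0:
            raise ValueError("order must be non-negative")
        self.order = order
        # counts[L][context (tuple of length L)] = Counter(next token)
        self.counts: list[dict[tuple, Counter]] = [defaultdict(Counter) for _ in range(order + 1)]
        self.vocabulary: set[str] = {BOS, EOS}

    def fit(self, corpus: Sequence[str]) -> "TokenPolicy":
        if not corpus:
            raise EmptyCorpusError("cannot fit a token policy on an empty corpus")
        for smiles in corpus:
            tokens = [BOS] + tokenize(smiles) + [EOS]
            self.vocabulary.update(tokens)
            for i in range(1, len(tokens)):
                for L in range(self.order + 1):
                    if i - L < 0:
                        break
                    self.counts[L][tuple(tokens[i - L : i])][tokens[i]] += 1
        return self

    def _backoff_counter(self, context: Sequence[str]) -> Counter:
        context = tuple(context)
        for L in range(min(self.order, len(context)), -1, -1):
            ctx = context[len(context) - L :]
            counter = self.counts[L].get(ctx)
            if counter:
                return counter
        raise EmptyCorpusError("policy has no counts; fit it first")

    def probabilities(self, context: Sequence[str]) -> dict[str, float]:
        """Next-token distribution for a context (sums to 1)."""
        counter = self._backoff_counter(context)
        total = sum(counter.values())
        return {tok: c / total for tok, c in sorted(counter.items())}

    def support(self, context: Sequence[str]) -> list[str]:
        """Tokens with positive probability after ``context``, sorted."""
        return sorted(self._backoff_counter(context))

    def sample(self, context: Sequence[str], rng: np.random.Generator) -> str:
        probs = self.probabilities(context)
        tokens = list(probs)
        return tokens[rng.choice(len(tokens), p=np.asarray(list(probs.values())))]


def train_policy(corpus: Sequence[str], order: int = 3) -> TokenPolicy:
    """Fit an n-gram token policy on a SMILES corpus."""
    return TokenPolicy(order=order).fit(corpus)


# ---------------------------------------------------------------------------
# Search tree
# ---------------------------------------------------------------------------

@dataclass
class SearchNode:
    """One token of a SMILES prefix in the search tree.

    ``visits`` counts backpropagations through the node; ``cumulative_reward``
    sums the rewards of those backpropagations (rewards live in [0, 1], so
    cumulative_reward <= visits always holds).
    """

    token: str
    visits: int = 0
    cumulative_reward: float = 0.0
    children: dict[str, "SearchNode"] = field(default_factory=dict)
    untried: list[str] | None = None  # lazily filled from the policy support

    @property
    def terminal(self) -> bool:
        return self.token == EOS

    @property
    def mean_reward(self) -> float:
        return self.cumulative_reward / self.visits if self.visits else 0.0


def ucb(node: SearchNode, parent_visits: int, C: float) -> float:
    """UCT score: mean reward plus C·sqrt(2 ln N_parent / N_child).

    Unvisited children score +inf, so they are always selected before any
    visited sibling.
    """
    if node.visits == 0:
        return math.inf
    return node.mean_reward + C * math.sqrt(2.0 * math.log(parent_visits) / node.visits)


def rollout(
    policy: TokenPolicy,
    prefix: Sequence[str],
    rng: np.random.Generator,
    max_tokens: int = DEFAULT_MAX_TOKENS,
) -> tuple[str, bool]:
    """Complete a token prefix into a full SMILES by sampling the policy.

    Returns ``(smiles, valid)``.  Hitting the length cutoff before the end
    sentinel yields ``valid=False``; validity of completed strings is checked
    by canonicalization.
    """
    if not prefix or prefix[0] != BOS:
        raise ValueError("prefix must start with the begin sentinel")
    tokens = list(prefix)
    while True:
        if tokens[-1] == EOS:
            break
        if len(tokens) - 1 >= max_tokens:  # BOS does not count against the budget
            return detokenize(tokens), False
        tokens.append(policy.sample(tokens, rng))
    smiles = detokenize(tokens)
    try:
        canonicalize(smiles)
    except InvalidSmilesError:
        return smiles, False
    return smiles, True


# ---------------------------------------------------------------------------
# Design runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignRecord:
    smiles: str
    valid: bool
    reward: float
    s: tuple[float, ...] = ()
    predictions: tuple[float, ...] = ()
    v: tuple[float, ...] = ()
    in_ad: bool = False


@dataclass
class DesignRun:
    """All molecules produced by one generator run at a fixed ρ."""

    records: list[DesignRecord]
    budget: int
    seed: int
    tree: "SearchNode | None" = field(default=None, compare=False, repr=False)

    @property
    def rewards(self) -> np.ndarray:
        return np.asarray([r.reward for r in self.records], dtype=float)

    @property
    def n_valid(self) -> int:
        return sum(r.valid for r in self.records)

    @property
    def n_in_ad(self) -> int:
        return sum(r.in_ad for r in self.records)

    def unique_valid(self) -> list[DesignRecord]:
        seen, out = set(), []
        for rec in self.records:
            if rec.valid and rec.smiles not in seen:
                seen.add(rec.smiles)
                out.append(rec)
        return out


RewardFn = Callable[[object], "RewardResult | float"]


def _as_record(item_label: str, valid: bool, result: "RewardResult | float") -> DesignRecord:
    if isinstance(result, RewardResult):
        return DesignRecord(
            smiles=item_label,
            valid=valid,
            reward=result.reward,
            s=result.s,
            predictions=result.predictions,
            v=result.v,
            in_ad=result.in_ad,
        )
    return DesignRecord(smiles=item_label, valid=valid, reward=float(result))


def reward_fn_from_spec(spec: RewardSpec) -> RewardFn:
    """Adapt a :class:`RewardSpec` into a generator reward function.

    Accepts a SMILES string, :class:`Molecule`, or :class:`Fingerprint`.
    """

    def fn(item):
        if isinstance(item, str):
            item = canonicalize(item)
        return gated_reward(item, spec)

    return fn


def run_design(
    reward_fn: RewardFn,
    policy: TokenPolicy,
    budget: int,
    C: float = DEFAULT_UCB_C,
    seed: int = 0,
    max_tokens: int = DEFAULT_MAX_TOKENS,
) -> DesignRun:
    """Run ``budget`` MCTS iterations maximizing ``reward_fn``.

    Each iteration appends one record (valid or not) to the run.  Duplicate
    SMILES are recorded every time they are generated but scored once via a
    canonical-SMILES cache.  Invalid completions receive reward 0 and are
    backpropagated like any other simulation.  Reproducible given ``seed``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    root = SearchNode(token=BOS)
    cache: dict[str, tuple[bool, RewardResult | float]] = {}
    records: list[DesignRecord] = []

    for _ in range(budget):
        # --- selection ---
        node, path, context = root, [root], [BOS]
        while not node.terminal:
            if node.untried is None:
                node.untried = policy.support(context)[::-1]  # pop() takes sorted order
            if node.untried or not node.children:
                break
            parent_visits = max(node.visits, 1)
            node = max(
                node.children.values(),
                key=lambda ch: (ucb(ch, parent_visits, C), ch.token),
            )
            path.append(node)
            context.append(node.token)

        # --- expansion ---
        if not node.terminal and node.untried:
            token = node.untried.pop()
            child = SearchNode(token=token)
            node.children[token] = child
            node, context = child, context + [token]
            path.append(node)

        # --- simulation ---
        if node.terminal:
            smiles = detokenize(context)
            valid_structure = True
        elif len(context) - 1 >= max_tokens:
            smiles, valid_structure = detokenize(context), False
        else:
            smiles, valid_structure = rollout(policy, context, rng, max_tokens)

        if smiles in cache:
            valid, result = cache[smiles]
        elif not valid_structure:
            valid, result = False, 0.0
            cache[smiles] = (valid, result)
        else:
            try:
                canonical = canonicalize(smiles).smiles
            except InvalidSmilesError:
                canonical = None
            if canonical is None:
                valid, result = False, 0.0
            elif canonical in cache:
                valid, result = cache[canonical]
            else:
                valid, result = True, reward_fn(canonical)
                cache[canonical] = (valid, result)
            cache[smiles] = (valid, result)
            smiles = canonical or smiles

        reward = result.reward if isinstance(result, RewardResult) else float(result)
        records.append(_as_record(smiles, valid, result))

        # --- backpropagation ---
        for n in path:
            n.visits += 1
            n.cumulative_reward += reward

    return DesignRun(records=records, budget=budget, seed=seed, tree=root)


class MCTSGenerator:
    """Generator interface wrapping :func:`run_design`."""

    def __init__(
        self,
        policy: TokenPolicy,
        C: float = DEFAULT_UCB_C,
        max_tokens: int = DEFAULT_MAX_TOKENS,
    ):
        self.policy = policy
        self.C = C
        self.max_tokens = max_tokens

    def design(self, reward_fn: RewardFn, budget: int, seed: int) -> DesignRun:
        return run_design(
            reward_fn, self.policy, budget, C=self.C, seed=seed, max_tokens=self.max_tokens
        )


class PoolGenerator:
    """Deterministic generator over a finite candidate pool.

    Evaluates exactly the pool, in order, once each — the enumerable stand-in
    for a stochastic search engine that makes brute-force oracles possible.
    Pool items may be SMILES strings, :class:`Molecule` objects, or
    ``(label, Fingerprint)`` pairs.
    """

    def __init__(self, pool: Sequence):
        if not pool:
            raise EmptyPoolError("candidate pool is empty")
        self.pool = list(pool)

    def design(self, reward_fn: RewardFn, budget: int | None = None, seed: int = 0) -> DesignRun:
        records = []
        for item in self.pool:
            if isinstance(item, tuple):
                label, payload = item
            elif isinstance(item, Molecule):
                label, payload = item.smiles, item
            elif isinstance(item, Fingerprint):
                label, payload = f"fp[{len(records)}]", item
            else:
                label, payload = str(item), item
            records.append(_as_record(str(label), True, reward_fn(payload)))
        return DesignRun(records=records, budget=len(self.pool), seed=seed)


def pool_generator(pool: Sequence) -> PoolGenerator:
    return PoolGenerator(pool)


def write_design_csv(run: DesignRun, path: str | Path, property_names: Sequence[str] | None = None) -> None:
    """Write a design run as CSV with per-property prediction/reliability columns."""
    n_props = max((len(r.s) for r in run.records), default=0)
    names = list(property_names) if property_names else [f"p{i}" for i in range(n_props)]
    header = ["smiles", "valid", "in_ad", "reward"]
    for name in names:
        header += [f"pred_{name}", f"rel_{name}", f"desirability_{name}"]
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(header)
        for rec in run.records:
            row = [rec.smiles, int(rec.valid), int(rec.in_ad), f"{rec.reward:.6f}"]
            for i in range(len(names)):
                row += [
                    f"{rec.predictions[i]:.6f}" if i < len(rec.predictions) else "",
                    f"{rec.s[i]:.6f}" if i < len(rec.s) else "",
                    f"{rec.v[i]:.6f}" if i < len(rec.v) else "",
                ]
            writer.writerow(row)
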
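"""Search for the optimal lumping: the minimum-state acceptable partition.

All methods share one incremental outer loop: start from the fully lumped
model (every free state in a single block, constrained states singleton),
ask an inner algorithm for an acceptable partition at the current number of
lumped states ``m``, and if none is found increment ``m`` and re-apply.  The
first ``m`` with an acceptable partition wins; in the worst case the loop
reaches ``m = n`` and returns the (exactly acceptable) identity model.

Inner algorithms:

* ``enumeration`` — exhaustively iterate every set partition of the free
  states (restricted growth strings; count = Stirling numbers of the second
  kind).
* ``nars`` — non-adaptive random search: uniform random legal partitions.
* ``scree-nars`` — NARS started at the state count suggested by the
  eigenvalue scree heuristic.
* ``sa`` — simulated annealing over partitions with a one-state-move
  neighbourhood and a Metropolis acceptance rule on the change in ARD%,
  with multiplicative cooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .criterion import CriterionConfig, PartitionEvaluator
from .linear_model import CompartmentalModel
from .lumping import LumpingPartition

__all__ = [
    "SearchConfig",
    "SAConfig",
    "SearchResult",
    "incremental_search",
    "enumerate_constrained_partitions",
    "count_constrained_partitions",
    "labeled_assignment_count",
    "full_enumeration_at_m",
    "sample_random_partition",
    "nars_at_m",
    "metropolis_accept",
    "sa_at_m",
]

METHODS = ("enumeration", "nars", "scree-nars", "sa")


@dataclass(frozen=True)
class SearchConfig:
    """Outer-loop settings shared by every method.

    ``tolerance`` is the ARD% acceptance threshold (percent).  ``start_m``
    is the first number of lumped states tried; the fully lumped start is
    ``1 + len(constrained_states)``.
    """

    method: str = "sa"
    tolerance: float = 0.002
    constrained_states: frozenset = frozenset()
    nars_samples: int = 10_000
    start_m: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; use one of {METHODS}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.nars_samples < 1:
            raise ValueError("nars_samples must be >= 1")
        object.__setattr__(
            self, "constrained_states", frozenset(self.constrained_states)
        )


@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing schedule: T_k = initial_temperature * cooling_factor**k."""

    initial_temperature: float = 1e4
    cooling_factor: float = 0.999
    max_iterations: int = 20_000

    def __post_init__(self) -> None:
        if self.initial_temperature <= 0:
            raise ValueError("initial temperature must be positive")
        if not (0 < self.cooling_factor < 1):
            raise ValueError("cooling factor must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class SearchResult:
    """Outcome of a search, including per-iteration traces for SA."""

    method: str
    final_partition: LumpingPartition
    m: int
    ard_percent: float
    evaluations: int
    accepted: bool
    seed: int
    traces: list = field(default_factory=list)  # (iteration, temperature, current, best)

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.traces,
            columns=["m", "iteration", "temperature", "current_ard", "best_ard"],
        )


# ---------------------------------------------------------------------------
# partition enumeration and sampling


def _free_states(n: int, constrained: frozenset) -> list:
    return [i for i in range(n) if i not in constrained]


def _compose(n: int, constrained: frozenset, free: Sequence[int], rgs: Sequence[int]) -> LumpingPartition:
    """Assemble a full partition from an RGS over the free states."""
    labels = [-1] * n
    base = 10**9  # temporary distinct labels; canonicalized by the constructor
    for j, i in enumerate(free):
        labels[i] = rgs[j]
    for k, i in enumerate(sorted(constrained)):
        labels[i] = base + k
    return LumpingPartition(tuple(labels), constrained)


def enumerate_constrained_partitions(
    n: int, blocks: int, constrained: Sequence[int] = ()
) -> Iterator[LumpingPartition]:
    """Every set partition of the free states into ``blocks - |constrained|``
    nonempty blocks, each constrained state its own singleton.

    Yields canonical partitions with no duplicates under block relabelling;
    the count is the Stirling number of the second kind S(n_free, k).
    An infeasible block count yields nothing.
    """
    constrained = frozenset(constrained)
    free = _free_states(n, constrained)
    k = blocks - len(constrained)
    if len(free) == 0:
        if k == 0:
            yield LumpingPartition.identity(n, constrained)
        return
    if k < 1 or k > len(free):
        return
    # iterate restricted growth strings with exactly k distinct labels
    f = len(free)
    rgs = [0] * f
    maxes = [0] * f  # maxes[j] = max(rgs[:j+1])

    def rec(j: int, cur_max: int):
        if j == f:
            if cur_max + 1 == k:
                yield tuple(rgs)
            return
        # prune: remaining positions must be able to reach k labels
        remaining = f - j
        for v in range(min(cur_max + 1, k - 1) + 1):
            new_max = max(cur_max, v)
            if (new_max + 1) + remaining - 1 < k:
                continue
            rgs[j] = v
            yield from rec(j + 1, new_max)

    for s in rec(1, 0) if f > 0 else iter(()):
        yield _compose(n, constrained, free, s)


def count_constrained_partitions(n: int, blocks: int, constrained: Sequence[int] = ()) -> int:
    """Stirling number S(n_free, blocks - |constrained|) by recurrence."""
    constrained = frozenset(constrained)
    f = n - len(constrained)
    k = blocks - len(constrained)
    if f == 0:
        return 1 if k == 0 else 0
    if k < 1 or k > f:
        return 0
    # S(i, j) table
    S = [[0] * (k + 1) for _ in range(f + 1)]
    S[0][0] = 1
    for i in range(1, f + 1):
        for j in range(1, min(i, k) + 1):
            S[i][j] = j * S[i - 1][j] + S[i - 1][j - 1]
    return S[f][k]


def labeled_assignment_count(n_free: int, blocks_free: int) -> int:
    """The naive labelled count ``blocks_free ** n_free`` (includes relabelled
    duplicates and assignments with empty blocks); exposed for reporting."""
    return blocks_free**n_free


def sample_random_partition(
    n: int, blocks: int, constrained: Sequence[int], rng: np.random.Generator
) -> LumpingPartition:
    """A uniform random legal partition with exactly ``blocks`` blocks.

    Free states get uniform labels in ``{0..k-1}``; assignments that leave a
    block empty are rejected and redrawn.  Every set partition into k blocks
    corresponds to exactly k! surviving labelled assignments, so the
    canonicalized result is uniform over set partitions.
    """
    constrained = frozenset(constrained)
    free = _free_states(n, constrained)
    k = blocks - len(constrained)
    if len(free) == 0 and k == 0:
        return LumpingPartition.identity(n, constrained)
    if k < 1 or k > len(free):
        raise ValueError(
            f"cannot split {len(free)} free states into {k} nonempty blocks"
        )
    while True:
        labels = rng.integers(0, k, size=len(free))
        if len(np.unique(labels)) == k:
            return _compose(n, constrained, free, labels.tolist())


# ---------------------------------------------------------------------------
# inner algorithms


def full_enumeration_at_m(
    evaluator: PartitionEvaluator,
    m: int,
    config: SearchConfig,
    short_circuit: bool = False,
):
    """Evaluate every partition at ``m`` blocks.

    Returns ``(best_partition, min_ard, first_accepted, first_ard)`` where
    ``first_accepted`` is the first partition in lexicographic RGS order
    meeting the tolerance (or None, with ``first_ard = inf``).  With
    ``short_circuit`` the scan stops at the first acceptable partition (then
    ``best`` is only best-so-far).
    """
    best = None
    best_ard = math.inf
    first_accepted = None
    first_ard = math.inf
    for part in enumerate_constrained_partitions(
        evaluator.model.n, m, config.constrained_states
    ):
        ard = evaluator.evaluate(part)
        if best is None or ard < best_ard:
            best, best_ard = part, ard
        if first_accepted is None and ard <= config.tolerance:
            first_accepted, first_ard = part, ard
            if short_circuit:
                break
    return best, best_ard, first_accepted, first_ard


def nars_at_m(
    evaluator: PartitionEvaluator,
    m: int,
    n_samples: int,
    config: SearchConfig,
    rng: np.random.Generator,
):
    """Non-adaptive random search at fixed ``m``: draw, evaluate, keep best.

    Short-circuits on the first partition meeting the tolerance.
    """
    best = None
    best_ard = math.inf
    for _ in range(n_samples):
        part = sample_random_partition(
            evaluator.model.n, m, config.constrained_states, rng
        )
        ard = evaluator.evaluate(part)
        if best is None or ard < best_ard:
            best, best_ard = part, ard
        if ard <= config.tolerance:
            break
    return best, best_ard


def metropolis_accept(
    delta_ard: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Accept an uphill move with probability ``exp(-delta/T)``; downhill always."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_ard <= 0:
        return True
    if not math.isfinite(delta_ard):
        return False
    arg = delta_ard / temperature
    if arg > 700:  # exp underflows anyway
        return False
    return rng.random() < math.exp(-arg)


def _propose_move(
    part: LumpingPartition, free: Sequence[int], k: int, rng: np.random.Generator
) -> Optional[LumpingPartition]:
    """Move one free state to a different free block, never emptying a block.

    Returns None when no legal move exists (all free blocks singleton).
    """
    block_of = list(part.block_of)
    free_labels = sorted({block_of[i] for i in free})
    if k <= 1:
        return None
    sizes = {lab: 0 for lab in free_labels}
    for i in free:
        sizes[block_of[i]] += 1
    movable = [i for i in free if sizes[block_of[i]] >= 2]
    if not movable:
        return None
    i = movable[int(rng.integers(0, len(movable)))]
    targets = [lab for lab in free_labels if lab != block_of[i]]
    block_of[i] = targets[int(rng.integers(0, len(targets)))]
    return LumpingPartition(tuple(block_of), part.constrained)


def sa_at_m(
    evaluator: PartitionEvaluator,
    m: int,
    sa: SAConfig,
    config: SearchConfig,
    rng: np.random.Generator,
):
    """Simulated annealing over partitions at fixed ``m``.

    Starts from a uniform random legal partition; one Metropolis proposal per
    cooling cycle, temperature multiplied by the cooling factor each cycle.
    Stops at the iteration budget or as soon as the best-ever partition meets
    the tolerance.  Returns ``(best_partition, best_ard, traces)`` with one
    ``(iteration, temperature, current_ard, best_ard)`` record per iteration.
    """
    n = evaluator.model.n
    free = _free_states(n, config.constrained_states)
    k = m - len(config.constrained_states)
    current = sample_random_partition(n, m, config.constrained_states, rng)
    current_ard = evaluator.evaluate(current)
    best, best_ard = current, current_ard
    T = sa.initial_temperature
    traces = [(0, T, current_ard, best_ard)]
    if best_ard <= config.tolerance:
        return best, best_ard, traces
    for it in range(1, sa.max_iterations + 1):
        prop = _propose_move(current, free, k, rng)
        if prop is None:
            break
        ard = evaluator.evaluate(prop)
        delta = ard - current_ard
        if math.isnan(delta):  # both infeasible (inf ARD): indifferent move
            delta = 0.0
        if metropolis_accept(delta, T, rng):
            current, current_ard = prop, ard
        if current_ard < best_ard:
            best, best_ard = current, current_ard
        T *= sa.cooling_factor
        traces.append((it, T, current_ard, best_ard))
        if best_ard <= config.tolerance:
            break
    return best, best_ard, traces


# ---------------------------------------------------------------------------
# outer loop


def incremental_search(
    model: CompartmentalModel,
    config: SearchConfig,
    sa: Optional[SAConfig] = None,
) -> SearchResult:
    """Find the minimum-m acceptable lumping by incrementing ``m``.

    Starts from the fully lumped model (``m = 1 + |constrained|``, or
    ``config.start_m`` if larger, e.g. from the scree heuristic) and applies
    the configured inner algorithm at each ``m`` until a partition meets the
    tolerance.  Reaching ``m = n`` returns the identity model, which is
    exact, with ``accepted=True``.
    """
    constrained = config.constrained_states
    for s in constrained:
        if not (0 <= s < model.n):
            raise ValueError(f"constrained state {s} out of range")
    sa = sa or SAConfig()
    evaluator = PartitionEvaluator(
        model, CriterionConfig(tolerance=config.tolerance)
    )
    rng = np.random.default_rng(config.seed)

    m0 = 1 + len(constrained)
    method = config.method
    if method == "scree-nars":
        from .scree import compute_scree, suggest_initial_states

        m0 = max(m0, suggest_initial_states(compute_scree(model.K)))
    if config.start_m is not None:
        m0 = max(m0, config.start_m)
    m0 = min(max(m0, 1), model.n)

    traces: list = []
    for m in range(m0, model.n):
        if method == "enumeration":
            best, best_ard, first, first_ard = full_enumeration_at_m(
                evaluator, m, config, short_circuit=True
            )
            found, found_ard = (first, first_ard) if first is not None else (best, best_ard)
        elif method in ("nars", "scree-nars"):
            found, found_ard = nars_at_m(
                evaluator, m, config.nars_samples, config, rng
            )
        else:  # sa
            found, found_ard, tr = sa_at_m(evaluator, m, sa, config, rng)
            traces.extend((m,) + t for t in tr)
        if found is not None and found_ard <= config.tolerance:
            return SearchResult(
                method=method,
                final_partition=found,
                m=m,
                ard_percent=found_ard,
                evaluations=evaluator.evaluations,
                accepted=True,
                seed=config.seed,
                traces=traces,
            )
    identity = LumpingPartition.identity(model.n, constrained)
    return SearchResult(
        method=method,
        final_partition=identity,
        m=model.n,
        ard_percent=0.0,
        evaluations=evaluator.evaluations,
        accepted=True,
        seed=config.seed,
        traces=traces,
    )
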
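"""Acceptance criteria comparing a lumped model with its original.

The headline statistic is ARD%: the absolute relative difference of the
output-state AUC, expressed as a percent,

    ARD% = |AUC_lumped - AUC_original| / AUC_original * 100.

A lumped model is acceptable when ARD% does not exceed the tolerance
(default 0.002%).  The original model's AUC is the fixed reference and is
computed once per evaluator.  A trajectory sum-of-squares criterion is
provided as an alternative discrepancy measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .linear_model import (
    CompartmentalModel,
    InfiniteAUCError,
    auc_to_infinity,
    simulate_matrix_exponential,
)
from .lumping import LumpingPartition, lump_rate_matrix

__all__ = [
    "CriterionConfig",
    "ard_percent",
    "PartitionEvaluator",
    "evaluate_partition",
    "TrajectorySSECriterion",
]


@dataclass(frozen=True)
class CriterionConfig:
    """Which discrepancy to use and how tight. ``tolerance`` is in percent."""

    kind: str = "ard-auc"
    tolerance: float = 0.002
    output_state: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def ard_percent(auc_original: float, auc_lumped: float) -> float:
    """``|auc_lumped - auc_original| / auc_original * 100``."""
    if auc_original <= 0:
        raise ValueError("reference AUC must be positive")
    return abs(auc_lumped - auc_original) / auc_original * 100.0


class PartitionEvaluator:
    """Caches the original model's AUC and scores partitions by ARD%.

    ``evaluate`` returns ``inf`` (never acceptable) when the lumped system
    has no finite output AUC; the diagnostic is kept in ``last_diagnostic``.
    ``evaluations`` counts every scored partition.
    """

    def __init__(self, model: CompartmentalModel, config: Optional[CriterionConfig] = None):
        self.model = model
        self.config = config or CriterionConfig()
        out = self.config.output_state
        self.output_state = model.output_state if out is None else out
        self.auc_reference = auc_to_infinity(model, self.output_state)
        if self.auc_reference <= 0:
            raise ValueError("original model has nonpositive output AUC")
        self.evaluations = 0
        self.last_diagnostic: Optional[str] = None
        # hoisted for speed inside combinatorial searches
        self._K = model.K
        self._y0 = model.y0
        self._n = model.n

    def evaluate(self, partition: LumpingPartition) -> float:
        """ARD% of ``partition`` against the cached reference AUC."""
        self.evaluations += 1
        self.last_diagnostic = None
        block_of = np.asarray(partition.block_of)
        m = partition.m
        # K_hat = M K M+ computed by group-summing rows and group-averaging
        # columns of K; y0_hat = block sums of y0.
        rowsum = np.zeros((m, self._n))
        np.add.at(rowsum, block_of, self._K)
        K_hat = np.zeros((m, m))
        np.add.at(K_hat.T, block_of, rowsum.T)
        sizes = np.bincount(block_of, minlength=m).astype(float)
        K_hat /= sizes[None, :]
        y0_hat = np.bincount(block_of, weights=self._y0, minlength=m)
        out_block = partition.block_of[self.output_state]

        eigs = np.linalg.eigvals(K_hat)
        scale = max(1.0, float(np.abs(K_hat).max()))
        if np.any(eigs.real > 1e-12 * scale) or np.any(
            np.abs(eigs) <= 1e-12 * scale
        ):
            self.last_diagnostic = (
                "lumped system has no finite output AUC (non-decaying or "
                "singular K_hat); partition not acceptable"
            )
            return float("inf")
        auc_l = float(np.linalg.solve(K_hat, -y0_hat)[out_block])
        return ard_percent(self.auc_reference, auc_l)

    def is_acceptable(self, value: float) -> bool:
        return value <= self.config.tolerance


def evaluate_partition(
    model: CompartmentalModel,
    partition: LumpingPartition,
    config: Optional[CriterionConfig] = None,
) -> float:
    """One-shot ARD% of a partition (builds a fresh evaluator)."""
    return PartitionEvaluator(model, config).evaluate(partition)


class TrajectorySSECriterion:
    """Sum of squared output-trajectory deviations on a fixed time grid.

    An alternative to the AUC-based ARD%: discrepancies that cancel in the
    integral still register here.  Not used for acceptance decisions by
    default.
    """

    kind = "trajectory-sse"

    def __init__(self, model: CompartmentalModel, times: np.ndarray):
        self.model = model
        self.times = np.asarray(times, dtype=float)
        self.reference = simulate_matrix_exponential(model, self.times).trajectories[
            model.output_state
        ]
        self.evaluations = 0

    def evaluate(self, partition: LumpingPartition) -> float:
        self.evaluations += 1
        lumped = lump_rate_matrix(self.model, partition)
        traj = simulate_matrix_exponential(lumped.as_model(), self.times).trajectories[
            lumped.output_block
        ]
        return float(np.sum((traj - self.reference) ** 2))
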
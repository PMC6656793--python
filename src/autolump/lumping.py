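"""Proper-lumping algebra: partitions, lumping matrices and lumped systems.

Proper lumping merges original states into pseudo-states so that each
original state belongs to exactly one lump.  A partition of the ``n`` states
into ``m`` blocks induces the 0/1 lumping matrix ``M`` (m-by-n, column sums
all 1) and the lumped rate matrix

    K_hat = M @ K @ pinv(M)

where ``pinv(M)`` is the Moore-Penrose pseudo-inverse.  The lumped state
vector is ``y_hat = M @ y`` and evolves as ``dy_hat/dt = K_hat @ y_hat``.

Partitions are stored as canonical restricted growth strings (block labels
in order of first appearance), which removes block-label symmetry: two equal
set partitions always compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .linear_model import CompartmentalModel, PhysiologicalParameters

__all__ = [
    "LumpingPartition",
    "LumpedModel",
    "make_lumping_matrix",
    "moore_penrose_pinv",
    "lump_rate_matrix",
    "lumped_physiological_parameters",
]


def _canonicalize(block_of: Sequence[int]) -> tuple:
    """Relabel blocks in order of first appearance (restricted growth string)."""
    mapping: dict = {}
    out = []
    for b in block_of:
        if b not in mapping:
            mapping[b] = len(mapping)
        out.append(mapping[b])
    return tuple(out)


@dataclass(frozen=True)
class LumpingPartition:
    """Assignment of ``n`` original states to ``m`` lumped blocks.

    ``block_of[i]`` is the block label of state ``i``; labels are canonical
    (0-based, in order of first appearance).  ``constrained`` states must each
    sit alone in their block (e.g. the observed output state).
    """

    block_of: tuple
    constrained: frozenset = frozenset()

    def __post_init__(self) -> None:
        block_of = _canonicalize(self.block_of)
        object.__setattr__(self, "block_of", block_of)
        object.__setattr__(self, "constrained", frozenset(self.constrained))
        n = len(block_of)
        if n == 0:
            raise ValueError("partition of zero states")
        m = max(block_of) + 1
        sizes = np.bincount(np.asarray(block_of), minlength=m)
        if np.any(sizes == 0):  # cannot happen after canonicalization
            raise ValueError("empty block")
        for s in self.constrained:
            if not (0 <= s < n):
                raise ValueError(f"constrained state {s} out of range")
            if sizes[block_of[s]] != 1:
                raise ValueError(
                    f"constrained state {s} must be a singleton block"
                )

    @property
    def n(self) -> int:
        return len(self.block_of)

    @property
    def m(self) -> int:
        return max(self.block_of) + 1

    @property
    def blocks(self) -> list:
        """Members of each block, as lists of original-state indices."""
        out: list = [[] for _ in range(self.m)]
        for i, b in enumerate(self.block_of):
            out[b].append(i)
        return out

    def is_identity(self) -> bool:
        return self.m == self.n

    @classmethod
    def identity(cls, n: int, constrained: Iterable[int] = ()) -> "LumpingPartition":
        return cls(tuple(range(n)), frozenset(constrained))

    @classmethod
    def fully_lumped(cls, n: int, constrained: Iterable[int] = ()) -> "LumpingPartition":
        """All free states in one block; each constrained state a singleton."""
        constrained = frozenset(constrained)
        labels = [-1] * n
        nxt = 0
        free_label = None
        for i in range(n):
            if i in constrained:
                labels[i] = nxt
                nxt += 1
            else:
                if free_label is None:
                    free_label = nxt
                    nxt += 1
                labels[i] = free_label
        return cls(tuple(labels), constrained)

    @classmethod
    def from_blocks(
        cls, blocks: Iterable[Iterable[int]], constrained: Iterable[int] = ()
    ) -> "LumpingPartition":
        blocks = [list(b) for b in blocks]
        n = sum(len(b) for b in blocks)
        labels = [-1] * n
        for lab, members in enumerate(blocks):
            for i in members:
                if not (0 <= i < n) or labels[i] != -1:
                    raise ValueError("blocks must partition 0..n-1")
                labels[i] = lab
        return cls(tuple(labels), frozenset(constrained))

    def to_frame(self, state_names: Optional[Sequence[str]] = None):
        import pandas as pd

        names = list(state_names) if state_names is not None else list(range(self.n))
        return pd.DataFrame({"state": names, "block": list(self.block_of)})


@dataclass(frozen=True)
class LumpedModel:
    """The reduced system ``dy_hat/dt = K_hat @ y_hat`` plus block bookkeeping."""

    K_hat: np.ndarray
    blocks: tuple
    y0_hat: np.ndarray
    output_block: int
    lumped_volumes: Optional[np.ndarray] = None
    state_names: Optional[tuple] = None

    @property
    def m(self) -> int:
        return self.K_hat.shape[0]

    def as_model(self) -> CompartmentalModel:
        """View the lumped system as a CompartmentalModel (no volume check)."""
        names = self.state_names or tuple(f"L{b}" for b in range(self.m))
        return CompartmentalModel(
            state_names=names,
            K=self.K_hat,
            y0=self.y0_hat,
            output_state=self.output_block,
        )


def make_lumping_matrix(partition: LumpingPartition) -> np.ndarray:
    """The m-by-n 0/1 matrix M: row b has ones at the members of block b."""
    M = np.zeros((partition.m, partition.n))
    M[np.asarray(partition.block_of), np.arange(partition.n)] = 1.0
    return M


def moore_penrose_pinv(M: np.ndarray) -> np.ndarray:
    """Moore-Penrose pseudo-inverse of a legal lumping matrix.

    For a 0/1 lumping matrix, ``M @ M.T`` is the diagonal matrix of block
    sizes, so ``pinv(M) = M.T @ inv(M @ M.T)`` has entry ``1/|block b|`` at
    each member of block ``b``; all four Penrose conditions hold.
    """
    M = np.asarray(M, dtype=float)
    sizes = M.sum(axis=1)
    if np.any(sizes < 1) or not np.array_equal(M.sum(axis=0), np.ones(M.shape[1])):
        raise ValueError("not a legal lumping matrix")
    return M.T / sizes[None, :]


def lump_rate_matrix(
    model: CompartmentalModel, partition: LumpingPartition
) -> LumpedModel:
    """Build the lumped system ``K_hat = M K pinv(M)``, ``y0_hat = M y0``."""
    if partition.n != model.n:
        raise ValueError(
            f"partition over {partition.n} states, model has {model.n}"
        )
    M = make_lumping_matrix(partition)
    Mp = moore_penrose_pinv(M)
    K_hat = M @ model.K @ Mp
    y0_hat = M @ model.y0
    blocks = tuple(tuple(b) for b in partition.blocks)
    output_block = partition.block_of[model.output_state]
    lumped_volumes = None
    if model.volumes is not None:
        lumped_volumes = M @ model.volumes
    names = tuple(
        "+".join(model.state_names[i] for i in b) for b in blocks
    )
    return LumpedModel(
        K_hat=K_hat,
        blocks=blocks,
        y0_hat=y0_hat,
        output_block=output_block,
        lumped_volumes=lumped_volumes,
        state_names=names,
    )


def lumped_physiological_parameters(
    params: PhysiologicalParameters,
    partition: LumpingPartition,
    tissue_state_index: dict,
) -> list:
    """Per-block lumped flow, volume and partition coefficient.

    ``tissue_state_index`` maps tissue name -> original state index.  Lumped
    volume and flow are sums over members.  The lumped partition coefficient
    uses a volume-weighted mean (``kp_rule = "volume_weighted_fallback"``),
    which is exact when members share a common Kp.  Blocks containing any
    non-tissue state (blood, lung, sub-compartments) get ``None`` parameters
    rather than an error.
    """
    by_state = {}
    for t in params.tissues:
        if t.name in tissue_state_index:
            by_state[tissue_state_index[t.name]] = t
    out = []
    for b, members in enumerate(partition.blocks):
        tissues = [by_state.get(i) for i in members]
        if any(t is None for t in tissues):
            out.append(
                {"block": b, "Q": None, "V": None, "Kp": None, "kp_rule": None}
            )
            continue
        V = sum(t.V for t in tissues)
        Q = sum(t.Q for t in tissues)
        Kp = sum(t.V * t.Kp for t in tissues) / V
        out.append(
            {
                "block": b,
                "Q": Q,
                "V": V,
                "Kp": Kp,
                "kp_rule": "volume_weighted_fallback",
            }
        )
    return out
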
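"""Eigenvalue scree heuristic for an informative starting number of states.

Ranking log10 of the absolute eigenvalues of the rate matrix K in descending
order gives a scree-plot curve; the count of values above a cutoff (default
log10|eig| = 0, i.e. |eig| = 1 in the model's time units) suggests how many
lumped states to start a random search from.  This is a rank-based heuristic
only: no correspondence between individual eigenvalues and compartments is
assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScreeData", "compute_scree", "suggest_initial_states"]


@dataclass(frozen=True)
class ScreeData:
    """Eigenvalues of K and their ranked log10 magnitudes (descending)."""

    eigenvalues: np.ndarray
    ranked_log_abs: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranked_log_abs) + 1),
                "log10_abs_eig": self.ranked_log_abs,
            }
        )


def compute_scree(K: np.ndarray) -> ScreeData:
    """Eigenvalues of K mapped to log10|lambda|, sorted descending.

    A zero eigenvalue (singular K) maps to the ``-inf`` sentinel rather than
    raising.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    eigs = np.linalg.eigvals(K)
    mags = np.abs(eigs)
    with np.errstate(divide="ignore"):
        log_abs = np.where(mags > 0, np.log10(np.where(mags > 0, mags, 1.0)), -np.inf)
    order = np.argsort(-log_abs, kind="stable")
    return ScreeData(eigenvalues=eigs[order], ranked_log_abs=log_abs[order])


def suggest_initial_states(
    scree: ScreeData, cutoff: float = 0.0, rule: str = "cutoff"
) -> int:
    """Suggested starting number of lumped states.

    ``rule="cutoff"`` counts ranked log10|eig| values strictly above
    ``cutoff``; ``rule="slope"`` places the cut at the largest consecutive
    drop in the ranked curve.  The result is floored at 2 so a constrained
    output state plus one lump always exist.
    """
    ranked = scree.ranked_log_abs
    if rule == "cutoff":
        count = int(np.sum(ranked > cutoff))
    elif rule == "slope":
        finite = ranked[np.isfinite(ranked)]
        if len(finite) < 2:
            count = len(finite)
        else:
            drops = -np.diff(finite)
            count = int(np.argmax(drops)) + 1
    else:
        raise ValueError("rule must be 'cutoff' or 'slope'")
    return max(2, min(count, len(ranked))) if len(ranked) >= 2 else len(ranked)
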
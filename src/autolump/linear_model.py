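"""Linear compartmental models and their closed-form simulation.

A compartmental model is the linear ODE system ``dy/dt = K @ y`` where ``y``
holds per-state concentrations and ``K`` is the micro-rate-constant matrix
(units: 1/time).  For perfusion-limited physiologically based pharmacokinetic
(PBPK) models, ``K`` is assembled from per-tissue blood flow ``Q``, tissue
volume ``V`` and tissue:blood partition coefficient ``Kp``:

* tissue ``i`` gains drug from arterial blood at rate ``Q_i / V_i`` and
  returns it to venous blood at rate ``Q_i / (V_i * Kp_i)``;
* the lung sits in series between venous and arterial blood and carries the
  whole cardiac output;
* portal tissues (spleen, gut) drain through the liver instead of directly
  into the venous pool;
* elimination appears as an extra first-order loss in the clearing tissue's
  column (hepatic metabolism in the bundled model);
* optional sub-compartments exchange first-order with their parent tissue.

Trajectories are computed with the matrix exponential, ``y(t) = expm(K t) y0``,
and the exposure metric is the area under the output-state concentration-time
curve integrated to infinity, ``AUC = (-K^{-1} y0)[output]`` for stable ``K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "CompartmentalModel",
    "TissueParameters",
    "PhysiologicalParameters",
    "SimulationResult",
    "InfiniteAUCError",
    "TopologyError",
    "build_rate_matrix",
    "simulate_matrix_exponential",
    "auc_to_infinity",
]


class InfiniteAUCError(ValueError):
    """The output trajectory does not decay, so the AUC diverges."""


class TopologyError(ValueError):
    """The physiological topology is not fully connected to the blood pool."""


@dataclass(frozen=True)
class CompartmentalModel:
    """A linear compartmental system ``dy/dt = K @ y`` in concentration units.

    Parameters
    ----------
    state_names
        One identifier per state.
    K
        Square micro-rate-constant matrix, 1/time.
    y0
        Initial concentrations (one positive entry for a bolus dose).
    output_state
        Index of the observation state (arterial blood in PBPK use).
    volumes
        Optional per-state volumes.  When given, mass balance is checked on
        the amount basis ``diag(V) K diag(V)^-1``: every column sum must be
        <= 0, strictly negative only where elimination occurs.
    dose_amount
        Bolus mass (bookkeeping only; ``y0`` already encodes it).
    provenance
        Free-form origin tag, e.g. ``"synthetic_placeholder"``.
    """

    state_names: tuple
    K: np.ndarray
    y0: np.ndarray
    output_state: int
    volumes: Optional[np.ndarray] = None
    dose_amount: Optional[float] = None
    provenance: str = "user"

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        y0 = np.asarray(self.y0, dtype=float)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "y0", y0)
        object.__setattr__(self, "state_names", tuple(self.state_names))
        n = K.shape[0]
        if K.ndim != 2 or K.shape != (n, n):
            raise ValueError("K must be a square matrix")
        if n < 2:
            raise ValueError("a compartmental model needs at least 2 states")
        if not np.all(np.isfinite(K)):
            raise ValueError("K contains non-finite entries")
        if len(self.state_names) != n:
            raise ValueError("state_names length must match K")
        if y0.shape != (n,):
            raise ValueError("y0 length must match K")
        if np.any(y0 < 0) or not np.any(y0 > 0):
            raise ValueError("y0 must be nonnegative with a positive entry")
        if not (0 <= self.output_state < n):
            raise ValueError("output_state out of range")
        if self.volumes is not None:
            V = np.asarray(self.volumes, dtype=float)
            object.__setattr__(self, "volumes", V)
            if V.shape != (n,) or np.any(V <= 0):
                raise ValueError("volumes must be positive, one per state")
            colsums = self.amount_basis_matrix().sum(axis=0)
            if np.any(colsums > 1e-9 * max(1.0, np.abs(K).max())):
                raise ValueError(
                    "mass balance violated: amount-basis column sums must be <= 0"
                )

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def amount_basis_matrix(self) -> np.ndarray:
        """Return ``diag(V) K diag(V)^-1``, the rate matrix on drug amounts."""
        if self.volumes is None:
            raise ValueError("model has no volumes")
        V = self.volumes
        return (V[:, None] * self.K) / V[None, :]

    def to_dict(self) -> dict:
        d = {
            "states": list(self.state_names),
            "rate_matrix": self.K.tolist(),
            "y0": self.y0.tolist(),
            "output_state": self.state_names[self.output_state],
            "provenance": self.provenance,
        }
        if self.volumes is not None:
            d["volumes"] = self.volumes.tolist()
        if self.dose_amount is not None:
            d["dose"] = {
                "state": self.state_names[int(np.argmax(self.y0))],
                "amount": self.dose_amount,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CompartmentalModel":
        states = list(d["states"])
        K = np.asarray(d["rate_matrix"], dtype=float)
        volumes = np.asarray(d["volumes"], dtype=float) if "volumes" in d else None
        out = d["output_state"]
        output_state = states.index(out) if isinstance(out, str) else int(out)
        dose_amount = None
        if "y0" in d:
            y0 = np.asarray(d["y0"], dtype=float)
        elif "dose" in d:
            if volumes is None:
                raise ValueError("a dose specification requires volumes")
            y0 = np.zeros(len(states))
            idx = states.index(d["dose"]["state"])
            dose_amount = float(d["dose"]["amount"])
            y0[idx] = dose_amount / volumes[idx]
        else:
            raise ValueError("model dict needs 'y0' or 'dose'")
        if dose_amount is None and "dose" in d:
            dose_amount = float(d["dose"]["amount"])
        return cls(
            state_names=tuple(states),
            K=K,
            y0=y0,
            output_state=output_state,
            volumes=volumes,
            dose_amount=dose_amount,
            provenance=d.get("provenance", "user"),
        )


@dataclass(frozen=True)
class TissueParameters:
    """Perfusion-limited parameters of one tissue.

    ``Q`` blood flow (volume/time), ``V`` tissue volume, ``Kp`` tissue:blood
    partition coefficient, ``clearance`` optional intrinsic loss (volume/time)
    applied to the tissue's emergent (venous-side) concentration.
    ``drains_to`` names the tissue that receives this tissue's venous outflow
    (portal drainage, e.g. spleen/gut -> liver); ``None`` drains to the venous
    pool.  ``sub_compartments`` are (name, volume, k_in, k_out) tuples for
    first-order deep compartments exchanging with this tissue (rates 1/time
    on the amount basis).
    """

    name: str
    Q: float
    V: float
    Kp: float
    clearance: float = 0.0
    drains_to: Optional[str] = None
    sub_compartments: tuple = ()

    def __post_init__(self) -> None:
        if self.Q <= 0 or self.V <= 0 or self.Kp <= 0:
            raise ValueError(f"tissue {self.name!r}: Q, V, Kp must be positive")
        if self.clearance < 0:
            raise ValueError(f"tissue {self.name!r}: clearance must be >= 0")
        for sub in self.sub_compartments:
            _, v, kin, kout = sub
            if v <= 0 or kin < 0 or kout < 0:
                raise ValueError(
                    f"tissue {self.name!r}: invalid sub-compartment {sub!r}"
                )


@dataclass(frozen=True)
class PhysiologicalParameters:
    """A per-tissue parameter table plus the blood-pool geometry.

    ``cardiac_output`` must equal the total venous return (the sum of flows of
    tissues draining directly to the venous pool plus portal flows routed via
    their receiving tissue) within ``flow_rtol``.
    """

    tissues: tuple
    arterial_volume: float
    venous_volume: float
    cardiac_output: float
    lung: TissueParameters
    flow_rtol: float = 1e-6

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissues", tuple(self.tissues))
        if self.arterial_volume <= 0 or self.venous_volume <= 0:
            raise ValueError("blood volumes must be positive")
        if self.cardiac_output <= 0:
            raise ValueError("cardiac output must be positive")
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tissue names")
        total = sum(t.Q for t in self.tissues)
        if abs(total - self.cardiac_output) > self.flow_rtol * self.cardiac_output:
            raise ValueError(
                f"sum of tissue flows ({total:g}) does not match cardiac "
                f"output ({self.cardiac_output:g})"
            )


@dataclass(frozen=True)
class SimulationResult:
    """Times, the n-by-T trajectory matrix and the output-state AUC."""

    times: np.ndarray
    trajectories: np.ndarray
    auc_output: float

    def to_frame(self, state_names: Sequence[str]):
        import pandas as pd

        df = pd.DataFrame(self.trajectories.T, columns=list(state_names))
        df.insert(0, "time", self.times)
        return df


def build_rate_matrix(params: PhysiologicalParameters) -> "CompartmentalModel":
    """Assemble the micro-rate-constant matrix K of a perfusion-limited model.

    State order: arterial, venous, lung, then each tissue followed by its
    sub-compartments.  Returns a model with a unit bolus into arterial blood;
    callers re-dose via :func:`apply_bolus`.

    Raises
    ------
    TopologyError
        If a tissue drains to an unknown tissue (orphaned from the blood pool).
    """
    tissues = params.tissues
    names = ["arterial", "venous", params.lung.name]
    idx = {"arterial": 0, "venous": 1, params.lung.name: 2}
    vols = [params.arterial_volume, params.venous_volume, params.lung.V]
    for t in tissues:
        idx[t.name] = len(names)
        names.append(t.name)
        vols.append(t.V)
        for sub_name, sub_v, _, _ in t.sub_compartments:
            idx[sub_name] = len(names)
            names.append(sub_name)
            vols.append(sub_v)
    tissue_by_name = {t.name: t for t in tissues}
    for t in tissues:
        if t.drains_to is not None and t.drains_to not in tissue_by_name:
            raise TopologyError(
                f"tissue {t.name!r} drains to unknown tissue {t.drains_to!r}"
            )

    n = len(names)
    V = np.array(vols, dtype=float)
    # Work on the amount basis A (column j = losses/gains per unit amount in j),
    # then convert: K = diag(1/V) @ A @ diag(V).
    A = np.zeros((n, n))
    i_art, i_ven = 0, 1
    lung = params.lung
    i_lung = 2
    CO = params.cardiac_output

    def transfer(src: int, dst: int, flow_over_volume: float) -> None:
        A[dst, src] += flow_over_volume
        A[src, src] -= flow_over_volume

    # venous -> lung -> arterial carries the whole cardiac output
    transfer(i_ven, i_lung, CO / params.venous_volume)
    transfer(i_lung, i_art, CO / (lung.V * lung.Kp))

    for t in tissues:
        i_t = idx[t.name]
        # arterial supply
        transfer(i_art, i_t, t.Q / params.arterial_volume)
        # venous return: portal tissues hand their outflow to the receiving
        # tissue (liver); the receiver's own Q already includes that flow on
        # the arterial side only, so its venous outflow must carry the total.
        inflow_portal = sum(s.Q for s in tissues if s.drains_to == t.name)
        out_total = t.Q + inflow_portal
        dest = idx[t.drains_to] if t.drains_to is not None else i_ven
        transfer(i_t, dest, out_total / (t.V * t.Kp))
        if t.clearance > 0:
            A[i_t, i_t] -= t.clearance / (t.V * t.Kp)
        for sub_name, _, k_in, k_out in t.sub_compartments:
            i_s = idx[sub_name]
            transfer(i_t, i_s, k_in)
            transfer(i_s, i_t, k_out)

    K = (A * V[None, :]) / V[:, None]
    y0 = np.zeros(n)
    y0[i_art] = 1.0 / params.arterial_volume  # unit bolus
    return CompartmentalModel(
        state_names=tuple(names),
        K=K,
        y0=y0,
        output_state=i_art,
        volumes=V,
        dose_amount=1.0,
    )


def apply_bolus(model: CompartmentalModel, state: str, amount: float) -> CompartmentalModel:
    """Return a copy of ``model`` dosed with a bolus of ``amount`` into ``state``."""
    if model.volumes is None:
        raise ValueError("bolus dosing requires volumes")
    i = model.state_names.index(state)
    y0 = np.zeros(model.n)
    y0[i] = amount / model.volumes[i]
    return CompartmentalModel(
        state_names=model.state_names,
        K=model.K,
        y0=y0,
        output_state=model.output_state,
        volumes=model.volumes,
        dose_amount=amount,
        provenance=model.provenance,
    )


def simulate_matrix_exponential(
    model: CompartmentalModel, times: Sequence[float]
) -> SimulationResult:
    """Closed-form trajectories ``y(t_j) = expm(K t_j) @ y0``.

    ``times`` must be nonnegative and sorted ascending.  Uniformly spaced
    grids are propagated with a single per-step exponential.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a nonempty 1-D array")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")

    K, y0 = model.K, model.y0
    Y = np.empty((model.n, t.size))
    dt = np.diff(t)
    uniform = t.size > 2 and np.allclose(dt, dt[0], rtol=1e-12, atol=0)
    if uniform and t[0] == 0.0:
        P = expm(K * dt[0])
        y = y0.copy()
        Y[:, 0] = y
        for j in range(1, t.size):
            y = P @ y
            Y[:, j] = y
    else:
        for j, tj in enumerate(t):
            Y[:, j] = y0 if tj == 0.0 else expm(K * tj) @ y0
    if not np.all(np.isfinite(Y)):
        raise FloatingPointError("trajectory overflowed; system may be unstable")
    try:
        auc = auc_to_infinity(model, model.output_state)
    except InfiniteAUCError:
        auc = float("inf")
    return SimulationResult(times=t, trajectories=Y, auc_output=auc)


def auc_to_infinity(model: CompartmentalModel, state: Optional[int] = None) -> float:
    """Area under the concentration-time curve of ``state``, to infinity.

    For nonsingular, stable ``K`` this is the linear-solve result
    ``(-K^{-1} y0)[state]``.  A singular ``K`` triggers a quadrature fallback
    on the matrix-exponential solution out to a horizon where the remaining
    tail is below 1e-9 relative; a trajectory that does not decay raises
    :class:`InfiniteAUCError`.
    """
    if state is None:
        state = model.output_state
    K, y0 = model.K, model.y0
    n = model.n
    # Stability gate: AUC converges iff the reachable dynamics decay.
    eigs = np.linalg.eigvals(K)
    scale = max(1.0, np.abs(K).max())
    if np.any(eigs.real > 1e-12 * scale):
        raise InfiniteAUCError("K has an eigenvalue with positive real part")
    near_singular = np.any(np.abs(eigs) <= 1e-12 * scale)
    if not near_singular:
        x = np.linalg.solve(K, -y0)
        return float(x[state])
    # Singular K: decaying modes may still make the observed AUC finite.
    # Integrate numerically and demand the tail vanish.
    t_end = 1.0 / max(1e-12, np.abs(eigs.real).max())
    total = 0.0
    y_start = y0
    t0 = 0.0
    for _ in range(60):
        grid = np.linspace(t0, t0 + t_end, 2001)
        sub = np.empty((n, grid.size))
        P = expm(K * (grid[1] - grid[0]))
        y = y_start.copy()
        sub[:, 0] = y
        for j in range(1, grid.size):
            y = P @ y
            sub[:, j] = y
        total += np.trapezoid(sub[state], grid)
        if sub[state, 0] != 0 and abs(sub[state, -1]) > 0.9 * abs(sub[state, 0]):
            raise InfiniteAUCError(
                "trajectory does not decay at the observed state; AUC is infinite"
            )
        y_start = sub[:, -1]
        t0 += t_end
        t_end *= 2.0
        # Remaining tail is negligible once the current level times the next
        # horizon falls below 1e-9 of what has been accumulated.
        if abs(y_start[state]) * t_end < 1e-9 * max(abs(total), 1e-300):
            return float(total)
    raise InfiniteAUCError(
        "trajectory does not decay at the observed state; AUC is infinite"
    )
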
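"""Bundled models: the 17-state fentanyl-topology case study and synthetic
generators, so every algorithm is testable without any download.

The fentanyl model reproduces the published 17-state topology (arterial and
venous blood, lung in series, perfused tissues, liver/spleen/gut with deep
sub-compartments, hepatic elimination, portal drainage of spleen and gut via
the liver).  Its numeric physiological values are SYNTHETIC placeholders —
plausible adult-human blood flows, volumes and lipophilic-drug partition
coefficients — because the reference per-tissue table was not available for
transcription.  The model carries ``provenance = "synthetic_placeholder"``;
results computed from it exercise the topology and the algorithms but are not
the published fentanyl numbers.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .linear_model import (
    CompartmentalModel,
    PhysiologicalParameters,
    TissueParameters,
    apply_bolus,
    build_rate_matrix,
)
from .lumping import LumpingPartition

__all__ = [
    "fentanyl_pbpk",
    "exactly_lumpable_system",
    "random_compartmental_system",
    "physiology_from_dict",
    "load_model",
]


def physiology_from_dict(d: dict) -> PhysiologicalParameters:
    """Build a physiological parameter table from the JSON schema."""
    lung = d["lung"]
    tissues = []
    for rec in d["physiology"]:
        subs = tuple(
            (s["name"], float(s["V"]), float(s["k_in"]), float(s["k_out"]))
            for s in rec.get("sub_compartments", ())
        )
        tissues.append(
            TissueParameters(
                name=rec["name"],
                Q=float(rec["Q"]),
                V=float(rec["V"]),
                Kp=float(rec["Kp"]),
                clearance=float(rec.get("clearance", 0.0)),
                drains_to=rec.get("drains_to"),
                sub_compartments=subs,
            )
        )
    return PhysiologicalParameters(
        tissues=tuple(tissues),
        arterial_volume=float(d["arterial_volume"]),
        venous_volume=float(d["venous_volume"]),
        cardiac_output=float(d["cardiac_output"]),
        lung=TissueParameters(
            name=lung.get("name", "lung"),
            Q=float(d["cardiac_output"]),
            V=float(lung["V"]),
            Kp=float(lung["Kp"]),
        ),
    )


def load_model(source) -> CompartmentalModel:
    """Load a model from a JSON file path, file object or dict.

    Accepts either the explicit rate-matrix schema (``states``,
    ``rate_matrix``, ...) or the physiological schema (``physiology``,
    ``cardiac_output``, ``dose``, ...).
    """
    if isinstance(source, dict):
        d = source
    elif hasattr(source, "read"):
        d = json.load(source)
    else:
        with open(source) as fh:
            d = json.load(fh)
    if "rate_matrix" in d:
        return CompartmentalModel.from_dict(d)
    if "physiology" not in d:
        raise ValueError("model JSON needs 'rate_matrix' or 'physiology'")
    params = physiology_from_dict(d)
    model = build_rate_matrix(params)
    dose = d.get("dose", {"state": "arterial", "amount": 1.0})
    model = apply_bolus(model, dose["state"], float(dose["amount"]))
    return CompartmentalModel(
        state_names=model.state_names,
        K=model.K,
        y0=model.y0,
        output_state=model.state_names.index(d.get("output_state", "arterial")),
        volumes=model.volumes,
        dose_amount=model.dose_amount,
        provenance=d.get("provenance", "user"),
    )


def fentanyl_pbpk() -> CompartmentalModel:
    """The bundled 17-state fentanyl-topology model, 750 ug arterial bolus.

    Topology: arterial + venous blood, lung in series carrying the cardiac
    output, seven directly-perfused tissues, liver with one deep compartment,
    spleen with one deep compartment, gut with two deep compartments; spleen
    and gut drain portally through the liver; the liver column is the only
    site of elimination; output state is arterial blood.

    The numeric parameters are synthetic placeholders (see module docstring);
    check ``model.provenance`` before treating derived numbers as published
    values.
    """
    ref = resources.files("autolump").joinpath("data/fentanyl_synthetic.json")
    with ref.open() as fh:
        return load_model(json.load(fh))


def exactly_lumpable_system(block_sizes, seed: int = 0):
    """A blood+lung+tissues system with identical tissue copies per block.

    Each entry of ``block_sizes`` produces that many tissues sharing one
    random (Q, V, Kp) draw; the first group also shares a clearance term so
    the system eliminates.  Merging exactly the copies in each group leaves
    the output trajectory unchanged, so the returned true partition has
    output ARD% at floating-point level.

    Returns ``(model, true_partition)``; the output (arterial) state is
    constrained in the partition.  ``block_sizes = [1]`` yields the identity
    partition.
    """
    block_sizes = list(block_sizes)
    if not block_sizes or any(c < 1 for c in block_sizes):
        raise ValueError("block sizes must be positive")
    rng = np.random.default_rng(seed)
    tissues = []
    for g, count in enumerate(block_sizes):
        Q = float(10 ** rng.uniform(-1, 0))
        V = float(10 ** rng.uniform(-0.7, 0.5))
        Kp = float(10 ** rng.uniform(-0.3, 0.7))
        cl = float(10 ** rng.uniform(-1.5, -0.5)) if g == 0 else 0.0
        for c in range(count):
            tissues.append(
                TissueParameters(
                    name=f"tissue{g}_{c}", Q=Q, V=V, Kp=Kp, clearance=cl
                )
            )
    co = sum(t.Q for t in tissues)
    params = PhysiologicalParameters(
        tissues=tuple(tissues),
        arterial_volume=1.5,
        venous_volume=3.0,
        cardiac_output=co,
        lung=TissueParameters(name="lung", Q=co, V=0.5, Kp=1.2),
    )
    model = build_rate_matrix(params)
    model = apply_bolus(model, "arterial", 100.0)
    # true partition: arterial, venous, lung singletons; one block per group
    labels = [0, 1, 2]
    nxt = 3
    for g, count in enumerate(block_sizes):
        labels.extend([nxt] * count)
        nxt += 1
    truth = LumpingPartition(tuple(labels), constrained=frozenset({0}))
    return model, truth


def random_compartmental_system(n: int, seed: int = 0) -> CompartmentalModel:
    """A random connected, mass-balanced, eliminating n-state system.

    Built on the amount basis: a directed cycle through all states plus ~n
    extra random edges, log-uniform rates, first-order elimination from one
    state, diagonal set to minus the column sums.  Gershgorin then puts every
    eigenvalue in the closed left half plane, and elimination plus strong
    connectivity make the system strictly stable (finite AUC).  Deterministic
    under ``seed``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n))
    perm = rng.permutation(n)
    for a, b in zip(perm, np.roll(perm, -1)):
        A[b, a] += 10 ** rng.uniform(-2, 0)
    for _ in range(n):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            A[i, j] += 10 ** rng.uniform(-2, 0)
    elim_state = int(rng.integers(0, n))
    elim = 10 ** rng.uniform(-2, -0.5)
    np.fill_diagonal(A, 0.0)
    diag = -A.sum(axis=0)
    diag[elim_state] -= elim
    np.fill_diagonal(A, diag)
    V = 10 ** rng.uniform(-1, 0.7, size=n)
    K = (A * V[None, :]) / V[:, None]
    y0 = np.zeros(n)
    y0[0] = 1.0 / V[0]
    return CompartmentalModel(
        state_names=tuple(f"s{i}" for i in range(n)),
        K=K,
        y0=y0,
        output_state=0,
        volumes=V,
        dose_amount=1.0,
        provenance=f"random(n={n}, seed={seed})",
    )
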
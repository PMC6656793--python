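import numpy as np
import pytest

import autolump as al


@pytest.fixture(scope="session")
def fentanyl():
    return al.fentanyl_pbpk()


@pytest.fixture(scope="session")
def lumpable_32():
    """Exactly-lumpable system with tissue groups of sizes 3 and 2 (n=8)."""
    return al.exactly_lumpable_system([3, 2], seed=7)


@pytest.fixture(scope="session")
def lumpable_412():
    """Exactly-lumpable system with tissue groups of sizes 4, 1, 2 (n=10)."""
    return al.exactly_lumpable_system([4, 1, 2], seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def quadrature_auc(model, state=None, pts_fast=200_001, pts_slow=400_001):
    """Trapezoid AUC oracle: a fine uniform grid over the fast transient and
    a second uniform grid out to many time constants of the slowest mode."""
    from scipy.linalg import expm

    if state is None:
        state = model.output_state
    rates = np.abs(np.linalg.eigvals(model.K).real)
    fastest, slowest = rates.max(), rates[rates > 1e-300].min()
    t_break = 20.0 / fastest
    t_end = max(t_break * 2, 80.0 / slowest)

    def segment(t0, t1, npts, y_start):
        grid = np.linspace(t0, t1, npts)
        P = expm(model.K * (grid[1] - grid[0]))
        vals = np.empty(npts)
        y = y_start.copy()
        vals[0] = y[state]
        for j in range(1, npts):
            y = P @ y
            vals[j] = y[state]
        return np.trapezoid(vals, grid), y

    total, y = segment(0.0, t_break, pts_fast, model.y0)
    t0 = t_break
    while t0 < t_end:  # geometric segments keep relative resolution constant
        t1 = min(t0 * 5.0, t_end)
        part, y = segment(t0, t1, pts_slow, y)
        total += part
        t0 = t1
    return total


def random_partition_brute(n, blocks, constrained=()):
    """Oracle: all canonical partitions by brute force over labelings."""
    constrained = frozenset(constrained)
    free = [i for i in range(n) if i not in constrained]
    k = blocks - len(constrained)
    seen = set()
    out = []
    if k < 1 or k > len(free):
        return out
    import itertools

    for labels in itertools.product(range(k), repeat=len(free)):
        if len(set(labels)) != k:
            continue
        full = [0] * n
        for j, i in enumerate(free):
            full[i] = labels[j]
        for off, i in enumerate(sorted(constrained)):
            full[i] = k + off
        p = al.LumpingPartition(tuple(full), constrained)
        if p.block_of not in seen:
            seen.add(p.block_of)
            out.append(p)
    return out
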
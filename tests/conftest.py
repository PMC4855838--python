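"""Shared fixtures: random nonnegative flux problems and the recovery study.

Random problems use entrywise nonnegative mode matrices and flux data —
the regime direction filtering produces in practice, and the regime in
which the gain-sum search bound is provably valid.
"""

from __future__ import annotations

import numpy as np
import pytest

from pema import EMSet, FluxData, PEMAConfig, build_problem
from pema.synthetic import recovery_study


def make_random_problem(rng, n_mes=5, m=8, n_d=4, density=0.7, scaling="none"):
    """A random nonnegative decomposition problem with ids attached."""
    E = rng.uniform(0.05, 1.0, size=(n_mes, m)) * (rng.random((n_mes, m)) < density)
    for j in range(m):  # no all-zero columns
        if not E[:, j].any():
            E[rng.integers(n_mes), j] = rng.uniform(0.05, 1.0)
    V = rng.uniform(0.05, 1.0, size=(n_mes, n_d))
    ems = EMSet(E, tuple(f"r{i}" for i in range(n_mes)), tuple(f"m{j:02d}" for j in range(m)))
    flux = FluxData(V, tuple(f"r{i}" for i in range(n_mes)), tuple(f"x{k}" for k in range(n_d)))
    config = PEMAConfig(n_fac=1, scaling_mode=scaling)
    return build_problem(flux, ems, config), ems, flux


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def greedy_trap():
    from pema.synthetic import toy_fixtures

    return toy_fixtures("greedy_trap")


@pytest.fixture(scope="session")
def greedy_trap_problem(greedy_trap):
    _, ems, flux, _ = greedy_trap
    return build_problem(flux, ems, PEMAConfig(n_fac=2, scaling_mode="none"))


@pytest.fixture(scope="session")
def recovery():
    """The 20-seed, three-noise-level recovery protocol (computed once)."""
    return recovery_study(n_seeds=20, noise_pcts=(0.0, 2.0, 10.0))
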
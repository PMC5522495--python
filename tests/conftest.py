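"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def mfpt_monte_carlo(
    v: float,
    D: float,
    L: float,
    n_walkers: int = 20_000,
    dt: float | None = None,
    seed: int = 0,
) -> float:
    """Monte-Carlo first-passage oracle: Euler-Maruyama drift-diffusion on
    [0, L], reflecting at 0, absorbing at L.

    Uses a Brownian-bridge crossing probability between steps so the
    absorbing boundary is not under-sampled at finite dt. Independent of
    the closed-form implementation it checks.
    """
    rng = np.random.default_rng(seed)
    if dt is None:
        dt = 1e-3 * L**2 / D
    sigma = np.sqrt(2 * D * dt)
    x = np.zeros(n_walkers)
    t = np.zeros(n_walkers)
    alive = np.ones(n_walkers, dtype=bool)
    fpt = np.empty(n_walkers)
    max_steps = int(5e6)
    for _ in range(max_steps):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        x0 = x[idx]
        x1 = x0 + v * dt + sigma * rng.standard_normal(idx.size)
        x1 = np.abs(x1)  # reflect at 0
        t[idx] += dt
        crossed = x1 >= L
        # bridge: crossing probability for paths ending below L
        below = ~crossed
        p_cross = np.exp(-np.maximum(L - x0[below], 0) * (L - x1[below]) / (D * dt))
        bridge = np.zeros(idx.size, dtype=bool)
        bridge[below] = rng.random(below.sum()) < p_cross
        done = crossed | bridge
        fpt[idx[done]] = t[idx[done]]
        alive[idx[done]] = False
        x[idx[~done]] = x1[~done]
    else:  # pragma: no cover - safety net
        raise RuntimeError("walkers did not all absorb")
    return float(fpt.mean())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
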
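"""Shared fixtures and the independent quadrature oracle.

The oracle solves the renewal (integral) equations for the PBD probabilities
directly by product integration of the convolution with the exponential
kernel, stepping forward in time with a fixed-point correction per step and
Richardson extrapolation (h and h/2) for accuracy.  It never touches the ODE
reduction used by the package, so it is an independent check of it.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from pbdrates.params import PBDParams, RATE_CURVE_DEFAULTS, TREE_SIM_DEFAULTS, SimulationConfig
from pbdrates.simulate import simulate_pbd_batch


@pytest.fixture(scope="session")
def rate_defaults() -> PBDParams:
    return RATE_CURVE_DEFAULTS


@pytest.fixture(scope="session")
def sim_defaults() -> PBDParams:
    return TREE_SIM_DEFAULTS


@pytest.fixture(scope="session")
def pbd_batch_small():
    """60 survival-conditioned PBD replicates at the tree-simulation defaults."""
    cfg = SimulationConfig(T=15.0, seed=2024)
    return simulate_pbd_batch(TREE_SIM_DEFAULTS, cfg, 60)


# ---------------------------------------------------------------------------
# Quadrature oracle
# ---------------------------------------------------------------------------


def _kernel_weights(rate: float, h: float) -> tuple[float, float]:
    """Exact integrals of e^{-rate (h - s)} * {1, s/h} over [0, h]."""
    x = rate * h
    if x < 1e-6:
        A = h * (1.0 - x / 2.0 + x * x / 6.0)
        B = (h / 2.0) * (1.0 - x / 3.0)
    else:
        A = -math.expm1(-x) / rate
        B = (h + math.expm1(-x) / rate) / (rate * h)
    return A, B


def _volterra(first_term, g_of, rate: float, grid: np.ndarray) -> np.ndarray:
    """Solve y(t) = F(t) + int_0^t e^{-rate (t-v)} g(y(v), v) dv on a uniform grid."""
    n = grid.size
    h = grid[1] - grid[0]
    A, B = _kernel_weights(rate, h)
    decay = math.exp(-rate * h)
    y = np.empty(n)
    y[0] = first_term(0.0)
    I = 0.0
    g_prev = g_of(y[0], 0)
    for i in range(1, n):
        yi = y[i - 1]  # predictor
        for _ in range(4):
            gi = g_of(yi, i)
            I_new = decay * I + g_prev * (A - B) + gi * B
            yi = first_term(grid[i]) + I_new
        y[i] = yi
        I = decay * I + g_prev * (A - B) + g_of(yi, i) * B
        g_prev = g_of(y[i], i)
    return y


def _solve_all(params: PBDParams, grid: np.ndarray):
    l1, l2, l3 = params.lambda1, params.lambda2, params.lambda3
    m1, m2 = params.mu1, params.mu2
    Lam, The = params.Lambda, params.Theta

    def F_ei(t):
        return m2 * t if Lam == 0 else m2 * -math.expm1(-Lam * t) / Lam

    pEI = _volterra(F_ei, lambda y, i: l3 * y * y, Lam, grid)

    def F_q(t):
        return F_ei(t) + math.exp(-Lam * t)

    q = _volterra(F_q, lambda y, i: l3 * y * y, Lam, grid)

    def F_eg(t):
        return m1 * t if The == 0 else m1 * -math.expm1(-The * t) / The

    pEG = _volterra(F_eg, lambda y, i: l1 * pEI[i] * y, The, grid)
    pSG = _volterra(
        lambda t: 0.0,
        lambda y, i: l1 * ((1.0 - q[i]) + q[i] * y),
        The,
        grid,
    )
    return pEI, q, pEG, pSG


def quadrature_oracle(params: PBDParams, grid: np.ndarray):
    """Quadrature solution of the four probability curves on ``grid``.

    ``grid`` must be uniform starting at 0; internally solved at 2x and 4x
    refinement and Richardson-extrapolated to the requested points.
    """
    grid = np.asarray(grid, dtype=float)
    steps = np.diff(grid)
    assert grid[0] == 0.0 and np.allclose(steps, steps[0])
    fine = np.linspace(0.0, grid[-1], (grid.size - 1) * 2 + 1)
    finer = np.linspace(0.0, grid[-1], (grid.size - 1) * 4 + 1)
    sol_h = _solve_all(params, fine)
    sol_h2 = _solve_all(params, finer)
    out = []
    for yh, yh2 in zip(sol_h, sol_h2):
        extrap = (4.0 * yh2[::2] - yh) / 3.0
        out.append(extrap[::2])
    return tuple(out)  # pEI, q, pEG, pSG at the requested grid points
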
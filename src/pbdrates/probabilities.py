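"""Speciation / extinction probabilities under the protracted birth-death model.

For a lineage alive at a time-horizon ``t`` before an observation point, the
model yields four first-event probabilities:

- ``pEI(t)`` / ``pCI(t)``: an *incipient* lineage (with all its incipient
  descendants) goes extinct / completes speciation within ``t``;
- ``pEG(t)`` / ``pSG(t)``: a *good* lineage (with its potential descendants)
  goes extinct / speciates within ``t``.

Each probability satisfies a renewal-type integral equation over the time of
the lineage's first event.  Differentiating those equations collapses them to
an ODE system, which is what this module integrates:

.. math::

    p_{EI}' &= \\mu_2 - \\Lambda p_{EI} + \\lambda_3 p_{EI}^2, \\quad p_{EI}(0) = 0 \\\\
    q'      &= \\mu_2 - \\Lambda q + \\lambda_3 q^2, \\quad q(0) = 1
             \\quad (q = 1 - p_{CI}) \\\\
    p_{EG}' &= \\mu_1 - \\Theta p_{EG} + \\lambda_1 p_{EI} p_{EG}, \\quad p_{EG}(0) = 0 \\\\
    p_{SG}' &= \\lambda_1 (1 - q) - \\Theta p_{SG} + \\lambda_1 q\\, p_{SG},
               \\quad p_{SG}(0) = 0

with ``Lambda = lambda2 + lambda3 + mu2`` and ``Theta = lambda1 + mu1``.
The incipient equations are the same Riccati flow started from the two ends
of the unit interval; both converge to the non-completion probability
``pi = (Lambda - k) / (2 lambda3)`` (the stable root).  The system is solved
jointly with tight tolerances because the equivalent-rate formulas later
divide by ``pNG -> 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .params import PBDParams

#: Solver tolerances; tight because downstream quantities divide by pNG -> 0.
RTOL = 1e-10
ATOL = 1e-12


def _rhs(params: PBDParams):
    l1, l3 = params.lambda1, params.lambda3
    m1, m2 = params.mu1, params.mu2
    Lam, The = params.Lambda, params.Theta

    def rhs(t, y):
        pEI, q, pEG, pSG = y
        return (
            m2 - Lam * pEI + l3 * pEI * pEI,
            m2 - Lam * q + l3 * q * q,
            m1 - The * pEG + l1 * pEI * pEG,
            l1 * (1.0 - q) - The * pSG + l1 * q * pSG,
        )

    return rhs


@dataclass
class ProbabilityCurves:
    """The four PBD probability curves on a shared horizon grid.

    ``pNG = 1 - pSG - pEG`` and ``pNI = 1 - pEI - pCI`` are the "no event"
    complements.  ``d_*`` hold the exact ODE right-hand sides evaluated at the
    grid points (no finite differencing), which downstream rate formulas use
    as the curve derivatives.
    """

    t: np.ndarray
    pEI: np.ndarray
    pCI: np.ndarray
    pEG: np.ndarray
    pSG: np.ndarray
    d_pEI: np.ndarray
    d_pCI: np.ndarray
    d_pEG: np.ndarray
    d_pSG: np.ndarray
    params: PBDParams

    @property
    def pNG(self) -> np.ndarray:
        return 1.0 - self.pSG - self.pEG

    @property
    def pNI(self) -> np.ndarray:
        return 1.0 - self.pEI - self.pCI

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "pEI": self.pEI,
                "pCI": self.pCI,
                "pEG": self.pEG,
                "pSG": self.pSG,
                "pNG": self.pNG,
                "pNI": self.pNI,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("grid must be a 1-D array of horizon times")
    if grid[0] != 0.0:
        raise ValueError("grid must start at 0")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    return grid


def solve_probability_curves(params: PBDParams, grid) -> ProbabilityCurves:
    """Solve the coupled probability system on a horizon grid starting at 0."""
    grid = _check_grid(grid)
    rhs = _rhs(params)
    y0 = (0.0, 1.0, 0.0, 0.0)
    if grid[-1] == 0.0:
        ys = np.array([y0], dtype=float).T
    else:
        sol = solve_ivp(
            rhs,
            (0.0, grid[-1]),
            y0,
            method="LSODA",
            t_eval=grid,
            rtol=RTOL,
            atol=ATOL,
        )
        if not sol.success:  # pragma: no cover - LSODA is robust here
            raise RuntimeError(f"probability ODE solve failed: {sol.message}")
        ys = sol.y
    pEI, q, pEG, pSG = np.clip(ys, 0.0, 1.0)
    d = np.array([rhs(ti, (pEI[i], q[i], pEG[i], pSG[i])) for i, ti in enumerate(grid)])
    return ProbabilityCurves(
        t=grid,
        pEI=pEI,
        pCI=1.0 - q,
        pEG=pEG,
        pSG=pSG,
        d_pEI=d[:, 0],
        d_pCI=-d[:, 1],
        d_pEG=d[:, 2],
        d_pSG=d[:, 3],
        params=params,
    )


# ---------------------------------------------------------------------------
# Individual curve solvers
# ---------------------------------------------------------------------------


def p_extinct_incipient(params: PBDParams, grid) -> np.ndarray:
    """Extinction probability of an incipient lineage and its descendants.

    Monotone non-decreasing from 0, bounded by the stable Riccati root
    ``(Lambda - k) / (2 lambda3)`` (the non-completion probability ``pi``).
    ``lambda3 = 0`` is the linear limit and needs no special casing.
    """
    return solve_probability_curves(params, grid).pEI


def p_noncompletion_incipient(params: PBDParams, grid) -> np.ndarray:
    """``q(t) = 1 - pCI(t)``: non-completion probability, non-increasing from 1."""
    return 1.0 - solve_probability_curves(params, grid).pCI


def _interp_ode(params: PBDParams, grid, curve, which: str) -> np.ndarray:
    """Solve the good-lineage ODE driven by a pre-computed incipient curve."""
    grid = _check_grid(grid)
    curve = np.asarray(curve, dtype=float)
    if curve.shape != grid.shape:
        raise ValueError("curve must be evaluated on the same grid")
    if grid.size < 2:
        return np.zeros_like(grid)
    f = PchipInterpolator(grid, curve)
    l1, m1, The = params.lambda1, params.mu1, params.Theta

    if which == "pEG":

        def rhs(t, y):
            return (m1 - The * y[0] + l1 * f(t) * y[0],)

    else:  # pSG, driven by pCI

        def rhs(t, y):
            c = f(t)
            return (l1 * c - The * y[0] + l1 * (1.0 - c) * y[0],)

    sol = solve_ivp(rhs, (0.0, grid[-1]), (0.0,), method="LSODA", t_eval=grid, rtol=RTOL, atol=ATOL)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"probability ODE solve failed: {sol.message}")
    return np.clip(sol.y[0], 0.0, 1.0)


def p_extinct_good(params: PBDParams, grid, pEI_curve=None) -> np.ndarray:
    """Extinction probability of a good lineage and its potential descendants.

    If ``pEI_curve`` (on the same grid) is given it drives the ODE through a
    monotone interpolant; otherwise the coupled system is solved directly.
    """
    if pEI_curve is None:
        return solve_probability_curves(params, grid).pEG
    return _interp_ode(params, grid, pEI_curve, "pEG")


def p_speciate_good(params: PBDParams, grid, pCI_curve=None) -> np.ndarray:
    """Speciation probability of a good lineage; initial slope is exactly 0
    (speciation needs an initiation followed by a completion)."""
    if pCI_curve is None:
        return solve_probability_curves(params, grid).pSG
    return _interp_ode(params, grid, pCI_curve, "pSG")


def closed_form_pEI(params: PBDParams, t):
    """Closed-form solution of the incipient extinction Riccati flow.

    With roots ``x± = (Lambda ± k) / (2 lambda3)`` of
    ``mu2 - Lambda x + lambda3 x**2`` the solution through ``pEI(0) = 0`` is

    .. math:: p_{EI}(t) = \\frac{x_- (1 - e^{-kt})}{1 - (x_-/x_+) e^{-kt}}

    pinned by the boundary condition at 0 and approaching the stable root
    ``x_-`` as ``t -> infinity``.  For the critical case ``k = 0`` (or
    ``lambda3 = 0``) the ODE solver is used instead.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    tt = np.atleast_1d(t)
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    if params.lambda3 <= 0 or params.k <= 0:
        order = np.argsort(tt)
        grid = np.unique(np.concatenate([[0.0], tt[order]]))
        vals = p_extinct_incipient(params, grid)
        out = np.interp(tt, grid, vals)
        return float(out[0]) if scalar else out
    lam3, Lam, k = params.lambda3, params.Lambda, params.k
    x_minus = (Lam - k) / (2.0 * lam3)
    x_plus = (Lam + k) / (2.0 * lam3)
    e = np.exp(-k * tt)
    out = x_minus * (1.0 - e) / (1.0 - (x_minus / x_plus) * e)
    return float(out[0]) if scalar else out
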
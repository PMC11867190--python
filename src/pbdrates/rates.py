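"""Equivalent birth-death rates of a protracted speciation process.

A standard BD process whose speciation/extinction probabilities match those
of a PBD process must have time-dependent rates.  Writing the horizon as
``h = T - t`` (time left until the present), the matching rates solve the
linear system implied by the good-lineage probability dynamics and come out
as the symmetric pair

.. math::

    \\hat\\lambda(t) &= \\frac{(1 - p_{EG}(h))\\, p_{SG}'(h)
                               + p_{SG}(h)\\, p_{EG}'(h)}{p_{NG}(h)} \\\\
    \\hat\\mu(t)     &= \\frac{(1 - p_{SG}(h))\\, p_{EG}'(h)
                               + p_{EG}(h)\\, p_{SG}'(h)}{p_{NG}(h)}

which satisfies ``lam_hat + mu_hat = (pSG' + pEG') / pNG``.  At the present
(``h = 0``) the birth rate is exactly 0 — speciation needs an initiation
*and* a completion, so its probability is ``o(dt)`` — while the death rate
equals ``mu1``.  Deep in the past both converge to the *equivalent constant
rates*

.. math:: \\tilde\\lambda = (1 - \\pi)\\,\\lambda_1, \\qquad \\tilde\\mu = \\mu_1

where ``pi`` is the probability that an incipient lineage never completes
speciation.  Far from the present the macroevolutionary death rate is just
the good-lineage extinction rate, and the birth rate is the initiation rate
discounted by the chance that the initiated lineage fails to ever complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import PBDParams
from .probabilities import solve_probability_curves

#: Below this pNG the rate formulas are 0/0; the analytic limit (the
#: equivalent constant rates) is substituted and flagged.
PNG_GUARD = 1e-10


@dataclass(frozen=True)
class EquivalentConstantRates:
    """Asymptotic (deep-past) equivalent BD rates and the non-completion
    probability ``pi``."""

    lambda_tilde: float
    mu_tilde: float
    pi: float

    def as_dict(self) -> dict[str, float]:
        return {
            "lambda_tilde": self.lambda_tilde,
            "mu_tilde": self.mu_tilde,
            "pi": self.pi,
        }


def equivalent_constant_rates(params: PBDParams) -> EquivalentConstantRates:
    """Constant equivalent rates: ``lambda_tilde = (1 - pi) * lambda1``,
    ``mu_tilde = mu1``.

    ``pi`` is the stable root of the incipient Riccati flow; the limit
    ``pi = mu2 / (lambda2 + mu2)`` applies when ``lambda3 = 0``, and ``pi = 0``
    by convention when all incipient rates vanish.
    """
    pi = params.pi_nc
    return EquivalentConstantRates(
        lambda_tilde=(1.0 - pi) * params.lambda1,
        mu_tilde=params.mu1,
        pi=pi,
    )


@dataclass
class RateTrajectory:
    """Equivalent time-dependent rates on a process-time grid.

    ``t`` runs forward from 0 (origin) to ``T`` (the present), matching the
    convention that the rate decline sits at the right edge of the axis.
    ``fallback`` marks grid points where ``pNG`` underflowed the guard and
    the asymptotic constant rates were substituted.
    """

    t: np.ndarray
    lambda_hat: np.ndarray
    mu_hat: np.ndarray
    fallback: np.ndarray
    T: float
    params: PBDParams
    constant: EquivalentConstantRates

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "lambda_hat": self.lambda_hat,
                "mu_hat": self.mu_hat,
                "fallback_flag": self.fallback.astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _rates_at_horizons(params: PBDParams, horizons: np.ndarray):
    """Evaluate (lam_hat, mu_hat, fallback) at the given horizon times >= 0."""
    horizons = np.asarray(horizons, dtype=float)
    order = np.argsort(horizons)
    grid = np.unique(np.concatenate([[0.0], horizons[order]]))
    curves = solve_probability_curves(params, grid)
    idx = np.searchsorted(grid, horizons)
    pSG, pEG = curves.pSG[idx], curves.pEG[idx]
    dSG, dEG = curves.d_pSG[idx], curves.d_pEG[idx]
    pNG = 1.0 - pSG - pEG
    const = equivalent_constant_rates(params)
    fallback = pNG < PNG_GUARD
    safe = np.where(fallback, 1.0, pNG)
    lam = ((1.0 - pEG) * dSG + pSG * dEG) / safe
    mu = ((1.0 - pSG) * dEG + pEG * dSG) / safe
    lam = np.where(fallback, const.lambda_tilde, np.maximum(lam, 0.0))
    mu = np.where(fallback, const.mu_tilde, np.maximum(mu, 0.0))
    return lam, mu, fallback, const


def equivalent_rate_trajectory(params: PBDParams, T: float, n_grid: int = 200) -> RateTrajectory:
    """Equivalent rates over process time ``t in [0, T]`` on ``n_grid`` points.

    The probability-curve derivatives are the exact ODE right-hand sides, so
    no finite differencing enters.  Where ``pNG(h)`` underflows the guard
    (very deep past), the analytic asymptote (the constant equivalent rates)
    is substituted and flagged.
    """
    if T <= 0:
        raise ValueError(f"T must be > 0, got {T}")
    if n_grid < 2:
        raise ValueError(f"n_grid must be >= 2, got {n_grid}")
    t = np.linspace(0.0, T, n_grid)
    lam, mu, fallback, const = _rates_at_horizons(params, T - t)
    return RateTrajectory(
        t=t, lambda_hat=lam, mu_hat=mu, fallback=fallback, T=T, params=params, constant=const
    )


@dataclass
class PiecewiseConstantRates:
    """Piecewise-constant birth/death rates on ``[0, T]`` for simulation.

    ``edges`` has ``n + 1`` entries; interval ``i`` spans
    ``[edges[i], edges[i+1])`` with rates ``lam[i]``, ``mu[i]``.
    """

    edges: np.ndarray
    lam: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if len(self.edges) != len(self.lam) + 1 or len(self.lam) != len(self.mu):
            raise ValueError("edges must have one more entry than the rate arrays")
        if np.any(self.lam < 0) or np.any(self.mu < 0):
            raise ValueError("rates must be non-negative")

    @classmethod
    def constant(cls, lam: float, mu: float, T: float) -> "PiecewiseConstantRates":
        return cls(edges=np.array([0.0, T]), lam=np.array([lam]), mu=np.array([mu]))

    @property
    def T(self) -> float:
        return float(self.edges[-1])

    def interval_at(self, t: float) -> int:
        i = int(np.searchsorted(self.edges, t, side="right") - 1)
        return min(max(i, 0), len(self.lam) - 1)

    def lambda_at(self, t: float) -> float:
        return float(self.lam[self.interval_at(t)])

    def mu_at(self, t: float) -> float:
        return float(self.mu[self.interval_at(t)])


def discretize_trajectory(traj: RateTrajectory, n_intervals: int) -> PiecewiseConstantRates:
    """Discretise a rate trajectory into piecewise-constant rates.

    Each interval takes the trajectory value at its midpoint, re-evaluated
    exactly (one extra ODE solve) rather than interpolated from the stored
    grid.
    """
    if n_intervals < 1:
        raise ValueError(f"n_intervals must be >= 1, got {n_intervals}")
    edges = np.linspace(0.0, traj.T, n_intervals + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    lam, mu, _, _ = _rates_at_horizons(traj.params, traj.T - mids)
    return PiecewiseConstantRates(edges=edges, lam=lam, mu=mu)
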
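"""Which step of speciation limits the macroevolutionary birth rate?

The equivalent constant birth rate is ``lambda_tilde = (1 - pi) * lambda1``
with ``pi`` the non-completion probability of an incipient lineage.  The
relative influence of each PBD parameter is defined as its absolute partial
derivative of ``lambda_tilde`` divided by the sum of the absolute partials.
A step with a large relative influence is the *limiting* factor of the
macroevolutionary speciation rate in that region of parameter space.

Two model variants are supported:

- ``"full"``: all five rates vary independently; the good-lineage extinction
  rate ``mu1`` has exactly zero influence on ``lambda_tilde``.
- ``"simplified"``: good and incipient lineages share their rates
  (``lambda1 = lambda3 = lambda``, ``mu1 = mu2 = mu``); tied derivatives are
  summed, giving one influence per speciation step (initiation, completion,
  extinction).

Initiation and completion influence the birth rate positively, population
extinction negatively; relative influences use absolute values, with the
signs reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import PBDParams
from .rates import equivalent_constant_rates

FULL_PARAMS = ("lambda1", "lambda2", "lambda3", "mu1", "mu2")
SIMPLIFIED_FACTORS = ("initiation", "completion", "extinction")

#: A factor is dominant when its relative influence exceeds the runner-up by
#: at least this margin; otherwise all factors within the margin of the
#: maximum are reported as co-dominant.
DOMINANCE_MARGIN = 0.05


def _pi_gradient(params: PBDParams) -> dict[str, float]:
    """Analytic partials of the non-completion probability pi.

    For ``lambda3 > 0``, ``pi = (Lambda - k) / (2 lambda3)`` with
    ``k = sqrt(Lambda^2 - 4 mu2 lambda3)``; the ``lambda3 -> 0`` limits are
    the derivatives of ``pi = mu2 / (lambda2 + mu2)``.
    """
    l2, l3, m2 = params.lambda2, params.lambda3, params.mu2
    if l3 > 0:
        Lam, k = params.Lambda, params.k
        if k == 0:
            raise ValueError("pi is not differentiable at the critical point k = 0")
        d_l2 = (1.0 - Lam / k) / (2.0 * l3)
        d_m2 = (1.0 - (Lam - 2.0 * l3) / k) / (2.0 * l3)
        d_l3 = (1.0 - (Lam - 2.0 * m2) / k) / (2.0 * l3) - (Lam - k) / (2.0 * l3 * l3)
        return {"lambda2": d_l2, "lambda3": d_l3, "mu2": d_m2}
    denom = l2 + m2
    if denom == 0:
        return {"lambda2": 0.0, "lambda3": 0.0, "mu2": 0.0}
    return {
        "lambda2": -m2 / denom**2,
        "lambda3": -m2 * l2 / denom**3,
        "mu2": l2 / denom**2,
    }


def lambda_tilde_partials(params: PBDParams) -> dict[str, float]:
    """Signed partial derivatives of ``lambda_tilde`` w.r.t. the five rates."""
    pi = params.pi_nc
    dpi = _pi_gradient(params)
    return {
        "lambda1": 1.0 - pi,
        "lambda2": -params.lambda1 * dpi["lambda2"],
        "lambda3": -params.lambda1 * dpi["lambda3"],
        "mu1": 0.0,
        "mu2": -params.lambda1 * dpi["mu2"],
    }


@dataclass
class InfluenceProfile:
    """Partial derivatives of ``lambda_tilde`` and normalised influences.

    ``derivatives`` are signed; ``relative`` are the absolute derivatives
    normalised to sum to 1, keyed by parameter (full variant) or by
    speciation step (simplified variant).
    """

    variant: str
    lambda_tilde: float
    derivatives: dict[str, float]
    relative: dict[str, float]

    def dominant(self, margin: float = DOMINANCE_MARGIN) -> str:
        """Label of the dominant factor; co-dominant labels joined by '+'."""
        best = max(self.relative.values())
        labels = [k for k, v in self.relative.items() if best - v < margin]
        if len(labels) == 1:
            return labels[0]
        # keep the canonical ordering of the keys
        return "+".join(k for k in self.relative if k in labels)


def lambda_tilde_gradient(params: PBDParams, variant: str = "simplified") -> InfluenceProfile:
    """Influence profile of the PBD parameters on ``lambda_tilde``.

    In the simplified variant the tied pairs must be equal on input and their
    derivatives are summed (``d/d_lambda = d/d_lambda1 + d/d_lambda3``,
    ``d/d_mu = d/d_mu1 + d/d_mu2``).
    """
    if variant not in ("full", "simplified"):
        raise ValueError(f"unknown variant {variant!r}")
    partials = lambda_tilde_partials(params)
    lt = equivalent_constant_rates(params).lambda_tilde
    if variant == "full":
        derivs = dict(partials)
    else:
        if not math.isclose(params.lambda1, params.lambda3, rel_tol=0, abs_tol=1e-12):
            raise ValueError("simplified variant requires lambda1 == lambda3")
        if not math.isclose(params.mu1, params.mu2, rel_tol=0, abs_tol=1e-12):
            raise ValueError("simplified variant requires mu1 == mu2")
        derivs = {
            "initiation": partials["lambda1"] + partials["lambda3"],
            "completion": partials["lambda2"],
            "extinction": partials["mu1"] + partials["mu2"],
        }
    total = sum(abs(v) for v in derivs.values())
    if total < 1e-12:
        raise ValueError("all partial derivatives are zero; relative influence undefined")
    relative = {k: abs(v) / total for k, v in derivs.items()}
    return InfluenceProfile(variant=variant, lambda_tilde=lt, derivatives=derivs, relative=relative)


def _params_from_factors(initiation: float, completion: float, extinction: float) -> PBDParams:
    return PBDParams(
        lambda1=initiation, lambda2=completion, lambda3=initiation, mu1=extinction, mu2=extinction
    )


def limiting_factor_map(
    vary: tuple[str, str] = ("initiation", "completion"),
    grid_x=None,
    grid_y=None,
    fixed: float | dict[str, float] = 0.1,
    variant: str = "simplified",
    margin: float = DOMINANCE_MARGIN,
) -> pd.DataFrame:
    """Relative-influence map over a 2-D grid of speciation-step rates.

    Uses the simplified model (tied good/incipient rates); ``vary`` names the
    two axes among ``initiation``, ``completion``, ``extinction``; the third
    is held at ``fixed`` (a scalar, or a dict keyed by factor name).  The
    default grids are 101 log-spaced points in ``[1e-3, 2]``.

    Returns one row per cell with the three relative influences and a
    ``dominant`` label (co-dominant labels joined by '+'; cells whose
    gradient is undefined get the label ``"error"`` rather than aborting).
    """
    for name in vary:
        if name not in SIMPLIFIED_FACTORS:
            raise ValueError(f"unknown factor {name!r}; choose from {SIMPLIFIED_FACTORS}")
    if vary[0] == vary[1]:
        raise ValueError("the two varied factors must differ")
    if grid_x is None:
        grid_x = np.geomspace(1e-3, 2.0, 101)
    if grid_y is None:
        grid_y = np.geomspace(1e-3, 2.0, 101)
    grid_x = np.asarray(grid_x, dtype=float)
    grid_y = np.asarray(grid_y, dtype=float)
    if np.any(grid_x <= 0) or np.any(grid_y <= 0):
        raise ValueError("grids must be strictly positive")
    if isinstance(fixed, dict):
        fixed_vals = dict(fixed)
    else:
        fixed_vals = {f: float(fixed) for f in SIMPLIFIED_FACTORS if f not in vary}

    rows = []
    for x in grid_x:
        for y in grid_y:
            factors = dict(fixed_vals)
            factors[vary[0]] = float(x)
            factors[vary[1]] = float(y)
            row = {vary[0]: float(x), vary[1]: float(y)}
            try:
                prof = lambda_tilde_gradient(_params_from_factors(**factors), variant=variant)
                if variant == "full":
                    # group the five partials by speciation step; the grid
                    # ties the rates so this matches the simplified profile
                    groups = {
                        "initiation": abs(prof.derivatives["lambda1"])
                        + abs(prof.derivatives["lambda3"]),
                        "completion": abs(prof.derivatives["lambda2"]),
                        "extinction": abs(prof.derivatives["mu1"])
                        + abs(prof.derivatives["mu2"]),
                    }
                    total = sum(groups.values())
                    rel = {f: v / total for f, v in groups.items()}
                    prof = InfluenceProfile(
                        variant="full", lambda_tilde=prof.lambda_tilde,
                        derivatives=prof.derivatives, relative=rel,
                    )
                for f in SIMPLIFIED_FACTORS:
                    row[f"infl_{f}"] = prof.relative[f]
                row["dominant"] = prof.dominant(margin)
            except ValueError:
                for f in SIMPLIFIED_FACTORS:
                    row[f"infl_{f}"] = np.nan
                row["dominant"] = "error"
            rows.append(row)
    return pd.DataFrame(rows)
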
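"""Parameter containers for the protracted birth-death (PBD) model.

The PBD model describes diversification with a two-step speciation process:
*initiation* creates an incipient lineage, which only becomes a recognised
("good") species after a *completion* event.  Five per-lineage rates (all in
events per lineage per Myr) govern the process:

==========  =====================================================
``lambda1``  speciation initiation from a good lineage
``lambda2``  speciation completion of an incipient lineage
``lambda3``  speciation initiation from an incipient lineage
``mu1``      extinction of a good lineage
``mu2``      extinction of an incipient lineage
==========  =====================================================
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class PBDParams:
    """The five PBD rates plus derived constants.

    Derived quantities:

    - ``Lambda = lambda2 + lambda3 + mu2``: total event rate of an incipient
      lineage.
    - ``Theta = lambda1 + mu1``: total event rate of a good lineage.
    - ``k = sqrt(Lambda**2 - 4*mu2*lambda3)``: decay constant of the incipient
      probability system (always real, by AM-GM on ``(lambda3 + mu2)**2``).
    - ``pi_nc``: probability that an incipient lineage, together with all its
      incipient descendants, fails to ever complete speciation.
    """

    lambda1: float
    lambda2: float
    lambda3: float
    mu1: float
    mu2: float

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3", "mu1", "mu2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def Lambda(self) -> float:
        return self.lambda2 + self.lambda3 + self.mu2

    @property
    def Theta(self) -> float:
        return self.lambda1 + self.mu1

    @property
    def k(self) -> float:
        # Lambda^2 - 4 mu2 lambda3 >= (lambda3 + mu2)^2 - 4 mu2 lambda3
        #                           = (lambda3 - mu2)^2 >= 0;
        # computed in ratio form so tiny rates do not underflow Lambda^2
        Lam = self.Lambda
        if Lam == 0.0:
            return 0.0
        x = 4.0 * (self.mu2 / Lam) * (self.lambda3 / Lam)
        return Lam * math.sqrt(max(1.0 - x, 0.0))

    @property
    def pi_nc(self) -> float:
        """Non-completion probability of an incipient lineage.

        The smaller root of ``lambda3*x**2 - Lambda*x + mu2 = 0``, evaluated
        in the rationalised form ``2*mu2 / (Lambda * (1 + sqrt(1 - x)))``
        (stable under cancellation and underflow); continuous limit
        ``mu2/(lambda2+mu2)`` when ``lambda3 == 0``, and 0 by convention when
        all incipient rates vanish.
        """
        Lam = self.Lambda
        if Lam == 0.0:
            return 0.0
        if self.lambda3 > 0:
            x = 4.0 * (self.mu2 / Lam) * (self.lambda3 / Lam)
            pi = 2.0 * self.mu2 / (Lam * (1.0 + math.sqrt(max(1.0 - x, 0.0))))
            return min(pi, 1.0)
        return self.mu2 / (self.lambda2 + self.mu2)

    def as_dict(self) -> dict[str, float]:
        return {
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "lambda3": self.lambda3,
            "mu1": self.mu1,
            "mu2": self.mu2,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PBDParams":
        return cls(
            lambda1=float(d["lambda1"]),
            lambda2=float(d["lambda2"]),
            lambda3=float(d["lambda3"]),
            mu1=float(d["mu1"]),
            mu2=float(d["mu2"]),
        )

    @classmethod
    def from_json(cls, text: str) -> "PBDParams":
        return cls.from_dict(json.loads(text))


#: Default parameter set used throughout the rate-trajectory examples
#: (lambda1 = lambda3 = 0.3, lambda2 = 0.4, mu1 = mu2 = 0.1).
RATE_CURVE_DEFAULTS = PBDParams(0.3, 0.4, 0.3, 0.1, 0.1)

#: Default parameter set used for the tree-simulation comparisons
#: (lambda1 = 0.5, lambda2 = 1.0, lambda3 = 0.4, mu1 = mu2 = 0.2).
TREE_SIM_DEFAULTS = PBDParams(0.5, 1.0, 0.4, 0.2, 0.2)


@dataclass
class SimulationConfig:
    """Settings shared by the PBD and BD tree simulators.

    Parameters
    ----------
    T
        Process duration in Myr; the process starts from a single good stem
        lineage at time 0 and runs to the present at time ``T``.
    n_grid
        Number of evaluation points / piecewise-constant intervals used when
        a rate trajectory is discretised for simulation.
    seed
        Root RNG seed; per-replicate streams are spawned from it.
    condition_on_survivors
        Minimum number of extant species required for a replicate to count
        as valid.
    max_attempts
        Maximum number of simulation attempts per replicate before the
        replicate is marked invalid.
    species_convention
        Which member lineage represents a species in the reconstructed tree:
        ``"oldest"`` (default) or ``"youngest"``.
    """

    T: float = 15.0
    n_grid: int = 200
    seed: int = 0
    condition_on_survivors: int = 2
    max_attempts: int = 100
    species_convention: str = "oldest"
    require_good_alive: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"T must be > 0, got {self.T}")
        if self.n_grid < 2:
            raise ValueError(f"n_grid must be >= 2, got {self.n_grid}")
        if self.max_attempts < 1:
            raise ValueError(f"max_attempts must be >= 1, got {self.max_attempts}")
        if self.species_convention not in ("oldest", "youngest"):
            raise ValueError(
                "species_convention must be 'oldest' or 'youngest', "
                f"got {self.species_convention!r}"
            )
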
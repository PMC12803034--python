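"""Shared low-level containers used across the simulation and analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional


@dataclass(frozen=True)
class OUParams:
    """Ornstein--Uhlenbeck noise model of rotor-bead angular fluctuations.

    The bead angle relaxes toward the state-dependent mean with
    characteristic time ``tau_c`` (s) and has stationary standard
    deviation ``sigma`` (turns).  This (tau_c, sigma) parameterization
    replaces the physical rotational friction coefficient, which is
    never needed by the analysis.
    """

    tau_c: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.tau_c > 0:
            raise ValueError(f"tau_c must be positive, got {self.tau_c}")
        if not self.sigma >= 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")

    def ar1_coeff(self, dt: float) -> float:
        """Lag-1 autoregression coefficient a = exp(-dt/tau_c)."""
        import math

        return math.exp(-dt / self.tau_c)

    def innovation_sd(self, dt: float) -> float:
        """Standard deviation of the exact-discretization innovation."""
        import math

        a = self.ar1_coeff(dt)
        return self.sigma * math.sqrt(max(0.0, 1.0 - a * a))


@dataclass
class Dwell:
    """A maximal constant-mean interval of a segmented trace.

    ``mean_level`` carries its own units flag (``turns`` or ``bp``) so
    that downstream stages can convert exactly once.
    """

    t_start: float
    t_end: float
    mean_level: float
    n_samples: int
    units: str = "turns"
    state: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(
                f"dwell must have t_end > t_start, got [{self.t_start}, {self.t_end}]"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def with_(self, **kw) -> "Dwell":
        return replace(self, **kw)
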
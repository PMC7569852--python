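"""The DNA predator-prey reaction operator.

Local kinetics of the two-species oscillator: a prey strand N replicating
autocatalytically with saturating growth, consumed by a predator strand P
with saturating predation,

    f1(N, P) = Cr·N/(1 + b·N) − Cp·N·P/(1 + b·P) − ε
    f2(N, P) = Cp·N·P/(1 + b·P) − ε

The small uniform decay ε regularizes the locally unstable null state:
without it, round-off can seed spontaneous growth of either species far
from any existing concentration.  ε drives tiny concentrations slightly
negative; the clamping rule (concentrations are set to 0 whenever they
become negative) restores the invariant and keeps the downstream linear
solver healthy.

The reaction operator is pointwise — each node evolves independently — so
the explicit-Euler reaction half-step is a vectorized one-liner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, StateError

__all__ = ["ReactionParams", "reaction_rates", "reaction_step", "clamp_nonnegative"]


@dataclass(frozen=True)
class ReactionParams:
    """Kinetic parameters of the predator-prey system.

    Attributes
    ----------
    cr:
        Prey autocatalytic growth rate, 1/time.
    cp:
        Predation rate, 1/(concentration·time).
    b:
        Saturation constant of growth and predation, 1/concentration.
    eps:
        Uniform regularization decay, concentration/time; suppresses
        round-off-driven spontaneous generation of species.
    """

    cr: float = 0.2
    cp: float = 0.2
    b: float = 0.1
    eps: float = 1e-13

    def __post_init__(self):
        if self.cr < 0 or self.cp < 0 or self.b < 0 or self.eps < 0:
            raise ParameterError("reaction parameters must be nonnegative")

    @classmethod
    def pure_diffusion(cls) -> "ReactionParams":
        """All rates zero: diffusion-only dynamics (mass is conserved)."""
        return cls(cr=0.0, cp=0.0, b=0.0, eps=0.0)


def reaction_rates(
    N: np.ndarray, P: np.ndarray, params: ReactionParams = ReactionParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (f1, f2) pointwise at each node.

    The denominators 1 + b·N and 1 + b·P are >= 1 for nonnegative fields,
    so no division guards are needed under the clamping contract.
    """
    N = np.asarray(N, dtype=float)
    P = np.asarray(P, dtype=float)
    if N.shape != P.shape:
        raise ParameterError(f"field length mismatch: {N.shape} vs {P.shape}")
    predation = params.cp * N * P / (1.0 + params.b * P)
    f1 = params.cr * N / (1.0 + params.b * N) - predation - params.eps
    f2 = predation - params.eps
    return f1, f2


def reaction_step(
    N: np.ndarray,
    P: np.ndarray,
    tau: float,
    params: ReactionParams = ReactionParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """One explicit-Euler reaction half-step with clamping.

    Ñ = N + τ·f1(N, P), P̃ = P + τ·f2(N, P), then negatives are set to 0.
    The exact zero state is therefore a fixed point: Euler gives −ετ and
    the clamp restores 0.
    """
    if tau <= 0:
        raise ParameterError("tau must be positive")
    if not (np.all(np.isfinite(N)) and np.all(np.isfinite(P))):
        raise StateError("non-finite concentrations entering reaction step")
    f1, f2 = reaction_rates(N, P, params)
    return clamp_nonnegative(N + tau * f1), clamp_nonnegative(P + tau * f2)


def clamp_nonnegative(field: np.ndarray) -> np.ndarray:
    """Set negative concentrations to 0 (idempotent)."""
    return np.maximum(np.asarray(field, dtype=float), 0.0)
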
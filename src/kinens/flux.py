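"""Steady-state fluxes from the mass-action law, and the zero-flux threshold.

Fluxes are evaluated at the final state of a run that passed the steady-state
criterion; values below 1e-10 are snapped to exactly zero so that the ">0" /
"=0" phenotype predicates are numerically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dynamics import build_rate_law
from .model_io import MetabolicModel
from .sampling import KineticParametrization

__all__ = ["FluxDistribution", "compute_fluxes", "threshold_fluxes", "DEFAULT_EPSILON"]

DEFAULT_EPSILON = 1e-10


@dataclass
class FluxDistribution:
    """Vector of non-negative directional reaction fluxes at steady state."""

    v: np.ndarray
    reaction_ids: list[str]
    parametrization_id: int | None = None
    condition_id: str | None = None
    thresholded: bool = False

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, float)
        if len(self.v) != len(self.reaction_ids):
            raise ValueError(
                f"flux vector length {len(self.v)} != {len(self.reaction_ids)} reactions"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.reaction_ids, self.v.tolist()))

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.v[self.reaction_ids.index(reaction_id)])


def compute_fluxes(
    model: MetabolicModel,
    parametrization: KineticParametrization | np.ndarray,
    steady_concentrations: np.ndarray,
    condition_id: str | None = None,
) -> FluxDistribution:
    """Evaluate ``v_i = k_i * prod_w x_w^(A_wi)`` at a steady concentration vector."""
    x = np.asarray(steady_concentrations, float)
    if len(x) != model.n_species:
        raise ValueError(
            f"concentration vector length {len(x)} != {model.n_species} species"
        )
    v = build_rate_law(model, parametrization)(x)
    pid = parametrization.id if isinstance(parametrization, KineticParametrization) else None
    return FluxDistribution(
        v=v, reaction_ids=model.reaction_ids,
        parametrization_id=pid, condition_id=condition_id,
    )


def threshold_fluxes(
    fluxes: FluxDistribution, epsilon: float = DEFAULT_EPSILON
) -> FluxDistribution:
    """Snap fluxes strictly below ``epsilon`` to exactly 0 (idempotent)."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    v = np.where(fluxes.v < epsilon, 0.0, fluxes.v)
    return replace(fluxes, v=v, thresholded=True)
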
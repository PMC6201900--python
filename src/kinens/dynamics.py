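"""Mass-action ODE construction, integration, and the steady-state criterion.

The rate of reaction i is ``v_i(x) = k_i * prod_w x_w^(A_wi)`` where ``A`` is
the reactant-order matrix; species derivatives are ``dx/dt = S v(x)`` with
clamped species forced to zero derivative.  A run is accepted as a metabolic
steady state when the mean, over non-excluded species, of the per-species
standard deviation of the concentration across the final fraction of the time
horizon falls below a tolerance theta (default 0.1%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model_io import MetabolicModel, build_matrices
from .sampling import KineticParametrization

__all__ = [
    "Trajectory",
    "SteadyStateReport",
    "IntegrationError",
    "build_rate_law",
    "build_odes",
    "simulate",
    "check_steady_state",
]


class IntegrationError(RuntimeError):
    """Solver failure; carries the parametrization id so the caller can count
    the sample as discarded."""

    def __init__(self, message: str, parametrization_id: int | None = None):
        super().__init__(message)
        self.parametrization_id = parametrization_id


@dataclass
class Trajectory:
    """Time grid plus concentration matrix (n_times x n_species) of one run."""

    times: np.ndarray
    concentrations: np.ndarray
    species_ids: list[str]
    parametrization_id: int | None = None
    condition_id: str | None = None

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def final_state(self) -> np.ndarray:
        return self.concentrations[-1].copy()


@dataclass
class SteadyStateReport:
    """Outcome of the steady-state criterion on one trajectory."""

    statistic: float
    theta: float
    window_start: float
    passed: bool
    per_species_sigma: np.ndarray


def _rates(k: np.ndarray, A: np.ndarray, x: np.ndarray) -> np.ndarray:
    # Evaluated as exp(sum_w A_wi * ln x_w) over reactant-side entries only:
    # uniformly robust for many-reactant (biomass-like) columns and yields an
    # exact 0 whenever a required reactant is absent.
    xs = np.clip(x, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        logx = np.log(xs)  # -inf where xs == 0
        contrib = np.where(A.T > 0, A.T * logx[None, :], 0.0)
    expo = contrib.sum(axis=1)
    with np.errstate(over="ignore"):
        return k * np.exp(expo)


def build_rate_law(
    model: MetabolicModel, parametrization: KineticParametrization | np.ndarray
) -> Callable[[np.ndarray], np.ndarray]:
    """Return ``v(x)``, the instantaneous mass-action flux vector.

    A reaction with an empty reactant side has rate ``k`` (empty product = 1).
    """
    k = parametrization.k if isinstance(parametrization, KineticParametrization) else np.asarray(parametrization, float)
    if len(k) != model.n_reactions:
        raise ValueError(
            f"parametrization length {len(k)} != number of reactions {model.n_reactions}"
        )
    _, A = build_matrices(model)
    return lambda x: _rates(k, A, np.asarray(x, float))


def build_odes(
    model: MetabolicModel, parametrization: KineticParametrization | np.ndarray
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Right-hand side ``f(t, x) = S v(x)`` with clamped rows zeroed."""
    k = parametrization.k if isinstance(parametrization, KineticParametrization) else np.asarray(parametrization, float)
    if len(k) != model.n_reactions:
        raise ValueError(
            f"parametrization length {len(k)} != number of reactions {model.n_reactions}"
        )
    S, A = build_matrices(model)
    free = ~model.clamped_mask()

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        dx = S @ _rates(k, A, x)
        return np.where(free, dx, 0.0)

    return rhs


def simulate(
    model: MetabolicModel,
    parametrization: KineticParametrization | np.ndarray,
    t_end: float = 100.0,
    n_points: int = 1001,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    condition_id: str | None = None,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the mass-action ODEs with LSODA on a fixed output grid.

    Solver non-convergence raises :class:`IntegrationError` carrying the
    parametrization id; callers count such runs as discarded samples.
    Reported concentrations are clipped at zero and clamped species rows are
    set bit-exactly to their initial value.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    rhs = build_odes(model, parametrization)
    x0 = model.initial_state() if x0 is None else np.asarray(x0, float)
    times = np.linspace(0.0, t_end, n_points)
    pid = parametrization.id if isinstance(parametrization, KineticParametrization) else None
    sol = solve_ivp(rhs, (0.0, t_end), x0, method="LSODA", t_eval=times,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"LSODA failed (parametrization {pid}): {sol.message}", parametrization_id=pid
        )
    conc = np.clip(sol.y.T, 0.0, None)
    clamped = model.clamped_mask()
    conc[:, clamped] = x0[clamped]
    return Trajectory(
        times=times,
        concentrations=conc,
        species_ids=model.species_ids,
        parametrization_id=pid,
        condition_id=condition_id,
    )


def default_excluded(model: MetabolicModel) -> set[str]:
    """Species excluded from the steady-state sum: clamped plus non-internal
    (e.g. accumulating exported species that never settle)."""
    return {s.id for s in model.species if s.clamped or not s.internal}


def check_steady_state(
    trajectory: Trajectory,
    theta: float = 1e-3,
    window_fraction: float = 0.1,
    excluded: Iterable[str] = (),
    relative: bool = False,
) -> SteadyStateReport:
    """Evaluate the steady-state criterion on the final window of a trajectory.

    The statistic is ``sum_w sigma_w / (M - S)`` where sigma_w is the standard
    deviation of species w over the last ``window_fraction`` of the horizon,
    M the number of species and S the number of excluded species (which
    contribute sigma = 0 exactly).  With ``relative=True`` each sigma is
    divided by the window mean of that species (species with near-zero mean
    are skipped).
    """
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    t_e = trajectory.t_end
    window_start = (1.0 - window_fraction) * t_e
    in_window = trajectory.times >= window_start - 1e-12 * max(t_e, 1.0)
    if in_window.sum() < 3:
        raise ValueError(
            f"steady-state window holds {int(in_window.sum())} points; need >= 3"
        )
    window = trajectory.concentrations[in_window]
    sigma = window.std(axis=0)
    excluded = set(excluded)
    mask = np.array([sid in excluded for sid in trajectory.species_ids])
    sigma = np.where(mask, 0.0, sigma)
    if relative:
        means = window.mean(axis=0)
        safe = (~mask) & (means > 1e-12)
        rel = np.zeros_like(sigma)
        rel[safe] = sigma[safe] / means[safe]
        sigma = rel
    M = len(trajectory.species_ids)
    S = int(mask.sum())
    if M - S <= 0:
        raise ValueError("all species excluded from the steady-state criterion")
    statistic = float(sigma.sum() / (M - S))
    return SteadyStateReport(
        statistic=statistic,
        theta=theta,
        window_start=window_start,
        passed=statistic < theta,
        per_species_sigma=sigma,
    )
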
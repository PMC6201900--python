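"""Reproducible uniform sampling of kinetic-constant vectors.

Each parametrization p draws one rate constant per (directional) reaction of
the split model from a uniform law on ``[low, high)`` (default ``[0, 100)``).
Per-parametrization generators are derived from the master seed through
``numpy.random.SeedSequence`` spawn keys, so vector p is reproducible in
isolation and independent of how many vectors are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import MetabolicModel

__all__ = ["KineticParametrization", "EnsembleConfig", "sample_parametrizations"]


class ConfigurationError(ValueError):
    pass


@dataclass
class KineticParametrization:
    """One sampled vector of rate constants (one per split reaction)."""

    id: int
    k: np.ndarray
    seed: int  # master seed this vector derives from

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, float)
        if np.any(self.k < 0):
            raise ConfigurationError("rate constants must be non-negative")


@dataclass
class EnsembleConfig:
    """Sampling configuration: ensemble size, bounds and master seed."""

    P: int
    low: float = 0.0
    high: float = 100.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ConfigurationError(f"P must be >= 1, got {self.P}")
        if not (0 <= self.low < self.high):
            raise ConfigurationError(
                f"invalid sampling bounds [{self.low}, {self.high})"
            )


def parametrization_rng(master_seed: int, p: int) -> np.random.Generator:
    """Generator for parametrization index ``p`` under ``master_seed``."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(p,)))


def sample_parametrizations(
    model: MetabolicModel, config: EnsembleConfig
) -> list[KineticParametrization]:
    """Draw ``config.P`` kinetic-constant vectors for the split ``model``."""
    if not model.is_irreversible:
        raise ConfigurationError("model must be split (irreversible) before sampling")
    M = model.n_reactions
    out = []
    for p in range(config.P):
        rng = parametrization_rng(config.master_seed, p)
        k = rng.uniform(config.low, config.high, size=M)
        out.append(KineticParametrization(id=p, k=k, seed=config.master_seed))
    return out
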
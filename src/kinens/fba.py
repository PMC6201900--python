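"""Flux balance analysis over the split irreversible model.

The linear program is max c.v subject to S_internal v = 0 and 0 <= v <= ub,
solved with the HiGHS backend of scipy.  Condition bounds encode the five
growth experiments (nutrient uptake opened at 10, other carbon uptakes closed,
oxygen uptake closed for the anaerobic condition) plus a rich medium "exp0"
with every carbon source open.  ``derive_filter_targets`` reconstructs the
condition-discriminating flux table: class A reactions carry flux in exactly
one condition, class B are the configured condition-defining exchanges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .flux import DEFAULT_EPSILON
from .model_io import MetabolicModel, build_matrices

__all__ = [
    "ConditionBounds",
    "FBAResult",
    "CONDITIONS",
    "CARBON_UPTAKES",
    "OXYGEN_UPTAKE",
    "condition_bounds",
    "run_fba",
    "derive_filter_targets",
]

# Condition-defining exchange reactions of the E. coli core experiments:
# one carbon source open per condition (upper bound 10), oxygen uptake closed
# only in the anaerobic condition.
CARBON_UPTAKES = ("GlcUp", "AcUp", "SuccUp", "GlycUp")
OXYGEN_UPTAKE = "O2Up"
UPTAKE_BOUND = 10.0

#: condition id -> (open carbon uptakes, aerobic?)
CONDITIONS: dict[str, tuple[tuple[str, ...], bool]] = {
    "exp0": (CARBON_UPTAKES, True),   # rich medium, not a phenotype
    "exp1": (("GlcUp",), True),       # aerobic growth on glucose
    "exp2": (("GlcUp",), False),      # anaerobic growth on glucose
    "exp3": (("AcUp",), True),        # aerobic growth on acetate
    "exp4": (("SuccUp",), True),      # aerobic growth on succinate
    "exp5": (("GlycUp",), True),      # aerobic growth on glycerol
}


@dataclass
class ConditionBounds:
    """Upper-bound overrides defining one experimental condition.

    ``upper_bounds`` maps reaction id -> upper bound; reactions not listed
    keep their model bound.
    """

    condition_id: str
    upper_bounds: dict[str, float] = field(default_factory=dict)


@dataclass
class FBAResult:
    objective_value: float
    flux_vector: np.ndarray
    reaction_ids: list[str]
    status: str  # "optimal" | "infeasible" | "unbounded"
    condition_id: str | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(self.flux_vector, index=self.reaction_ids)


def condition_bounds(
    condition_id: str,
    carbon_uptakes: tuple[str, ...] = CARBON_UPTAKES,
    oxygen_uptake: str = OXYGEN_UPTAKE,
    uptake_bound: float = UPTAKE_BOUND,
) -> ConditionBounds:
    """Bounds for one built-in experimental condition (exp0..exp5)."""
    if condition_id not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition_id!r}; known: {sorted(CONDITIONS)}"
        )
    open_carbons, aerobic = CONDITIONS[condition_id]
    ub = {c: (uptake_bound if c in open_carbons else 0.0) for c in carbon_uptakes}
    if not aerobic:
        ub[oxygen_uptake] = 0.0
    return ConditionBounds(condition_id=condition_id, upper_bounds=ub)


def run_fba(
    model: MetabolicModel,
    bounds: ConditionBounds | None = None,
    objective: str = "BIOMASS",
) -> FBAResult:
    """Maximize one reaction's flux over the steady-state flux cone.

    The model must already be split (all fluxes non-negative).  Infeasible or
    unbounded programs are reported through ``status``, not raised.
    """
    if not model.is_irreversible:
        raise ValueError("run_fba requires a split (irreversible) model")
    ridx = model.reaction_index()
    if objective not in ridx:
        raise ValueError(f"objective reaction {objective!r} not in model")
    S, _ = build_matrices(model)
    internal = np.array([s.internal and not s.clamped for s in model.species])
    A_eq = S[internal]
    b_eq = np.zeros(A_eq.shape[0])
    ub = np.array([r.upper_bound for r in model.reactions], float)
    if bounds is not None:
        for rid, val in bounds.upper_bounds.items():
            if rid in ridx:
                ub[ridx[rid]] = val
    c = np.zeros(model.n_reactions)
    c[ridx[objective]] = -1.0  # linprog minimizes
    lp_bounds = [(0.0, None if math.isinf(u) else u) for u in ub]
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=lp_bounds, method="highs")
    cid = bounds.condition_id if bounds is not None else None
    if res.status == 2:
        status, obj, v = "infeasible", float("nan"), np.full(model.n_reactions, np.nan)
    elif res.status == 3:
        status, obj, v = "unbounded", float("inf"), np.full(model.n_reactions, np.nan)
    elif res.status == 0:
        status, obj, v = "optimal", -float(res.fun), np.asarray(res.x, float)
    else:
        raise RuntimeError(f"LP solver failed: {res.message}")
    return FBAResult(objective_value=obj, flux_vector=v,
                     reaction_ids=model.reaction_ids, status=status,
                     condition_id=cid)


def _fva_bounds(model, bounds, objective, optimum, reaction):
    """Min and max flux of one reaction at the FBA optimum (flux variability)."""
    ridx = model.reaction_index()
    S, _ = build_matrices(model)
    internal = np.array([s.internal and not s.clamped for s in model.species])
    ub = np.array([r.upper_bound for r in model.reactions], float)
    if bounds is not None:
        for rid, val in bounds.upper_bounds.items():
            if rid in ridx:
                ub[ridx[rid]] = val
    A_eq = np.vstack([S[internal], np.eye(model.n_reactions)[ridx[objective]]])
    b_eq = np.append(np.zeros(int(internal.sum())), optimum)
    lp_bounds = [(0.0, None if math.isinf(u) else u) for u in ub]
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(model.n_reactions)
        c[ridx[reaction]] = sign
        res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=lp_bounds, method="highs")
        out.append(sign * float(res.fun) if res.status == 0 else float("nan"))
    return out[0], -(-out[1])  # (min, max)


def derive_filter_targets(
    results: dict[str, FBAResult],
    condition_defining: dict[str, tuple[str, ...]] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    model: MetabolicModel | None = None,
    objective: str = "BIOMASS",
    check_degeneracy: bool = False,
) -> pd.DataFrame:
    """Tabulate condition-discriminating fluxes from per-condition FBA results.

    Returns a DataFrame indexed by reaction with one flux column per
    condition plus a ``class`` column: ``"A"`` for reactions non-zero (after
    the epsilon threshold) in exactly one condition, ``"B"`` for the
    condition-defining uptakes, and the associated condition in ``condition``.
    With ``check_degeneracy=True`` (requires ``model``) class-A calls are
    verified by flux variability at the optimum; calls whose non-zero status
    is not unique are flagged in a ``degenerate`` column.
    """
    if not results:
        raise ValueError("no FBA results given")
    for cid, r in results.items():
        if r.status != "optimal":
            raise ValueError(f"condition {cid!r}: FBA status {r.status!r}, need optimal")
    conditions = list(results)
    table = pd.DataFrame(
        {cid: results[cid].as_series() for cid in conditions}
    )
    active = table.abs() >= epsilon
    n_active = active.sum(axis=1)

    if condition_defining is None:
        defining = {OXYGEN_UPTAKE, *CARBON_UPTAKES}
        def_map = {}
        for c in CARBON_UPTAKES:
            for cid in conditions:
                if cid in CONDITIONS and c in CONDITIONS[cid][0] and len(CONDITIONS[cid][0]) == 1:
                    def_map.setdefault(c, cid)
    else:
        defining = {rid for rids in condition_defining.values() for rid in rids}
        def_map = {rid: cid for cid, rids in condition_defining.items() for rid in rids}

    klass = pd.Series("", index=table.index, dtype=object)
    assoc = pd.Series("", index=table.index, dtype=object)
    for rid in table.index:
        if rid in defining:
            klass[rid] = "B"
            assoc[rid] = def_map.get(rid, "")
        elif n_active[rid] == 1:
            klass[rid] = "A"
            assoc[rid] = table.columns[active.loc[rid]][0]
    out = table.copy()
    out["class"] = klass
    out["condition"] = assoc

    if check_degeneracy:
        if model is None:
            raise ValueError("check_degeneracy requires the model")
        flags = pd.Series(False, index=table.index)
        for rid in table.index[klass == "A"]:
            cid = assoc[rid]
            for other in conditions:
                b = condition_bounds(other) if other in CONDITIONS else None
                lo, hi = _fva_bounds(model, b, objective, results[other].objective_value, rid)
                if other == cid and lo < epsilon:
                    flags[rid] = True  # could be zero in its own condition
                if other != cid and hi >= epsilon:
                    flags[rid] = True  # could be non-zero elsewhere
        out["degenerate"] = flags
    return out
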
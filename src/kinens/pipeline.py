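"""End-to-end experiment driver.

For each sampled kinetic parametrization and each experimental condition the
driver clamps the condition's feed concentrations, integrates the mass-action
ODEs, applies the steady-state criterion, back-calculates thresholded fluxes,
and writes the record to the store.  A parametrization is retained only if
every one of its condition runs reaches a steady state (non-steady runs and
solver failures are both counted as discards); phenotype membership is then
evaluated on the retained records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import IntegrationError, check_steady_state, default_excluded, simulate, SteadyStateReport
from .flux import compute_fluxes, threshold_fluxes, DEFAULT_EPSILON
from .model_io import MetabolicModel, split_reversible
from .phenotype_filters import PhenotypeFilter, build_membership, builtin_filters, cardinality_analysis
from .sampling import EnsembleConfig, sample_parametrizations
from .storage import ExperimentStore

__all__ = ["PipelineResult", "apply_condition", "run_experiment"]


@dataclass
class PipelineResult:
    n_sampled: int
    n_retained: int
    discard_fraction: float
    membership: pd.DataFrame
    cardinality_record: dict
    cardinality_parametrization: dict
    store_path: Path | None = None
    flux_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    k_table: pd.DataFrame | None = None


def apply_condition(model: MetabolicModel, feeds: Mapping[str, float]) -> MetabolicModel:
    """Copy of ``model`` with the feed species clamped at the given values."""
    out = model.copy()
    idx = {s.id: s for s in out.species}
    for sid, val in feeds.items():
        if sid not in idx:
            raise KeyError(f"feed species {sid!r} not in model")
        sp = idx[sid]
        sp.initial_concentration = float(val)
        sp.clamped = True
    return out


def run_experiment(
    model: MetabolicModel,
    conditions: Mapping[str, Mapping[str, float]],
    config: EnsembleConfig,
    filters: Sequence[PhenotypeFilter] | None = None,
    store_path: str | Path | None = None,
    t_end: float = 100.0,
    n_points: int = 1001,
    theta: float = 1e-3,
    window_fraction: float = 0.1,
    epsilon: float = DEFAULT_EPSILON,
) -> PipelineResult:
    """Run the full sample-simulate-filter pipeline.

    ``conditions`` maps condition id -> clamped feed concentrations.  The
    model is split if it still contains reversible reactions.  Results are
    written to an HDF5 store when ``store_path`` is given; the in-memory
    result carries the membership table, both cardinality views and the
    per-condition flux tables of retained parametrizations.
    """
    if not model.is_irreversible:
        model = split_reversible(model)
    filters = builtin_filters() if filters is None else list(filters)
    params = sample_parametrizations(model, config)

    cond_models = {cid: apply_condition(model, feeds) for cid, feeds in conditions.items()}
    excluded = {cid: default_excluded(m) for cid, m in cond_models.items()}

    store = ExperimentStore(store_path, mode="w") if store_path is not None else None
    if store is not None:
        store.write_model_meta(model)
        store.write_parametrizations(params)

    runs: dict[str, list] = {cid: [] for cid in conditions}
    retained_ids = []
    for p in params:
        results = {}
        ok = True
        for cid, m in cond_models.items():
            try:
                traj = simulate(m, p, t_end=t_end, n_points=n_points, condition_id=cid)
                report = check_steady_state(traj, theta=theta,
                                            window_fraction=window_fraction,
                                            excluded=excluded[cid])
                final = traj.final_state()
            except IntegrationError:
                report = SteadyStateReport(statistic=float("inf"), theta=theta,
                                           window_start=(1 - window_fraction) * t_end,
                                           passed=False,
                                           per_species_sigma=np.full(m.n_species, np.nan))
                final = np.full(m.n_species, np.nan)
            fluxes = None
            if report.passed:
                fluxes = threshold_fluxes(
                    compute_fluxes(m, p, final, condition_id=cid), epsilon=epsilon
                )
            else:
                ok = False
            results[cid] = (final, report, fluxes)
        if ok:
            retained_ids.append(p.id)
        for cid, (final, report, fluxes) in results.items():
            if store is not None:
                store.write_run(p, cid, final, report, fluxes)
            if ok:
                runs[cid].append((p.id, fluxes))

    records = []
    for cid in conditions:
        for pid, fluxes in runs[cid]:
            records.append((pid, cid, fluxes.as_dict()))
    membership = build_membership(records, filters)
    card_rec = cardinality_analysis(membership, per="record") if len(membership) else {
        "combinations": {}, "marginals": {}, "totals": {"entities": 0, "assigned": 0}}
    card_par = cardinality_analysis(membership, per="parametrization") if len(membership) else card_rec

    flux_tables = {}
    for cid in conditions:
        if runs[cid]:
            flux_tables[cid] = pd.DataFrame(
                [f.as_dict() for _, f in runs[cid]],
                index=pd.Index([pid for pid, _ in runs[cid]], name="parametrization_id"),
            )
    k_table = pd.DataFrame(
        np.stack([p.k for p in params]), columns=model.reaction_ids,
        index=pd.Index([p.id for p in params], name="parametrization_id"),
    )

    if store is not None:
        if len(membership):
            store.write_membership(membership)
        store.close()

    P = config.P
    return PipelineResult(
        n_sampled=P,
        n_retained=len(retained_ids),
        discard_fraction=1.0 - len(retained_ids) / P,
        membership=membership,
        cardinality_record=card_rec,
        cardinality_parametrization=card_par,
        store_path=Path(store_path) if store_path is not None else None,
        flux_tables=flux_tables,
        k_table=k_table,
    )
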
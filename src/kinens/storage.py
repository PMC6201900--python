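"""Hierarchical HDF5 store for the experiment pipeline.

Layout (version 1):

    /model_meta                  species and reaction ids
    /parametrizations            kinetic-constant matrix (P x M), ids, seeds
    /conditions/<id>/            per-condition run records, appendable:
        parametrization_ids, final_states, fluxes,
        steady_statistic, steady_passed
    /membership                  membership table columns
    /analysis                    free-form analysis payloads

Only final states are kept by default; storing full trajectories at ensemble
scale is the multi-gigabyte regime this layout avoids.  Numeric round trips
are lossless (float64 throughout).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .flux import FluxDistribution
from .dynamics import SteadyStateReport
from .model_io import MetabolicModel
from .sampling import KineticParametrization

__all__ = ["ExperimentStore", "StorageError", "QueryError", "write_run", "query"]

LAYOUT_VERSION = 1
_STR = h5py.string_dtype(encoding="utf-8")


class StorageError(RuntimeError):
    pass


class QueryError(KeyError):
    pass


class ExperimentStore:
    """Thin wrapper around an HDF5 file holding one experiment hierarchy."""

    def __init__(self, path: str | Path, mode: str = "a"):
        self.path = Path(path)
        self._f = h5py.File(self.path, mode)
        if "layout_version" in self._f.attrs:
            found = int(self._f.attrs["layout_version"])
            if found != LAYOUT_VERSION:
                raise StorageError(
                    f"store {self.path} has layout version {found}, expected {LAYOUT_VERSION}"
                )
        elif mode != "r":
            self._f.attrs["layout_version"] = LAYOUT_VERSION

    # -- context management ----------------------------------------------
    def close(self) -> None:
        self._f.close()

    def __enter__(self) -> "ExperimentStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- model metadata ----------------------------------------------------
    def write_model_meta(self, model: MetabolicModel) -> None:
        g = self._f.require_group("model_meta")
        for name in ("species_ids", "reaction_ids", "clamped", "internal"):
            if name in g:
                del g[name]
        g.create_dataset("species_ids", data=model.species_ids, dtype=_STR, track_times=False)
        g.create_dataset("reaction_ids", data=model.reaction_ids, dtype=_STR, track_times=False)
        g.create_dataset("clamped", data=model.clamped_mask(), track_times=False)
        g.create_dataset("internal", data=[s.internal for s in model.species], track_times=False)

    def reaction_ids(self) -> list[str]:
        return [s.decode() for s in self._f["model_meta/reaction_ids"][()]]

    def species_ids(self) -> list[str]:
        return [s.decode() for s in self._f["model_meta/species_ids"][()]]

    # -- parametrizations ---------------------------------------------------
    def write_parametrizations(self, params: Sequence[KineticParametrization]) -> None:
        g = self._f.require_group("parametrizations")
        for name in ("k", "ids", "seeds"):
            if name in g:
                del g[name]
        g.create_dataset("k", data=np.stack([p.k for p in params]), track_times=False)
        g.create_dataset("ids", data=[p.id for p in params], track_times=False)
        g.create_dataset("seeds", data=[p.seed for p in params], track_times=False)

    def read_parametrizations(self) -> pd.DataFrame:
        g = self._f["parametrizations"]
        return pd.DataFrame(g["k"][()], index=g["ids"][()],
                            columns=self.reaction_ids())

    # -- run records ---------------------------------------------------------
    def _condition_group(self, condition_id: str, n_species: int, n_reactions: int) -> h5py.Group:
        g = self._f.require_group(f"conditions/{condition_id}")
        if "parametrization_ids" not in g:
            g.create_dataset("parametrization_ids", shape=(0,), maxshape=(None,), dtype="i8", track_times=False)
            g.create_dataset("final_states", shape=(0, n_species),
                             maxshape=(None, n_species), dtype="f8", track_times=False)
            g.create_dataset("fluxes", shape=(0, n_reactions),
                             maxshape=(None, n_reactions), dtype="f8", track_times=False)
            g.create_dataset("steady_statistic", shape=(0,), maxshape=(None,), dtype="f8", track_times=False)
            g.create_dataset("steady_passed", shape=(0,), maxshape=(None,), dtype="?", track_times=False)
        return g

    def write_run(
        self,
        parametrization: KineticParametrization | int,
        condition_id: str,
        final_state: np.ndarray,
        steady_report: SteadyStateReport,
        fluxes: FluxDistribution | np.ndarray | None,
        overwrite: bool = False,
    ) -> tuple[str, int]:
        """Append one run record; returns ``(condition_id, row)``.

        A second write for the same (parametrization_id, condition_id) raises
        unless ``overwrite=True``, in which case the row is replaced.  For
        runs that failed the criterion ``fluxes`` may be None (stored as NaN).
        """
        pid = parametrization.id if isinstance(parametrization, KineticParametrization) else int(parametrization)
        final_state = np.asarray(final_state, float)
        n_species = len(final_state)
        if fluxes is None:
            v = None
        elif isinstance(fluxes, FluxDistribution):
            v = fluxes.v
        else:
            v = np.asarray(fluxes, float)
        n_reactions = len(v) if v is not None else len(self._f["model_meta/reaction_ids"])
        g = self._condition_group(condition_id, n_species, n_reactions)
        existing = g["parametrization_ids"][()]
        where = np.nonzero(existing == pid)[0]
        if len(where) and not overwrite:
            raise StorageError(
                f"run ({pid}, {condition_id!r}) already stored; pass overwrite=True to replace"
            )
        row = int(where[0]) if len(where) else len(existing)
        if not len(where):
            for name in ("parametrization_ids", "final_states", "fluxes",
                         "steady_statistic", "steady_passed"):
                ds = g[name]
                ds.resize(row + 1, axis=0)
        g["parametrization_ids"][row] = pid
        g["final_states"][row] = final_state
        g["fluxes"][row] = v if v is not None else np.full(n_reactions, np.nan)
        g["steady_statistic"][row] = steady_report.statistic
        g["steady_passed"][row] = steady_report.passed
        return condition_id, row

    def conditions(self) -> list[str]:
        if "conditions" not in self._f:
            return []
        return sorted(self._f["conditions"].keys())

    def read_records(self, condition_id: str) -> pd.DataFrame:
        g = self._f[f"conditions/{condition_id}"]
        return pd.DataFrame({
            "parametrization_id": g["parametrization_ids"][()],
            "condition_id": condition_id,
            "statistic": g["steady_statistic"][()],
            "passed": g["steady_passed"][()],
        })

    def read_fluxes(self, condition_id: str) -> pd.DataFrame:
        g = self._f[f"conditions/{condition_id}"]
        df = pd.DataFrame(g["fluxes"][()], columns=self.reaction_ids())
        df.index = pd.Index(g["parametrization_ids"][()], name="parametrization_id")
        return df

    def read_final_states(self, condition_id: str) -> pd.DataFrame:
        g = self._f[f"conditions/{condition_id}"]
        df = pd.DataFrame(g["final_states"][()], columns=self.species_ids())
        df.index = pd.Index(g["parametrization_ids"][()], name="parametrization_id")
        return df

    # -- membership -----------------------------------------------------------
    def write_membership(self, membership: pd.DataFrame) -> None:
        if "membership" in self._f:
            del self._f["membership"]
        g = self._f.create_group("membership")
        for col in membership.columns:
            data = membership[col].to_numpy()
            if data.dtype.kind in ("O", "U"):
                g.create_dataset(col, data=[str(x) for x in data], dtype=_STR, track_times=False)
            else:
                g.create_dataset(col, data=data, track_times=False)
        g.attrs["columns"] = list(membership.columns)

    def read_membership(self) -> pd.DataFrame:
        g = self._f["membership"]
        cols = list(g.attrs["columns"])
        out = {}
        for col in cols:
            data = g[col][()]
            if data.dtype.kind in ("S", "O"):
                data = np.array([d.decode() if isinstance(d, bytes) else d for d in data])
            out[col] = data
        return pd.DataFrame(out, columns=cols)

    # -- queries ----------------------------------------------------------------
    _QUERY_FIELDS = {"condition", "steady", "parametrization_id", "phenotype"}

    def query(self, selector: Mapping[str, object] | None = None) -> pd.DataFrame:
        """Select run records by condition, steady verdict, parametrization id,
        or phenotype membership.  An empty selector returns all records."""
        selector = dict(selector or {})
        unknown = set(selector) - self._QUERY_FIELDS
        if unknown:
            raise QueryError(f"unknown query fields: {sorted(unknown)}")
        conds = [selector["condition"]] if "condition" in selector else self.conditions()
        frames = [self.read_records(c) for c in conds]
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["parametrization_id", "condition_id", "statistic", "passed"])
        if "steady" in selector:
            df = df[df["passed"] == bool(selector["steady"])]
        if "parametrization_id" in selector:
            df = df[df["parametrization_id"] == int(selector["parametrization_id"])]
        if "phenotype" in selector:
            mem = self.read_membership()
            e = str(selector["phenotype"])
            if e not in mem.columns:
                raise QueryError(f"unknown phenotype {e!r}")
            keys = set(map(tuple, mem.loc[mem[e].astype(bool),
                                          ["parametrization_id", "condition_id"]].to_numpy()))
            df = df[[tuple(x) in keys for x in
                     df[["parametrization_id", "condition_id"]].to_numpy()]]
        return df.reset_index(drop=True)

    # -- export ---------------------------------------------------------------
    def export_tsv(self, what: str, path: str | Path, condition_id: str | None = None) -> None:
        """Write one table (``parametrizations``, ``fluxes``, ``final_states``,
        ``records`` or ``membership``) as TSV."""
        if what == "parametrizations":
            df = self.read_parametrizations()
        elif what == "membership":
            df = self.read_membership()
        elif what in ("fluxes", "final_states", "records"):
            if condition_id is None:
                raise ValueError(f"export of {what!r} needs a condition_id")
            df = getattr(self, f"read_{what}")(condition_id)
        else:
            raise ValueError(f"unknown table {what!r}")
        df.to_csv(path, sep="\t")


def write_run(store: ExperimentStore, parametrization, condition_id, final_state,
              steady_report, fluxes, overwrite: bool = False):
    return store.write_run(parametrization, condition_id, final_state,
                           steady_report, fluxes, overwrite=overwrite)


def query(store: ExperimentStore, selector: Mapping[str, object] | None = None) -> pd.DataFrame:
    return store.query(selector)
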
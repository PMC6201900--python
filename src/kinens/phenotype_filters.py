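"""Phenotype filters: conjunctions of flux-sign predicates, membership
assignment, and ensemble-intersection cardinalities.

A metabolic phenotype is defined by a conjunction of predicates of the form
``v_reaction > 0`` or ``v_reaction = 0`` evaluated on thresholded steady-state
fluxes.  A simulation record is assigned to a phenotype iff every predicate
holds; records may belong to zero, one, or several phenotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .flux import FluxDistribution

__all__ = [
    "GREATER_THAN_ZERO",
    "EQUAL_ZERO",
    "PhenotypeFilter",
    "builtin_filters",
    "assign",
    "build_membership",
    "cardinality_analysis",
    "filters_to_json",
    "filters_from_json",
]

GREATER_THAN_ZERO = "greater_than_zero"
EQUAL_ZERO = "equal_zero"
_OPS = {GREATER_THAN_ZERO, EQUAL_ZERO}


@dataclass
class PhenotypeFilter:
    """Conjunction of flux predicates defining one metabolic phenotype."""

    phenotype_id: str
    predicates: list[tuple[str, str]]  # (reaction_id, comparator)

    def __post_init__(self) -> None:
        if not self.predicates:
            raise ValueError(f"filter {self.phenotype_id!r}: empty predicate list")
        for rid, op in self.predicates:
            if op not in _OPS:
                raise ValueError(f"filter {self.phenotype_id!r}: unknown comparator {op!r}")

    def reaction_ids(self) -> list[str]:
        return [rid for rid, _ in self.predicates]

    def satisfied_by(self, fluxes: Mapping[str, float]) -> bool:
        for rid, op in self.predicates:
            if rid not in fluxes:
                raise KeyError(
                    f"filter {self.phenotype_id!r}: reaction {rid!r} absent from flux distribution"
                )
            v = fluxes[rid]
            if op == GREATER_THAN_ZERO and not v > 0:
                return False
            if op == EQUAL_ZERO and not v == 0:
                return False
        return True


def builtin_filters() -> list[PhenotypeFilter]:
    """The five built-in phenotype filters of the E. coli growth experiments.

    exp1 aerobic glucose, exp2 anaerobic glucose (the only filter with an
    equal-zero predicate, on oxygen uptake), exp3 aerobic acetate, exp4
    aerobic succinate, exp5 aerobic glycerol.  Every filter constrains O2Up,
    which encodes the oxygenation state.
    """
    gt, eq = GREATER_THAN_ZERO, EQUAL_ZERO
    return [
        PhenotypeFilter("exp1", [("G6PDH2r", gt), ("GND", gt), ("PGL", gt),
                                 ("GLCptspp", gt), ("O2Up", gt)]),
        PhenotypeFilter("exp2", [("AcEx", gt), ("ALCD2x", gt), ("EthEx", gt),
                                 ("GLCptspp", gt), ("O2Up", eq)]),
        PhenotypeFilter("exp3", [("MALS", gt), ("ICL", gt), ("AcUp", gt), ("O2Up", gt)]),
        PhenotypeFilter("exp4", [("SUCCt2_2pp", gt), ("ME2", gt), ("O2Up", gt)]),
        PhenotypeFilter("exp5", [("GLYK", gt), ("F6PA", gt), ("GLYCDx", gt), ("O2Up", gt)]),
    ]


def assign(
    flux_distribution: FluxDistribution | Mapping[str, float],
    filters: Sequence[PhenotypeFilter],
) -> set[str]:
    """Phenotypes whose every predicate holds on the (thresholded) fluxes."""
    if isinstance(flux_distribution, FluxDistribution):
        if not flux_distribution.thresholded:
            raise ValueError("assign requires a thresholded flux distribution")
        fluxes: Mapping[str, float] = flux_distribution.as_dict()
    else:
        fluxes = flux_distribution
    return {f.phenotype_id for f in filters if f.satisfied_by(fluxes)}


def build_membership(
    records: Iterable[FluxDistribution | tuple[int, str, Mapping[str, float]]],
    filters: Sequence[PhenotypeFilter],
) -> pd.DataFrame:
    """Membership table: one row per simulation record, one boolean column per
    phenotype, plus ``parametrization_id`` and ``condition_id`` columns."""
    rows = []
    for rec in records:
        if isinstance(rec, FluxDistribution):
            pid, cid, fluxes = rec.parametrization_id, rec.condition_id, rec.as_dict()
            if not rec.thresholded:
                raise ValueError("membership requires thresholded flux distributions")
        else:
            pid, cid, fluxes = rec
        member = assign(fluxes, filters)
        row = {"parametrization_id": pid, "condition_id": cid}
        row.update({f.phenotype_id: (f.phenotype_id in member) for f in filters})
        rows.append(row)
    return pd.DataFrame(rows)


def _combo_label(names: Sequence[str], members: Sequence[bool]) -> str:
    # "135" style: strip the shared "exp" prefix when present
    parts = [n for n, m in zip(names, members) if m]
    short = [p[3:] if p.startswith("exp") else p for p in parts]
    return "".join(short)


def cardinality_analysis(
    membership: pd.DataFrame, per: str = "record"
) -> dict[str, dict[str, int]]:
    """Counts per exact phenotype combination plus marginal totals.

    ``per="record"`` counts simulation records by their exact membership set.
    ``per="parametrization"`` uses matched membership: a parametrization
    belongs to phenotype e iff its record simulated under condition e
    satisfies filter e (the condition and phenotype ids must coincide).
    Combination counts partition the entities with non-empty membership.
    """
    phen_cols = [c for c in membership.columns
                 if c not in ("parametrization_id", "condition_id")]
    if per == "record":
        table = membership[phen_cols]
    elif per == "parametrization":
        rows = []
        for pid, grp in membership.groupby("parametrization_id"):
            row = {}
            for e in phen_cols:
                under_e = grp[grp["condition_id"] == e]
                row[e] = bool(under_e[e].any()) if len(under_e) else False
            rows.append(row)
        table = pd.DataFrame(rows, columns=phen_cols)
    else:
        raise ValueError(f"per must be 'record' or 'parametrization', got {per!r}")

    combos: dict[str, int] = {}
    for _, row in table.iterrows():
        members = [bool(row[e]) for e in phen_cols]
        if not any(members):
            continue
        label = _combo_label(phen_cols, members)
        combos[label] = combos.get(label, 0) + 1
    marginals = {e: int(table[e].sum()) for e in phen_cols}
    return {
        "combinations": combos,
        "marginals": marginals,
        "totals": {
            "entities": int(len(table)),
            "assigned": int(table.any(axis=1).sum()),
        },
    }


# ---------------------------------------------------------------------------
# JSON interface
# ---------------------------------------------------------------------------

_OP_TO_JSON = {GREATER_THAN_ZERO: ">", EQUAL_ZERO: "="}
_JSON_TO_OP = {v: k for k, v in _OP_TO_JSON.items()}


def filters_to_json(filters: Sequence[PhenotypeFilter]) -> str:
    payload = [
        {
            "phenotype": f.phenotype_id,
            "all_of": [
                {"flux": rid, "op": _OP_TO_JSON[op], "value": 0}
                for rid, op in f.predicates
            ],
        }
        for f in filters
    ]
    return json.dumps(payload, indent=2)


def filters_from_json(source: str | Path) -> list[PhenotypeFilter]:
    text = Path(source).read_text() if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("[")
    ) else source
    payload = json.loads(text)
    out = []
    for entry in payload:
        preds = []
        for p in entry["all_of"]:
            if p.get("value", 0) != 0:
                raise ValueError("only comparisons against 0 are supported")
            preds.append((p["flux"], _JSON_TO_OP[p["op"]]))
        out.append(PhenotypeFilter(entry["phenotype"], preds))
    return out
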
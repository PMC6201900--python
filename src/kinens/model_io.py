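"""Metabolic model containers and readers.

A model is a list of species and a list of reactions from which the signed
stoichiometric matrix ``S`` (products positive, reactants negative) and the
reactant-order matrix ``A`` (reactant-side coefficients, the kinetic orders of
the mass-action law) are built.  Models can be read from SBML (Level 2/3) or
from a small tabular dialect, and reversible reactions can be split into
irreversible forward/backward pairs, which every downstream stage requires.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "ModelParseError",
    "load_model",
    "load_reaction_table",
    "load_sbml",
    "split_reversible",
    "build_matrices",
    "load_concentrations",
    "model_to_table",
]

REVERSE_SUFFIX = "_reverse"


class ModelValidationError(ValueError):
    """A structurally invalid model (duplicate ids, unknown species, ...)."""


class ModelParseError(ValueError):
    """An input document that cannot be parsed as a model."""


@dataclass
class Species:
    """One chemical species.

    ``internal`` species participate in the steady-state criterion; ``clamped``
    species are held at their initial concentration throughout a simulation
    (boundary nutrients, ions, exchanged species) and never enter the
    steady-state denominator.
    """

    id: str
    name: str = ""
    internal: bool = True
    clamped: bool = False
    initial_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise ModelValidationError(
                f"species {self.id!r}: negative initial concentration "
                f"{self.initial_concentration}"
            )


@dataclass
class Reaction:
    """One reaction: reactant/product maps of positive coefficients.

    One side may be empty (pure exchange).  After :func:`split_reversible`
    every reaction has ``reversible=False``.
    """

    id: str
    reactants: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)
    reversible: bool = False
    upper_bound: float = math.inf

    def __post_init__(self) -> None:
        for side, coeffs in (("reactant", self.reactants), ("product", self.products)):
            for sid, c in coeffs.items():
                if c <= 0:
                    raise ModelValidationError(
                        f"reaction {self.id!r}: non-positive {side} coefficient "
                        f"{c} for {sid!r}"
                    )


@dataclass
class MetabolicModel:
    species: list[Species]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def is_irreversible(self) -> bool:
        return all(not r.reversible for r in self.reactions)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], float)

    def clamped_mask(self) -> np.ndarray:
        return np.array([s.clamped for s in self.species], bool)

    def validate(self) -> None:
        if not self.species or not self.reactions:
            raise ModelValidationError("empty model: need at least one species and one reaction")
        seen: set[str] = set()
        for s in self.species:
            if s.id in seen:
                raise ModelValidationError(f"duplicate species id {s.id!r}")
            seen.add(s.id)
        known = seen
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            for sid in list(r.reactants) + list(r.products):
                if sid not in known:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references unknown species {sid!r}"
                    )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            species=[replace(s) for s in self.species],
            reactions=[
                replace(r, reactants=dict(r.reactants), products=dict(r.products))
                for r in self.reactions
            ],
        )


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def _parse_side(text: str, rxn_id: str) -> dict[str, float]:
    text = text.strip()
    if not text:
        return {}
    coeffs: dict[str, float] = {}
    for term in text.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ModelParseError(f"reaction {rxn_id!r}: cannot parse term {term.strip()!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        sid = m.group(2)
        coeffs[sid] = coeffs.get(sid, 0.0) + coef
    return coeffs


def parse_equation(rxn_id: str, equation: str) -> Reaction:
    """Parse ``"2 A + B -> C"``; ``<->`` marks a reversible reaction."""
    if "<->" in equation:
        lhs, rhs = equation.split("<->", 1)
        reversible = True
    elif "->" in equation:
        lhs, rhs = equation.split("->", 1)
        reversible = False
    else:
        raise ModelParseError(f"reaction {rxn_id!r}: no arrow in equation {equation!r}")
    return Reaction(
        id=rxn_id,
        reactants=_parse_side(lhs, rxn_id),
        products=_parse_side(rhs, rxn_id),
        reversible=reversible,
    )


def load_reaction_table(source: str | Path | Iterable[str]) -> MetabolicModel:
    """Read the TSV dialect: columns ``reaction_id``, ``equation``."""
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = list(source)
    reactions: list[Reaction] = []
    species_ids: list[str] = []
    seen_species: set[str] = set()
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:  # allow "R1: eq" convenience form
            if ":" not in line:
                raise ModelParseError(f"line {lineno}: expected 'id<TAB>equation' or 'id: equation'")
            rid, eq = line.split(":", 1)
        else:
            rid, eq = parts[0], parts[1]
        rid = rid.strip()
        if rid.lower() == "reaction_id":  # header
            continue
        rxn = parse_equation(rid, eq.strip())
        reactions.append(rxn)
        for sid in list(rxn.reactants) + list(rxn.products):
            if sid not in seen_species:
                seen_species.add(sid)
                species_ids.append(sid)
    if not reactions:
        raise ModelValidationError("empty model: no reactions in table")
    return MetabolicModel(
        species=[Species(id=sid) for sid in species_ids],
        reactions=reactions,
    )


def model_to_table(model: MetabolicModel) -> str:
    """Serialize to the tabular dialect (canonical form: one TSV row per reaction)."""

    def fmt_coef(c: float) -> str:
        return "" if c == 1 else (f"{int(c)} " if float(c).is_integer() else f"{c} ")

    def fmt_side(coeffs: Mapping[str, float]) -> str:
        return " + ".join(f"{fmt_coef(c)}{sid}" for sid, c in coeffs.items())

    lines = []
    for r in model.reactions:
        arrow = "<->" if r.reversible else "->"
        lines.append(f"{r.id}\t{fmt_side(r.reactants)} {arrow} {fmt_side(r.products)}".rstrip())
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

_EXTERNAL_COMPARTMENTS = {"e", "ext", "extern", "external", "out", "outside"}


def load_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML Level 2/3 document.

    Species with ``boundaryCondition=True`` are clamped; species in an external
    compartment (or with a boundary condition) are flagged non-internal.
    """
    import libsbml

    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ModelParseError(f"SBML error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError("document contains no SBML model")

    species = []
    for sp in sbml_model.getListOfSpecies():
        boundary = bool(sp.getBoundaryCondition())
        external = boundary or sp.getCompartment().lower() in _EXTERNAL_COMPARTMENTS
        conc = sp.getInitialConcentration()
        if math.isnan(conc):
            amt = sp.getInitialAmount()
            conc = 0.0 if math.isnan(amt) else amt
        species.append(
            Species(
                id=sp.getId(),
                name=sp.getName() or "",
                internal=not external,
                clamped=boundary,
                initial_concentration=max(conc, 0.0) if not math.isnan(conc) else 0.0,
            )
        )

    reactions = []
    for rx in sbml_model.getListOfReactions():
        reactants: dict[str, float] = {}
        products: dict[str, float] = {}
        for ref in rx.getListOfReactants():
            reactants[ref.getSpecies()] = reactants.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        for ref in rx.getListOfProducts():
            products[ref.getSpecies()] = products.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        ub = math.inf
        fbc = rx.getPlugin("fbc")
        if fbc is not None and fbc.isSetUpperFluxBound():
            p = sbml_model.getParameter(fbc.getUpperFluxBound())
            if p is not None:
                ub = p.getValue()
        reactions.append(
            Reaction(
                id=rx.getId(),
                reactants=reactants,
                products=products,
                reversible=bool(rx.getReversible()),
                upper_bound=ub,
            )
        )
    if not species or not reactions:
        raise ModelValidationError("empty model: SBML document has no species or no reactions")
    return MetabolicModel(species=species, reactions=reactions)


def load_model(source: str | Path, fmt: str | None = None) -> MetabolicModel:
    """Read a model from SBML or from the tabular dialect.

    ``fmt`` may be ``"sbml"`` or ``"table"``; by default it is sniffed from
    the file suffix/content.
    """
    path = Path(source)
    if fmt is None:
        if path.suffix.lower() in {".xml", ".sbml"}:
            fmt = "sbml"
        else:
            head = path.read_text()[:200].lstrip()
            fmt = "sbml" if head.startswith("<?xml") or head.startswith("<sbml") else "table"
    if fmt == "sbml":
        return load_sbml(path)
    if fmt == "table":
        return load_reaction_table(path)
    raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def split_reversible(model: MetabolicModel) -> MetabolicModel:
    """Replace each reversible reaction by a forward copy (same id) and a
    backward copy (id + ``"_reverse"``, reactants/products swapped).

    Reaction count of the result = #irreversible + 2 * #reversible.
    """
    reactions: list[Reaction] = []
    for r in model.reactions:
        if not r.reversible:
            reactions.append(replace(r, reactants=dict(r.reactants), products=dict(r.products)))
            continue
        reactions.append(
            Reaction(id=r.id, reactants=dict(r.reactants), products=dict(r.products),
                     reversible=False, upper_bound=r.upper_bound)
        )
        reactions.append(
            Reaction(id=r.id + REVERSE_SUFFIX, reactants=dict(r.products),
                     products=dict(r.reactants), reversible=False, upper_bound=r.upper_bound)
        )
    return MetabolicModel(species=[replace(s) for s in model.species], reactions=reactions)


def build_matrices(model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
    """Build the signed stoichiometric matrix S and reactant-order matrix A.

    Both are dense ``(n_species, n_reactions)``; ``S[w, i]`` is the net
    coefficient of species w in reaction i and ``A[w, i]`` the reactant-side
    coefficient used as the kinetic order in the mass-action rate.
    """
    if not model.is_irreversible:
        raise ModelValidationError("build_matrices requires an irreversible (split) model")
    idx = model.species_index()
    S = np.zeros((model.n_species, model.n_reactions))
    A = np.zeros_like(S)
    for j, r in enumerate(model.reactions):
        for sid, c in r.reactants.items():
            S[idx[sid], j] -= c
            A[idx[sid], j] += c
        for sid, c in r.products.items():
            S[idx[sid], j] += c
    return S, A


def load_concentrations(
    model: MetabolicModel,
    table: Mapping[str, float] | str | Path,
    clamped: Iterable[str] | str | Path = (),
) -> MetabolicModel:
    """Return a copy of ``model`` with initial concentrations and clamp flags.

    ``table`` maps species ids to non-negative concentrations (or is a TSV
    path with columns ``species_id``, ``concentration``).  Species without a
    listed value receive the mean of the listed values.  ``clamped`` is an
    iterable of species ids (or a path with one id per line).
    """
    if isinstance(table, (str, Path)):
        conc: dict[str, float] = {}
        for line in Path(table).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, _, val = line.partition("\t")
            if sid.strip().lower() == "species_id":
                continue
            conc[sid.strip()] = float(val)
    else:
        conc = dict(table)
    if isinstance(clamped, (str, Path)):
        clamp_set = {
            ln.strip() for ln in Path(clamped).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        }
    else:
        clamp_set = set(clamped)

    for sid, val in conc.items():
        if val < 0:
            raise ModelValidationError(f"negative concentration {val} for species {sid!r}")
    known = set(model.species_ids)
    unknown = clamp_set - known
    if unknown:
        raise ModelValidationError(f"clamped species not in model: {sorted(unknown)}")

    listed = [conc[s.id] for s in model.species if s.id in conc]
    fallback = float(np.mean(listed)) if listed else 0.0

    out = model.copy()
    for s in out.species:
        if conc:  # empty table: keep the model's own concentrations
            s.initial_concentration = conc.get(s.id, fallback)
        if s.id in clamp_set:
            s.clamped = True
    return out
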
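"""Synthetic models and datasets with known closed-form behavior.

Three generators make every pipeline stage testable without any external
model file:

* linear chains with a clamped source, whose steady state and throughput are
  analytic (the end-to-end oracle for the ODE and flux stages);
* a synthetic "marker network" carrying the phenotype filter reactions, wired
  so each growth condition's FBA optimum satisfies exactly its own filter;
* planted flux tables and per-condition samples with known memberships and
  known KS-relevant reactions.

Fixture randomness lives in its own seed namespace (plain ``default_rng``
seeds), never the sampling module's spawn scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import MetabolicModel, Reaction, Species, split_reversible

__all__ = [
    "ChainSpec",
    "make_linear_chain",
    "marker_network",
    "condition_feeds",
    "MARKER_FBA_OPTIMA",
    "make_phenotype_fixture",
    "make_ks_fixture",
]


# ---------------------------------------------------------------------------
# linear chains
# ---------------------------------------------------------------------------

@dataclass
class ChainSpec:
    """Chain X0 (clamped) -> X1 -> ... -> Xn -> sink with rates k1..k_{n+1}.

    The steady state is analytic: throughput J = k1 * X0 and [Xi] = J / k_{i+1}
    (for all rates positive).
    """

    n: int
    source_concentration: float = 1.0
    k: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"chain length must be >= 1, got {self.n}")
        if not self.k:
            self.k = tuple([1.0] * (self.n + 1))
        if len(self.k) != self.n + 1:
            raise ValueError(
                f"chain of length {self.n} needs {self.n + 1} rate constants, got {len(self.k)}"
            )


def make_linear_chain(
    spec: ChainSpec,
) -> tuple[MetabolicModel, dict[str, float], dict[str, float]]:
    """Build the chain model plus its analytic fixed point and fluxes.

    Returns ``(model, steady_concentrations, steady_fluxes)``.  When some
    internal rate constant is zero the fixed point does not exist (the species
    upstream of the dead step accumulates linearly) and the returned steady
    maps are empty.
    """
    n = spec.n
    species = [Species(id="X0", clamped=True, internal=False,
                       initial_concentration=spec.source_concentration)]
    species += [Species(id=f"X{i}", initial_concentration=0.0) for i in range(1, n + 1)]
    reactions = [Reaction(id="R1", reactants={"X0": 1}, products={"X1": 1})]
    for i in range(2, n + 1):
        reactions.append(Reaction(id=f"R{i}", reactants={f"X{i-1}": 1},
                                  products={f"X{i}": 1}))
    reactions.append(Reaction(id=f"R{n+1}", reactants={f"X{n}": 1}, products={}))
    model = MetabolicModel(species=species, reactions=reactions)

    if any(ki <= 0 for ki in spec.k[1:]):
        return model, {}, {}
    J = spec.k[0] * spec.source_concentration
    conc = {"X0": spec.source_concentration}
    conc.update({f"X{i}": J / spec.k[i] for i in range(1, n + 1)})
    flux = {f"R{i}": J for i in range(1, n + 2)}
    return model, conc, flux


# ---------------------------------------------------------------------------
# marker network
# ---------------------------------------------------------------------------

_FEED_SPECIES = ("glc_ex", "ac_ex", "succ_ex", "glyc_ex", "o2_ex")
FEED_CONCENTRATION = 10.0

#: hand-derived biomass optima of the marker network per condition
MARKER_FBA_OPTIMA = {"exp0": 50.0, "exp1": 20.0, "exp2": 10.0,
                     "exp3": 10.0, "exp4": 10.0, "exp5": 10.0}


def marker_network(split: bool = True) -> MetabolicModel:
    """Synthetic network carrying the phenotype marker reactions.

    Each condition's carbon source funnels into biomass through its own
    marker reactions; oxygen exchange is reversible (split into O2Up and
    O2Up_reverse) and overflow exports give every internal species a linear
    sink, so a mass-action steady state exists for generic positive rates.
    The topology is synthetic — it is not the compressed E. coli core, only a
    minimal network on which the same filters are self-consistent with FBA.
    """
    ext = [Species(id=s, clamped=True, internal=False,
                   initial_concentration=FEED_CONCENTRATION) for s in _FEED_SPECIES]
    internal_ids = [
        "glc_c", "g6p", "pgl_m", "pgc", "x5p", "acald", "ac_i", "etoh",
        "ac_c", "accoa", "glx", "succ_c", "succ_p", "glyc_c", "g3p_m",
        "dha", "f6p", "o2_c", "biomass_m",
    ]
    species = ext + [Species(id=s, initial_concentration=1.0) for s in internal_ids]

    def rxn(rid, reactants, products, reversible=False):
        return Reaction(id=rid, reactants=reactants, products=products,
                        reversible=reversible)

    reactions = [
        # condition-defining exchanges
        rxn("GlcUp", {"glc_ex": 1}, {"glc_c": 1}),
        rxn("AcUp", {"ac_ex": 1}, {"ac_c": 1}),
        rxn("SuccUp", {"succ_ex": 1}, {"succ_c": 1}),
        rxn("GlycUp", {"glyc_ex": 1}, {"glyc_c": 1}),
        rxn("O2Up", {"o2_ex": 1}, {"o2_c": 1}, reversible=True),
        # aerobic glucose route (exp1 markers)
        rxn("GLCptspp", {"glc_c": 1}, {"g6p": 1}),
        rxn("G6PDH2r", {"g6p": 1}, {"pgl_m": 1}),
        rxn("PGL", {"pgl_m": 1}, {"pgc": 1}),
        rxn("GND", {"pgc": 1}, {"x5p": 1}),
        rxn("RespG", {"x5p": 1, "o2_c": 1}, {"biomass_m": 2}),
        # fermentation route (exp2 markers)
        rxn("FERM", {"g6p": 1}, {"acald": 1, "ac_i": 1, "biomass_m": 1}),
        rxn("ALCD2x", {"acald": 1}, {"etoh": 1}),
        rxn("EthEx", {"etoh": 1}, {}),
        rxn("AcEx", {"ac_i": 1}, {}),
        # acetate route (exp3 markers)
        rxn("ACS", {"ac_c": 1}, {"accoa": 1}),
        rxn("ICL", {"accoa": 1}, {"glx": 1}),
        rxn("MALS", {"glx": 1, "o2_c": 1}, {"biomass_m": 1}),
        # succinate route (exp4 markers)
        rxn("SUCCt2_2pp", {"succ_c": 1}, {"succ_p": 1}),
        rxn("ME2", {"succ_p": 1, "o2_c": 1}, {"biomass_m": 1}),
        # glycerol route (exp5 markers) — biomass needs both branches
        rxn("GLYK", {"glyc_c": 1}, {"g3p_m": 1}),
        rxn("GLYCDx", {"glyc_c": 1}, {"dha": 1}),
        rxn("F6PA", {"dha": 1}, {"f6p": 1}),
        rxn("BM5", {"g3p_m": 1, "f6p": 1, "o2_c": 2}, {"biomass_m": 2}),
        # overflow valves: linear sinks so mismatched branches still settle
        rxn("X5PEx", {"x5p": 1}, {}),
        rxn("GLXEx", {"glx": 1}, {}),
        rxn("SUCCPEx", {"succ_p": 1}, {}),
        rxn("G3PEx", {"g3p_m": 1}, {}),
        rxn("F6PEx", {"f6p": 1}, {}),
        # growth sink
        rxn("BIOMASS", {"biomass_m": 1}, {}),
    ]
    model = MetabolicModel(species=species, reactions=reactions)
    return split_reversible(model) if split else model


def condition_feeds(condition_id: str) -> dict[str, float]:
    """Clamped feed concentrations of the marker network per condition."""
    carbon = {"exp1": "glc_ex", "exp2": "glc_ex", "exp3": "ac_ex",
              "exp4": "succ_ex", "exp5": "glyc_ex"}
    feeds = {s: 0.0 for s in _FEED_SPECIES}
    if condition_id == "exp0":
        feeds = {s: FEED_CONCENTRATION for s in _FEED_SPECIES}
        return feeds
    if condition_id not in carbon:
        raise ValueError(f"unknown condition {condition_id!r}")
    feeds[carbon[condition_id]] = FEED_CONCENTRATION
    feeds["o2_ex"] = 0.0 if condition_id == "exp2" else FEED_CONCENTRATION
    return feeds


# ---------------------------------------------------------------------------
# planted phenotype fixture
# ---------------------------------------------------------------------------

_MARKERS: dict[str, tuple[str, ...]] = {
    "exp1": ("G6PDH2r", "GND", "PGL", "GLCptspp"),
    "exp2": ("AcEx", "ALCD2x", "EthEx", "GLCptspp"),
    "exp3": ("MALS", "ICL", "AcUp"),
    "exp4": ("SUCCt2_2pp", "ME2"),
    "exp5": ("GLYK", "F6PA", "GLYCDx"),
}
_AEROBIC = ("exp1", "exp3", "exp4", "exp5")
_ALL_MARKER_COLUMNS = tuple(
    dict.fromkeys([m for ms in _MARKERS.values() for m in ms] + ["O2Up"])
)


def _plant_vector(rng: np.random.Generator, membership: frozenset[str]) -> dict[str, float]:
    if "exp2" in membership and membership & set(_AEROBIC):
        raise ValueError(
            f"impossible combination {sorted(membership)}: exp2 requires zero "
            "oxygen uptake while aerobic phenotypes require it positive"
        )
    v = {m: 0.0 for m in _ALL_MARKER_COLUMNS}
    if "exp2" in membership:
        v["O2Up"] = 0.0
    elif membership:
        v["O2Up"] = float(rng.uniform(1.0, 20.0))
    else:
        # empty membership: oxygen present but every phenotype misses a marker
        v["O2Up"] = float(rng.uniform(1.0, 20.0)) if rng.random() < 0.5 else 0.0
    for e in membership:
        for m in _MARKERS[e]:
            v[m] = float(rng.uniform(0.5, 10.0))
    return v


_DEFAULT_COMBOS: tuple[frozenset[str], ...] = tuple(
    frozenset(c) for c in (
        (), ("exp1",), ("exp2",), ("exp3",), ("exp4",), ("exp5",),
        ("exp1", "exp3", "exp4", "exp5"),   # the all-aerobic subset
        ("exp3", "exp4"), ("exp1", "exp5"),
    )
)


def make_phenotype_fixture(
    seed: int,
    n_records: int,
    combos: tuple[frozenset[str], ...] | None = None,
) -> tuple[pd.DataFrame, list[set[str]]]:
    """Synthetic flux table over the marker reactions with planted memberships.

    Cycles through ``combos`` (defaults include singletons, the empty set and
    the all-aerobic intersection).  Requesting a combination that mixes exp2
    with an aerobic phenotype raises — such ensembles are structurally empty.
    Returns the flux table and the ground-truth membership per record.
    """
    rng = np.random.default_rng(seed)
    combos = _DEFAULT_COMBOS if combos is None else combos
    for c in combos:  # refuse impossible plants up front
        if "exp2" in c and set(c) & set(_AEROBIC):
            raise ValueError(
                f"impossible combination {sorted(c)}: exp2 requires zero "
                "oxygen uptake while aerobic phenotypes require it positive"
            )
    rows, truth = [], []
    for i in range(n_records):
        combo = combos[i % len(combos)]
        rows.append(_plant_vector(rng, combo))
        truth.append(set(combo))
    return pd.DataFrame(rows, columns=list(_ALL_MARKER_COLUMNS)), truth


# ---------------------------------------------------------------------------
# KS fixture
# ---------------------------------------------------------------------------

def make_ks_fixture(
    seed: int, effect_size: float, n: int
) -> tuple[dict[str, pd.DataFrame], set[str]]:
    """Per-condition flux samples with planted KS-relevant reactions.

    ``REL1``/``REL2`` are separated by ``effect_size`` standard deviations
    between every pair of the five conditions; ``PART`` differs in only one
    condition; ``NULL1``/``NULL2`` are identically distributed everywhere.
    Ground truth is {REL1, REL2} for a positive effect size, empty otherwise.
    """
    if n < 10:
        raise ValueError(f"need n >= 10 samples per condition, got {n}")
    rng = np.random.default_rng(seed)
    conditions = [f"exp{i}" for i in range(1, 6)]
    samples: dict[str, pd.DataFrame] = {}
    for ci, cid in enumerate(conditions):
        df = pd.DataFrame({
            "REL1": rng.normal(ci * effect_size, 1.0, n),
            "REL2": rng.normal(-ci * effect_size, 1.0, n),
            "PART": rng.normal(effect_size if ci == 0 else 0.0, 1.0, n),
            "NULL1": rng.normal(0.0, 1.0, n),
            "NULL2": rng.normal(5.0, 2.0, n),
        })
        samples[cid] = df
    truth = {"REL1", "REL2"} if effect_size > 0 else set()
    return samples, truth
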
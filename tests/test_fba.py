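import math
from itertools import combinations, product

import numpy as np
import pytest

from kinens.fba import (
    CONDITIONS,
    FBAResult,
    condition_bounds,
    derive_filter_targets,
    run_fba,
)
from kinens.flux import FluxDistribution, threshold_fluxes
from kinens.model_io import MetabolicModel, Reaction, Species, build_matrices, load_reaction_table
from kinens.phenotype_filters import assign, builtin_filters
from kinens.synthetic_fixtures import MARKER_FBA_OPTIMA, marker_network


def enumerate_lp_max(c, A_eq, ub):
    """Brute-force LP oracle: enumerate basic solutions of
    max c.v s.t. A_eq v = 0, 0 <= v <= ub (all ub finite)."""
    n = len(c)
    r = np.linalg.matrix_rank(A_eq) if A_eq.size else 0
    best = -math.inf
    for basic in combinations(range(n), r):
        nonbasic = [j for j in range(n) if j not in basic]
        AB = A_eq[:, list(basic)]
        if r and np.linalg.matrix_rank(AB) < r:
            continue
        for vals in product(*[(0.0, ub[j]) for j in nonbasic]):
            v = np.zeros(n)
            v[nonbasic] = vals
            if r:
                vB, *_ = np.linalg.lstsq(AB, -A_eq[:, nonbasic] @ np.asarray(vals), rcond=None)
                v[list(basic)] = vB
            if (np.allclose(A_eq @ v, 0, atol=1e-9)
                    and (v >= -1e-9).all() and (v <= ub + 1e-9).all()):
                best = max(best, float(c @ v))
    return best


class TestRunFBA:
    def test_hand_solvable_chain(self):
        m = load_reaction_table(["Up\t -> A", "Obj\tA -> "])
        m.reactions[0].upper_bound = 10.0
        res = run_fba(m, objective="Obj")
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(10.0)

    def test_all_uptakes_closed_means_zero_growth(self, marker_model):
        bounds = condition_bounds("exp1")
        bounds.upper_bounds = {rid: 0.0 for rid in
                               ("GlcUp", "AcUp", "SuccUp", "GlycUp", "O2Up")}
        res = run_fba(marker_model, bounds)
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_vertex_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_sp, n_rx = 3, 6
        species = [Species(id=f"S{i}") for i in range(n_sp)]
        reactions = []
        for j in range(n_rx):
            lhs = {f"S{rng.integers(n_sp)}": 1} if rng.random() < 0.8 else {}
            rhs = {f"S{rng.integers(n_sp)}": 1} if rng.random() < 0.8 else {}
            if lhs == rhs:
                rhs = {}
            if not lhs and not rhs:
                lhs = {"S0": 1}
            reactions.append(Reaction(id=f"R{j}", reactants=lhs, products=rhs,
                                      upper_bound=float(rng.integers(1, 8))))
        model = MetabolicModel(species=species, reactions=reactions)
        res = run_fba(model, objective="R0")
        S, _ = build_matrices(model)
        ub = np.array([r.upper_bound for r in model.reactions])
        c = np.zeros(n_rx)
        c[0] = 1.0
        expected = enumerate_lp_max(c, S, ub)
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(expected, abs=1e-8)

    def test_objective_invariant_under_reordering(self, marker_model):
        res = run_fba(marker_model, condition_bounds("exp1"))
        rng = np.random.default_rng(5)
        sp = [marker_model.species[i] for i in rng.permutation(marker_model.n_species)]
        rx = [marker_model.reactions[i] for i in rng.permutation(marker_model.n_reactions)]
        shuffled = MetabolicModel(species=sp, reactions=rx)
        res2 = run_fba(shuffled, condition_bounds("exp1"))
        assert res2.objective_value == pytest.approx(res.objective_value)

    def test_requires_split_model(self):
        m = load_reaction_table(["R\tA <-> B", "Obj\tB -> "])
        with pytest.raises(ValueError, match="split"):
            run_fba(m, objective="Obj")

    def test_unknown_objective_rejected(self, marker_model):
        with pytest.raises(ValueError, match="objective"):
            run_fba(marker_model, objective="NOPE")


class TestConditionBounds:
    def test_glucose_aerobic_opens_only_glucose(self):
        b = condition_bounds("exp1")
        assert b.upper_bounds["GlcUp"] == 10.0
        assert b.upper_bounds["AcUp"] == 0.0
        assert b.upper_bounds["SuccUp"] == 0.0
        assert b.upper_bounds["GlycUp"] == 0.0
        assert "O2Up" not in b.upper_bounds  # oxygen unconstrained

    def test_anaerobic_closes_oxygen(self):
        b = condition_bounds("exp2")
        assert b.upper_bounds["GlcUp"] == 10.0 and b.upper_bounds["O2Up"] == 0.0

    def test_succinate_condition(self):
        b = condition_bounds("exp4")
        assert b.upper_bounds["SuccUp"] == 10.0 and b.upper_bounds["GlcUp"] == 0.0

    def test_rich_medium_opens_every_carbon_source(self):
        b = condition_bounds("exp0")
        assert all(b.upper_bounds[c] == 10.0
                   for c in ("GlcUp", "AcUp", "SuccUp", "GlycUp"))

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="unknown condition"):
            condition_bounds("exp9")


class TestMarkerNetworkGrowth:
    def test_growth_rates_match_hand_derived_optima(self, marker_model):
        for cid, mu in MARKER_FBA_OPTIMA.items():
            res = run_fba(marker_model, condition_bounds(cid))
            assert res.status == "optimal"
            assert res.objective_value == pytest.approx(mu, abs=1e-6), cid

    def test_growth_rates_cross_checked_with_cobra(self, marker_model):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("synthetic-markers")
        mets = {s.id: cobra.Metabolite(s.id) for s in marker_model.species
                if s.internal and not s.clamped}
        rxns = []
        for r in marker_model.reactions:
            rx = cobra.Reaction(r.id)
            rx.lower_bound = 0.0
            rx.upper_bound = r.upper_bound if math.isfinite(r.upper_bound) else 1e6
            rxns.append(rx)
        cm.add_reactions(rxns)
        for r, rx in zip(marker_model.reactions, rxns):
            stoich = {}
            for sid, c in r.reactants.items():
                if sid in mets:
                    stoich[mets[sid]] = stoich.get(mets[sid], 0.0) - c
            for sid, c in r.products.items():
                if sid in mets:
                    stoich[mets[sid]] = stoich.get(mets[sid], 0.0) + c
            rx.add_metabolites(stoich)
        cm.objective = "BIOMASS"
        for cid in CONDITIONS:
            b = condition_bounds(cid)
            with cm as scoped:
                for rid, ubv in b.upper_bounds.items():
                    scoped.reactions.get_by_id(rid).upper_bound = ubv
                sol = scoped.optimize()
            mine = run_fba(marker_model, b)
            assert sol.status == "optimal"
            assert mine.objective_value == pytest.approx(sol.objective_value, abs=1e-6)

    def test_each_condition_vector_satisfies_its_own_filter(self, marker_model):
        filters = builtin_filters()
        for cid in ("exp1", "exp2", "exp3", "exp4", "exp5"):
            res = run_fba(marker_model, condition_bounds(cid))
            fd = threshold_fluxes(FluxDistribution(res.flux_vector,
                                                   res.reaction_ids, condition_id=cid))
            assert assign(fd, filters) == {cid}


def _fake_results(table, conditions):
    return {
        cid: FBAResult(objective_value=1.0,
                       flux_vector=np.array([table[rid][i] for rid in table]),
                       reaction_ids=list(table), status="optimal", condition_id=cid)
        for i, cid in enumerate(conditions)
    }


class TestDeriveFilterTargets:
    CONDS = ["exp1", "exp2", "exp3", "exp4", "exp5"]

    def test_planted_single_condition_reactions_recovered(self):
        table = {
            "G6PDH2r": [4.142, 0, 0, 0, 0],     # class A, exp1
            "MALS":    [0, 0, 2.627, 0, 0],     # class A, exp3
            "PGI":     [3.0, 1.0, 0, 0, 0],     # active twice -> excluded
            "ATPM":    [1, 1, 1, 1, 1],         # active everywhere -> excluded
            "DEAD":    [0, 0, 0, 0, 0],         # never active -> excluded
            "GlcUp":   [10, 10, 0, 0, 0],       # class B by configuration
        }
        out = derive_filter_targets(
            _fake_results(table, self.CONDS),
            condition_defining={"exp1": ("GlcUp",)},
        )
        assert out.loc["G6PDH2r", "class"] == "A" and out.loc["G6PDH2r", "condition"] == "exp1"
        assert out.loc["MALS", "class"] == "A" and out.loc["MALS", "condition"] == "exp3"
        assert out.loc["GlcUp", "class"] == "B"
        for rid in ("PGI", "ATPM", "DEAD"):
            assert out.loc[rid, "class"] == ""

    def test_bruteforce_scan_agrees_on_random_tables(self):
        rng = np.random.default_rng(4)
        reactions = [f"R{i}" for i in range(30)]
        table = {rid: list(np.where(rng.random(5) < 0.4, rng.uniform(1, 5, 5), 0.0))
                 for rid in reactions}
        out = derive_filter_targets(_fake_results(table, self.CONDS),
                                    condition_defining={})
        for rid in reactions:
            active = [c for c, v in zip(self.CONDS, table[rid]) if v >= 1e-10]
            if len(active) == 1:
                assert out.loc[rid, "class"] == "A"
                assert out.loc[rid, "condition"] == active[0]
            else:
                assert out.loc[rid, "class"] == ""

    def test_sub_threshold_flux_counts_as_zero(self):
        table = {"R1": [5e-11, 0, 0, 0, 2.0], "R2": [1.0, 0, 0, 0, 0]}
        out = derive_filter_targets(_fake_results(table, self.CONDS),
                                    condition_defining={})
        assert out.loc["R1", "class"] == "A" and out.loc["R1", "condition"] == "exp5"

    def test_non_optimal_input_rejected(self):
        res = _fake_results({"R1": [1, 0, 0, 0, 0]}, self.CONDS)
        res["exp2"].status = "infeasible"
        with pytest.raises(ValueError, match="optimal"):
            derive_filter_targets(res, condition_defining={})

    def test_degeneracy_check_on_marker_network(self, marker_model):
        results = {cid: run_fba(marker_model, condition_bounds(cid))
                   for cid in self.CONDS}
        out = derive_filter_targets(results, model=marker_model,
                                    check_degeneracy=True)
        # exp1's optimum is forced through the oxidative route: its markers
        # are class A and unambiguously non-zero there
        for rid in ("G6PDH2r", "GND", "PGL"):
            assert out.loc[rid, "class"] == "A"
            assert not out.loc[rid, "degenerate"]
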
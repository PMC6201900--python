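import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinens.model_io import (
    MetabolicModel,
    ModelParseError,
    ModelValidationError,
    Reaction,
    Species,
    build_matrices,
    load_concentrations,
    load_model,
    load_reaction_table,
    load_sbml,
    model_to_table,
    split_reversible,
)


class TestTabularDialect:
    def test_simple_reaction(self):
        m = load_reaction_table(["R1: A + B -> C"])
        assert m.n_species == 3 and m.n_reactions == 1
        assert not m.reactions[0].reversible
        assert m.reactions[0].reactants == {"A": 1.0, "B": 1.0}
        assert m.reactions[0].products == {"C": 1.0}

    def test_coefficients_and_reversible(self):
        m = load_reaction_table(["R1\t2 A + B <-> C"])
        assert m.reactions[0].reversible
        assert m.reactions[0].reactants == {"A": 2.0, "B": 1.0}

    def test_exchange_sides_may_be_empty(self):
        m = load_reaction_table(["Up\t -> A", "Ex\tA -> "])
        assert m.reactions[0].reactants == {} and m.reactions[1].products == {}

    def test_duplicate_reaction_id_rejected(self):
        with pytest.raises(ModelValidationError, match="duplicate reaction id"):
            load_reaction_table(["R1: A -> B", "R1: B -> C"])

    def test_empty_model_rejected(self):
        with pytest.raises(ModelValidationError, match="empty model"):
            load_reaction_table([])

    def test_missing_arrow_is_parse_error(self):
        with pytest.raises(ModelParseError):
            load_reaction_table(["R1\tA + B C"])

    def test_roundtrip_is_identity_on_canonical_form(self):
        text = "R1\t2 A + B -> C\nR2\tC <-> D\nUp\t -> A\n"
        m = load_reaction_table(text.splitlines())
        assert model_to_table(m) == text

    def test_load_model_sniffs_table(self, tmp_path):
        p = tmp_path / "toy.tsv"
        p.write_text("R1\tA -> B\n")
        assert load_model(p).n_reactions == 1


class TestSplitReversible:
    def test_named_forward_backward_pair(self):
        m = load_reaction_table(["PGM: A <-> B"])
        s = split_reversible(m)
        assert s.reaction_ids == ["PGM", "PGM_reverse"]
        fwd, rev = s.reactions
        assert fwd.reactants == rev.products and fwd.products == rev.reactants
        assert s.is_irreversible

    def test_irreversible_model_is_fixed_point(self):
        m = load_reaction_table(["R1: A -> B", "R2: B -> C"])
        s = split_reversible(m)
        assert s.reaction_ids == m.reaction_ids
        assert [r.reactants for r in s.reactions] == [r.reactants for r in m.reactions]

    def test_count_formula(self):
        m = load_reaction_table(
            ["R1: A -> B", "R2: B -> C", "R3: C -> A", "R4: A <-> C", "R5: B <-> A"]
        )
        assert split_reversible(m).n_reactions == 3 + 2 * 2


@st.composite
def random_models(draw):
    n_sp = draw(st.integers(2, 6))
    ids = [f"S{i}" for i in range(n_sp)]
    n_rx = draw(st.integers(1, 8))
    reactions = []
    for j in range(n_rx):
        lhs = draw(st.dictionaries(st.sampled_from(ids), st.integers(1, 3), max_size=3))
        rhs = draw(st.dictionaries(st.sampled_from(ids), st.integers(1, 3), max_size=3))
        if not lhs and not rhs:
            lhs = {ids[0]: 1}
        reactions.append(Reaction(id=f"R{j}", reactants=lhs, products=rhs,
                                  reversible=draw(st.booleans())))
    return MetabolicModel(species=[Species(id=s) for s in ids], reactions=reactions)


@given(random_models())
@settings(max_examples=50, deadline=None, derandomize=True)
def test_split_and_matrices_properties(model):
    """Column count follows the split formula; A >= 0; every S column equals
    product-minus-reactant coefficients of its reaction."""
    n_rev = sum(r.reversible for r in model.reactions)
    s = split_reversible(model)
    assert s.n_reactions == (model.n_reactions - n_rev) + 2 * n_rev
    S, A = build_matrices(s)
    assert S.shape == (s.n_species, s.n_reactions) and A.shape == S.shape
    assert (A >= 0).all()
    idx = s.species_index()
    for j, r in enumerate(s.reactions):
        expected = np.zeros(s.n_species)
        for sid, c in r.products.items():
            expected[idx[sid]] += c
        for sid, c in r.reactants.items():
            expected[idx[sid]] -= c
            assert A[idx[sid], j] == c
        assert np.array_equal(S[:, j], expected)


class TestMatrices:
    def test_unimolecular_columns(self):
        m = load_reaction_table(["R: A -> B"])
        S, A = build_matrices(m)
        assert list(S[:, 0]) == [-1, 1] and list(A[:, 0]) == [1, 0]

    def test_order_two_reactant(self):
        m = load_reaction_table(["R: 2 A -> B"])
        S, A = build_matrices(m)
        ia = m.species_index()["A"]
        assert S[ia, 0] == -2 and A[ia, 0] == 2

    def test_requires_split_model(self):
        m = load_reaction_table(["R: A <-> B"])
        with pytest.raises(ModelValidationError, match="irreversible"):
            build_matrices(m)

    def test_unknown_species_rejected(self):
        with pytest.raises(ModelValidationError, match="unknown species"):
            MetabolicModel(
                species=[Species(id="A")],
                reactions=[Reaction(id="R", reactants={"A": 1}, products={"Z": 1})],
            )


class TestConcentrations:
    def test_missing_species_get_mean_of_listed(self):
        m = load_reaction_table(["R1: A + B -> C"])
        out = load_concentrations(m, {"A": 1.0, "B": 3.0})
        assert out.get_species("C").initial_concentration == pytest.approx(2.0)

    def test_all_listed_is_noop_substitution(self):
        m = load_reaction_table(["R1: A -> B"])
        out = load_concentrations(m, {"A": 1.5, "B": 0.5})
        assert [s.initial_concentration for s in out.species] == [1.5, 0.5]

    def test_negative_concentration_rejected(self):
        m = load_reaction_table(["R1: A -> B"])
        with pytest.raises(ModelValidationError, match="negative concentration"):
            load_concentrations(m, {"A": -1.0})

    def test_unknown_clamped_id_rejected(self):
        m = load_reaction_table(["R1: A -> B"])
        with pytest.raises(ModelValidationError, match="clamped species not in model"):
            load_concentrations(m, {"A": 1.0}, clamped=["Z"])

    def test_clamped_flags_and_tsv_inputs(self, tmp_path):
        m = load_reaction_table(["R1: A -> B"])
        conc = tmp_path / "conc.tsv"
        conc.write_text("species_id\tconcentration\nA\t2.0\n")
        clamp = tmp_path / "clamped.txt"
        clamp.write_text("A\n")
        out = load_concentrations(m, conc, clamp)
        a = out.get_species("A")
        assert a.clamped and a.initial_concentration == 2.0
        assert out.get_species("B").initial_concentration == 2.0  # mean fallback


def _write_tiny_sbml(path):
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    m = doc.createModel()
    m.setId("toy")
    for cid in ("c", "e"):
        comp = m.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
        comp.setSize(1.0)
    for sid, comp, boundary, conc in [("A", "c", False, 1.0),
                                      ("B", "c", False, 0.5),
                                      ("X", "e", True, 2.0)]:
        s = m.createSpecies()
        s.setId(sid)
        s.setCompartment(comp)
        s.setBoundaryCondition(boundary)
        s.setHasOnlySubstanceUnits(False)
        s.setConstant(False)
        s.setInitialConcentration(conc)
    for rid, lhs, rhs, rev in [("R1", "X", "A", True), ("R2", "A", "B", False)]:
        r = m.createReaction()
        r.setId(rid)
        r.setReversible(rev)
        r.setFast(False)
        sr = r.createReactant()
        sr.setSpecies(lhs)
        sr.setStoichiometry(1.0)
        sr.setConstant(True)
        sp = r.createProduct()
        sp.setSpecies(rhs)
        sp.setStoichiometry(1.0)
        sp.setConstant(True)
    assert libsbml.writeSBMLToFile(doc, str(path)) == 1


class TestSBML:
    def test_parse_species_reactions_flags(self, tmp_path):
        p = tmp_path / "toy.xml"
        _write_tiny_sbml(p)
        m = load_model(p)
        assert m.n_species == 3 and m.n_reactions == 2
        x = m.get_species("X")
        assert x.clamped and not x.internal and x.initial_concentration == 2.0
        assert m.get_species("A").internal
        assert m.reactions[0].reversible and not m.reactions[1].reversible
        s = split_reversible(m)
        assert s.n_reactions == 3 and "R1_reverse" in s.reaction_ids

    def test_malformed_document_raises_parse_error(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<?xml version='1.0'?><sbml><oops></sbml>")
        with pytest.raises((ModelParseError, ModelValidationError)):
            load_model(p)
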
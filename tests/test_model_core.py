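"""Universe/environment/annotation readers, writers and invariant checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fluxmod as fm
from fluxmod import model_core as mc


def write_model(tmp_path, reactions, metabolites):
    tmp_path.mkdir(parents=True, exist_ok=True)
    (tmp_path / "reactions.tsv").write_text(
        "reaction_id\tequation\trole\tswappable\n"
        + "".join("\t".join(r) + "\n" for r in reactions))
    (tmp_path / "metabolites.tsv").write_text(
        "metabolite_id\texternal\n"
        + "".join("\t".join(m) + "\n" for m in metabolites))
    return tmp_path


MINIMAL_METS = [("A_ext", "1"), ("B", "0")]
MINIMAL_RXNS = [
    ("EX_A", "A_ext =>", "exchange", "0"),
    ("R1", "A_ext => B", "metabolic", "1"),
    ("BIOMASS", "B =>", "biomass", "0"),
]


class TestEquationGrammar:
    @pytest.mark.parametrize(
        "eq, subs, prods, rev",
        [
            ("A_ext => B", [(1.0, "A_ext")], [(1.0, "B")], False),
            ("2 A + B <=> C", [(2.0, "A"), (1.0, "B")], [(1.0, "C")], True),
            ("A =>", [(1.0, "A")], [], False),
            ("0.5 A => B", [(0.5, "A")], [(1.0, "B")], False),
        ],
    )
    def test_parse(self, eq, subs, prods, rev):
        assert mc.parse_equation(eq) == (subs, prods, rev)

    @pytest.mark.parametrize("eq", ["A - B", "A + => B", "-1 A => B"])
    def test_malformed(self, eq):
        with pytest.raises(mc.MalformedEquationError):
            mc.parse_equation(eq)

    def test_format_is_inverse_and_canonical(self):
        subs, prods, rev = mc.parse_equation("B + 2 A <=> C")
        assert mc.format_equation(subs, prods, rev) == "2 A + B <=> C"


class TestReadUniverse:
    def test_single_reaction_transcription(self, tmp_path):
        universe = mc.read_universe(write_model(tmp_path, MINIMAL_RXNS, MINIMAL_METS))
        assert universe.n_reactions == 3
        j = universe.reaction_index["R1"]
        col = universe.S.getcol(j).toarray().ravel()
        assert col[universe.metabolite_index["A_ext"]] == -1
        assert col[universe.metabolite_index["B"]] == 1
        assert not universe.reversible[j]
        assert universe.swappable[j]

    def test_biomass_precursors_from_equation(self, tmp_path):
        universe = mc.read_universe(write_model(tmp_path, MINIMAL_RXNS, MINIMAL_METS))
        assert universe.biomass_precursors == {"B": 1.0}

    @pytest.mark.parametrize(
        "mutate, error",
        [
            (lambda r, m: (r + [("R1", "A_ext => B", "metabolic", "1")], m),
             mc.DuplicateIdentifierError),
            (lambda r, m: ([("EX_A", "A_ext =>", "exchange", "0"),
                            ("R1", "A_ext => Z", "metabolic", "1"),
                            ("BIOMASS", "B =>", "biomass", "0")], m),
             mc.UnknownMetaboliteError),
            (lambda r, m: (r[:2], m), mc.MissingBiomassError),
            (lambda r, m: ([("EX_A", "A_ext B", "exchange", "0")] + r[1:], m),
             mc.MalformedEquationError),
        ],
    )
    def test_named_parse_errors(self, tmp_path, mutate, error):
        rxns, mets = mutate(list(MINIMAL_RXNS), list(MINIMAL_METS))
        with pytest.raises(error):
            mc.read_universe(write_model(tmp_path, rxns, mets))

    def test_empty_reaction_table(self, tmp_path):
        with pytest.raises(mc.EmptyTableError):
            mc.read_universe(write_model(tmp_path, [], MINIMAL_METS))


class TestRoundTrip:
    def test_write_then_read_is_identity_and_canonical(self, tmp_path):
        universe = mc.read_universe(write_model(tmp_path / "a", MINIMAL_RXNS, MINIMAL_METS))
        mc.write_universe(universe, tmp_path / "b")
        second = mc.read_universe(tmp_path / "b")
        mc.write_universe(second, tmp_path / "c")
        for name in ("reactions.tsv", "metabolites.tsv"):
            assert (tmp_path / "b" / name).read_bytes() == (tmp_path / "c" / name).read_bytes()
        assert second.reaction_index.keys() == universe.reaction_index.keys()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_random_universe_round_trip(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        universe = fm.random_toy_universe(rng, n_reactions=int(rng.integers(2, 10)))
        out = tmp_path_factory.mktemp("rt")
        mc.write_universe(universe, out)
        back = mc.read_universe(out)
        assert back.reaction_index.keys() == universe.reaction_index.keys()

        def column(u, rid):
            col = u.S.getcol(u.reaction_index[rid]).tocoo()
            return {u.metabolite_ids[int(i)]: v for i, v in zip(col.row, col.data)}

        for rid, j in universe.reaction_index.items():
            k = back.reaction_index[rid]
            assert column(universe, rid) == pytest.approx(column(back, rid))
            assert universe.reversible[j] == back.reversible[k]
            assert universe.role[j] == back.role[k]
        mc.write_universe(back, out)  # idempotent
        again = mc.read_universe(out)
        assert again.reaction_index.keys() == back.reaction_index.keys()

    def test_environment_round_trip(self, tmp_path):
        envs = [fm.Environment("glc", frozenset({"A_ext"}))]
        mc.write_environments(envs, tmp_path / "env.json")
        assert mc.read_environments(tmp_path / "env.json") == envs

    def test_annotation_round_trip_accumulates(self, tmp_path):
        (tmp_path / "ann.tsv").write_text(
            "reaction_id\tpathway\nR1\tglycolysis\nR1\tTCA\n")
        ann = mc.read_annotations(tmp_path / "ann.tsv")
        assert ann["R1"] == frozenset({"glycolysis", "TCA"})
        mc.write_annotations(ann, tmp_path / "ann2.tsv")
        assert mc.read_annotations(tmp_path / "ann2.tsv") == ann


class TestSBMLDialect:
    def test_round_trip_through_cobra_sbml(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        model = cobra.Model("toy")
        a = cobra.Metabolite("A_e", compartment="e")
        b = cobra.Metabolite("B_c", compartment="c")
        ex = cobra.Reaction("EX_A")
        ex.lower_bound, ex.upper_bound = -1000, 1000
        ex.add_metabolites({a: -1})
        r1 = cobra.Reaction("R1")
        r1.upper_bound = 1000
        r1.add_metabolites({a: -1, b: 1})
        bm = cobra.Reaction("BIOMASS")
        bm.upper_bound = 1000
        bm.add_metabolites({b: -1})
        model.add_reactions([ex, r1, bm])
        model.objective = "BIOMASS"
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(model, str(path))
        universe = mc.read_universe(path, dialect="sbml")
        universe.validate()
        assert universe.role[universe.reaction_index["EX_A"]] == "exchange"
        assert universe.role[universe.reaction_index["BIOMASS"]] == "biomass"
        assert universe.external[universe.metabolite_index["A_e"]]
        assert not universe.external[universe.metabolite_index["B_c"]]


class TestAnnotationAndEnvironmentErrors:
    def test_unknown_annotated_reaction(self, tmp_path):
        universe = mc.read_universe(write_model(tmp_path, MINIMAL_RXNS, MINIMAL_METS))
        (tmp_path / "ann.tsv").write_text("reaction_id\tpathway\nRX\tnope\n")
        with pytest.raises(mc.UnknownReactionError):
            mc.read_annotations(tmp_path / "ann.tsv", universe)

    def test_empty_annotation_file(self, tmp_path):
        (tmp_path / "ann.tsv").write_text("reaction_id\tpathway\n")
        with pytest.raises(mc.EmptyTableError):
            mc.read_annotations(tmp_path / "ann.tsv")

    def test_internal_importable_rejected(self, tmp_path):
        universe = mc.read_universe(write_model(tmp_path, MINIMAL_RXNS, MINIMAL_METS))
        (tmp_path / "env.json").write_text(
            '[{"label": "bad", "importable": ["B"]}]')
        with pytest.raises(mc.InvalidEnvironmentError):
            mc.read_environments(tmp_path / "env.json", universe)


class TestValidate:
    def test_generated_universes_validate(self, study):
        study[0].validate()

    def test_exchange_on_internal_metabolite_rejected(self, tmp_path):
        rxns = [("EX_B", "B =>", "exchange", "0")] + MINIMAL_RXNS[1:]
        with pytest.raises(mc.InvalidExchangeError):
            mc.read_universe(write_model(tmp_path, rxns, MINIMAL_METS))

    def test_swappable_exchange_rejected(self, tmp_path):
        rxns = [("EX_A", "A_ext =>", "exchange", "1")] + MINIMAL_RXNS[1:]
        with pytest.raises(mc.ValidationError):
            mc.read_universe(write_model(tmp_path, rxns, MINIMAL_METS))

    def test_genotype_cannot_clear_fixed_bits(self, tmp_path):
        universe = mc.read_universe(write_model(tmp_path, MINIMAL_RXNS, MINIMAL_METS))
        bits = np.ones(universe.n_reactions, dtype=bool)
        bits[universe.biomass_index] = False
        with pytest.raises(mc.ValidationError):
            universe.check_genotype(fm.Genotype(bits))
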
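"""SBML parsing, flattening, stoichiometry and export round-trips."""

import numpy as np
import pytest
import sympy

import libsbml

import kinfit as kf
from kinfit.errors import (
    CyclicRuleError,
    UnknownParameterError,
    UnresolvedSymbolError,
    UnsupportedSBMLFeatureError,
)
from kinfit.sbml import TIME


def _doc(body: str, extra: str = "") -> str:
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" level="3" version="2">
  <model id="m">{extra}
    <listOfCompartments><compartment id="cell" size="1" constant="true"/></listOfCompartments>
    {body}
  </model>
</sbml>"""


def _species(sid, init, boundary="false"):
    return (
        f'<species id="{sid}" compartment="cell" initialConcentration="{init}" '
        f'constant="false" boundaryCondition="{boundary}" hasOnlySubstanceUnits="false"/>'
    )


def _mass_action_reaction(rid, sub, prod, rate_mathml, local_params=""):
    return f"""<reaction id="{rid}" reversible="false">
      <listOfReactants><speciesReference species="{sub}" stoichiometry="1" constant="true"/></listOfReactants>
      <listOfProducts><speciesReference species="{prod}" stoichiometry="1" constant="true"/></listOfProducts>
      <kineticLaw>
        <math xmlns="http://www.w3.org/1998/Math/MathML">{rate_mathml}</math>
        {local_params}
      </kineticLaw>
    </reaction>"""


class TestParse:
    def test_toy_mass_action_document(self, toy_sbml):
        spec = kf.parse_sbml(toy_sbml)
        assert [s.id for s in spec.species] == ["A", "B"]
        assert spec.global_params == {"k": 0.5}
        assert len(spec.reactions) == 1
        k, A = sympy.symbols("k A")
        assert sympy.simplify(spec.reactions[0].rate - k * A) == 0
        assert spec.reactions[0].reactants == {"A": 1.0}
        assert spec.reactions[0].products == {"B": 1.0}

    def test_local_parameters_namespaced_without_collision(self):
        body = (
            "<listOfSpecies>" + _species("A", 1) + _species("B", 0) + _species("C", 0)
            + "</listOfSpecies><listOfReactions>"
            + _mass_action_reaction(
                "R1", "A", "B",
                "<apply><times/><ci>k</ci><ci>A</ci></apply>",
                '<listOfLocalParameters><localParameter id="k" value="0.5"/></listOfLocalParameters>',
            )
            + _mass_action_reaction(
                "R2", "B", "C",
                "<apply><times/><ci>k</ci><ci>B</ci></apply>",
                '<listOfLocalParameters><localParameter id="k" value="0.9"/></listOfLocalParameters>',
            )
            + "</listOfReactions>"
        )
        spec = kf.parse_sbml(_doc(body))
        assert spec.global_params == {"R1__k": 0.5, "R2__k": 0.9}
        assert str(spec.reactions[0].rate) == "A*R1__k"
        assert str(spec.reactions[1].rate) == "B*R2__k"

    def test_function_definition_inlined(self):
        fd = """<listOfFunctionDefinitions>
          <functionDefinition id="f">
            <math xmlns="http://www.w3.org/1998/Math/MathML">
              <lambda><bvar><ci>x</ci></bvar>
                <apply><times/><cn>2</cn><ci>x</ci></apply>
              </lambda>
            </math>
          </functionDefinition>
        </listOfFunctionDefinitions>"""
        body = (
            "<listOfSpecies>" + _species("A", 1) + _species("B", 0) + "</listOfSpecies>"
            + "<listOfReactions>"
            + _mass_action_reaction("R1", "A", "B", "<apply><ci>f</ci><ci>A</ci></apply>")
            + "</listOfReactions>"
        )
        spec = kf.parse_sbml(_doc(body, extra=fd))
        A = sympy.Symbol("A")
        assert sympy.simplify(spec.reactions[0].rate - 2 * A) == 0
        assert "f" in spec.function_defs

    @pytest.mark.parametrize(
        "extra, feature",
        [
            (
                """<listOfEvents><event id="e1" useValuesFromTriggerTime="true">
                     <trigger initialValue="true" persistent="true">
                       <math xmlns="http://www.w3.org/1998/Math/MathML"><true/></math>
                     </trigger></event></listOfEvents>""",
                "event",
            ),
        ],
    )
    def test_unsupported_features_rejected(self, extra, feature):
        body = (
            "<listOfSpecies>" + _species("A", 1) + _species("B", 0) + "</listOfSpecies>"
            + "<listOfReactions>"
            + _mass_action_reaction("R1", "A", "B", "<apply><times/><cn>1</cn><ci>A</ci></apply>")
            + "</listOfReactions>" + extra
        )
        with pytest.raises(UnsupportedSBMLFeatureError) as err:
            kf.parse_sbml(_doc(body))
        assert err.value.feature == feature

    def test_rate_rule_rejected(self):
        rules = """<listOfRules><rateRule variable="A">
          <math xmlns="http://www.w3.org/1998/Math/MathML"><cn>1</cn></math>
        </rateRule></listOfRules>"""
        body = (
            "<listOfSpecies>" + _species("A", 1) + _species("B", 0) + "</listOfSpecies>"
            + rules + "<listOfReactions>"
            + _mass_action_reaction("R1", "A", "B", "<apply><times/><cn>1</cn><ci>A</ci></apply>")
            + "</listOfReactions>"
        )
        with pytest.raises(UnsupportedSBMLFeatureError):
            kf.parse_sbml(_doc(body))

    def test_unresolved_symbol_rejected(self):
        body = (
            "<listOfSpecies>" + _species("A", 1) + _species("B", 0) + "</listOfSpecies>"
            + "<listOfReactions>"
            + _mass_action_reaction(
                "R1", "A", "B", "<apply><times/><ci>mystery</ci><ci>A</ci></apply>"
            )
            + "</listOfReactions>"
        )
        with pytest.raises(UnresolvedSymbolError):
            kf.parse_sbml(_doc(body))


class TestFlatten:
    def test_assignment_rule_substituted_into_rate(self):
        rules = """<listOfRules><assignmentRule variable="E">
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><cn>2</cn><ci>P</ci></apply>
          </math></assignmentRule></listOfRules>"""
        body = (
            "<listOfSpecies>" + _species("A", 1) + _species("P", 0.5) + "</listOfSpecies>"
            + '<listOfParameters><parameter id="E" value="0" constant="false"/>'
            + '<parameter id="k" value="1" constant="true"/></listOfParameters>'
            + rules + "<listOfReactions>"
            + _mass_action_reaction(
                "R1", "A", "P",
                "<apply><times/><ci>k</ci><ci>E</ci><ci>A</ci></apply>",
            )
            + "</listOfReactions>"
        )
        flat = kf.flatten_model(kf.parse_sbml(_doc(body)))
        k, P, A = sympy.symbols("k P A")
        assert sympy.simplify(flat.reactions[0].rate - k * 2 * P * A) == 0

    def test_chained_rules_resolve_to_fixpoint(self):
        # a = 2 b, b = 3 c  =>  a = 6 c
        rules = {"a": sympy.sympify("2*b"), "b": sympy.sympify("3*c")}
        from kinfit.sbml import _resolve_rules

        resolved = _resolve_rules(rules)
        c = sympy.Symbol("c")
        assert sympy.simplify(resolved["a"] - 6 * c) == 0

    def test_cyclic_rules_raise(self):
        from kinfit.sbml import _resolve_rules

        with pytest.raises(CyclicRuleError):
            _resolve_rules({"a": sympy.sympify("b + 1"), "b": sympy.sympify("a")})

    def test_boundary_species_becomes_constant(self):
        body = (
            "<listOfSpecies>" + _species("Glc_ext", 5.0, boundary="true")
            + _species("A", 0) + "</listOfSpecies>"
            + '<listOfParameters><parameter id="k" value="1" constant="true"/></listOfParameters>'
            + "<listOfReactions>"
            + _mass_action_reaction(
                "R1", "Glc_ext", "A",
                "<apply><times/><ci>k</ci><ci>Glc_ext</ci></apply>",
            )
            + "</listOfReactions>"
        )
        flat = kf.flatten_model(kf.parse_sbml(_doc(body)))
        assert [s.id for s in flat.dynamic_species] == ["A"]
        k = sympy.Symbol("k")
        assert sympy.simplify(flat.reactions[0].rate - 5.0 * k) == 0

    def test_initial_assignment_applied(self):
        ia = """<listOfInitialAssignments><initialAssignment symbol="A">
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><cn>3</cn><ci>k</ci></apply>
          </math></initialAssignment></listOfInitialAssignments>"""
        body = (
            "<listOfSpecies>" + _species("A", 1) + _species("B", 0) + "</listOfSpecies>"
            + '<listOfParameters><parameter id="k" value="0.5" constant="true"/></listOfParameters>'
            + ia + "<listOfReactions>"
            + _mass_action_reaction(
                "R1", "A", "B", "<apply><times/><ci>k</ci><ci>A</ci></apply>"
            )
            + "</listOfReactions>"
        )
        flat = kf.flatten_model(kf.parse_sbml(_doc(body)))
        assert flat.species_by_id("A").initial_value == pytest.approx(1.5)


class TestStoichiometry:
    def test_unimolecular_column(self, toy_sbml):
        spec = kf.flatten_model(kf.parse_sbml(toy_sbml))
        S = kf.build_stoichiometric_matrix(spec)
        assert S.shape == (2, 1)
        np.testing.assert_array_equal(S[:, 0], [-1.0, 1.0])

    def test_coefficient_two(self):
        from kinfit.sbml import Reaction, ModelSpec, Species

        spec = ModelSpec(
            species=[Species("A", 1, "cell"), Species("B", 0, "cell")],
            compartments={"cell": 1.0},
            global_params={"k": 1.0},
            reactions=[
                Reaction("R1", {"A": 2.0}, {"B": 1.0}, rate=sympy.sympify("k*A**2"))
            ],
            flattened=True,
        )
        S = kf.build_stoichiometric_matrix(spec)
        np.testing.assert_array_equal(S[:, 0], [-2.0, 1.0])

    def test_modifier_row_is_zero(self):
        from kinfit.sbml import Reaction, ModelSpec, Species

        spec = ModelSpec(
            species=[Species("A", 1, "cell"), Species("B", 0, "cell"), Species("E", 1, "cell")],
            compartments={"cell": 1.0},
            global_params={"k": 1.0},
            reactions=[
                Reaction("R1", {"A": 1.0}, {"B": 1.0}, modifiers=("E",),
                         rate=sympy.sympify("k*E*A"))
            ],
            flattened=True,
        )
        S = kf.build_stoichiometric_matrix(spec)
        np.testing.assert_array_equal(S[:, 0], [-1.0, 1.0, 0.0])


def _equivalent(spec_a, spec_b):
    a, b = kf.flatten_model(spec_a), kf.flatten_model(spec_b)
    if [s.id for s in a.dynamic_species] != [s.id for s in b.dynamic_species]:
        return False
    if not np.array_equal(kf.build_stoichiometric_matrix(a), kf.build_stoichiometric_matrix(b)):
        return False
    for ra, rb in zip(a.reactions, b.reactions):
        if sympy.simplify(ra.rate - rb.rate) != 0:
            return False
    return True


class TestExport:
    def test_round_trip_identity(self, toy_sbml):
        spec = kf.parse_sbml(toy_sbml)
        again = kf.parse_sbml(kf.export_sbml(spec))
        assert _equivalent(spec, again)
        assert again.global_params == spec.global_params

    def test_round_trip_idempotent(self, f2, f3):
        for model, _, _ in (f2, f3):
            once = kf.export_sbml(model.spec)
            spec1 = kf.parse_sbml(once)
            twice = kf.export_sbml(kf.flatten_model(spec1))
            assert _equivalent(spec1, kf.parse_sbml(twice))

    def test_theta_override(self, toy_sbml):
        spec = kf.parse_sbml(toy_sbml)
        again = kf.parse_sbml(kf.export_sbml(spec, theta={"k": 0.9}))
        assert again.global_params["k"] == pytest.approx(0.9)

    def test_unknown_parameter_rejected(self, toy_sbml):
        spec = kf.parse_sbml(toy_sbml)
        with pytest.raises(UnknownParameterError):
            kf.export_sbml(spec, theta={"nope": 1.0})

    def test_mechanism_model_exports_valid_sbml(self, f3):
        model, _, _ = f3
        text = kf.export_sbml(model.spec)
        doc = libsbml.readSBMLFromString(text)
        doc.checkConsistency()
        assert doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) == 0
        again = kf.KineticModel.from_sbml(text)
        # numeric constants survive to the MathML writer's 15-significant-digit
        # limit; compare rates pointwise at machine-level tolerance
        rng = np.random.default_rng(0)
        for r1, r2 in zip(model.spec.reactions, again.spec.reactions):
            syms = sorted(r1.rate.free_symbols, key=str)
            assert syms == sorted(r2.rate.free_symbols, key=str)
            for _ in range(5):
                env = dict(zip(syms, rng.uniform(0.1, 2.0, len(syms))))
                a = float(r1.rate.subs(env))
                b = float(r2.rate.subs(env))
                assert a == pytest.approx(b, rel=1e-12)

    def test_fixture_documents_validate(self, f1, f2, f4):
        for model, _, _ in (f1, f2, f4):
            doc = libsbml.readSBMLFromString(kf.export_sbml(model.spec))
            doc.checkConsistency()
            assert doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) == 0
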
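import numpy as np
import pytest

import kinfit as kf

TOY_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" level="3" version="2">
  <model id="toy">
    <listOfCompartments>
      <compartment id="cell" size="1" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="cell" initialConcentration="2" constant="false" boundaryCondition="false" hasOnlySubstanceUnits="false"/>
      <species id="B" compartment="cell" initialConcentration="0" constant="false" boundaryCondition="false" hasOnlySubstanceUnits="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="k" value="0.5" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="R1" reversible="false">
        <listOfReactants><speciesReference species="A" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="B" stoichiometry="1" constant="true"/></listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci>k</ci><ci>A</ci></apply>
          </math>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


@pytest.fixture(scope="session")
def toy_sbml():
    return TOY_SBML


@pytest.fixture(scope="session")
def f1():
    return kf.fixture("f1")


@pytest.fixture(scope="session")
def f2():
    return kf.fixture("f2")


@pytest.fixture(scope="session")
def f3():
    return kf.fixture("f3")


@pytest.fixture(scope="session")
def f4():
    return kf.fixture("f4")


@pytest.fixture(scope="session")
def f1_dataset(f1):
    model, theta, t_end = f1
    return kf.generate_synthetic_dataset(model, None, t_end)


@pytest.fixture(scope="session")
def f2_dataset(f2):
    model, theta, t_end = f2
    return kf.generate_synthetic_dataset(model, None, t_end)


@pytest.fixture(scope="session")
def chain3():
    """3-parameter irreversible mass-action chain A -> B -> C -> (sink)."""
    from kinfit.evaluation import _with_product
    from kinfit.mechanisms import instantiate_law

    r1 = _with_product(instantiate_law("mass_action_irrev_uni", {"S": "A"}, {"k": "k1"}, "v1"), "B")
    r2 = _with_product(instantiate_law("mass_action_irrev_uni", {"S": "B"}, {"k": "k2"}, "v2"), "C")
    r3 = instantiate_law("mass_action_irrev_uni", {"S": "C"}, {"k": "k3"}, "v3")
    model = kf.KineticModel.from_reactions(
        [("A", 2.0), ("B", 0.3), ("C", 0.1)],
        [r1, r2, r3],
        {"k1": 0.7, "k2": 0.3, "k3": 0.5},
        model_id="chain3",
    )
    return model, np.array([0.7, 0.3, 0.5]), 10.0
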
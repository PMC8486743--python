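"""Shared fixtures: toy networks and their (session-cached) equilibria."""

import numpy as np
import pytest

from crnsim import conservation as cons
from crnsim import equilibrium as eq
from crnsim import fixtures as fx
from crnsim.perturbation import MutationSpec, apply_gof


@pytest.fixture(scope="session")
def toy_binding_bundle():
    return fx.toy_binding()


@pytest.fixture(scope="session")
def cascade_bundle():
    return fx.cascade()


@pytest.fixture(scope="session")
def cascade_laws(cascade_bundle):
    return cons.conservation_laws(cascade_bundle.crn)


@pytest.fixture(scope="session")
def cascade_phys_eq(cascade_bundle, cascade_laws):
    res = eq.find_equilibrium(cascade_bundle.crn, laws=cascade_laws)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def cascade_gof_crn(cascade_bundle):
    spec = MutationSpec(
        "GoF",
        cascade_bundle.meta["gof_protein"],
        1.0,
        cascade_bundle.meta["gof_reactions"],
    )
    return apply_gof(cascade_bundle.crn, spec)


@pytest.fixture(scope="session")
def cascade_mut_eq(cascade_gof_crn, cascade_bundle, cascade_laws):
    res = eq.find_equilibrium(
        cascade_gof_crn, cascade_bundle.x0, laws=cascade_laws
    )
    assert res.converged
    return res


@pytest.fixture(scope="session")
def phospho_bundle():
    return fx.phospho_cycle()


SBML_TOY = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="toy">
    <listOfCompartments><compartment id="cell" size="1"/></listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="cell" initialConcentration="1.0"/>
      <species id="B" compartment="cell" initialConcentration="1.0"/>
      <species id="C" compartment="cell" initialConcentration="0.0"/>
      <species id="G" compartment="cell" initialConcentration="5.0" boundaryCondition="true"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="bindR" reversible="true">
        <listOfReactants>
          <speciesReference species="A"/><speciesReference species="B"/>
        </listOfReactants>
        <listOfProducts><speciesReference species="C"/></listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><minus/>
              <apply><times/><ci>kf</ci><ci>A</ci><ci>B</ci></apply>
              <apply><times/><ci>kr</ci><ci>C</ci></apply>
            </apply>
          </math>
          <listOfParameters>
            <parameter id="kf" value="0.7"/><parameter id="kr" value="0.2"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
      <reaction id="syn" reversible="false">
        <listOfReactants><speciesReference species="G"/></listOfReactants>
        <listOfProducts>
          <speciesReference species="G"/>
          <speciesReference species="A" stoichiometry="2"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci>ks</ci><ci>G</ci></apply>
          </math>
          <listOfParameters><parameter id="ks" value="0.01"/></listOfParameters>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


@pytest.fixture()
def sbml_toy_path(tmp_path):
    p = tmp_path / "toy.xml"
    p.write_text(SBML_TOY)
    return p


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
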
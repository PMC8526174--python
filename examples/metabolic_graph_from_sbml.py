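"""Metabolite-centric graph from an SBML model's stoichiometric matrix.

Writes a small synthetic SBML model (a toy four-metabolite pathway),
extracts its metabolites x reactions stoichiometric matrix S, and builds
the metabolite graph by linking every pair of metabolites that share a
reaction (non-zero entries of S*S^T).  The same two calls applied to the
BIGG e_coli_core model yield the 72-node, 486-edge core metabolic graph.
"""

import tempfile

import netdyn as nd
from netdyn.io import stoichiometric_matrix_from_sbml

SYNTHETIC_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="toy_pathway">
    <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
    <listOfSpecies>
      <species id="glc" compartment="c" constant="false"
               hasOnlySubstanceUnits="false" boundaryCondition="false"/>
      <species id="g6p" compartment="c" constant="false"
               hasOnlySubstanceUnits="false" boundaryCondition="false"/>
      <species id="f6p" compartment="c" constant="false"
               hasOnlySubstanceUnits="false" boundaryCondition="false"/>
      <species id="pyr" compartment="c" constant="false"
               hasOnlySubstanceUnits="false" boundaryCondition="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="HEX" reversible="false" fast="false">
        <listOfReactants><speciesReference species="glc" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="g6p" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
      <reaction id="PGI" reversible="true" fast="false">
        <listOfReactants><speciesReference species="g6p" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="f6p" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
      <reaction id="GLY" reversible="false" fast="false">
        <listOfReactants><speciesReference species="f6p" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="pyr" stoichiometry="2" constant="true"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

with tempfile.NamedTemporaryFile("w", suffix=".xml", delete=False) as fh:
    fh.write(SYNTHETIC_SBML)
    path = fh.name

S, metabolites = stoichiometric_matrix_from_sbml(path)
print("stoichiometric matrix (metabolites x reactions):")
for met, row in zip(metabolites, S):
    print(f"  {met:4s} {row}")

A = nd.graph_from_stoichiometry(S)
print(f"\nmetabolite graph: {A.shape[0]} nodes, {int(A.sum()) // 2} edges")
print("edges:", [(metabolites[i], metabolites[j])
                 for i in range(len(metabolites))
                 for j in range(i + 1, len(metabolites)) if A[i, j]])
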
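import numpy as np
import networkx as nx
import pytest

from mapclust import (
    AnnotationArea,
    DistanceMatrix,
    InteractionMap,
    MapElement,
    OntologyAnnotation,
    Reaction,
)
from mapclust.synthetic import SyntheticConfig, generate

# A minimal CellDesigner SBML Level 2 export: three species (PROTEIN, GENE,
# RNA) with one alias each carrying layout bounds, one reaction joining all
# three, and a MIRIAM GO annotation on the protein.
CELLDESIGNER_FIXTURE = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4"
      xmlns:celldesigner="http://www.sbml.org/2001/ns/celldesigner">
 <model id="m1">
  <annotation>
   <celldesigner:extension>
    <celldesigner:listOfSpeciesAliases>
     <celldesigner:speciesAlias id="sa1" species="s1">
      <celldesigner:bounds x="10" y="20" w="80" h="40"/>
     </celldesigner:speciesAlias>
     <celldesigner:speciesAlias id="sa2" species="s2">
      <celldesigner:bounds x="100" y="200" w="20" h="20"/>
     </celldesigner:speciesAlias>
     <celldesigner:speciesAlias id="sa3" species="s3">
      <celldesigner:bounds x="300" y="400" w="40" h="20"/>
     </celldesigner:speciesAlias>
    </celldesigner:listOfSpeciesAliases>
   </celldesigner:extension>
  </annotation>
  <listOfSpecies>
   <species id="s1" name="ProteinA">
    <annotation>
     <celldesigner:extension>
      <celldesigner:speciesIdentity>
       <celldesigner:class>PROTEIN</celldesigner:class>
      </celldesigner:speciesIdentity>
     </celldesigner:extension>
     <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
              xmlns:bqbiol="http://biomodels.net/biology-qualifiers/">
      <rdf:Description rdf:about="#s1">
       <bqbiol:is>
        <rdf:Bag>
         <rdf:li rdf:resource="urn:miriam:obo.go:GO%3A0005634"/>
         <rdf:li rdf:resource="urn:miriam:uniprot:P12345"/>
        </rdf:Bag>
       </bqbiol:is>
      </rdf:Description>
     </rdf:RDF>
    </annotation>
   </species>
   <species id="s2" name="GeneB">
    <annotation>
     <celldesigner:extension>
      <celldesigner:speciesIdentity>
       <celldesigner:class>GENE</celldesigner:class>
      </celldesigner:speciesIdentity>
     </celldesigner:extension>
    </annotation>
   </species>
   <species id="s3" name="RnaC">
    <annotation>
     <celldesigner:extension>
      <celldesigner:speciesIdentity>
       <celldesigner:class>RNA</celldesigner:class>
      </celldesigner:speciesIdentity>
     </celldesigner:extension>
    </annotation>
   </species>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="re1">
    <listOfReactants><speciesReference species="s1"/></listOfReactants>
    <listOfProducts><speciesReference species="s2"/></listOfProducts>
    <listOfModifiers><modifierSpeciesReference species="s3"/></listOfModifiers>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""

EMPTY_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="m0"><listOfSpecies/></model>
</sbml>
"""


@pytest.fixture
def celldesigner_file(tmp_path):
    path = tmp_path / "fixture.xml"
    path.write_text(CELLDESIGNER_FIXTURE)
    return path


@pytest.fixture
def empty_sbml_file(tmp_path):
    path = tmp_path / "empty.xml"
    path.write_text(EMPTY_SBML)
    return path


@pytest.fixture
def four_class_map():
    """Four elements, one per class, two reactions; two annotation areas."""
    elements = [
        MapElement("A", element_class="protein", x=0.0, y=0.0),
        MapElement("B", element_class="gene", x=3.0, y=4.0),
        MapElement("C", element_class="mRNA", x=1.0, y=1.0),
        MapElement("D", element_class="other", x=2.0, y=2.0),
    ]
    reactions = [
        Reaction("r1", [("A", "reactant"), ("B", "product"), ("C", "modifier")]),
        Reaction("r2", [("C", "reactant"), ("D", "product")]),
    ]
    areas = [
        AnnotationArea("left", {"A", "C"}),
        AnnotationArea("right", {"B", "D"}),
    ]
    return InteractionMap(elements=elements, reactions=reactions, areas=areas)


@pytest.fixture(scope="session")
def toy_dag():
    """root -> P -> {a, b}, all is_a edges of weight 0.8, plus a disjoint
    second component root2 -> c.  Wang values on it are hand-checkable."""
    dag = nx.DiGraph()
    for child, parent in [("P", "root"), ("a", "P"), ("b", "P"), ("c", "root2")]:
        dag.add_edge(child, parent, relation="is_a", weight=0.8)
    return dag


@pytest.fixture
def toy_ann(toy_dag):
    return OntologyAnnotation(
        dag=toy_dag.copy(),
        element_terms={"e1": {"a"}, "e2": {"a", "b"}, "e3": {"c"}, "e4": {"b"}},
    )


@pytest.fixture(scope="session")
def aligned_synthetic():
    """Aligned-mode synthetic map: 3 groups x 20 elements, wide separation."""
    return generate(SyntheticConfig(rng_seed=11))


def random_distance_matrix(n: int, rng: np.random.Generator,
                           metric: str = "combined") -> DistanceMatrix:
    raw = rng.random((n, n))
    values = (raw + raw.T) / 2.0 + 0.05
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=[f"n{i}" for i in range(n)], values=values,
                          metric=metric)
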
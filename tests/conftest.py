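import numpy as np
import pytest

from necbiome.io import OtuTable, TaxonomyMap, Lineage
from necbiome.simulate import CohortDesign, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-design cohort, shared across read-only tests."""
    return generate_cohort(CohortDesign(seed=7))


@pytest.fixture()
def tiny_table():
    return OtuTable(["s1", "s2"], ["A", "B", "C"], np.array([[5, 0, 1], [0, 2, 2]]))


@pytest.fixture()
def tiny_taxonomy():
    proteo = ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
              "Enterobacteriales", "Enterobacteriaceae")
    return TaxonomyMap(
        {
            "A": Lineage(*proteo, "Enterobacter"),
            "B": Lineage("Bacteria", "Firmicutes", "Bacilli", "Bacillales",
                         "Staphylococcaceae", "Staphylococcus"),
            "C": Lineage("Bacteria", "Actinobacteria", "Actinobacteria",
                         "Actinomycetales", "Propionibacteriaceae", "Propionibacterium"),
        }
    )
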
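import pytest

from gutnet.model import (Association, Compound, DegradationRule, Network,
                          Organism)


def make_toy_network() -> Network:
    """Two species, one host cell, four compounds, a degradation rule."""
    organisms = {
        "Bacteroides alpha": Organism("Bacteroides alpha", "Bacteroides alpha",
                                      rank="species", ncbi_taxid=101,
                                      lineage={"domain": "Bacteria",
                                               "phylum": "Bacteroidota",
                                               "genus": "Bacteroides"}),
        "Clostridium beta": Organism("Clostridium beta", "Clostridium beta",
                                     rank="species", ncbi_taxid=102,
                                     lineage={"domain": "Bacteria",
                                              "phylum": "Bacillota",
                                              "genus": "Clostridium"}),
        "absorptive cell": Organism("absorptive cell", "absorptive cell",
                                    rank="cell_type", kind="host_cell"),
    }
    compounds = {
        "glucose": Compound("glucose", "glucose", kegg_cid="C00031"),
        "acetate": Compound("acetate", "acetate", kegg_cid="C00033"),
        "cellobiose": Compound("cellobiose", "cellobiose", kegg_cid="C00185"),
        "cellulose": Compound("cellulose", "cellulose", klass="macromolecule"),
    }
    associations = [
        Association("NJC19_00001", "Bacteroides alpha", "glucose", "import",
                    refs=("1",)),
        Association("NJC19_00002", "Bacteroides alpha", "acetate", "export",
                    refs=("1", "2")),
        Association("NJC19_00003", "Clostridium beta", "glucose", "import",
                    refs=("2",)),
        Association("NJC19_00004", "Clostridium beta", "cellulose",
                    "degradation", refs=("2",)),
        Association("NJC19_00005", "Clostridium beta", "acetate", "import",
                    sign="negative", refs=("1",)),
        Association("NJC19_00006", "absorptive cell", "glucose", "import",
                    refs=("3",)),
    ]
    rules = [DegradationRule("cellulose", ("glucose", "cellobiose"))]
    references = {"1": "Author A et al. (2001)",
                  "2": "Author B et al. (2005)",
                  "3": "Author C, textbook (2010)"}
    return Network(organisms=organisms, compounds=compounds,
                   associations=associations, degradation_rules=rules,
                   references=references)


@pytest.fixture
def toy_net() -> Network:
    return make_toy_network()


def assoc_multiset(net: Network, with_provenance: bool = True):
    """Name-based association multiset, for round-trip comparisons."""
    rows = []
    for a in net.associations:
        row = (net.organisms[a.organism_id].name,
               net.compounds[a.compound_id].name,
               a.activity, a.sign, a.refs)
        if with_provenance:
            row += (a.provenance,)
        rows.append(row)
    return sorted(rows)
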
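import pytest

from pgxlink.corpus import ASSOCIATED, GeneDrugPair
from pgxlink.graph import PGxGraph
from pgxlink.labels import ATTRIBUTE, DRUG, GENE, PHENOTYPE, Label
from pgxlink.synth import SynthConfig, generate


@pytest.fixture
def egfr_graph():
    """Hand-built sample mirroring the published worked example: a gene
    with two pathway annotations in one namespace, a shared phenotype
    annotated through two different gene-phenotype predicates, a drug
    with one ATC class, a direct antagonist link, and one drug-phenotype
    indication edge."""
    g = PGxGraph()
    gene = Label("genea", "EGFR")
    gene2 = Label("geneb", "EGFR")
    drug = Label("druga", "Gefitinib")
    pheno = Label("phena", "C0007131")
    g.add_node(gene, GENE)
    g.add_node(gene2, GENE)
    g.add_node(drug, DRUG)
    g.add_node(pheno, PHENOTYPE)
    for attr in ("Signal transduction", "Immune system"):
        a = Label("pathway", attr)
        g.add_node(a, ATTRIBUTE)
        g.add_edge(gene, Label("pgxa", "has_pathway"), a)
    atc = Label("atc", "L01XE2")
    g.add_node(atc, ATTRIBUTE)
    g.add_edge(drug, Label("pgxa", "has_atc"), atc)
    g.add_edge(gene, Label("clinvar", "so_0001575"), pheno)
    g.add_edge(gene2, Label("clinvar", "so_0001619"), pheno)
    g.add_edge(gene, Label("pgx", "mapped_to"), gene2)
    g.add_edge(gene2, Label("pgx", "mapped_to"), gene)
    g.add_edge(gene, Label("drugbank", "antagonist"), drug)
    g.add_edge(drug, Label("sider", "indication"), pheno)
    return g


@pytest.fixture
def egfr_pair():
    return GeneDrugPair(Label("genea", "EGFR"), Label("druga", "Gefitinib"), 1, ASSOCIATED)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions for fast integration tests."""
    return SynthConfig(
        n_genes=50,
        n_drugs=25,
        n_phenotypes=80,
        n_positive=24,
        n_negative_pool=48,
        n_test=10,
        signal_phenotype_pool=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate(small_config)
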
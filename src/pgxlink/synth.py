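"""Seeded synthetic pharmacogenomic linked-data graphs.

The generator emulates the schema of an assembled multi-source PGx
dataset at desk scale: gene, drug and phenotype entities split over two
namespaces per type (with equivalence mappings), SO-coded gene-phenotype
edges, indication / side-effect drug-phenotype edges, drug-target
gene-drug edges, pathway-like gene attributes and ATC-like drug
attributes. A configurable association *signal* plants, for each positive
pair, a phenotype reachable from both the gene and the drug — the
structural footprint the downstream classifiers are meant to pick up.
Drug-response phenotypes are drawn from a small dedicated pool, mirroring
the fact that pharmacogenomic annotations concentrate on a limited
vocabulary of response/toxicity phenotypes.

Only schema and signal structure are emulated; no attempt is made to
match the degree distributions of any real source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple, Union

import numpy as np

from . import graph as G
from .corpus import (
    ASSOCIATED,
    NOT_ASSOCIATED,
    UNKNOWN,
    GeneDrugPair,
    VariantAnnotation,
    write_annotations,
    write_exclusion,
    write_pairs,
)
from .labels import ATTRIBUTE, CLASS, DRUG, GENE, PHENOTYPE, PAIR, PGX_NS, PRED_MAPPED_TO, Label

# Namespaces of the synthetic sources (two per entity type).
GENE_NS = ("genea", "geneb")
DRUG_NS = ("druga", "drugb")
PHENO_NS = ("phena", "phenb")

PRED_GP = [Label("clinvar", "so_0001575"), Label("clinvar", "so_0001619"), Label("disgenet", "so_0001583")]
PRED_DP = [Label("sider", "indication"), Label("sider", "side_effect")]
PRED_GD = [Label("drugbank", "target"), Label("drugbank", "antagonist")]
PRED_INTERACTS = Label("dgidb", "interacts")
PRED_HAS_PATHWAY = Label("pgxa", "has_pathway")
PRED_HAS_ATC = Label("pgxa", "has_atc")
PRED_HAS_MESH = Label("pgxa", "has_mesh_class")

DEFAULT_SCHEMA: Dict[str, str] = {
    GENE_NS[0]: GENE,
    GENE_NS[1]: GENE,
    DRUG_NS[0]: DRUG,
    DRUG_NS[1]: DRUG,
    PHENO_NS[0]: PHENOTYPE,
    PHENO_NS[1]: PHENOTYPE,
    "pathway": ATTRIBUTE,
    "atc": ATTRIBUTE,
    "mesh": ATTRIBUTE,
    "pair": PAIR,
    PGX_NS: CLASS,
}

#: identifier extractors for :func:`pgxlink.graph.infer_mappings` — the
#: local id is the shared identifier in every synthetic namespace.
DEFAULT_EXTRACTORS: Dict[str, str] = {ns: r":(.+)$" for ns in GENE_NS + DRUG_NS + PHENO_NS}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults echo the seed corpus of the real task (about ninety-five
    level-1/2 positive pairs against twice as many negatives) at a size
    that keeps every downstream stage running in seconds.
    """

    n_genes: int = 200
    n_drugs: int = 100
    n_phenotypes: int = 300
    n_positive: int = 95
    n_negative_pool: int = 190
    n_test: int = 40
    signal: float = 1.0
    test_signal_fraction: float = 0.5
    noise_edge_rate: float = 2.0
    dual_namespace_fraction: float = 0.2
    attribute_vocab_sizes: Tuple[int, int] = (12, 10)  # (gene pathways, drug ATC codes)
    signal_phenotype_pool: int = 25
    interaction_coverage: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError("signal must lie in [0, 1]")
        if not 0.0 <= self.test_signal_fraction <= 1.0:
            raise ValueError("test_signal_fraction must lie in [0, 1]")
        for name in ("n_genes", "n_drugs", "n_phenotypes", "n_positive", "n_negative_pool", "n_test"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_pairs = self.n_genes * self.n_drugs
        if self.n_positive + self.n_test > n_pairs:
            raise ValueError(
                f"cannot place {self.n_positive} positives and {self.n_test} test pairs "
                f"in a {self.n_genes}x{self.n_drugs} gene-drug grid"
            )


@dataclass
class GroundTruth:
    positive_pairs: List[GeneDrugPair] = field(default_factory=list)
    negative_pairs: List[GeneDrugPair] = field(default_factory=list)
    test_pairs: List[GeneDrugPair] = field(default_factory=list)
    planted_shared_phenotypes: Dict[Tuple[Label, Label], List[Label]] = field(default_factory=dict)
    annotations: List[VariantAnnotation] = field(default_factory=list)
    exclusion: Set[Tuple[Label, Label]] = field(default_factory=set)


def generate(config: SynthConfig) -> Tuple[G.PGxGraph, GroundTruth]:
    """Generate a graph plus ground truth; byte-deterministic under the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    g = G.PGxGraph()
    truth = GroundTruth()

    # RDF graphs are statement sets: never emit the same triple twice.
    seen_triples: Set[Tuple[Label, Label, Label]] = set()
    plain_add = g.add_edge

    def add_edge_once(s: Label, p: Label, o: Label) -> None:
        if (s, p, o) not in seen_triples:
            seen_triples.add((s, p, o))
            plain_add(s, p, o)

    g.add_edge = add_edge_once  # type: ignore[method-assign]

    genes = [Label(GENE_NS[0], f"G{i:04d}") for i in range(config.n_genes)]
    drugs = [Label(DRUG_NS[0], f"D{i:04d}") for i in range(config.n_drugs)]
    phenos = [Label(PHENO_NS[0], f"C{i:07d}") for i in range(config.n_phenotypes)]
    for lab, typ in [(genes, GENE), (drugs, DRUG), (phenos, PHENOTYPE)]:
        for l in lab:
            g.add_node(l, typ)

    # Second-namespace twins with symmetric mapping edges.
    twins: Dict[Label, Label] = {}
    for primary, second_ns, typ in [
        (genes, GENE_NS[1], GENE),
        (drugs, DRUG_NS[1], DRUG),
        (phenos, PHENO_NS[1], PHENOTYPE),
    ]:
        n_dual = int(round(config.dual_namespace_fraction * len(primary)))
        for l in primary[:n_dual]:
            twin = Label(second_ns, l.local_id)
            g.add_node(twin, typ)
            g.add_edge(l, PRED_MAPPED_TO, twin)
            g.add_edge(twin, PRED_MAPPED_TO, l)
            twins[l] = twin

    def carrier(entity: Label) -> Label:
        """Attach edges to the primary node or, sometimes, its twin."""
        twin = twins.get(entity)
        if twin is not None and rng.random() < 0.3:
            return twin
        return entity

    # Attributes: pathway-like gene annotations, ATC-like drug codes.
    n_pw, n_atc = config.attribute_vocab_sizes
    pathways = [Label("pathway", f"PW{i:02d}") for i in range(n_pw)]
    atcs = [Label("atc", f"L01XE{i}") for i in range(n_atc)]
    for gene in genes:
        if n_pw:
            k = 1 + int(rng.random() < 0.5)
            for j in sorted(set(rng.integers(0, n_pw, size=k).tolist())):
                g.add_node(pathways[j], ATTRIBUTE)
                g.add_edge(carrier(gene), PRED_HAS_PATHWAY, pathways[j])
    for drug in drugs:
        if n_atc:
            atc = atcs[int(rng.integers(0, n_atc))]
            g.add_node(atc, ATTRIBUTE)
            g.add_edge(carrier(drug), PRED_HAS_ATC, atc)

    # Background noise edges.
    gd_wired: Set[Tuple[Label, Label]] = set()
    if config.n_phenotypes:
        for gene in genes:
            for _ in range(rng.poisson(config.noise_edge_rate)):
                ph = phenos[int(rng.integers(0, config.n_phenotypes))]
                g.add_edge(carrier(gene), PRED_GP[int(rng.integers(0, len(PRED_GP)))], carrier(ph))
        for drug in drugs:
            for _ in range(rng.poisson(config.noise_edge_rate)):
                ph = phenos[int(rng.integers(0, config.n_phenotypes))]
                g.add_edge(carrier(drug), PRED_DP[int(rng.integers(0, len(PRED_DP)))], carrier(ph))
    if config.n_genes and config.n_drugs:
        n_gd = rng.poisson(config.noise_edge_rate * max(config.n_genes, config.n_drugs) / 2)
        for _ in range(n_gd):
            gene = genes[int(rng.integers(0, config.n_genes))]
            drug = drugs[int(rng.integers(0, config.n_drugs))]
            g.add_edge(carrier(gene), PRED_GD[int(rng.integers(0, len(PRED_GD)))], carrier(drug))
            gd_wired.add((gene, drug))

    # Positive, test and negative pairs.
    n_pairs = config.n_genes * config.n_drugs
    n_special = config.n_positive + config.n_test
    chosen = rng.choice(n_pairs, size=n_special, replace=False) if n_special else np.array([], dtype=int)
    as_pair = lambda idx: (genes[idx // config.n_drugs], drugs[idx % config.n_drugs])

    signal_pool = phenos[: min(config.signal_phenotype_pool, config.n_phenotypes)]

    def plant(gene: Label, drug: Label) -> List[Label]:
        """Wire shared drug-response phenotypes to both pair members.

        An established pair typically carries annotations for more than
        one response phenotype (efficacy, toxicity, dosage), so two pool
        phenotypes are planted. Curated annotations reference canonical
        identifiers, so planted edges always attach to the
        primary-namespace nodes (unlike background edges, which may hit a
        provenance twin)."""
        k = min(2, len(signal_pool))
        idx = rng.choice(len(signal_pool), size=k, replace=False)
        planted = [signal_pool[i] for i in sorted(idx.tolist())]
        for ph in planted:
            n_gp = 1 + int(rng.random() < 0.5)
            for j in sorted(set(rng.integers(0, len(PRED_GP), size=n_gp).tolist())):
                g.add_edge(gene, PRED_GP[j], ph)
            n_dp = 1 + int(rng.random() < 0.5)
            for j in sorted(set(rng.integers(0, len(PRED_DP), size=n_dp).tolist())):
                g.add_edge(drug, PRED_DP[j], ph)
        return planted

    footprint: List[Tuple[Label, Label]] = []
    for idx in sorted(chosen[: config.n_positive].tolist()):
        gene, drug = as_pair(idx)
        level = int(rng.integers(1, 3))
        truth.positive_pairs.append(GeneDrugPair(gene, drug, level, ASSOCIATED))
        if signal_pool and rng.random() < config.signal:
            truth.planted_shared_phenotypes[(gene, drug)] = plant(gene, drug)
            footprint.append((gene, drug))
    for idx in sorted(chosen[config.n_positive :].tolist()):
        gene, drug = as_pair(idx)
        level = int(rng.integers(3, 5))
        truth.test_pairs.append(GeneDrugPair(gene, drug, level, UNKNOWN))
        if signal_pool and rng.random() < config.test_signal_fraction:
            truth.planted_shared_phenotypes[(gene, drug)] = plant(gene, drug)
            footprint.append((gene, drug))

    # Established pairs carry a known target-style relation in the graph.
    # The DGIdb-like interaction screen additionally lists — without graph
    # edges, it is a screening list rather than a data source — candidate
    # interactions of each well-studied pharmacogene across all assayed
    # drugs, with quasi-exhaustive coverage (the screen aggregates known
    # and predicted interactions from many databases and is organized by
    # gene). Negatives are later sampled outside these records,
    # reproducing the selection bias of checking candidate negatives
    # against such a screen: a random pair touching a well-known
    # pharmacogene is likely listed and therefore never becomes a negative.
    screened: Set[Tuple[Label, Label]] = set()
    for gene, drug in footprint:
        g.add_edge(gene, PRED_GD[int(rng.integers(0, len(PRED_GD)))], drug)
        gd_wired.add((gene, drug))
    for gene in sorted({gn for gn, _ in footprint}):
        for dd in drugs:
            if rng.random() < config.interaction_coverage:
                screened.add((gene, dd))

    # Exclusion list: every pair wired with a gene-drug edge, planted with
    # a signal, or listed by the interaction screen.
    truth.exclusion = gd_wired | screened | set(truth.planted_shared_phenotypes)

    special = {p.key for p in truth.positive_pairs} | {p.key for p in truth.test_pairs}
    inadmissible = truth.exclusion | special
    admissible = [
        (genes[i // config.n_drugs], drugs[i % config.n_drugs])
        for i in range(n_pairs)
        if (genes[i // config.n_drugs], drugs[i % config.n_drugs]) not in inadmissible
    ]
    if config.n_negative_pool > len(admissible):
        raise ValueError(
            f"cannot sample {config.n_negative_pool} negatives from {len(admissible)} admissible pairs"
        )
    if config.n_negative_pool:
        neg_idx = rng.choice(len(admissible), size=config.n_negative_pool, replace=False)
        for i in sorted(neg_idx.tolist()):
            gene, drug = admissible[i]
            truth.negative_pairs.append(GeneDrugPair(gene, drug, None, NOT_ASSOCIATED))

    # Variant-level annotations behind the positive/test pairs.
    for p in truth.positive_pairs + truth.test_pairs:
        n_var = 1 + int(rng.integers(0, 3))
        levels = [p.evidence_level] + [int(rng.integers(p.evidence_level, 5)) for _ in range(n_var - 1)]
        for v, lvl in enumerate(levels):
            truth.annotations.append(
                VariantAnnotation(p.gene, f"rs{p.gene.local_id[1:]}{v}", p.drug, lvl)
            )
    del g.add_edge  # restore the class method
    return g, truth


def write_fixture(g: G.PGxGraph, truth: GroundTruth, out_dir: Union[str, Path]) -> Dict:
    """Write graph.nt, pairs.tsv, exclusion.tsv, annotations.tsv and a
    manifest of exact counts. Re-loading graph.nt reproduces the graph."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    G.write_graph(g, out_dir / "graph.nt")
    write_pairs(truth.positive_pairs + truth.negative_pairs + truth.test_pairs, out_dir / "pairs.tsv")
    write_exclusion(truth.exclusion, out_dir / "exclusion.tsv")
    write_annotations(truth.annotations, out_dir / "annotations.tsv")
    manifest = {
        "n_nodes": g.n_nodes,
        "n_edges": g.n_edges,
        "node_counts": g.type_counts(),
        "n_positive": len(truth.positive_pairs),
        "n_negative": len(truth.negative_pairs),
        "n_test": len(truth.test_pairs),
        "n_planted": len(truth.planted_shared_phenotypes),
        "n_exclusion": len(truth.exclusion),
        "n_annotations": len(truth.annotations),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
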
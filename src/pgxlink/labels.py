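"""Node and predicate labels for the pharmacogenomic linked-data graph.

Every resource in the graph is identified by a :class:`Label`, a
``namespace:local_id`` pair. Namespaces play the role of data-source
prefixes (a ClinVar-like vs a DisGeNET-like origin for the same gene, an
ATC code book for drug attributes, ...). Rendering is injective because
the namespace never contains ``:``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Union

URI_BASE = "http://pgx.example/"


@dataclass(frozen=True, order=True)
class Label:
    """A namespaced identifier, rendered as ``namespace:local_id``."""

    namespace: str
    local_id: str

    def __post_init__(self) -> None:
        if ":" in self.namespace:
            raise ValueError(f"namespace must not contain ':': {self.namespace!r}")

    def __str__(self) -> str:
        return f"{self.namespace}:{self.local_id}"

    @classmethod
    def parse(cls, text: str) -> "Label":
        ns, _, local = text.partition(":")
        if not _:
            raise ValueError(f"not a namespace:local_id label: {text!r}")
        return cls(ns, local)

    def uri(self) -> str:
        return f"{URI_BASE}{self.namespace}/{self.local_id}"


class Triple(NamedTuple):
    """One edge of the graph. ``obj`` may be a literal string only for
    attribute edges; the graph model turns such literals into
    attribute-value nodes on ingestion."""

    subject: Label
    predicate: Label
    obj: Union[Label, str]


# Node types (Gene / Drug / Phenotype entities, plus artificial nodes).
GENE = "Gene"
DRUG = "Drug"
PHENOTYPE = "Phenotype"
PAIR = "GeneDrugPairNode"
ATTRIBUTE = "AttributeValue"
CLASS = "ClassNode"
GENERIC = "Entity"

NODE_TYPES = (GENE, DRUG, PHENOTYPE, PAIR, ATTRIBUTE, CLASS, GENERIC)

# Reserved vocabulary used by the pipeline itself.
PGX_NS = "pgx"
PAIR_NS = "pair"
LITERAL_NS = "literal"

PRED_PAIR_GENE = Label(PGX_NS, "pair_gene")
PRED_PAIR_DRUG = Label(PGX_NS, "pair_drug")
PRED_HAS_CLASS = Label(PGX_NS, "has_class")
PRED_MAPPED_TO = Label(PGX_NS, "mapped_to")

CLASS_ASSOCIATED = Label(PGX_NS, "associated")
CLASS_NOT_ASSOCIATED = Label(PGX_NS, "not_associated")


def pair_label(gene: Label, drug: Label) -> Label:
    """Deterministic label for the artificial node of a gene-drug pair."""
    return Label(PAIR_NS, f"{gene.namespace}_{gene.local_id}--{drug.namespace}_{drug.local_id}")
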
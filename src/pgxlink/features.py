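"""Multi-instance path features for gene-drug pairs.

A pair is described by the set of length-1 paths leaving its gene and its
drug: gene attributes (pathway-like), drug attributes (ATC-like), direct
gene-drug links, and — for every phenotype reachable from *both* members —
the (gene-phenotype predicate, phenotype, drug-phenotype predicate)
triple. One categorical instance row is emitted per combination of these
slot values, so a single pair becomes a *bag* of rows and the classifier
output must later be aggregated back to the pair level.

Slot values are read from a pair's entity and all its mapped equivalents,
so attributes spread over provenance namespaces are not lost. A slot with
no observed value holds the reserved token ``NA``.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .corpus import ASSOCIATED, NOT_ASSOCIATED, GeneDrugPair
from .graph import PGxGraph
from .labels import ATTRIBUTE, DRUG, GENE, PGX_NS, PHENOTYPE, Label

logger = logging.getLogger(__name__)

NA = "NA"

#: slot order of the instance table
SLOTS = ["gene_attribute", "phenotype", "drug_attribute", "gd_link", "gp_link", "dp_link"]
DISEASE_SLOT = "disease_attribute"


@dataclass(frozen=True)
class FeatureConfig:
    """Slot-extraction rules.

    ``include_disease_attribute`` adds a seventh slot holding attribute
    values of the shared phenotype (MeSH-class-like); it is off by default
    because it carries little information relative to the other slots and
    can be re-enabled for ablations.
    """

    include_disease_attribute: bool = False


@dataclass(frozen=True)
class InstanceRow:
    pair_id: Tuple[str, str]
    gene_attribute: str
    phenotype: str
    drug_attribute: str
    gd_link: str
    gp_link: str
    dp_link: str
    klass: str
    disease_attribute: Optional[str] = None


@dataclass
class Bag:
    pair_id: Tuple[str, str]
    rows: List[InstanceRow]

    @property
    def n_i(self) -> int:
        return len(self.rows)


def _class_token(pair: GeneDrugPair) -> str:
    return {ASSOCIATED: "1", NOT_ASSOCIATED: "0"}.get(pair.label, "unknown")


def build_instances(g: PGxGraph, pair: GeneDrugPair, cfg: FeatureConfig = FeatureConfig()) -> Bag:
    """Enumerate the instance rows of one pair (cartesian product of the
    non-empty slot value sets; empty slots contribute ``NA``)."""
    if pair.gene not in g.node_types or pair.drug not in g.node_types:
        raise ValueError(f"pair {pair.gene}-{pair.drug} not present in graph")
    gene_eq = g.equivalence_class(pair.gene)
    drug_eq = g.equivalence_class(pair.drug)

    gene_attrs: Set[str] = set()
    gp: List[Tuple[str, Label]] = []  # (predicate, phenotype node)
    gd: Set[str] = set()
    for node in gene_eq:
        for e in g.out_edges(node):
            if not isinstance(e.obj, Label) or e.predicate.namespace == PGX_NS:
                continue
            t = g.node_types.get(e.obj)
            if t == ATTRIBUTE:
                gene_attrs.add(e.obj.local_id)
            elif t == PHENOTYPE:
                gp.append((str(e.predicate), e.obj))
            elif t == DRUG and e.obj in drug_eq:
                gd.add(str(e.predicate))
        for e in g.in_edges(node):
            if e.predicate.namespace == PGX_NS:
                continue
            if g.node_types.get(e.subject) == DRUG and e.subject in drug_eq:
                gd.add(str(e.predicate))

    drug_attrs: Set[str] = set()
    dp: List[Tuple[str, Label]] = []
    for node in drug_eq:
        for e in g.out_edges(node):
            if not isinstance(e.obj, Label) or e.predicate.namespace == PGX_NS:
                continue
            t = g.node_types.get(e.obj)
            if t == ATTRIBUTE:
                drug_attrs.add(e.obj.local_id)
            elif t == PHENOTYPE:
                dp.append((str(e.predicate), e.obj))

    # Shared phenotypes: canonicalize each side's phenotype through its
    # equivalence class, then join.
    canon_cache: Dict[Label, Label] = {}

    def canon(ph: Label) -> Label:
        if ph not in canon_cache:
            rep = min(g.equivalence_class(ph))
            for m in g.equivalence_class(ph):
                canon_cache[m] = rep
        return canon_cache[ph]

    gp_by_ph: Dict[Label, Set[str]] = defaultdict(set)
    for pred, ph in gp:
        gp_by_ph[canon(ph)].add(pred)
    dp_by_ph: Dict[Label, Set[str]] = defaultdict(set)
    for pred, ph in dp:
        dp_by_ph[canon(ph)].add(pred)
    triples: List[Tuple[str, str, str]] = []
    disease_attrs: Set[str] = set()
    for ph in sorted(set(gp_by_ph) & set(dp_by_ph)):
        for gpl in sorted(gp_by_ph[ph]):
            for dpl in sorted(dp_by_ph[ph]):
                triples.append((gpl, ph.local_id, dpl))
        if cfg.include_disease_attribute:
            for member in g.equivalence_class(ph):
                for e in g.out_edges(member):
                    if isinstance(e.obj, Label) and g.node_types.get(e.obj) == ATTRIBUTE:
                        disease_attrs.add(e.obj.local_id)

    pair_id = (str(pair.gene), str(pair.drug))
    klass = _class_token(pair)
    rows = []
    slot_sets = [
        sorted(gene_attrs) or [NA],
        sorted(triples) or [(NA, NA, NA)],
        sorted(drug_attrs) or [NA],
        sorted(gd) or [NA],
    ]
    if cfg.include_disease_attribute:
        slot_sets.append(sorted(disease_attrs) or [NA])
    for combo in itertools.product(*slot_sets):
        ga, (gpl, ph, dpl), da, gdl = combo[:4]
        rows.append(
            InstanceRow(
                pair_id=pair_id,
                gene_attribute=ga,
                phenotype=ph,
                drug_attribute=da,
                gd_link=gdl,
                gp_link=gpl,
                dp_link=dpl,
                klass=klass,
                disease_attribute=combo[4] if cfg.include_disease_attribute else None,
            )
        )
    return Bag(pair_id=pair_id, rows=rows)


def build_bags(
    g: PGxGraph, pairs: Sequence[GeneDrugPair], cfg: FeatureConfig = FeatureConfig()
) -> List[Bag]:
    return [build_instances(g, p, cfg) for p in pairs]


# -- encoding ----------------------------------------------------------


class FeatureMatrix:
    """Categorical instance table plus a frozen one-hot encoding.

    The encoding vocabulary is fixed at construction (training time);
    values unseen later fall back to the ``NA`` column of their slot, so
    test rows always encode into the same column space.
    """

    def __init__(self, frame: pd.DataFrame, slots: Optional[List[str]] = None):
        self.frame = frame.reset_index(drop=True)
        self.slots = list(slots) if slots is not None else [s for s in SLOTS + [DISEASE_SLOT] if s in frame.columns]
        self.vocab: Dict[str, Dict[str, int]] = {}
        col = 0
        for slot in self.slots:
            values = sorted(set(self.frame[slot].astype(str))) if len(self.frame) else []
            if NA not in values:
                values.append(NA)
            self.vocab[slot] = {v: col + i for i, v in enumerate(values)}
            col += len(values)
        self.n_columns = col

    @classmethod
    def from_bags(cls, bags: Sequence[Bag]) -> "FeatureMatrix":
        return cls(bags_to_frame(bags))

    # encoding --------------------------------------------------------

    def encode(self, frame: Optional[pd.DataFrame] = None) -> sp.csr_matrix:
        frame = self.frame if frame is None else frame
        rows, cols = [], []
        for slot in self.slots:
            v = self.vocab[slot]
            na = v[NA]
            for i, value in enumerate(frame[slot].astype(str)):
                rows.append(i)
                cols.append(v.get(value, na))
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(len(frame), self.n_columns))

    def decode(self, X: sp.csr_matrix) -> pd.DataFrame:
        rev: Dict[int, Tuple[str, str]] = {}
        for slot, v in self.vocab.items():
            for value, c in v.items():
                rev[c] = (slot, value)
        out = []
        for i in range(X.shape[0]):
            row = {slot: NA for slot in self.slots}
            for c in X[i].indices:
                slot, value = rev[c]
                row[slot] = value
            out.append(row)
        return pd.DataFrame(out, columns=self.slots)

    @property
    def labels(self) -> pd.Series:
        return self.frame["class"]


def bags_to_frame(bags: Sequence[Bag]) -> pd.DataFrame:
    records = []
    for bag in bags:
        for r in bag.rows:
            rec = {
                "pair_id": f"{r.pair_id[0]}|{r.pair_id[1]}",
                "gene_attribute": r.gene_attribute,
                "phenotype": r.phenotype,
                "drug_attribute": r.drug_attribute,
                "gd_link": r.gd_link,
                "gp_link": r.gp_link,
                "dp_link": r.dp_link,
                "class": r.klass,
            }
            if r.disease_attribute is not None:
                rec[DISEASE_SLOT] = r.disease_attribute
            records.append(rec)
    columns = ["pair_id"] + SLOTS + ["class"]
    if records and DISEASE_SLOT in records[0]:
        columns = ["pair_id"] + SLOTS + [DISEASE_SLOT] + ["class"]
    return pd.DataFrame(records, columns=columns)


def build_matrix(bags: Sequence[Bag]) -> FeatureMatrix:
    """One-hot feature matrix over the union of observed slot values."""
    return FeatureMatrix.from_bags(bags)


# -- information gain --------------------------------------------------


def _entropy(counts: Iterable[int]) -> float:
    total = sum(counts)
    if total == 0:
        return 0.0
    return -sum((c / total) * math.log2(c / total) for c in counts if c)


def information_gain(m: FeatureMatrix, slot: str) -> float:
    """H(class) - H(class | slot) in bits, over labeled rows only."""
    if slot not in m.slots:
        raise ValueError(f"unknown slot {slot!r}; have {m.slots}")
    labeled = m.frame[m.frame["class"].isin(["0", "1"])]
    n = len(labeled)
    if n == 0:
        return 0.0
    h_class = _entropy(Counter(labeled["class"]).values())
    h_cond = 0.0
    for _, sub in labeled.groupby(slot):
        h_cond += len(sub) / n * _entropy(Counter(sub["class"]).values())
    return max(0.0, h_class - h_cond)


def filter_features(m: FeatureMatrix, threshold: float) -> FeatureMatrix:
    """Drop every slot with information gain below ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    gains = {slot: information_gain(m, slot) for slot in m.slots}
    kept = [s for s in m.slots if gains[s] >= threshold]
    dropped = [s for s in m.slots if s not in kept]
    for s in dropped:
        logger.info("dropping slot %s (information gain %.4f < %.4f)", s, gains[s], threshold)
    if not kept:
        raise ValueError(f"threshold {threshold} would drop every slot (gains: {gains})")
    return FeatureMatrix(m.frame, slots=kept)
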
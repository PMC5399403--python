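"""Training and test pair sets for gene-drug association learning.

Source annotations relate gene *variants* to drugs with an evidence level
from 1 (best validated) to 4 (weakest). The corpus builder collapses
variants to the gene level keeping the strongest level, selects level-1/2
pairs as positives, samples negatives outside an exclusion list of known
gene-drug interactions, and keeps the level-3/4 pairs as the unknown test
set to be prioritized.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .labels import Label

ASSOCIATED = "associated"
NOT_ASSOCIATED = "not_associated"
UNKNOWN = "unknown"

VALID_LEVELS = {1, 2, 3, 4}


@dataclass(frozen=True)
class VariantAnnotation:
    gene: Label
    variant_id: str
    drug: Label
    evidence_level: int


@dataclass(frozen=True)
class GeneDrugPair:
    """A candidate gene-drug pair.

    label=associated requires evidence level 1 or 2; label=unknown means
    insufficiently validated (level 3/4) or unannotated.
    """

    gene: Label
    drug: Label
    evidence_level: Optional[int] = None
    label: str = UNKNOWN

    @property
    def key(self) -> Tuple[Label, Label]:
        return (self.gene, self.drug)


def collapse_variants(annotations: Iterable[VariantAnnotation]) -> List[GeneDrugPair]:
    """Collapse variant-level annotations to one pair per (gene, drug),
    keeping the strongest evidence level (numerically smallest; level 1 is
    the best validated)."""
    best: dict = {}
    for a in annotations:
        if a.evidence_level not in VALID_LEVELS:
            raise ValueError(
                f"evidence level {a.evidence_level!r} outside 1-4 for "
                f"{a.gene}-{a.drug} variant {a.variant_id!r}"
            )
        k = (a.gene, a.drug)
        if k not in best or a.evidence_level < best[k]:
            best[k] = a.evidence_level
    return [
        GeneDrugPair(g, d, lvl, ASSOCIATED if lvl <= 2 else UNKNOWN)
        for (g, d), lvl in sorted(best.items())
    ]


def select_positives(pairs: Iterable[GeneDrugPair]) -> List[GeneDrugPair]:
    """Pairs with a high level of validation (evidence level 1 or 2)."""
    out = [
        replace(p, label=ASSOCIATED)
        for p in pairs
        if p.evidence_level in (1, 2)
    ]
    return sorted(out, key=lambda p: p.key)


def select_test(pairs: Iterable[GeneDrugPair]) -> List[GeneDrugPair]:
    """Insufficiently validated pairs (evidence level 3 or 4)."""
    out = [replace(p, label=UNKNOWN) for p in pairs if p.evidence_level in (3, 4)]
    return sorted(out, key=lambda p: p.key)


def sample_negatives(
    gene_pool: Sequence[Label],
    drug_pool: Sequence[Label],
    exclusion: Set[Tuple[Label, Label]],
    n: int,
    seed: int,
) -> List[GeneDrugPair]:
    """Sample ``n`` distinct gene-drug pairs uniformly without replacement
    from the cartesian product of the pools minus the exclusion list.

    The pools are the entities listed in the seed pair table (not all
    graph entities). Sampling is sorted-then-shuffled so the result is
    stable across platforms.
    """
    genes = sorted(set(gene_pool))
    drugs = sorted(set(drug_pool))
    admissible = [(g, d) for g in genes for d in drugs if (g, d) not in exclusion]
    if n > len(admissible):
        raise ValueError(f"requested {n} negatives but only {len(admissible)} admissible pairs exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(admissible), size=n, replace=False)
    chosen = sorted(admissible[i] for i in idx)
    return [GeneDrugPair(g, d, None, NOT_ASSOCIATED) for g, d in chosen]


# -- TSV interchange ---------------------------------------------------

PAIR_COLUMNS = ["gene_label", "drug_label", "evidence_level", "class"]


def pairs_to_frame(pairs: Iterable[GeneDrugPair]) -> pd.DataFrame:
    rows = [
        {
            "gene_label": str(p.gene),
            "drug_label": str(p.drug),
            "evidence_level": "" if p.evidence_level is None else p.evidence_level,
            "class": p.label,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def write_pairs(pairs: Iterable[GeneDrugPair], path: Union[str, Path]) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_pairs(path: Union[str, Path]) -> List[GeneDrugPair]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        level = int(r["evidence_level"]) if r["evidence_level"] else None
        out.append(
            GeneDrugPair(
                Label.parse(r["gene_label"]),
                Label.parse(r["drug_label"]),
                level,
                r["class"] or UNKNOWN,
            )
        )
    return out


def write_exclusion(exclusion: Iterable[Tuple[Label, Label]], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [(str(g), str(d)) for g, d in sorted(exclusion)], columns=["gene_label", "drug_label"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_exclusion(path: Union[str, Path]) -> Set[Tuple[Label, Label]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {(Label.parse(g), Label.parse(d)) for g, d in zip(df["gene_label"], df["drug_label"])}


def read_annotations(path: Union[str, Path]) -> List[VariantAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        VariantAnnotation(
            Label.parse(r["gene_label"]), r["variant_id"], Label.parse(r["drug_label"]), int(r["evidence_level"])
        )
        for _, r in df.iterrows()
    ]


def write_annotations(annotations: Iterable[VariantAnnotation], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_label": str(a.gene),
                "variant_id": a.variant_id,
                "drug_label": str(a.drug),
                "evidence_level": a.evidence_level,
            }
            for a in annotations
        ],
        columns=["gene_label", "variant_id", "drug_label", "evidence_level"],
    )
    df.to_csv(path, sep="\t", index=False)
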
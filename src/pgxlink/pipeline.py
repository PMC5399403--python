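"""End-to-end wiring of the two branches over a loaded graph and pair sets."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .corpus import ASSOCIATED, GeneDrugPair
from .features import FeatureConfig, build_bags
from .graph import PGxGraph, add_pair_nodes
from .kernels import KernelConfig, pair_kernel
from .labels import pair_label
from .learn import (
    BagScore,
    CVReport,
    ForestBagLearner,
    KernelSVMLearner,
    NestedKernelSVMLearner,
    RankedCandidate,
    combine_rankings,
    crossvalidate,
    score_test_bags,
)


def _labels(pairs: Sequence[GeneDrugPair]) -> np.ndarray:
    return np.array([1 if p.label == ASSOCIATED else 0 for p in pairs], dtype=int)


def forest_cv(
    g: PGxGraph,
    train_pairs: Sequence[GeneDrugPair],
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    feature_cfg: FeatureConfig = FeatureConfig(),
    n_estimators: int = 100,
    ig_threshold: float = 0.0,
    repeat_seeds: Optional[Sequence[int]] = None,
) -> CVReport:
    """Repeated stratified CV of the forest branch at the pair level."""
    bags = build_bags(g, train_pairs, feature_cfg)
    y = _labels(train_pairs)
    learner = ForestBagLearner(bags, y, seed=seed, n_estimators=n_estimators, ig_threshold=ig_threshold)
    return crossvalidate(y, learner, folds=folds, repeats=repeats, base_seed=seed,
                         pair_ids=[b.pair_id for b in bags], seeds=repeat_seeds)


#: kernel settings offered to the nested (inner-fold) optimization; the
#: three substructure families at the default tree neighborhood
DEFAULT_SETTING_GRID: Dict[str, KernelConfig] = {
    "tree_subtrees": KernelConfig(),
    "tree_bag_of_labels": KernelConfig(substructure="bag_of_labels"),
    "tree_walks": KernelConfig(substructure="walks"),
}


def kernel_cv(
    g: PGxGraph,
    train_pairs: Sequence[GeneDrugPair],
    kernel_cfg: KernelConfig = KernelConfig(),
    folds: int = 10,
    repeats: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
    C_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0),
    setting_grid: Optional[Dict[str, KernelConfig]] = None,
    repeat_seeds: Optional[Sequence[int]] = None,
) -> CVReport:
    """Repeated stratified CV of the graph-kernel/SVM branch.

    With ``setting_grid``, the inner folds jointly optimize the kernel
    setting and C (the nested protocol of the final evaluation);
    otherwise only C is tuned on the single ``kernel_cfg`` kernel.
    """
    y = _labels(train_pairs)
    ids = [(str(p.gene), str(p.drug)) for p in train_pairs]
    if setting_grid is None:
        K, _ = train_kernel(g, train_pairs, kernel_cfg)
        learner = KernelSVMLearner(K, y, C_grid=C_grid, inner_folds=inner_folds, seed=seed)
    else:
        kernels = {name: train_kernel(g, train_pairs, cfg)[0] for name, cfg in setting_grid.items()}
        learner = NestedKernelSVMLearner(kernels, y, C_grid=C_grid,
                                         inner_folds=inner_folds, seed=seed)
    return crossvalidate(y, learner, folds=folds, repeats=repeats, base_seed=seed,
                         pair_ids=ids, seeds=repeat_seeds)


def train_kernel(
    g: PGxGraph, pairs: Sequence[GeneDrugPair], kernel_cfg: KernelConfig
) -> Tuple[np.ndarray, List]:
    """Augment the graph with pair nodes and compute their kernel matrix.

    Class-membership edges never reach the kernel features (stripped at
    reification), so the same matrix is reusable across CV folds.
    """
    g2 = add_pair_nodes(g, pairs)
    nodes = [pair_label(p.gene, p.drug) for p in pairs]
    return pair_kernel(g2, nodes, kernel_cfg), nodes


def rank_candidates(
    g: PGxGraph,
    train_pairs: Sequence[GeneDrugPair],
    test_pairs: Sequence[GeneDrugPair],
    kernel_cfg: KernelConfig = KernelConfig(),
    feature_cfg: FeatureConfig = FeatureConfig(),
    seed: int = 0,
    k: int = 20,
    n_estimators: int = 100,
    inner_folds: int = 10,
) -> Tuple[List[RankedCandidate], List[BagScore], List[BagScore]]:
    """Train both branches on the labeled pairs, score the unknown test
    pairs, and return the combined top-k ranking plus both score lists."""
    y = _labels(train_pairs)
    # forest branch
    train_bags = build_bags(g, train_pairs, feature_cfg)
    forest = ForestBagLearner(train_bags, y, seed=seed, n_estimators=n_estimators)
    forest.fit(list(range(len(train_bags))))
    rf_scores = score_test_bags(forest, build_bags(g, test_pairs, feature_cfg))
    # kernel branch
    all_pairs = list(train_pairs) + list(test_pairs)
    K, _ = train_kernel(g, all_pairs, kernel_cfg)
    y_all = np.concatenate([y, np.zeros(len(test_pairs), dtype=int)])
    svm = KernelSVMLearner(K, y_all, inner_folds=inner_folds, seed=seed)
    svm.fit(list(range(len(train_pairs))))
    ids = [(str(p.gene), str(p.drug)) for p in all_pairs]
    gk_scores = svm.score_pairs(ids, list(range(len(train_pairs), len(all_pairs))))
    return combine_rankings(rf_scores, gk_scores, k=k), rf_scores, gk_scores
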
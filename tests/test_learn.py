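import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxlink.corpus import ASSOCIATED, NOT_ASSOCIATED, GeneDrugPair
from pgxlink.features import NA, Bag, InstanceRow
from pgxlink.labels import Label
from pgxlink.learn import (
    BagScore,
    ConstantLearner,
    ForestBagLearner,
    KernelSVMLearner,
    aggregate_bag,
    combine_rankings,
    crossvalidate,
    evaluate_metrics,
    score_test_bags,
)

# -- bag aggregation ---------------------------------------------------


def test_aggregate_examples():
    assert aggregate_bag([(1.0, 1)] * 5) == 1.0
    assert aggregate_bag([(0.8, 1), (0.8, 0)]) == 0.0
    assert aggregate_bag([(0.9, 1), (0.6, 1), (0.3, 0)]) == pytest.approx(0.4)


def test_aggregate_empty_bag_errors():
    with pytest.raises(ValueError, match="empty bag"):
        aggregate_bag([])


@settings(max_examples=200, deadline=None)
@given(
    st.lists(
        st.tuples(st.floats(0, 1), st.integers(0, 1)), min_size=1, max_size=20
    )
)
def test_aggregate_bounds_and_sign_flip(instances):
    p = aggregate_bag(instances)
    assert -1.0 <= p <= 1.0
    flipped = [(pij, 1 - c) for pij, c in instances]
    assert aggregate_bag(flipped) == pytest.approx(-p)


# -- metrics -----------------------------------------------------------


def test_metrics_perfect_predictions():
    y = np.array([1, 1, 0, 0])
    m = evaluate_metrics(y, y.astype(float), y)
    assert m["per_class"]["1"]["f"] == 1.0
    assert m["weighted_f"] == 1.0
    assert m["rmse"] == 0.0
    assert m["auc_roc"] == 1.0


def test_metrics_hand_confusion_matrix():
    # TP=2 FP=1 FN=1 TN=6 -> precision = recall = F = 2/3 for the positives
    y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    d = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0])
    m = evaluate_metrics(y, d.astype(float), d)
    assert m["per_class"]["1"]["precision"] == pytest.approx(2 / 3)
    assert m["per_class"]["1"]["recall"] == pytest.approx(2 / 3)
    assert m["per_class"]["1"]["f"] == pytest.approx(2 / 3)


def test_metrics_constant_half_probability():
    y = np.array([1, 0] * 10)
    m = evaluate_metrics(y, np.full(20, 0.5), np.ones(20, dtype=int))
    assert m["rmse"] == pytest.approx(0.5)
    assert m["auc_roc"] == pytest.approx(0.5)


def test_metrics_single_class_auc_absent():
    y = np.ones(4, dtype=int)
    m = evaluate_metrics(y, np.ones(4), np.ones(4, dtype=int))
    assert m["auc_roc"] is None


def test_weighted_f_between_class_f_values():
    y = np.array([1] * 5 + [0] * 15)
    rng = np.random.default_rng(0)
    d = (rng.random(20) > 0.5).astype(int)
    m = evaluate_metrics(y, d.astype(float), d)
    f1, f0 = m["per_class"]["1"]["f"], m["per_class"]["0"]["f"]
    assert min(f1, f0) - 1e-12 <= m["weighted_f"] <= max(f1, f0) + 1e-12


# -- cross-validation protocol ----------------------------------------


def test_constant_classifier_closed_form_f():
    # prevalence 1/2 and constant positive predictions: F = 2p/(p+1) = 2/3
    y = np.array([1, 0] * 20)
    rep = crossvalidate(y, ConstantLearner(y, klass=1), folds=5, repeats=2, base_seed=3)
    assert rep.per_class_mean("1", "f") == pytest.approx(2 / 3)
    assert rep.per_class_mean("0", "f") == 0.0


def test_duplicated_pairs_stay_in_one_fold():
    y = np.array([1, 1, 0, 0] * 10)
    ids = [(f"g{i // 2}", f"d{i // 2}") for i in range(len(y))]  # duplicate every pair
    rep = crossvalidate(ConstantLearner(y).y, ConstantLearner(y), folds=4, repeats=2,
                        base_seed=0, pair_ids=ids)
    assert rep.repeats == 2  # completing without the leakage guard firing


# -- learners ----------------------------------------------------------


def _bag(pid, rows_spec, klass):
    rows = [
        InstanceRow((pid, pid), ga, NA, NA, NA, NA, NA, klass) for ga in rows_spec
    ]
    return Bag((pid, pid), rows)


def _separable_bags(n_per_class=12):
    bags, y = [], []
    for i in range(n_per_class):
        bags.append(_bag(f"p{i}", ["hit"], "1"))
        y.append(1)
        bags.append(_bag(f"n{i}", ["miss"], "0"))
        y.append(0)
    return bags, np.array(y)


def test_forest_perfectly_separable_training_accuracy():
    bags, y = _separable_bags()
    learner = ForestBagLearner(bags, y, seed=0)
    learner.fit(np.arange(len(y)))
    scores = learner.score_bags(bags)
    assert all(s.score > 0.5 for s, yi in zip(scores, y) if yi == 1)
    assert all(s.score < -0.5 for s, yi in zip(scores, y) if yi == 0)


def test_forest_single_class_errors():
    bags, y = _separable_bags()
    learner = ForestBagLearner(bags, y, seed=0)
    with pytest.raises(ValueError, match="single class"):
        learner.fit(np.where(y == 1)[0])


def test_forest_shuffled_labels_near_chance_auc():
    rng = np.random.default_rng(1)
    aucs = []
    for s in range(5):
        bags, y = _separable_bags(16)
        y_shuf = rng.permutation(y)
        learner = ForestBagLearner(bags, y_shuf, seed=s)
        rep = crossvalidate(y_shuf, learner, folds=4, repeats=1, base_seed=s,
                            pair_ids=[b.pair_id for b in bags])
        aucs.append(rep.auc_roc)
    assert abs(np.mean(aucs) - 0.5) < 0.15


def test_memorized_bag_scores_high():
    bags, y = _separable_bags()
    learner = ForestBagLearner(bags, y, seed=0).fit(np.arange(len(y)))
    test_bag = _bag("new", ["hit"], "unknown")
    scores = score_test_bags(learner, [test_bag])
    assert scores[0].score >= 0.5
    assert score_test_bags(learner, []) == []


def test_empty_test_bag_gets_na_row_and_warning():
    bags, y = _separable_bags()
    learner = ForestBagLearner(bags, y, seed=0).fit(np.arange(len(y)))
    empty = Bag(("gx", "dx"), [])
    with pytest.warns(UserWarning, match="no instances"):
        scores = score_test_bags(learner, [empty])
    assert len(scores) == 1


def test_svm_block_diagonal_kernel_perfect_cv():
    n = 40
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    K = np.zeros((n, n))
    K[: n // 2, : n // 2] = 1.0
    K[n // 2 :, n // 2 :] = 1.0
    np.fill_diagonal(K, 1.0)
    learner = KernelSVMLearner(K, y, inner_folds=3, seed=0)
    rep = crossvalidate(y, learner, folds=4, repeats=1, base_seed=0)
    assert rep.weighted_f == 1.0


def test_svm_rejects_non_psd_kernel():
    K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
    with pytest.raises(ValueError, match="not PSD"):
        KernelSVMLearner(K, [1, 0])


def test_svm_zero_offdiagonal_majority_baseline():
    n = 30
    y = np.array([1] * 10 + [0] * 20)
    K = np.eye(n)
    learner = KernelSVMLearner(K, y, inner_folds=3, seed=0)
    rep = crossvalidate(y, learner, folds=3, repeats=1, base_seed=0)
    # nothing to learn from: accuracy collapses to the majority class
    assert rep.per_class_mean("0", "recall") >= 0.9


# -- ranking -----------------------------------------------------------


def _table9_scores():
    rf = [
        BagScore(("MAP3K1", "Carboplatin"), 0.993),
        BagScore(("EGFR", "Erlotinib"), 0.992),
        BagScore(("EGFR", "Fluorouracil"), 0.989),
        BagScore(("OTHER", "DrugX"), 0.10),
    ]
    gk = [
        BagScore(("MAP3K1", "Carboplatin"), 0.991),
        BagScore(("EGFR", "Erlotinib"), 0.980),
        BagScore(("EGFR", "Fluorouracil"), 0.966),
        BagScore(("OTHER", "DrugY"), 0.05),
    ]
    return rf, gk


def test_combine_published_top_scores_order():
    rf, gk = _table9_scores()
    ranked = combine_rankings(rf, gk, k=3)
    assert [(r.gene, r.drug) for r in ranked[:2]] == [
        ("MAP3K1", "Carboplatin"),
        ("EGFR", "Erlotinib"),
    ]
    assert ranked[0].rank == 1 and ranked[1].rank == 2
    assert ranked[0].p_rf == 0.993 and ranked[0].p_gk == 0.991


def test_combine_disjoint_lists_empty():
    rf = [BagScore(("a", "x"), 0.9)]
    gk = [BagScore(("b", "y"), 0.9)]
    assert combine_rankings(rf, gk, k=1) == []


def test_combine_identical_lists_sorted_by_rf():
    scores = [BagScore(("a", "x"), 0.3), BagScore(("b", "y"), 0.9), BagScore(("c", "z"), 0.6)]
    ranked = combine_rankings(scores, list(scores), k=3)
    assert [r.gene for r in ranked] == ["b", "c", "a"]


def test_combine_invariant_to_input_order():
    rf, gk = _table9_scores()
    a = combine_rankings(rf, gk, k=3)
    b = combine_rankings(rf[::-1], gk[::-1], k=3)
    assert a == b


def test_combine_k_larger_than_list_warns_and_uses_all():
    rf, gk = _table9_scores()
    with pytest.warns(UserWarning, match="whole list"):
        ranked = combine_rankings(rf, gk, k=10)
    assert len(ranked) == 3


def test_nested_kernel_learner_selects_discriminative_kernel():
    from pgxlink.learn import NestedKernelSVMLearner

    n = 40
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    good = np.zeros((n, n))
    good[: n // 2, : n // 2] = 1.0
    good[n // 2 :, n // 2 :] = 1.0
    np.fill_diagonal(good, 1.0)
    useless = np.eye(n)
    learner = NestedKernelSVMLearner({"good": good, "useless": useless}, y,
                                     inner_folds=3, seed=0)
    from pgxlink.learn import crossvalidate

    rep = crossvalidate(y, learner, folds=4, repeats=1, base_seed=0)
    assert rep.weighted_f == 1.0
    assert learner.best_setting[0] == "good"
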
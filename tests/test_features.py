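"""Entropy/IG oracles, filter behaviour, wrapper and elimination stages."""

import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from graftsurv.errors import ConfigurationError, DataError
from graftsurv.features import (
    BinningConfig,
    ClassifierConfig,
    FeatureMask,
    SelectionConfig,
    _SubsetScorer,
    abo_wrapper_select,
    backward_eliminate,
    entropy,
    hybrid_select,
    ig_filter,
    information_gain,
    rank_features,
)


# -- independent brute-force oracle ----------------------------------------


def entropy_oracle(labels) -> float:
    counts = Counter(labels)
    n = len(labels)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def ig_oracle(feature, labels) -> float:
    """Contingency-table information gain by explicit enumeration."""
    n = len(labels)
    total = entropy_oracle(labels)
    cond = 0.0
    for v in set(feature):
        sub = [l for f, l in zip(feature, labels) if f == v]
        cond += (len(sub) / n) * entropy_oracle(sub)
    return total - cond


# -- entropy ----------------------------------------------------------------


def test_entropy_known_values():
    assert entropy([1, 1, 1, 1]) == 0.0
    assert entropy([1, 1, 0, 0]) == pytest.approx(1.0)
    assert entropy([1, 1, 1, 0]) == pytest.approx(0.8112781244591328, abs=1e-12)


def test_entropy_empty_errors():
    with pytest.raises(DataError):
        entropy([])


@given(st.lists(st.integers(0, 4), min_size=1, max_size=50))
def test_entropy_bounded_by_log_cardinality(labels):
    h = entropy(labels)
    k = len(set(labels))
    assert -1e-12 <= h <= math.log2(k) + 1e-12
    assert h == pytest.approx(entropy_oracle(labels), abs=1e-12)


# -- information gain --------------------------------------------------------


def test_ig_constant_feature_is_zero():
    labels = [0, 1, 0, 1, 1]
    assert information_gain([7.0] * 5, labels) == 0.0


def test_ig_perfect_feature_equals_label_entropy():
    labels = [0, 1, 0, 1, 1, 0]
    assert information_gain(labels, labels) == pytest.approx(
        entropy(labels), abs=1e-12
    )


def test_ig_two_by_two_contingency_case():
    # H(y) = 0.811278; H(y|A)=0, H(y|B)=1 -> IG = 0.311278
    feature = ["A", "A", "B", "B"]
    labels = [1, 1, 1, 0]
    assert information_gain(feature, labels) == pytest.approx(
        0.3112781244591328, abs=1e-12
    )
    assert ig_oracle(feature, labels) == pytest.approx(
        0.3112781244591328, abs=1e-12
    )


def test_ig_length_mismatch_errors():
    with pytest.raises(DataError):
        information_gain([1, 2], [0, 1, 0])


def test_ig_agrees_with_bruteforce_on_random_tables(rng):
    """100 random small categorical tables against the enumeration oracle."""
    for _ in range(100):
        n = int(rng.integers(3, 40))
        feature = rng.integers(0, 4, size=n).tolist()
        labels = rng.integers(0, 3, size=n).tolist()
        ours = information_gain(feature, labels)
        ref = ig_oracle(feature, labels)
        assert ours == pytest.approx(ref, rel=1e-12, abs=1e-12)


@given(
    st.integers(5, 60).flatmap(
        lambda n: st.tuples(
            st.lists(st.integers(0, 3), min_size=n, max_size=n),
            st.lists(st.integers(0, 1), min_size=n, max_size=n),
        )
    )
)
def test_ig_bounded_by_label_entropy(pair):
    feature, labels = pair
    ig = information_gain(feature, labels)
    assert -1e-12 <= ig <= entropy(labels) + 1e-12


def test_continuous_feature_is_binned_equal_frequency():
    rng = np.random.default_rng(0)
    x = rng.normal(size=500)
    y = (x > 0).astype(int)
    # a strongly informative continuous feature keeps high gain after binning
    assert information_gain(x, y, BinningConfig(n_bins=10)) > 0.5


# -- filter ------------------------------------------------------------------


def test_ig_filter_rejects_constant_keeps_perfect():
    X = pd.DataFrame({"const": [3.0] * 6, "perfect": [0, 1, 0, 1, 1, 0]})
    y = [0, 1, 0, 1, 1, 0]
    mask = ig_filter(X, y, threshold=0.0)
    np.testing.assert_array_equal(mask.values, [False, True])
    assert mask.provenance == "ig_filter"


def test_ig_filter_threshold_zero_selects_positive_gain():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, size=200)
    X = pd.DataFrame(
        {
            "signal": y + rng.normal(scale=0.1, size=200),
            "const": np.ones(200),
        }
    )
    mask = ig_filter(X, y, threshold=0.0)
    gains = rank_features(X, y).gains
    np.testing.assert_array_equal(mask.values, gains > 0)


def test_ig_filter_empty_result_repaired_to_top_feature():
    X = pd.DataFrame({"c1": [1.0] * 8, "c2": [2.0] * 8})
    mask = ig_filter(X, [0, 1] * 4, threshold=0.0)
    assert mask.n_selected == 1


def test_ig_filter_recovers_planted_informative_features():
    """All planted features pass the zero-threshold filter (median of seeds)."""
    from graftsurv import preprocessing as pp
    from graftsurv.synthetic import CohortSpec, generate_cohort

    recalls = []
    for seed in range(5):
        table, truth = generate_cohort(CohortSpec(n_patients=2000, seed=seed))
        table = pp.attach_labels(pp.impute_table(pp.clean_table(table)))
        X = table.frame[table.columns_by_tag("preop")]
        y = table.frame[table.outcome_column].to_numpy()
        mask = ig_filter(X, y, threshold=0.0)
        selected = set(mask.selected_names())
        recalls.append(
            len(selected & set(truth.informative_columns))
            / len(truth.informative_columns)
        )
    assert np.median(recalls) == 1.0


# -- feature mask ------------------------------------------------------------


def test_feature_mask_must_be_non_empty():
    with pytest.raises(ConfigurationError):
        FeatureMask(np.zeros(3, dtype=bool), "ig_filter")


# -- wrapper -----------------------------------------------------------------


def _two_feature_problem(seed, n=80):
    """One separable signal feature, one actively misleading noise feature."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    signal = y * 2.0 - 1.0 + rng.normal(scale=0.05, size=n)
    noise = rng.normal(size=n)
    return pd.DataFrame({"signal": signal, "noise": noise}), y


def test_wrapper_single_feature_mask_returned_unchanged():
    X, y = _two_feature_problem(0)
    mask_in = FeatureMask(np.array([True, False]), "ig_filter", list(X.columns))
    out = abo_wrapper_select(X, y, mask_in, seed=0)
    np.testing.assert_array_equal(out.values, mask_in.values)


def test_wrapper_matches_exhaustive_subset_oracle():
    """Returned subset scores as well as the best of all non-empty subsets."""
    from graftsurv.abo import ABOConfig

    wins = 0
    for seed in range(5):
        X, y = _two_feature_problem(seed)
        cfg = ClassifierConfig(kind="tree")
        mask_in = FeatureMask(np.ones(2, dtype=bool), "input", list(X.columns))
        out = abo_wrapper_select(
            X, y, mask_in, classifier_config=cfg,
            abo_config=ABOConfig(n_buffalo=8, max_iterations=10, bounds=(-4, 4)),
            seed=seed,
        )
        scorer = _SubsetScorer(X, y, cfg, 0.2, seed)
        best = max(
            scorer.accuracy(np.array(m))
            for m in itertools.product([False, True], repeat=2)
            if any(m)
        )
        achieved = scorer.accuracy(out.values)
        assert achieved == pytest.approx(best)
        wins += not out.values[1]  # noise excluded?
    assert wins >= 3  # majority of seeds


def test_wrapper_never_scores_worse_than_input_mask(processed_cohort):
    table, _ = processed_cohort
    X = table.frame[table.columns_by_tag("preop")].iloc[:, :12]
    y = table.frame[table.outcome_column].to_numpy()
    cfg = ClassifierConfig()
    mask_in = FeatureMask(np.ones(12, dtype=bool), "input", list(X.columns))
    from graftsurv.abo import ABOConfig

    out = abo_wrapper_select(
        X, y, mask_in, classifier_config=cfg,
        abo_config=ABOConfig(n_buffalo=8, max_iterations=8, bounds=(-4, 4)),
        seed=4,
    )
    scorer = _SubsetScorer(X, y, cfg, 0.2, 4)
    assert scorer.accuracy(out.values) >= scorer.accuracy(mask_in.values)


# -- backward elimination ----------------------------------------------------


def _harmful_feature_problem(seed=0, n=60):
    """A perfect predictor plus a feature that strictly hurts a small tree."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    perfect = y.astype(float)
    # harmful: nearly predictive on train but inverted in distribution tails,
    # so a depth-1 tree that uses it generalizes worse than one using 'perfect'
    harmful = rng.normal(size=n) + (1 - y) * 0.8
    return pd.DataFrame({"perfect": perfect, "harmful": harmful}), y


def test_elimination_drops_harmful_feature_keeps_predictor():
    X, y = _harmful_feature_problem()
    cfg = ClassifierConfig(kind="tree", params={"max_depth": 2})
    mask_in = FeatureMask(np.ones(2, dtype=bool), "input", list(X.columns))
    out = backward_eliminate(X, y, mask_in, classifier_config=cfg, seed=0)
    assert out.values[0]  # perfect predictor kept
    scorer = _SubsetScorer(X, y, cfg, 0.2, 0)
    assert scorer.accuracy(out.values) >= scorer.accuracy(mask_in.values)


def test_elimination_keeps_feature_on_exact_tie():
    # removing a constant never changes accuracy: a tie, so it is kept
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, size=100)
    X = pd.DataFrame(
        {"signal": y + rng.normal(scale=0.2, size=100), "const": np.ones(100)}
    )
    mask_in = FeatureMask(np.ones(2, dtype=bool), "input", list(X.columns))
    out = backward_eliminate(X, y, mask_in, seed=1)
    assert out.values.all()


def test_elimination_never_decreases_validation_accuracy(processed_cohort):
    table, _ = processed_cohort
    X = table.frame[table.columns_by_tag("preop")].iloc[:, :15]
    y = table.frame[table.outcome_column].to_numpy()
    cfg = ClassifierConfig()
    mask_in = FeatureMask(np.ones(15, dtype=bool), "input", list(X.columns))
    out = backward_eliminate(X, y, mask_in, classifier_config=cfg, seed=7)
    scorer = _SubsetScorer(X, y, cfg, 0.2, 7)
    assert scorer.accuracy(out.values) >= scorer.accuracy(mask_in.values)
    assert out.provenance == "backward_elimination"


def test_elimination_single_feature_returned_as_is():
    X = pd.DataFrame({"only": [0.0, 1.0] * 10})
    y = [0, 1] * 10
    mask_in = FeatureMask(np.array([True]), "input", list(X.columns))
    out = backward_eliminate(X, y, mask_in, seed=0)
    assert out.values[0]


# -- hybrid pipeline ---------------------------------------------------------


def test_hybrid_all_stages_disabled_returns_full_mask(processed_cohort):
    table, _ = processed_cohort
    X = table.frame[table.columns_by_tag("preop")]
    y = table.frame[table.outcome_column].to_numpy()
    cfg = SelectionConfig(
        use_ig_filter=False, use_abo_wrapper=False, use_backward_elimination=False
    )
    result = hybrid_select(X, y, cfg)
    assert result.mask.values.all()
    assert result.stage_masks == {}


def test_hybrid_stage_masks_are_nested(processed_cohort):
    table, _ = processed_cohort
    X = table.frame[table.columns_by_tag("preop")].iloc[:, :20]
    y = table.frame[table.outcome_column].to_numpy()
    from graftsurv.abo import ABOConfig

    cfg = SelectionConfig(
        wrapper_abo=ABOConfig(n_buffalo=6, max_iterations=6, bounds=(-4, 4)),
        seed=2,
    )
    result = hybrid_select(X, y, cfg)
    ig = result.stage_masks["ig_filter"].values
    wrap = result.stage_masks["abo_wrapper"].values
    final = result.mask.values
    assert not (wrap & ~ig).any()  # wrapper only removes
    assert not (final & ~wrap).any()  # elimination only removes
    assert final.sum() >= 1
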
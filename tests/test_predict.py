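"""Feature selection, SVM cross-validation and sequential elimination."""

import numpy as np
import pandas as pd
import pytest

from rettnet import (FeatureTable, PredictorSpec, ResponsePredictor,
                     crossvalidate, crossvalidate_nested, select_features,
                     sequential_elimination)
from rettnet.exceptions import EmptySelectionError
from rettnet.predict import _make_folds
from rettnet.stats import PosthocTable


def _posthoc_frame(rows):
    df = pd.DataFrame(rows)
    return PosthocTable(table=df, contrast="test", test="Mann-Whitney U",
                        alpha=0.05)


def test_select_singleton():
    ph = _posthoc_frame([
        {"pair": "O1-O2", "p": 0.01, "median_diff": 0.3},
        {"pair": "F3-F4", "p": 0.4, "median_diff": 0.0}])
    assert select_features(ph) == ["O1-O2"]


def test_select_sorts_by_p():
    ph = _posthoc_frame([
        {"pair": "F3-F4", "p": 0.04, "median_diff": 0.1},
        {"pair": "O1-O2", "p": 0.01, "median_diff": 0.1}])
    assert select_features(ph) == ["O1-O2", "F3-F4"]


def test_select_ties_break_by_effect_size_then_canonical_order():
    ph = _posthoc_frame([
        {"pair": "F3-O1", "p": 0.016, "median_diff": 0.15},
        {"pair": "O1-O2", "p": 0.016, "median_diff": 0.30},
        {"pair": "F3-F4", "p": 0.016, "median_diff": 0.15}])
    assert select_features(ph) == ["O1-O2", "F3-F4", "F3-O1"]


def test_empty_selection_raises():
    ph = _posthoc_frame([{"pair": "O1-O2", "p": 0.2, "median_diff": 0.1}])
    with pytest.raises(EmptySelectionError):
        select_features(ph)


def test_study_cohort_ranks_o1o2_first(study_features):
    ft, _ = study_features
    predictor = ResponsePredictor(ft)
    ranked = predictor.rank_features()
    assert ranked[0] == "O1-O2"


def test_separable_cohort_predicts_perfectly(study_features):
    """Under the emulated study conditions (strongly separated responder
    coherence at baseline) pooled 5-fold CV is perfect."""
    ft, _ = study_features
    report = ResponsePredictor(ft, spec=PredictorSpec(seed=0)).fit(k=5)
    assert report.n == 9
    assert report.accuracy == 1.0
    assert report.sensitivity == 1.0
    assert report.specificity == 1.0
    # every subject held out exactly once
    assert report.fold_assignments["subject"].is_unique
    assert report.confusion_matrix.sum() == 9


def test_metrics_consistent_with_confusion_matrix(study_features):
    ft, _ = study_features
    report = ResponsePredictor(ft, spec=PredictorSpec(seed=0)).fit(k=5)
    tp, fn = report.confusion_matrix[0]
    fp, tn = report.confusion_matrix[1]
    assert report.accuracy == (tp + tn) / report.n
    assert report.sensitivity == tp / (tp + fn)
    assert report.specificity == tn / (tn + fp)


def test_fold_sizes_as_equal_as_possible(study_features):
    ft, _ = study_features
    report = ResponsePredictor(ft, spec=PredictorSpec(seed=0)).fit(k=5)
    sizes = sorted(report.fold_assignments["fold"].value_counts())
    assert sizes == [1, 2, 2, 2, 2]


def test_leave_one_out_matches_on_separable_data(study_features):
    ft, _ = study_features
    predictor = ResponsePredictor(ft, spec=PredictorSpec(seed=0))
    x, y = predictor._baseline_xy()
    feats = predictor.rank_features()
    loo = crossvalidate(x, y, k=len(y), spec=PredictorSpec(seed=0),
                        features=feats)
    assert loo.accuracy == 1.0


def test_permutation_null_accuracy_is_chance(study_features):
    """With labels randomly permuted, mean CV accuracy sits at chance."""
    ft, _ = study_features
    predictor = ResponsePredictor(ft, spec=PredictorSpec(seed=0))
    x, y = predictor._baseline_xy()
    feats = predictor.rank_features()
    rng = np.random.default_rng(0)
    accs = []
    for i in range(500):
        perm = rng.permutation(len(y))
        rep = crossvalidate(x, y[perm], k=5, spec=PredictorSpec(seed=i),
                            features=feats)
        accs.append(rep.accuracy)
    assert np.mean(accs) == pytest.approx(0.5, abs=0.1)


def test_elimination_keeps_the_informative_feature():
    """One informative feature among noise survives to the final
    single-feature model."""
    rng = np.random.default_rng(1)
    n = 10
    y = np.array(["responder"] * 5 + ["nonresponder"] * 5)
    cols = {"O1-O2": np.where(y == "responder", 0.7, 0.3)
            + rng.normal(0, 0.03, n)}
    for j, name in enumerate(["F3-F4", "F3-T3", "T3-T4", "P3-P4", "F4-T4"]):
        cols[name] = rng.uniform(0.2, 0.6, n)
    x = pd.DataFrame(cols, index=[f"S{i}" for i in range(n)])
    ranked = ["O1-O2", "F3-F4", "F3-T3", "T3-T4", "P3-P4", "F4-T4"]
    curve = sequential_elimination(x, y, ranked, k=5,
                                   spec=PredictorSpec(seed=1))
    assert len(curve) == 6
    assert curve.iloc[-1]["features"] == ("O1-O2",)
    assert curve.iloc[-1]["accuracy"] == 1.0


def test_elimination_on_pure_noise_hovers_at_chance():
    rng = np.random.default_rng(2)
    n = 10
    y = np.array(["responder"] * 5 + ["nonresponder"] * 5)
    names = ["F3-F4", "F3-T3", "T3-T4", "P3-P4"]
    accs = []
    for rep in range(30):
        x = pd.DataFrame(rng.uniform(0.2, 0.6, size=(n, 4)), columns=names,
                         index=[f"S{i}" for i in range(n)])
        curve = sequential_elimination(x, y, names, k=5,
                                       spec=PredictorSpec(seed=rep))
        accs.extend(curve["accuracy"])
    assert np.mean(accs) == pytest.approx(0.5, abs=0.15)


def test_folds_are_deterministic_for_fixed_seed():
    y = np.array([True] * 5 + [False] * 4)
    f1 = _make_folds(y, 5, seed=3)
    f2 = _make_folds(y, 5, seed=3)
    for (tr1, te1), (tr2, te2) in zip(f1, f2):
        assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)


def test_nested_mode_runs_and_reports_no_leakage_note(study_features):
    ft, _ = study_features
    report = crossvalidate_nested(ft, k=5, spec=PredictorSpec(seed=0))
    assert report.mode == "nested"
    assert "nested" in report.note
    assert report.n == 9
    # strongly separated data stays perfectly classified even without
    # selection leakage
    assert report.accuracy == 1.0


def test_report_flags_selection_leakage(study_features):
    ft, _ = study_features
    report = ResponsePredictor(ft, spec=PredictorSpec(seed=0)).fit(k=5)
    assert "before cross-validation" in report.note
    assert "before cross-validation" in report.summary()
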
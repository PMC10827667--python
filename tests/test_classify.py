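"""Classifier bank, metrics, ROC/AUC and evaluation protocols."""

import numpy as np
import pandas as pd
import pytest

from lithopredict import simcohort
from lithopredict.classify import (
    ClassifierSpec,
    ConfusionMatrix,
    cross_cohort_eval,
    default_specs,
    metrics,
    predict_scores,
    repeated_split_eval,
    roc_auc,
    train,
)
from lithopredict.diffexpr import _u_statistic


def test_metrics_worked_example():
    acc, prec, rec, cm = metrics(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0]))
    assert acc == prec == rec == 0.5
    assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 1, 1, 1)


def test_metrics_edge_cases():
    y = np.array([1, 0, 1, 0, 1])
    acc, prec, rec, cm = metrics(y, y)
    assert acc == prec == rec == 1.0
    acc, prec, rec, cm = metrics(y, np.ones_like(y))
    assert rec == 1.0
    assert prec == pytest.approx(3 / 5)  # prevalence
    # accuracy always equals (tp+tn)/total
    assert acc == pytest.approx((cm.tp + cm.tn) / cm.total)
    with pytest.raises(ValueError, match="length"):
        metrics(np.array([1, 0]), np.array([1]))


def test_zero_denominator_metrics_report_zero():
    y = np.array([0, 0, 0])
    acc, prec, rec, cm = metrics(y, y)
    assert prec == 0.0 and rec == 0.0 and cm.tp == 0


def test_roc_auc_worked_examples():
    _, auc = roc_auc([0.9, 0.8, 0.3, 0.2], np.array([1, 1, 0, 0]))
    assert auc == 1.0
    _, auc = roc_auc([0.9, 0.8, 0.7, 0.1], np.array([1, 0, 1, 0]))
    assert auc == pytest.approx(0.75)
    _, auc = roc_auc([0.5] * 6, np.array([1, 0, 1, 0, 1, 0]))
    assert auc == 0.5
    with pytest.raises(ValueError, match="class"):
        roc_auc([0.1, 0.2], np.array([1, 1]))


def test_auc_equals_normalized_u_statistic():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n1 = int(rng.integers(2, 10))
        n0 = int(rng.integers(2, 10))
        scores = rng.integers(0, 6, n1 + n0).astype(float)  # force ties
        y = np.array([1] * n1 + [0] * n0)
        _, auc = roc_auc(scores, y, positive=1)
        u = _u_statistic(scores[:n1], scores[n1:])
        assert auc == pytest.approx(u / (n1 * n0))


def test_all_five_classifiers_fit_separable_toy():
    rng = np.random.default_rng(1)
    y = np.array([0] * 20 + [1] * 20)
    X = rng.normal(size=(40, 2)) + 6 * y[:, None]
    for spec in default_specs(seed=0):
        clf = train(spec, X, y)
        assert (clf.predict(X) == y).all()
        scores = predict_scores(clf, X)
        _, auc = roc_auc(scores, y, positive=1)
        assert auc == 1.0


def test_training_determinism_and_single_class_error():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(30, 3))
    y = np.array([0, 1] * 15)
    for spec in default_specs(seed=3):
        p1 = train(spec, X, y).predict(X)
        p2 = train(spec, X, y).predict(X)
        assert (p1 == p2).all()
    with pytest.raises(ValueError, match="single class"):
        train(ClassifierSpec(kind="Lr"), X, np.zeros(30))


def test_constant_feature_column_is_tolerated():
    rng = np.random.default_rng(3)
    y = np.array([0, 1] * 10)
    X = np.column_stack([np.ones(20), rng.normal(size=20) + 3 * y])
    clf = train(ClassifierSpec(kind="Lr"), X, y)
    assert len(clf.predict(X)) == 20


def _panel_frame(rng, n_subjects=40, n_genes=5, effect=0.0, replicates=False):
    labels = np.array(["LR", "NR"] * (n_subjects // 2))
    subj = np.array([f"p{i}" for i in range(n_subjects)])
    X = rng.normal(size=(n_genes, n_subjects)) + effect * (labels == "NR")
    cols = subj.copy()
    if replicates:
        X = np.concatenate([X, X[:, :6] + rng.normal(0, 0.1, (n_genes, 6))], axis=1)
        cols = np.concatenate([subj, subj[:6]])
        labels = np.concatenate([labels, labels[:6]])
        subj = cols
    df = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)],
                      columns=[f"c{i}" for i in range(len(cols))])
    return df, labels, subj


def test_repeated_split_accounting_and_grouping():
    rng = np.random.default_rng(4)
    X, labels, subj = _panel_frame(rng, effect=4.0, replicates=True)
    specs = [ClassifierSpec(kind="Lr"), ClassifierSpec(kind="SVM")]
    rep = repeated_split_eval(X, labels, subj, specs, n_reps=8, seed=5)
    assert len(rep.records) == 8 * len(specs)
    for kind in ("Lr", "SVM"):
        recs = rep.records[rep.records["classifier"] == kind]
        assert rep.confusion[kind].total == recs["n_test"].sum()
        assert (recs["accuracy"] == 1.0).all()
        assert rep.auc_mean[kind] == 1.0


def test_repeated_split_chance_level_under_permutation():
    rng = np.random.default_rng(5)
    X, labels, subj = _panel_frame(rng, effect=0.0)
    rep = repeated_split_eval(X, labels, subj, [ClassifierSpec(kind="Lr")],
                              n_reps=20, seed=6)
    assert abs(rep.records["accuracy"].mean() - 0.5) < 0.15


def test_repeated_split_determinism():
    rng = np.random.default_rng(6)
    X, labels, subj = _panel_frame(rng, effect=1.0)
    r1 = repeated_split_eval(X, labels, subj, [ClassifierSpec(kind="Lr")],
                             n_reps=5, seed=9)
    r2 = repeated_split_eval(X, labels, subj, [ClassifierSpec(kind="Lr")],
                             n_reps=5, seed=9)
    pd.testing.assert_frame_equal(r1.records, r2.records)


def test_scale_invariance_after_standardization():
    rng = np.random.default_rng(7)
    X, labels, subj = _panel_frame(rng, effect=1.5)
    specs = [ClassifierSpec(kind=k) for k in ("Lr", "SVM", "KNN")]
    r1 = repeated_split_eval(X, labels, subj, specs, n_reps=5, seed=2)
    r2 = repeated_split_eval(X * 37.0 + 11.0, labels, subj, specs, n_reps=5, seed=2)
    assert np.allclose(r1.records["accuracy"], r2.records["accuracy"])


# ---------------------------------------------------------------------------
# cross-cohort transfer


def _cohort_pair(seed, shift=1.0):
    cfg1 = simcohort.two_group_config(seed=seed, n_per_group=10, n_genes=300,
                                      n_batches=1)
    cfg2 = simcohort.cohort2_config(seed=seed + 100, n_genes=300,
                                    batches=[simcohort.BatchSpec(
                                        batch_id="batch4", cohort_id="cohort2",
                                        location_shift_sigma=shift,
                                        scale_factor_range=(0.7, 1.4),
                                        sample_allocation={"LR": 12, "NR": 12})])
    return simcohort.generate_cohort_pair(cfg1, cfg2)


def test_transfer_to_identical_cohort_equals_resubstitution():
    (c1, m1, a1), _ = _cohort_pair(seed=8, shift=0.0)
    # a verbatim copy with renamed subjects/samples stands in for the test cohort
    c2 = c1.copy()
    c2.columns = [f"T{c}" for c in c1.columns]
    m2 = m1.copy()
    m2["sample_id"] = [f"T{s}" for s in m1["sample_id"]]
    m2["subject_id"] = [f"T{s}" for s in m1["subject_id"]]
    markers = a1.loc[a1["is_planted_marker"], "gene_id"].tolist()[:5]
    rep = cross_cohort_eval(c1, m1, c2, m2, markers,
                            specs=[ClassifierSpec(kind="Lr")], harmonize=False)
    acc_transfer = rep.records["accuracy"].iloc[0]
    # manual resubstitution on the identical collapsed features
    from lithopredict.diffexpr import collapse_replicates
    from lithopredict.featselect import _standardize
    from lithopredict.harmonize import log_normalize

    joint = pd.concat([c1, c2], axis=1)
    X = log_normalize(joint)
    Xp, sm = collapse_replicates(X.loc[markers], pd.concat([m1, m2], ignore_index=True))
    tr = sm["subject_id"].isin(m1["subject_id"]).to_numpy()
    Xtr = Xp.loc[:, tr].to_numpy().T
    ytr = sm.loc[tr, "response"].to_numpy()
    Xtr_s, _ = _standardize(Xtr, Xtr)
    clf = train(ClassifierSpec(kind="Lr"), Xtr_s, ytr)
    resub = (clf.predict(Xtr_s) == ytr).mean()
    assert acc_transfer == pytest.approx(resub)


def test_transfer_needs_harmonization_under_batch_shift():
    (c1, m1, a1), (c2, m2, _) = _cohort_pair(seed=9, shift=1.2)
    markers = a1.loc[a1["is_planted_marker"], "gene_id"].tolist()[:5]
    spec = [ClassifierSpec(kind="Lr")]
    acc_h = cross_cohort_eval(c1, m1, c2, m2, markers, spec,
                              harmonize=True).records["accuracy"].iloc[0]
    acc_n = cross_cohort_eval(c1, m1, c2, m2, markers, spec,
                              harmonize=False).records["accuracy"].iloc[0]
    assert acc_h >= 0.9
    assert acc_h > acc_n


def test_transfer_null_labels_near_prevalence():
    (c1, m1, a1), (c2, m2, _) = _cohort_pair(seed=10, shift=0.5)
    rng = np.random.default_rng(0)
    m2 = m2.copy()
    m2["response"] = rng.permutation(m2["response"].to_numpy())
    markers = a1.loc[a1["is_planted_marker"], "gene_id"].tolist()[:5]
    rep = cross_cohort_eval(c1, m1, c2, m2, markers, [ClassifierSpec(kind="Lr")])
    assert abs(rep.records["accuracy"].iloc[0] - 0.5) <= 0.3


def test_transfer_missing_panel_gene_is_reported():
    (c1, m1, _), (c2, m2, _) = _cohort_pair(seed=11)
    with pytest.raises(ValueError, match="GHOST"):
        cross_cohort_eval(c1, m1, c2, m2, ["GHOST"], [ClassifierSpec(kind="Lr")])
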
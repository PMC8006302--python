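import numpy as np
import pandas as pd
import pytest

from repstrat import (
    PipelineConfig,
    combine_chains,
    permutation_control,
    rank_and_associate,
    repeated_cv,
    run_iteration,
)
from repstrat.classify import _ZScore, lr_rfe, rf_rank, rfecv_choose_n


def _toy_matrix(rng, n=40, n_noise=20, effect=3.0):
    y = pd.Series(["case"] * (n // 2) + ["control"] * (n // 2),
                  index=[f"s{i}" for i in range(n)])
    X = pd.DataFrame(
        rng.normal(size=(n, n_noise)),
        index=y.index,
        columns=[f"noise{i}" for i in range(n_noise)],
    )
    X.insert(0, "signal", np.where(y == "case", effect, -effect) + rng.normal(size=n))
    return X, y


CFG = PipelineConfig(rf_cv_folds=5, rf_keep=1000, rfe_keep=5, n_iterations=5, seed=0)


def test_rf_rank_puts_separating_column_first(rng):
    X, y = _toy_matrix(rng)
    top = rf_rank(X, y, CFG, seed=0)
    assert top[0] == "signal"
    assert len(top) == X.shape[1]  # rf_keep >= n_features returns everything


def test_rf_rank_rejects_single_class(rng):
    X, y = _toy_matrix(rng)
    with pytest.raises(ValueError):
        rf_rank(X, pd.Series("case", index=X.index), CFG)


def test_lr_rfe_identity_and_survival(rng):
    X, y = _toy_matrix(rng, n=200, n_noise=30)
    assert lr_rfe(X, y, X.shape[1], CFG) == list(X.columns)
    kept = lr_rfe(X, y, 3, CFG)
    assert len(kept) == 3 and "signal" in kept
    with pytest.raises(ValueError):
        lr_rfe(X, y, X.shape[1] + 1, CFG)


def test_rfecv_finds_planted_support(rng):
    # five complementary planted features: each separates only its own block
    # of subjects, so near-perfect CV F1 needs all of them together and the
    # smallest-size tie-break cannot collapse to one column
    n = 60
    y = pd.Series((["case"] * 6 + ["control"] * 6) * 5, index=[f"s{i}" for i in range(n)])
    X = pd.DataFrame(rng.normal(size=(n, 15)), index=y.index,
                     columns=[f"noise{i}" for i in range(15)])
    for j in range(5):
        block = np.zeros(n)
        block[12 * j : 12 * (j + 1)] = np.where(y[12 * j : 12 * (j + 1)] == "case", 4.0, -4.0)
        X[f"planted{j}"] = block + 0.3 * rng.normal(size=n)
    chosen = rfecv_choose_n(X, y, CFG, seed=1)
    assert chosen >= 5


def test_rfecv_rejects_too_few_subjects(rng):
    X, y = _toy_matrix(rng, n=6)
    with pytest.raises(ValueError):
        rfecv_choose_n(X, y, PipelineConfig(rf_cv_folds=10), seed=0)


def test_zscore_contract(rng):
    X, _ = _toy_matrix(rng)
    X["constant"] = 1.0
    train, test = X.iloc[:30], X.iloc[30:]
    sc = _ZScore().fit(train)
    assert "constant" not in sc.columns_ and sc.n_dropped_ == 1
    Xtr = sc.transform(train)
    assert np.allclose(Xtr.mean(), 0, atol=1e-12) and np.allclose(Xtr.std(ddof=0), 1)
    # holdout scaled by training parameters, not its own
    Xte = sc.transform(test)
    manual = (test[sc.columns_] - train[sc.columns_].mean()) / train[sc.columns_].std(ddof=0)
    assert np.allclose(Xte, manual)


def test_run_iteration_deterministic(rng):
    X, y = _toy_matrix(rng)
    a = run_iteration(X, CFG, 777, labels=y)
    b = run_iteration(X, CFG, 777, labels=y)
    assert a.f1 == b.f1 and a.coefs == b.coefs and a.holdout_ids == b.holdout_ids


def test_constant_features_fall_back_to_majority(rng):
    y = pd.Series(["case"] * 12 + ["control"] * 10, index=[f"s{i}" for i in range(22)])
    X = pd.DataFrame(1.0, index=y.index, columns=["c1", "c2"])
    rec = run_iteration(X, CFG, 5, labels=y)
    assert rec.fallback and rec.selected == ()
    assert 0 <= rec.accuracy <= 1


def test_holdout_labels_never_touch_fitted_parameters(rng):
    X, y = _toy_matrix(rng)
    split = (list(y.index[:16]) + list(y.index[20:36]), list(y.index[16:20]) + list(y.index[36:]))
    flipped = y.copy()
    flipped.loc[split[1]] = np.where(flipped.loc[split[1]] == "case", "control", "case")
    a = run_iteration(X, CFG, 1, labels=y, split=split)
    b = run_iteration(X, CFG, 1, labels=y, split=split, holdout_labels=flipped)
    assert a.coefs == b.coefs and a.intercept == b.intercept and a.selected == b.selected
    assert a.f1 != b.f1  # only the score changes


def test_repeated_cv_single_iteration_matches_record(rng):
    X, y = _toy_matrix(rng)
    res = repeated_cv(X, CFG, labels=y, n_iterations=1)
    assert len(res.records) == 1
    assert res.mean_f1 == res.records[0].f1 and res.sd_f1 == 0.0


def test_signal_beats_permutation_control(rng):
    X, y = _toy_matrix(rng, n=60)
    true = repeated_cv(X, CFG, labels=y, n_iterations=10)
    perm = permutation_control(X, CFG, labels=y, n_iterations=10)
    assert true.mean_f1 > perm.mean_f1 + 0.2
    assert 0.2 <= perm.mean_accuracy <= 0.8


def test_rank_and_associate_directions(rng):
    X, y = _toy_matrix(rng, n=60)
    res = repeated_cv(X, CFG, labels=y, n_iterations=10)
    ranked = rank_and_associate(res)
    frame = ranked.frame
    assert frame["selection_frequency"].between(0, 1).all()
    assert frame.loc["signal", "selection_frequency"] == 1.0
    # the planted column separates case-high, so its summed weight is positive
    assert frame.loc["signal", "association"] == "case"
    assert "signal" in ranked.above(0.4).index
    # never-selected features simply do not appear
    assert set(frame.index) <= set(X.columns)


def test_no_planted_signal_stays_at_chance():
    """With zero planted clusters no cluster feature separates the cohorts:
    holdout prediction stays within the binomial band around chance."""
    from repstrat import SimConfig, generate_repertoires

    reps, truth = generate_repertoires(
        SimConfig(n_case=10, n_control=10, seqs_per_subject=200,
                  n_planted_clusters=0, seed=21)
    )
    assert truth.table.empty
    cfg = PipelineConfig(rf_cv_folds=4, rfe_keep=50, seed=4)
    res = repeated_cv(reps, cfg, n_iterations=10)
    assert 0.3 <= res.mean_accuracy <= 0.7


def test_combine_chains_inner_join():
    a = pd.DataFrame({"f1": [1.0, 2.0]}, index=["s1", "s2"])
    b = pd.DataFrame({"f2": [3.0, 4.0]}, index=["s2", "s3"])
    both = combine_chains(a, b)
    assert list(both.index) == ["s2"] and list(both.columns) == ["f1", "f2"]
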
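"""Repeated-holdout repertoire classification with nested feature selection.

One iteration of the pipeline, in order and using only training data for
every fitted component:

1. stratified 80/20 subject split;
2. (cluster representation only) complete-linkage clustering of the
   training subjects' sequences, then selection of group-biased clusters
   (>= 70% of member sequences from one cohort);
3. z-score normalisation fitted on the training rows and applied with
   the same parameters to the holdout rows;
4. random-forest importance ranking (100 trees, averaged over 10-fold
   CV inside the training set) keeping the top 1,000 features;
5. logistic-regression recursive feature elimination down to 300
   features (or an RFECV-chosen size);
6. L2 (ridge) logistic regression, scored by F1 on the holdout subjects.

The split/train/score cycle is repeated many times (1,000 in the full
design); the permutation control runs the identical pipeline with the
*training* labels shuffled per iteration while holdout labels stay intact
for scoring, so chance-level holdout performance (~50%) is the expected
outcome. Feature importance is aggregated over iterations as the
selection frequency, and the sign of the summed logistic weight gives the
cohort a feature is associated with (positive = case).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .clustering import (
    build_cluster_matrix,
    cluster_repertoires,
    _dedup_table,
    select_group_biased_clusters,
)
from .io import CASE, CONTROL, RepertoireSet


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the classification pipeline."""

    n_trees: int = 100
    rf_cv_folds: int = 10
    rf_keep: int = 1000
    rfe_keep: int = 300
    rfe_step: float = 0.1          # fraction of features dropped per RFE round
    use_rfecv: bool = False        # choose rfe_keep by cross-validated F1 instead
    holdout_fraction: float = 0.2
    n_iterations: int = 1000
    threshold: float = 0.15        # cluster diameter bound T
    n_min: int = 7                 # minimum independent cluster members
    purity: float = 0.7            # group-bias cluster selection
    l2_strength: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_trees", "rf_cv_folds", "rf_keep", "rfe_keep", "n_iterations", "n_min"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("holdout_fraction", "rfe_step", "threshold"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.l2_strength <= 0:
            raise ValueError("l2_strength must be positive")


@dataclass
class IterationRecord:
    iteration_seed: int
    holdout_ids: tuple = ()
    f1: float = np.nan
    accuracy: float = np.nan
    selected: tuple = ()
    coefs: dict = field(default_factory=dict)
    intercept: float = np.nan
    n_features_in: int = 0
    fallback: bool = False   # no feature survived; majority-class prediction
    skipped: str | None = None


@dataclass
class CVResult:
    """Aggregate of repeated-holdout iterations."""

    records: list
    config: PipelineConfig

    @property
    def completed(self) -> list:
        return [r for r in self.records if r.skipped is None]

    @property
    def f1_scores(self) -> np.ndarray:
        return np.array([r.f1 for r in self.completed])

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.completed])

    @property
    def mean_f1(self) -> float:
        return float(self.f1_scores.mean())

    @property
    def sd_f1(self) -> float:
        return float(self.f1_scores.std())

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std())

    def summary(self) -> dict:
        return {
            "n_iterations": len(self.completed),
            "mean_f1": self.mean_f1,
            "sd_f1": self.sd_f1,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration_seed": [r.iteration_seed for r in self.records],
                "f1": [r.f1 for r in self.records],
                "accuracy": [r.accuracy for r in self.records],
                "n_selected": [len(r.selected) for r in self.records],
                "fallback": [r.fallback for r in self.records],
                "skipped": [r.skipped for r in self.records],
            }
        )


@dataclass
class RankedFeatures:
    """Feature selection frequency and association direction over iterations."""

    frame: pd.DataFrame  # columns: selection_frequency, sum_weight, mean_weight, association

    def above(self, cutoff: float = 0.4) -> pd.DataFrame:
        """Features selected in more than ``cutoff`` of the iterations."""
        return self.frame[self.frame["selection_frequency"] > cutoff]


def _lr(cfg: PipelineConfig) -> LogisticRegression:
    # liblinear with C = 1/strength is ridge-penalised LR
    return LogisticRegression(C=1.0 / cfg.l2_strength, solver="liblinear", random_state=0)


def _check_two_classes(y: pd.Series) -> None:
    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least two subjects per class")


def rf_rank(X: pd.DataFrame, y: pd.Series, cfg: PipelineConfig, seed: int = 0) -> list:
    """Rank features by random-forest impurity importance, CV-averaged.

    A forest of ``cfg.n_trees`` is fitted on the training portion of each
    of ``cfg.rf_cv_folds`` stratified folds (capped by the minority class
    count); per-feature mean decrease in impurity is averaged over folds.
    Returns the top ``cfg.rf_keep`` feature names, best first.
    """
    _check_two_classes(y)
    folds = min(cfg.rf_cv_folds, int(y.value_counts().min()))
    yc = y.to_numpy()
    importances = np.zeros(X.shape[1])
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = [tr for tr, _ in skf.split(X, yc)]
    else:
        splits = [np.arange(len(X))]
    for tr in splits:
        rf = RandomForestClassifier(n_estimators=cfg.n_trees, random_state=seed)
        rf.fit(X.iloc[tr], yc[tr])
        importances += rf.feature_importances_
    importances /= len(splits)
    order = np.argsort(-importances, kind="stable")  # ties keep column order
    return [X.columns[i] for i in order[: cfg.rf_keep]]


def lr_rfe(X: pd.DataFrame, y: pd.Series, n_keep: int, cfg: PipelineConfig) -> list:
    """Recursive feature elimination under a ridge logistic model.

    Features with the smallest absolute LR coefficients are dropped,
    ``cfg.rfe_step`` of the remainder per round, until ``n_keep`` remain.
    """
    if n_keep > X.shape[1]:
        raise ValueError("n_keep exceeds the number of features")
    _check_two_classes(y)
    if n_keep == X.shape[1]:
        return list(X.columns)
    rfe = RFE(_lr(cfg), n_features_to_select=n_keep, step=cfg.rfe_step)
    rfe.fit(X, y.to_numpy())
    return [c for c, keep in zip(X.columns, rfe.support_) if keep]


def rfecv_choose_n(X: pd.DataFrame, y: pd.Series, cfg: PipelineConfig, seed: int = 0) -> int:
    """Pick the retained feature count maximising cross-validated F1.

    Candidate sizes follow the RFE elimination path down to one feature;
    for each fold the elimination is re-run on the fold's training part
    and a ridge LR is scored on the fold's test part. Ties go to the
    smallest size.
    """
    _check_two_classes(y)
    folds = cfg.rf_cv_folds
    if len(y) < folds or int(y.value_counts().min()) < folds:
        raise ValueError("too few subjects for the requested folds")
    sizes = []
    n = X.shape[1]
    while n > 1:
        sizes.append(n)
        n -= max(1, int(np.floor(X.shape[1] * cfg.rfe_step)))
    sizes.append(1)
    sizes = sorted(set(s for s in sizes if s >= 1))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    yc = y.to_numpy()
    scores = np.zeros(len(sizes))
    for tr, te in skf.split(X, yc):
        Xtr, Xte = X.iloc[tr], X.iloc[te]
        ytr, yte = y.iloc[tr], yc[te]
        for k, size in enumerate(sizes):
            cols = lr_rfe(Xtr, ytr, size, cfg)
            model = _lr(cfg).fit(Xtr[cols], ytr.to_numpy())
            pred = model.predict(Xte[cols])
            scores[k] += f1_score(yte, pred, pos_label=CASE, zero_division=0)
    return int(sizes[int(np.argmax(scores))])  # first max = smallest size


class _ZScore:
    """Train-fitted per-column standardisation; zero-variance columns dropped."""

    def fit(self, X: pd.DataFrame) -> "_ZScore":
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=0)
        self.columns_ = X.columns[self.sd_ > 0]
        self.n_dropped_ = X.shape[1] - len(self.columns_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        c = self.columns_
        return (X[c] - self.mean_[c]) / self.sd_[c]


def _iteration_seed(master_seed: int, i: int) -> int:
    return int((master_seed * 1_000_003 + i) % (2**31 - 1))


def run_iteration(
    data,
    cfg: PipelineConfig,
    iteration_seed: int,
    labels: pd.Series | None = None,
    permute_training: bool = False,
    split: tuple | None = None,
    holdout_labels: pd.Series | None = None,
    _dedup=None,
) -> IterationRecord:
    """One stratified holdout iteration of the full pipeline.

    ``data`` is either a :class:`RepertoireSet` (cluster features are then
    built from the training split alone) or a precomputed subjects x
    features DataFrame with ``labels`` supplied. ``split`` may fix the
    (train_ids, holdout_ids) partition, e.g. for leakage audits;
    ``holdout_labels`` overrides holdout scoring labels only and cannot
    influence any fitted parameter. Deterministic in ``iteration_seed``.
    """
    if isinstance(data, RepertoireSet):
        labels = data.label_series()
    elif labels is None:
        raise ValueError("labels are required for a precomputed feature matrix")
    subjects = list(labels.index)

    rec = IterationRecord(iteration_seed=iteration_seed)
    if split is None:
        try:
            train_ids, test_ids = train_test_split(
                subjects,
                test_size=cfg.holdout_fraction,
                stratify=labels.to_numpy(),
                random_state=iteration_seed,
            )
        except ValueError as exc:
            rec.skipped = f"degenerate split: {exc}"
            return rec
    else:
        train_ids, test_ids = (list(split[0]), list(split[1]))
    rec.holdout_ids = tuple(test_ids)

    y_train = labels.loc[train_ids].copy()
    if permute_training:
        rng = np.random.default_rng(iteration_seed)
        y_train[:] = rng.permutation(y_train.to_numpy())
    y_test = (holdout_labels if holdout_labels is not None else labels).loc[test_ids]
    if y_train.nunique() < 2 or labels.loc[test_ids].nunique() < 2:
        rec.skipped = "degenerate split: single-class train or holdout"
        return rec

    if isinstance(data, RepertoireSet):
        clusters = cluster_repertoires(
            data, T=cfg.threshold, n_min=cfg.n_min, subjects=train_ids, _dedup=_dedup
        )
        kept = select_group_biased_clusters(clusters, y_train, purity=cfg.purity)
        matrix = build_cluster_matrix(
            kept, data, subjects=train_ids + list(test_ids), member_based=train_ids
        )
        X = matrix.values
    else:
        X = data
    X_train, X_test = X.loc[train_ids], X.loc[test_ids]
    rec.n_features_in = X.shape[1]

    scaler = _ZScore().fit(X_train)
    if len(scaler.columns_) == 0:
        # nothing informative survived; fall back to majority-class prediction
        counts = y_train.value_counts()
        majority = CASE if counts.get(CASE, 0) >= counts.get(CONTROL, 0) else CONTROL
        pred = np.repeat(majority, len(test_ids))
        rec.fallback = True
    else:
        Xtr = scaler.transform(X_train)
        Xte = scaler.transform(X_test)
        top = rf_rank(Xtr, y_train, cfg, seed=iteration_seed)
        if cfg.use_rfecv:
            n_keep = min(rfecv_choose_n(Xtr[top], y_train, cfg, seed=iteration_seed), len(top))
        else:
            n_keep = min(cfg.rfe_keep, len(top))
        selected = lr_rfe(Xtr[top], y_train, n_keep, cfg)
        model = _lr(cfg).fit(Xtr[selected], y_train.to_numpy())
        pred = model.predict(Xte[selected])
        rec.selected = tuple(selected)
        case_index = list(model.classes_).index(CASE)
        sign = 1.0 if case_index == 1 else -1.0
        rec.coefs = dict(zip(selected, sign * model.coef_[0]))
        rec.intercept = sign * float(model.intercept_[0])
    rec.f1 = f1_score(y_test, pred, pos_label=CASE, zero_division=0)
    rec.accuracy = accuracy_score(y_test, pred)
    return rec


def repeated_cv(
    data,
    cfg: PipelineConfig,
    labels: pd.Series | None = None,
    permute_training: bool = False,
    n_iterations: int | None = None,
) -> CVResult:
    """Repeat the holdout pipeline and aggregate mean +/- sd performance."""
    n_iter = cfg.n_iterations if n_iterations is None else n_iterations
    dedup = _dedup_table(data) if isinstance(data, RepertoireSet) else None
    records = []
    for i in range(n_iter):
        records.append(
            run_iteration(
                data,
                cfg,
                _iteration_seed(cfg.seed, i),
                labels=labels,
                permute_training=permute_training,
                _dedup=dedup,
            )
        )
    return CVResult(records=records, config=cfg)


def permutation_control(
    data,
    cfg: PipelineConfig,
    labels: pd.Series | None = None,
    n_iterations: int | None = None,
) -> CVResult:
    """The chance-level control: training labels permuted each iteration.

    Holdout labels are left intact for scoring, so the reported holdout
    performance estimates the probability of classifying correctly by
    chance (expected ~50% for balanced cohorts).
    """
    return repeated_cv(
        data, cfg, labels=labels, permute_training=True, n_iterations=n_iterations
    )


def rank_and_associate(result: CVResult, cutoff: float = 0.4) -> RankedFeatures:
    """Aggregate feature selections and LR weights over iterations.

    Selection frequency is the fraction of completed iterations in which
    a feature survived elimination; the sign of its summed coefficient
    over those iterations gives the associated cohort (positive = case).
    ``cutoff`` marks the report threshold used downstream (features
    selected in more than 40% of subsamples by default).
    """
    completed = result.completed
    if not completed:
        raise ValueError("no completed iterations to rank")
    n = len(completed)
    freq: dict = {}
    wsum: dict = {}
    for r in completed:
        for f in r.selected:
            freq[f] = freq.get(f, 0) + 1
            wsum[f] = wsum.get(f, 0.0) + r.coefs[f]
    frame = pd.DataFrame(
        {
            "selection_frequency": {f: c / n for f, c in freq.items()},
            "sum_weight": wsum,
        }
    )
    frame["mean_weight"] = frame["sum_weight"] / (frame["selection_frequency"] * n)
    frame["association"] = np.where(frame["sum_weight"] > 0, CASE, CONTROL)
    frame = frame.sort_values(
        ["selection_frequency", "sum_weight"], ascending=False, kind="stable"
    )
    frame.index.name = "feature"
    return RankedFeatures(frame=frame)


def combine_chains(*matrices: pd.DataFrame) -> pd.DataFrame:
    """Column-concatenate per-chain feature matrices on shared subjects.

    Subjects missing from any chain are dropped (inner join).
    """
    common = matrices[0].index
    for m in matrices[1:]:
        common = common.intersection(m.index)
    return pd.concat([m.loc[common] for m in matrices], axis=1)
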
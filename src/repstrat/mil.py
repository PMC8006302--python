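"""Multiple-instance learning on cluster consensus sequences.

Bags are cluster consensus CDR3s labelled by the cohort the cluster is
associated with; instances are the consensus' contiguous 3-mers, each
encoded as 5 Atchley factors x 3 positions plus the 3-mer's relative
position within the CDR3. A bag's score is the logistic transform of the
*maximum* linear score over its instances, so one sufficiently motif-like
3-mer anywhere in the sequence can label the whole bag; the model is
fitted by gradient ascent on the bag-level penalised log-likelihood with
a subgradient through the hard max. The fitted weight vector, reshaped
to factor x position, is the positional biophysicochemical motif report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FACTOR_NAMES, atchley_encode
from .io import CASE, CONTROL

K = 3  # instance 3-mers

INSTANCE_FEATURES = tuple(
    f"p{pos}_{fac}" for pos in range(K) for fac in FACTOR_NAMES
) + ("rel_position",)


@dataclass
class Bag:
    """One cluster consensus with its encoded 3-mer instances."""

    bag_id: str
    label: str  # 'case' | 'control'
    instances: np.ndarray  # (n_instances, 16)

    def __post_init__(self):
        self.instances = np.atleast_2d(np.asarray(self.instances, dtype=float))
        if self.instances.shape[0] < 1:
            raise ValueError("a bag needs at least one instance")


def encode_consensus(seq: str) -> np.ndarray:
    """Instance matrix of a consensus sequence: one row per 3-mer.

    The relative position is ``start / (n_kmers - 1)`` in [0, 1], taken
    as 0 when the sequence holds exactly one 3-mer.
    """
    n = len(seq) - K + 1
    if n < 1:
        raise ValueError(f"sequence shorter than {K}")
    rows = np.empty((n, 5 * K + 1))
    for i in range(n):
        rows[i, :-1] = atchley_encode(seq[i : i + K])
        rows[i, -1] = i / (n - 1) if n > 1 else 0.0
    return rows


def make_bags(ranked_frame: pd.DataFrame, clusters, n_top: int = 300) -> list[Bag]:
    """Build bags from the top associated clusters, ``n_top // 2`` per cohort.

    ``ranked_frame`` is the importance-sorted frame from
    ``classify.rank_and_associate`` (index: cluster id, ``association``
    column). Clusters whose consensus is shorter than 3 are skipped with
    a warning.
    """
    by_id = {c.cluster_id: c for c in clusters}
    per_side = n_top // 2
    taken = {CASE: 0, CONTROL: 0}
    bags = []
    for fid, row in ranked_frame.iterrows():
        c = by_id.get(fid)
        if c is None:
            continue
        side = row["association"]
        if taken[side] >= per_side:
            continue
        if len(c.consensus) < K:
            warnings.warn(f"cluster {fid} consensus shorter than {K}; skipped")
            continue
        bags.append(Bag(bag_id=str(fid), label=side, instances=encode_consensus(c.consensus)))
        taken[side] += 1
    return bags


@dataclass
class MILModel:
    weights: np.ndarray           # (16,)
    intercept: float
    feature_names: tuple = INSTANCE_FEATURES
    mean: np.ndarray = None       # instance standardisation (training stats)
    scale: np.ndarray = None
    trace: list = field(default_factory=list)  # objective per epoch
    converged: bool = False

    def bag_logits(self, bags) -> np.ndarray:
        out = np.empty(len(bags))
        for i, b in enumerate(bags):
            X = (b.instances - self.mean) / self.scale
            out[i] = np.max(X @ self.weights) + self.intercept
        return out

    def bag_probabilities(self, bags) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.bag_logits(bags)))


def _stack(bags):
    X = np.vstack([b.instances for b in bags])
    sizes = np.array([len(b.instances) for b in bags])
    starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    y = np.array([1.0 if b.label == CASE else 0.0 for b in bags])
    return X, starts, sizes, y


def mil_fit(
    bags,
    seed: int = 0,
    l2: float = 0.01,
    lr: float = 0.05,
    max_epochs: int = 2000,
    tol: float = 1e-8,
) -> MILModel:
    """Fit the max-instance logistic model by full-batch Adam.

    Instances are standardised with statistics over all training
    instances; the L2 penalty applies to the weights, not the intercept.
    Deterministic (zero initialisation, full-batch updates). If the
    objective has not converged within ``max_epochs`` a warning is issued
    and the best iterate is returned.
    """
    labels = {b.label for b in bags}
    if labels != {CASE, CONTROL}:
        raise ValueError("both case and control bags are required")
    X, starts, sizes, y = _stack(bags)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    nb = len(bags)
    owner = np.repeat(np.arange(nb), sizes)

    d = Xs.shape[1]
    w = np.zeros(d)
    b0 = 0.0
    m = np.zeros(d + 1)
    v = np.zeros(d + 1)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    best = (np.inf, w.copy(), b0)
    trace = []
    converged = False
    prev_obj = np.inf
    for epoch in range(1, max_epochs + 1):
        s = Xs @ w
        seg_max = np.maximum.reduceat(s, starts)
        # first argmax instance per bag (deterministic subgradient)
        is_max = s == seg_max[owner]
        cand = np.where(is_max, np.arange(len(s)), len(s))
        first_idx = np.minimum.reduceat(cand, starts)
        logits = seg_max + b0
        p = 1.0 / (1.0 + np.exp(-logits))
        obj = float(
            -np.mean(y * np.log(p + 1e-12) + (1 - y) * np.log(1 - p + 1e-12))
            + 0.5 * l2 * w @ w
        )
        trace.append(obj)
        if obj < best[0]:
            best = (obj, w.copy(), b0)
        resid = p - y
        gw = Xs[first_idx].T @ resid / nb + l2 * w
        gb = float(resid.mean())
        g = np.concatenate([gw, [gb]])
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        mh = m / (1 - beta1**epoch)
        vh = v / (1 - beta2**epoch)
        step = lr * mh / (np.sqrt(vh) + eps)
        w = w - step[:-1]
        b0 = b0 - step[-1]
        if abs(prev_obj - obj) < tol:
            converged = True
            break
        prev_obj = obj
    if not converged:
        warnings.warn("MIL fit did not converge; returning the best iterate")
        _, w, b0 = best
    return MILModel(
        weights=w, intercept=b0, mean=mean, scale=scale, trace=trace, converged=converged
    )


def mil_evaluate(model: MILModel, bags) -> tuple[float, pd.DataFrame]:
    """Accuracy and per-bag scores; a bag is called case when p > 0.5."""
    p = model.bag_probabilities(bags)
    pred = np.where(p > 0.5, CASE, CONTROL)
    truth = np.array([b.label for b in bags])
    scores = pd.DataFrame(
        {"bag_id": [b.bag_id for b in bags], "label": truth, "probability": p, "predicted": pred}
    )
    return float((pred == truth).mean()), scores


def split_bags(bags, test_fraction: float = 0.2, seed: int = 0):
    """Stratified, seeded bag-level train/validation split."""
    rng = np.random.default_rng(seed)
    train, test = [], []
    for side in (CASE, CONTROL):
        side_bags = [b for b in bags if b.label == side]
        order = rng.permutation(len(side_bags))
        n_test = max(1, int(round(test_fraction * len(side_bags))))
        test.extend(side_bags[i] for i in order[:n_test])
        train.extend(side_bags[i] for i in order[n_test:])
    return train, test


def position_weight_report(model: MILModel) -> pd.DataFrame:
    """Signed weight per (Atchley factor, 3-mer position), plus position term.

    Rows are the five factors; columns are the three residue positions.
    The separate relative-position weight is attached as attribute
    ``rel_position_weight`` (pandas attrs).
    """
    table = pd.DataFrame(
        model.weights[: 5 * K].reshape(K, 5).T,
        index=list(FACTOR_NAMES),
        columns=[f"position_{i + 1}" for i in range(K)],
    )
    table.attrs["rel_position_weight"] = float(model.weights[-1])
    return table
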
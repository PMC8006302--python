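"""Cluster-set enrichment analysis and k-mer enrichment between cohorts.

CSEA asks whether clusters sharing an attribute (same V gene, J gene or
CDR3 length) sit unexpectedly high in the importance ranking produced by
the classifier. Walking the ranked list, a running score increases by
``|r_i| / sum_{j in S} |r_j|`` on members of the set ``S`` and decreases
by ``1 / (N - |S|)`` on non-members (a Kolmogorov-Smirnov-like
statistic); the enrichment score is the maximum absolute deviation from
zero. Significance comes from permuting the attribute labels over
clusters; the normalized enrichment score ``NES = ES / mean(null ES)``
accounts for set size, and an FDR is estimated by comparing the observed
and null NES tails.

k-mer enrichment contrasts case- and control-associated sequence sets
(after exact length balancing) by counting overlapping k-mers in a raw
amino-acid, nucleotide or conjoint-triad (CT) class representation and
testing each k-mer's 2x2 count table with the two-sided exact Fisher
test, Benjamini-Hochberg corrected. Fold changes are oriented as
case/control (log2FC > 0 means case-enriched).
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AA_ALPHABET

#: conjoint-triad classes: the 20 AAs grouped by side-chain dipole and volume
CT_CLASSES: dict[int, str] = {
    1: "AGV",
    2: "ILFP",
    3: "YMTS",
    4: "HNQW",
    5: "RK",
    6: "DE",
    7: "C",
}

CT_MAP: dict[str, int] = {aa: cls for cls, aas in CT_CLASSES.items() for aa in aas}
assert len(CT_MAP) == 20 and set(CT_MAP) == set(AA_ALPHABET)

_CT_TRANS = str.maketrans({aa: str(cls) for aa, cls in CT_MAP.items()})


def ct_encode_sequence(cdr3_aa: str) -> str:
    """Per-residue conjoint-triad class ids, e.g. ``"YMT" -> "333"``."""
    bad = set(cdr3_aa) - set(CT_MAP)
    if bad:
        raise ValueError(f"non-standard residue(s): {sorted(bad)}")
    return cdr3_aa.translate(_CT_TRANS)


# ---------------------------------------------------------------------------
# CSEA
# ---------------------------------------------------------------------------

def enrichment_score(importances, in_set) -> tuple[float, np.ndarray]:
    """ES of one cluster set over a ranked list, plus the running walk.

    ``importances`` must already be in rank order (most important first);
    ``in_set`` is the matching boolean membership vector. The walk's
    increments sum to 1 and its decrements sum to 1, so it must end at 0;
    this is asserted on every call.
    """
    r = np.abs(np.asarray(importances, dtype=float))
    m = np.asarray(in_set, dtype=bool)
    n = len(r)
    size = int(m.sum())
    if size == 0 or size == n:
        raise ValueError("set must be a proper non-empty subset of the list")
    denom = r[m].sum()
    if denom == 0:
        raise ValueError("importance values within the set are all zero")
    steps = np.where(m, r / denom, -1.0 / (n - size))
    walk = np.cumsum(steps)
    assert abs(walk[-1]) < 1e-9, "ES walk failed to return to zero"
    return float(np.max(np.abs(walk))), walk


def csea(
    importance: pd.Series,
    sets: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation CSEA of every level of one grouping attribute.

    Parameters
    ----------
    importance
        Cluster importance values indexed by cluster id (e.g. selection
        frequency over subsamples).
    sets
        Attribute level per cluster id (same index), e.g. the V gene.
    n_perm
        Number of attribute-label permutations for the null (>= 100).

    Returns one row per testable set with ES, NES, permutation p and a
    GSEA-style FDR (observed vs pooled null NES tails). Sets violating
    the ES preconditions are skipped with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    idx = importance.sort_values(ascending=False, kind="stable").index
    # deterministic tie-break: stable sort then id order among equal values
    order = sorted(range(len(idx)), key=lambda i: (-importance[idx[i]], str(idx[i])))
    idx = idx[order]
    r = np.abs(importance.loc[idx].to_numpy(dtype=float))
    labels = sets.loc[idx].to_numpy()
    n = len(r)
    levels = pd.unique(sets)
    if len(levels) < 2:
        raise ValueError("need >= 2 sets under the grouping attribute")

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    perm_labels = labels[perms]  # (n_perm, n)

    rows = []
    null_nes_pool = []
    obs_nes = {}
    for level in levels:
        mask = labels == level
        size = int(mask.sum())
        try:
            es, _ = enrichment_score(r, mask)
        except ValueError as exc:
            warnings.warn(f"CSEA: set {level!r} skipped ({exc})")
            continue
        pm = perm_labels == level  # (n_perm, n)
        denom = (r[None, :] * pm).sum(axis=1)
        ok = denom > 0
        steps = np.where(pm, r[None, :] / denom[:, None], -1.0 / (n - size))
        walks = np.cumsum(steps, axis=1)
        null_es = np.max(np.abs(walks), axis=1)[ok]
        p = (1 + int((null_es >= es).sum())) / (1 + len(null_es))
        mean_null = float(null_es.mean())
        nes = es / mean_null
        null_nes = null_es / mean_null
        rows.append({"set_id": level, "size": size, "es": es, "nes": nes, "p": p})
        obs_nes[level] = nes
        null_nes_pool.append(null_nes)

    if not rows:
        return pd.DataFrame(columns=["set_id", "size", "es", "nes", "p", "fdr"])
    pool = np.concatenate(null_nes_pool)
    observed = np.array([row["nes"] for row in rows])
    for row in rows:
        tail_null = float((pool >= row["nes"]).mean())
        tail_obs = float((observed >= row["nes"]).mean())
        row["fdr"] = min(1.0, tail_null / tail_obs) if tail_obs > 0 else 1.0
    return pd.DataFrame(rows)


def cluster_attribute_sets(clusters, attribute: str) -> pd.Series:
    """Map cluster id -> attribute level for ``v_gene``/``j_gene``/``cdr3_length``."""
    if attribute not in ("v_gene", "j_gene", "cdr3_length"):
        raise ValueError("attribute must be v_gene, j_gene or cdr3_length")
    return pd.Series({c.cluster_id: getattr(c, attribute) for c in clusters})


# ---------------------------------------------------------------------------
# k-mer enrichment
# ---------------------------------------------------------------------------

def length_balanced_sets(set_a, set_b, seed: int = 0) -> tuple[list, list]:
    """Subsample both sequence sets to exactly matching length histograms.

    For every observed length, ``min(count_a, count_b)`` sequences are
    drawn without replacement from each side.
    """
    rng = np.random.default_rng(seed)
    a_by_len: dict[int, list] = {}
    b_by_len: dict[int, list] = {}
    for s in set_a:
        a_by_len.setdefault(len(s), []).append(s)
    for s in set_b:
        b_by_len.setdefault(len(s), []).append(s)
    common = sorted(set(a_by_len) & set(b_by_len))
    if not common:
        raise ValueError("length supports of the two sets do not overlap")
    out_a, out_b = [], []
    for L in common:
        k = min(len(a_by_len[L]), len(b_by_len[L]))
        out_a.extend(rng.choice(a_by_len[L], size=k, replace=False))
        out_b.extend(rng.choice(b_by_len[L], size=k, replace=False))
    return out_a, out_b


def fisher_exact_two_sided(a, b, c, d) -> np.ndarray:
    """Vectorised two-sided Fisher exact p for tables ``[[a, b], [c, d]]``.

    The two-sided p is the total hypergeometric probability of all tables
    (same margins) no more likely than the observed one. Tables sharing
    margins are solved per family so the pmf is computed once each.
    """
    a, b, c, d = (np.atleast_1d(np.asarray(x, dtype=np.int64)) for x in (a, b, c, d))
    M = a + b + c + d
    n1 = a + b        # first-row total
    K = a + c         # first-column total
    p = np.ones(len(a))
    fams: dict[tuple, list] = {}
    for i in range(len(a)):
        fams.setdefault((int(M[i]), int(n1[i]), int(K[i])), []).append(i)
    for (m, n_draw, k_succ), members in fams.items():
        if m == 0:  # empty table: nothing to test
            continue
        lo = max(0, k_succ - (m - n_draw))
        hi = min(k_succ, n_draw)
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, m, k_succ, n_draw)
        for i in members:
            cutoff = pmf[int(a[i]) - lo] * (1 + 1e-7)
            p[i] = min(1.0, float(pmf[pmf <= cutoff].sum()))
    return p


def kmer_enrichment(
    set_a,
    set_b,
    k: int = 3,
    representation: str = "aa",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-k-mer differential abundance between two balanced sequence sets.

    Set A is the case-associated set, set B the control-associated set;
    sequences should already be length-balanced. ``representation`` is
    ``"aa"`` (raw residues), ``"ct"`` (conjoint-triad class strings) or
    ``"nt"`` (raw nucleotide strings). Each k-mer's 2x2 table of (count,
    remaining k-mers) per set is tested with the two-sided exact Fisher
    test; q-values are Benjamini-Hochberg over all tested k-mers; the
    fold change is freq_A / freq_B on a log2 scale with a 0.5 pseudocount
    on zero counts.
    """
    if representation not in ("aa", "ct", "nt"):
        raise ValueError("representation must be 'aa', 'ct' or 'nt'")
    if representation == "ct":
        set_a = [ct_encode_sequence(s) for s in set_a]
        set_b = [ct_encode_sequence(s) for s in set_b]

    def count(seqs):
        ctr: Counter = Counter()
        for s in seqs:
            for i in range(len(s) - k + 1):
                ctr[s[i : i + k]] += 1
        return ctr

    ca, cb = count(set_a), count(set_b)
    total_a, total_b = sum(ca.values()), sum(cb.values())
    kmers = sorted(set(ca) | set(cb))
    if not kmers or total_a == 0 or total_b == 0:
        return pd.DataFrame(
            columns=["kmer", "count_a", "count_b", "freq_a", "freq_b",
                     "log2_fc", "p", "q", "significant"]
        )
    na = np.array([ca.get(m, 0) for m in kmers])
    nb = np.array([cb.get(m, 0) for m in kmers])
    p = fisher_exact_two_sided(na, total_a - na, nb, total_b - nb)
    q = multipletests(p, method="fdr_bh")[1]
    pc = np.where((na == 0) | (nb == 0), 0.5, 0.0)
    log2_fc = np.log2(((na + pc) / total_a) / ((nb + pc) / total_b))
    out = pd.DataFrame(
        {
            "kmer": kmers,
            "count_a": na,
            "count_b": nb,
            "freq_a": na / total_a,
            "freq_b": nb / total_b,
            "log2_fc": log2_fc,
            "p": p,
            "q": q,
            "significant": q < alpha,
        }
    )
    return out.sort_values("q", kind="stable").reset_index(drop=True)


def association_sequence_sets(ranked_frame: pd.DataFrame, clusters, n_top: int = 100):
    """Consensus-sequence sets of the top case- and control-associated clusters.

    ``ranked_frame`` is the frame from ``rank_and_associate`` (index:
    feature/cluster id, with ``association`` column, importance-sorted).
    Returns ``(case_consensus, control_consensus)`` capped at ``n_top``
    sequences each.
    """
    by_id = {c.cluster_id: c for c in clusters}
    case_seqs, ctrl_seqs = [], []
    for fid, row in ranked_frame.iterrows():
        c = by_id.get(fid)
        if c is None:
            continue
        target = case_seqs if row["association"] == "case" else ctrl_seqs
        if len(target) < n_top:
            target.append(c.consensus)
    return case_seqs, ctrl_seqs
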
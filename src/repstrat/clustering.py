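"""Similarity-cluster repertoire representation.

Sequences are pooled across subjects and partitioned into clonal clusters:
all members of a cluster share the V gene, J gene and CDR3 amino-acid
length, and the normalized Hamming distance between *any* two member CDR3s
never exceeds the threshold ``T`` (complete linkage, so every cluster has a
bounded diameter). Clusters with fewer than ``n_min`` independent members
are discarded; each surviving cluster is summarised by a consensus sequence
(per-position majority residue, the minimiser of the summed Hamming
distance to all member sequences).

The per-subject feature value of a cluster is the fraction of that
subject's retained sequences assigned to the cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .io import AA_ALPHABET, RepertoireSet
from .features import strip_allele


def normalized_hamming(a: str, b: str) -> float:
    """Fraction of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    return sum(x != y for x, y in zip(a, b)) / len(a)


@dataclass
class Cluster:
    """A V/J/length-homogeneous group of similar CDR3s."""

    cluster_id: str
    v_gene: str
    j_gene: str
    cdr3_length: int
    #: distinct (subject_id, cdr3_aa) pairs with their sequence multiplicity
    members: list  # of (subject_id, cdr3_aa, count)
    consensus: str
    threshold: float

    @property
    def n_members(self) -> int:
        """Independent members: distinct (subject, CDR3) pairs."""
        return len(self.members)

    @property
    def n_subjects(self) -> int:
        return len({s for s, _, _ in self.members})

    @property
    def n_sequences(self) -> int:
        return sum(c for _, _, c in self.members)

    def max_pairwise_distance(self) -> float:
        seqs = sorted({m[1] for m in self.members})
        if len(seqs) == 1:
            return 0.0
        M = _encode(seqs)
        return float(pdist(M, "hamming").max())


def consensus_sequence(members, weights=None) -> str:
    """Per-position majority residue over equal-length member sequences.

    Minimises the (weight-)summed Hamming distance to the members, which
    decomposes per column. Ties are broken by amino-acid alphabetical
    order, so the result is deterministic.
    """
    members = list(members)
    if not members:
        raise ValueError("consensus of zero members")
    L = len(members[0])
    if any(len(m) != L for m in members):
        raise ValueError("members must have equal length")
    if weights is None:
        weights = np.ones(len(members))
    weights = np.asarray(weights, dtype=float)
    M = _encode(members)
    out = []
    alpha = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)
    for col in range(L):
        tallies = np.zeros(len(alpha))
        for code, w in zip(M[:, col], weights):
            tallies[np.searchsorted(alpha, code)] += w
        # argmax returns the first (alphabetically smallest) maximiser
        out.append(chr(alpha[int(np.argmax(tallies))]))
    return "".join(out)


def _encode(seqs) -> np.ndarray:
    """Equal-length AA strings -> (n, L) uint8 matrix."""
    n = len(seqs)
    L = len(seqs[0]) if n else 0
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(n, L)


def complete_linkage_labels(D: np.ndarray, T: float) -> np.ndarray:
    """Cut a complete-linkage agglomeration of distance matrix ``D`` at ``T``.

    Greedy agglomeration: repeatedly merge the pair of clusters with the
    smallest complete-linkage distance (ties broken by the smallest
    row-major index pair) until that distance exceeds ``T``. Because
    complete linkage is monotone, stopping there is equivalent to cutting
    the full dendrogram at height ``T``. To keep the quadratic argmin
    cheap, merging is performed independently inside each connected
    component of the ``distance <= T`` graph (complete-linkage clusters
    can never straddle two components).
    """
    n = len(D)
    labels = np.arange(n)
    if n <= 1:
        return labels
    adj = csr_matrix(D <= T)
    ncomp, comp = connected_components(adj, directed=False)
    for c in range(ncomp):
        idx = np.flatnonzero(comp == c)
        if len(idx) < 2:
            continue
        sub = D[np.ix_(idx, idx)].astype(float).copy()
        np.fill_diagonal(sub, np.inf)
        owner = [[i] for i in range(len(idx))]
        while True:
            flat = int(np.argmin(sub))
            i, j = divmod(flat, len(idx))
            if sub[i, j] > T:
                break
            if i > j:  # row-major argmin gives i<j for symmetric matrices, be safe
                i, j = j, i
            merged = np.maximum(sub[i], sub[j])
            sub[i], sub[:, i] = merged, merged
            sub[i, i] = np.inf
            sub[j], sub[:, j] = np.inf, np.inf
            owner[i].extend(owner[j])
            owner[j] = []
        for group in owner:
            if group:
                root = idx[min(group)]
                labels[idx[group]] = root
    # relabel to consecutive ids in order of first appearance
    _, inv = np.unique(labels, return_inverse=True)
    first = {}
    out = np.empty(n, dtype=int)
    for pos, lab in enumerate(inv):
        out[pos] = first.setdefault(lab, len(first))
    return out


def _threshold_edges(M: np.ndarray, T: float) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i < j) with normalized Hamming distance <= T.

    Uses the pigeonhole screen: a pair with at most ``m = floor(T*L)``
    mismatches must agree exactly on one of ``m + 1`` contiguous column
    chunks, so only pairs sharing a chunk value are verified. Exact —
    candidates are checked against the true distance.
    """
    n, L = M.shape
    max_mm = int(np.floor(T * L + 1e-9))
    nparts = max_mm + 1  # always <= L because T < 1
    bounds = np.linspace(0, L, nparts + 1).astype(int)
    cand_i, cand_j = [], []
    for p in range(nparts):
        chunk = np.ascontiguousarray(M[:, bounds[p] : bounds[p + 1]])
        keys = chunk.view(np.dtype((np.void, chunk.shape[1]))).ravel()
        order = np.argsort(keys, kind="stable")
        sk = keys[order]
        starts = np.flatnonzero(np.concatenate(([True], sk[1:] != sk[:-1])))
        ends = np.concatenate((starts[1:], [n]))
        for s, e in zip(starts, ends):
            if e - s < 2:
                continue
            grp = np.sort(order[s:e])
            ii, jj = np.triu_indices(len(grp), k=1)
            cand_i.append(grp[ii])
            cand_j.append(grp[jj])
    if not cand_i:
        return np.array([], int), np.array([], int)
    ci = np.concatenate(cand_i)
    cj = np.concatenate(cand_j)
    # dedupe pairs found via several chunks
    packed = ci.astype(np.int64) * n + cj
    packed = np.unique(packed)
    ci, cj = packed // n, packed % n
    mm = (M[ci] != M[cj]).sum(axis=1)
    ok = mm <= max_mm
    return ci[ok], cj[ok]


def _class_labels(M: np.ndarray, T: float) -> np.ndarray:
    """Complete-linkage cut at ``T`` for one V/J/length class.

    Connected components of the ``<= T`` graph are found with the sparse
    pigeonhole screen; the quadratic agglomeration runs only inside
    multi-member components, which keeps large classes of mutually
    dissimilar sequences linear-time.
    """
    n = len(M)
    ci, cj = _threshold_edges(M, T)
    labels = np.arange(n)
    if len(ci):
        graph = csr_matrix((np.ones(len(ci)), (ci, cj)), shape=(n, n))
        _, comp = connected_components(graph, directed=False)
        for c in np.unique(comp):
            idx = np.flatnonzero(comp == c)
            if len(idx) < 2:
                continue
            D = squareform(pdist(M[idx], "hamming"))
            sub = complete_linkage_labels(D, T)
            for lab in np.unique(sub):
                grp = idx[sub == lab]
                labels[grp] = grp.min()
    # consecutive ids in order of first appearance
    first: dict = {}
    out = np.empty(n, dtype=int)
    for pos, lab in enumerate(labels):
        out[pos] = first.setdefault(lab, len(first))
    return out


def _dedup_table(reps: RepertoireSet) -> pd.DataFrame:
    df = reps.df
    tab = (
        df.assign(
            v_gene=strip_allele(df["v_call"]),
            j_gene=strip_allele(df["j_call"]),
            cdr3_length=df["cdr3_aa"].str.len(),
        )
        .groupby(
            ["v_gene", "j_gene", "cdr3_length", "subject_id", "cdr3_aa"],
            sort=True,
            observed=True,
        )
        .size()
        .rename("count")
        .reset_index()
    )
    return tab


def cluster_repertoires(
    reps: RepertoireSet,
    T: float = 0.15,
    n_min: int = 7,
    subjects=None,
    independent: str = "pairs",
    _dedup: pd.DataFrame | None = None,
) -> list[Cluster]:
    """Build complete-linkage CDR3 clusters over the pooled repertoires.

    Parameters
    ----------
    T
        Normalized-Hamming diameter bound. Paired defaults from the method:
        ``T=0.15, n_min=7``; ``T=0.25, n_min=10``; ``T=0.6, n_min=20``.
    n_min
        Minimum number of independent members a cluster must reach.
    subjects
        Optional subject subset (e.g. the training split); clustering is
        blind to cohort labels either way.
    independent
        ``"pairs"`` counts distinct (subject, CDR3) pairs after per-subject
        deduplication of identical CDR3s (default); ``"subjects"`` counts
        distinct subjects.
    """
    if not (0 < T < 1):
        raise ValueError("T must be in (0, 1)")
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    if independent not in ("pairs", "subjects"):
        raise ValueError("independent must be 'pairs' or 'subjects'")
    tab = _dedup if _dedup is not None else _dedup_table(reps)
    if subjects is not None:
        tab = tab[tab["subject_id"].isin(set(subjects))]
    clusters: list[Cluster] = []
    for (v, j, L), grp in tab.groupby(["v_gene", "j_gene", "cdr3_length"], sort=True, observed=True):
        if len(grp) < n_min:
            continue
        uniq = np.unique(grp["cdr3_aa"].to_numpy())  # sorted
        if len(uniq) == 1:
            labels = np.zeros(1, dtype=int)
        else:
            labels = _class_labels(_encode(list(uniq)), T)
        grp = grp.assign(_cl=labels[np.searchsorted(uniq, grp["cdr3_aa"].to_numpy())])
        if independent == "subjects":
            sizes = grp.groupby("_cl")["subject_id"].nunique()
        else:
            sizes = grp["_cl"].value_counts()
        viable = set(sizes[sizes >= n_min].index)
        if not viable:
            continue
        grp = grp[grp["_cl"].isin(viable)]
        seen_ids: set = set()
        for cl_id, members in grp.groupby("_cl", sort=True):
            triples = list(
                members[["subject_id", "cdr3_aa", "count"]].itertuples(index=False, name=None)
            )
            cons = consensus_sequence(
                [t[1] for t in triples], weights=[t[2] for t in triples]
            )
            cid = f"{v}|{j}|{L}|{cons}"
            while cid in seen_ids:  # rare: two clusters of one class share a consensus
                cid += "+"
            seen_ids.add(cid)
            clusters.append(
                Cluster(
                    cluster_id=cid,
                    v_gene=v,
                    j_gene=j,
                    cdr3_length=int(L),
                    members=triples,
                    consensus=cons,
                    threshold=T,
                )
            )
    return clusters


@dataclass
class ClusterFeatureMatrix:
    """Subjects x clusters frequency matrix with cohort labels."""

    values: pd.DataFrame  # index: subject_id, columns: cluster_id
    labels: pd.Series
    clusters: list = field(default_factory=list)


def build_cluster_matrix(
    clusters: list[Cluster],
    reps: RepertoireSet,
    subjects=None,
    assign_new: bool = True,
    member_based=None,
) -> ClusterFeatureMatrix:
    """Frequency of each subject's sequences attributed to each cluster.

    Subjects already contributing members are scored by their member
    counts. Sequences of other subjects (e.g. a holdout split scored
    against training-derived clusters) are assigned, when ``assign_new``,
    to the nearest cluster consensus of the matching V/J/length class
    provided the distance stays within the cluster threshold; otherwise
    they fall in no cluster. ``member_based`` fixes which subjects are
    scored purely by membership (e.g. the training split clusters were
    built from); by default it is the set of subjects contributing
    members. Denominators are each subject's total retained sequences,
    so all-zero rows are legal.
    """
    if subjects is None:
        subjects = reps.subjects
    subjects = list(subjects)
    totals = reps.df["subject_id"].value_counts()
    ids = [c.cluster_id for c in clusters]
    counts = pd.DataFrame(0.0, index=subjects, columns=ids)

    member_subjects = set() if member_based is None else set(member_based)
    for c in clusters:
        for s, _, n in c.members:
            if member_based is None:
                member_subjects.add(s)
            if s in counts.index:
                counts.at[s, c.cluster_id] += n

    new_subjects = [s for s in subjects if s not in member_subjects]
    if assign_new and new_subjects and clusters:
        by_class: dict[tuple, list[Cluster]] = {}
        for c in clusters:
            by_class.setdefault((c.v_gene, c.j_gene, c.cdr3_length), []).append(c)
        df = reps.df[reps.df["subject_id"].isin(new_subjects)]
        tab = (
            df.assign(
                v_gene=strip_allele(df["v_call"]),
                j_gene=strip_allele(df["j_call"]),
                cdr3_length=df["cdr3_aa"].str.len(),
            )
            .groupby(["v_gene", "j_gene", "cdr3_length", "subject_id", "cdr3_aa"], sort=True)
            .size()
            .rename("count")
            .reset_index()
        )
        for key, grp in tab.groupby(["v_gene", "j_gene", "cdr3_length"], sort=True):
            cands = by_class.get((key[0], key[1], int(key[2])))
            if not cands:
                continue
            cons = _encode([c.consensus for c in cands])
            seqs = grp["cdr3_aa"].to_numpy()
            M = _encode(list(seqs))
            # distances (n_seqs, n_clusters)
            Dm = (M[:, None, :] != cons[None, :, :]).mean(axis=2)
            best = Dm.argmin(axis=1)  # first minimiser = cluster order tie-break
            ok = Dm[np.arange(len(seqs)), best] <= cands[0].threshold
            for row, b, keep in zip(grp.itertuples(index=False), best, ok):
                if keep:
                    counts.at[row.subject_id, cands[int(b)].cluster_id] += row.count
    freqs = counts.div(totals.reindex(subjects).fillna(0).replace(0, np.nan), axis=0).fillna(0.0)
    labels = pd.Series({s: reps.labels[s] for s in subjects}, name="label")
    return ClusterFeatureMatrix(values=freqs, labels=labels, clusters=list(clusters))


def select_group_biased_clusters(
    clusters: list[Cluster],
    labels: dict | pd.Series,
    purity: float = 0.7,
) -> list[Cluster]:
    """Keep clusters dominated by one cohort.

    A cluster survives when at least ``purity`` of its member *sequences*
    (count-weighted) originate from subjects of a single label. Must be
    applied with training-subject labels only to avoid leakage.
    """
    if not (0.5 < purity <= 1):
        raise ValueError("purity must be in (0.5, 1]")
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    kept = []
    for c in clusters:
        case = sum(n for s, _, n in c.members if labels.get(s) == "case")
        total = sum(n for s, _, n in c.members if s in labels)
        if total == 0:
            continue
        frac = case / total
        if frac >= purity or (1 - frac) >= purity:
            kept.append(c)
    return kept


def cluster_purity(cluster: Cluster, labels) -> float:
    """Count-weighted fraction of member sequences from case subjects."""
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    case = sum(n for s, _, n in cluster.members if labels.get(s) == "case")
    total = sum(n for s, _, n in cluster.members if s in labels)
    return case / total if total else float("nan")


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    """Tabular cluster summary (one row per cluster), e.g. for TSV export."""
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "v_gene": [c.v_gene for c in clusters],
            "j_gene": [c.j_gene for c in clusters],
            "cdr3_length": [c.cdr3_length for c in clusters],
            "size": [c.n_members for c in clusters],
            "n_subjects": [c.n_subjects for c in clusters],
            "n_sequences": [c.n_sequences for c in clusters],
            "consensus": [c.consensus for c in clusters],
        }
    )
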
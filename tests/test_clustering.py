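import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repstrat import (
    build_cluster_matrix,
    cluster_repertoires,
    consensus_sequence,
    normalized_hamming,
    select_group_biased_clusters,
)
from repstrat.clustering import _class_labels, _encode, cluster_purity

from _reference import (
    brute_force_consensus_cost,
    consensus_cost,
    naive_complete_linkage,
)
from conftest import make_reps


# --- normalized Hamming ----------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [("CARDY", "CARDY", 0.0), ("CARDY", "CARDW", 0.2), ("AAAA", "BBBB", 1.0)],
)
def test_normalized_hamming_values(a, b, expected):
    assert normalized_hamming(a, b) == pytest.approx(expected)


def test_normalized_hamming_rejects_unequal_lengths():
    with pytest.raises(ValueError):
        normalized_hamming("AB", "ABC")


@given(st.text(alphabet="ACDE", min_size=1, max_size=12), st.data())
@settings(max_examples=50, deadline=None, derandomize=True)
def test_normalized_hamming_symmetric_and_bounded(a, data):
    b = data.draw(st.text(alphabet="ACDE", min_size=len(a), max_size=len(a)))
    d = normalized_hamming(a, b)
    assert d == normalized_hamming(b, a)
    assert 0.0 <= d <= 1.0


# --- clustering ------------------------------------------------------------

def _subject_labels(n_case, n_control):
    labels = {f"c{i}": "case" for i in range(n_case)}
    labels.update({f"h{i}": "control" for i in range(n_control)})
    return labels


def test_identical_cdr3s_across_seven_subjects_form_one_cluster():
    rows = [(f"c{i}", "IGHV1-2*01", "IGHJ4*01", "ARDYW", "IgM") for i in range(7)]
    reps = make_reps(rows, _subject_labels(7, 0))
    clusters = cluster_repertoires(reps, T=0.15, n_min=7)
    assert len(clusters) == 1
    assert clusters[0].n_members == 7
    assert clusters[0].consensus == "ARDYW"


def test_different_v_genes_never_co_cluster():
    rows = [(f"c{i}", "IGHV1-2*01", "IGHJ4*01", "ARDYW", "IgM") for i in range(4)]
    rows += [(f"c{i+4}", "IGHV3-7*01", "IGHJ4*01", "ARDYW", "IgM") for i in range(4)]
    reps = make_reps(rows, _subject_labels(8, 0))
    clusters = cluster_repertoires(reps, T=0.15, n_min=4)
    assert len(clusters) == 2
    assert {c.v_gene for c in clusters} == {"IGHV1-2", "IGHV3-7"}


def _partition_from_labels(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return {frozenset(v) for v in groups.values()}


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("alphabet,length,T", [("ABC", 6, 0.34), ("ACDEFG", 12, 0.15)])
def test_cluster_assignment_matches_naive_oracle(seed, alphabet, length, T):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 40))
    seqs = sorted(
        {"".join(rng.choice(list(alphabet), size=length)) for _ in range(n)}
    )
    labels = _class_labels(_encode(seqs), T)
    assert _partition_from_labels(labels) == naive_complete_linkage(seqs, T)


def test_emitted_clusters_respect_diameter_bound(small_sim):
    reps, _ = small_sim
    for T, n_min in [(0.15, 7), (0.25, 10)]:
        for c in cluster_repertoires(reps, T=T, n_min=n_min):
            assert c.max_pairwise_distance() <= T + 1e-12
            assert {len(m[1]) for m in c.members} == {c.cdr3_length}


def test_clustering_is_label_blind(small_sim):
    reps, _ = small_sim
    flipped = reps.__class__(reps.df, {s: ("case" if l == "control" else "control")
                                       for s, l in reps.labels.items()})
    a = cluster_repertoires(reps, T=0.15, n_min=7)
    b = cluster_repertoires(flipped, T=0.15, n_min=7)
    assert [c.cluster_id for c in a] == [c.cluster_id for c in b]
    assert [c.members for c in a] == [c.members for c in b]


def test_independent_member_modes_differ_when_one_subject_repeats():
    # one subject contributes 5 distinct CDR3 variants, two others one each:
    # 7 (subject, cdr3) pairs but only 3 subjects
    rows = [("c0", "V1", "J1", f"ARD{aa}W", "IgM") for aa in "ACDEF"]
    rows += [("c1", "V1", "J1", "ARDAW", "IgM"), ("c2", "V1", "J1", "ARDCW", "IgM")]
    reps = make_reps(rows, _subject_labels(3, 0))
    by_pairs = cluster_repertoires(reps, T=0.4, n_min=7, independent="pairs")
    by_subjects = cluster_repertoires(reps, T=0.4, n_min=7, independent="subjects")
    assert len(by_pairs) == 1 and len(by_subjects) == 0


# --- consensus -------------------------------------------------------------

def test_consensus_trivial_cases():
    assert consensus_sequence(["AAA"]) == "AAA"
    assert consensus_sequence(["AAC", "AAC", "AAA"]) == "AAC"
    # ties broken by alphabetical order
    assert consensus_sequence(["AC", "CA"]) == "AA"
    with pytest.raises(ValueError):
        consensus_sequence([])


@pytest.mark.parametrize("seed", range(20))
def test_consensus_attains_brute_force_minimum(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 9))
    L = int(rng.integers(1, 9))
    members = ["".join(rng.choice(list("ACDE"), size=L)) for _ in range(n)]
    cons = consensus_sequence(members)
    assert consensus_cost(cons, members) == brute_force_consensus_cost(members)


# --- feature matrix and selection -----------------------------------------

def test_cluster_matrix_frequencies_and_zero_rows():
    rows = [("c0", "V1", "J1", "ARDYW", "IgM")] * 10
    rows += [("c0", "V1", "J1", "".join(aa), "IgM")
             for aa in np.random.default_rng(0).choice(list("FGHIKLMN"), size=(90, 5))]
    rows += [("c1", "V1", "J1", "ARDYW", "IgM")] * 3
    rows += [("h0", "V2", "J1", "WWWWW", "IgM")] * 5
    reps = make_reps(rows, {"c0": "case", "c1": "case", "h0": "control"})
    clusters = cluster_repertoires(reps, T=0.15, n_min=2)
    target = [c for c in clusters if c.consensus == "ARDYW"]
    assert len(target) == 1
    m = build_cluster_matrix(target, reps)
    assert m.values.at["c0", target[0].cluster_id] == pytest.approx(0.10)
    assert m.values.loc["h0"].eq(0).all()


def test_planted_clusters_are_case_enriched_in_matrix(small_sim):
    reps, truth = small_sim
    clusters = cluster_repertoires(reps, T=0.15, n_min=7)
    m = build_cluster_matrix(clusters, reps)
    case_rows = m.labels == "case"
    seeds = dict(zip(truth.table.index, truth.table["seed_cdr3"]))
    hits = 0
    for idx, row in truth.table.iterrows():
        matching = [
            c.cluster_id
            for c in clusters
            if c.cdr3_length == len(seeds[idx])
            and normalized_hamming(c.consensus, seeds[idx]) <= 0.15
            and c.v_gene == row["v_gene"]
        ]
        if not matching:
            continue
        col = m.values[matching].sum(axis=1)
        case_mean, ctrl_mean = col[case_rows].mean(), col[~case_rows].mean()
        if row["biased_label"] == "case":
            assert case_mean > ctrl_mean
        else:
            assert ctrl_mean > case_mean
        hits += 1
    assert hits >= 5  # nearly all planted seeds recovered


def test_purity_selection_thresholds():
    rows = [(f"c{i}", "V1", "J1", "ARDYW", "IgM") for i in range(8)]
    rows += [(f"h{i}", "V1", "J1", "ARDYW", "IgM") for i in range(2)]
    rows += [(f"c{i}", "V2", "J1", "TTTTT", "IgM") for i in range(6)]
    rows += [(f"h{i}", "V2", "J1", "TTTTT", "IgM") for i in range(4)]
    labels = _subject_labels(8, 4)
    reps = make_reps(rows, labels)
    clusters = cluster_repertoires(reps, T=0.15, n_min=5)
    kept = select_group_biased_clusters(clusters, labels, purity=0.7)
    assert {c.consensus for c in clusters} == {"ARDYW", "TTTTT"}
    assert {c.consensus for c in kept} == {"ARDYW"}  # 8/10 kept, 6/10 dropped
    with pytest.raises(ValueError):
        select_group_biased_clusters(clusters, labels, purity=0.5)


def test_planted_purity_clusters_survive_selection(small_sim):
    reps, truth = small_sim
    clusters = cluster_repertoires(reps, T=0.15, n_min=7)
    kept = select_group_biased_clusters(clusters, reps.labels, purity=0.7)
    # every recovered planted cluster (consensus near a seed) passes 70% purity
    for c in clusters:
        near_seed = any(
            c.cdr3_length == len(s) and normalized_hamming(c.consensus, s) <= 0.15
            for s in truth.table["seed_cdr3"]
        )
        if near_seed and c.n_sequences >= 20:
            assert c in kept
            assert not 0.3 < cluster_purity(c, reps.labels) < 0.7
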
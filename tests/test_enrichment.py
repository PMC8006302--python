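from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from repstrat import (
    csea,
    ct_encode_sequence,
    enrichment_score,
    fisher_exact_two_sided,
    kmer_enrichment,
    length_balanced_sets,
)
from repstrat.enrichment import CT_CLASSES, CT_MAP

from _reference import exact_fisher_two_sided, naive_bh


# --- conjoint-triad encoding ----------------------------------------------

def test_ct_classes_partition_the_alphabet():
    assert sorted("".join(CT_CLASSES.values())) == sorted("ACDEFGHIKLMNPQRSTVWY")
    assert len(CT_MAP) == 20


def test_ct_encoding_examples():
    assert ct_encode_sequence("YMT") == "333"
    assert len(set(ct_encode_sequence("RK"))) == 1
    assert ct_encode_sequence("C") == "7"
    with pytest.raises(ValueError, match="X"):
        ct_encode_sequence("AXC")


# --- enrichment score ------------------------------------------------------

def test_es_is_one_when_set_occupies_top_ranks():
    r = [5.0, 4.0, 3.0, 2.0, 1.0]
    es, walk = enrichment_score(r, [True, True, False, False, False])
    assert es == pytest.approx(1.0)
    assert walk[-1] == pytest.approx(0.0, abs=1e-12)


def test_es_worked_example_hand_computed():
    # N=4, S at ranks {1,3}, importances (4,3,2,1):
    # walk = 4/6, 4/6-1/2, 4/6-1/2+2/6, 0  ->  ES = 2/3
    es, walk = enrichment_score([4.0, 3.0, 2.0, 1.0], [True, False, True, False])
    assert abs(es - 2.0 / 3.0) < 1e-12
    assert np.allclose(walk, [4 / 6, 4 / 6 - 1 / 2, 4 / 6 - 1 / 2 + 2 / 6, 0.0], atol=1e-12)


def test_es_increments_and_decrements_each_sum_to_one(rng):
    for _ in range(20):
        n = int(rng.integers(4, 40))
        r = rng.random(n) + 0.01
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
        es, walk = enrichment_score(r, mask)
        steps = np.diff(np.concatenate(([0.0], walk)))
        assert steps[mask].sum() == pytest.approx(1.0)
        assert steps[~mask].sum() == pytest.approx(-1.0)
        assert 0 < es <= 1 + 1e-12


def test_es_rejects_degenerate_sets():
    with pytest.raises(ValueError):
        enrichment_score([1.0, 2.0], [True, True])
    with pytest.raises(ValueError):
        enrichment_score([1.0, 2.0], [False, False])
    with pytest.raises(ValueError):
        enrichment_score([0.0, 1.0], [True, False])


# --- CSEA ------------------------------------------------------------------

def _ranked(rng, n=30, levels=("a", "b", "c")):
    ids = [f"cl{i}" for i in range(n)]
    importance = pd.Series(rng.random(n), index=ids)
    sets = pd.Series(rng.choice(levels, size=n), index=ids)
    return importance, sets


def test_csea_extreme_set_gets_minimal_p(rng):
    ids = [f"cl{i}" for i in range(40)]
    importance = pd.Series(np.linspace(2.0, 0.1, 40), index=ids)
    sets = pd.Series(["top"] * 8 + ["rest"] * 32, index=ids)
    out = csea(importance, sets, n_perm=200, seed=1)
    row = out[out["set_id"] == "top"].iloc[0]
    assert row["es"] == pytest.approx(1.0)
    assert row["p"] <= 1 / 200
    assert row["nes"] > 1.5


def test_csea_null_sets_are_insignificant(rng):
    sig = 0
    for seed in range(3):
        importance, sets = _ranked(np.random.default_rng(seed))
        out = csea(importance, sets, n_perm=300, seed=seed)
        sig += int((out["fdr"] < 0.05).sum())
    assert sig == 0


def test_csea_deterministic_given_seed(rng):
    importance, sets = _ranked(rng)
    a = csea(importance, sets, n_perm=150, seed=9)
    b = csea(importance, sets, n_perm=150, seed=9)
    pd.testing.assert_frame_equal(a, b)


# --- Fisher / BH -----------------------------------------------------------

def test_vectorised_fisher_matches_scipy(rng):
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            continue
        ours = fisher_exact_two_sided([a], [b], [c], [d])[0]
        theirs = scipy_fisher([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(theirs, abs=1e-10)


def test_fisher_matches_exact_rational_oracle():
    ours = fisher_exact_two_sided([90], [910], [10], [990])[0]
    assert ours == pytest.approx(exact_fisher_two_sided(90, 910, 10, 990), abs=1e-12)


# --- length balancing and k-mer enrichment ---------------------------------

def test_length_balancing_exact_histogram_match(rng):
    a = ["A" * 12] * 10 + ["C" * 8] * 3
    b = ["D" * 12] * 4 + ["E" * 8] * 5 + ["F" * 20] * 2
    a2, b2 = length_balanced_sets(a, b, seed=0)
    ha = Counter(len(s) for s in a2)
    hb = Counter(len(s) for s in b2)
    assert ha == hb == {12: 4, 8: 3}
    # identical histograms: everything retained
    a3, b3 = length_balanced_sets(a, a, seed=0)
    assert sorted(a3) == sorted(b3) == sorted(a)
    with pytest.raises(ValueError):
        length_balanced_sets(["AAA"], ["AAAA"])


def test_kmer_enrichment_symmetric_input_is_null():
    seqs = ["CARDYW", "TRDFYW", "ARDLLW"]
    out = kmer_enrichment(seqs, list(seqs), k=3)
    assert np.allclose(out["log2_fc"], 0.0)
    assert np.allclose(out["p"], 1.0)
    assert not out["significant"].any()


def test_kmer_enrichment_qvalues_match_bh_oracle(rng):
    a = ["".join(rng.choice(list("ACDE"), size=8)) for _ in range(40)]
    b = ["".join(rng.choice(list("ACDF"), size=8)) for _ in range(40)]
    out = kmer_enrichment(a, b, k=2)
    assert (out["q"] >= out["p"] - 1e-12).all()
    expected = naive_bh(list(out["p"]))
    assert np.allclose(out["q"], expected)


def test_kmer_enrichment_detects_planted_difference():
    a = ["YMTSYMTS"] * 30 + ["ACDEACDE"] * 30
    b = ["ACDEACDE"] * 60
    a2, b2 = length_balanced_sets(a, b, seed=1)
    out = kmer_enrichment(a2, b2, k=3, representation="ct").set_index("kmer")
    assert out.loc["333", "significant"]
    assert out.loc["333", "log2_fc"] > 0  # enriched in the case set
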
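"""Independent reference implementations used as test oracles.

Deliberately naive: pure-Python, exact-arithmetic where possible, and
sharing no code with the package paths they check.
"""

from fractions import Fraction
from math import comb


def hamming_frac(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


def naive_complete_linkage(seqs, T):
    """O(n^3) agglomerative complete-linkage partition cut at ``T``.

    Works on the all-pairs distance matrix; at each step the active pair
    of clusters with the smallest complete-linkage distance is merged
    (ties broken by the smallest index pair, clusters keyed by their
    smallest member index; inter-cluster distances maintained by the
    max-update rule) until that distance exceeds ``T``. Returns a set of
    frozensets of sequence indices.
    """
    n = len(seqs)
    D = {
        (i, j): hamming_frac(seqs[i], seqs[j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    members = {i: {i} for i in range(n)}
    while len(members) > 1:
        d, i, j = min((d, i, j) for (i, j), d in D.items())
        if d > T:
            break
        D.pop((i, j))
        members[i] |= members.pop(j)
        for k in members:
            if k == i:
                continue
            key_ik = (min(i, k), max(i, k))
            key_jk = (min(j, k), max(j, k))
            D[key_ik] = max(D[key_ik], D.pop(key_jk))
    return {frozenset(v) for v in members.values()}


def brute_force_consensus_cost(members):
    """Minimum summed Hamming distance attainable by any consensus string.

    The objective separates per column, so the exact minimum is the sum
    over columns of (n - max residue multiplicity).
    """
    n = len(members)
    total = 0
    for col in zip(*members):
        counts = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        total += n - max(counts.values())
    return total


def consensus_cost(consensus, members):
    return sum(sum(a != b for a, b in zip(consensus, m)) for m in members)


def exact_fisher_two_sided(a, b, c, d) -> float:
    """Two-sided Fisher exact p in exact rational arithmetic.

    Sums the hypergeometric pmf over all tables with the same margins
    whose probability does not exceed the observed one (with the
    conventional 1e-7 relative tie tolerance, applied in rationals).
    """
    M, n1, K = a + b + c + d, a + b, a + c
    denom = comb(M, n1)
    lo, hi = max(0, K - (M - n1)), min(K, n1)
    pmf = {k: Fraction(comb(K, k) * comb(M - K, n1 - k), denom) for k in range(lo, hi + 1)}
    cutoff = pmf[a] * (Fraction(10**7 + 1, 10**7))
    return float(min(Fraction(1), sum(v for v in pmf.values() if v <= cutoff)))


def naive_bh(pvalues):
    """Benjamini-Hochberg adjusted p-values, textbook implementation."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adj = [0.0] * n
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = n - rank_from_end
        val = min(prev, pvalues[i] * n / rank)
        adj[i] = val
        prev = val
    return adj
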
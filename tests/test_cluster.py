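import numpy as np
import pytest

from iscensus.align import pairwise_identity
from iscensus.cluster import build_consensus, classify_family, cluster_isoforms
from iscensus.model import Interval


def test_identity_of_identical_strings():
    assert pairwise_identity("ACGTACGT", "ACGTACGT") == (1.0, 1.0)


def test_identity_counts_mismatches():
    ident, cov = pairwise_identity("AAAA", "AAAT")
    assert ident == 0.75
    assert cov == 1.0


def test_identity_against_dp_reference(rng):
    """Alignment score equals an independent quadratic DP on random pairs."""
    from .oracles import rc

    def dp_score(a, b, match=2.0, mismatch=-3.0, open_=-5.0, ext=-2.0):
        # affine-gap global alignment (Gotoh)
        inf = float("-inf")
        n, m = len(a), len(b)
        M = [[inf] * (m + 1) for _ in range(n + 1)]
        X = [[inf] * (m + 1) for _ in range(n + 1)]  # gap in b
        Y = [[inf] * (m + 1) for _ in range(n + 1)]  # gap in a
        M[0][0] = 0.0
        for i in range(1, n + 1):
            X[i][0] = open_ + ext * (i - 1)
        for j in range(1, m + 1):
            Y[0][j] = open_ + ext * (j - 1)
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                s = match if a[i - 1] == b[j - 1] else mismatch
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1]) + s
                X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext)
                Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext)
        return max(M[n][m], X[n][m], Y[n][m])

    from iscensus.align import _aligner
    for _ in range(25):
        n = int(rng.integers(30, 300))
        a = "".join(rng.choice(list("ACGT"), size=n))
        b = list(a)
        for _k in range(int(rng.integers(0, n // 3))):
            p = int(rng.integers(len(b)))
            op = rng.random()
            if op < 0.7:
                b[p] = "ACGT"[int(rng.integers(4))]
            elif op < 0.85 and len(b) > 10:
                del b[p]
            else:
                b.insert(p, "ACGT"[int(rng.integers(4))])
        b = "".join(b)
        got = _aligner("nt").score(a, b)
        assert got == pytest.approx(dp_score(a, b), abs=1e-6)


class Unit:
    def __init__(self, nt, aa, start):
        self.nt = nt
        self.aa = aa
        self.interval = Interval("chr", start, start + len(nt), "+")


def _mutate(seq, frac, rng):
    out = list(seq)
    for p in rng.choice(len(out), size=int(frac * len(out)), replace=False):
        out[p] = next(c for c in "ACGT" if c != out[p])
    return "".join(out)


def test_isoforms_cluster_and_families_separate():
    rng = np.random.default_rng(11)
    base1 = "".join(rng.choice(list("ACGT"), size=600))
    base2 = "".join(rng.choice(list("ACGT"), size=600))
    a = Unit(base1, base1[:200], 0)
    b = Unit(_mutate(base1, 0.05, rng), _mutate(base1[:200], 0.05, rng), 1000)
    c = Unit(base2, base2[:200], 2000)
    clusters = cluster_isoforms([a, b, c])
    sizes = sorted(len(cl) for cl in clusters)
    assert sizes == [1, 2]
    big = max(clusters, key=len)
    assert {u.interval.start for u in big} == {0, 1000}


def test_single_linkage_chains_transitively():
    rng = np.random.default_rng(4242)  # local: construction must be stable
    base = "".join(rng.choice(list("ACGT"), size=600))
    b = _mutate(base, 0.18, rng)
    c = _mutate(b, 0.18, rng)
    a_c_ident, _ = pairwise_identity(base, c)
    assert a_c_ident < 0.8, "construction: a-c must be below the threshold"
    units = [Unit(base, base[:200], 0), Unit(b, b[:200], 1000),
             Unit(c, c[:200], 2000)]
    clusters = cluster_isoforms(units)
    assert len(clusters) == 1 and len(clusters[0]) == 3


def test_clustering_is_order_invariant():
    rng = np.random.default_rng(12)
    seqs = []
    for fam in range(3):
        base = "".join(rng.choice(list("ACGT"), size=500))
        for copy in range(3):
            seqs.append(_mutate(base, 0.04, rng))
    units = [Unit(s, s[:160], 1000 * i) for i, s in enumerate(seqs)]
    ref = [sorted(u.interval.start for u in cl)
           for cl in cluster_isoforms(units)]
    perm = list(units)
    np.random.default_rng(1).shuffle(perm)
    got = [sorted(u.interval.start for u in cl)
           for cl in cluster_isoforms(perm)]
    assert sorted(ref) == sorted(got)


def test_consensus_of_single_member_is_the_member():
    assert build_consensus(["ACGTACGT"]) == "ACGTACGT"


def test_consensus_majority_recovers_planted():
    rng = np.random.default_rng(13)
    planted = "".join(rng.choice(list("ACGT"), size=800))
    members = [_mutate(planted, 0.05, rng) for _ in range(5)]
    cons = build_consensus(members)
    ident, _ = pairwise_identity(cons, planted)
    assert ident >= 0.99


def test_consensus_majority_column_rule():
    seqs = ["A", "A", "A", "G", "G"]
    assert build_consensus(seqs) == "A"


def test_classification_criteria():
    from iscensus.model import InvertedRepeatPair

    ir = InvertedRepeatPair(left_arm=Interval("e", 0, 18, "+"),
                            right_arm=Interval("e", 700, 718, "+"),
                            arm_len=18, matches=18)
    ok, _ = classify_family(n_copies=10, ir=ir, family_class="IS5",
                            homology_ok=True)
    assert ok
    # single copy: rejected whatever else holds
    ok, reason = classify_family(n_copies=1, ir=ir, family_class="IS5",
                                 homology_ok=True)
    assert not ok and "copy" in reason
    # IR-less families of the exempt classes still classify
    ok, _ = classify_family(n_copies=3, ir=None, family_class="IS110",
                            homology_ok=True)
    assert ok
    ok, _ = classify_family(n_copies=3, ir=None, family_class="IS5",
                            homology_ok=True)
    assert not ok
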
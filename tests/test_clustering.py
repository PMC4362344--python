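import numpy as np
import pytest
from Bio.Align import substitution_matrices

from holoest.clustering import (
    Peptide,
    alignment_identities,
    collapse_to_unigenes,
    greedy_cluster,
    identity,
    lcs_length,
    six_frame_peptides,
    venn_counts,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")
_B = substitution_matrices.load("BLOSUM62")


def _lcs_recursive(a, b):
    """Independent quadratic LCS (plain table, no bit tricks)."""
    la, lb = len(a), len(b)
    T = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            T[i][j] = (
                T[i - 1][j - 1] + 1
                if a[i - 1] == b[j - 1]
                else max(T[i - 1][j], T[i][j - 1])
            )
    return T[la][lb]


def _identity_oracle(a, b, open_=10, ext=1):
    """Semi-global Gotoh maximising (score, identities) lexicographically,
    written directly from the recurrences with tuple arithmetic."""
    la, lb = len(a), len(b)
    NEG = (-(10 ** 9), 0)
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]
    V = [[NEG] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        V[i][0] = (0, 0)
    for j in range(lb + 1):
        V[0][j] = (0, 0)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = _B[a[i - 1], b[j - 1]]
            M = (V[i - 1][j - 1][0] + s, V[i - 1][j - 1][1] + (a[i - 1] == b[j - 1]))
            X[i][j] = max(
                (V[i - 1][j][0] - open_ - ext, V[i - 1][j][1]),
                (X[i - 1][j][0] - ext, X[i - 1][j][1]),
            )
            Y[i][j] = max(
                (V[i][j - 1][0] - open_ - ext, V[i][j - 1][1]),
                (Y[i][j - 1][0] - ext, Y[i][j - 1][1]),
            )
            V[i][j] = max(M, X[i][j], Y[i][j])
    best = (0, 0)
    for j in range(lb + 1):
        best = max(best, V[la][j])
    for i in range(la + 1):
        best = max(best, V[i][lb])
    return best[1] / min(la, lb)


def test_lcs_length_matches_plain_table(rng):
    for _ in range(60):
        a = "".join(rng.choice(AA, rng.integers(0, 40)))
        b = "".join(rng.choice(AA, rng.integers(0, 40)))
        assert lcs_length(a, b) == _lcs_recursive(a, b)


def test_alignment_identities_matches_tuple_dp_oracle(rng):
    for _ in range(150):
        a = "".join(rng.choice(AA, rng.integers(1, 30)))
        b = "".join(rng.choice(AA, rng.integers(1, 30)))
        assert alignment_identities(a, b) / min(len(a), len(b)) == pytest.approx(
            _identity_oracle(a, b)
        )


def test_identity_basics():
    assert identity("ACDEFGHIK", "ACDEFGHIK") == 1.0
    assert identity("ACDEF", "GGACDEFGG") == 1.0  # substring, free end gaps
    assert identity("AAAAAAAAAA", "CCCCCCCCCC") == 0.0
    with pytest.raises(ValueError):
        identity("", "ACD")


def test_two_identical_peptides_form_one_cluster():
    peps = [Peptide("a", "s1", "MKVLAEQTWP"), Peptide("b", "s2", "MKVLAEQTWP")]
    cs = greedy_cluster(peps, 0.5)
    assert len(cs) == 1
    assert {p.id for p in cs.clusters[0].members} == {"a", "b"}


def test_dissimilar_peptides_stay_apart():
    peps = [Peptide("a", "s1", "AAAAAAAAAA"), Peptide("b", "s1", "CCCCCCCCCC")]
    assert len(greedy_cluster(peps, 0.5)) == 2


def _brute_force_greedy(peptides, threshold):
    order = sorted(peptides, key=lambda p: (-len(p.seq), p.id))
    clusters = []
    for pep in order:
        for cl in clusters:
            if _identity_oracle(pep.seq, cl[0].seq) >= threshold:
                cl.append(pep)
                break
        else:
            clusters.append([pep])
    return [{p.id for p in cl} for cl in clusters]


def test_greedy_cluster_matches_brute_force_oracle(rng):
    """Membership identical to re-running the same greedy rule with an
    exhaustive tuple-DP alignment oracle."""
    peps = []
    base = "".join(rng.choice(AA, 20))
    for i in range(30):
        if rng.random() < 0.5:  # related: mutate the base
            seq = list(base[: rng.integers(12, 21)])
            for k in rng.choice(len(seq), 3, replace=False):
                seq[k] = str(rng.choice(AA))
            seq = "".join(seq)
        else:
            seq = "".join(rng.choice(AA, rng.integers(8, 25)))
        peps.append(Peptide(f"p{i:02d}", f"s{i % 3}", seq))
    got = [{p.id for p in cl.members} for cl in greedy_cluster(peps, 0.5).clusters]
    assert got == _brute_force_greedy(peps, 0.5)


def test_cluster_count_monotone_in_threshold():
    rng = np.random.default_rng(5)
    base = "".join(rng.choice(AA, 30))
    peps = []
    for i in range(20):
        seq = list(base)
        for k in rng.choice(30, rng.integers(0, 12), replace=False):
            seq[k] = str(rng.choice(AA))
        peps.append(Peptide(f"p{i:02d}", "s", "".join(seq)))
    sizes = [len(greedy_cluster(peps, t)) for t in (0.3, 0.5, 0.7, 0.9)]
    assert sizes == sorted(sizes)


def test_venn_counts_direct_example():
    peps = {
        "c1": [("x1", "A")],
        "c2": [("x2", "A"), ("x3", "B")],
        "c3": [("x4", "A"), ("x5", "B"), ("x6", "C")],
    }
    from holoest.clustering import Cluster, ClusterSet

    cs = ClusterSet(
        clusters=[
            Cluster(representative=m[0][0], rep_seq="X",
                    members=[Peptide(i, s, "X") for i, s in m])
            for m in peps.values()
        ],
        threshold=0.5,
    )
    subsets, private = venn_counts(cs)
    assert subsets == {
        frozenset({"A"}): 1,
        frozenset({"A", "B"}): 1,
        frozenset({"A", "B", "C"}): 1,
    }
    assert private["A"] == pytest.approx(1 / 3)
    assert sum(subsets.values()) == len(cs)


def test_single_sample_clusters_are_all_private():
    peps = [Peptide(f"p{i}", "only", "".join(np.random.default_rng(i).choice(AA, 15)))
            for i in range(4)]
    cs = greedy_cluster(peps, 0.9)
    _, private = venn_counts(cs)
    assert private["only"] == 1.0


def test_six_frame_peptides_and_collapse():
    translations = {"u1": {1: "MKV", -2: "LLA"}, "u2": {1: "MKV"}}
    sample_of = {"u1": "s1", "u2": "s2"}
    peps = six_frame_peptides(translations, sample_of)
    assert {p.id for p in peps} == {"u1|+1", "u1|-2", "u2|+1"}
    cs = greedy_cluster(peps, 1.0)
    unigene_sets = collapse_to_unigenes(cs)
    assert {"u1", "u2"} in unigene_sets
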
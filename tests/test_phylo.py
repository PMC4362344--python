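import numpy as np
import pytest
from skbio import DistanceMatrix

from holoest.phylo import (
    CurationParams,
    Msa,
    bipartitions,
    bootstrap_support,
    curate_blocks,
    distance_matrix,
    is_monophyletic_unrooted,
    nj_tree,
    progressive_align,
    protein_distance,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def test_msa_rejects_ragged_rows():
    with pytest.raises(ValueError):
        Msa(ids=["a", "b"], rows=["ACD", "AC"])


def test_identical_pair_aligns_gap_free():
    msa = progressive_align([("a", "MKVLAE"), ("b", "MKVLAE")])
    assert msa.rows == ["MKVLAE", "MKVLAE"]


def test_single_deletion_yields_five_columns():
    msa = progressive_align([("a", "ACDEF"), ("b", "ACEF")])
    assert msa.n_cols == 5
    row = dict(zip(msa.ids, msa.rows))
    assert row["a"] == "ACDEF"
    assert row["b"].count("-") == 1
    assert row["b"].replace("-", "") == "ACEF"


def test_progressive_align_degap_recovers_inputs(rng):
    seqs = [
        (f"s{i}", "".join(rng.choice(AA, rng.integers(8, 30)))) for i in range(8)
    ]
    msa = progressive_align(seqs)
    originals = dict(seqs)
    for sid, row in zip(msa.ids, msa.rows):
        assert row.replace("-", "") == originals[sid]


def test_progressive_align_needs_two_sequences():
    with pytest.raises(ValueError):
        progressive_align([("a", "MKV")])


def test_curation_keeps_fully_conserved_alignment():
    msa = Msa(ids=["a", "b", "c"], rows=["M" * 20] * 3)
    curated, kept = curate_blocks(msa)
    assert kept == list(range(20))
    assert curated.rows == msa.rows


def test_curation_removes_gap_columns_and_short_flanks():
    # columns 5-8 are gapped in one row; left flank (5 cols) is shorter than
    # min_block_length and must go too, right flank (12 cols) survives
    top = "MKVLA" + "ACDE" + "M" * 12
    bottom = "MKVLA" + "----" + "M" * 12
    msa = Msa(ids=["a", "b"], rows=[top, bottom])
    curated, kept = curate_blocks(msa, CurationParams(min_block_length=10))
    assert kept == list(range(9, 21))
    assert curated.rows == ["M" * 12, "M" * 12]


def test_permissive_curation_is_identity():
    msa = Msa(ids=["a", "b"], rows=["MK-LA", "MKV-A"])
    params = CurationParams(max_gap_fraction=1.0, min_conservation=0.0, min_block_length=1)
    curated, kept = curate_blocks(msa, params)
    assert curated.rows == msa.rows and kept == [0, 1, 2, 3, 4]


def test_curation_can_empty_an_alignment_with_warning():
    msa = Msa(ids=["a", "b"], rows=["M-", "-M"])
    with pytest.warns(UserWarning):
        curated, kept = curate_blocks(msa)
    assert kept == [] and curated.rows == ["", ""]


def test_protein_distance_cases():
    assert protein_distance("MKVLA", "MKVLA") == 0.0
    assert protein_distance("M" * 9 + "K", "M" * 10) == pytest.approx(0.1)
    assert protein_distance("M-KVA", "MAKVA") == 0.0  # gap column skipped
    assert protein_distance("M" * 9 + "K", "M" * 10, poisson=True) == pytest.approx(
        0.10536, abs=1e-5
    )
    with pytest.raises(ValueError):
        protein_distance("M-", "-M")


def test_nj_recovers_four_taxon_tree():
    # tree ((A:1,B:2):1,(C:3,D:1)) -> path distances below
    dm = DistanceMatrix(
        [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]],
        ids=["A", "B", "C", "D"],
    )
    tree = nj_tree(dm)
    assert is_monophyletic_unrooted(tree, {"A", "B"})
    assert is_monophyletic_unrooted(tree, {"C", "D"})


def test_nj_three_taxa_is_a_star():
    tree = nj_tree(DistanceMatrix([[0, 2, 3], [2, 0, 4], [3, 4, 0]], ids=list("ABC")))
    assert {t.name for t in tree.tips()} == {"A", "B", "C"}
    assert bipartitions(tree) == set()


def test_nj_rejects_asymmetric_matrix():
    with pytest.raises(ValueError):
        nj_tree(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]), ids=list("ABC"))


def _random_additive(rng, n):
    """Random unrooted binary tree on n leaves; returns (distance matrix,
    set of nontrivial splits) computed by path lengths - the NJ oracle."""
    nodes = [(i, None) for i in range(n)]
    edges = {}
    next_id = n
    ids = list(range(n))
    children = {}
    while len(ids) > 3:
        i, j = sorted(rng.choice(len(ids), 2, replace=False), reverse=True)
        a, b = ids.pop(i), ids.pop(j)
        children[next_id] = (a, b)
        edges[(next_id, a)] = rng.uniform(0.1, 1.0)
        edges[(next_id, b)] = rng.uniform(0.1, 1.0)
        ids.append(next_id)
        next_id += 1
    center = next_id
    for a in ids:
        edges[(center, a)] = rng.uniform(0.1, 1.0)
    children[center] = tuple(ids)

    # adjacency + BFS distances between leaves
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    import collections

    def dists_from(s):
        d = {s: 0.0}
        q = collections.deque([s])
        while q:
            u = q.popleft()
            for v, w in adj[u]:
                if v not in d:
                    d[v] = d[u] + w
                    q.append(v)
        return d

    D = np.zeros((n, n))
    for i in range(n):
        di = dists_from(i)
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = di[j]

    def leafset(node, parent):
        if node < n:
            return frozenset({str(node)})
        out = frozenset()
        for v, _ in adj[node]:
            if v != parent:
                out |= leafset(v, node)
        return out

    all_leaves = frozenset(str(i) for i in range(n))
    splits = set()
    for (u, v) in edges:
        side = leafset(v, u)
        if 1 < len(side) < n - 1:
            splits.add(min(side, all_leaves - side, key=lambda s: (len(s), sorted(s))))
    return D, splits


def test_nj_exact_on_random_additive_matrices(rng):
    """Neighbor joining provably recovers the generating topology from any
    additive matrix; checked on 50 random trees with up to 8 leaves."""
    for _ in range(50):
        n = int(rng.integers(4, 9))
        D, want = _random_additive(rng, n)
        tree = nj_tree(D, ids=[str(i) for i in range(n)])
        assert bipartitions(tree) == want


def test_nj_topology_invariant_under_taxon_permutation(rng):
    D, _ = _random_additive(rng, 7)
    ids = [str(i) for i in range(7)]
    base = bipartitions(nj_tree(D, ids=ids))
    perm = rng.permutation(7)
    D2 = D[np.ix_(perm, perm)]
    ids2 = [ids[k] for k in perm]
    assert bipartitions(nj_tree(D2, ids=ids2)) == base


def test_distance_matrix_and_bootstrap_on_clear_signal(rng):
    group1 = ["MKVLAEQTWPMKVLAEQTWP", "MKVLAEQTWPMKVLAEQSWP"]
    group2 = ["GGDDHHRRSSGGDDHHRRSS", "GGDDHHRRSSGGDDHHRRTS"]
    seqs = [(f"a{i}", s) for i, s in enumerate(group1)] + [
        (f"b{i}", s) for i, s in enumerate(group2)
    ]
    msa = progressive_align(seqs)
    dm = distance_matrix(msa)
    assert dm["a0", "a1"] < dm["a0", "b0"]
    support = bootstrap_support(msa, n_replicates=30, seed=1)
    for split, value in support.items():
        assert value > 0.8
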
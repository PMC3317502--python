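"""p-distance, neighbour joining, bootstrap, consensus, family assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nj_oracle
from igreceptor import (
    DistanceMatrix,
    DomainAlignment,
    assign_family,
    bootstrap_supports,
    build_domain_alignment,
    build_pssm,
    distance_matrix,
    majority_consensus,
    nj_tree,
    p_distance,
)
from igreceptor.discovery import AA_ALPHABET

ROW_ALPHABET = "ACDEF-X"


def make_dm(labels, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(tuple(labels), d, np.full_like(d, 10, dtype=np.int64))


# ---------------------------------------------------------------------------
# p-distance


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACDEF", "ACDEF", (0.0, 5)),
        ("ACDEF", "ACDKF", (0.2, 5)),
        ("A-DEF", "ACDKL", (0.5, 4)),
    ],
)
def test_p_distance_worked_examples(a, b, expected):
    assert p_distance(a, b) == expected


def test_p_distance_undefined_when_nothing_comparable():
    d, sites = p_distance("--X", "AC-")
    assert sites == 0 and np.isnan(d)


@settings(derandomize=True, max_examples=300)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(ROW_ALPHABET), st.sampled_from(ROW_ALPHABET)
        ),
        min_size=1,
        max_size=40,
    )
)
def test_p_distance_matches_direct_column_count(pairs):
    a = "".join(x for x, _ in pairs)
    b = "".join(y for _, y in pairs)
    comp = [(x, y) for x, y in pairs if x not in "-X" and y not in "-X"]
    d, sites = p_distance(a, b)
    assert sites == len(comp)
    if comp:
        assert d == pytest.approx(sum(x != y for x, y in comp) / len(comp))
        assert 0.0 <= d <= 1.0
        assert p_distance(b, a) == (d, sites)
    assert p_distance(a, a)[0] in (0.0,) or np.isnan(p_distance(a, a)[0])


def test_distance_matrix_equals_pairwise_recomputation(rng):
    rows = [
        "".join(ROW_ALPHABET[i] for i in rng.integers(0, len(ROW_ALPHABET), 60))
        for _ in range(50)
    ]
    labels = [f"s{i}" for i in range(50)]
    dm = distance_matrix(DomainAlignment(tuple(labels), tuple(rows)))
    for i in range(50):
        assert dm.d[i, i] == 0.0
        for j in range(i + 1, 50):
            d, sites = p_distance(rows[i], rows[j])
            assert dm.sites[i, j] == sites
            if sites == 0:
                assert np.isnan(dm.d[i, j])
            else:
                assert dm.d[i, j] == pytest.approx(d)
                assert dm.d[j, i] == dm.d[i, j]


# ---------------------------------------------------------------------------
# neighbour joining


def test_nj_two_taxa_splits_distance_evenly():
    tree = nj_tree(make_dm(["a", "b"], [[0, 0.4], [0.4, 0]]))
    assert tree.path_length("a", "b") == pytest.approx(0.4)
    lengths = sorted(w for _, _, w in tree.edges)
    assert lengths == pytest.approx([0.2, 0.2])


def test_nj_three_taxa_closed_form():
    d12, d13, d23 = 0.3, 0.5, 0.6
    tree = nj_tree(
        make_dm(["a", "b", "c"], [[0, d12, d13], [d12, 0, d23], [d13, d23, 0]])
    )
    by_leaf = {
        n: w for n, m, w in tree.edges if isinstance(n, str)
    }
    assert by_leaf["a"] == pytest.approx((d12 + d13 - d23) / 2)
    assert by_leaf["b"] == pytest.approx((d12 + d23 - d13) / 2)
    assert by_leaf["c"] == pytest.approx((d13 + d23 - d12) / 2)


def test_nj_recovers_random_additive_trees_exactly():
    rng = np.random.default_rng(77)
    for _ in range(30):
        n = int(rng.integers(5, 9))
        adj, leaves = nj_oracle.random_additive_tree(rng, n)
        D = nj_oracle.tree_distances(adj, leaves)
        tree = nj_tree(make_dm(leaves, D))
        assert tree.bipartitions() == nj_oracle.tree_bipartitions(adj, leaves)
        for i, a in enumerate(leaves):
            for j in range(i + 1, n):
                assert tree.path_length(a, leaves[j]) == pytest.approx(
                    D[i, j], abs=1e-9
                )


def test_nj_output_invariant_under_label_permutation(rng):
    adj, leaves = nj_oracle.random_additive_tree(rng, 8)
    D = nj_oracle.tree_distances(adj, leaves)
    t1 = nj_tree(make_dm(leaves, D))
    perm = rng.permutation(len(leaves))
    leaves_p = [leaves[i] for i in perm]
    D_p = D[np.ix_(perm, perm)]
    t2 = nj_tree(make_dm(leaves_p, D_p))
    assert t1.bipartitions() == t2.bipartitions()
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            assert t1.path_length(a, b) == pytest.approx(t2.path_length(a, b))


def test_nj_topology_matches_dendropy_on_random_matrix(rng):
    dendropy = pytest.importorskip("dendropy")
    labels = [f"t{i}" for i in range(8)]
    M = rng.uniform(0.1, 1.0, size=(8, 8))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0.0)
    ours = nj_tree(make_dm(labels, D)).bipartitions()

    import io

    csv = "," + ",".join(labels) + "\n"
    for i, lab in enumerate(labels):
        csv += lab + "," + ",".join(f"{D[i, j]:.10f}" for j in range(8)) + "\n"
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        io.StringIO(csv), delimiter=","
    )
    dtree = pdm.nj_tree()
    smallest = min(labels)
    theirs = set()
    total = set(labels)
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is None or edge.head_node.is_leaf():
            continue
        side = {
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        }
        if 1 < len(side) < len(labels) - 1:
            if smallest in side:
                side = total - side
            theirs.add(frozenset(side))
    assert ours == theirs


def test_nj_refuses_undefined_matrices():
    d = np.array([[0.0, np.nan], [np.nan, 0.0]])
    dm = DistanceMatrix(("a", "b"), d, np.zeros((2, 2), dtype=np.int64))
    with pytest.raises(ValueError):
        nj_tree(dm)


def test_n5_least_squares_oracle_agrees_with_nj():
    rng = np.random.default_rng(13)
    for _ in range(20):
        adj, leaves = nj_oracle.random_additive_tree(rng, 5)
        D = nj_oracle.tree_distances(adj, leaves)
        fits = [
            (nj_oracle.least_squares_fit(top, leaves, D)[0], top)
            for top in nj_oracle.five_leaf_topologies(leaves)
        ]
        best = min(fits, key=lambda t: t[0])
        assert best[0] < 1e-18
        nj_splits = nj_tree(make_dm(leaves, D)).bipartitions()
        assert nj_oracle.topology_bipartitions(best[1], leaves) == nj_splits


# ---------------------------------------------------------------------------
# bootstrap and consensus


def two_block_alignment(n_per_block=4, cols=40):
    rows = []
    labels = []
    for i in range(n_per_block):
        labels.append(f"a{i}")
        rows.append("A" * cols)
    for i in range(n_per_block):
        labels.append(f"b{i}")
        rows.append("C" * cols)
    return DomainAlignment(tuple(labels), tuple(rows))


def test_two_block_split_gets_full_support():
    aln = two_block_alignment()
    tree, redraws = bootstrap_supports(aln, 25, seed=3)
    split = frozenset({"b0", "b1", "b2", "b3"})
    assert tree.supports[split] == 100.0
    assert redraws == 0


def test_bootstrap_supports_bounded_and_deterministic(rng):
    rows = tuple(
        "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 50)) for _ in range(6)
    )
    aln = DomainAlignment(tuple(f"s{i}" for i in range(6)), rows)
    t1, _ = bootstrap_supports(aln, 40, seed=9)
    t2, _ = bootstrap_supports(aln, 40, seed=9)
    assert t1.supports == t2.supports
    assert all(0.0 <= v <= 100.0 for v in t1.supports.values())


def test_bootstrap_on_three_leaves_has_no_supports():
    aln = DomainAlignment(("a", "b", "c"), ("AA", "AC", "CC"))
    tree, _ = bootstrap_supports(aln, 10, seed=0)
    assert tree.supports == {}


def test_consensus_of_identical_trees_is_that_topology(rng):
    adj, leaves = nj_oracle.random_additive_tree(rng, 6)
    D = nj_oracle.tree_distances(adj, leaves)
    tree = nj_tree(make_dm(leaves, D))
    cons = majority_consensus([tree, tree, tree], threshold=50)
    assert cons.bipartitions() == tree.bipartitions()
    assert all(v == 100.0 for v in cons.supports.values())


def test_consensus_majority_split_retained_with_frequency():
    # three 4-leaf trees; split ab|cd occurs twice, ac|bd once
    def quartet(pair):
        a, b = pair
        c, d = [x for x in "abcd" if x not in pair]
        return nj_tree(
            make_dm(
                [a, b, c, d],
                np.array(
                    [
                        [0.0, 0.2, 1.0, 1.0],
                        [0.2, 0.0, 1.0, 1.0],
                        [1.0, 1.0, 0.0, 0.2],
                        [1.0, 1.0, 0.2, 0.0],
                    ]
                ),
            )
        )

    trees = [quartet("ab"), quartet("ab"), quartet("ac")]
    cons = majority_consensus(trees, threshold=50)
    assert len(cons.supports) == 1
    ((split, freq),) = cons.supports.items()
    assert freq == pytest.approx(200 / 3)
    assert split in (frozenset({"c", "d"}), frozenset({"b", "d"}))
    # full agreement demanded: disputed edges collapse to a star
    star = majority_consensus(trees, threshold=100)
    assert star.supports == {}
    with pytest.raises(ValueError):
        majority_consensus(trees, threshold=40)


# ---------------------------------------------------------------------------
# star alignment and family assignment


def anchor_profile(consensus):
    return build_pssm("anchor", [consensus], 1.0)


def test_star_alignment_identity_case(profiles3):
    anchor = profiles3.profiles()[0]
    cons = anchor.consensus
    aln, dropped = build_domain_alignment({"q1": cons, "q2": cons}, anchor)
    assert aln.column_count == len(cons)
    assert dropped == 0
    assert set(aln.rows) == {cons}


def test_star_alignment_marks_deletion_with_gaps(profiles3):
    anchor = profiles3.profiles()[0]
    cons = anchor.consensus
    deleted = cons[:30] + cons[33:]
    aln, _ = build_domain_alignment({"full": cons, "del": deleted}, anchor)
    row = aln.row("del")
    assert row.count("-") == 3
    with pytest.raises(ValueError):
        build_domain_alignment({"only": cons}, anchor)


def test_assign_family_self_match_and_equidistance():
    refs = {"ra": ("famA", "A" * 10), "rc": ("famC", "C" * 10)}
    res = assign_family(
        {"q": "A" * 10}, refs, {"q": "r1"}, ambiguity_margin=0.05
    )
    assert res.domains[0].best_family == "famA"
    assert res.domains[0].margin > 0
    res = assign_family(
        {"q": "AAAAACCCCC"}, refs, {"q": "r1"}, ambiguity_margin=0.05
    )
    assert res.domains[0].best_family == "unassigned"
    with pytest.raises(ValueError):
        assign_family({"q": "A" * 10}, {}, {"q": "r1"})


def test_chimeric_receptor_flagged():
    refs = {"ra": ("famA", "A" * 10), "rc": ("famC", "C" * 10)}
    res = assign_family(
        {"r|d1": "A" * 10, "r|d2": "C" * 10},
        refs,
        {"r|d1": "r", "r|d2": "r"},
    )
    (rc,) = res.receptors
    assert rc.chimeric
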
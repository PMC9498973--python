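import itertools
import math

import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix, pairwise_matrix
from barcodekit.phylo import (
    Node,
    Tree,
    bootstrap_support,
    k80_loglik,
    k80_transition_matrix,
    ml_search,
    monophyly,
    neighbor_joining,
    read_newick,
    root_and_monophyly,
    root_on_outgroup,
    write_newick,
)
from barcodekit.synth import SimulationConfig, evolve_k80, simulate_dataset
from conftest import make_alignment


def dm(labels, values):
    arr = np.array(values, dtype=float)
    return DistanceMatrix(list(labels), arr, np.ones(arr.shape, dtype=bool))


def tree_distances(tree: Tree) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths (independent check of NJ output)."""
    chains = {}

    def collect(node, chain):
        chain = chain + [node]
        if node.is_leaf:
            chains[node.name] = chain
        for c in node.children:
            collect(c, chain)

    collect(tree.root, [])
    out = {}
    for a, b in itertools.combinations(chains, 2):
        ca, cb = chains[a], chains[b]
        shared = 0
        for x, y in zip(ca, cb):
            if x is y:
                shared += 1
            else:
                break
        d = sum(n.length or 0.0 for n in ca[shared:]) + sum(
            n.length or 0.0 for n in cb[shared:]
        )
        out[frozenset((a, b))] = d
    return out


def random_additive_matrix(rng, n_taxa):
    """A random binary tree with positive branch lengths -> its path metric."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [Node(name=l) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = Node()
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        parent.add(a)
        parent.add(b)
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    root = Node()
    for node in nodes:
        node.length = float(rng.uniform(0.05, 1.0))
        root.add(node)
    tree = Tree(root)
    dists = tree_distances(tree)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dists[frozenset((labels[i], labels[j]))]
    return tree, dm(labels, values)


# ---------------------------------------------------------------------------
# Newick


def test_newick_round_trip_preserves_everything():
    text = "((A:0.1,B:0.2)95:0.05,(C:0.3,D:0.4)80:0.06,E:0.5);"
    tree = read_newick(text)
    again = read_newick(write_newick(tree))
    assert again.bipartitions() == tree.bipartitions()
    assert {n.name: n.length for n in again.root.leaves()} == pytest.approx(
        {"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.4, "E": 0.5}, abs=1e-9
    )
    supports = sorted(n.support for n in again.internal_edges())
    assert supports == [80.0, 95.0]


def test_newick_three_leaf_shape():
    root = Node()
    for name in "ABC":
        root.add(Node(name=name, length=0.1))
    assert write_newick(Tree(root)) == "(A:0.1,B:0.1,C:0.1);"


def test_newick_quotes_awkward_labels():
    root = Node()
    root.add(Node(name="Saurauia tristyla", length=0.1))
    root.add(Node(name="sp(2)", length=0.2))
    root.add(Node(name="plain", length=0.3))
    text = write_newick(Tree(root))
    assert "'Saurauia tristyla'" in text and "'sp(2)'" in text
    back = read_newick(text)
    assert back.leaf_names == {"Saurauia tristyla", "sp(2)", "plain"}


def test_newick_agrees_with_dendropy():
    dendropy = pytest.importorskip("dendropy")
    text = "((A:0.1,'two words':0.2)90:0.05,C:0.3,D:0.4);"
    ours = read_newick(text)
    theirs = dendropy.Tree.get(data=write_newick(ours), schema="newick")
    assert {l.taxon.label for l in theirs.leaf_node_iter()} == set(ours.leaf_names)
    their_len = {
        l.taxon.label: l.edge.length for l in theirs.leaf_node_iter()
    }
    our_len = {n.name: n.length for n in ours.root.leaves()}
    assert their_len == pytest.approx(our_len, abs=1e-9)


# ---------------------------------------------------------------------------
# Neighbor joining


def test_nj_recovers_four_taxon_tree_exactly():
    # tree ((A:1,B:2):3,C:4,D:5) as a path metric
    values = [
        [0, 3, 8, 9],
        [3, 0, 9, 10],
        [8, 9, 0, 9],
        [9, 10, 9, 0],
    ]
    tree = neighbor_joining(dm("ABCD", values))
    assert tree.bipartitions() == {frozenset({"A", "B"})} or tree.bipartitions() == {
        frozenset({"C", "D"})
    }
    recovered = tree_distances(tree)
    for (i, a), (j, b) in itertools.combinations(enumerate("ABCD"), 2):
        assert recovered[frozenset((a, b))] == pytest.approx(values[i][j])


def test_nj_three_taxa_three_point_formula():
    values = [[0, 5, 9], [5, 0, 10], [9, 10, 0]]
    tree = neighbor_joining(dm("ABC", values))
    lengths = {n.name: n.length for n in tree.root.children}
    assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
    assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
    assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)


def test_nj_deterministic_on_all_equal_distances():
    values = np.ones((5, 5)) - np.eye(5)
    t1 = write_newick(neighbor_joining(dm("ABCDE", values)))
    t2 = write_newick(neighbor_joining(dm("ABCDE", values)))
    assert t1 == t2


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
def test_nj_exact_on_random_additive_matrices(n_taxa, rng):
    for _ in range(10):
        true_tree, matrix = random_additive_matrix(rng, n_taxa)
        recovered = neighbor_joining(matrix)
        assert recovered.bipartitions() == true_tree.bipartitions()
        rd = tree_distances(recovered)
        td = tree_distances(true_tree)
        for pair in td:
            assert rd[pair] == pytest.approx(td[pair], abs=1e-9)


def test_nj_refuses_undefined_pairs():
    values = np.ones((4, 4)) - np.eye(4)
    defined = np.ones((4, 4), dtype=bool)
    defined[0, 1] = defined[1, 0] = False
    matrix = DistanceMatrix(list("ABCD"), values, defined)
    with pytest.raises(ValueError, match="undefined"):
        neighbor_joining(matrix)


# ---------------------------------------------------------------------------
# K80 likelihood


def test_transition_matrix_is_stochastic_and_nests_jc():
    for t in (0.01, 0.1, 1.0):
        for kappa in (0.5, 1.0, 4.0):
            P = k80_transition_matrix(t, kappa)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert np.allclose(P, P.T)
    # kappa = 1 reduces to Jukes-Cantor
    t = 0.3
    P = k80_transition_matrix(t, 1.0)
    jc_same = 0.25 + 0.75 * math.exp(-4 * t / 3)
    jc_diff = 0.25 - 0.25 * math.exp(-4 * t / 3)
    assert P[0, 0] == pytest.approx(jc_same)
    assert P[0, 1] == pytest.approx(jc_diff)
    assert P[0, 2] == pytest.approx(jc_diff)


def test_single_invariant_column_star_tree_loglik():
    aln = make_alignment({"A": "A", "B": "A", "C": "A"})
    root = Node()
    for name in "ABC":
        root.add(Node(name=name, length=0.0))
    ll = k80_loglik(Tree(root), aln, kappa=2.0)
    assert ll == pytest.approx(math.log(0.25))


def test_two_taxon_likelihood_matches_pair_formula():
    rng = np.random.default_rng(3)
    L = 200
    a = rng.integers(0, 4, size=L).astype(np.int8)
    b = evolve_k80(a, 0.15, 3.0, rng)
    seq_a = "".join("ACGT"[int(x)] for x in a)
    seq_b = "".join("ACGT"[int(x)] for x in b)
    aln = make_alignment({"A": seq_a, "B": seq_b})
    t, kappa = 0.21, 3.0
    root = Node()
    root.add(Node(name="A", length=t))
    root.add(Node(name="B", length=0.0))
    ll = k80_loglik(Tree(root), aln, kappa)
    P = k80_transition_matrix(t, kappa)
    expected = sum(math.log(0.25 * P[int(x), int(y)]) for x, y in zip(a, b))
    assert ll == pytest.approx(expected, abs=1e-8)


def test_loglik_invariant_under_rerooting():
    rng = np.random.default_rng(11)
    cfg = SimulationConfig(
        n_species=4, samples_per_species=(1, 1, 1, 1),
        haplotypes_per_species=(1, 1, 1, 1),
        n_diagnostic_per_species=(0, 0, 0, 0),
        indel_rate=0.0, ambiguity_rate=0.0, seed=2,
    )
    ds = simulate_dataset(cfg)
    ids = [r.id for r in ds.alignment.records]
    aln = ds.alignment.subset(ids[:4])
    t1 = read_newick(f"(({ids[0]}:0.1,{ids[1]}:0.2):0.05,{ids[2]}:0.3,{ids[3]}:0.15);")
    # same unrooted tree, written rooted at a different place
    t2 = read_newick(f"({ids[2]}:0.3,({ids[0]}:0.1,{ids[1]}:0.2):0.05,{ids[3]}:0.15);")
    assert k80_loglik(t1, aln, 2.5) == pytest.approx(k80_loglik(t2, aln, 2.5))


def test_gaps_are_missing_data():
    aln = make_alignment({"A": "A-", "B": "AN"})
    root = Node()
    root.add(Node(name="A", length=0.0))
    root.add(Node(name="B", length=0.0))
    ll = k80_loglik(Tree(root), aln, 2.0)
    # column 1: identical A (lik 1/4); column 2: fully missing (lik 1)
    assert ll == pytest.approx(math.log(0.25))


def test_ml_search_keeps_optimal_tree_and_improves_loglik():
    cfg = SimulationConfig(
        n_species=4, samples_per_species=(1, 1, 1, 1),
        haplotypes_per_species=(1, 1, 1, 1),
        n_diagnostic_per_species=(0, 0, 0, 0),
        indel_rate=0.0, ambiguity_rate=0.0,
        between_divergence=(0.05, 0.2), seed=6,
    )
    ds = simulate_dataset(cfg)
    ids = [r.id for r in ds.alignment.records][:4]
    aln = ds.alignment.subset(ids)
    result = ml_search(aln)
    # running again from the found tree changes nothing (NNI fixed point)
    again = ml_search(aln, start=result.tree, kappa=result.kappa)
    assert again.tree.bipartitions() == result.tree.bipartitions()
    assert again.loglik == pytest.approx(result.loglik, abs=1e-3)
    # the search never ends below its NJ starting point
    start = neighbor_joining(pairwise_matrix(aln))
    start_ll = ml_search(aln, start=start, max_rounds=0).loglik
    assert result.loglik >= start_ll - 1e-6


# ---------------------------------------------------------------------------
# Bootstrap


def test_bootstrap_same_seed_reproduces_supports():
    cfg = SimulationConfig(
        n_species=3, samples_per_species=(2, 2, 2),
        haplotypes_per_species=(2, 2, 2),
        n_diagnostic_per_species=(0, 0, 0),
        ambiguity_rate=0.0, seed=8,
    )
    ds = simulate_dataset(cfg)
    r1 = bootstrap_support(ds.alignment, reps=50, seed=123)
    r2 = bootstrap_support(ds.alignment, reps=50, seed=123)
    assert write_newick(r1.tree) == write_newick(r2.tree)
    supports = [n.support for n in r1.tree.internal_edges() if n.support is not None]
    assert supports and all(0.0 <= s <= 100.0 for s in supports)


def test_bootstrap_strong_structure_gets_full_support():
    cfg = SimulationConfig(
        n_species=3, samples_per_species=(3, 3, 3),
        haplotypes_per_species=(3, 3, 3),
        n_diagnostic_per_species=(0, 0, 0),
        between_divergence=(0.15, 0.3),
        within_divergence=(0.001, 0.003),
        indel_rate=0.0, ambiguity_rate=0.0, seed=12,
    )
    ds = simulate_dataset(cfg)
    result = bootstrap_support(ds.alignment, reps=100, seed=5)
    species_of = ds.truth.sample_species
    rooted, mono = root_and_monophyly(result.tree, species_of, "outgroup")
    assert all(mono.values())
    # the species-defining splits should be (near-)unanimous
    by_species = {}
    for leaf, sp in species_of.items():
        by_species.setdefault(sp, set()).add(leaf)
    for node in result.tree.internal_edges():
        if node.leaf_names() in (frozenset(v) for v in by_species.values()):
            assert node.support >= 99.0


def test_bootstrap_identical_sequences_degenerate_but_defined():
    aln = make_alignment({f"r{i}": "ACGTACGTAC" for i in range(4)})
    result = bootstrap_support(aln, reps=20, seed=1)
    assert result.n_replicates == 20
    for node in result.tree.internal_edges():
        if node.support is not None:
            assert 0.0 <= node.support <= 100.0


# ---------------------------------------------------------------------------
# Rooting and monophyly


def test_rooting_and_planted_paraphyly_detection():
    text = "((a1:0.1,(b1:0.1,a2:0.1):0.05):0.1,(b2:0.1,c1:0.1):0.08,og:0.5);"
    tree = read_newick(text)
    species_of = {
        "a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "og": "OG"
    }
    rooted, mono = root_and_monophyly(tree, species_of, "OG")
    assert rooted.is_rooted
    assert mono == {"A": False, "B": False, "C": True}  # singleton C counts


def test_rooting_errors():
    tree = read_newick("(a:0.1,b:0.1,c:0.1);")
    with pytest.raises(ValueError, match="not in tree"):
        root_and_monophyly(tree, {"a": "A", "b": "B", "c": "C"}, "OG")
    with pytest.raises(ValueError, match="no outgroup"):
        root_on_outgroup(tree, [])


def test_root_bisects_outgroup_edge():
    tree = read_newick("((a:0.1,b:0.2):0.05,c:0.3,og:0.4);")
    rooted = root_on_outgroup(tree, ["og"])
    children = {c.name: c.length for c in rooted.root.children}
    assert children.get("og") == pytest.approx(0.2)
    total_before = sum(n.length or 0 for n in tree.edges())
    total_after = sum(n.length or 0 for n in rooted.edges())
    assert total_after == pytest.approx(total_before)
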
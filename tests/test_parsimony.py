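import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import barcomm as bc
from barcomm.parsimony_engine import (SearchConfig, TreeSet,
                                      exhaustive_constrained_search,
                                      majority_consensus, parsimony_length,
                                      random_addition_tree, ratchet_search)
from barcomm.trees import enumerate_binary_refinements

# ---------------------------------------------------------------- oracle

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "?": 15, "-": 15, "N": 15,
         "R": 5, "Y": 10, "M": 3, "K": 12}


class _Matrix:
    """Plain taxa/rows holder usable inside hypothesis-driven tests."""

    def __init__(self, taxa, rows):
        self.taxa = list(taxa)
        self.rows = list(rows)


def brute_force_length(tree, taxa, rows):
    """Independent oracle: minimize changes over all internal state
    assignments, leaves free to pick any state in their ambiguity set."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    k = len(internals)
    pos = {id(n): i for i, n in enumerate(internals)}
    lookup = dict(zip(taxa, rows))
    grid = np.array(list(itertools.product(range(4), repeat=k)))  # (4^k, k)
    total = 0
    for col in range(len(rows[0])):
        cost = np.zeros(len(grid), dtype=int)
        for n in nodes:
            if n.parent is None:
                continue
            ps = grid[:, pos[id(n.parent)]]
            if n.is_leaf:
                mask = _BITS[lookup[n.label][col]]
                cost += ((mask >> ps) & 1) == 0
            else:
                cost += grid[:, pos[id(n)]] != ps
        total += int(cost.min())
    return total


# ------------------------------------------------------------ unit scoring


class TestParsimonyLength:
    def test_constant_columns_cost_zero(self, fake_matrix_cls):
        m = fake_matrix_cls(list("abcd"), ["AAAA"] * 4)
        t = bc.Tree.from_newick("((a,b),(c,d));")
        assert parsimony_length(t, m) == 0

    def test_single_forced_change(self, fake_matrix_cls):
        m = fake_matrix_cls(["a1", "a2", "t1", "t2"], ["A", "A", "T", "T"])
        t = bc.Tree.from_newick("((a1,a2),(t1,t2));")
        assert parsimony_length(t, m) == 1

    def test_missing_and_ambiguity_are_free_when_consistent(self, fake_matrix_cls):
        m = fake_matrix_cls(list("abcd"), ["A?", "AR", "A-", "AN"])
        t = bc.Tree.from_newick("((a,b),(c,d));")
        assert parsimony_length(t, m) == 0

    def test_column_weights_multiply(self, fake_matrix_cls):
        m = fake_matrix_cls(["a1", "a2", "t1", "t2"], ["AC", "AC", "TC", "TA"])
        t = bc.Tree.from_newick("((a1,a2),(t1,t2));")
        assert parsimony_length(t, m) == 2
        assert parsimony_length(t, m, weights=[3, 5]) == 3 + 5

    def test_unknown_tip_rejected(self, fake_matrix_cls):
        m = fake_matrix_cls(["a", "b", "c"], ["A", "C", "G"])
        with pytest.raises(ValueError, match="absent"):
            parsimony_length(bc.Tree.from_newick("(a,b,zz);"), m)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_including_polytomies(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(5)]
        rows = ["".join(rng.choice(list("ACGT?RY"), size=6)) for _ in taxa]
        m = _Matrix(taxa, rows)
        shapes = ["((t0,t1),(t2,(t3,t4)));", "(t0,t1,(t2,t3,t4));",
                  "(t0,(t1,t2,t3,t4));", "((((t0,t1),t2),t3),t4);"]
        for nwk in shapes:
            t = bc.Tree.from_newick(nwk)
            assert parsimony_length(t, m) == brute_force_length(t, taxa, rows)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_under_rerooting(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(6)]
        rows = ["".join(rng.choice(list("ACGT"), size=10)) for _ in taxa]
        m = _Matrix(taxa, rows)
        t1 = bc.Tree.from_newick("((t0,t1),((t2,t3),(t4,t5)));")
        t2 = bc.Tree.from_newick("(t2,(t3,((t4,t5),(t0,t1))));")  # same unrooted tree
        assert parsimony_length(t1, m) == parsimony_length(t2, m)

    def test_all_missing_taxon_adds_nothing(self, fake_matrix_cls):
        taxa = ["a", "b", "c", "d"]
        rows = ["ACGT", "ACGA", "TCGT", "TCGA"]
        m1 = fake_matrix_cls(taxa, rows)
        m2 = fake_matrix_cls(taxa + ["ghost"], rows + ["????"])
        t1 = bc.Tree.from_newick("((a,b),(c,d));")
        t2 = bc.Tree.from_newick("((a,b),((c,d),ghost));")
        assert parsimony_length(t1, m1) == parsimony_length(t2, m2)


# ---------------------------------------------------------------- addition


class TestRandomAddition:
    @pytest.fixture
    def setup(self, fake_matrix_cls):
        rng = np.random.default_rng(42)
        taxa = [f"t{i}" for i in range(8)]
        rows = ["".join(rng.choice(list("ACGT"), size=24)) for _ in taxa]
        cons = bc.Tree.from_newick("((t0,t1,t2,t3),(t4,t5,t6,t7));")
        return fake_matrix_cls(taxa, rows), cons

    def test_deterministic_given_seed(self, setup):
        m, cons = setup
        t1 = random_addition_tree(m, cons, seed=3)
        t2 = random_addition_tree(m, cons, seed=3)
        assert t1.canonical_form() == t2.canonical_form()

    def test_output_binary_and_compatible(self, setup):
        m, cons = setup
        for seed in range(5):
            t = random_addition_tree(m, cons, seed=seed)
            assert t.is_binary()
            assert bc.is_compatible(t, cons)

    def test_star_constraint_four_taxa_locally_optimal_score(self, fake_matrix_cls):
        rng = np.random.default_rng(0)
        taxa = list("abcd")
        rows = ["".join(rng.choice(list("ACGT"), size=12)) for _ in taxa]
        m = fake_matrix_cls(taxa, rows)
        star = bc.Tree.from_newick("(a,b,c,d);")
        scores = {parsimony_length(t, m) for t in enumerate_binary_refinements(star)}
        t = random_addition_tree(m, star, seed=1)
        assert parsimony_length(t, m) in scores


# ------------------------------------------------------------------ search


class TestRatchetSearch:
    def test_matches_exhaustive_on_six_taxa_star(self, fake_matrix_cls):
        rng = np.random.default_rng(11)
        taxa = [f"t{i}" for i in range(6)]
        rows = ["".join(rng.choice(list("ACGT"), size=20)) for _ in taxa]
        m = fake_matrix_cls(taxa, rows)
        star = bc.Tree.from_newick("(" + ",".join(taxa) + ");")
        ex = exhaustive_constrained_search(m, star)
        ts = ratchet_search(m, star, SearchConfig(
            n_addition_replicates=3, ratchet_iterations=4, seed=2))
        assert ts.score == ex.score

    def test_matches_constrained_exhaustive_with_clade(self, fake_matrix_cls):
        rng = np.random.default_rng(13)
        taxa = [f"t{i}" for i in range(8)]
        rows = ["".join(rng.choice(list("ACGT"), size=20)) for _ in taxa]
        m = fake_matrix_cls(taxa, rows)
        cons = bc.Tree.from_newick("((t0,t1,t2,t3),(t4,t5,t6,t7));")
        ex = exhaustive_constrained_search(m, cons)
        ts = ratchet_search(m, cons, SearchConfig(
            n_addition_replicates=3, ratchet_iterations=4, seed=2))
        assert ts.score == ex.score
        for t in ts.trees:
            assert bc.is_compatible(t, cons)

    def test_never_worse_than_its_starting_tree(self, fake_matrix_cls):
        rng = np.random.default_rng(5)
        taxa = [f"t{i}" for i in range(7)]
        rows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in taxa]
        m = fake_matrix_cls(taxa, rows)
        star = bc.Tree.from_newick("(" + ",".join(taxa) + ");")
        cfg = SearchConfig(n_addition_replicates=1, ratchet_iterations=2, seed=9)
        start = random_addition_tree(m, star, seed=cfg.seed)
        ts = ratchet_search(m, star, cfg)
        assert ts.score <= parsimony_length(start, m)


# --------------------------------------------------------------- consensus


class TestMajorityConsensus:
    def test_identical_trees_full_support(self):
        t = bc.Tree.from_newick("((a,b),(c,d));")
        ts = TreeSet(trees=[t.copy() for _ in range(10)], score=0)
        cons = majority_consensus(ts)
        assert cons.canonical_form() == t.canonical_form()
        assert all(n.support == 100 for n in cons.internal_nodes())

    def test_two_thirds_clade(self):
        trees = [bc.Tree.from_newick("((A,B),(C,D));"),
                 bc.Tree.from_newick("((A,B),(C,D));"),
                 bc.Tree.from_newick("((A,C),(B,D));")]
        cons = majority_consensus(TreeSet(trees=trees, score=0))
        ab = [n for n in cons.internal_nodes()
              if {l.label for l in bc.Tree(n).leaves()} == {"A", "B"}]
        assert len(ab) == 1 and ab[0].support == 67

    def test_conflicting_pair_gives_star(self):
        trees = [bc.Tree.from_newick("((a,b),(c,d));"),
                 bc.Tree.from_newick("((a,c),(b,d));")]
        cons = majority_consensus(TreeSet(trees=trees, score=0))
        assert cons.canonical_form() == "(a,b,c,d)"

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            TreeSet(trees=[], score=0)

    def test_supports_are_achievable_frequencies(self):
        trees = [bc.Tree.from_newick("(((a,b),c),(d,e));")] * 4 + \
                [bc.Tree.from_newick("((a,b),(c,(d,e)));")] * 3
        cons = majority_consensus(TreeSet(trees=[t.copy() for t in trees], score=0))
        n = 7
        achievable = {round(100 * k / n) for k in range(1, n + 1)}
        for node in cons.internal_nodes(include_root=False):
            assert node.support in achievable
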
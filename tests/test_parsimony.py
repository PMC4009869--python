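import numpy as np
import pytest

from conftest import binary_matrix, brute_force_fitch, min_max_steps_over_trees
from gaptree import parsimony as mp
from gaptree import trees


class TestFitchLength:
    def test_invariant_character_is_zero(self):
        t = trees.parse_newick("((A,B),(C,D));")
        m = binary_matrix("ABCD", [[1], [1], [1], [1]])
        assert mp.fitch_length(t, m, 0) == 0

    def test_incongruent_and_congruent_patterns(self):
        t = trees.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        m = binary_matrix("ABCD", [[1, 1], [0, 1], [1, 0], [0, 0]])
        assert mp.fitch_length(t, m, 0) == 2  # A,C vs B,D crosses the split
        assert mp.fitch_length(t, m, 1) == 1  # A,B synapomorphy

    def test_all_missing_warns_and_is_zero(self):
        t = trees.parse_newick("((A,B),(C,D));")
        m = binary_matrix("ABCD", [[-1], [-1], [-1], [-1]])
        with pytest.warns(UserWarning):
            assert mp.fitch_length(t, m, 0) == 0

    def test_matches_brute_force_on_random_characters(self, rng):
        for _ in range(150):
            n = int(rng.integers(4, 9))
            taxa = [f"t{i}" for i in range(n)]
            tree = trees.random_topology(taxa, rng)
            col = rng.choice([0, 1, -1], size=n, p=[0.4, 0.4, 0.2])
            m = binary_matrix(taxa, [[c] for c in col])
            oracle = brute_force_fitch(
                tree, {t: (None if s == -1 else int(s)) for t, s in zip(taxa, col)}
            )
            assert mp.fitch_length(tree, m, 0) == oracle

    def test_nucleotide_characters_with_ambiguity(self, rng):
        from gaptree.io_formats import Alignment

        t = trees.parse_newick("((A,B),(C,D));")
        aln = Alignment("ABCD", ["A", "G", "R", "T"])
        # R = {A,G} can satisfy either side: one change A<->G plus T
        assert mp.fitch_length(t, aln, 0) == 2


class TestTreelength:
    def test_sums_per_character_steps(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        tree = trees.random_topology(taxa, rng)
        states = rng.choice([0, 1], size=(6, 15))
        m = binary_matrix(taxa, states.tolist())
        assert mp.treelength(tree, m) == sum(
            mp.fitch_length(tree, m, j) for j in range(15)
        )

    def test_equals_brute_force_sum(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        tree = trees.random_topology(taxa, rng)
        states = rng.choice([0, 1, -1], size=(6, 10))
        m = binary_matrix(taxa, states.tolist())
        oracle = sum(
            brute_force_fitch(
                tree,
                {t: (None if s == -1 else int(s)) for t, s in zip(taxa, states[:, j])},
            )
            for j in range(10)
        )
        assert mp.treelength(tree, m) == oracle


class TestRatchetSearch:
    def test_recovers_tree_from_clean_matrix(self):
        taxa = [f"t{i}" for i in range(6)]
        true = trees.random_topology(taxa, np.random.default_rng(7))
        cols = [
            [1 if t in b else 0 for t in taxa] for b in true.bipartitions()
        ] * 4
        m = binary_matrix(taxa, np.array(cols).T.tolist())
        res = mp.ratchet_search(m, mp.RatchetConfig(iterations=8, seed=1, swap="spr"))
        assert res.tree.is_same_topology(true)
        assert res.length == len(cols)  # one step per clean character

    def test_attains_exhaustive_optimum(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        for trial in range(5):
            states = np.random.default_rng(trial).choice([0, 1], size=(7, 25))
            m = binary_matrix(taxa, states.tolist())
            res = mp.ratchet_search(
                m, mp.RatchetConfig(iterations=10, seed=trial, swap="spr")
            )
            best = min(
                mp.treelength(t, m) for t in trees.enumerate_topologies(taxa)
            )
            assert res.length == best

    def test_deterministic_under_seed(self):
        taxa = [f"t{i}" for i in range(6)]
        states = np.random.default_rng(3).choice([0, 1], size=(6, 20))
        m = binary_matrix(taxa, states.tolist())
        cfg = mp.RatchetConfig(iterations=6, seed=42)
        r1, r2 = mp.ratchet_search(m, cfg), mp.ratchet_search(m, cfg)
        assert r1.length == r2.length
        assert r1.tree.is_same_topology(r2.tree)

    def test_degenerate_three_taxa(self):
        m = binary_matrix("ABC", [[1], [0], [0]])
        res = mp.ratchet_search(m, mp.RatchetConfig(iterations=2, seed=0))
        assert res.tree.n_tips() == 3

    def test_never_worse_than_plain_hill_climb(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        states = rng.choice([0, 1], size=(7, 30))
        m = binary_matrix(taxa, states.tolist())
        start = trees.random_topology(taxa, np.random.default_rng(0))
        taxa_l, sets = mp.state_sets(m)
        plain, plain_len = mp._hill_climb(
            start, taxa_l, sets, np.ones(30, dtype=np.int64), "nni"
        )
        res = mp.ratchet_search(
            m, mp.RatchetConfig(iterations=5, seed=0), start_tree=start
        )
        assert res.length <= plain_len


class TestBootstrap:
    def test_clean_matrix_gives_unanimous_support(self):
        taxa = [f"t{i}" for i in range(6)]
        true = trees.random_topology(taxa, np.random.default_rng(5))
        cols = [
            [1 if t in b else 0 for t in taxa] for b in true.bipartitions()
        ] * 5
        m = binary_matrix(taxa, np.array(cols).T.tolist())
        table = mp.mp_bootstrap(
            m, 12, mp.RatchetConfig(iterations=3, seed=2, swap="spr")
        )
        for b in true.bipartitions():
            assert table.get(b) == pytest.approx(1.0)

    def test_supports_in_unit_interval_and_reproducible(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        states = rng.choice([0, 1], size=(6, 12))
        m = binary_matrix(taxa, states.tolist())
        cfg = mp.RatchetConfig(iterations=2, seed=9)
        t1 = mp.mp_bootstrap(m, 8, cfg)
        t2 = mp.mp_bootstrap(m, 8, cfg)
        assert t1.support == t2.support
        assert all(0 <= v <= 1 for v in t1.support.values())


class TestHomoplasyIndices:
    def test_perfect_fit_has_ri_one(self):
        t = trees.parse_newick("((A,B),(C,D),(E,F));")
        m = binary_matrix("ABCDEF", [[1], [1], [0], [0], [0], [0]])
        h = mp.homoplasy_indices(t, m)
        assert h.per_character.ri.iloc[0] == 1.0

    def test_half_retained_character(self):
        # a=3, b=3 alternating on a tree forcing s=2: ri = (3-2)/(3-1)
        t = trees.parse_newick("(((A,B),C),((D,E),F));")
        m = binary_matrix("ABCDEF", [[1], [0], [1], [0], [1], [0]])
        h = mp.homoplasy_indices(t, m)
        row = h.per_character.iloc[0]
        assert (row.s, row.s_min, row.g) == (3, 1, 3)
        m2 = binary_matrix("ABCDEF", [[1], [1], [0], [1], [0], [0]])
        row2 = mp.homoplasy_indices(t, m2).per_character.iloc[0]
        assert row2.ri == pytest.approx((row2.g - row2.s) / (row2.g - row2.s_min))

    def test_max_homoplasy_has_ri_zero(self):
        t = trees.parse_newick("((A,C),(B,D),(E,F));")
        m = binary_matrix("ABCDEF", [[1], [1], [0], [0], [0], [0]])
        h = mp.homoplasy_indices(t, m)
        row = h.per_character.iloc[0]
        if row.s == row.g:
            assert row.ri == 0.0

    def test_bounds_match_brute_force_over_all_trees(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        for _ in range(5):
            col = rng.choice([0, 1, -1], size=6, p=[0.4, 0.4, 0.2])
            if min((col == 0).sum(), (col == 1).sum()) == 0:
                continue
            m = binary_matrix(taxa, [[c] for c in col])
            lo, hi = min_max_steps_over_trees(taxa, col)
            tree = trees.random_topology(taxa, rng)
            row = mp.homoplasy_indices(tree, m).per_character.iloc[0]
            assert row.s_min == lo
            assert row.g == hi

    def test_ensemble_ri_invariant_to_duplication(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        tree = trees.random_topology(taxa, rng)
        states = rng.choice([0, 1], size=(6, 10))
        m = binary_matrix(taxa, states.tolist())
        doubled = binary_matrix(taxa, np.hstack([states, states]).tolist())
        h1, h2 = mp.homoplasy_indices(tree, m), mp.homoplasy_indices(tree, doubled)
        assert h1.ensemble_ri == pytest.approx(h2.ensemble_ri)

    def test_no_variable_characters_flagged(self):
        t = trees.parse_newick("((A,B),(C,D));")
        m = binary_matrix("ABCD", [[1], [1], [1], [1]])
        with pytest.warns(UserWarning):
            h = mp.homoplasy_indices(t, m)
        assert h.ensemble_ri is None
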
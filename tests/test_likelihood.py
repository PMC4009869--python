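import numpy as np
import pytest

from conftest import binary_matrix, brute_force_cfn_likelihood
from gaptree import likelihood as lk
from gaptree import trees
from gaptree.io_formats import Alignment
from gaptree.synthetic_data import simulate_binary_characters


class TestClosedForms:
    def test_cfn_transition_probabilities(self):
        P = lk.cfn_prob(0.1)
        assert P[0, 1] == pytest.approx(0.0906346, abs=5e-8)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_cfn_limits(self):
        assert np.allclose(lk.cfn_prob(0.0), np.eye(2))
        assert np.allclose(lk.cfn_prob(400.0), np.full((2, 2), 0.5))

    def test_negative_length_rejected(self):
        with pytest.raises(lk.ModelError):
            lk.cfn_prob(-0.1)

    def test_gamma_category_rates_average_to_one(self):
        for alpha in (0.2, 1.0, 5.0):
            rates = lk.discrete_gamma_rates(alpha, 4)
            assert rates.mean() == pytest.approx(1.0, abs=1e-10)
            assert (np.diff(rates) > 0).all()

    def test_two_taxon_variable_pattern(self):
        tree = trees.parse_newick("(a:0.1,b:0.1);")
        m = binary_matrix(["a", "b"], [[0], [1]])
        L = np.exp(lk.log_likelihood(tree, m, lk.ModelSpec("cfn")))
        assert L == pytest.approx(0.0824200, abs=5e-8)

    @pytest.mark.parametrize("total", [0.01, 0.2, 1.0, 5.0])
    def test_two_taxon_conditional_likelihood_is_half(self, total):
        tree = trees.parse_newick(f"(a:{total / 2},b:{total / 2});")
        for pattern in ([0], [1]), ([1], [0]):
            m = binary_matrix(["a", "b"], pattern)
            L = np.exp(
                lk.log_likelihood(tree, m, lk.ModelSpec("cfn", correction="conditional"))
            )
            assert L == pytest.approx(0.5, abs=1e-12)

    def test_gtr_transition_matrix_matches_expm(self):
        # unequal frequencies and exchangeabilities: eigendecomposition
        # route must equal the matrix exponential of the normalised Q
        from scipy.linalg import expm
        from gaptree.likelihood import _transition_matrices

        fr = np.array([0.1, 0.2, 0.3, 0.4])
        ex = np.array([1.5, 3.0, 0.5, 0.7, 4.0, 1.0])
        model = lk.ModelSpec("gtr", base_frequencies=fr, gtr_exchangeabilities=ex)
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        Q = np.zeros((4, 4))
        for (i, j), s in zip(pairs, ex):
            Q[i, j] = s * fr[j]
            Q[j, i] = s * fr[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        Q /= -(fr * np.diag(Q)).sum()
        for t in (0.01, 0.3, 2.0):
            P = _transition_matrices(model, np.array([t]))[0, 0]
            assert np.abs(P - expm(Q * t)).max() < 1e-12

    def test_gtr_reduces_to_jukes_cantor(self):
        t = 0.37
        tree = trees.parse_newick(f"(a:{t / 2},b:{t / 2});")
        jc = lk.ModelSpec(
            "gtr", base_frequencies=np.full(4, 0.25), gtr_exchangeabilities=np.ones(6)
        )
        p_diff_total = 0.0
        for x, y in (("A", "C"), ("A", "G"), ("A", "T")):
            aln = Alignment(["a", "b"], [x, y])
            p_diff_total += np.exp(lk.log_likelihood(tree, aln, jc)) / 0.25
        assert p_diff_total == pytest.approx(
            (3 / 4) * (1 - np.exp(-4 * t / 3)), abs=1e-12
        )


class TestPruning:
    def test_matches_enumeration_on_random_instances(self, rng):
        for trial in range(60):
            n = int(rng.integers(4, 7))
            taxa = [f"t{i}" for i in range(n)]
            tree = trees.yule_tree(taxa, rng, 0.3)
            shape = 0.6 if trial % 2 else None
            model = lk.ModelSpec("cfn", gamma_shape=shape)
            col = rng.choice([0, 1, -1], size=n, p=[0.4, 0.4, 0.2])
            m = binary_matrix(taxa, [[c] for c in col])
            got = lk.log_likelihood(tree, m, model)
            want = np.log(
                brute_force_cfn_likelihood(
                    trees.unroot(tree), dict(zip(taxa, (int(c) for c in col))), shape
                )
            )
            assert got == pytest.approx(want, abs=1e-10)

    def test_invariant_to_taxon_and_character_order(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        tree = trees.yule_tree(taxa, rng, 0.2)
        states = rng.choice([0, 1, -1], size=(6, 8), p=[0.4, 0.4, 0.2])
        m = binary_matrix(taxa, states.tolist())
        model = lk.ModelSpec("cfn", gamma_shape=1.0)
        base = lk.log_likelihood(tree, m, model)
        perm = rng.permutation(6)
        m_rows = binary_matrix([taxa[i] for i in perm], states[perm].tolist())
        assert lk.log_likelihood(tree, m_rows, model) == pytest.approx(base, abs=1e-9)
        cperm = rng.permutation(8)
        m_cols = binary_matrix(taxa, states[:, cperm].tolist())
        assert lk.log_likelihood(tree, m_cols, model) == pytest.approx(base, abs=1e-9)

    def test_rooting_invariance(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        tree = trees.yule_tree(taxa, rng, 0.25)
        states = rng.choice([0, 1], size=(6, 5))
        m = binary_matrix(taxa, states.tolist())
        model = lk.ModelSpec("cfn")
        base = lk.log_likelihood(tree, m, model)
        rerooted = trees.unroot(tree)
        internal = [
            n for n in rerooted.postorder() if not n.is_leaf and n.parent is not None
        ]
        rerooted.reroot_at(internal[0])
        assert lk.log_likelihood(rerooted, m, model) == pytest.approx(base, abs=1e-9)


class TestCorrections:
    def test_conditional_normalises_over_variable_patterns(self, rng):
        # summed over every variable pattern, conditional likelihoods = 1
        taxa = ["a", "b", "c", "d"]
        tree = trees.yule_tree(taxa, rng, 0.3)
        model = lk.ModelSpec("cfn", correction="conditional")
        total = 0.0
        for bits in range(1, 15):  # exclude 0000 and 1111
            col = [(bits >> i) & 1 for i in range(4)]
            m = binary_matrix(taxa, [[c] for c in col])
            total += np.exp(lk.log_likelihood(tree, m, model))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_augmentation_m0_equals_uncorrected(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        tree = trees.yule_tree(taxa, rng, 0.2)
        states = rng.choice([0, 1], size=(5, 10))
        m = binary_matrix(taxa, states.tolist())
        plain = lk.log_likelihood(tree, m, lk.ModelSpec("cfn"))
        aug = lk.log_likelihood(
            tree, m, lk.ModelSpec("cfn", correction="augmentation", m_added=0)
        )
        assert aug == pytest.approx(plain, abs=1e-12)

    def test_augmentation_appends_constant_columns(self, rng):
        taxa = [f"t{i}" for i in range(4)]
        tree = trees.yule_tree(taxa, rng, 0.2)
        m = binary_matrix(taxa, [[1], [0], [0], [1]])
        aug = lk.log_likelihood(
            tree, m, lk.ModelSpec("cfn", correction="augmentation", m_added=4)
        )
        const0 = binary_matrix(taxa, [[0], [0], [0], [0]])
        const1 = binary_matrix(taxa, [[1], [1], [1], [1]])
        expected = (
            lk.log_likelihood(tree, m, lk.ModelSpec("cfn"))
            + 2 * lk.log_likelihood(tree, const0, lk.ModelSpec("cfn"))
            + 2 * lk.log_likelihood(tree, const1, lk.ModelSpec("cfn"))
        )
        assert aug == pytest.approx(expected, abs=1e-10)

    def test_pinv_with_correction_rejected(self):
        with pytest.raises(lk.ModelError):
            lk.ModelSpec("cfn", p_invariant=0.2, correction="conditional")

    def test_odd_m_added_rejected(self):
        with pytest.raises(lk.ModelError):
            lk.ModelSpec("cfn", correction="augmentation", m_added=3)


class TestOptimisation:
    def test_branch_length_recovery_from_long_characters(self):
        taxa = [f"t{i}" for i in range(8)]
        true = trees.unroot(trees.yule_tree(taxa, np.random.default_rng(5), 0.2))
        m = simulate_binary_characters(true, 4000, seed=6, variable_only=False)
        fit = lk.optimize_branch_lengths_and_params(
            true.copy(), m, lk.ModelSpec("cfn"), optimize_model=False
        )
        true_lengths = {e: n for e, n in _edge_map(true).items()}
        fit_lengths = _edge_map(fit.tree)
        rel_errors = [
            abs(fit_lengths[k] - v) / v for k, v in true_lengths.items() if v > 0.02
        ]
        assert np.median(rel_errors) < 0.15

    def test_invariant_matrix_drives_lengths_to_zero(self):
        taxa = ["a", "b", "c", "d"]
        tree = trees.parse_newick("((a:0.2,b:0.2):0.2,(c:0.2,d:0.2):0.2);")
        m = binary_matrix(taxa, [[0, 1]] * 4)
        fit = lk.optimize_branch_lengths_and_params(
            tree, m, lk.ModelSpec("cfn"), optimize_model=False
        )
        assert fit.tree.total_length() < 1e-5

    def test_restart_stability(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        true = trees.unroot(trees.yule_tree(taxa, np.random.default_rng(2), 0.25))
        m = simulate_binary_characters(true, 500, seed=3, variable_only=True)
        model = lk.ModelSpec("cfn", correction="conditional")
        fits = []
        for scale in (0.5, 2.0):
            start = true.scale_lengths(scale)
            fits.append(
                lk.optimize_branch_lengths_and_params(
                    start, m, model, optimize_model=False, tol=1e-9
                ).lnl
            )
        assert fits[0] == pytest.approx(fits[1], abs=1e-4)


class TestAugmentationEstimator:
    def test_m0_entry_matches_uncorrected_fit(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        true = trees.unroot(trees.yule_tree(taxa, np.random.default_rng(4), 0.3))
        m = simulate_binary_characters(true, 150, seed=5)
        model = lk.ModelSpec("cfn")
        _, table, _ = lk.estimate_invariant_augmentation(
            m, true, grid=[0, 20], model=model, refine=False, optimize_model=False
        )
        fit = lk.optimize_branch_lengths_and_params(
            true.copy(), m, model, optimize_model=False
        )
        cond = lk.log_likelihood(
            fit.tree, m, lk.ModelSpec("cfn", correction="conditional")
        )
        row0 = table[table.m == 0].iloc[0]
        assert row0.conditional_lnl == pytest.approx(cond, abs=1e-3)

    def test_conditional_lnl_unimodal_on_fixture(self):
        taxa = [f"t{i}" for i in range(6)]
        true = trees.unroot(trees.yule_tree(taxa, np.random.default_rng(8), 0.15))
        m = simulate_binary_characters(true, 300, seed=9, variable_only=True)
        _, table, _ = lk.estimate_invariant_augmentation(
            m, true, grid=[0, 50, 150, 400, 1000, 3000], model=lk.ModelSpec("cfn"),
            refine=False, optimize_model=False,
        )
        values = table.sort_values("m").conditional_lnl.to_numpy()
        peak = values.argmax()
        assert (np.diff(values[: peak + 1]) > 0).all()
        assert (np.diff(values[peak:]) < 0).all()


class TestPartitioned:
    def test_single_partition_reduces_to_plain(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        tree = trees.yule_tree(taxa, rng, 0.2)
        m = simulate_binary_characters(tree, 40, seed=1)
        model = lk.ModelSpec("cfn")
        pm = lk.PartitionedModel([lk.Partition(m, model, 1.0)])
        assert lk.combined_log_likelihood(pm, tree) == pytest.approx(
            lk.log_likelihood(tree, m, model), abs=1e-12
        )

    def test_two_identical_partitions_double_lnl(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        tree = trees.yule_tree(taxa, rng, 0.2)
        m = simulate_binary_characters(tree, 40, seed=2)
        model = lk.ModelSpec("cfn")
        pm = lk.PartitionedModel(
            [lk.Partition(m, model, 1.0), lk.Partition(m, model, 1.0)]
        )
        assert lk.combined_log_likelihood(pm, tree) == pytest.approx(
            2 * lk.log_likelihood(tree, m, model), abs=1e-10
        )

    def test_mixed_partition_additivity(self, rng):
        from gaptree.synthetic_data import SimulationConfig, simulate_evolution

        taxa = [f"t{i}" for i in range(5)]
        tree = trees.unroot(trees.yule_tree(taxa, np.random.default_rng(3), 0.15))
        sim = simulate_evolution(SimulationConfig(tree=tree, root_length=300, seed=4))
        from gaptree.gap_coding import simple_indel_coding

        gaps = simple_indel_coding(sim.alignment)
        nuc_model = lk.ModelSpec("gtr")
        gap_model = lk.ModelSpec("cfn", correction="conditional")
        pm = lk.PartitionedModel(
            [
                lk.Partition(sim.alignment, nuc_model, 1.0),
                lk.Partition(gaps, gap_model, 0.1),
            ]
        )
        total = lk.combined_log_likelihood(pm, tree)
        parts = lk.log_likelihood(tree, sim.alignment, nuc_model) + lk.log_likelihood(
            tree, gaps, gap_model, rate_multiplier=0.1
        )
        assert total == pytest.approx(parts, abs=1e-10)

    def test_mismatched_tips_rejected(self, rng):
        m1 = simulate_binary_characters(
            trees.yule_tree(["a", "b", "c", "d"], rng, 0.2), 10, seed=0
        )
        m2 = simulate_binary_characters(
            trees.yule_tree(["a", "b", "c", "e"], rng, 0.2), 10, seed=0
        )
        with pytest.raises(lk.ModelError):
            lk.PartitionedModel(
                [lk.Partition(m1, lk.ModelSpec("cfn")), lk.Partition(m2, lk.ModelSpec("cfn"))]
            )


class TestMLSearch:
    def test_recovers_strong_signal_topology(self):
        # balanced tree with resolvable internal edges: at 1000 variable
        # characters the ML topology should match the generating tree
        true = trees.parse_newick(
            "((t0:0.15,t1:0.15):0.1,(t2:0.15,t3:0.15):0.1,(t4:0.15,t5:0.15):0.1);"
        )
        m = simulate_binary_characters(true, 1000, seed=12, variable_only=True)
        res = lk.ml_search(
            m,
            lk.ModelSpec("cfn", correction="conditional"),
            lk.MLSearchConfig(restarts=1, seed=1, optimize_model=False),
        )
        assert res.tree.is_same_topology(true)

    def test_attains_exhaustive_optimum_six_taxa(self):
        taxa = [f"t{i}" for i in range(6)]
        true = trees.unroot(trees.yule_tree(taxa, np.random.default_rng(21), 0.25))
        m = simulate_binary_characters(true, 120, seed=22, variable_only=True)
        model = lk.ModelSpec("cfn", correction="conditional")
        res = lk.ml_search(
            m, model, lk.MLSearchConfig(restarts=2, seed=2, optimize_model=False)
        )
        best_exhaustive = -np.inf
        for topo in trees.enumerate_topologies(taxa):
            fit = lk.optimize_branch_lengths_and_params(
                topo, m, model, optimize_model=False, tol=1e-5
            )
            best_exhaustive = max(best_exhaustive, fit.lnl)
        assert res.lnl >= best_exhaustive - 1e-3

    def test_seed_reproducibility(self):
        taxa = [f"t{i}" for i in range(6)]
        true = trees.unroot(trees.yule_tree(taxa, np.random.default_rng(31), 0.2))
        m = simulate_binary_characters(true, 200, seed=32, variable_only=True)
        cfg = lk.MLSearchConfig(restarts=2, seed=7, optimize_model=False)
        model = lk.ModelSpec("cfn", correction="conditional")
        r1, r2 = lk.ml_search(m, model, cfg), lk.ml_search(m, model, cfg)
        assert r1.tree.is_same_topology(r2.tree)
        assert r1.lnl == pytest.approx(r2.lnl, abs=1e-9)


class TestMLBootstrap:
    def test_unanimous_fixture_and_reproducibility(self):
        # clean matrix: every character a perfect synapomorphy of the true
        # tree, so no resample can support a conflicting bipartition
        taxa = [f"t{i}" for i in range(6)]
        true = trees.unroot(trees.yule_tree(taxa, np.random.default_rng(41), 0.3))
        patterns = [
            [1 if t in b else 0 for t in taxa] for b in true.bipartitions()
        ] + [[1 if t == s else 0 for t in taxa] for s in taxa]
        m = binary_matrix(taxa, (np.array(patterns).T.repeat(12, axis=1)).tolist())
        cfg = lk.MLSearchConfig(restarts=1, seed=3, optimize_model=False)
        model = lk.ModelSpec("cfn", correction="conditional")
        t1 = lk.ml_bootstrap(m, 5, model, cfg)
        t2 = lk.ml_bootstrap(m, 5, model, cfg)
        assert t1.support == t2.support
        assert all(0 <= v <= 1 for v in t1.support.values())
        for b in true.bipartitions():
            assert t1.get(b) == pytest.approx(1.0)


def _edge_map(tree):
    out = {}
    all_taxa = frozenset(tree.taxa)
    ref = min(all_taxa)
    below = {}
    for n in tree.postorder():
        if n.is_leaf:
            below[id(n)] = frozenset([n.label])
        else:
            below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
        if n.parent is None:
            continue
        block = below[id(n)]
        side = block if ref not in block else all_taxa - block
        out[side] = out.get(side, 0.0) + n.length
    return out
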
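import numpy as np
import pytest

from phylodo import (
    AnnotatedAlignment,
    Phylogeny,
    SimulationConfig,
    alignment_log_likelihood,
    assign_rate_classes,
    build_ls_tree,
    column_log_likelihood,
    discrete_gamma_rates,
    distance_matrix,
    make_benchmark_set,
    pairwise_ml_distance,
    per_column_log_likelihoods,
    simulate_alignment,
    simulate_tree,
)
from phylodo.likelihood import optimize_branch_lengths


class TestNewick:
    def test_parse_and_tree_length(self):
        tree = Phylogeny.from_newick("((A:0.1,B:0.1):0.05,C:0.2);")
        assert sorted(tree.leaf_names) == ["A", "B", "C"]
        assert abs(tree.tree_length() - 0.45) < 1e-12

    def test_roundtrip_stable(self, quartet):
        once = quartet.to_newick()
        again = Phylogeny.from_newick(once).to_newick()
        assert once == again

    def test_simulated_tree_roundtrip(self):
        rng = np.random.default_rng(3)
        tree = simulate_tree(16, 0.8, rng)
        back = Phylogeny.from_newick(tree.to_newick())
        assert abs(back.tree_length() - tree.tree_length()) < 1e-9
        assert sorted(back.leaf_names) == sorted(tree.leaf_names)

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Phylogeny.from_newick("((A:0.1,A:0.1):0.05,C:0.2);")


class TestPruning:
    def test_single_leaf_is_log_frequency(self, toy3):
        tree = Phylogeny.from_newick("(A:0.0);")
        ll = column_log_likelihood({"A": "b"}, tree, toy3)
        assert abs(ll - np.log(toy3.pi[1])) < 1e-12

    def test_matches_brute_force_enumeration(self, toy3, quartet):
        # sum over all internal-node state combinations of the quartet
        from phylodo.substitution import transition_probabilities as tp

        rng = np.random.default_rng(1)
        P = {t: tp(toy3, t) for t in (0.05, 0.1, 0.15, 0.2, 0.3)}
        for _ in range(25):
            obs = rng.integers(0, 3, size=4)
            total = 0.0
            for r in range(3):
                for x in range(3):
                    for y in range(3):
                        total += (
                            toy3.pi[r]
                            * P[0.05][r, x] * P[0.1][r, y]
                            * P[0.1][x, obs[0]] * P[0.2][x, obs[1]]
                            * P[0.15][y, obs[2]] * P[0.3][y, obs[3]]
                        )
            ll = column_log_likelihood(
                {"A": "abc"[obs[0]], "B": "abc"[obs[1]],
                 "C": "abc"[obs[2]], "D": "abc"[obs[3]]},
                quartet, toy3,
            )
            assert abs(ll - np.log(total)) < 1e-10

    def test_branch_scaling_equals_rate_scaling(self, toy3, quartet):
        ll_rate = column_log_likelihood({"A": "a", "B": "b", "C": "c", "D": "a"},
                                        quartet, toy3, rate=2.0)
        ll_scaled = column_log_likelihood({"A": "a", "B": "b", "C": "c", "D": "a"},
                                          quartet.scaled(2.0), toy3)
        assert abs(ll_rate - ll_scaled) < 1e-12

    def test_missing_data_partial_ones(self, toy3, quartet):
        full = column_log_likelihood({"A": "a", "B": "?", "C": "c", "D": "a"},
                                     quartet, toy3)
        # marginalizing B by hand
        total = 0.0
        for b in "abc":
            total += np.exp(
                column_log_likelihood({"A": "a", "B": b, "C": "c", "D": "a"},
                                      quartet, toy3)
            )
        assert abs(full - np.log(total)) < 1e-10

    def test_rerooting_invariance(self, toy3, quartet):
        # pulley principle: reversible likelihood does not depend on root
        ll = column_log_likelihood({"A": "a", "B": "b", "C": "c", "D": "a"},
                                   quartet, toy3)
        for leaf in ("A", "C", "D"):
            rerooted = quartet.rerooted_above(leaf, 0.3)
            ll2 = column_log_likelihood({"A": "a", "B": "b", "C": "c", "D": "a"},
                                        rerooted, toy3)
            assert abs(ll - ll2) < 1e-10

    def test_perturbing_branches_lowers_simulated_likelihood(self, toy3):
        rng = np.random.default_rng(8)
        tree = simulate_tree(6, 0.6, rng)
        cfg = SimulationConfig(seed=9, model_d=toy3, model_o=toy3,
                               rate_classes=1)
        mask = np.zeros(1500, dtype=np.int8)
        aln, _ = simulate_alignment(tree, mask, cfg, rng)
        base = alignment_log_likelihood(aln, tree, toy3)
        worse = 0
        trials = 0
        while trials < 20:
            factor = float(np.exp(rng.normal(0, 0.35)))
            if abs(np.log(factor)) < 0.1:
                continue
            trials += 1
            if alignment_log_likelihood(aln, tree.scaled(factor), toy3) < base:
                worse += 1
        assert worse >= 18  # 90% of clear perturbations lower the likelihood


class TestRateClasses:
    def test_k1_trivial(self, toy3, quartet, tiny_alignment):
        rm = assign_rate_classes(tiny_alignment, quartet, toy3, 1)
        assert rm.n_classes == 1
        assert np.all(rm.column_assignment == 0)
        assert rm.class_rates.tolist() == [1.0]

    def test_discrete_gamma_properties(self):
        for alpha in (0.3, 1.0, 5.0):
            rates = discrete_gamma_rates(alpha, 4)
            assert abs(rates.mean() - 1.0) < 1e-12
            assert np.all(np.diff(rates) > 0)
        # shape -> infinity: rates approach 1
        assert abs(discrete_gamma_rates(500.0, 4) - 1).max() < 0.1

    def test_simulated_slow_fast_separation(self, do_models):
        from phylodo import base_fixture_model

        # per-column rate information comes from the taxa: a reasonably
        # deep 32-leaf tree makes the 0.2 / 3.0 rate mixture separable
        model = base_fixture_model()
        rng = np.random.default_rng(21)
        tree = simulate_tree(32, 1.5, rng)
        cfg = SimulationConfig(seed=1, model_d=model, model_o=model,
                               rate_classes=1)
        mask = np.zeros(500, dtype=np.int8)
        slow, _ = simulate_alignment(tree.scaled(0.2), mask, cfg, rng)
        fast, _ = simulate_alignment(tree.scaled(3.0), mask, cfg, rng)
        combined = AnnotatedAlignment(
            names=list(slow.names),
            codes=np.hstack([slow.codes, fast.codes]),
            alphabet=model.alphabet,
        )
        rm = assign_rate_classes(combined, tree, model, 4)
        slow_cls = rm.column_assignment[:500]
        fast_cls = rm.column_assignment[500:]
        assert np.mean(slow_cls <= 1) >= 0.9
        assert np.mean(fast_cls >= 2) >= 0.9

    def test_invariant_column_lowest_class(self, toy3, quartet):
        aln = AnnotatedAlignment(
            names=["A", "B", "C", "D"],
            codes=np.zeros((4, 1), dtype=np.int8),
            alphabet=toy3.alphabet,
        )
        rates = discrete_gamma_rates(1.0, 4)
        ll = per_column_log_likelihoods(aln, quartet, toy3, rates)
        assert int(np.argmax(ll[0])) == 0


class TestDistances:
    def test_identical_sequences_near_zero(self, toy3):
        row = np.array([0, 1, 2, 0, 1, 2, 1, 1, 0, 2] * 5, dtype=np.int8)
        assert pairwise_ml_distance(row, row, toy3) <= 1e-4

    def test_too_little_overlap_rejected(self, toy3):
        a = np.array([0, -1, -1], dtype=np.int8)
        b = np.array([1, 0, 2], dtype=np.int8)
        with pytest.raises(ValueError, match="overlap"):
            pairwise_ml_distance(a, b, toy3)

    def test_nj_ols_exact_on_additive_matrix(self):
        # quartet with branch lengths A:2 B:3 C:4 D:5, internal 1
        names = ["A", "B", "C", "D"]
        dist = np.array(
            [[0, 5, 7, 8],
             [5, 0, 8, 9],
             [7, 8, 0, 9],
             [8, 9, 9, 0]], dtype=float,
        )
        tree = build_ls_tree(dist, names)
        assert abs(tree.tree_length() - 15.0) < 1e-6

    def test_distance_estimate_consistency(self, toy3):
        rng = np.random.default_rng(17)
        cfg = SimulationConfig(seed=2, model_d=toy3, model_o=toy3, rate_classes=1)
        tree = Phylogeny.from_newick("(A:0.25,B:0.25);")
        estimates = []
        for _ in range(30):
            aln, _ = simulate_alignment(tree, np.zeros(1000, dtype=np.int8),
                                        cfg, rng)
            estimates.append(
                pairwise_ml_distance(aln.codes[0], aln.codes[1], toy3)
            )
        assert abs(np.mean(estimates) - 0.5) < 0.05

    def test_distance_matrix_symmetry(self, toy3, tiny_alignment):
        dm = distance_matrix(tiny_alignment, toy3)
        assert np.allclose(dm, dm.T)
        assert np.all(np.diag(dm) == 0)

    def test_distance_tsv_roundtrip(self, toy3, tiny_alignment):
        from phylodo.likelihood import read_distance_tsv, write_distance_tsv

        dm = distance_matrix(tiny_alignment, toy3)
        text = write_distance_tsv(dm, list(tiny_alignment.names))
        back, names = read_distance_tsv(text)
        assert names == list(tiny_alignment.names)
        assert np.allclose(back, dm, atol=1e-9)


class TestBranchLengthML:
    def test_recovers_scaled_lengths(self, toy3):
        rng = np.random.default_rng(5)
        tree = simulate_tree(4, 0.5, rng)
        cfg = SimulationConfig(seed=6, model_d=toy3, model_o=toy3, rate_classes=1)
        aln, _ = simulate_alignment(tree, np.zeros(2000, dtype=np.int8), cfg, rng)
        start = tree.scaled(3.0)
        fitted = optimize_branch_lengths(aln, start, toy3, max_sweeps=3)
        assert abs(fitted.tree_length() - tree.tree_length()) < 0.2 * tree.tree_length()
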
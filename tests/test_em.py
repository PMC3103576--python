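import numpy as np
import pytest
from scipy.integrate import quad

from phylodo import (
    AnnotatedAlignment,
    EMConfig,
    EMError,
    Phylogeny,
    SimulationConfig,
    SufficientStatistics,
    em_fit,
    expected_sufficient_statistics,
    fit_do_model,
    free_parameter_count,
    m_step_update,
    make_benchmark_set,
    simulate_alignment,
    simulate_tree,
)
from phylodo.substitution import transition_probabilities as tp


def two_leaf_stats(model, t, x, y):
    """E-step on a branch of length t with the far endpoint pinned."""
    tree = Phylogeny.from_newick(f"(A:{t},B:0.0);")
    aln = AnnotatedAlignment(
        names=["A", "B"],
        codes=np.array([[x], [y]], dtype=np.int8),
        alphabet=model.alphabet,
    )
    return expected_sufficient_statistics([aln], [tree], model)


def quadrature_oracle(model, t, a, b):
    """Simpson-style numerical integration of the path integral."""
    n = model.size
    Pt = tp(model, t)
    C = np.zeros((n, n))
    W = np.zeros(n)
    for i in range(n):
        W[i] = quad(lambda u: tp(model, u)[a, i] * tp(model, t - u)[i, b],
                    0, t, limit=200)[0] / Pt[a, b]
        for j in range(n):
            if i != j:
                C[i, j] = model.Q[i, j] * quad(
                    lambda u: tp(model, u)[a, i] * tp(model, t - u)[j, b],
                    0, t, limit=200,
                )[0] / Pt[a, b]
    return C, W


class TestEStep:
    def test_short_branch_identical_endpoints(self, toy2):
        st = two_leaf_stats(toy2, 1e-7, 0, 0)
        assert st.counts.sum() < 1e-6
        assert abs(st.dwell[0] - 1e-7) < 1e-12
        assert st.dwell[1] < 1e-12

    @pytest.mark.parametrize("t", [0.01, 0.1, 0.5, 1.0, 2.0])
    def test_matches_quadrature_two_states(self, toy2, t):
        for a in range(2):
            for b in range(2):
                st = two_leaf_stats(toy2, t, b, a)  # leaf B pins the root at a
                C, W = quadrature_oracle(toy2, t, a, b)
                assert abs(st.counts - C).max() < 1e-6
                assert abs(st.dwell - W).max() < 1e-6

    def test_dwell_sums_to_tree_length_times_columns(self, toy3, quartet,
                                                     tiny_alignment):
        st = expected_sufficient_statistics([tiny_alignment], [quartet], toy3)
        expected = quartet.tree_length() * tiny_alignment.n_cols
        assert abs(st.dwell.sum() - expected) < 1e-6

    def test_unit_mean_rate_on_simulated_star_tree(self, toy3):
        rng = np.random.default_rng(4)
        tree = Phylogeny.from_newick("(A:0.3,B:0.3,C:0.3,D:0.3);")
        cfg = SimulationConfig(seed=5, model_d=toy3, model_o=toy3, rate_classes=1)
        aln, _ = simulate_alignment(tree, np.zeros(10_000, dtype=np.int8), cfg, rng)
        st = expected_sufficient_statistics([aln], [tree], toy3)
        assert abs(st.counts.sum() / st.dwell.sum() - 1.0) < 0.05


class TestMStep:
    def test_fixed_point_at_exact_expectations(self, toy3):
        # stationary complete-data expectations over total time T
        T = 37.0
        stats = SufficientStatistics(
            counts=toy3.pi[:, None] * toy3.Q * T * (1 - np.eye(3)),
            dwell=toy3.pi * T,
            log_likelihood=0.0,
        )
        model = m_step_update(stats, alphabet=toy3.alphabet)
        assert abs(model.s - toy3.s).max() < 1e-8
        assert abs(model.pi - toy3.pi).max() < 1e-12

    def test_symmetric_stats_give_uniform_frequencies(self, toy3):
        counts = np.array([[0, 3.0, 2.0], [3.0, 0, 1.0], [2.0, 1.0, 0]])
        stats = SufficientStatistics(counts=counts, dwell=np.ones(3),
                                     log_likelihood=0.0)
        model = m_step_update(stats, alphabet=toy3.alphabet)
        assert np.allclose(model.pi, 1 / 3)

    def test_hand_formula_three_letters(self, toy3):
        counts = np.array([[0, 4.0, 1.0], [2.0, 0, 6.0], [1.0, 2.0, 0]])
        dwell = np.array([5.0, 3.0, 2.0])
        stats = SufficientStatistics(counts=counts, dwell=dwell,
                                     log_likelihood=0.0)
        model = m_step_update(stats, alphabet=toy3.alphabet)
        pi = dwell / dwell.sum()
        sym = counts + counts.T
        expect = sym / (np.outer(dwell, pi) + np.outer(dwell, pi).T)
        np.fill_diagonal(expect, 0.0)
        # joint rescaling preserves ratios
        ratio = model.s[0, 1] / expect[0, 1]
        assert np.allclose(model.s[expect > 0], expect[expect > 0] * ratio)

    def test_rejects_empty_statistics(self, toy3):
        with pytest.raises(ValueError, match="no signal"):
            m_step_update(
                SufficientStatistics(counts=np.zeros((3, 3)),
                                     dwell=np.ones(3), log_likelihood=0.0),
                alphabet=toy3.alphabet,
            )


class TestEMFit:
    def test_monotone_trace_on_fixtures(self, small_corpus):
        cfg = EMConfig(rate_classes=2, max_iterations=40)
        res = em_fit(small_corpus.alignments, small_corpus.trees, cfg)
        assert np.all(np.diff(res.trace) >= -1e-6)

    def test_truth_start_converges_immediately(self, toy3):
        rng = np.random.default_rng(12)
        tree = simulate_tree(6, 0.6, rng)
        cfg = SimulationConfig(seed=13, model_d=toy3, model_o=toy3, rate_classes=1)
        aln, _ = simulate_alignment(tree, np.zeros(4000, dtype=np.int8), cfg, rng)
        emcfg = EMConfig(rate_classes=1, log_likelihood_tolerance=1.0,
                         exchangeability_pseudocount=0.0)
        res = em_fit([aln], [tree], emcfg, initial_model=toy3)
        assert len(res.trace) <= 3
        assert res.converged

    def test_parameter_recovery_small(self, toy3):
        rng = np.random.default_rng(14)
        trees = [simulate_tree(6, 0.7, rng) for _ in range(3)]
        cfg = SimulationConfig(seed=15, model_d=toy3, model_o=toy3, rate_classes=1)
        alns = [simulate_alignment(t, np.zeros(800, dtype=np.int8), cfg, rng)[0]
                for t in trees]
        res = em_fit(alns, trees, EMConfig(rate_classes=1))
        assert abs(res.model.pi - toy3.pi).max() < 0.02
        off = ~np.eye(3, dtype=bool)
        assert abs(np.log(res.model.s[off]) - np.log(toy3.s[off])).max() < 0.15

    def test_recovery_improves_with_data(self, toy3):
        rng = np.random.default_rng(16)
        tree = simulate_tree(6, 0.7, rng)
        cfg = SimulationConfig(seed=17, model_d=toy3, model_o=toy3, rate_classes=1)
        off = ~np.eye(3, dtype=bool)
        errs = {}
        for n_cols in (200, 2000):
            errors = []
            for _ in range(8):
                aln, _ = simulate_alignment(tree, np.zeros(n_cols, dtype=np.int8),
                                            cfg, rng)
                res = em_fit([aln], [tree], EMConfig(rate_classes=1))
                errors.append(
                    np.median(np.abs(np.log(res.model.s[off] / toy3.s[off])))
                )
            errs[n_cols] = np.median(errors)
        assert errs[2000] < errs[200]

    def test_bad_estep_aborts(self, toy3, quartet, tiny_alignment, monkeypatch):
        # corrupt the likelihood sign mid-run to exercise the guard
        import phylodo.em as em_mod

        real = em_mod.expected_sufficient_statistics
        calls = {"n": 0}

        def corrupted(*args, **kwargs):
            st = real(*args, **kwargs)
            calls["n"] += 1
            if calls["n"] >= 3:
                st.log_likelihood -= 1e6
            return st

        monkeypatch.setattr(em_mod, "expected_sufficient_statistics", corrupted)
        with pytest.raises(EMError):
            em_fit([tiny_alignment], [quartet],
                   EMConfig(rate_classes=1, max_iterations=10))


class TestDOFit:
    def test_parameter_counting(self):
        assert free_parameter_count(20) == 208

    def test_nesting_and_aic(self, small_corpus):
        cfg = EMConfig(rate_classes=2, max_iterations=40)
        fit = fit_do_model(small_corpus.alignments, small_corpus.trees, cfg)
        assert fit.lnl_do >= fit.lnl_single - 1e-6
        assert fit.n_parameters_do == 416
        assert fit.aic_do == 2 * 416 - 2 * fit.lnl_do

    def test_missing_region_class_rejected(self, toy3, quartet):
        rng = np.random.default_rng(19)
        codes = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
        aln = AnnotatedAlignment(names=["A", "B", "C", "D"], codes=codes,
                                 mask=np.zeros(30, dtype=np.int8),
                                 alphabet=toy3.alphabet)
        with pytest.raises(ValueError, match="absent"):
            fit_do_model([aln], [quartet], EMConfig(rate_classes=1))
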
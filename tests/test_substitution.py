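import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from phylodo import (
    AMINO,
    ClassPartition,
    build_model,
    class_rate_statistics,
    fixture_models,
    jukes_cantor_like,
    read_paml_matrix,
    toy_alphabet,
    transition_probabilities,
    write_paml_matrix,
)


def random_model(seed, n=20):
    rng = np.random.default_rng(seed)
    s = rng.random((n, n))
    s = s + s.T
    np.fill_diagonal(s, 0.0)
    pi = rng.dirichlet(np.full(n, 5.0))
    ab = AMINO if n == 20 else toy_alphabet("abcdefghij"[:n])
    return build_model(pi, s, alphabet=ab)


class TestBuildModel:
    def test_jukes_cantor_rates(self, jc20):
        off = ~np.eye(20, dtype=bool)
        assert np.allclose(jc20.Q[off], 1 / 19)
        assert np.allclose(np.diag(jc20.Q), -1.0)

    def test_three_letter_hand_assembly(self, toy3):
        # q_ij = s_ij * pi_j, diagonal closes rows, then global rescale to
        # unit mean rate
        pi = np.array([0.5, 0.3, 0.2])
        s = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 4.0], [2.0, 4.0, 0.0]])
        q = s * pi[None, :]
        np.fill_diagonal(q, -q.sum(axis=1) + np.diag(q))
        scale = -np.dot(pi, np.diag(q))
        assert np.allclose(toy3.Q, q / scale, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariants(self, seed):
        m = random_model(seed)
        flux = m.pi[:, None] * m.Q
        assert abs(flux - flux.T).max() < 1e-10  # detailed balance
        assert abs(m.Q.sum(axis=1)).max() < 1e-10
        assert abs(-np.dot(m.pi, np.diag(m.Q)) - 1.0) < 1e-10

    def test_rejects_degenerate_inputs(self):
        n = 20
        pi = np.full(n, 1 / n)
        with pytest.raises(ValueError, match="zero"):
            build_model(pi, np.zeros((n, n)))
        s = np.ones((n, n))
        np.fill_diagonal(s, 0.0)
        bad = pi.copy()
        bad[0] = 0.0
        bad[1] += 1 / n
        with pytest.raises(ValueError):
            build_model(bad, s)
        asym = s.copy()
        asym[0, 1] = 2.0
        with pytest.raises(ValueError, match="symmetric"):
            build_model(pi, asym)


class TestTransitionProbabilities:
    def test_identity_at_zero(self, toy3):
        assert np.allclose(transition_probabilities(toy3, 0.0), np.eye(3),
                           atol=1e-12)

    def test_ergodic_limit(self, jc20):
        P = transition_probabilities(jc20, 1000.0)
        assert abs(P - jc20.pi[None, :]).max() < 1e-6

    def test_matches_generic_matrix_exponential(self):
        m = random_model(7)
        P = transition_probabilities(m, 0.37)
        assert abs(P - expm(m.Q * 0.37)).max() < 1e-9

    def test_rejects_negative_time(self, jc20):
        with pytest.raises(ValueError):
            transition_probabilities(jc20, -0.1)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(s=st.floats(0.0, 2.0), t=st.floats(0.0, 2.0))
    def test_chapman_kolmogorov(self, s, t):
        m = random_model(11)
        lhs = transition_probabilities(m, s) @ transition_probabilities(m, t)
        assert abs(lhs - transition_probabilities(m, s + t)).max() < 1e-9


class TestClassRateStatistics:
    def test_uniform_model_equal_normalized_rates(self, jc20):
        summary = class_rate_statistics(jc20, ClassPartition())
        vals = list(summary.normalized_rates.values())
        assert max(vals) - min(vals) < 1e-10

    def test_blocked_exchange_gives_zero_between(self):
        part = ClassPartition()
        idx_o = part.indices("order")
        idx_d = part.indices("disorder")
        s = np.ones((20, 20))
        s[np.ix_(idx_o, idx_d)] = 0.0
        s[np.ix_(idx_d, idx_o)] = 0.0
        np.fill_diagonal(s, 0.0)
        m = build_model(np.full(20, 0.05), s)
        summary = class_rate_statistics(m, part)
        assert summary.raw_rates["OD"] == 0.0
        assert summary.normalized_rates["OD"] == 0.0

    def test_three_letter_hand_computation(self, toy3):
        # order = {a}, disorder = {b, c}
        part = ClassPartition(order_set=("a",), disorder_set=("b", "c"),
                              alphabet=toy3.alphabet)
        summary = class_rate_statistics(toy3, part)
        pi, Q = toy3.pi, toy3.Q
        raw_dd = pi[1] * Q[1, 2] + pi[2] * Q[2, 1]
        raw_od = pi[0] * (Q[0, 1] + Q[0, 2]) + pi[1] * Q[1, 0] + pi[2] * Q[2, 0]
        mass_dd = 2 * pi[1] * pi[2]
        mass_od = 2 * pi[0] * (pi[1] + pi[2])
        assert abs(summary.raw_rates["DD"] - raw_dd) < 1e-12
        assert abs(summary.raw_rates["OD"] - raw_od) < 1e-12
        assert abs(summary.normalized_rates["DD"] - raw_dd / mass_dd) < 1e-12
        assert abs(summary.normalized_rates["OD"] - raw_od / mass_od) < 1e-12

    def test_normalized_rates_stable_under_rebuild(self, do_models):
        d, _ = do_models
        part = ClassPartition()
        a = class_rate_statistics(d, part).normalized_rates
        rebuilt = build_model(d.pi, d.s, alphabet=d.alphabet)
        b = class_rate_statistics(rebuilt, part).normalized_rates
        for key in a:
            assert abs(a[key] - b[key]) < 1e-10


class TestPamlIO:
    def test_roundtrip_identity(self, jc20):
        again = read_paml_matrix(write_paml_matrix(jc20))
        assert abs(again.s - jc20.s).max() < 1e-6
        assert abs(again.pi - jc20.pi).max() < 1e-6

    def test_fixture_models_roundtrip(self, do_models, tmp_path):
        for m in do_models:
            path = tmp_path / f"{m.name}.dat"
            write_paml_matrix(m, path)
            again = read_paml_matrix(path, name=m.name)
            assert np.allclose(again.s, m.s, rtol=1e-5)
            assert np.allclose(again.pi, m.pi, rtol=1e-5, atol=1e-7)
            assert abs(again.pi.sum() - 1.0) < 1e-12

    def test_three_letter_transcription(self):
        ab = toy_alphabet("abc")
        model = read_paml_matrix("1\n2 4\n\n0.5 0.3 0.2\n", alphabet=ab)
        # parsed values are renormalized jointly with Q; ratios survive
        assert abs(model.s[1, 0] / model.s[2, 0] - 1 / 2) < 1e-12
        assert abs(model.s[2, 1] / model.s[2, 0] - 2.0) < 1e-12
        assert np.allclose(model.pi, [0.5, 0.3, 0.2])

    @pytest.mark.parametrize(
        "text, match",
        [
            ("1\n2\n\n0.5 0.3 0.2\n", "expected 2 values"),
            ("1\n-2 4\n\n0.5 0.3 0.2\n", "negative"),
            ("1\n2 4\n\n0.6 0.3 0.2\n", "sum"),
        ],
    )
    def test_reader_diagnostics(self, text, match):
        with pytest.raises(ValueError, match=match):
            read_paml_matrix(text, alphabet=toy_alphabet("abc"))


class TestClassPartition:
    def test_default_partition_covers_alphabet(self):
        part = ClassPartition()
        members = set(part.order_set) | set(part.disorder_set) | set(part.neutral_set)
        assert members == set(AMINO.residues)

    def test_json_roundtrip(self, tmp_path):
        part = ClassPartition(order_set=("I", "L"), disorder_set=("P", "S"))
        path = tmp_path / "partition.json"
        part.to_json(path)
        again = ClassPartition.from_json(path)
        assert again.order_set == ("I", "L")
        assert again.disorder_set == ("P", "S")

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ClassPartition(order_set=("I", "P"), disorder_set=("P", "S"))
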
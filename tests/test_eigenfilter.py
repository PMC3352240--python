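"""The Hebbian learning kernel and its batch/stream training regimes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hebbsort as h
from hebbsort.complexity import instrumented_hebbian_step
from hebbsort.exceptions import (
    InvalidInputError,
    StreamExhaustedError,
)


def learning_state(W, eta=0.1):
    """A state in the learning phase with explicit weights and constant eta."""
    W = np.atleast_2d(np.asarray(W, dtype=np.float64))
    st_ = h.EigenfilterState(l=W.shape[0], d=W.shape[1], eta=eta,
                             schedule="constant", symmetry_break=0.0)
    st_.phase = "learning"
    st_.W = W.copy()
    return st_


class TestLtOperator:
    def test_examples(self):
        assert np.array_equal(
            h.lt_lower_triangular([[1, 2], [3, 4]]), [[1, 0], [3, 4]]
        )
        D = np.diag([1.0, 2.0, 3.0])
        assert np.array_equal(h.lt_lower_triangular(D), D)
        assert np.array_equal(
            h.lt_lower_triangular(np.ones((3, 3))), np.tri(3)
        )

    @given(st.integers(0, 2**31 - 1), st.integers(1, 6))
    @settings(max_examples=25, deadline=None)
    def test_elementwise_property(self, seed, k):
        M = np.random.default_rng(seed).standard_normal((k, k))
        L = h.lt_lower_triangular(M)
        for i in range(k):
            for j in range(k):
                assert L[i, j] == (M[i, j] if j <= i else 0.0)

    def test_non_square_rejected(self):
        with pytest.raises(InvalidInputError):
            h.lt_lower_triangular(np.ones((2, 3)))


class TestHebbianStep:
    def test_zero_input_is_identity(self):
        state = learning_state(np.array([[0.3, -0.2], [0.1, 0.4]]))
        W_before = state.W.copy()
        h.hebbian_step(state, np.zeros(2))
        assert np.array_equal(state.W, W_before)
        assert state.j == 2

    def test_scalar_worked_example(self):
        """l=d=1, W=0.5, x=2, eta=0.1: y=1, dW=0.1*(2-0.5)=0.15."""
        state = learning_state([[0.5]])
        h.hebbian_step(state, np.array([2.0]))
        assert state.W[0, 0] == pytest.approx(0.65)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        """The vectorized update equals an element-by-element evaluation."""
        rng = np.random.default_rng(seed)
        l = int(rng.integers(1, 4))
        d = int(rng.integers(l, 7))
        W = rng.standard_normal((l, d))
        x = rng.standard_normal(d)
        expected, _, _ = instrumented_hebbian_step(W, x, 0.07)
        state = learning_state(W, eta=0.07)
        h.hebbian_step(state, x)
        assert np.allclose(state.W, expected, atol=1e-12)

    def test_dimension_mismatch(self):
        state = learning_state(np.ones((2, 3)))
        with pytest.raises(InvalidInputError):
            h.hebbian_step(state, np.ones(4))


class TestAccumulateMean:
    def test_two_spike_example(self):
        state = h.EigenfilterState(l=1, d=2, n=2)
        h.accumulate_mean(state, np.array([1.0, 3.0]))
        assert state.phase == "mean_accumulation"
        h.accumulate_mean(state, np.array([3.0, 5.0]))
        assert np.array_equal(state.mu, [2.0, 4.0])
        assert state.phase == "learning"

    def test_single_spike_mean(self):
        state = h.EigenfilterState(l=1, d=3, n=1)
        h.accumulate_mean(state, np.array([1.0, -2.0, 5.0]))
        assert np.array_equal(state.mu, [1.0, -2.0, 5.0])

    def test_identical_spikes_exact(self):
        state = h.EigenfilterState(l=1, d=4, n=1024)
        s = np.array([0.25, -1.5, 3.0, 0.125])
        for _ in range(1024):
            h.accumulate_mean(state, s)
        assert np.array_equal(state.mu, s)


class TestTraining:
    def test_eta_zero_returns_initial_weights(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 6))
        W, state = h.train_stream(iter(X), l=2, d=6, eta=0.0, n=16, N=16)
        assert np.array_equal(W, state.W_init)
        Wb, sb = h.train_batch(X, l=2, eta=0.0, N=64)
        assert np.array_equal(Wb, sb.W_init)

    def test_stream_exhaustion_diagnostic(self):
        X = np.random.default_rng(1).standard_normal((10, 4))
        with pytest.raises(StreamExhaustedError, match="10 spikes"):
            h.train_stream(iter(X), l=1, d=4, n=8, N=8)

    def test_diagonal_covariance_first_component(self):
        """On a stream with covariance diag(9,1,...), w1 aligns with axis 0."""
        rng = np.random.default_rng(42)
        sd = np.ones(8)
        sd[0] = 3.0
        X = rng.standard_normal((2048, 8)) * sd
        W, _ = h.train_stream(iter(X), l=1, d=8, n=1024, N=1024)
        e1 = np.eye(8)[0]
        assert h.error_pc(W[0], e1) <= 0.05

    def test_stream_matches_pca_oracle_on_spike_data(self, stream_runs):
        """With n = N = 1024 on a 2-neuron train, each stream-learned
        component deviates from its batch-PCA counterpart by <= 0.05."""
        run = stream_runs[0]
        assert np.all(run["error_pc"] <= 0.05)

    def test_batch_agrees_with_stream_on_stationary_source(self):
        rng = np.random.default_rng(7)
        sd = np.ones(8)
        sd[0], sd[1] = 3.0, 2.0
        X = rng.standard_normal((2048, 8)) * sd
        Wb, _ = h.train_batch(X[1024:], l=2, N=1024)
        Ws, _ = h.train_stream(iter(X), l=2, d=8, n=1024, N=1024)
        for i in range(2):
            assert h.error_pc(Wb[i], Ws[i]) <= 0.05

    def test_norm_convergence(self):
        """Each learned weight norm approaches 1 within 0.1 after 2048
        presentations on stationary data."""
        rng = np.random.default_rng(3)
        sd = np.ones(8)
        sd[0], sd[1] = 3.0, 2.0
        X = rng.standard_normal((3072, 8)) * sd
        W, _ = h.train_stream(iter(X), l=2, d=8, n=1024, N=2048)
        assert np.all(np.abs(np.linalg.norm(W, axis=1) - 1.0) < 0.1)

    def test_deflation_ordering(self, detected):
        n = min(1024, detected.n // 2)
        res = h.StreamingHebbianEigenfilter(n_mean=n, n_learn=n).fit(
            iter(detected.spikes)
        )
        var = res.score_variances(detected.spikes[n : 2 * n])
        assert var[0] >= var[1]

    def test_determinism(self, detected):
        n = min(1024, detected.n // 2)
        runs = [
            h.train_stream(iter(detected.spikes), l=2, n=n, N=n)[0]
            for _ in range(2)
        ]
        assert np.array_equal(runs[0], runs[1])

    def test_streaming_memory_contract(self, detected):
        """Instrumentation confirms at most 2 spike vectors are retained."""
        n = min(1024, detected.n // 2)
        held = []
        h.train_stream(iter(detected.spikes), l=2, n=n, N=n, monitor=held.append)
        assert len(held) == 2 * n
        assert max(held) <= 2

    def test_batch_constant_data_keeps_init(self):
        """A single repeated spike zero-means to nothing: W stays at init."""
        X = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (16, 1))
        W, state = h.train_batch(X, l=2, N=64)
        assert np.allclose(W, state.W_init)


class TestProjection:
    def test_spike_equal_to_mean_scores_zero(self):
        W = np.eye(2, 5)
        mu = np.arange(5.0)
        fs = h.project(mu[None, :], W, mu)
        assert np.allclose(fs.scores, 0.0)

    def test_identity_components_pick_samples(self):
        W = np.eye(2, 6)
        X = np.random.default_rng(0).standard_normal((7, 6))
        fs = h.project(X, W, np.zeros(6))
        assert np.allclose(fs.scores, X[:, :2])

    def test_agrees_with_pca_projection_after_sign_alignment(self, stream_runs):
        run = stream_runs[0]
        res, basis, spikes = run["results"], run["basis"], run["spikes"]
        W = h.sign_align(res.components_, basis)
        ours = h.project(spikes, W, res.mu)
        ref = basis.project(spikes)
        # directions agree to error_pc <= 0.02, so scores correlate strongly
        for i in range(2):
            r = np.corrcoef(ours.scores[:, i], ref.scores[:, i])[0, 1]
            assert r > 0.99

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidInputError):
            h.project(np.ones((3, 5)), np.ones((2, 4)), np.zeros(4))


class TestResultsObject:
    def test_summary_and_roundtrip(self, detected, tmp_path):
        n = min(256, detected.n // 2)
        res = h.StreamingHebbianEigenfilter(n_mean=n, n_learn=n).fit(
            iter(detected.spikes)
        )
        text = res.summary()
        assert "stream_gha" in text and "eta0" in text
        path = tmp_path / "filter.json"
        res.save(path)
        from hebbsort.io import read_filter

        bundle = read_filter(path)
        assert np.array_equal(bundle["W"], res.W)
        assert np.array_equal(bundle["mu"], res.mu)
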
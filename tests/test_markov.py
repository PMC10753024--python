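"""The Markov core: delta indices, normalization, propagation, stationarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affectdyn import (
    assemble_delta_matrix,
    delta_index,
    eigen_stationary,
    extract_windows,
    normalize_rows,
    propagate,
    source_receiver,
    steady_state,
    uniform_distribution,
)
from affectdyn.design import STATE_LABELS, STATE_ORDER, AffectiveState
from affectdyn.errors import (
    DegenerateSegmentError,
    InvalidInputError,
    InvalidMatrixError,
    InvalidParameterError,
    NonNormalizableError,
    ReducibleChainError,
)
from affectdyn.markov import (
    StateDistribution,
    TransitionMatrix,
    load_matrix_csv,
    read_transition_matrix,
    to_dot,
    write_matrix_csv,
)
from affectdyn.reference import reference_matrix_raw
from conftest import random_stochastic_matrix


class TestDeltaIndex:
    def test_constant_segment_has_zero_variability(self):
        assert delta_index(np.array([5.0, 5.0, 5.0, 5.0])) == 0.0

    def test_hand_computed_value(self):
        # sample SD of (1,2,3) is 1, mean is 2
        assert delta_index(np.array([1.0, 2.0, 3.0])) == pytest.approx(0.5)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(derandomize=True)
    def test_invariant_under_positive_rescaling(self, scale):
        x = np.array([0.8, 1.1, 0.9, 1.4, 1.0])
        assert delta_index(scale * x) == pytest.approx(delta_index(x), rel=1e-9)

    def test_rejects_short_and_degenerate_segments(self):
        with pytest.raises(InvalidInputError):
            delta_index(np.array([1.0]))
        with pytest.raises(DegenerateSegmentError):
            delta_index(np.array([1.0, -1.0, 1.0, -1.0]))


class TestAssembleDeltaMatrix:
    def test_session_yields_sixteen_indices(self, high_session):
        _, result = high_session
        delta = assemble_delta_matrix(result.windows, result.signal)
        assert len(delta.delta) == 16

    def test_constant_self_windows_give_zero_self_delta(self, high_session):
        spec, result = high_session
        windows = result.windows
        samples = result.signal.samples.copy()
        fs = result.signal.sampling_rate
        target = AffectiveState.BORING
        for w in windows.self_windows:
            if w.state == target:
                i0, i1 = int(w.start_s * fs), int(w.end_s * fs)
                samples[i0:i1] = 3.0
        flattened = type(result.signal)(samples=samples, sampling_rate=fs)
        delta = assemble_delta_matrix(windows, flattened)
        assert delta[(target, target)] == 0.0

    def test_amplitude_rescaling_leaves_indices_unchanged(self, high_session):
        _, result = high_session
        delta = assemble_delta_matrix(result.windows, result.signal)
        doubled = type(result.signal)(
            samples=2.0 * result.signal.samples,
            sampling_rate=result.signal.sampling_rate,
        )
        delta2 = assemble_delta_matrix(result.windows, doubled)
        for pair, value in delta.delta.items():
            assert delta2[pair] == pytest.approx(value, rel=1e-12)

    def test_degenerate_window_error_names_the_window(self, schedule):
        from affectdyn.signal import EnvelopeSignal

        zero = EnvelopeSignal(samples=np.zeros(156000), sampling_rate=100.0)
        with pytest.raises(DegenerateSegmentError, match=r"\["):
            assemble_delta_matrix(extract_windows(schedule), zero)


class TestNormalizeRows:
    def test_uniform_row(self):
        arr = np.ones((4, 4))
        assert np.allclose(normalize_rows(arr).values, 0.25)

    def test_hand_normalized_row(self):
        arr = np.ones((4, 4))
        arr[0] = [3.0, 1.0, 4.0, 2.0]
        assert np.allclose(normalize_rows(arr).values[0], [0.3, 0.1, 0.4, 0.2])

    def test_zero_row_raises_and_names_the_state(self):
        arr = np.ones((4, 4))
        arr[2] = 0.0
        with pytest.raises(NonNormalizableError, match="Boring"):
            normalize_rows(arr)


class TestPropagation:
    def test_one_step_from_uniform_matches_published_table(self, high_matrix):
        s1 = propagate(high_matrix, uniform_distribution(), 1)
        assert np.round(s1.probs, 2).tolist() == [0.31, 0.20, 0.39, 0.10]

    def test_published_propagation_table_all_steps(self, high_matrix):
        expected = {
            1: [0.31, 0.20, 0.39, 0.10],
            2: [0.29, 0.20, 0.42, 0.09],
            3: [0.29, 0.20, 0.42, 0.09],
            4: [0.28, 0.20, 0.43, 0.09],
            5: [0.28, 0.20, 0.43, 0.09],
        }
        for k, row in expected.items():
            sk = propagate(high_matrix, uniform_distribution(), k)
            assert np.round(sk.probs, 2).tolist() == row

    def test_identity_matrix_is_a_fixed_point(self):
        identity = TransitionMatrix(values=np.eye(4))
        s0 = StateDistribution(probs=np.array([0.1, 0.2, 0.3, 0.4]))
        assert np.allclose(propagate(identity, s0, 7).probs, s0.probs)

    def test_negative_step_count_is_rejected(self, high_matrix):
        with pytest.raises(InvalidParameterError):
            propagate(high_matrix, uniform_distribution(), -1)

    @given(seed=st.integers(0, 10_000), a=st.integers(0, 6), b=st.integers(0, 6))
    @settings(derandomize=True, max_examples=50)
    def test_propagation_is_compositional_and_simplex_preserving(self, seed, a, b):
        rng = np.random.default_rng(seed)
        matrix = TransitionMatrix(values=random_stochastic_matrix(rng))
        s0 = uniform_distribution()
        two_leg = propagate(matrix, propagate(matrix, s0, a), b)
        one_leg = propagate(matrix, s0, a + b)
        assert np.allclose(two_leg.probs, one_leg.probs, atol=1e-12)
        assert one_leg.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(one_leg.probs >= -1e-9)


class TestSteadyState:
    def test_high_flexibility_five_step_steady_state(self, high_matrix):
        assert np.round(steady_state(high_matrix).probs, 2).tolist() == [
            0.28, 0.20, 0.43, 0.09,
        ]

    def test_low_flexibility_peaks_on_stress(self, low_matrix):
        probs = steady_state(low_matrix).probs
        assert int(np.argmax(probs)) == int(AffectiveState.STRESS)
        assert round(float(probs.max()), 2) == 0.29

    def test_zero_steps_returns_the_start(self, high_matrix):
        assert np.allclose(steady_state(high_matrix, steps=0).probs, 0.25)

    def test_symmetric_two_block_chain_stays_uniform_on_its_support(self):
        # a 4-state lift of the 2-state flip chain: (A<->B), (C<->D)
        flip = np.zeros((4, 4))
        flip[0, 1] = flip[1, 0] = flip[2, 3] = flip[3, 2] = 1.0
        matrix = TransitionMatrix(values=flip)
        s0 = StateDistribution(probs=np.array([0.5, 0.5, 0.0, 0.0]))
        probs = steady_state(matrix, steps=5, s0=s0).probs
        assert np.allclose(probs, [0.5, 0.5, 0.0, 0.0])


class TestEigenStationary:
    def test_doubly_stochastic_matrix_has_uniform_stationary(self):
        rng = np.random.default_rng(1)
        # symmetrize a random stochastic matrix via Sinkhorn iterations
        arr = rng.random((4, 4)) + 0.1
        for _ in range(200):
            arr /= arr.sum(axis=1, keepdims=True)
            arr /= arr.sum(axis=0, keepdims=True)
        arr /= arr.sum(axis=1, keepdims=True)
        pi = eigen_stationary(TransitionMatrix(values=arr))
        assert np.allclose(pi.probs, 0.25, atol=1e-6)

    def test_identity_matrix_has_no_unique_stationary(self):
        with pytest.raises(ReducibleChainError):
            eigen_stationary(TransitionMatrix(values=np.eye(4)))

    def test_matches_long_power_iteration(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            matrix = TransitionMatrix(values=random_stochastic_matrix(rng))
            pi = eigen_stationary(matrix)
            power = propagate(matrix, uniform_distribution(), 10_000)
            assert np.allclose(pi.probs, power.probs, atol=1e-8)

    def test_five_step_estimate_approaches_the_eigenvector(self, high_matrix):
        pi = eigen_stationary(high_matrix)
        five = steady_state(high_matrix)
        assert np.max(np.abs(pi.probs - five.probs)) < 0.01


class TestSourceReceiver:
    def test_published_high_flexibility_values(self, high_matrix):
        sr = source_receiver(high_matrix)
        source, receiver = sr[AffectiveState.STRESS]
        assert source == pytest.approx(0.52, abs=1e-9)
        assert receiver == pytest.approx(0.77, abs=1e-9)

    def test_identity_has_no_off_diagonal_mass(self):
        sr = source_receiver(TransitionMatrix(values=np.eye(4)))
        assert all(pair == (0.0, 0.0) for pair in sr.values())

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=50)
    def test_source_plus_diagonal_is_one(self, seed):
        rng = np.random.default_rng(seed)
        matrix = TransitionMatrix(values=random_stochastic_matrix(rng))
        sr = source_receiver(matrix)
        for s in STATE_ORDER:
            source, _ = sr[s]
            assert source + matrix[s, s] == pytest.approx(1.0, abs=1e-9)


class TestMatrixIO:
    @pytest.mark.parametrize("flexibility", ["high", "low"])
    def test_published_matrices_roundtrip_bit_exact(self, flexibility, tmp_path):
        raw = reference_matrix_raw(flexibility)
        write_matrix_csv(raw, tmp_path / "m.csv")
        assert np.array_equal(load_matrix_csv(tmp_path / "m.csv"), raw)

    def test_tolerant_reader_renormalizes_printed_rounding(self, tmp_path):
        write_matrix_csv(reference_matrix_raw("low"), tmp_path / "m.csv")
        matrix, warnings = read_transition_matrix(tmp_path / "m.csv")
        assert len(warnings) == 1 and "Engagement" in warnings[0]
        assert np.allclose(matrix.values.sum(axis=1), 1.0, atol=1e-12)

    def test_reader_rejects_rows_far_from_stochastic(self, tmp_path):
        bad = reference_matrix_raw("high")
        bad[0, 0] -= 0.1
        write_matrix_csv(bad, tmp_path / "m.csv")
        with pytest.raises(InvalidMatrixError, match="Stress"):
            read_transition_matrix(tmp_path / "m.csv")

    def test_dot_export_lists_weighted_edges(self, high_matrix):
        dot = to_dot(high_matrix)
        assert dot.startswith("digraph")
        assert 'Stress -> Boring [label="0.30"' in dot
        for label in STATE_LABELS:
            assert label in dot
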
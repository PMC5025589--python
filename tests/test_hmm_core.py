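"""Unit and property tests of the log-space HMM engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tahmm
from tahmm.alphabet import ALPHABET, AminoAcidSequence, SequenceError
from tahmm.hmm import (
    HmmParameters,
    NoAdmissiblePathError,
    baum_welch_fit,
    forward_log_likelihood,
    sample_sequence,
    viterbi_decode,
)
from _oracles import (
    brute_force_forward,
    brute_force_viterbi,
    random_dense_hmm,
    scaled_forward,
)


def single_state_hmm(letter_prob=None):
    if letter_prob is None:
        em = np.full((1, 20), 1 / 20)
    else:
        em = np.array([letter_prob])
    with np.errstate(divide="ignore"):
        log_em = np.log(em)
    return HmmParameters(
        state_ids=["s0"],
        regions=["globular"],
        log_initial=np.array([0.0]),
        log_transition=np.array([[0.0]]),
        log_emission=log_em,
    )


class TestForward:
    def test_single_state_closed_form(self):
        """One state emitting A with p=0.25: P('AAAA') = 0.25^4."""
        probs = np.full(20, 0.75 / 19)
        probs[ALPHABET.index("A")] = 0.25
        params = single_state_hmm(probs)
        ll = forward_log_likelihood(params, "AAAA")
        assert ll == pytest.approx(4 * math.log(0.25), abs=1e-12)

    @pytest.mark.parametrize("n_states,length", [(2, 4), (3, 5), (1, 6)])
    def test_matches_brute_force_enumeration(self, rng, n_states, length):
        for _ in range(5):
            params = random_dense_hmm(rng, n_states)
            codes = rng.integers(0, 20, length)
            seq = "".join(ALPHABET[c] for c in codes)
            assert forward_log_likelihood(params, seq) == pytest.approx(
                brute_force_forward(params, codes), rel=1e-10
            )

    def test_forward_at_least_viterbi(self, rng):
        for n in (1, 2, 3):
            params = random_dense_hmm(rng, n)
            seq = "".join(ALPHABET[c] for c in rng.integers(0, 20, 30))
            fwd = forward_log_likelihood(params, seq)
            _, joint = viterbi_decode(params, seq)
            assert fwd >= joint - 1e-12

    def test_empty_sequence_rejected(self):
        with pytest.raises(SequenceError):
            forward_log_likelihood(single_state_hmm(), "")

    def test_no_underflow_matches_scaled_arithmetic_at_length_5000(self, rng):
        """Log-space forward equals the scaled linear-space forward to 1e-9
        relative for a 5000-residue sequence (no underflow)."""
        params = random_dense_hmm(rng, 3)
        codes = rng.integers(0, 20, 5000)
        seq = "".join(ALPHABET[c] for c in codes)
        ll = forward_log_likelihood(params, seq)
        assert np.isfinite(ll)
        assert ll == pytest.approx(scaled_forward(params, codes), rel=1e-9)

    def test_ambiguous_residues_are_class_neutral(self, rng):
        """An X contributes exactly log(1/20) under any model."""
        params = random_dense_hmm(rng, 2)
        base = forward_log_likelihood(params, "ACDEF")
        with_x = forward_log_likelihood(params, "ACDEFX")
        # appending X multiplies by sum_j P(trans to j)/20 summed over paths:
        # bounded between base + log(1/20) + min/max transition structure;
        # with dense transitions the exact increment is log(1/20).
        assert with_x == pytest.approx(base + math.log(1 / 20), rel=1e-9)


class TestViterbi:
    def test_single_state_path(self):
        params = single_state_hmm()
        path, joint = viterbi_decode(params, "MKLV")
        assert list(path) == [0, 0, 0, 0]
        assert joint == pytest.approx(4 * math.log(1 / 20))

    def test_matches_brute_force_argmax(self, rng):
        """3-state model, length-6 sequences: path equals the argmax over
        all 3^6 enumerated paths."""
        for _ in range(5):
            params = random_dense_hmm(rng, 3)
            codes = rng.integers(0, 20, 6)
            seq = "".join(ALPHABET[c] for c in codes)
            path, joint = viterbi_decode(params, seq)
            bf_path, bf_joint = brute_force_viterbi(params, codes)
            assert joint == pytest.approx(bf_joint, rel=1e-10)
            assert tuple(path) == bf_path

    def test_exhaustive_small_models(self, rng):
        """Forward and Viterbi agree with enumeration on every small random
        instance (up to 3 states, sequences up to length 7)."""
        for n_states in (1, 2, 3):
            for length in (1, 3, 7):
                params = random_dense_hmm(rng, n_states)
                codes = rng.integers(0, 20, length)
                seq = "".join(ALPHABET[c] for c in codes)
                assert forward_log_likelihood(params, seq) == pytest.approx(
                    brute_force_forward(params, codes), rel=1e-9
                )
                path, joint = viterbi_decode(params, seq)
                _, bf_joint = brute_force_viterbi(params, codes)
                assert joint == pytest.approx(bf_joint, rel=1e-9)

    def test_tie_break_lowest_state_index(self):
        """Two interchangeable states: the decoded path must stay on the
        lower-indexed one."""
        em = np.full((2, 20), 1 / 20)
        params = HmmParameters(
            state_ids=["a", "b"],
            regions=["globular", "globular"],
            log_initial=np.log([0.5, 0.5]),
            log_transition=np.log([[0.5, 0.5], [0.5, 0.5]]),
            log_emission=np.log(em),
        )
        path, _ = viterbi_decode(params, "AAAAA")
        assert list(path) == [0, 0, 0, 0, 0]

    def test_no_admissible_path_signalled(self):
        """Hand-made zero emission makes every path impossible."""
        em = np.zeros((1, 20))
        em[0, : 10] = 0.1  # letters beyond index 10 have probability zero
        with np.errstate(divide="ignore"):
            log_em = np.log(em)
        params = HmmParameters(
            state_ids=["s0"],
            regions=["globular"],
            log_initial=np.array([0.0]),
            log_transition=np.array([[0.0]]),
            log_emission=log_em,
        )
        with pytest.raises(NoAdmissiblePathError):
            viterbi_decode(params, "YYY")  # Y has zero emission


class TestBaumWelch:
    def test_loglik_never_decreases_on_self_sampled_data(self, rng):
        params = random_dense_hmm(rng, 2)
        seqs = [sample_sequence(params, 25, rng)[0] for _ in range(5)]
        _, trace = baum_welch_fit(params, seqs, max_iter=5)
        assert all(b - a >= -1e-8 for a, b in zip(trace, trace[1:]))

    def test_one_step_matches_enumeration_posteriors(self, rng):
        """Expected-count M-step on 5 short sequences equals the update
        computed from exact path posteriors by enumeration."""
        from tahmm.hmm import PSEUDOCOUNT
        from _oracles import enumerate_paths

        params = random_dense_hmm(rng, 2)
        seq_codes = [rng.integers(0, 20, 4) for _ in range(5)]
        seqs = [
            AminoAcidSequence(f"s{i}", "".join(ALPHABET[c] for c in cs))
            for i, cs in enumerate(seq_codes)
        ]
        n = params.n_states
        init_c = np.zeros(n)
        trans_c = np.zeros((n, n))
        emit_c = np.zeros((n, 20))
        for codes in seq_codes:
            paths = list(enumerate_paths(params, codes))
            logs = np.array([lp for _, lp in paths])
            w = np.exp(logs - logs.max())
            w /= w.sum()
            for (path, _), wp in zip(paths, w):
                init_c[path[0]] += wp
                for t in range(1, len(codes)):
                    trans_c[path[t - 1], path[t]] += wp
                for t, c in enumerate(codes):
                    emit_c[path[t], c] += wp
        init = init_c + PSEUDOCOUNT
        init /= init.sum()
        trans = trans_c + PSEUDOCOUNT
        trans /= trans.sum(axis=1, keepdims=True)
        emit = emit_c + PSEUDOCOUNT
        emit /= emit.sum(axis=1, keepdims=True)
        fitted, _ = baum_welch_fit(params, seqs, max_iter=1)
        np.testing.assert_allclose(np.exp(fitted.log_initial), init, rtol=1e-8)
        np.testing.assert_allclose(
            np.exp(fitted.log_transition), trans, rtol=1e-8
        )
        np.testing.assert_allclose(np.exp(fitted.log_emission), emit, rtol=1e-8)

    def test_structural_zeros_preserved(self, small_ta_dataset):
        model = tahmm.build_ta_model(2)
        seqs = [r.sequence.reversed() for r in small_ta_dataset]
        fitted, trace = baum_welch_fit(model, seqs, max_iter=3)
        assert np.all(np.isneginf(fitted.log_transition[~model.transition_mask]))
        assert np.all(np.isneginf(fitted.log_initial[~model.initial_mask]))
        assert all(b - a >= -1e-8 for a, b in zip(trace, trace[1:]))
        fitted.validate()  # row normalisation holds after training

    def test_model_longer_than_data_warns(self):
        em = np.full((2, 20), 1 / 20)
        params = HmmParameters(
            state_ids=["a", "b"],
            regions=["globular", "globular"],
            log_initial=np.log([1.0, 1e-300]).clip(min=-np.inf),
            log_transition=np.log([[1e-12, 1 - 1e-12], [1e-12, 1 - 1e-12]]),
            log_emission=np.log(em),
        )
        seqs = [AminoAcidSequence("a", "A"), AminoAcidSequence("b", "K")]
        with pytest.warns(UserWarning, match="model longer than data"):
            baum_welch_fit(params, seqs, max_iter=2)

    def test_requires_sequences(self):
        with pytest.raises(Exception):
            baum_welch_fit(single_state_hmm(), [])


class TestSampling:
    def test_degenerate_emission_is_deterministic(self):
        probs = np.zeros(20)
        probs[ALPHABET.index("L")] = 1.0
        params = single_state_hmm(probs)
        seq, path = sample_sequence(params, 5, 0)
        assert seq.residues == "LLLLL"
        assert list(path) == [0] * 5

    def test_same_seed_reproduces(self, ta_model):
        s1, p1 = sample_sequence(ta_model, 60, 99)
        s2, p2 = sample_sequence(ta_model, 60, 99)
        assert s1.residues == s2.residues
        assert np.array_equal(p1, p2)

    def test_initial_state_frequencies_within_binomial_bounds(self, ta_model):
        """First states of 10,000 TA-model samples hit the 0.5/0.5 initial
        distribution within 3 sigma of the binomial."""
        rng = np.random.default_rng(5)
        n = 10_000
        counts = {}
        for _ in range(n):
            _, path = sample_sequence(ta_model, 60, rng)
            counts[path[0]] = counts.get(path[0], 0) + 1
        assert set(counts) <= {0, 2}  # tail_01 or tmd_01
        sigma = math.sqrt(n * 0.25)
        for state in counts:
            assert abs(counts[state] - n * 0.5) < 3 * sigma


class TestSerialization:
    def test_round_trip_is_exact(self, ta_model):
        clone = HmmParameters.from_json(ta_model.to_json())
        np.testing.assert_array_equal(clone.log_initial, ta_model.log_initial)
        np.testing.assert_array_equal(
            clone.log_transition, ta_model.log_transition
        )
        np.testing.assert_array_equal(
            clone.log_emission, ta_model.log_emission
        )
        assert clone.orientation == ta_model.orientation
        assert clone.regions == ta_model.regions

    def test_corrupt_payload_rejected(self, ta_model):
        data = ta_model.to_dict()
        del data["transitions"]
        with pytest.raises(Exception, match="corrupt|transitions"):
            HmmParameters.from_dict(data)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.integers(min_value=1, max_value=3),
    st.integers(min_value=1, max_value=7),
    st.integers(min_value=0, max_value=2**31 - 1),
)
def test_forward_viterbi_enumeration_property(n_states, length, seed):
    """Exhaustive-path equivalence holds over randomly drawn instances."""
    rng = np.random.default_rng(seed)
    params = random_dense_hmm(rng, n_states)
    codes = rng.integers(0, 20, length)
    seq = "".join(ALPHABET[c] for c in codes)
    assert forward_log_likelihood(params, seq) == pytest.approx(
        brute_force_forward(params, codes), rel=1e-9
    )
    _, joint = viterbi_decode(params, seq)
    _, bf_joint = brute_force_viterbi(params, codes)
    assert joint == pytest.approx(bf_joint, rel=1e-9)
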
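"""Frequency-counting fit and forward-backward posterior decoding."""

import math

import numpy as np
import pytest

from tailhmm.hmm_core import (
    NONTAIL,
    TAIL,
    TailHmm,
    backward_log_likelihood,
    call_tails,
    fit,
    load_model,
    posterior_decode,
    save_model,
    viterbi_decode,
)
from tailhmm.synthetic import GeneratorSpec, generate

from oracles import brute_force_posteriors
from conftest import random_model


class TestFit:
    def test_toy_corpus_count_ratios(self, toy_corpus):
        model = fit(toy_corpus, epsilon=0.0)
        np.testing.assert_array_equal(model.pi, [0.5, 0.5])
        np.testing.assert_array_equal(model.A, [[0.5, 0.5], [0.5, 0.5]])
        assert model.B[TAIL]["d1"] == 2 / 3
        assert model.B[TAIL]["d2"] == 1 / 3
        assert model.B[NONTAIL]["d3"] == 2 / 3

    def test_transitions_do_not_cross_genome_boundaries(self):
        # the N->T pair formed by concatenating G1 end and G2 start must
        # not be counted: A[N][T] stays 0
        corpus = [[("a", NONTAIL), ("b", NONTAIL)], [("c", TAIL), ("d", TAIL)]]
        model = fit(corpus)
        assert model.A[1, 0] == 0.0
        assert model.A[0, 1] == 0.0

    def test_all_nontail_corpus_raises(self):
        with pytest.raises(ValueError, match="TAIL"):
            fit([[("a", NONTAIL), ("b", NONTAIL)]])

    def test_single_protein_genomes_raise_for_transitions(self):
        with pytest.raises(ValueError):
            fit([[("a", TAIL)], [("b", NONTAIL)]])

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            fit([])

    def test_duplicated_corpus_gives_identical_parameters(self, toy_corpus):
        m1 = fit(toy_corpus)
        m3 = fit(toy_corpus * 3)
        np.testing.assert_array_equal(m1.pi, m3.pi)
        np.testing.assert_array_equal(m1.A, m3.A)
        assert m1.B == m3.B

    def test_fit_equals_empirical_frequencies(self):
        # counting fit reproduces the corpus's own start/transition
        # frequencies exactly; closeness to the generating chain is a
        # separate sampling-error question
        spec = GeneratorSpec(n_genomes=200, length_range=(30, 50), seed=7)
        corpus = generate(spec)
        seqs = list(corpus.sequences.values())
        model = fit(seqs)
        starts = np.array([
            sum(1 for s in seqs if s[0][1] == TAIL),
            sum(1 for s in seqs if s[0][1] == NONTAIL)])
        np.testing.assert_array_equal(model.pi, starts / starts.sum())
        trans = np.zeros((2, 2))
        idx = {TAIL: 0, NONTAIL: 1}
        for s in seqs:
            for (_, a), (_, b) in zip(s, s[1:]):
                trans[idx[a], idx[b]] += 1
        np.testing.assert_allclose(
            model.A, trans / trans.sum(axis=1, keepdims=True), atol=1e-15)

    def test_global_pi_mode_counts_positions(self, toy_corpus):
        # toy corpus: 3 TAIL of 6 positions either way, but an asymmetric
        # corpus separates the two modes
        corpus = [[("a", TAIL), ("b", NONTAIL), ("c", NONTAIL)]]
        assert fit(corpus, pi_mode="global").pi[0] == pytest.approx(1 / 3)
        assert fit(corpus, pi_mode="start").pi[0] == 1.0


class TestPosteriorDecode:
    def test_length_one_genome_is_bayes_rule(self, rng):
        model = random_model(rng)
        track = posterior_decode(model, ["s0"])
        bt = model.B[TAIL]["s0"] * model.pi[0]
        bn = model.B[NONTAIL]["s0"] * model.pi[1]
        assert track.posteriors[0] == pytest.approx(bt / (bt + bn), abs=1e-12)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(25):
            model = random_model(rng)
            n = int(rng.integers(1, 9))
            obs = [f"s{rng.integers(5)}" for _ in range(n)]
            track = posterior_decode(model, obs)
            expected = brute_force_posteriors(model, obs)
            np.testing.assert_allclose(track.posteriors, expected, atol=1e-10)

    def test_identical_emissions_depend_only_on_chain(self, rng):
        # B_T == B_N: evidence is uninformative, posterior follows the
        # chain alone and still matches exhaustive enumeration
        shared = {f"s{i}": 0.2 * (1 - 1e-4) for i in range(5)}
        model = TailHmm(
            pi=np.array([0.3, 0.7]),
            A=np.array([[0.6, 0.4], [0.2, 0.8]]),
            B={TAIL: dict(shared), NONTAIL: dict(shared)},
            alphabet=frozenset(shared),
        )
        obs = ["s0", "s3", "s1", "s1", "s4"]
        track = posterior_decode(model, obs)
        np.testing.assert_allclose(
            track.posteriors, brute_force_posteriors(model, obs), atol=1e-12
        )
        # any other observation sequence of the same length is equivalent
        track2 = posterior_decode(model, ["s2"] * 5)
        np.testing.assert_allclose(track.posteriors, track2.posteriors, atol=1e-12)

    def test_long_genome_does_not_underflow(self, rng):
        model = random_model(rng)
        obs = [f"s{rng.integers(5)}" for _ in range(10_000)]
        track = posterior_decode(model, obs)
        assert np.all(np.isfinite(track.posteriors))
        assert np.isfinite(track.log_likelihood)

    def test_unseen_symbol_uses_epsilon_mass(self, rng):
        model = random_model(rng)
        track = posterior_decode(model, ["never_seen", "s1"])
        assert np.all(np.isfinite(track.posteriors))

    def test_empty_observations_raise(self, rng):
        with pytest.raises(ValueError):
            posterior_decode(random_model(rng), [])

    def test_posteriors_normalized_and_likelihood_symmetric(self, rng):
        for _ in range(10):
            model = random_model(rng)
            obs = [f"s{rng.integers(5)}" for _ in range(int(rng.integers(2, 50)))]
            track = posterior_decode(model, obs)
            assert np.all((0 <= track.posteriors) & (track.posteriors <= 1))
            # forward and backward passes agree on the sequence likelihood
            assert track.log_likelihood == pytest.approx(
                backward_log_likelihood(model, obs), rel=1e-9
            )


class TestCallTails:
    def test_threshold_calls(self):
        track = posterior_track([0.9, 0.2])
        assert call_tails(track, 0.5).calls == [TAIL, NONTAIL]

    def test_tau_zero_calls_everything(self):
        assert call_tails(posterior_track([0.0, 0.3]), 0.0).calls == [TAIL, TAIL]

    def test_boundary_is_inclusive(self):
        assert call_tails(posterior_track([0.5]), 0.5).calls == [TAIL]

    @pytest.mark.parametrize("tau", [-0.1, 1.1])
    def test_tau_out_of_range(self, tau):
        with pytest.raises(ValueError):
            call_tails(posterior_track([0.5]), tau)


def posterior_track(values):
    from tailhmm.hmm_core import PosteriorTrack

    return PosteriorTrack(genome_id="G", posteriors=np.array(values))


class TestModelPersistence:
    def test_round_trip_identity(self, toy_corpus, tmp_path):
        model = fit(toy_corpus)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(model.pi, back.pi)
        np.testing.assert_array_equal(model.A, back.A)
        assert model.B == back.B
        assert model.alphabet == back.alphabet
        assert model.epsilon == back.epsilon

    def test_large_alphabet_round_trip(self, rng, tmp_path):
        model = random_model(rng, n_symbols=1000)
        path = tmp_path / "big.json"
        save_model(model, path)
        back = load_model(path)
        assert model.B == back.B
        assert len(back.alphabet) == 1000

    def test_invalid_transition_row_rejected_on_load(self, toy_corpus, tmp_path):
        import json

        path = tmp_path / "model.json"
        save_model(fit(toy_corpus), path)
        doc = json.loads(path.read_text())
        doc["A"][TAIL][TAIL] = 0.4  # row now sums to 0.9
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="A row"):
            load_model(path)

    def test_missing_field_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"pi": {"TAIL": 0.5, "NONTAIL": 0.5}}')
        with pytest.raises(ValueError, match="missing field"):
            load_model(path)


class TestViterbi:
    def test_recovers_obvious_path(self, toy_corpus):
        model = fit(toy_corpus)
        path = viterbi_decode(model, ["d1", "d1", "d3", "d3"])
        assert path == [TAIL, TAIL, NONTAIL, NONTAIL]
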
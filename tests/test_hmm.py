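"""HMM fitting, likelihood, decoding, and canonical state labeling."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from mihmm import (
    HMMConfig,
    HMMModel,
    SyntheticSpec,
    ValidationError,
    fit_hmm,
    generate_dataset,
    label_states,
    log_likelihood,
    viterbi_decode,
)
from mihmm.hmm import fit_bank, pad_sequences

from conftest import random_hmm_model


def brute_force_loglik(model, x):
    """Exhaustive sum over all K^T state paths."""
    k, t = model.n_states, len(x)
    lps = []
    for path in itertools.product(range(k), repeat=t):
        lp = np.log(model.pi[path[0]]) + norm.logpdf(x[0], model.means[path[0]], model.sds[path[0]])
        for s in range(1, t):
            lp += np.log(model.A[path[s - 1], path[s]])
            lp += norm.logpdf(x[s], model.means[path[s]], model.sds[path[s]])
        lps.append(lp)
    return lps


class TestForwardOracle:
    def test_t1_closed_form(self):
        rng = np.random.default_rng(1)
        m = random_hmm_model(rng)
        x = 1.7
        expected = np.log(np.sum(m.pi * norm.pdf(x, m.means, m.sds)))
        assert log_likelihood(m, [x]) == pytest.approx(expected, abs=1e-12)

    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            m = random_hmm_model(rng)
            x = rng.uniform(-5, 5, int(rng.integers(2, 7)))
            expected = logsumexp(brute_force_loglik(m, x))
            assert log_likelihood(m, x) == pytest.approx(expected, abs=1e-9)

    def test_empty_sequence_rejected(self):
        m = random_hmm_model(np.random.default_rng(3))
        with pytest.raises(ValidationError):
            log_likelihood(m, [])


class TestBinnedLikelihoodOracle:
    def test_integer_scores_use_bin_probabilities(self):
        """T=1: likelihood equals sum_k pi_k * P(score bin | state k)."""
        from scipy.stats import norm as norm_dist

        rng = np.random.default_rng(8)
        m = random_hmm_model(rng, discretization="bins")
        for v in (-5, -2, 0, 3, 5):
            lo = -np.inf if v == -5 else v - 0.5
            hi = np.inf if v == 5 else v + 0.5
            bins = norm_dist.cdf(hi, m.means, m.sds) - norm_dist.cdf(lo, m.means, m.sds)
            expected = np.log(np.sum(m.pi * bins))
            assert log_likelihood(m, [v]) == pytest.approx(expected, abs=1e-12)

    def test_integer_sequence_matches_enumeration(self):
        from scipy.stats import norm as norm_dist

        rng = np.random.default_rng(9)
        m = random_hmm_model(rng, discretization="bins")

        def binprob(v, k):
            lo = -np.inf if v == -5 else v - 0.5
            hi = np.inf if v == 5 else v + 0.5
            return norm_dist.cdf(hi, m.means[k], m.sds[k]) - norm_dist.cdf(lo, m.means[k], m.sds[k])

        x = rng.integers(-5, 6, 5)
        lps = []
        for path in itertools.product(range(3), repeat=len(x)):
            lp = np.log(m.pi[path[0]]) + np.log(binprob(x[0], path[0]))
            for s in range(1, len(x)):
                lp += np.log(m.A[path[s - 1], path[s]]) + np.log(binprob(x[s], path[s]))
            lps.append(lp)
        assert log_likelihood(m, x) == pytest.approx(logsumexp(lps), abs=1e-9)


class TestViterbi:
    def test_emissions_dominate(self):
        m = HMMModel(
            pi=np.full(3, 1 / 3), A=np.full((3, 3), 1 / 3),
            means=np.array([3.0, 0.0, -3.0]), sds=np.full(3, 0.3),
            emission_probs=None, log_likelihood_trace=[0.0], converged=True,
            config=HMMConfig(),
        )
        assert viterbi_decode(m, [3, 3, -3]).tolist() == [0, 0, 2]

    def test_matches_enumerated_maximum(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            m = random_hmm_model(rng)
            x = rng.uniform(-5, 5, int(rng.integers(2, 7)))
            lps = brute_force_loglik(m, x)
            path = viterbi_decode(m, x)
            lp_path = lps[int(np.ravel_multi_index(path, (3,) * len(x)))]
            assert lp_path == pytest.approx(max(lps), abs=1e-9)

    def test_uniform_model_tie_breaks_to_state_zero(self):
        m = HMMModel(
            pi=np.full(3, 1 / 3), A=np.full((3, 3), 1 / 3),
            means=np.zeros(3), sds=np.ones(3),
            emission_probs=None, log_likelihood_trace=[0.0], converged=True,
            config=HMMConfig(),
        )
        assert viterbi_decode(m, [1, 2, 0, -1]).tolist() == [0, 0, 0, 0]


class TestFit:
    def test_constant_data_forces_occupied_state_mean(self):
        m = fit_hmm([[3] * 40], HMMConfig(max_iter=200, tol=1e-8))
        lab = label_states(m)
        # the dominant (Towards) state's mean collapses to the data value
        assert abs(lab.labeled_means[0] - 3.0) < 0.01

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValidationError, match="insufficient"):
            fit_hmm([[1], [2]], HMMConfig())
        with pytest.raises(ValidationError):
            fit_hmm([], HMMConfig())

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            fit_hmm([[0, 1, 9, 0, 0, 0, 0, 0, 0]], HMMConfig())

    def test_em_loglik_nondecreasing(self, study_sessions, relaxed_config):
        m = fit_hmm(study_sessions.by_quality("high").score_sequences(), relaxed_config)
        trace = np.array(m.log_likelihood_trace)
        assert np.all(np.diff(trace) > -1e-8)

    def test_parameter_recovery(self, study_sessions):
        """60 sessions x length 80 from known truth: A within 0.05, means within 0.3."""
        from mihmm import GeneratorProfile, default_high_profile

        base = default_high_profile()
        prof = GeneratorProfile(name="fix80", pi=base.pi, A=base.A, length_range=(80, 80))
        sset = generate_dataset(SyntheticSpec(n_high=60, n_low=0, high_profile=prof, seed=42))
        lab = label_states(fit_hmm(sset.score_sequences(), HMMConfig()))
        assert lab.gradient_valid
        assert np.max(np.abs(lab.labeled_A - prof.A_array())) < 0.05
        assert np.max(np.abs(lab.labeled_means - np.array(prof.emission_means))) < 0.3

    def test_variance_floor_respected(self):
        m = fit_hmm([[0, 0, 0, 0, 1, 0, 0, 0, 0, 0]], HMMConfig(max_iter=100))
        assert np.all(m.sds >= np.sqrt(m.config.variance_floor) - 1e-12)

    def test_categorical_constant_data_flags_degenerate(self):
        cfg = HMMConfig(emission_family="categorical11", max_iter=20)
        with pytest.warns(UserWarning, match="degenerate"):
            m = fit_hmm([[2] * 20], cfg)
        assert m.degenerate

    def test_categorical_family_fits(self, study_sessions):
        cfg = HMMConfig(emission_family="categorical11", max_iter=40, tol=1e-4)
        m = fit_hmm(study_sessions.by_quality("high").score_sequences(), cfg)
        assert m.emission_probs.shape == (3, 11)
        assert np.allclose(m.emission_probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(np.array(m.log_likelihood_trace)) > -1e-8)

    def test_fix_start_from_first_score(self):
        seqs = [[3, 1, 2, 0, -1], [-2, 0, 1, 1, 0], [0, 0, 1, -1, 2], [4, 2, 1, 0, 0]]
        cfg = HMMConfig(max_iter=30, tol=1e-4, fix_start_from_first_score=True)
        m = fit_hmm(seqs, cfg)
        # first-score signs: 2 positive, 1 zero, 1 negative over 4 sequences
        assert m.pi.tolist() == pytest.approx([0.5, 0.25, 0.25])

    def test_restarts_keep_best_loglik(self, short_profile):
        sset = generate_dataset(SyntheticSpec(n_high=6, n_low=0, high_profile=short_profile, seed=9))
        base = HMMConfig(max_iter=40, tol=1e-4)
        restarted = HMMConfig(max_iter=40, tol=1e-4, n_restarts=3, seed=5)
        ll0 = fit_hmm(sset.score_sequences(), base).log_likelihood_trace[-1]
        ll1 = fit_hmm(sset.score_sequences(), restarted).log_likelihood_trace[-1]
        assert ll1 >= ll0 - 1e-6


class TestBankConsistency:
    def test_bank_fit_matches_individual_fits(self, short_profile):
        sset = generate_dataset(SyntheticSpec(n_high=10, n_low=0, high_profile=short_profile, seed=13))
        seqs = sset.score_sequences()
        cfg = HMMConfig(max_iter=50, tol=1e-4)
        obs, lengths, _ = pad_sequences(seqs)
        weights = np.zeros((2, len(seqs)))
        weights[0, :5] = 1.0
        weights[1, 5:] = 1.0
        bank = fit_bank(obs, lengths, weights, cfg)
        for m, sel in enumerate([seqs[:5], seqs[5:]]):
            solo = fit_hmm(sel, cfg)
            assert np.allclose(bank.A[m], solo.A, atol=1e-8)
            assert np.allclose(bank.means[m], solo.means, atol=1e-8)
            assert bank.loglik[m] == pytest.approx(solo.log_likelihood_trace[-1], abs=1e-6)


class TestLabeling:
    def _model_with_means(self, means, A=None):
        k = len(means)
        A = np.full((k, k), 1 / k) if A is None else np.asarray(A, float)
        return HMMModel(
            pi=np.full(k, 1 / k), A=A, means=np.array(means, float), sds=np.ones(k),
            emission_probs=None, log_likelihood_trace=[0.0], converged=True,
            config=HMMConfig(n_states=k),
        )

    def test_sorted_by_descending_mean(self):
        lab = label_states(self._model_with_means([3.1, -2.8, 0.2]))
        assert lab.state_order == (0, 2, 1)
        assert lab.gradient_valid
        assert lab.labels == ("Towards Change", "Non-Determined", "Away From Change")

    def test_tied_means_invalidate_gradient(self):
        lab = label_states(self._model_with_means([0.2, 0.2, -1.0]))
        assert not lab.gradient_valid

    def test_permuting_states_leaves_labeled_A_unchanged(self):
        rng = np.random.default_rng(6)
        A = rng.dirichlet(np.ones(3), size=3)
        means = [2.0, 0.0, -2.0]
        base = label_states(self._model_with_means(means, A))
        perm = [2, 0, 1]
        m2 = self._model_with_means(
            [means[i] for i in perm], A[np.ix_(perm, perm)]
        )
        assert np.allclose(label_states(m2).labeled_A, base.labeled_A)

    def test_canonicalization_idempotent(self):
        rng = np.random.default_rng(7)
        m = random_hmm_model(rng)
        lab = label_states(m)
        relabeled = HMMModel(
            pi=lab.labeled_pi, A=lab.labeled_A, means=lab.labeled_means,
            sds=m.sds[list(lab.state_order)], emission_probs=None,
            log_likelihood_trace=[0.0], converged=True, config=m.config,
        )
        assert label_states(relabeled).state_order == (0, 1, 2)


class TestSerialization:
    def test_json_round_trip_bit_stable(self, tmp_path, study_sessions, relaxed_config):
        m = fit_hmm(study_sessions.by_quality("low").score_sequences(), relaxed_config)
        path = tmp_path / "model.json"
        m.save(path)
        back = HMMModel.load(path)
        assert np.array_equal(back.A, m.A)
        assert np.array_equal(back.pi, m.pi)
        assert np.array_equal(back.means, m.means)
        assert back.config == m.config
        back.save(tmp_path / "model2.json")
        assert (tmp_path / "model2.json").read_bytes() == path.read_bytes()


class TestHmmlearnCrossCheck:
    def test_forward_loglik_agrees_with_hmmlearn(self, study_sessions, relaxed_config):
        """Independent implementation check: score a fixed model both ways."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        seqs = study_sessions.by_quality("high").score_sequences()[:5]
        cfg = HMMConfig(max_iter=60, tol=1e-4, discretization="none")
        m = fit_hmm(seqs, cfg)
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        ref.startprob_ = m.pi
        ref.transmat_ = m.A
        ref.means_ = m.means.reshape(-1, 1)
        ref.covars_ = (m.sds**2).reshape(-1, 1)
        for seq in seqs:
            x = np.asarray(seq, float).reshape(-1, 1)
            assert log_likelihood(m, seq) == pytest.approx(ref.score(x), abs=1e-8)
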
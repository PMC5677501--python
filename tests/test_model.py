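"""Model probability pieces and the forward-algorithm likelihood oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

import jollyseber as js
from jollyseber.catalog import CaptureHistoryMatrix, CatalogData, CovariateSet, KnownStateMatrix
from jollyseber.model import forward_pass


def make_params(T, N, **kw):
    base = dict(
        beta1=2.2,
        beta2=-0.7,
        beta3=0.3,
        alpha1=1.0,
        alpha2=0.8,
        eps=np.zeros(T - 1),
        time=np.zeros(T),
        gamma=np.full(T, 0.3),
        zeta=np.zeros(N),
    )
    base.update(kw)
    return js.ModelParameters(**base)


# ---------------------------------------------------------------------------
# closed-form probability pieces


class TestSurvivalProb:
    def test_logit_zero_is_half(self):
        p = make_params(3, 1, beta1=0.0, beta2=0.0, beta3=0.0)
        assert js.survival_prob(p, sex=0, adult=0, age=0, t=0) == pytest.approx(0.5)

    def test_age_slope_is_an_odds_ratio(self):
        # a slope of 0.296 multiplies the survival odds by e^0.296 ~ 1.34 per class
        p = make_params(3, 1, beta1=1.0, beta2=0.0, beta3=0.296)
        odds = lambda a: js.survival_prob(p, 0, 0, a, 0) / (1 - js.survival_prob(p, 0, 0, a, 0))
        assert odds(3) / odds(2) == pytest.approx(np.exp(0.296), rel=1e-12)

    def test_adult_male_scale(self):
        # logit of 4.18 corresponds to survival ~0.985
        p = make_params(3, 1, beta1=2.2, beta2=0.0, beta3=(4.18 - 2.2) / 5)
        assert js.survival_prob(p, sex=0, adult=1, age=5, t=0) == pytest.approx(
            expit(4.18), abs=1e-12
        )
        assert js.survival_prob(p, 0, 1, 5, 0) == pytest.approx(0.985, abs=5e-4)

    def test_age_out_of_range_errors(self):
        with pytest.raises(ValueError):
            js.survival_prob(make_params(3, 1), 0, 0, 6, 0)

    def test_monotone_in_age_slope(self):
        lo = make_params(3, 1, beta3=0.1)
        hi = make_params(3, 1, beta3=0.4)
        for age in range(1, 6):
            assert js.survival_prob(hi, 0, 0, age, 0) > js.survival_prob(lo, 0, 0, age, 0)
        assert js.survival_prob(hi, 0, 0, 0, 0) == js.survival_prob(lo, 0, 0, 0, 0)


class TestCaptureProb:
    def test_logit_zero_is_half(self):
        p = make_params(3, 1, alpha1=0.0, alpha2=0.0)
        assert js.capture_prob(p, sex=1, t=0) == pytest.approx(0.5)

    def test_male_independent_of_female_intercept(self):
        a = make_params(3, 1, alpha1=5.0)
        b = make_params(3, 1, alpha1=-5.0)
        assert js.capture_prob(a, sex=0, t=1) == js.capture_prob(b, sex=0, t=1)

    def test_logistic_evaluation(self):
        p = make_params(3, 1, alpha1=1.386, alpha2=0.0)
        assert js.capture_prob(p, sex=1, t=0) == pytest.approx(0.800, abs=5e-4)


class TestTransitionAndObservation:
    def test_dead_row_absorbing(self):
        m = js.transition_matrix(make_params(3, 1), 0, 1, 5, 0)
        np.testing.assert_allclose(m[2], [0, 0, 1])

    def test_zero_entry_keeps_not_entered(self):
        p = make_params(3, 1, gamma=np.zeros(3))
        m = js.transition_matrix(p, 0, 1, 5, 0)
        np.testing.assert_allclose(m[0], [1, 0, 0])

    @given(
        st.floats(0, 1),
        st.floats(-5, 5),
        st.floats(-5, 5),
        st.floats(-2, 2),
        st.integers(0, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_rows_sum_to_one(self, g, b1, b3, eps, age):
        p = make_params(3, 1, beta1=b1, beta3=b3, eps=np.full(2, eps), gamma=np.full(3, g))
        m = js.transition_matrix(p, 1, 1, age, 0)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_observation_table(self):
        assert js.observation_prob(1, 0.9) == 0.0
        assert js.observation_prob(3, 0.9) == 0.0
        assert js.observation_prob(2, 0.9) == 0.9
        with pytest.raises(ValueError):
            js.observation_prob(0, 0.5)


# ---------------------------------------------------------------------------
# forward algorithm vs brute-force enumeration


def brute_force_loglik(hist, known, phi, p, gamma):
    """Enumerate every latent state sequence; independent of the forward code."""
    N, T = hist.shape
    total = np.zeros(N)
    for i in range(N):
        prob_sum = 0.0
        for seq in itertools.product((1, 2, 3), repeat=T):
            pr = {1: 1 - gamma[0], 2: gamma[0], 3: 0.0}[seq[0]]
            for t in range(1, T):
                prev, cur = seq[t - 1], seq[t]
                g, ph = gamma[t], phi[i, t - 1]
                trans = {
                    (1, 1): 1 - g, (1, 2): g, (1, 3): 0.0,
                    (2, 2): ph, (2, 3): 1 - ph, (2, 1): 0.0,
                    (3, 3): 1.0, (3, 1): 0.0, (3, 2): 0.0,
                }[(prev, cur)]
                pr *= trans
            for t in range(T):
                if known[i, t] and seq[t] != known[i, t]:
                    pr = 0.0
                seen_p = p[i, t] if seq[t] == 2 else 0.0
                pr *= seen_p if hist[i, t] == 1 else 1.0 - seen_p
            prob_sum += pr
        total[i] = np.log(prob_sum) if prob_sum > 0 else -np.inf
    return total


def known_to_mask(known):
    N, T = known.shape
    mask = np.ones((N, 3, T), dtype=bool)
    for code in (1, 2, 3):
        hit = known == code
        for s in range(3):
            if s != code - 1:
                mask[:, s, :] &= ~hit
    return mask


def random_dataset(rng, N, T):
    """Random but self-consistent (history, known-state) pair from a true path."""
    hist = np.zeros((N, T), dtype=np.int8)
    known = np.zeros((N, T), dtype=np.int8)
    for i in range(N):
        entry = rng.integers(0, T + 1)  # T means never enters
        death = rng.integers(entry, T + 2)
        path = np.ones(T, dtype=np.int8)
        path[entry:] = 2
        if death <= T:
            path[death:] = 3
        hist[i] = (path == 2) & (rng.random(T) < 0.6)
        reveal = rng.random(T) < 0.4
        known[i, reveal] = path[reveal]
        known[i, hist[i] == 1] = np.where(
            rng.random((hist[i] == 1).sum()) < 0.5, 2, known[i, hist[i] == 1]
        )
        # seen years are known alive or unknown, never a contradiction
        known[i, (hist[i] == 1) & (known[i] != 2)] = 0
    return hist, known


class TestForwardOracle:
    def test_hand_case_two_occasions(self):
        # one individual, history (1, 0), everything latent
        hist = np.array([[1, 0]], dtype=np.int8)
        known = np.zeros((1, 2), dtype=np.int8)
        phi = np.array([[0.9]])
        p = np.array([[0.7, 0.6]])
        gamma = np.array([0.4, 0.5])
        got = forward_pass(hist, known_to_mask(known), phi, p, gamma)
        want = brute_force_loglik(hist, known, phi, p, gamma)
        np.testing.assert_allclose(got, want, atol=1e-12)
        # and against an explicit hand enumeration of the two live paths:
        # enter@1&seen, then survive-unseen or die
        hand = 0.4 * 0.7 * (0.9 * 0.4 + 0.1 * 1.0)
        assert got[0] == pytest.approx(np.log(hand), abs=1e-12)

    def test_never_enters_has_probability_one(self):
        hist = np.zeros((1, 4), dtype=np.int8)
        known = np.zeros((1, 4), dtype=np.int8)
        phi = np.full((1, 3), 0.9)
        p = np.full((1, 4), 0.8)
        gamma = np.zeros(4)
        ll = forward_pass(hist, known_to_mask(known), phi, p, gamma)
        assert ll[0] == pytest.approx(0.0, abs=1e-15)

    def test_perfect_detection_contradiction(self):
        hist = np.array([[1, 0, 1]], dtype=np.int8)
        known = np.zeros((1, 3), dtype=np.int8)
        phi = np.full((1, 2), 0.9)
        p = np.ones((1, 3))
        gamma = np.full(3, 0.5)
        ll = forward_pass(hist, known_to_mask(known), phi, p, gamma)
        assert ll[0] == -np.inf

    @pytest.mark.parametrize("N,T", [(1, 2), (2, 3), (3, 4), (3, 5), (1, 5), (2, 5)])
    def test_matches_enumeration_on_random_datasets(self, N, T):
        rng = np.random.default_rng(100 * N + T)
        for _ in range(12):
            hist, known = random_dataset(rng, N, T)
            phi = rng.uniform(0.3, 0.99, size=(N, T - 1))
            p = rng.uniform(0.1, 0.95, size=(N, T))
            gamma = rng.uniform(0.05, 0.8, size=T)
            got = forward_pass(hist, known_to_mask(known), phi, p, gamma)
            want = brute_force_loglik(hist, known, phi, p, gamma)
            finite = np.isfinite(want)
            np.testing.assert_allclose(got[finite], want[finite], atol=1e-10)
            assert np.array_equal(np.isfinite(got), finite)

    def test_model_loglik_agrees_with_enumeration(self):
        """Through the full model surface (covariates -> phi/p -> forward)."""
        rng = np.random.default_rng(0)
        N, T = 3, 4
        hist, _ = random_dataset(rng, N, T)
        hist[0, 1] = 1  # ensure at least one sighting
        known = np.zeros((N, T), dtype=np.int8)
        ch = CaptureHistoryMatrix([f"w{i}" for i in range(N)], np.arange(1990, 1990 + T), hist)
        ks = KnownStateMatrix(known)
        cov = CovariateSet(
            sex=np.array([1.0, 0.0, 1.0]),
            age=np.tile(np.array([5, 2, 0])[:, None], (1, T)).astype(np.int8),
            adult=np.tile(np.array([1, 0, 0])[:, None], (1, T)).astype(np.int8),
        )
        model = js.JollySeberModel(CatalogData(ch, ks, cov))
        params = make_params(T, N, zeta=rng.normal(0, 0.5, N), eps=rng.normal(0, 0.3, T - 1))
        sex = cov.sex
        phi = expit(
            params.beta1
            + params.beta2 * sex[:, None] * cov.adult[:, :-1]
            + params.beta3 * cov.age[:, :-1]
            + params.eps[None, :]
        )
        p = expit(
            params.alpha1 * sex[:, None]
            + params.alpha2 * (1 - sex[:, None])
            + params.time[None, :]
            + params.zeta[:, None]
        )
        want = brute_force_loglik(hist, known, phi, p, params.gamma).sum()
        assert model.log_likelihood(params) == pytest.approx(want, abs=1e-10)


class TestLogPrior:
    def test_outside_uniform_support(self):
        model = _tiny_model()
        params = make_params(model.T, model.N, beta1=11.0)
        assert model.log_prior(params) == -np.inf

    def test_finite_at_reasonable_values(self):
        model = _tiny_model()
        assert np.isfinite(model.log_prior(make_params(model.T, model.N)))

    def test_normal_terms_match_closed_form(self):
        from scipy.stats import beta as beta_dist, norm

        model = _tiny_model()
        eps = np.array([0.2, -0.4])
        zeta = np.array([0.1, -0.2, 0.3])
        p1 = make_params(model.T, model.N, eps=eps, zeta=zeta, delta=0.5, sigma=0.8)
        p0 = make_params(
            model.T, model.N, eps=np.zeros(2), zeta=np.zeros(3), delta=0.5, sigma=0.8
        )
        diff = model.log_prior(p1) - model.log_prior(p0)
        want = (
            norm.logpdf(eps, 0, 0.5).sum()
            - norm.logpdf(np.zeros(2), 0, 0.5).sum()
            + norm.logpdf(zeta, 0, 0.8).sum()
            - norm.logpdf(np.zeros(3), 0, 0.8).sum()
        )
        assert diff == pytest.approx(want, abs=1e-10)


def _tiny_model():
    hist = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 1]], dtype=np.int8)
    ch = CaptureHistoryMatrix(["a", "b", "c"], np.arange(1990, 1993), hist)
    ks = KnownStateMatrix(np.zeros((3, 3), dtype=np.int8))
    cov = CovariateSet(
        sex=np.array([1.0, 0.0, np.nan]),
        age=np.full((3, 3), 5, dtype=np.int8),
        adult=np.ones((3, 3), dtype=np.int8),
    )
    return js.JollySeberModel(CatalogData(ch, ks, cov))


def test_invalid_known_pattern_rejected_by_model():
    hist = np.array([[1, 0]], dtype=np.int8)
    ch = CaptureHistoryMatrix(["a"], np.arange(1990, 1992), hist)
    with pytest.raises(Exception):
        KnownStateMatrix(np.array([[3, 2]], dtype=np.int8))
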
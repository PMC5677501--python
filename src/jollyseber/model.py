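"""Hierarchical multistate Jolly-Seber model for open-population mark-recapture.

The population process is a three-state hidden Markov chain per individual
(not-yet-entered, alive, dead) observed through imperfect detection:

* entry:     a not-yet-entered individual enters at occasion t with
             probability ``gamma_t`` (entry at the first occasion means being
             alive when the study starts);
* survival:  ``logit(phi_it) = beta1 + beta2 * sex_i * adult_it
             + beta3 * age_it + eps_t`` so ``beta1`` is calf survival on the
             logit scale, ``beta2`` the added effect of being an adult female,
             ``beta3`` a linear age effect, and ``eps_t ~ N(0, delta)`` a year
             random effect on each between-occasion interval;
* detection: ``logit(p_it) = alpha1 * sex_i + alpha2 * (1 - sex_i)
             + time_t + zeta_i`` with the first year's time effect fixed to 0
             and ``zeta_i ~ N(0, sigma)`` capturing individual catchability;
* death is absorbing and dead (or not-yet-entered) individuals are never seen.

Capture histories are augmented with all-zero pseudo-individuals so that the
entry probabilities determine how many never-seen individuals the posterior
adds to the population (parameter-expanded data augmentation).

The likelihood marginalizes the latent state sequence of each individual with
the forward algorithm, constrained to agree with every known state (alive
years between sightings, discovered deaths, not-entered before known births).
Latent-state draws needed for abundance are recovered by backward sampling
from the same forward quantities, which is distribution-identical to sampling
the states directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import beta as beta_dist

from .catalog import (
    CatalogData,
    CaptureHistoryMatrix,
    CovariateSet,
    KnownStateMatrix,
    MAX_AGE_CLASS,
    STATE_UNKNOWN,
    validate_state_pattern,
)

__all__ = [
    "ModelParameters",
    "PriorBounds",
    "JollySeberModel",
    "survival_prob",
    "capture_prob",
    "transition_matrix",
    "observation_prob",
]

# floating-point safety floor for probabilities entering logs
P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-15


@dataclass
class PriorBounds:
    """Support of the vague priors (defaults follow the fitted model)."""

    logit_low: float = -10.0
    logit_high: float = 10.0
    sd_low: float = 0.001
    sd_high: float = 10.0
    rho_a: float = 5.0
    rho_b: float = 5.0


@dataclass
class ModelParameters:
    """One point in parameter space.

    ``eps`` has one entry per between-occasion interval (T-1 of them),
    ``time`` and ``gamma`` one per occasion (T), with ``time[0]`` fixed at 0.
    ``zeta`` has one entry per (real + augmented) individual.
    """

    beta1: float
    beta2: float
    beta3: float
    alpha1: float
    alpha2: float
    eps: np.ndarray
    time: np.ndarray
    gamma: np.ndarray
    zeta: np.ndarray
    delta: float = 1.0
    sigma: float = 1.0
    rho: float = 0.5

    def __post_init__(self):
        self.eps = np.atleast_1d(np.asarray(self.eps, dtype=float))
        self.time = np.atleast_1d(np.asarray(self.time, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.zeta = np.atleast_1d(np.asarray(self.zeta, dtype=float))
        if self.time[0] != 0.0:
            raise ValueError("time effect of the first survey year is fixed at 0")
        if not (self.delta > 0 and self.sigma > 0):
            raise ValueError("delta and sigma must be positive")
        if np.any((self.gamma < 0) | (self.gamma > 1)):
            raise ValueError("entry probabilities must lie in [0, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")


def survival_prob(params: ModelParameters, sex: int, adult: int, age: int, t: int) -> float:
    """Annual survival probability for the interval starting at occasion ``t``."""
    if not 0 <= age <= MAX_AGE_CLASS:
        raise ValueError(f"age class must be 0..{MAX_AGE_CLASS}, got {age}")
    lp = params.beta1 + params.beta2 * sex * adult + params.beta3 * age + params.eps[t]
    return float(expit(lp))


def capture_prob(params: ModelParameters, sex: int, t: int, zeta: float = 0.0) -> float:
    """Detection probability of an alive individual at occasion ``t``."""
    lp = params.alpha1 * sex + params.alpha2 * (1 - sex) + params.time[t] + zeta
    return float(expit(lp))


def transition_matrix(
    params: ModelParameters, sex: int, adult: int, age: int, t: int
) -> np.ndarray:
    """3x3 state-transition matrix for the interval from occasion ``t`` to ``t+1``.

    Rows/columns are ordered (not entered, alive, dead); entry happens with
    probability ``gamma[t+1]``, survival with the individual's ``phi`` for
    interval ``t``, and death is absorbing.
    """
    phi = survival_prob(params, sex, adult, age, t)
    g = float(params.gamma[t + 1])
    return np.array(
        [
            [1.0 - g, g, 0.0],
            [0.0, phi, 1.0 - phi],
            [0.0, 0.0, 1.0],
        ]
    )


def observation_prob(state: int, p: float) -> float:
    """Probability of being seen given the latent state (alive: p, else 0)."""
    if state not in (1, 2, 3):
        raise ValueError(f"state must be 1, 2 or 3, got {state}")
    return float(p) if state == 2 else 0.0


def _clip(p):
    return np.clip(p, P_FLOOR, P_CEIL)


try:  # compiled kernel for the likelihood hot loop; numpy path remains the reference
    import numba as _numba

    @_numba.njit(cache=True, fastmath=False)
    def _forward_kernel(hist, mask, phi, p, gamma):  # pragma: no cover - jit
        N, T = hist.shape
        ll = np.zeros(N)
        for i in range(N):
            a0 = 1.0 - gamma[0]
            a1 = gamma[0]
            a2 = 0.0
            lli = 0.0
            dead = False
            for t in range(T):
                if t > 0:
                    ph = phi[i, t - 1]
                    g = gamma[t]
                    b0 = a0 * (1.0 - g)
                    b1 = a0 * g + a1 * ph
                    b2 = a1 * (1.0 - ph) + a2
                    a0, a1, a2 = b0, b1, b2
                if not mask[i, 0, t]:
                    a0 = 0.0
                if not mask[i, 1, t]:
                    a1 = 0.0
                if not mask[i, 2, t]:
                    a2 = 0.0
                if hist[i, t] == 1:
                    a0 = 0.0
                    a2 = 0.0
                    a1 *= p[i, t]
                else:
                    a1 *= 1.0 - p[i, t]
                c = a0 + a1 + a2
                if c <= 0.0:
                    dead = True
                    break
                lli += np.log(c)
                a0 /= c
                a1 /= c
                a2 /= c
            ll[i] = -np.inf if dead else lli
        return ll

except ImportError:  # pragma: no cover
    _forward_kernel = None


def forward_pass(hist, mask, phi, p, gamma, keep_alphas=False):
    """Forward algorithm over all individuals at once.

    Parameters
    ----------
    hist : (N, T) int array of 0/1 observations.
    mask : (N, 3, T) boolean array; False forbids a latent state at (i, t).
    phi : (N, T-1) survival for each interval.
    p : (N, T) detection for each occasion.
    gamma : (T,) entry probabilities.

    Returns
    -------
    ll : (N,) per-individual log-likelihoods (-inf where the known states or
        observations are impossible under the parameters).
    alphas : (N, 3, T) normalized filtered state distributions, only when
        ``keep_alphas`` is True (used for backward sampling).
    """
    if not keep_alphas and _forward_kernel is not None:
        return _forward_kernel(
            np.ascontiguousarray(hist),
            np.ascontiguousarray(mask),
            np.ascontiguousarray(phi),
            np.ascontiguousarray(p),
            np.ascontiguousarray(gamma),
        )
    N, T = hist.shape
    ll = np.zeros(N)
    dead_flag = np.zeros(N, dtype=bool)
    alphas = np.empty((N, 3, T)) if keep_alphas else None
    a = np.empty((N, 3))
    seen_mat = hist == 1
    for t in range(T):
        if t == 0:
            a[:, 0] = 1.0 - gamma[0]
            a[:, 1] = gamma[0]
            a[:, 2] = 0.0
        else:
            ph = phi[:, t - 1]
            g = gamma[t]
            a0, a1, a2 = a[:, 0].copy(), a[:, 1].copy(), a[:, 2].copy()
            a[:, 0] = a0 * (1.0 - g)
            a[:, 1] = a0 * g + a1 * ph
            a[:, 2] = a1 * (1.0 - ph) + a2
        a *= mask[:, :, t]
        seen = seen_mat[:, t]
        pe = p[:, t]
        a[:, 0] *= ~seen
        a[:, 1] *= np.where(seen, pe, 1.0 - pe)
        a[:, 2] *= ~seen
        c = a.sum(axis=1)
        dead = c <= 0.0
        dead_flag |= dead
        c_safe = np.where(dead, 1.0, c)
        ll += np.log(c_safe)
        a /= c_safe[:, None]
        a[dead] = 1.0 / 3.0  # keep propagating; row is already -inf
        if keep_alphas:
            alphas[:, :, t] = a
    ll[dead_flag] = -np.inf
    if keep_alphas:
        return ll, alphas
    return ll


def backward_sample(rng, alphas, phi, gamma):
    """Draw one latent-state path per individual given forward quantities.

    Returns an (N, T) int8 array over {1, 2, 3}.
    """
    N, _, T = alphas.shape
    states = np.empty((N, T), dtype=np.int8)
    s = _categorical_rows(rng, alphas[:, :, T - 1])
    states[:, T - 1] = s
    for t in range(T - 2, -1, -1):
        g = gamma[t + 1]
        ph = phi[:, t]
        w = np.empty((N, 3))
        nxt = states[:, t + 1]
        # transition probabilities into the sampled next state, from each state
        w[:, 0] = np.select([nxt == 0, nxt == 1], [1.0 - g, g], 0.0)
        w[:, 1] = np.select([nxt == 1, nxt == 2], [ph, 1.0 - ph], 0.0)
        w[:, 2] = (nxt == 2).astype(float)
        w *= alphas[:, :, t]
        states[:, t] = _categorical_rows(rng, w)
    return states + 1  # 1-based codes


def _categorical_rows(rng, w):
    tot = w.sum(axis=1, keepdims=True)
    bad = tot[:, 0] <= 0
    if bad.any():
        w = w.copy()
        w[bad] = 1.0
        tot = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w / tot, axis=1)
    u = rng.random((w.shape[0], 1))
    return (u > cum[:, :2]).sum(axis=1)


class JollySeberModel:
    """Multistate Jolly-Seber model bound to a prepared dataset.

    Parameters
    ----------
    data : CatalogData
        Aligned capture histories, known states and covariates, typically
        produced by :meth:`jollyseber.catalog.CatalogData.from_records` and
        already augmented.
    prior_bounds : PriorBounds, optional

    Examples
    --------
    >>> data = CatalogData.from_records(records, 1990, 2015, n_aug=200)
    >>> model = JollySeberModel(data)
    >>> results = model.fit(chains=3, n_adapt_burn=5000, n_samples=20000, seed=7)
    >>> results.summary()
    """

    def __init__(self, data: CatalogData, prior_bounds: PriorBounds | None = None):
        self.data = data
        self.prior = prior_bounds or PriorBounds()
        self.hist = np.asarray(data.histories.histories, dtype=np.int8)
        self.years = np.asarray(data.histories.years)
        self.N, self.T = self.hist.shape
        validate_state_pattern(data.known_states.states)
        self.mask = self._build_mask(data.known_states.states)
        self.age = np.asarray(data.covariates.age, dtype=float)
        self.adult = np.asarray(data.covariates.adult, dtype=float)
        self.sex_obs = np.asarray(data.covariates.sex, dtype=float)
        self.missing_sex = np.isnan(self.sex_obs)
        # any state-2 cell must be compatible with the observation model
        impossible = (self.hist == 1) & ~self.mask[:, 1, :]
        if impossible.any():
            raise ValueError("an individual was seen in a year it is known dead/not entered")

    @classmethod
    def from_records(
        cls, records, first_year, last_year, pre_study_records=(), n_aug=200, **kw
    ) -> "JollySeberModel":
        data = CatalogData.from_records(
            records, first_year, last_year, pre_study_records, n_aug=n_aug
        )
        return cls(data, **kw)

    @staticmethod
    def _build_mask(states) -> np.ndarray:
        N, T = states.shape
        mask = np.ones((N, 3, T), dtype=bool)
        for code in (1, 2, 3):
            known = states == code
            for s in range(3):
                if s != code - 1:
                    mask[:, s, :] &= ~known
        return mask

    # ---- probability pieces -------------------------------------------------

    def _phi_matrix(self, params: ModelParameters, sex: np.ndarray) -> np.ndarray:
        """(N, T-1) survival for each interval, using covariates at the interval start."""
        lp = (
            params.beta1
            + params.beta2 * sex[:, None] * self.adult[:, :-1]
            + params.beta3 * self.age[:, :-1]
            + params.eps[None, :]
        )
        return _clip(expit(lp))

    def _p_matrix(self, params: ModelParameters, sex: np.ndarray) -> np.ndarray:
        lp = (
            params.alpha1 * sex[:, None]
            + params.alpha2 * (1.0 - sex[:, None])
            + params.time[None, :]
            + params.zeta[:, None]
        )
        return _clip(expit(lp))

    def _resolve_sex(self, params: ModelParameters, imputed=None) -> np.ndarray:
        sex = self.sex_obs.copy()
        if imputed is not None:
            sex[self.missing_sex] = imputed[self.missing_sex]
        else:
            sex[self.missing_sex] = params.rho  # expected-value plug-in
        return sex

    def loglik_by_individual(
        self, params: ModelParameters, imputed_sex=None, keep_alphas=False
    ):
        """Per-individual marginal log-likelihood via the forward algorithm.

        Missing sexes use ``imputed_sex`` (0/1 per individual) when given,
        otherwise the expected value ``rho`` as a deterministic plug-in.
        """
        sex = self._resolve_sex(params, imputed_sex)
        phi = self._phi_matrix(params, sex)
        p = self._p_matrix(params, sex)
        return forward_pass(self.hist, self.mask, phi, p, params.gamma, keep_alphas)

    def log_likelihood(self, params: ModelParameters, imputed_sex=None) -> float:
        return float(self.loglik_by_individual(params, imputed_sex).sum())

    def log_prior(self, params: ModelParameters) -> float:
        """Joint log prior density.

        Uniform(-10, 10) on every fixed logit-scale effect (including each
        free time effect), N(0, delta) on the year effects, N(0, sigma) on
        individual catchability, Uniform(0.001, 10) on both standard
        deviations, Uniform(0, 1) on each entry probability and Beta(5, 5) on
        the probability that an unknown-sex individual is female.
        """
        b = self.prior
        flat = np.array(
            [params.beta1, params.beta2, params.beta3, params.alpha1, params.alpha2]
        )
        flat = np.concatenate([flat, params.time[1:]])
        if np.any((flat < b.logit_low) | (flat > b.logit_high)):
            return -np.inf
        if not (b.sd_low <= params.delta <= b.sd_high):
            return -np.inf
        if not (b.sd_low <= params.sigma <= b.sd_high):
            return -np.inf
        if np.any((params.gamma < 0) | (params.gamma > 1)):
            return -np.inf
        if not 0 < params.rho < 1:
            return -np.inf
        span = b.logit_high - b.logit_low
        lp = -len(flat) * np.log(span)
        lp -= 2.0 * np.log(b.sd_high - b.sd_low)  # delta and sigma, uniform
        lp += _normal_logpdf(params.eps, params.delta).sum()
        lp += _normal_logpdf(params.zeta, params.sigma).sum()
        lp += beta_dist.logpdf(params.rho, b.rho_a, b.rho_b)
        return float(lp)

    def log_posterior(self, params: ModelParameters, imputed_sex=None) -> float:
        lp = self.log_prior(params)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_likelihood(params, imputed_sex)

    # ---- fitting ------------------------------------------------------------

    def fit(
        self,
        chains: int = 3,
        n_adapt_burn: int = 5000,
        n_samples: int = 20000,
        seed: int | None = None,
        thin: int = 1,
        store_states: bool = False,
        progress: bool = False,
    ):
        """Sample the posterior with an adaptive Metropolis-within-Gibbs sampler.

        Defaults mirror the reference protocol: 3 chains, 5,000 adaptation +
        burn-in iterations, 20,000 retained samples per chain. Missing sexes
        are imputed inside the sampler; latent states are backward-sampled per
        retained draw to produce abundance ``N_t`` (total and by sex).

        Returns a :class:`jollyseber.results.JollySeberResults`.
        """
        from .sampler import run_chains

        return run_chains(
            self,
            chains=chains,
            n_adapt_burn=n_adapt_burn,
            n_samples=n_samples,
            seed=seed,
            thin=thin,
            store_states=store_states,
            progress=progress,
        )

    # alias matching the field's verb
    sample_posterior = fit


def _normal_logpdf(x, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * (np.asarray(x) / sd) ** 2
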
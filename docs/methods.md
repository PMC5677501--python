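# Methods

## The model

`jollyseber` fits an open-population Jolly–Seber model in state–space form to
annual photo-identification capture histories. Each individual *i* follows a
three-state Markov chain over survey years *t*: **not yet entered** (1),
**alive** (2), **dead** (3). Transitions are

|             | not entered | alive    | dead       |
|-------------|-------------|----------|------------|
| not entered | 1 − γ_t     | γ_t      | 0          |
| alive       | 0           | φ_{i,t}  | 1 − φ_{i,t}|
| dead        | 0           | 0        | 1          |

and the observation process is Bernoulli: an alive individual is seen with
probability p_{i,t}, any other state with probability 0. Entry at the first
occasion means being part of the population when the study opens, so γ_1 is
an initial-membership probability rather than a birth rate.

Survival and detection are logit-linear:

    logit(φ_{i,t}) = β₁ + β₂·sex_i·Adult_{i,t} + β₃·Age_{i,t} + ε_t
    logit(p_{i,t}) = α₁·sex_i + α₂·(1 − sex_i) + Time_t + ζ_i

with sex_i = 1 for females, Age in classes 0–5 (5 meaning 5+), Adult = 1 for
the 5+ class, ε_t ~ N(0, δ) a per-interval year effect, Time_t a per-year
fixed detection effect with Time fixed to 0 in the first year (the
identifiability constraint), and ζ_i ~ N(0, σ) individual catchability.
Priors: Uniform(−10, 10) on every fixed logit-scale effect, Uniform(0.001,
10) on δ and σ, Uniform(0, 1) on each γ_t, and Beta(5, 5) on ρ, the
probability that an individual of unrecorded sex is female. Missing sexes
are latent Bernoulli(ρ) variables used consistently in both the survival and
detection equations within a draw.

Never-photographed members of the superpopulation are represented by
parameter-expanded data augmentation: `n_aug` all-zero pseudo-histories
(default 200) with unknown sex and 5+ age are appended, and the entry
probabilities determine how many of them the posterior treats as real. The
results object warns if the posterior number-ever-entered approaches the
real + augmented capacity, which means `n_aug` is binding and should be
raised.

## Data construction

A survey year runs 1 December–30 November (December sightings belong to the
following survey year, matching the onset of the calving season). Multiple
sightings of an individual within one survey year compress to a single
binary observation. The known-state matrix encodes hard information the
sampler must respect: alive (2) in every year between the first and last
year an animal was known alive — including gap years and years established
by pre- or post-study sightings — dead (3) from a discovered death onward,
not-entered (1) before a known birth year, and unknown elsewhere. Animals of
unknown age are treated as age 5+ throughout, as are augmented rows. If a
death is discovered in the same survey year as a live sighting, the dead
code starts the following year, since a year with a sighting must admit the
alive state.

## Computation

Rather than Gibbs-sampling the discrete states, the likelihood marginalizes
each individual's state sequence with the forward algorithm, constrained to
the known states (forbidden states get zero mass at their occasion). This is
mathematically identical to the state-sampling formulation and considerably
faster; the equivalence is enforced in the test suite by brute-force
enumeration over all 3^T state sequences on small datasets (agreement to
1e-10 in log-likelihood). Latent-state draws — needed for the abundance
series N_t = #{i : state = alive} — are recovered per retained draw by
backward sampling from the stored forward quantities, which reproduces the
exact joint posterior of the states. The per-individual forward recursion is
compiled with numba; a pure-numpy implementation of the same recursion backs
it and is exercised whenever filtered state distributions are requested.

Posterior sampling is adaptive Metropolis-within-Gibbs:

* single-site random-walk updates for each fixed effect, year effect and
  entry probability;
* vectorized elementwise random-walk updates for the ζ_i;
* conjugate Gibbs for ρ and for each missing sex (the forward likelihood is
  evaluated under both sexes and the posterior odds combined with ρ);
* prior-conditional random-walk updates for δ and σ, which do not enter the
  likelihood;
* two joint "ridge" moves — shifting (β₁, β₃) along the direction that keeps
  adult survival β₁ + 5β₃ fixed, and translating (α₁, α₂) against the Time
  profile — because those combinations are far better identified than their
  components;
* joint scale moves (c·ε, c·δ) and (c·ζ, c·σ) whose prior-plus-Jacobian
  terms collapse to a single log c, breaking the funnel between random
  effects and their standard deviations;
* exact Gibbs recentering along the two likelihood-invariant ridges:
  (β₁ + s, ε − s) leaves every survival logit unchanged, so s is drawn
  directly from N(mean(ε), δ/√(T−1)); likewise (α₁ + s, α₂ + s, ζ − s) for
  detection with s ~ N(mean(ζ), σ/√N). Without these the intercepts and the
  mean of their random effects mix very slowly.

Proposal scales adapt in batches of 50 toward a 44% acceptance rate during
the adaptation/burn-in phase and are frozen afterwards, so retained draws
come from a fixed transition kernel. Starting values are drawn randomly
within prior support, from a moderate sub-range (logit effects U(−3, 3),
γ U(0.02, 0.5), δ and σ U(0.1, 1.5)): starts in the far tails of a
Uniform(−10, 10) box are legal but waste the burn-in of a random-walk
sampler without making the diagnostics more honest, since chains are still
dispersed relative to the posterior.

Default protocol: 3 chains, 5,000 adaptation + burn-in iterations, 20,000
retained draws, convergence required at split-chain Gelman–Rubin R-hat < 1.1
for all monitored parameters (the fixed effects, year effects, entry
probabilities, δ, σ and ρ; not the per-individual ζ_i, matching the usual
monitor set for this model family). The classic unsplit statistic is
available via `gelman_rubin(..., split=False)`. All probabilities are
clipped to [1e-300, 1 − 1e-15] before logs.

Equal-tailed 2.5/97.5 percentile intervals are reported everywhere; highest-
density regions are not computed.

## Derived quantities

* **Abundance** N_t (total, and by sex using each draw's imputed sexes) is
  counted from the sampled states per draw; summaries are posterior medians
  and 95% intervals.
* **MNA** (minimum number alive) is pure sighting accounting: an individual
  counts in year t if seen in t or seen both before and after t. It uses no
  model output and, by construction, never counts an animal that was not
  alive — so it lower-bounds true abundance and increasingly undercounts
  toward the end of a series as detection falls. A presumed-alive census
  variant (alive until 6 years after the last sighting, configurable) is
  provided for comparison.
* **API** (annual productivity index) = detected calves / posterior median
  abundance, with the final abundance carried forward if the calf series is
  longer.
* **Crude growth** is the ratio of successive posterior medians;
  **periodic growth** N_t/N_{t−k} is computed per draw, preserving the
  posterior correlation of the endpoints, and summarized by its median, 95%
  interval and P(ratio < 1) — the posterior probability of decline.

## The synthetic-data generator

Because the underlying catalog is proprietary, the generator is the test
bed. It simulates the exact generative process the model assumes — same
transition structure, same logit-linear survival and detection, entries via
per-occasion probabilities over a finite superpopulation — sharing the
conditional-entry construction with the fitted model so recovery tests
isolate inference quality. Entrants after the first occasion are calves
(known birth year, age 0) with probability `calf_fraction` (default 0.75)
and unknown-age adults otherwise; first-occasion entrants are unknown-age
adults, some of which (default 40%) also carry a pre-study sighting so the
known-state gap-filling path is exercised. Deaths are discovered with
probability 0.15, producing death dates; sexes are masked for 8% of
individuals (emulating the ~50 of 658 unknown-sex animals in the study
system) and calf birth years for 10%.

Defaults emulate the North Atlantic right whale study: 26 survey years from
1990, superpopulation 860, adult male survival 0.985, adult female 0.968,
calf 0.955 (so β₁ = logit(0.955), β₃ = (logit(0.985) − β₁)/5,
β₂ = logit(0.968) − logit(0.985)), year-effect spread δ = 0.15, individual
catchability spread σ = 0.5, and an abundance path growing 2.8%/yr to a peak
before declining ~1%/yr. The named `declining_capture_config` fixture adds
the observed detection pattern: a rise to ~0.9, then a fall to 0.65–0.80 in
the final four years. Entry probabilities for a target abundance path are
derived in expectation (`gamma_for_trajectory`).

What the generator does **not** emulate: spatial structure and
habitat-driven sighting correlation, temporary emigration, tag
misidentification, survival heterogeneity beyond the sex/age/year terms,
and effort covariates. Passing recovery tests therefore demonstrates
correct inference under the model's own assumptions, not robustness to
their violation.

## Problem sizes and test design

The test suite and the acceptance script run desk-scale versions of each
check, chosen as the smallest sizes at which the scientific property is
informative: likelihood-oracle equivalence on all dataset shapes up to 3
individuals × 5 occasions; parameter recovery on a 150-strong
superpopulation over 10 occasions fitted with 3 chains × 2,000 retained
draws (after 700 adaptation/burn-in); trend detection on a 20-year
growth-then-decline population of ~300 with detection falling 0.9 → 0.7,
fitted with 2 chains × 1,200 draws. A full-scale run (≈660 individuals,
26 years, the default protocol) takes a few tens of minutes on one core.

Two honest caveats from our own full-scale experiments. First, in a
population of a few hundred, 5-year realized growth varies substantially
around its expectation (demographic stochasticity), so the posterior
probability of decline should be compared against the realized trajectory,
not the configured trend; the acceptance script reports both. Second, with
detection near 0.9 the posterior N_t intervals are only a few individuals
wide, and the small bias introduced by fitting masked-birth-year calves as
5+ adults can push year-wise interval coverage below nominal at full scale
even though class-survival estimates stay within ±0.01 of truth.

## Known limitations

* Entry probabilities and final-year detection are weakly separated at the
  series ends; this surfaces as slower mixing (lower ESS) for the last Time
  effect rather than being reparameterized away.
* Calf survival is only weakly identified in short series with few known
  births; its posterior leans on the age-slope prior range.
* The sampler is single-process; chains run sequentially.
* MNA's default, literal sighting-based definition deliberately ignores
  known-alive information from pre-study sightings and deaths (that
  information serves the model's known states); passing the known-state
  matrix to `jollyseber.derived.mna` enables the informed variant.
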
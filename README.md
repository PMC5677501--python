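# jollyseber

Bayesian state–space Jolly–Seber mark–recapture estimation of abundance and
survival from photo-identification capture histories.

## The problem

Long-lived, individually identifiable animals — the motivating system is the
North Atlantic right whale (*Eubalaena glacialis*), cataloged by callosity
patterns — accumulate decades of annual resighting records. When detection is
near-complete, simple accounting (the "minimum number alive", MNA) tracks
abundance well; when resighting rates fall, MNA increasingly mistakes
unseen-but-alive animals for dead ones, exactly when a real decline matters
most. An open-population Jolly–Seber model separates the biological process
(entry by birth or discovery, survival, death) from the observation process
(imperfect, heterogeneous detection), so trend inference remains valid as
capture probability changes.

## The model

Each individual follows a three-state Markov chain per survey year (1 Dec –
30 Nov): not-yet-entered → alive → dead, with entry probability γ_t,
logit-linear survival and detection,

    logit(φ_it) = β₁ + β₂·sex_i·Adult_it + β₃·Age_it + ε_t,   ε_t ~ N(0, δ)
    logit(p_it) = α₁·sex_i + α₂·(1−sex_i) + Time_t + ζ_i,     ζ_i ~ N(0, σ)

and Bernoulli observation of alive individuals. Never-photographed animals
are handled by parameter-expanded data augmentation; missing sexes are
imputed as Bernoulli(ρ) inside the sampler. The likelihood marginalizes the
latent states with the forward algorithm (verified against brute-force
enumeration) and recovers per-draw abundance N_t by backward sampling.
Derived outputs include sex-specific abundance, MNA, the annual productivity
index (calves / median N), crude growth N_t/N_{t−1} of the medians, and the
posterior of periodic growth N_t/N_{t−k} with its probability of decline.
See `docs/methods.md` for full details.

## Worked example

Simulate a 10-year catalog from a 150-strong superpopulation (adult male
survival 0.985, adult female 0.968, calf 0.955, detection 0.8 with
individual spread σ = 0.5), rebuild it through the catalog stage, and fit:

```python
import numpy as np
import jollyseber as js
from jollyseber.simulate import SimulationConfig, simulate
from jollyseber.derived import mna, periodic_growth

cfg = SimulationConfig(n_years=10, m_super=150, target_n=np.linspace(80, 120, 10),
                       capture=0.8, sigma=0.5)
sim = simulate(cfg, seed=1)
data = js.CatalogData.from_records(sim.records, 1990, 1999,
                                   sim.pre_study_records, n_aug=40)
res = js.JollySeberModel(data).fit(chains=3, n_adapt_burn=1000,
                                   n_samples=2000, seed=3)
print(res.convergence())
print(res.summary().loc[["surv_calf", "surv_adult_male", "surv_adult_female"]])
```

prints

```
<ConvergenceReport PASS: max R-hat = 1.0495 over 36 parameters (threshold 1.1)>
                   median  lower  upper
surv_calf           0.982  0.908  0.999
surv_adult_male     0.988  0.964  0.998
surv_adult_female   0.966  0.930  0.992
```

— every 95% interval covers its generating value. The abundance series
tracks the truth (true N ran 88 → 123; posterior medians 85 → 121 with
intervals covering all ten years), and the model does not invent a decline
the data do not support:

```python
ab = res.abundance()
pg = periodic_growth(ab, 1999, 5)
print(f"P(N_1999/N_1994 < 1) = {pg.p_decline:.3f}")   # 0.071
print(mna(data.histories))  # [63 83 91 95 105 112 115 117 114 104]
```

Note the MNA's end-of-series droop (104 in 1999 vs true 123) — the
accounting artifact the model corrects.

A command-line interface mirrors the library:
`jollyseber simulate | build | fit | derive | report` (see `--help`);
`report` runs the full pipeline and writes abundance, summary, convergence
and periodic-growth files plus a reproducibility log.

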
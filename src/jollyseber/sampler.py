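"""Adaptive Metropolis-within-Gibbs sampler for the multistate Jolly-Seber model.

The posterior is explored by single-site random-walk Metropolis updates on
every fixed effect, year effect and entry probability, elementwise vectorized
Metropolis on the individual catchability effects, conjugate Gibbs steps for
the sex-ratio parameter rho and the missing sexes, and prior-conditional
Metropolis for the two random-effect standard deviations (which do not touch
the likelihood). Proposal scales adapt toward a 44% acceptance rate during
the adaptation/burn-in phase and are frozen afterwards, so the retained
draws form a valid Markov chain.

Latent states are never held in the chain state: the likelihood marginalizes
them with the forward algorithm, and one state path per retained draw is
recovered by backward sampling to form the abundance series.
"""

from __future__ import annotations

import numpy as np

from .model import backward_sample, forward_pass

TARGET_ACC = 0.44
BATCH = 50

# parameters monitored for convergence (vector entries expanded at report time)
MONITORED = ["beta1", "beta2", "beta3", "alpha1", "alpha2", "delta", "sigma", "rho"]


def _init_state(model, rng):
    T, N = model.T, model.N
    st = {
        "beta1": rng.uniform(-3, 3),
        "beta2": rng.uniform(-3, 3),
        "beta3": rng.uniform(-3, 3),
        "alpha1": rng.uniform(-3, 3),
        "alpha2": rng.uniform(-3, 3),
        "delta": rng.uniform(0.1, 1.5),
        "sigma": rng.uniform(0.1, 1.5),
        "rho": rng.beta(model.prior.rho_a, model.prior.rho_b),
        "eps": rng.normal(0.0, 0.3, size=T - 1),
        "time": np.concatenate([[0.0], rng.uniform(-2, 2, size=T - 1)]),
        "gamma": rng.uniform(0.02, 0.5, size=T),
        "zeta": rng.normal(0.0, 0.3, size=N),
        "sex": model.sex_obs.copy(),
    }
    st["sex"][model.missing_sex] = rng.integers(0, 2, model.missing_sex.sum()).astype(float)
    return st


def _phi_p(model, st, rows=None, sex_override=None):
    sex = st["sex"] if sex_override is None else sex_override
    if rows is None:
        rows = slice(None)
    sx = sex[rows]
    age = model.age[rows]
    adult = model.adult[rows]
    zeta = st["zeta"][rows]
    lphi = (
        st["beta1"]
        + st["beta2"] * sx[:, None] * adult[:, :-1]
        + st["beta3"] * age[:, :-1]
        + st["eps"][None, :]
    )
    lp = (
        st["alpha1"] * sx[:, None]
        + st["alpha2"] * (1.0 - sx[:, None])
        + st["time"][None, :]
        + zeta[:, None]
    )
    from .model import _clip
    from scipy.special import expit

    return _clip(expit(lphi)), _clip(expit(lp))


def _ll_vec(model, st, rows=None, sex_override=None, keep_alphas=False):
    phi, p = _phi_p(model, st, rows, sex_override)
    if rows is None:
        rows = slice(None)
    return forward_pass(
        model.hist[rows], model.mask[rows], phi, p, st["gamma"], keep_alphas
    )


class _Adapt:
    """Per-site proposal scales with batch Robbins-Monro adaptation."""

    def __init__(self, shape, init=0.2):
        self.log_scale = np.full(shape, np.log(init))
        self.acc = np.zeros(shape)
        self.n = np.zeros(shape)
        self.batch = 0

    @property
    def scale(self):
        return np.exp(self.log_scale)

    def record(self, accepted):
        self.acc += accepted
        self.n += 1

    def maybe_adapt(self):
        if np.all(self.n >= BATCH):
            self.batch += 1
            rate = self.acc / self.n
            step = min(0.25, 1.0 / np.sqrt(self.batch))
            self.log_scale += np.where(rate > TARGET_ACC, step, -step)
            np.clip(self.log_scale, np.log(1e-4), np.log(10.0), out=self.log_scale)
            self.acc[...] = 0.0
            self.n[...] = 0.0


def _run_single_chain(
    model, rng, n_adapt_burn, n_samples, thin, store_states, progress=False
):
    T, N = model.T, model.N
    b = model.prior
    st = _init_state(model, rng)
    ll = _ll_vec(model, st)
    if not np.all(np.isfinite(ll)):
        # extremely unlucky start; nudge entry probabilities up and retry
        st["gamma"] = np.full(T, 0.3)
        ll = _ll_vec(model, st)
    if not np.all(np.isfinite(ll)):
        raise RuntimeError("could not find a finite-likelihood starting point")

    scalar_names = ["beta1", "beta2", "beta3", "alpha1", "alpha2"]
    ad = {nm: _Adapt(()) for nm in scalar_names}
    ad["eps"] = _Adapt(T - 1)
    ad["time"] = _Adapt(T - 1)  # free entries 1..T-1
    ad["gamma"] = _Adapt(T, init=0.1)
    ad["zeta"] = _Adapt(N, init=0.5)
    ad["delta"] = _Adapt((), init=0.3)
    ad["sigma"] = _Adapt((), init=0.3)
    ad["ridge_b13"] = _Adapt((), init=0.5)
    ad["ridge_cap"] = _Adapt((), init=0.3)
    ad["scale_sigma"] = _Adapt((), init=0.3)
    ad["scale_delta"] = _Adapt((), init=0.3)

    n_iter = n_adapt_burn + n_samples * thin
    out = {nm: np.empty(n_samples) for nm in scalar_names + ["delta", "sigma", "rho"]}
    out["eps"] = np.empty((n_samples, T - 1))
    out["time"] = np.empty((n_samples, T))
    out["gamma"] = np.empty((n_samples, T))
    out["n_total"] = np.empty((n_samples, T))
    out["n_female"] = np.empty((n_samples, T))
    out["n_male"] = np.empty((n_samples, T))
    out["ever_entered"] = np.empty(n_samples)
    states_out = (
        np.empty((n_samples, N, T), dtype=np.int8) if store_states else None
    )

    miss = np.flatnonzero(model.missing_sex)
    save_idx = 0
    for it in range(n_iter):
        adapting = it < n_adapt_burn

        # --- fixed effects (uniform priors) --------------------------------
        for nm in scalar_names:
            old = st[nm]
            new = old + ad[nm].scale * rng.standard_normal()
            if b.logit_low <= new <= b.logit_high:
                st[nm] = new
                ll_new = _ll_vec(model, st)
                if np.log(rng.random()) < ll_new.sum() - ll.sum():
                    ll = ll_new
                    acc = 1.0
                else:
                    st[nm] = old
                    acc = 0.0
            else:
                acc = 0.0
            if adapting:
                ad[nm].record(acc)

        # --- joint moves along known posterior ridges ----------------------
        # (a) calf intercept vs age slope: adult survival beta1 + 5*beta3 is
        #     far better identified than either coefficient alone
        d = ad["ridge_b13"].scale * rng.standard_normal()
        nb1, nb3 = st["beta1"] + d, st["beta3"] - d / 5.0
        acc = 0.0
        if b.logit_low <= nb1 <= b.logit_high and b.logit_low <= nb3 <= b.logit_high:
            old1, old3 = st["beta1"], st["beta3"]
            st["beta1"], st["beta3"] = nb1, nb3
            ll_new = _ll_vec(model, st)
            if np.log(rng.random()) < ll_new.sum() - ll.sum():
                ll = ll_new
                acc = 1.0
            else:
                st["beta1"], st["beta3"] = old1, old3
        if adapting:
            ad["ridge_b13"].record(acc)

        # (b) capture intercepts vs the year profile (translation ridge)
        d = ad["ridge_cap"].scale * rng.standard_normal()
        na1, na2 = st["alpha1"] + d, st["alpha2"] + d
        ntime = st["time"].copy()
        ntime[1:] -= d
        acc = 0.0
        if (
            b.logit_low <= na1 <= b.logit_high
            and b.logit_low <= na2 <= b.logit_high
            and np.all((ntime[1:] >= b.logit_low) & (ntime[1:] <= b.logit_high))
        ):
            old = (st["alpha1"], st["alpha2"], st["time"])
            st["alpha1"], st["alpha2"], st["time"] = na1, na2, ntime
            ll_new = _ll_vec(model, st)
            if np.log(rng.random()) < ll_new.sum() - ll.sum():
                ll = ll_new
                acc = 1.0
            else:
                st["alpha1"], st["alpha2"], st["time"] = old
        if adapting:
            ad["ridge_cap"].record(acc)

        # --- year effects on survival (normal prior) -----------------------
        for t in range(T - 1):
            old = st["eps"][t]
            new = old + ad["eps"].scale[t] * rng.standard_normal()
            st["eps"][t] = new
            ll_new = _ll_vec(model, st)
            dprior = -0.5 * (new**2 - old**2) / st["delta"] ** 2
            if np.log(rng.random()) < ll_new.sum() - ll.sum() + dprior:
                ll = ll_new
                acc = 1.0
            else:
                st["eps"][t] = old
                acc = 0.0
            if adapting:
                ad["eps"].acc[t] += acc
                ad["eps"].n[t] += 1

        # --- year effects on capture (uniform prior, first fixed) ----------
        for t in range(1, T):
            old = st["time"][t]
            new = old + ad["time"].scale[t - 1] * rng.standard_normal()
            acc = 0.0
            if b.logit_low <= new <= b.logit_high:
                st["time"][t] = new
                ll_new = _ll_vec(model, st)
                if np.log(rng.random()) < ll_new.sum() - ll.sum():
                    ll = ll_new
                    acc = 1.0
                else:
                    st["time"][t] = old
            if adapting:
                ad["time"].acc[t - 1] += acc
                ad["time"].n[t - 1] += 1

        # --- entry probabilities -------------------------------------------
        for t in range(T):
            old = st["gamma"][t]
            new = old + ad["gamma"].scale[t] * rng.standard_normal()
            acc = 0.0
            if 0.0 < new < 1.0:
                st["gamma"][t] = new
                ll_new = _ll_vec(model, st)
                if np.log(rng.random()) < ll_new.sum() - ll.sum():
                    ll = ll_new
                    acc = 1.0
                else:
                    st["gamma"][t] = old
            if adapting:
                ad["gamma"].acc[t] += acc
                ad["gamma"].n[t] += 1

        # --- extra refreshes of the weakly identified series-end block -----
        # final-occasion detection, survival and entry trade off against each
        # other; revisiting them a few extra times per sweep lifts their ESS
        for _ in range(2):
            t = T - 1
            old = st["time"][t]
            new = old + ad["time"].scale[t - 1] * rng.standard_normal()
            if b.logit_low <= new <= b.logit_high:
                st["time"][t] = new
                ll_new = _ll_vec(model, st)
                if np.log(rng.random()) < ll_new.sum() - ll.sum():
                    ll = ll_new
                else:
                    st["time"][t] = old
            old = st["eps"][T - 2]
            new = old + ad["eps"].scale[T - 2] * rng.standard_normal()
            st["eps"][T - 2] = new
            ll_new = _ll_vec(model, st)
            dprior = -0.5 * (new**2 - old**2) / st["delta"] ** 2
            if np.log(rng.random()) < ll_new.sum() - ll.sum() + dprior:
                ll = ll_new
            else:
                st["eps"][T - 2] = old
            old = st["gamma"][T - 1]
            new = old + ad["gamma"].scale[T - 1] * rng.standard_normal()
            if 0.0 < new < 1.0:
                st["gamma"][T - 1] = new
                ll_new = _ll_vec(model, st)
                if np.log(rng.random()) < ll_new.sum() - ll.sum():
                    ll = ll_new
                else:
                    st["gamma"][T - 1] = old

        # --- individual catchability, elementwise --------------------------
        prop = st["zeta"] + ad["zeta"].scale * rng.standard_normal(N)
        st_new = dict(st)
        st_new["zeta"] = prop
        ll_new = _ll_vec(model, st_new)
        dprior = -0.5 * (prop**2 - st["zeta"] ** 2) / st["sigma"] ** 2
        accept = np.log(rng.random(N)) < (ll_new - ll + dprior)
        st["zeta"] = np.where(accept, prop, st["zeta"])
        ll = np.where(accept, ll_new, ll)
        if adapting:
            ad["zeta"].record(accept.astype(float))

        # --- random-effect standard deviations (no likelihood term) --------
        for nm, vec in (("delta", st["eps"]), ("sigma", st["zeta"])):
            old = st[nm]
            new = old + ad[nm].scale * rng.standard_normal()
            acc = 0.0
            if b.sd_low <= new <= b.sd_high:
                k = len(vec)
                ss = float(np.sum(vec**2))
                logr = (
                    -k * np.log(new)
                    - 0.5 * ss / new**2
                    + k * np.log(old)
                    + 0.5 * ss / old**2
                )
                if np.log(rng.random()) < logr:
                    st[nm] = new
                    acc = 1.0
            if adapting:
                ad[nm].record(acc)

        # --- exact recentering along likelihood-invariant ridges -----------
        # shifting (beta1 + s, eps - s) leaves every survival logit unchanged,
        # so s can be Gibbs-sampled from the eps prior: N(mean(eps), delta/sqrt(T-1))
        s = rng.normal(st["eps"].mean(), st["delta"] / np.sqrt(T - 1))
        if b.logit_low <= st["beta1"] + s <= b.logit_high:
            st["beta1"] += s
            st["eps"] = st["eps"] - s
        # likewise (alpha1 + s, alpha2 + s, zeta - s) leaves detection unchanged
        s = rng.normal(st["zeta"].mean(), st["sigma"] / np.sqrt(N))
        if (
            b.logit_low <= st["alpha1"] + s <= b.logit_high
            and b.logit_low <= st["alpha2"] + s <= b.logit_high
        ):
            st["alpha1"] += s
            st["alpha2"] += s
            st["zeta"] = st["zeta"] - s

        # --- joint scale moves breaking the sd/effects ridge ---------------
        # propose (c*effects, c*sd); the normal-prior terms and the Jacobian
        # collapse to a single +log(c), so only the likelihood must be redone
        # (for delta the likelihood does not involve delta itself, so the
        # effects are rescaled and the likelihood re-evaluated through eps)
        for nm_sd, nm_vec, mv in (("sigma", "zeta", "scale_sigma"), ("delta", "eps", "scale_delta")):
            u = ad[mv].scale * rng.standard_normal()
            c = np.exp(u)
            new_sd = st[nm_sd] * c
            acc = 0.0
            if b.sd_low <= new_sd <= b.sd_high:
                old_sd, old_vec = st[nm_sd], st[nm_vec]
                st[nm_sd], st[nm_vec] = new_sd, old_vec * c
                ll_new = _ll_vec(model, st)
                if np.log(rng.random()) < ll_new.sum() - ll.sum() + u:
                    ll = ll_new
                    acc = 1.0
                else:
                    st[nm_sd], st[nm_vec] = old_sd, old_vec
            if adapting:
                ad[mv].record(acc)

        # --- missing sexes (Gibbs) and rho (conjugate Gibbs) ---------------
        if miss.size:
            ll_f = _ll_vec(model, st, rows=miss, sex_override=_const_sex(st, miss, 1.0))
            ll_m = _ll_vec(model, st, rows=miss, sex_override=_const_sex(st, miss, 0.0))
            logit_odds = np.log(st["rho"]) - np.log1p(-st["rho"]) + ll_f - ll_m
            pf = 1.0 / (1.0 + np.exp(-logit_odds))
            draw = (rng.random(miss.size) < pf).astype(float)
            st["sex"][miss] = draw
            ll[miss] = np.where(draw == 1.0, ll_f, ll_m)
        nf = float(st["sex"].sum())
        st["rho"] = rng.beta(b.rho_a + nf, b.rho_b + (N - nf))

        if adapting:
            for a in ad.values():
                a.maybe_adapt()

        # --- save ----------------------------------------------------------
        if not adapting and (it - n_adapt_burn + 1) % thin == 0 and save_idx < n_samples:
            for nm in scalar_names + ["delta", "sigma", "rho"]:
                out[nm][save_idx] = st[nm]
            out["eps"][save_idx] = st["eps"]
            out["time"][save_idx] = st["time"]
            out["gamma"][save_idx] = st["gamma"]
            phi, p = _phi_p(model, st)
            _, alphas = forward_pass(
                model.hist, model.mask, phi, p, st["gamma"], keep_alphas=True
            )
            states = backward_sample(rng, alphas, phi, st["gamma"])
            alive = states == 2
            out["n_total"][save_idx] = alive.sum(axis=0)
            fem = st["sex"] == 1.0
            out["n_female"][save_idx] = (alive & fem[:, None]).sum(axis=0)
            out["n_male"][save_idx] = (alive & ~fem[:, None]).sum(axis=0)
            out["ever_entered"][save_idx] = (states[:, -1] >= 2).sum()
            if states_out is not None:
                states_out[save_idx] = states
            save_idx += 1

    return out, states_out


def _const_sex(st, rows, value):
    sex = st["sex"].copy()
    sex[rows] = value
    return sex


def run_chains(
    model,
    chains=3,
    n_adapt_burn=5000,
    n_samples=20000,
    seed=None,
    thin=1,
    store_states=False,
    progress=False,
):
    if chains < 1 or n_adapt_burn < 0 or n_samples < 1:
        raise ValueError("chains and sample sizes must be positive")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(chains)
    per_chain = []
    states_all = []
    for c in range(chains):
        rng = np.random.default_rng(children[c])
        out, states = _run_single_chain(
            model, rng, n_adapt_burn, n_samples, thin, store_states, progress
        )
        per_chain.append(out)
        if store_states:
            states_all.append(states)

    draws = {}
    for nm in per_chain[0]:
        draws[nm] = np.stack([pc[nm] for pc in per_chain])
    states = np.stack(states_all) if store_states else None

    from .results import JollySeberResults

    return JollySeberResults(
        model=model,
        draws=draws,
        states=states,
        seed=seed,
        config={
            "chains": chains,
            "n_adapt_burn": n_adapt_burn,
            "n_samples": n_samples,
            "thin": thin,
        },
    )
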
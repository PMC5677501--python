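"""Posterior results container for the fitted Jolly-Seber model."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import expit

from .diagnostics import ConvergenceReport, gelman_rubin

__all__ = ["JollySeberResults"]


class JollySeberResults:
    """MCMC draws, derived abundance and summaries from :meth:`JollySeberModel.fit`.

    Attributes
    ----------
    draws : dict
        Per-parameter arrays of shape (chains, draws) for scalars and
        (chains, draws, dim) for vector parameters (``eps``, ``time``,
        ``gamma``) and the abundance series (``n_total``, ``n_female``,
        ``n_male``).
    states : (chains, draws, N, T) int8 array or None
        Backward-sampled latent states, kept only when requested at fit time.
    """

    SCALARS = ["beta1", "beta2", "beta3", "alpha1", "alpha2", "delta", "sigma", "rho"]
    VECTORS = ["eps", "time", "gamma"]

    def __init__(self, model, draws, states=None, seed=None, config=None):
        self.model = model
        self.draws = draws
        self.states = states
        self.seed = seed
        self.config = config or {}
        self.years = np.asarray(model.years)
        cap = model.N
        if draws["ever_entered"].max() >= 0.98 * cap:
            warnings.warn(
                "posterior number-ever-entered approaches the real+augmented "
                "capacity; increase n_aug and refit",
                stacklevel=2,
            )

    @property
    def n_chains(self) -> int:
        return self.draws["beta1"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["beta1"].shape[1]

    # ---- parameter access ---------------------------------------------------

    def monitored_draws(self, include_vectors: bool = True) -> dict[str, np.ndarray]:
        """Per-parameter (chains, draws) arrays for convergence monitoring."""
        out = {nm: self.draws[nm] for nm in self.SCALARS}
        if include_vectors:
            for nm in self.VECTORS:
                arr = self.draws[nm]
                for j in range(arr.shape[2]):
                    if nm == "time" and j == 0:
                        continue  # fixed at 0
                    out[f"{nm}[{j}]"] = arr[:, :, j]
        return out

    def class_survival_draws(self) -> dict[str, np.ndarray]:
        """Year-effect-free survival of the three reference classes, per draw.

        Calf: inverse-logit(beta1); adult male: beta1 + 5*beta3; adult female
        adds beta2. These are the survival means usually reported.
        """
        b1, b2, b3 = (self.draws[k] for k in ("beta1", "beta2", "beta3"))
        return {
            "surv_calf": expit(b1),
            "surv_adult_male": expit(b1 + 5.0 * b3),
            "surv_adult_female": expit(b1 + b2 + 5.0 * b3),
        }

    # ---- summaries ----------------------------------------------------------

    def summary(self, include_derived: bool = True) -> pd.DataFrame:
        """Posterior medians, 95% equal-tailed intervals, R-hat and ESS."""
        mon = self.monitored_draws()
        report = gelman_rubin(mon) if self.n_chains >= 2 else None
        rows = []
        for name, arr in mon.items():
            flat = arr.reshape(-1)
            rows.append(
                {
                    "parameter": name,
                    "median": np.median(flat),
                    "lower": np.percentile(flat, 2.5),
                    "upper": np.percentile(flat, 97.5),
                    "rhat": report.table.loc[name, "rhat"] if report is not None else np.nan,
                    "ess": report.table.loc[name, "ess"] if report is not None else np.nan,
                }
            )
        if include_derived:
            for name, arr in self.class_survival_draws().items():
                flat = arr.reshape(-1)
                rows.append(
                    {
                        "parameter": name,
                        "median": np.median(flat),
                        "lower": np.percentile(flat, 2.5),
                        "upper": np.percentile(flat, 97.5),
                        "rhat": np.nan,
                        "ess": np.nan,
                    }
                )
        return pd.DataFrame(rows).set_index("parameter")

    def convergence(self, threshold: float = 1.1, split: bool = True) -> ConvergenceReport:
        """Gelman-Rubin report over the monitored parameters."""
        return gelman_rubin(self.monitored_draws(), threshold=threshold, split=split)

    def abundance(self):
        """Posterior abundance series (total and by sex); see :mod:`jollyseber.derived`."""
        from .derived import abundance_from_draws

        return abundance_from_draws(self)

    # ---- persistence --------------------------------------------------------

    def draws_frame(self) -> pd.DataFrame:
        """Long-format table of draws: chain, iteration, parameter, value."""
        recs = []
        for name, arr in self.monitored_draws().items():
            C, S = arr.shape
            for c in range(C):
                recs.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(S),
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)

    def abundance_frame(self) -> pd.DataFrame:
        """Long-format abundance draws: chain, iteration, year, total, female, male."""
        C, S, T = self.draws["n_total"].shape
        chain, it, yr = np.meshgrid(
            np.arange(C), np.arange(S), self.years, indexing="ij"
        )
        return pd.DataFrame(
            {
                "chain": chain.ravel(),
                "iteration": it.ravel(),
                "year": yr.ravel(),
                "total": self.draws["n_total"].ravel(),
                "female": self.draws["n_female"].ravel(),
                "male": self.draws["n_male"].ravel(),
            }
        )

    def plot_abundance(self, ax=None, mna=None):
        """Posterior median abundance with 95% credible band (optionally vs MNA)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ab = self.abundance()
        med = ab.median_series("total")
        lo, hi = ab.interval("total")
        ax.fill_between(self.years, lo, hi, alpha=0.3, label="95% credible interval")
        ax.plot(self.years, med, marker="o", label="posterior median N")
        if mna is not None:
            ax.plot(self.years, mna, marker="d", linestyle="--", label="MNA")
        ax.set_xlabel("survey year")
        ax.set_ylabel("abundance")
        ax.legend()
        return ax
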
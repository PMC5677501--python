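"""MCMC convergence diagnostics: Gelman-Rubin statistic and effective sample size.

The potential scale reduction factor (R-hat) compares between- and
within-chain variance; values near 1 indicate the chains have mixed over the
same distribution. The default is the split version (each chain halved, so
within-chain drift also counts against convergence); the classic unsplit
statistic is available for comparison with older software. The fitted model
is accepted only when every monitored parameter has R-hat < 1.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["gelman_rubin", "psrf", "effective_sample_size", "ConvergenceReport"]


def psrf(chains: np.ndarray, split: bool = True) -> float:
    """Potential scale reduction factor for one parameter.

    Parameters
    ----------
    chains : (n_chains, n_draws) array
    split : bool
        Halve each chain first (the modern, stricter convention).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("chains must be a 2-D (n_chains, n_draws) array")
    if x.shape[0] < 2:
        raise ValueError("at least two chains are required for R-hat")
    if split:
        half = x.shape[1] // 2
        x = np.vstack([x[:, :half], x[:, half : 2 * half]])
    m, n = x.shape
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0 if B <= 0 else np.inf
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """Effective sample size from pooled autocorrelations.

    Uses Geyer's initial positive sequence on the chain-averaged
    autocorrelation function.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    if n < 4:
        return float(m * n)
    acov = np.zeros(n)
    for row in x:
        r = row - row.mean()
        f = np.fft.rfft(np.concatenate([r, np.zeros(n)]))
        ac = np.fft.irfft(f * np.conj(f))[:n] / n
        acov += ac
    acov /= m
    if acov[0] <= 0:
        return float(m * n)
    rho = acov / acov[0]
    # sum pairs rho[2k-1] + rho[2k] while positive
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        tau += 2 * pair
        k += 2
    return float(m * n / max(tau, 1.0))


@dataclass
class ConvergenceReport:
    """Per-parameter R-hat and ESS with an overall pass flag at a threshold."""

    table: pd.DataFrame  # index: parameter; columns: rhat, ess
    threshold: float = 1.1

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())

    @property
    def passed(self) -> bool:
        return bool((self.table["rhat"] < self.threshold).all())

    def __repr__(self):
        verdict = "PASS" if self.passed else "FAIL"
        return (
            f"<ConvergenceReport {verdict}: max R-hat = {self.max_rhat:.4f} "
            f"over {len(self.table)} parameters (threshold {self.threshold})>"
        )


def gelman_rubin(
    draws: dict[str, np.ndarray], threshold: float = 1.1, split: bool = True
) -> ConvergenceReport:
    """Convergence report over a dictionary of per-parameter chain draws.

    Each value must be an (n_chains, n_draws) array; vector parameters should
    be expanded to one entry per element before calling.
    """
    rows = {}
    for name, arr in draws.items():
        rows[name] = {
            "rhat": psrf(arr, split=split),
            "ess": effective_sample_size(arr),
        }
    table = pd.DataFrame(rows).T
    return ConvergenceReport(table=table, threshold=threshold)
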
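"""Derived population statistics: abundance series, MNA, productivity and growth.

Two kinds of quantity live here. Model-based ones (abundance, periodic
growth) are computed per posterior draw by counting individuals whose latent
state is "alive", so their uncertainty is the posterior's. Accounting ones
(minimum number alive, the presumed-alive census variant) are computed from
the raw capture histories alone and carry no model assumptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import CaptureHistoryMatrix

__all__ = [
    "AbundanceSeries",
    "PeriodicGrowth",
    "abundance_from_draws",
    "mna",
    "api",
    "crude_growth",
    "periodic_growth",
    "presumed_alive",
]


@dataclass
class AbundanceSeries:
    """Posterior draws of annual abundance, total and by (imputed) sex."""

    years: np.ndarray  # (T,)
    total: np.ndarray  # (S, T) pooled over chains
    female: np.ndarray  # (S, T)
    male: np.ndarray  # (S, T)

    def draws(self, which: str = "total") -> np.ndarray:
        return getattr(self, which)

    def median_series(self, which: str = "total") -> np.ndarray:
        return np.median(self.draws(which), axis=0)

    def interval(self, which: str = "total", level: float = 0.95):
        a = (1.0 - level) / 2.0 * 100.0
        d = self.draws(which)
        return np.percentile(d, a, axis=0), np.percentile(d, 100.0 - a, axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = {"year": self.years}
        for which in ("total", "female", "male"):
            lo, hi = self.interval(which)
            rows[f"{which}_median"] = self.median_series(which)
            rows[f"{which}_lower"] = lo
            rows[f"{which}_upper"] = hi
        return pd.DataFrame(rows)


def abundance_from_draws(results) -> AbundanceSeries:
    """Pool the per-draw alive-counts into an :class:`AbundanceSeries`."""
    d = results.draws
    C, S, T = d["n_total"].shape
    return AbundanceSeries(
        years=np.asarray(results.years),
        total=d["n_total"].reshape(C * S, T),
        female=d["n_female"].reshape(C * S, T),
        male=d["n_male"].reshape(C * S, T),
    )


def mna(histories: CaptureHistoryMatrix, known_states=None) -> np.ndarray:
    """Minimum number alive per year from sightings alone.

    An individual counts toward year t if it was seen in t, or seen in some
    earlier and some later year. Augmented pseudo-individuals are ignored, so
    MNA is invariant to augmentation. This is a deliberate undercount: it
    misses animals never cataloged and animals alive after their last
    sighting, a bias that grows toward the end of the series.

    Passing a :class:`~jollyseber.catalog.KnownStateMatrix` switches on the
    known-state-informed variant, which additionally counts years an
    individual is known alive from outside information (pre-study sightings,
    deaths); the default is the pure sighting-based definition.
    """
    h = np.asarray(histories.histories[: histories.n_real], dtype=bool)
    if h.size == 0:
        return np.zeros(histories.n_years, dtype=int)
    seen_before = np.zeros_like(h)
    seen_after = np.zeros_like(h)
    seen_before[:, 1:] = np.cumsum(h[:, :-1], axis=1) > 0
    seen_after[:, :-1] = np.cumsum(h[:, :0:-1], axis=1)[:, ::-1] > 0
    known_alive = h | (seen_before & seen_after)
    if known_states is not None:
        from .catalog import STATE_ALIVE

        known_alive |= known_states.states[: histories.n_real] == STATE_ALIVE
    return known_alive.sum(axis=0).astype(int)


def api(calves: np.ndarray, abundance, extend_last: bool = True) -> np.ndarray:
    """Annual productivity index: detected calves / median abundance.

    ``abundance`` may be an :class:`AbundanceSeries` or an array of median
    abundances. If the calf series runs past the abundance series and
    ``extend_last`` is True, the final abundance is carried forward (the
    convention used when calf counts outpace the estimation window).
    """
    medians = (
        abundance.median_series("total")
        if isinstance(abundance, AbundanceSeries)
        else np.asarray(abundance, dtype=float)
    )
    calves = np.asarray(calves, dtype=float)
    if calves.shape[0] > medians.shape[0]:
        if not extend_last:
            raise ValueError("calf series longer than abundance series")
        pad = np.full(calves.shape[0] - medians.shape[0], medians[-1])
        medians = np.concatenate([medians, pad])
    medians = medians[: calves.shape[0]]
    if np.any(medians <= 0):
        raise ValueError("abundance must be positive to form a productivity index")
    return calves / medians


def crude_growth(abundance: AbundanceSeries, which: str = "total") -> np.ndarray:
    """Year-over-year growth of the posterior medians, N_t / N_{t-1}."""
    med = (
        abundance.median_series(which)
        if isinstance(abundance, AbundanceSeries)
        else np.asarray(abundance, dtype=float)
    )
    if med.shape[0] < 2:
        raise ValueError("need at least two years for a growth series")
    return med[1:] / med[:-1]


@dataclass
class PeriodicGrowth:
    """Posterior summary of N_t / N_{t-k} over a multi-year period."""

    year: int
    lag: int
    median: float
    lower: float
    upper: float
    p_decline: float
    n_draws: int

    def to_dict(self) -> dict:
        return {
            "t": self.year,
            "k": self.lag,
            "median": self.median,
            "ci": [self.lower, self.upper],
            "p_decline": self.p_decline,
        }


def periodic_growth(
    abundance: AbundanceSeries, t: int, k: int, which: str = "total"
) -> PeriodicGrowth:
    """Posterior of the growth ratio N_t / N_{t-k} and the decline probability.

    Computed per posterior draw, so the full uncertainty of both endpoints
    (and their correlation) carries through. ``p_decline`` is the posterior
    probability the ratio is below 1. Draws with a zero denominator are
    excluded with a warning.
    """
    years = list(abundance.years)
    if t not in years or (t - k) not in years:
        raise ValueError(f"years {t} and {t - k} must both be in the series")
    it, i0 = years.index(t), years.index(t - k)
    num = abundance.draws(which)[:, it].astype(float)
    den = abundance.draws(which)[:, i0].astype(float)
    ok = den > 0
    if not ok.all():
        warnings.warn(f"excluding {np.sum(~ok)} draws with zero denominator")
    ratio = num[ok] / den[ok]
    return PeriodicGrowth(
        year=t,
        lag=k,
        median=float(np.median(ratio)),
        lower=float(np.percentile(ratio, 2.5)),
        upper=float(np.percentile(ratio, 97.5)),
        p_decline=float(np.mean(ratio < 1.0)),
        n_draws=int(ratio.size),
    )


def presumed_alive(
    histories: CaptureHistoryMatrix, lag: int = 6, death_years: dict | None = None
) -> np.ndarray:
    """Census variant: an individual is presumed alive for ``lag`` years after
    its last sighting (or until a discovered death).

    This buffers the end-of-series undercount of MNA at the risk of positive
    bias when the assumed persistence overstates true survival.
    """
    years = np.asarray(histories.years)
    h = np.asarray(histories.histories[: histories.n_real], dtype=bool)
    out = np.zeros(len(years), dtype=int)
    for k in range(h.shape[0]):
        seen = np.flatnonzero(h[k])
        if seen.size == 0:
            continue
        first, last = seen[0], min(seen[-1] + lag, len(years) - 1)
        if death_years is not None:
            dy = death_years.get(histories.ids[k])
            if dy is not None:
                last = min(last, int(dy) - int(years[0]) - 1) if dy <= years[-1] else last
        if last >= first:
            out[first : last + 1] += 1
    return out
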
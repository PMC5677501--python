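"""Published North Atlantic right whale abundance medians and the ratios they imply.

The 1990-2015 analysis of the western North Atlantic right whale population
reported posterior median abundance (total and by sex) for the key years.
The underlying photo-identification catalog is proprietary, so these point
estimates serve as a worked example: the sex ratios, percent declines and
the period growth ratio below are recomputed from them, not stored.
"""

from __future__ import annotations

REPORTED_MEDIANS = {
    "total": {1990: 270, 2010: 483, 2015: 458},
    "male": {1990: 142, 2010: 283, 2015: 272},
    "female": {1990: 123, 2010: 200, 2015: 186},
}


def sex_ratio(year: int, medians: dict | None = None) -> float:
    """Males per female in a given year, from the median abundances."""
    m = medians or REPORTED_MEDIANS
    return m["male"][year] / m["female"][year]


def percent_decline(which: str, y0: int, y1: int, medians: dict | None = None) -> float:
    """Percent decline of a series between two years (positive = decline)."""
    m = medians or REPORTED_MEDIANS
    return 100.0 * (1.0 - m[which][y1] / m[which][y0])


def growth_ratio(y0: int, y1: int, medians: dict | None = None) -> float:
    """Ratio of median abundances N_{y1} / N_{y0}."""
    m = medians or REPORTED_MEDIANS
    return m["total"][y1] / m["total"][y0]
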
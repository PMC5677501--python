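"""Build capture histories, known-state matrices and covariates from sighting records.

Photo-identification catalogs store one row per identification event. For an
open-population mark-recapture analysis these are compressed into one binary
observation per individual per survey year, together with a "known state"
matrix (not-yet-entered / known-alive / known-dead / unknown) and per-individual
covariates (sex, age class, adult indicator).

The survey year runs 1 December through 30 November: a sighting in December of
calendar year Y-1 belongs to survey year Y, because December marks the start of
the calving season and late autumn has very few sightings.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SightingRecord",
    "CaptureHistoryMatrix",
    "KnownStateMatrix",
    "CovariateSet",
    "CatalogData",
    "survey_year",
    "read_sightings",
    "compress_to_survey_years",
    "build_known_states",
    "build_covariates",
    "augment",
]

# known-state codes (0 is "unknown" internally, written as NA on disk)
STATE_UNKNOWN = 0
STATE_NOT_ENTERED = 1
STATE_ALIVE = 2
STATE_DEAD = 3

MAX_AGE_CLASS = 5  # age classes 0,1,2,3,4,5+


class CatalogError(ValueError):
    """Inconsistent or unparseable sighting data."""


@dataclass(frozen=True)
class SightingRecord:
    """One identification event of a cataloged individual.

    Parameters
    ----------
    individual_id : str
        Opaque catalog identifier.
    date : datetime.date
        Date of the sighting.
    sex : {"F", "M", "U"}
        Sex if known, "U" otherwise.
    birth_year : int or None
        Survey year of birth for known-age individuals.
    death_date : datetime.date or None
        Date the individual was discovered dead, if ever.
    """

    individual_id: str
    date: _dt.date
    sex: str = "U"
    birth_year: int | None = None
    death_date: _dt.date | None = None

    def __post_init__(self):
        if self.sex not in ("F", "M", "U"):
            raise CatalogError(f"sex must be F/M/U, got {self.sex!r}")


def survey_year(date: _dt.date) -> int:
    """Survey year of a calendar date (year + 1 for December dates)."""
    return date.year + 1 if date.month == 12 else date.year


def _parse_date(value) -> _dt.date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def read_sightings(path) -> list[SightingRecord]:
    """Read a sightings CSV (columns ``id,date,sex,birth_year,death_date``).

    Dates are ISO-8601; empty cells mean missing. Raises :class:`CatalogError`
    listing every offending row if any date fails to parse.
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str}, keep_default_na=True)
    records, bad = [], []
    for idx, row in df.iterrows():
        try:
            date = _parse_date(row["date"])
            if date is None:
                raise ValueError("missing date")
            death = _parse_date(row.get("death_date"))
        except (ValueError, TypeError) as exc:
            bad.append(f"row {idx}: {exc}")
            continue
        sex = row.get("sex")
        sex = "U" if (not isinstance(sex, str) or sex not in ("F", "M")) else sex
        by = row.get("birth_year")
        by = None if pd.isna(by) else int(by)
        records.append(SightingRecord(str(row["id"]), date, sex, by, death))
    if bad:
        raise CatalogError("unparseable sighting records:\n" + "\n".join(bad))
    return records


@dataclass
class CaptureHistoryMatrix:
    """Binary seen/not-seen matrix, individuals x survey years.

    Augmented (pseudo-individual, all-zero) rows, if any, are the trailing
    ``n_augmented`` rows and carry ids ``AUG0001``, ``AUG0002``, ...
    """

    ids: list[str]
    years: np.ndarray  # (T,) ints
    histories: np.ndarray  # (N, T) int8 in {0, 1}
    n_augmented: int = 0

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.histories = np.asarray(self.histories, dtype=np.int8)
        if self.histories.shape != (len(self.ids), len(self.years)):
            raise CatalogError("histories shape does not match ids/years")
        # all-zero real rows are legal (individuals gap-filled alive through
        # the window from outside sightings), so only augmented rows are
        # checked strictly
        if self.n_augmented and self.histories[self.n_real :].any():
            raise CatalogError("augmented rows must be all zero")

    @property
    def n_real(self) -> int:
        return len(self.ids) - self.n_augmented

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.histories, columns=[str(y) for y in self.years])
        df.insert(0, "id", self.ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CaptureHistoryMatrix":
        df = pd.read_csv(path, dtype={"id": str})
        years = np.array([int(c) for c in df.columns[1:]])
        ids = df["id"].tolist()
        n_aug = sum(1 for i in ids if i.startswith("AUG"))
        return cls(ids, years, df.iloc[:, 1:].to_numpy(dtype=np.int8), n_aug)


@dataclass
class KnownStateMatrix:
    """Known latent states, individuals x years: 1 not-entered, 2 alive, 3 dead, 0 unknown."""

    states: np.ndarray  # (N, T) int8 over {0,1,2,3}

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        validate_state_pattern(self.states)

    def to_csv(self, path, ids, years) -> None:
        vals = self.states.astype(object)
        vals[self.states == STATE_UNKNOWN] = "NA"
        df = pd.DataFrame(vals, columns=[str(y) for y in years])
        df.insert(0, "id", ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "KnownStateMatrix":
        df = pd.read_csv(path, dtype={"id": str})
        arr = df.iloc[:, 1:].to_numpy(dtype=object)
        out = np.zeros(arr.shape, dtype=np.int8)
        for code in (1, 2, 3):
            out[arr == code] = code
            out[arr == str(code)] = code
        return cls(out)


def validate_state_pattern(states: np.ndarray) -> None:
    """Known cells of every row must be consistent with a 1*2*3* trajectory."""
    for i, row in enumerate(np.asarray(states)):
        known = row[row != STATE_UNKNOWN]
        if np.any(np.diff(known) < 0):
            raise CatalogError(
                f"row {i}: known states {row.tolist()} violate the "
                "not-entered -> alive -> dead ordering"
            )


@dataclass
class CovariateSet:
    """Per-individual sex and per-individual-per-year age class / adult flag.

    ``sex`` is 1.0 female, 0.0 male, NaN unknown. ``age`` is the integer age
    class 0..5 (5 meaning 5+); individuals of unknown age carry age 5 and
    adult 1 in every year, as do augmented pseudo-individuals.
    """

    sex: np.ndarray  # (N,) float, nan = missing
    age: np.ndarray  # (N, T) int8 in 0..5
    adult: np.ndarray  # (N, T) int8 in {0, 1}

    def __post_init__(self):
        self.sex = np.asarray(self.sex, dtype=float)
        self.age = np.asarray(self.age, dtype=np.int8)
        self.adult = np.asarray(self.adult, dtype=np.int8)
        if self.age.min() < 0 or self.age.max() > MAX_AGE_CLASS:
            raise CatalogError("age classes must lie in 0..5")


def _survey_years_by_id(records) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {}
    for r in records:
        out.setdefault(r.individual_id, set()).add(survey_year(r.date))
    return out


def compress_to_survey_years(
    records: list[SightingRecord], first_year: int, last_year: int
) -> CaptureHistoryMatrix:
    """Compress sighting records into one binary observation per survey year.

    Multiple sightings of an individual within one survey year collapse to a
    single 1. An individual is included as a row if its sighting span
    ``[first seen, last seen]`` (in survey years) intersects the study window —
    this keeps individuals seen before the window and again after it, whose
    in-window history is all zeros but who are known alive throughout.
    Individuals whose sightings all fall strictly outside (and do not bracket)
    the window are excluded.
    """
    if not records:
        raise CatalogError("no sighting records supplied")
    if first_year > last_year:
        raise CatalogError("first_year must not exceed last_year")
    years = np.arange(first_year, last_year + 1)
    by_id = _survey_years_by_id(records)
    ids = [
        i
        for i, ys in sorted(by_id.items())
        if min(ys) <= last_year and max(ys) >= first_year
    ]
    hist = np.zeros((len(ids), len(years)), dtype=np.int8)
    for k, i in enumerate(ids):
        for y in by_id[i]:
            if first_year <= y <= last_year:
                hist[k, y - first_year] = 1
    return CaptureHistoryMatrix(ids, years, hist, n_augmented=0)


def build_known_states(
    histories: CaptureHistoryMatrix,
    records: list[SightingRecord],
    pre_study_records: list[SightingRecord] = (),
) -> KnownStateMatrix:
    """Derive the known-state matrix from sightings, deaths and birth years.

    State 2 (alive) fills every year from the first to the last year the
    individual was known alive, including years it was not seen (an animal
    seen in 1989 and next in 1992 is known alive 1990 and 1991). Pre- and
    post-study sightings extend that span into the window. State 3 (dead)
    starts at the survey year of a discovered death (or the following year if
    the animal was also seen alive during the death year) and is absorbing.
    State 1 (not entered) fills years strictly before a known birth year.
    Everything else is unknown.
    """
    all_records = list(records) + list(pre_study_records)
    by_id = _survey_years_by_id(all_records)
    birth = _birth_year_by_id(all_records)
    death = {}
    for r in all_records:
        if r.death_date is not None:
            death[r.individual_id] = survey_year(r.death_date)

    first_year = int(histories.years[0])
    last_year = int(histories.years[-1])
    T = histories.n_years
    states = np.zeros((histories.n_individuals, T), dtype=np.int8)

    for k, i in enumerate(histories.ids[: histories.n_real]):
        seen = by_id.get(i, set())
        if not seen:
            continue
        lo, hi = min(seen), max(seen)
        if i in death and death[i] < hi:
            raise CatalogError(
                f"{i}: death in survey year {death[i]} precedes live sighting in {hi}"
            )
        a = max(lo, first_year) - first_year
        b = min(hi, last_year) - first_year
        if a <= b:
            states[k, a : b + 1] = STATE_ALIVE
        if i in death:
            d = death[i] if death[i] > hi else death[i] + 1
            if d <= last_year:
                states[k, max(d - first_year, 0) :] = STATE_DEAD
        if birth.get(i) is not None:
            nb = min(birth[i], last_year + 1) - first_year
            if nb > 0:
                states[k, :nb] = STATE_NOT_ENTERED
    return KnownStateMatrix(states)


def _birth_year_by_id(records) -> dict[str, int | None]:
    out: dict[str, int | None] = {}
    for r in records:
        if r.individual_id not in out or out[r.individual_id] is None:
            out[r.individual_id] = r.birth_year
    return out


def _sex_by_id(records) -> dict[str, float]:
    out: dict[str, float] = {}
    for r in records:
        if r.sex in ("F", "M"):
            out.setdefault(r.individual_id, 1.0 if r.sex == "F" else 0.0)
    return out


def build_covariates(
    records: list[SightingRecord],
    histories: CaptureHistoryMatrix,
    first_year: int | None = None,
) -> CovariateSet:
    """Sex, age-class and adult-indicator covariates aligned to the histories.

    Known-age individuals get age ``min(year - birth_year, 5)``; individuals
    of unknown age are treated as age 5+ (age 5, adult 1) in every year, as
    are augmented rows. A sighting in a year before a known birth year is a
    consistency error.
    """
    if first_year is None:
        first_year = int(histories.years[0])
    birth = _birth_year_by_id(records)
    sex_map = _sex_by_id(records)
    N, T = histories.n_individuals, histories.n_years
    years = np.asarray(histories.years)
    sex = np.full(N, np.nan)
    age = np.full((N, T), MAX_AGE_CLASS, dtype=np.int8)
    for k, i in enumerate(histories.ids[: histories.n_real]):
        sex[k] = sex_map.get(i, np.nan)
        by = birth.get(i)
        if by is None:
            continue
        raw = years - by
        if np.any((raw < 0) & (histories.histories[k] == 1)):
            raise CatalogError(f"{i}: seen before birth year {by}")
        age[k] = np.clip(raw, 0, MAX_AGE_CLASS)
    adult = (age >= MAX_AGE_CLASS).astype(np.int8)
    return CovariateSet(sex, age, adult)


def augment(histories: CaptureHistoryMatrix, n_aug: int) -> CaptureHistoryMatrix:
    """Append ``n_aug`` all-zero pseudo-individual rows (data augmentation).

    The augmented rows stand for members of the superpopulation that may have
    entered but were never photographed; the model's entry probabilities
    determine how many of them the posterior treats as real.
    """
    if n_aug < 0:
        raise CatalogError("n_aug must be non-negative")
    if n_aug == 0:
        return histories
    ids = list(histories.ids) + [
        f"AUG{j + 1:04d}" for j in range(histories.n_augmented, histories.n_augmented + n_aug)
    ]
    hist = np.vstack(
        [histories.histories, np.zeros((n_aug, histories.n_years), dtype=np.int8)]
    )
    return CaptureHistoryMatrix(ids, histories.years, hist, histories.n_augmented + n_aug)


@dataclass
class CatalogData:
    """Bundle of aligned histories, known states and covariates ready to fit."""

    histories: CaptureHistoryMatrix
    known_states: KnownStateMatrix
    covariates: CovariateSet

    @classmethod
    def from_records(
        cls,
        records: list[SightingRecord],
        first_year: int,
        last_year: int,
        pre_study_records: list[SightingRecord] = (),
        n_aug: int = 0,
    ) -> "CatalogData":
        hist = compress_to_survey_years(records, first_year, last_year)
        ks = build_known_states(hist, records, pre_study_records)
        cov = build_covariates(list(records) + list(pre_study_records), hist)
        data = cls(hist, ks, cov)
        return data.augment(n_aug) if n_aug else data

    def augment(self, n_aug: int) -> "CatalogData":
        """Augmented copy: all-zero histories, unknown states, missing sex, age 5+."""
        hist = augment(self.histories, n_aug)
        T = hist.n_years
        states = np.vstack(
            [self.known_states.states, np.zeros((n_aug, T), dtype=np.int8)]
        )
        cov = CovariateSet(
            np.concatenate([self.covariates.sex, np.full(n_aug, np.nan)]),
            np.vstack([self.covariates.age, np.full((n_aug, T), MAX_AGE_CLASS, np.int8)]),
            np.vstack([self.covariates.adult, np.ones((n_aug, T), np.int8)]),
        )
        return CatalogData(hist, KnownStateMatrix(states), cov)
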
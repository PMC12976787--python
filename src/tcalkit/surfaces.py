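"""In-memory containers for age x calendar-year mortality data.

All surfaces live on a rectangular Lexis grid of 1-year x 1-year
age-period cells: cell ``(x, t)`` covers ages ``[x, x+1)`` and calendar
time ``[t, t+1)``.  Ages run ``0..omega`` with the last age optionally
flagged as an open interval (``110+`` in HMD files); years run ``t0..T``.
Arrays are indexed ``[age, year]`` (causes first for count cubes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "MortalitySurface",
    "CauseDeathSurface",
    "ExposureSurface",
    "CauseFractionSurface",
    "check_same_grid",
]


def _as_consecutive_int_axis(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.int64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-d integer array")
    if arr.size > 1 and not np.all(np.diff(arr) == 1):
        raise ValueError(f"{name} must increase in steps of 1, got {arr[:5]}...")
    return arr


def _check_sex(sex: str) -> str:
    sex = str(sex).lower()
    if sex not in ("female", "male", "total"):
        raise ValueError(f"sex must be 'female', 'male' or 'total', got {sex!r}")
    return sex


@dataclass(frozen=True)
class MortalitySurface:
    """Central death rates ``m(x, t)`` for one sex on an age x year grid.

    Parameters
    ----------
    sex : {'female', 'male', 'total'}
    ages : array of int
        Consecutive single ages ``0..omega``.
    years : array of int
        Consecutive calendar years ``t0..T``.
    rates : ndarray, shape (n_ages, n_years)
        Central death rates per person-year.  Must be finite and
        non-negative wherever not flagged missing.
    open_age : bool
        Whether the last age is an open interval (e.g. ``110+``).
    missing : ndarray of bool, optional
        Mask of cells with no observation.  Missing cells are explicit;
        they are never silently treated as zero.
    """

    sex: str
    ages: np.ndarray
    years: np.ndarray
    rates: np.ndarray
    open_age: bool = True
    missing: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "sex", _check_sex(self.sex))
        ages = _as_consecutive_int_axis(self.ages, "ages")
        years = _as_consecutive_int_axis(self.years, "years")
        rates = np.asarray(self.rates, dtype=float)
        if rates.shape != (ages.size, years.size):
            raise ValueError(
                f"rates shape {rates.shape} does not match grid "
                f"({ages.size} ages x {years.size} years)"
            )
        missing = self.missing
        if missing is not None:
            missing = np.asarray(missing, dtype=bool)
            if missing.shape != rates.shape:
                raise ValueError("missing mask shape must match rates")
            if not missing.any():
                missing = None
        observed = rates if missing is None else rates[~missing]
        if observed.size and (not np.all(np.isfinite(observed)) or np.any(observed < 0)):
            raise ValueError("rates must be finite and >= 0 at observed cells")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "missing", missing)

    # -- convenience -------------------------------------------------
    @property
    def omega(self) -> int:
        return int(self.ages[-1])

    def year_index(self, year: int) -> int:
        if not (self.years[0] <= year <= self.years[-1]):
            raise ValueError(
                f"year {year} outside grid {self.years[0]}..{self.years[-1]}"
            )
        return int(year - self.years[0])

    def rate_column(self, year: int) -> np.ndarray:
        """Rates for one calendar year (errors on missing cells)."""
        j = self.year_index(year)
        if self.missing is not None and self.missing[:, j].any():
            bad = self.ages[self.missing[:, j]]
            raise ValueError(f"year {year} has missing rates at ages {bad.tolist()}")
        return self.rates[:, j].copy()

    def with_rates(self, rates: np.ndarray) -> "MortalitySurface":
        return replace(self, rates=np.asarray(rates, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rates, index=self.ages, columns=self.years)
        df.index.name = "age"
        df.columns.name = "year"
        return df


@dataclass(frozen=True)
class ExposureSurface:
    """Person-years of exposure ``E(x, t)`` for one sex."""

    sex: str
    ages: np.ndarray
    years: np.ndarray
    person_years: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sex", _check_sex(self.sex))
        ages = _as_consecutive_int_axis(self.ages, "ages")
        years = _as_consecutive_int_axis(self.years, "years")
        py = np.asarray(self.person_years, dtype=float)
        if py.shape != (ages.size, years.size):
            raise ValueError("person_years shape must match grid")
        if not np.all(np.isfinite(py)) or np.any(py < 0):
            raise ValueError("person_years must be finite and >= 0")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "person_years", py)


@dataclass(frozen=True)
class CauseDeathSurface:
    """Death counts ``D_i(x, t)`` by cause category for one sex.

    ``counts`` is a cube indexed ``[cause, band, year]``.  The age axis
    is a list of bands ``(start, end)`` with inclusive ends (``end is
    None`` marks the open interval); single-year data use width-1 bands
    and expose an ``ages`` vector.  Counts from sampled or registered
    data are integers; deterministic expected-count surfaces may be
    real-valued, which ``integer_valued`` reports.
    """

    sex: str
    years: np.ndarray
    causes: tuple
    counts: np.ndarray
    bands: tuple = None  # ((start, end_inclusive_or_None), ...)

    def __post_init__(self):
        object.__setattr__(self, "sex", _check_sex(self.sex))
        years = _as_consecutive_int_axis(self.years, "years")
        causes = tuple(str(c) for c in self.causes)
        if len(set(causes)) != len(causes):
            raise ValueError("cause labels must be unique")
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 3 or counts.shape[0] != len(causes):
            raise ValueError(
                f"counts must have shape (n_causes, n_bands, n_years), got {counts.shape}"
            )
        if counts.shape[2] != years.size:
            raise ValueError("counts year axis does not match years")
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise ValueError("counts must be finite and >= 0")
        bands = self.bands
        if bands is None:
            bands = tuple((a, a) for a in range(counts.shape[1]))
        bands = tuple(
            (int(lo), None if hi is None else int(hi)) for lo, hi in bands
        )
        if len(bands) != counts.shape[1]:
            raise ValueError("bands do not match counts age axis")
        for lo, hi in bands:
            if hi is not None and hi < lo:
                raise ValueError(f"band ({lo}, {hi}) has end before start")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "causes", causes)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "bands", bands)

    # -- properties --------------------------------------------------
    @property
    def total(self) -> np.ndarray:
        """All-cause deaths ``D(x, t)`` per cell."""
        return self.counts.sum(axis=0)

    @property
    def integer_valued(self) -> bool:
        return bool(np.allclose(self.counts, np.round(self.counts), atol=1e-9))

    @property
    def single_year(self) -> bool:
        return all(hi == lo for lo, hi in self.bands[:-1]) and (
            self.bands[-1][1] is None or self.bands[-1][1] == self.bands[-1][0]
        )

    @property
    def ages(self) -> np.ndarray:
        if not self.single_year:
            raise ValueError("surface is age-banded; expand to single ages first")
        return np.array([lo for lo, _ in self.bands], dtype=np.int64)

    def cause_index(self, cause: str) -> int:
        try:
            return self.causes.index(cause)
        except ValueError:
            raise KeyError(f"unknown cause {cause!r}; have {self.causes}") from None

    def with_counts(self, counts: np.ndarray) -> "CauseDeathSurface":
        return replace(self, counts=np.asarray(counts, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, cause in enumerate(self.causes):
            df = pd.DataFrame(self.counts[k], columns=self.years)
            df.insert(0, "age_start", [lo for lo, _ in self.bands])
            df.insert(1, "age_end", [lo if hi is None else hi for lo, hi in self.bands])
            df.insert(0, "cause", cause)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class CauseFractionSurface:
    """Cause-of-death fractions by single age for one sex.

    ``fractions[cause, age]`` gives the share of deaths at that age
    attributed to the cause; shares are non-negative and sum to one at
    every age.  The schedule is taken as constant over calendar time.
    """

    sex: str
    ages: np.ndarray
    causes: tuple
    fractions: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sex", _check_sex(self.sex))
        ages = _as_consecutive_int_axis(self.ages, "ages")
        causes = tuple(str(c) for c in self.causes)
        frac = np.asarray(self.fractions, dtype=float)
        if frac.shape != (len(causes), ages.size):
            raise ValueError("fractions must have shape (n_causes, n_ages)")
        if np.any(frac < 0) or not np.all(np.isfinite(frac)):
            raise ValueError("fractions must be finite and >= 0")
        colsums = frac.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-12):
            bad = ages[np.argmax(np.abs(colsums - 1.0))]
            raise ValueError(f"cause fractions do not sum to 1 at age {bad}")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "causes", causes)
        object.__setattr__(self, "fractions", frac)


def check_same_grid(a, b, what: str = "surfaces") -> None:
    """Raise if two grid-carrying objects disagree on ages/bands or years."""
    ax_a = a.bands if isinstance(a, CauseDeathSurface) else tuple(np.asarray(a.ages))
    ax_b = b.bands if isinstance(b, CauseDeathSurface) else tuple(np.asarray(b.ages))
    if isinstance(a, CauseDeathSurface) != isinstance(b, CauseDeathSurface):
        # compare a banded object against a single-year one via age starts
        ages_a = [lo for lo, _ in a.bands] if isinstance(a, CauseDeathSurface) else list(np.asarray(a.ages))
        ages_b = [lo for lo, _ in b.bands] if isinstance(b, CauseDeathSurface) else list(np.asarray(b.ages))
        same_ages = ages_a == ages_b
    else:
        same_ages = list(ax_a) == list(ax_b)
    if not same_ages or not np.array_equal(a.years, b.years):
        raise ValueError(f"{what} are not on the same age x year grid")
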
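"""Synthetic sex- and cause-specific mortality surfaces with known truth.

The generator stands in for registered-access mortality databases: it
produces all-cause rate surfaces in the same shape as single-age,
single-year national series, plus cause-of-death count tables, so the
whole pipeline (IO, TCAL, decomposition, bootstrap) is testable offline
against known ground truth.

Hazard family
-------------
Gompertz-Makeham with a multiplicative period decline on the senescent
term:

    m(x, t) = a + b * exp(beta * x) * exp(-rho * (t - t0)),

per sex.  This is the simplest family with realistic age profiles and
secularly improving mortality; cohort structure arises implicitly from
the age x period surface, which is all TCAL consumes.

Cause structure
---------------
Each cause category carries an age profile (uniform, Gaussian bump with
a stated modal age, or a young-adult hump for external causes) and a
weight, possibly sex-specific; realized cause fractions at an age are
the weighted profile densities renormalised to sum to one.  The default
"paper-like" preset encodes a male excess in all-cause mortality at
every age together with a female excess in neoplasm mortality between
ages 35 and 60 driven by breast and gynecological cancers.

One integer seed governs a whole generation run; per-sex sub-streams are
derived from it deterministically, so generating the sexes in any order
gives identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from ._sampling import multinomial_split, rng_for
from .surfaces import (
    CauseDeathSurface,
    CauseFractionSurface,
    ExposureSurface,
    MortalitySurface,
)

__all__ = [
    "HazardParams",
    "CauseProfile",
    "SyntheticParams",
    "make_hazard_surface",
    "make_cause_fraction_surface",
    "expected_death_counts",
    "sample_death_counts",
    "generate_dataset",
    "paper_like_params",
    "write_fixture_files",
    "params_to_yaml",
    "params_from_yaml",
]

_SEX_STREAM = {"female": 0, "male": 1, "total": 2}


@dataclass(frozen=True)
class HazardParams:
    """Gompertz-Makeham-with-decline parameters for one sex.

    makeham_a : baseline (age-independent) hazard, per person-year
    gompertz_b : senescent hazard scale at age 0, per person-year
    gompertz_beta : log-slope of the senescent hazard per year of age
    period_rho : proportional mortality decline per calendar year
    """

    makeham_a: float
    gompertz_b: float
    gompertz_beta: float
    period_rho: float

    def __post_init__(self):
        for name in ("makeham_a", "gompertz_b", "gompertz_beta", "period_rho"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"hazard parameter {name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"hazard parameter {name} must be >= 0, got {v!r}")
        if self.gompertz_beta <= 0:
            raise ValueError("hazard parameter gompertz_beta must be > 0")


@dataclass(frozen=True)
class CauseProfile:
    """Age profile and weight of one cause category.

    kind is one of ``uniform`` (flat), ``gaussian`` (bump with modal age
    ``mean`` and width ``sd``, peak-normalised to 1) or
    ``young_adult_hump`` (accident hump centred near age 22 on a small
    flat floor).  ``weight`` may be a single number or a per-sex mapping.
    """

    cause: str
    sexes: tuple = ("female", "male")
    kind: str = "uniform"
    weight: float | dict = 1.0
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "sexes", tuple(self.sexes))
        if self.kind not in ("uniform", "gaussian", "young_adult_hump"):
            raise ValueError(f"unknown age-profile kind {self.kind!r}")
        if self.kind == "gaussian" and (self.mean is None or self.sd is None or self.sd <= 0):
            raise ValueError(f"gaussian profile for {self.cause!r} needs mean and sd > 0")
        for w in (self.weight.values() if isinstance(self.weight, dict) else [self.weight]):
            if not math.isfinite(w) or w < 0:
                raise ValueError(f"cause weight for {self.cause!r} must be finite and >= 0")

    def weight_for(self, sex: str) -> float:
        if sex not in self.sexes:
            return 0.0
        if isinstance(self.weight, dict):
            return float(self.weight.get(sex, 0.0))
        return float(self.weight)

    def density(self, ages: np.ndarray) -> np.ndarray:
        x = np.asarray(ages, dtype=float)
        if self.kind == "uniform":
            return np.ones_like(x)
        if self.kind == "gaussian":
            return np.exp(-0.5 * ((x - self.mean) / self.sd) ** 2)
        # young-adult hump: bump at 22 with width 8 on a floor of 0.15
        return 0.15 + 0.85 * np.exp(-0.5 * ((x - 22.0) / 8.0) ** 2)


@dataclass(frozen=True)
class SyntheticParams:
    """Full configuration of one synthetic two-sex population."""

    hazards: dict
    cause_profiles: tuple
    exposure: float = 1.5e5
    age_max: int = 110
    year_start: int = 1955
    year_end: int = 2020
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "cause_profiles", tuple(self.cause_profiles))
        for sex, hp in self.hazards.items():
            if not isinstance(hp, HazardParams):
                raise TypeError(f"hazards[{sex!r}] must be HazardParams")
        if self.age_max < 1:
            raise ValueError("age_max must be >= 1")
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        if not math.isfinite(self.exposure) or self.exposure < 0:
            raise ValueError("exposure must be finite and >= 0")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_max + 1)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def causes(self) -> tuple:
        seen = []
        for p in self.cause_profiles:
            if p.cause not in seen:
                seen.append(p.cause)
        return tuple(seen)


def make_hazard_surface(params: SyntheticParams, sex: str) -> MortalitySurface:
    """Deterministic all-cause rate surface m(x,t) for one sex."""
    if sex not in params.hazards:
        raise ValueError(f"no hazard parameters for sex {sex!r}")
    hp = params.hazards[sex]
    x = params.ages[:, None].astype(float)
    t = (params.years[None, :] - params.year_start).astype(float)
    rates = hp.makeham_a + hp.gompertz_b * np.exp(hp.gompertz_beta * x) * np.exp(
        -hp.period_rho * t
    )
    return MortalitySurface(sex=sex, ages=params.ages, years=params.years, rates=rates)


def make_cause_fraction_surface(params: SyntheticParams, sex: str) -> CauseFractionSurface:
    """Per-age cause fractions for one sex (weights x profile densities, renormalised)."""
    profiles = params.cause_profiles
    if not profiles:
        raise ValueError("cause_profiles is empty")
    if not any(sex in p.sexes for p in profiles):
        raise ValueError(f"no cause profile applies to sex {sex!r}")
    causes = params.causes
    raw = np.zeros((len(causes), params.ages.size))
    for p in profiles:
        k = causes.index(p.cause)
        raw[k] += p.weight_for(sex) * p.density(params.ages)
    colsum = raw.sum(axis=0)
    if np.any(colsum <= 0):
        age = int(params.ages[np.argmax(colsum <= 0)])
        raise ValueError(f"all cause weights are zero at age {age} for sex {sex!r}")
    return CauseFractionSurface(
        sex=sex, ages=params.ages, causes=causes, fractions=raw / colsum
    )


def _exposure_surface(params: SyntheticParams, sex: str) -> ExposureSurface:
    py = np.full((params.ages.size, params.years.size), float(params.exposure))
    return ExposureSurface(sex=sex, ages=params.ages, years=params.years, person_years=py)


def expected_death_counts(
    rates: MortalitySurface,
    fractions: CauseFractionSurface,
    exposure: ExposureSurface,
) -> CauseDeathSurface:
    """Deterministic counts D_i = m * E * f_i (real-valued; oracle mode)."""
    _check_alignment(rates, fractions, exposure)
    total = rates.rates * exposure.person_years
    counts = fractions.fractions[:, :, None] * total[None, :, :]
    return CauseDeathSurface(
        sex=rates.sex, years=rates.years, causes=fractions.causes, counts=counts
    )


def sample_death_counts(
    rates: MortalitySurface,
    fractions: CauseFractionSurface,
    exposure: ExposureSurface,
    seed: int,
) -> CauseDeathSurface:
    """Poisson totals per cell, multinomially split over causes.

    Identical seed gives bitwise-identical tables; the sex label selects
    an independent sub-stream of the seed.
    """
    _check_alignment(rates, fractions, exposure)
    rng = rng_for(seed, _SEX_STREAM[rates.sex])
    mean = rates.rates * exposure.person_years
    totals = rng.poisson(mean)
    counts = multinomial_split(rng, totals, fractions.fractions[:, :, None])
    return CauseDeathSurface(
        sex=rates.sex, years=rates.years, causes=fractions.causes, counts=counts
    )


def _check_alignment(rates, fractions, exposure):
    if not np.array_equal(rates.ages, fractions.ages):
        raise ValueError("rates and cause fractions are on different age grids")
    if not np.array_equal(rates.ages, exposure.ages) or not np.array_equal(
        rates.years, exposure.years
    ):
        raise ValueError("rates and exposure are on different grids")


def generate_dataset(params: SyntheticParams, mode: str = "sampled", seed: int | None = None) -> dict:
    """Generate both sexes' rates, fractions, exposures and counts.

    mode is ``expected`` (deterministic, counts = rate x exposure, for
    exact oracle tests) or ``sampled`` (Poisson totals + multinomial
    cause split).  Returns ``{sex: {"rates", "fractions", "exposure",
    "counts"}}`` for every sex with hazard parameters.
    """
    if mode not in ("expected", "sampled"):
        raise ValueError(f"mode must be 'expected' or 'sampled', got {mode!r}")
    seed = params.seed if seed is None else int(seed)
    out = {}
    for sex in params.hazards:
        rates = make_hazard_surface(params, sex)
        fracs = make_cause_fraction_surface(params, sex)
        exp = _exposure_surface(params, sex)
        if mode == "expected":
            counts = expected_death_counts(rates, fracs, exp)
        else:
            counts = sample_death_counts(rates, fracs, exp, seed)
        out[sex] = {"rates": rates, "fractions": fracs, "exposure": exp, "counts": counts}
    return out


def paper_like_params(
    age_max: int = 110,
    year_start: int = 1955,
    year_end: int = 2020,
    exposure: float = 1.5e5,
    seed: int = 0,
) -> SyntheticParams:
    """Default preset emulating a low-mortality country pair of sexes.

    Male all-cause hazards exceed female hazards at every age (doubled
    baseline, 1.5x senescent scale); both sexes improve at 1% per year.
    The cause schedule gives females a midlife neoplasm excess through
    breast and gynecological cancer bumps centred in the early 50s,
    while males carry heavier lung/larynx/trachea/bronchus, external
    and cardiovascular shares.  Default exposure of 150 000 person-years
    per age-year cell is in the range implied by national populations of
    tens of millions spread over ~111 ages.
    """
    hazards = {
        "female": HazardParams(2.0e-4, 3.0e-5, 0.095, 0.010),
        "male": HazardParams(4.0e-4, 4.5e-5, 0.095, 0.010),
    }
    profiles = (
        CauseProfile("breast", ("female",), "gaussian", 0.12, mean=52, sd=11),
        CauseProfile("gynecological", ("female",), "gaussian", 0.08, mean=54, sd=12),
        CauseProfile(
            "lung_larynx_trachea_bronchus",
            ("female", "male"),
            "gaussian",
            {"female": 0.05, "male": 0.08},
            mean=66,
            sd=10,
        ),
        CauseProfile("prostate", ("male",), "gaussian", 0.05, mean=76, sd=9),
        CauseProfile(
            "other_cancers",
            ("female", "male"),
            "gaussian",
            {"female": 0.10, "male": 0.09},
            mean=63,
            sd=18,
        ),
        # cardiovascular mortality peaks later in women than in men
        CauseProfile("cardiovascular", ("female",), "gaussian", 0.32, mean=78, sd=14),
        CauseProfile("cardiovascular", ("male",), "gaussian", 0.35, mean=74, sd=14),
        CauseProfile(
            "external",
            ("female", "male"),
            "young_adult_hump",
            {"female": 0.04, "male": 0.09},
        ),
        CauseProfile("residual", ("female", "male"), "uniform", 0.34),
    )
    return SyntheticParams(
        hazards=hazards,
        cause_profiles=profiles,
        exposure=exposure,
        age_max=age_max,
        year_start=year_start,
        year_end=year_end,
        seed=seed,
    )


def write_fixture_files(out_dir, rates: dict, counts: dict, exposures: dict) -> dict:
    """Write generated surfaces in the two on-disk dialects.

    Emits an HMD-style Mx_1x1 rate file (both sexes), a WHO-style long
    cause-count CSV and an HMD-style exposure file, such that the
    ``mortality_io`` readers recover the inputs (rates to 1e-12, counts
    exactly).  Returns the paths written.
    """
    from . import mortality_io as mio

    if not rates or not counts:
        raise ValueError("nothing to write: empty rate or count set")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rates": out_dir / "Mx_1x1.txt",
        "cause_counts": out_dir / "who_cause_counts.csv",
        "exposures": out_dir / "Exposures_1x1.txt",
    }
    mio.write_hmd_rates(paths["rates"], rates)
    mio.write_who_mdb(paths["cause_counts"], counts)
    mio.write_hmd_exposures(paths["exposures"], exposures)
    return paths


# ----------------------------------------------------------------------
# YAML round-trip of SyntheticParams

def params_to_yaml(params: SyntheticParams, path) -> None:
    doc = {
        "exposure": params.exposure,
        "age_max": params.age_max,
        "year_start": params.year_start,
        "year_end": params.year_end,
        "seed": params.seed,
        "hazards": {
            sex: {
                "makeham_a": hp.makeham_a,
                "gompertz_b": hp.gompertz_b,
                "gompertz_beta": hp.gompertz_beta,
                "period_rho": hp.period_rho,
            }
            for sex, hp in params.hazards.items()
        },
        "cause_profiles": [
            {
                "cause": p.cause,
                "sexes": list(p.sexes),
                "kind": p.kind,
                "weight": p.weight,
                **({"mean": p.mean, "sd": p.sd} if p.kind == "gaussian" else {}),
            }
            for p in params.cause_profiles
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def params_from_yaml(path) -> SyntheticParams:
    doc = yaml.safe_load(Path(path).read_text())
    hazards = {sex: HazardParams(**hp) for sex, hp in doc["hazards"].items()}
    profiles = tuple(
        CauseProfile(
            cause=p["cause"],
            sexes=tuple(p.get("sexes", ("female", "male"))),
            kind=p.get("kind", "uniform"),
            weight=p.get("weight", 1.0),
            mean=p.get("mean"),
            sd=p.get("sd"),
        )
        for p in doc["cause_profiles"]
    )
    return SyntheticParams(
        hazards=hazards,
        cause_profiles=profiles,
        exposure=float(doc.get("exposure", 1.5e5)),
        age_max=int(doc.get("age_max", 110)),
        year_start=int(doc.get("year_start", 1955)),
        year_end=int(doc.get("year_end", 2020)),
        seed=int(doc.get("seed", 0)),
    )
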
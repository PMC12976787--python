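"""Readers/writers for mortality-data dialects and ICD cause mapping.

Two on-disk dialects are supported:

* an HMD-style ``Mx_1x1`` fixed-column text table (columns ``Year Age
  Female Male Total``, ages ``0..109`` then ``110+`` for the open
  interval, ``.`` for missing values) for all-cause rates and for
  exposures;
* a WHO-mortality-database-style long CSV of cause-of-death counts, one
  row per (year, sex, ICD revision, cause code) with age-group columns
  (``Age50`` single year, ``Age35_39`` five-year band, ``Age95p`` open).

ICD codes are harmonised into eight analysis categories (breast,
gynecological, lung/larynx/trachea/bronchus, prostate, other cancers,
cardiovascular, external, residual) through a declarative, user-editable
:class:`CauseMapping`.  A documented default ships for ICD-9 and ICD-10;
ICD-7/8 data require user-supplied rules.  "Female reproductive
cancers" is the derived union breast + gynecological, never stored.

Cause-specific rate surfaces are built by scaling the all-cause rates
with the cause fractions of the count data, ``m_i = m * D_i / D``, which
keeps the all-cause TCAL identical to the rate source regardless of any
denominator quirks in the count source.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .surfaces import (
    CauseDeathSurface,
    ExposureSurface,
    MortalitySurface,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "NEOPLASM_CATEGORIES",
    "FEMALE_REPRODUCTIVE_CATEGORIES",
    "CauseMapping",
    "MappingRule",
    "default_cause_mapping",
    "load_cause_mapping",
    "read_hmd_rates",
    "read_hmd_exposures",
    "write_hmd_rates",
    "write_hmd_exposures",
    "read_who_mdb",
    "write_who_mdb",
    "distribute_to_single_ages",
    "cause_specific_rates",
]

CATEGORIES = (
    "breast",
    "gynecological",
    "lung_larynx_trachea_bronchus",
    "prostate",
    "other_cancers",
    "cardiovascular",
    "external",
    "residual",
)

#: Cancer categories making up the neoplasm aggregate.
NEOPLASM_CATEGORIES = (
    "breast",
    "gynecological",
    "lung_larynx_trachea_bronchus",
    "prostate",
    "other_cancers",
)

#: Breast plus gynecological cancers (derived union, not a stored category).
FEMALE_REPRODUCTIVE_CATEGORIES = ("breast", "gynecological")

_SEX_TO_WHO = {"male": 1, "female": 2}
_OPEN_RE = re.compile(r"^(\d+)\+$")


# ======================================================================
# ICD code handling

def _code_key(code: str, revision: int):
    """Comparable (letter, number) key for an ICD code root.

    ICD-10: letter + two digits (4th characters are truncated to the
    3-character root).  ICD-7/8/9: first three digits; ICD-9 external
    E-codes keep their ``E`` marker so they sort separately.
    """
    code = str(code).strip().upper().replace(".", "")
    if not code:
        raise ValueError("empty ICD code")
    if revision >= 10:
        if not code[0].isalpha() or len(code) < 3 or not code[1:3].isdigit():
            raise ValueError(f"malformed ICD-10 code {code!r}")
        return (code[0], int(code[1:3]))
    if code[0] == "E":
        if len(code) < 4 or not code[1:4].isdigit():
            raise ValueError(f"malformed ICD-{revision} E-code {code!r}")
        return ("E!", int(code[1:4]))  # '!' keeps E-codes off the letter axis
    if len(code) < 3 or not code[:3].isdigit():
        raise ValueError(f"malformed ICD-{revision} code {code!r}")
    return ("#", int(code[:3]))


def _expand_key_range(start, end, revision: int):
    """All 3-character roots between two keys, inclusive."""
    if revision >= 10:
        lo_letter, hi_letter = start[0], end[0]
        if lo_letter > hi_letter or (lo_letter == hi_letter and start[1] > end[1]):
            raise ValueError(f"ICD range runs backwards: {start}..{end}")
        roots = []
        for letter in map(chr, range(ord(lo_letter), ord(hi_letter) + 1)):
            n0 = start[1] if letter == lo_letter else 0
            n1 = end[1] if letter == hi_letter else 99
            roots.extend((letter, n) for n in range(n0, n1 + 1))
        return roots
    if start[0] != end[0]:
        raise ValueError("ICD-7/8/9 range cannot mix E-codes and numeric codes")
    if start[1] > end[1]:
        raise ValueError(f"ICD range runs backwards: {start}..{end}")
    return [(start[0], n) for n in range(start[1], end[1] + 1)]


@dataclass(frozen=True)
class MappingRule:
    """One declarative rule: ICD revision + code (range) -> category."""

    revision: int
    codes: str  # "C50" or "C51-C58"
    category: str

    def roots(self):
        text = self.codes.strip()
        if "-" in text:
            lo, hi = (p.strip() for p in text.split("-", 1))
        else:
            lo = hi = text
        return _expand_key_range(
            _code_key(lo, self.revision), _code_key(hi, self.revision), self.revision
        )


@dataclass(frozen=True)
class CauseMapping:
    """Harmonisation of ICD (revision, code) pairs into analysis categories.

    ``revisions`` lists the ICD revisions the mapping claims to cover;
    codes in a covered revision that match no rule fall into
    ``residual``.  Data in a revision outside ``revisions`` are rejected
    rather than silently dumped into residual.
    """

    rules: tuple = ()
    categories: tuple = CATEGORIES
    revisions: frozenset = frozenset()

    def __post_init__(self):
        rules = tuple(self.rules)
        categories = tuple(self.categories)
        if "residual" not in categories:
            categories = categories + ("residual",)
        revisions = frozenset(self.revisions) | {r.revision for r in rules}
        lookup = {}
        for rule in rules:
            if rule.category not in categories:
                raise ValueError(
                    f"rule {rule.codes!r} maps to undeclared category {rule.category!r}"
                )
            for root in rule.roots():
                prev = lookup.setdefault((rule.revision, root), rule)
                if prev is not rule and prev.category != rule.category:
                    raise ValueError(
                        f"ICD-{rule.revision} code {root} assigned to both "
                        f"{prev.category!r} (rule {prev.codes!r}) and "
                        f"{rule.category!r} (rule {rule.codes!r})"
                    )
        object.__setattr__(self, "rules", rules)
        object.__setattr__(self, "categories", categories)
        object.__setattr__(self, "revisions", revisions)
        object.__setattr__(self, "_lookup", lookup)

    def category_for(self, revision: int, code: str) -> str:
        """Category of one code; unmapped codes in a covered revision -> residual."""
        revision = int(revision)
        if revision not in self.revisions:
            raise ValueError(
                f"ICD revision {revision} is not covered by the cause mapping "
                f"(covered: {sorted(self.revisions) or 'none'}); supply rules for it"
            )
        rule = self._lookup.get((revision, _code_key(code, revision)))
        return rule.category if rule is not None else "residual"


def default_cause_mapping() -> CauseMapping:
    """Default ICD-9/ICD-10 mapping for the eight analysis categories.

    The lists are deliberately coarse 3-character ranges (e.g. breast =
    C50 / 174, gynecological = C51-C58 / 179-184); users with stricter
    coding requirements can supply their own configuration.  ICD-7/8
    ship no default rules: reading ICD-7/8 data without user-supplied
    rules raises a "mapping required" error.
    """
    r = MappingRule
    rules = (
        # ICD-10
        r(10, "C50", "breast"),
        r(10, "C51-C58", "gynecological"),
        r(10, "C32-C34", "lung_larynx_trachea_bronchus"),
        r(10, "C61", "prostate"),
        r(10, "C00-C31", "other_cancers"),
        r(10, "C35-C49", "other_cancers"),
        r(10, "C59-C60", "other_cancers"),
        r(10, "C62-C97", "other_cancers"),
        r(10, "I00-I99", "cardiovascular"),
        r(10, "V01-Y89", "external"),
        # ICD-9
        r(9, "174", "breast"),
        r(9, "179-184", "gynecological"),
        r(9, "161-162", "lung_larynx_trachea_bronchus"),
        r(9, "185", "prostate"),
        r(9, "140-160", "other_cancers"),
        r(9, "163-173", "other_cancers"),
        r(9, "175-178", "other_cancers"),
        r(9, "186-208", "other_cancers"),
        r(9, "390-459", "cardiovascular"),
        r(9, "E800-E999", "external"),
    )
    return CauseMapping(rules=rules, categories=CATEGORIES, revisions=frozenset({9, 10}))


def load_cause_mapping(path) -> CauseMapping:
    """Parse a YAML cause-mapping configuration.

    Schema::

        categories: [breast, ...]      # optional, defaults to the eight
        revisions: [9, 10]             # optional; default = rule revisions
        rules:
          - revision: 10
            category: breast
            codes: [C50]               # single codes or "C51-C58" ranges

    An empty file is a valid mapping covering every revision with
    residual-only behaviour (all codes fall into ``residual``).
    """
    doc = yaml.safe_load(Path(path).read_text())
    if doc is None:
        doc = {}
    categories = tuple(doc.get("categories", CATEGORIES))
    rules = []
    for entry in doc.get("rules", []) or []:
        rev = int(entry["revision"])
        cat = str(entry["category"])
        codes = entry["codes"]
        if isinstance(codes, str):
            codes = [codes]
        rules.extend(MappingRule(rev, str(c), cat) for c in codes)
    if "revisions" in doc:
        revisions = frozenset(int(r) for r in doc["revisions"])
    elif rules:
        revisions = frozenset()
    else:
        revisions = frozenset({7, 8, 9, 10})
    return CauseMapping(rules=tuple(rules), categories=categories, revisions=revisions)


# ======================================================================
# HMD-style fixed-column tables

def _parse_hmd_table(path, value_columns=("Female", "Male", "Total")):
    """Parse the HMD 1x1 dialect into {column: {(year, age): value}}."""
    lines = Path(path).read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if tokens[:2] == ["Year", "Age"]:
            header_idx = i
            columns = tokens
            break
    if header_idx is None:
        raise ValueError(f"{path}: no 'Year Age ...' header line found")
    missing_cols = [c for c in value_columns if c not in columns]
    if missing_cols:
        raise ValueError(f"{path}: header lacks columns {missing_cols}")

    data = {c: {} for c in value_columns}
    open_ages = set()
    seen = set()
    last_year = None
    n_rows = 0
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != len(columns):
            raise ValueError(
                f"{path}:{lineno}: expected {len(columns)} fields, got {len(tokens)}"
            )
        row = dict(zip(columns, tokens))
        try:
            year = int(row["Year"])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: bad year {row['Year']!r}") from None
        age_token = row["Age"]
        m = _OPEN_RE.match(age_token)
        if m:
            age = int(m.group(1))
            open_ages.add(age)
        elif age_token.isdigit():
            age = int(age_token)
        else:
            raise ValueError(f"{path}:{lineno}: unknown age token {age_token!r}")
        if last_year is not None and year < last_year:
            raise ValueError(f"{path}:{lineno}: years not in nondecreasing order")
        last_year = year
        if (year, age) in seen:
            raise ValueError(f"{path}:{lineno}: duplicate entry for year {year}, age {age}")
        seen.add((year, age))
        for col in value_columns:
            token = row[col]
            if token == ".":
                data[col][(year, age)] = None
            else:
                try:
                    data[col][(year, age)] = float(token)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: bad value {token!r} in column {col}"
                    ) from None
        n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{path}: table has no data rows")
    logger.info("%s: parsed %d rows", path, n_rows)
    return data, open_ages


def _hmd_to_surface(path, sex, cls, field):
    column = sex.capitalize()
    data, open_ages = _parse_hmd_table(path, value_columns=(column,))
    cells = data[column]
    years = sorted({y for y, _ in cells})
    ages = sorted({a for _, a in cells})
    years_axis = np.arange(years[0], years[-1] + 1)
    ages_axis = np.arange(ages[0], ages[-1] + 1)
    values = np.zeros((ages_axis.size, years_axis.size))
    missing = np.ones_like(values, dtype=bool)  # absent cells stay flagged
    for (year, age), v in cells.items():
        i, j = age - ages_axis[0], year - years_axis[0]
        if v is None:
            continue
        values[i, j] = v
        missing[i, j] = False
    kwargs = {field: values}
    if cls is MortalitySurface:
        kwargs["missing"] = missing
        kwargs["open_age"] = bool(open_ages)
        return MortalitySurface(sex=sex, ages=ages_axis, years=years_axis, **kwargs)
    if missing.any():
        raise ValueError(f"{path}: exposure table has missing cells")
    return ExposureSurface(sex=sex, ages=ages_axis, years=years_axis, **kwargs)


def read_hmd_rates(path, sex: str) -> MortalitySurface:
    """Read one sex's central death rates from an Mx_1x1-style file.

    ``110+`` (or any ``N+``) is parsed as the open age group; ``.`` and
    absent (year, age) pairs become missing-flagged cells.
    """
    return _hmd_to_surface(path, sex, MortalitySurface, "rates")


def read_hmd_exposures(path, sex: str) -> ExposureSurface:
    """Read one sex's person-years from an Exposures_1x1-style file."""
    return _hmd_to_surface(path, sex, ExposureSurface, "person_years")


def _write_hmd_table(path, surfaces: dict, field: str, title: str) -> None:
    sexes = {s: surf for s, surf in surfaces.items()}
    ref = next(iter(sexes.values()))
    for surf in sexes.values():
        if not np.array_equal(surf.ages, ref.ages) or not np.array_equal(
            surf.years, ref.years
        ):
            raise ValueError("all sexes must share one grid when writing")
    if ref.ages.size == 0 or ref.years.size == 0:
        raise ValueError("refusing to write an empty grid")

    def value(surf, i, j):
        if isinstance(surf, MortalitySurface) and surf.missing is not None and surf.missing[i, j]:
            return "."
        return f"{getattr(surf, field)[i, j]:.14f}"

    female = sexes.get("female")
    male = sexes.get("male")
    total = sexes.get("total")
    lines = [title, ""]
    lines.append(f"{'Year':>6}{'Age':>8}{'Female':>22}{'Male':>22}{'Total':>22}")
    omega = int(ref.ages[-1])
    open_age = getattr(ref, "open_age", True)
    for j, year in enumerate(ref.years):
        for i, age in enumerate(ref.ages):
            age_token = f"{age}+" if (open_age and age == omega) else str(age)
            cells = []
            for surf in (female, male):
                cells.append(value(surf, i, j) if surf is not None else ".")
            if total is not None:
                cells.append(value(total, i, j))
            elif female is not None and male is not None:
                fv, mv = cells
                if fv == "." or mv == ".":
                    cells.append(".")
                else:
                    cells.append(f"{(float(fv) + float(mv)) / 2:.14f}")
            else:
                cells.append(".")
            lines.append(
                f"{year:>6}{age_token:>8}{cells[0]:>22}{cells[1]:>22}{cells[2]:>22}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_hmd_rates(path, surfaces: dict) -> None:
    """Write rate surfaces (keys 'female'/'male'[/'total']) in the Mx_1x1 dialect."""
    _write_hmd_table(path, surfaces, "rates", "Synthetic population, Death rates (period 1x1)")


def write_hmd_exposures(path, surfaces: dict) -> None:
    _write_hmd_table(
        path, surfaces, "person_years", "Synthetic population, Exposure to risk (period 1x1)"
    )


# ======================================================================
# WHO-MDB-style cause-of-death tables

#: Representative ICD-10 code used when writing synthetic category counts.
CATEGORY_CODES = {
    "breast": "C50",
    "gynecological": "C53",
    "lung_larynx_trachea_bronchus": "C34",
    "prostate": "C61",
    "other_cancers": "C18",
    "cardiovascular": "I25",
    "external": "V99",
    "residual": "R99",
}

_AGE_COL_RE = re.compile(r"^Age(\d+)(?:_(\d+)|(p))?$")


def _band_to_column(lo: int, hi) -> str:
    if hi is None:
        return f"Age{lo}p"
    if hi == lo:
        return f"Age{lo}"
    return f"Age{lo}_{hi}"


def write_who_mdb(path, counts: dict, codes: dict | None = None, revision: int = 10) -> None:
    """Write cause-count surfaces as a WHO-style long CSV.

    One row per (year, sex, cause); age-group columns named from the
    surface's bands.  ``codes`` maps cause labels to ICD codes (default:
    representative ICD-10 codes for the standard categories).
    """
    codes = {**CATEGORY_CODES, **(codes or {})}
    frames = []
    for sex, surf in counts.items():
        if surf.counts.size == 0:
            raise ValueError("refusing to write an empty count grid")
        unmatched = [c for c in surf.causes if c not in codes]
        if unmatched:
            raise ValueError(f"no ICD code assigned for causes {unmatched}")
        age_cols = [_band_to_column(lo, hi) for lo, hi in surf.bands]
        for k, cause in enumerate(surf.causes):
            block = pd.DataFrame(surf.counts[k].T, columns=age_cols)
            block.insert(0, "Year", surf.years)
            block.insert(1, "Sex", _SEX_TO_WHO[sex])
            block.insert(2, "Revision", revision)
            block.insert(3, "Cause", codes[cause])
            frames.append(block)
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["Year", "Sex", "Cause"], kind="stable")
    table.to_csv(path, index=False, float_format="%.10g")


def read_who_mdb(path, mapping: CauseMapping, sex: str) -> CauseDeathSurface:
    """Read one sex's cause-of-death counts, harmonised through ``mapping``.

    Codes matching no rule of a covered revision accumulate into
    ``residual``; a revision outside the mapping's coverage raises.  Age
    bands are kept as-is — expand with :func:`distribute_to_single_ages`.
    """
    table = pd.read_csv(path)
    required = {"Year", "Sex", "Revision", "Cause"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(table.columns))}")
    bands = []
    age_cols = []
    for col in table.columns:
        m = _AGE_COL_RE.match(str(col))
        if m:
            lo = int(m.group(1))
            hi = None if m.group(3) else int(m.group(2) or m.group(1))
            bands.append((lo, hi))
            age_cols.append(col)
    if not age_cols:
        raise ValueError(f"{path}: no age-group columns found")
    order = np.argsort([lo for lo, _ in bands])
    bands = [bands[i] for i in order]
    age_cols = [age_cols[i] for i in order]

    sel = table[table["Sex"] == _SEX_TO_WHO[sex.lower()]]
    if sel.empty:
        raise ValueError(f"{path}: no rows for sex {sex!r}")
    values = sel[age_cols].to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{path}: negative death counts present")

    years_axis = np.arange(int(sel["Year"].min()), int(sel["Year"].max()) + 1)
    mapping_cats = mapping.categories
    counts = np.zeros((len(mapping_cats), len(bands), years_axis.size))
    unmapped = 0
    for (year, rev, code), block in sel.groupby(["Year", "Revision", "Cause"], sort=False):
        category = mapping.category_for(int(rev), str(code))
        if category == "residual":
            unmapped += 1
        k = mapping_cats.index(category)
        j = int(year) - years_axis[0]
        counts[k, :, j] += block[age_cols].to_numpy(dtype=float).sum(axis=0)
    logger.info(
        "%s: %d rows for %s, %d (year, code) groups in residual",
        path, len(sel), sex, unmapped,
    )
    return CauseDeathSurface(
        sex=sex, years=years_axis, causes=mapping_cats, counts=counts, bands=tuple(bands)
    )


# ======================================================================
# Age-band expansion and cause-specific rates

def distribute_to_single_ages(
    banded: CauseDeathSurface,
    weights: MortalitySurface | None = None,
    integer: bool | None = None,
) -> CauseDeathSurface:
    """Expand age-banded counts to single years of age.

    Within each band and (cause, year) cell, counts are spread
    proportionally to ``weights`` — typically the same sex/year's
    all-cause death distribution (counts, or rates as a proxy) on the
    single-age grid — falling back to a uniform split where no weights
    are available or they sum to zero over the band.  Band totals are
    conserved exactly; integer input is kept integer through
    largest-remainder rounding (ties resolved toward the youngest age).
    Single-year input is returned unchanged.
    """
    if banded.single_year:
        return banded
    bands = banded.bands
    order = sorted(range(len(bands)), key=lambda i: bands[i][0])
    prev_end = -1
    for i in order:
        lo, hi = bands[i]
        if lo <= prev_end:
            raise ValueError(f"overlapping age bands at ({lo}, {hi})")
        prev_end = lo if hi is None else hi
    if integer is None:
        integer = banded.integer_valued

    omega = max(hi if hi is not None else lo for lo, hi in bands)
    if weights is not None:
        omega = max(omega, int(weights.ages[-1]))
    ages_axis = np.arange(omega + 1)
    n_years = banded.years.size
    out = np.zeros((len(banded.causes), ages_axis.size, n_years))

    for i, (lo, hi) in enumerate(bands):
        hi_eff = omega if hi is None else hi
        span = np.arange(lo, hi_eff + 1)
        for j in range(n_years):
            w = None
            if weights is not None:
                year = int(banded.years[j])
                if (
                    weights.years[0] <= year <= weights.years[-1]
                    and lo >= weights.ages[0]
                    and hi_eff <= weights.ages[-1]
                ):
                    col = weights.rates[:, year - weights.years[0]]
                    cand = col[span - weights.ages[0]]
                    if (
                        weights.missing is None
                        or not weights.missing[span - weights.ages[0], year - weights.years[0]].any()
                    ) and cand.sum() > 0:
                        w = cand / cand.sum()
            if w is None:
                w = np.full(span.size, 1.0 / span.size)
            for k in range(len(banded.causes)):
                total = banded.counts[k, i, j]
                if total == 0:
                    continue
                shares = total * w
                if integer:
                    base = np.floor(shares)
                    short = int(round(total - base.sum()))
                    if short > 0:
                        frac = shares - base
                        top = np.argsort(-frac, kind="stable")[:short]
                        base[top] += 1
                    shares = base
                out[k, span, j] = shares
    return CauseDeathSurface(
        sex=banded.sex, years=banded.years, causes=banded.causes, counts=out
    )


def cause_specific_rates(
    all_cause: MortalitySurface, counts: CauseDeathSurface
) -> dict:
    """Split an all-cause rate surface into per-cause surfaces.

    ``m_i(x,t) = m(x,t) * D_i(x,t) / D(x,t)``.  Cells with no recorded
    deaths (``D = 0``) give ``m_i = 0`` for every cause; if the rate
    source nevertheless has ``m > 0`` there (source discordance) the
    whole rate is assigned to ``residual`` and a warning is logged, so
    the cause surfaces always sum to the all-cause surface.
    """
    if not counts.single_year:
        raise ValueError("counts must be on single ages; expand bands first")
    if not np.array_equal(all_cause.ages, counts.ages) or not np.array_equal(
        all_cause.years, counts.years
    ):
        raise ValueError("all-cause rates and counts are on different grids")
    D = counts.total
    m = all_cause.rates
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(D > 0, counts.counts / np.where(D > 0, D, 1.0), 0.0)
    causes = list(counts.causes)
    rates = {c: m * frac[k] for k, c in enumerate(causes)}
    discordant = (D == 0) & (m > 0)
    if discordant.any():
        logger.warning(
            "%d cells have positive all-cause rates but zero recorded deaths; "
            "their rate mass is assigned to 'residual'",
            int(discordant.sum()),
        )
        if "residual" not in rates:
            causes.append("residual")
            rates["residual"] = np.zeros_like(m)
        rates["residual"] = np.where(discordant, m, rates["residual"])
    return {
        c: MortalitySurface(
            sex=all_cause.sex, ages=all_cause.ages, years=all_cause.years,
            rates=rates[c], open_age=all_cause.open_age,
        )
        for c in causes
    }
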
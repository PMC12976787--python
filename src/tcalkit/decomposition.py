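"""Exact additive decomposition of a female-male TCAL gap on the Lexis plane.

For each cohort aged x at the terminal year T, the difference between
the two sexes' observed survival products is allocated exactly over the
cohort's Lexis cells by symmetrised stepwise replacement.  Writing
``p_s(a) = exp(-m_s(a, T-x+a))`` for the per-cell survival factor, a
product difference telescopes exactly in either replacement order:

    prod p_f - prod p_m
      = sum_a [prod_{b<a} p_f] (p_f(a) - p_m(a)) [prod_{b>a} p_m],

and likewise with the prefix/suffix roles of the sexes swapped; each
cell gets the average of the two orders, which removes the
replacement-order asymmetry while preserving exact telescoping.  Cohort
allocations are combined across ages with the same trapezoidal weights
TCAL itself uses, so the cell contributions sum to TCAL_f - TCAL_m to
machine precision.

Within a cell, the contribution is split over causes of death
proportionally to the cause-specific rate differences,
``(m_i^m - m_i^f) / (m^m - m^f)`` — the standard cause-of-death
decomposition step.  When the all-cause rates are equal in a cell (the
denominator vanishes, and with it the cell's contribution) every cause
is assigned zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .surfaces import MortalitySurface, check_same_grid
from .tcal import cause_deleted_surface, compute_tcal

__all__ = [
    "LexisDecomposition",
    "decompose_gap",
    "split_by_cause",
    "cause_contribution_table",
    "elimination_gap_change",
    "neoplasm_gap_scenarios",
    "plot_lexis",
]


@dataclass(frozen=True)
class LexisDecomposition:
    """Per-cell (and optionally per-cause) contributions to a TCAL gap.

    ``cells[x, j]`` is the signed contribution in years of the Lexis
    cell at age ``x`` and year ``window_start + j`` (positive = female
    advantage); cells cover ages ``0..omega-1`` and years
    ``window_start..terminal_year-1``.  ``per_cause`` maps cause labels
    to arrays of the same shape.
    """

    terminal_year: int
    window_start: int
    ages: np.ndarray
    years: np.ndarray
    cells: np.ndarray
    total_gap: float
    per_cause: dict | None = None

    def cohort_totals(self) -> pd.Series:
        """Aggregate cell contributions along Lexis diagonals (birth cohorts)."""
        cohort = self.years[None, :] - self.ages[:, None]
        s = pd.Series(self.cells.ravel(), index=cohort.ravel())
        out = s.groupby(level=0).sum()
        out.index.name = "cohort"
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: age, year, cohort, cause, contribution_years."""
        ages = np.repeat(self.ages, self.years.size)
        years = np.tile(self.years, self.ages.size)
        blocks = [
            pd.DataFrame(
                {
                    "age": ages,
                    "year": years,
                    "cohort": years - ages,
                    "cause": "all",
                    "contribution_years": self.cells.ravel(),
                }
            )
        ]
        if self.per_cause is not None:
            for cause, arr in self.per_cause.items():
                blocks.append(
                    pd.DataFrame(
                        {
                            "age": ages,
                            "year": years,
                            "cohort": years - ages,
                            "cause": cause,
                            "contribution_years": arr.ravel(),
                        }
                    )
                )
        return pd.concat(blocks, ignore_index=True)


def _diagonal(surface: MortalitySurface, x: int, T: int, a: np.ndarray) -> np.ndarray:
    y0 = int(surface.years[0])
    return surface.rates[a, a + (T - x - y0)]


def decompose_gap(
    surface_f: MortalitySurface, surface_m: MortalitySurface, T: int, t0: int
) -> LexisDecomposition:
    """Allocate TCAL_f - TCAL_m exactly over Lexis cells."""
    check_same_grid(surface_f, surface_m)
    res_f = compute_tcal(surface_f, T, t0)
    res_m = compute_tcal(surface_m, T, t0)
    total_gap = res_f.value - res_m.value

    omega = surface_f.omega
    W = T - t0
    ages = np.arange(omega)
    years = np.arange(t0, T)
    cells = np.zeros((omega, W)) if W > 0 else np.zeros((omega, 0))

    for x in range(1, omega + 1):
        a = np.arange(max(0, x - W), x)
        if a.size == 0:
            continue
        pf = np.exp(-_diagonal(surface_f, x, T, a))
        pm = np.exp(-_diagonal(surface_m, x, T, a))
        delta = pf - pm
        # prefix products Pi_{b<a} p, suffix products Pi_{b>a} p
        pref_f = np.concatenate([[1.0], np.cumprod(pf[:-1])])
        pref_m = np.concatenate([[1.0], np.cumprod(pm[:-1])])
        suff_f = np.concatenate([np.cumprod(pf[::-1])[-2::-1], [1.0]])
        suff_m = np.concatenate([np.cumprod(pm[::-1])[-2::-1], [1.0]])
        contrib = 0.5 * delta * (pref_f * suff_m + pref_m * suff_f)
        w_x = 0.5 if x == omega else 1.0  # trapezoidal cohort weight
        cols = a + (T - x - t0)
        cells[a, cols] += w_x * contrib
    return LexisDecomposition(
        terminal_year=int(T),
        window_start=int(t0),
        ages=ages,
        years=years,
        cells=cells,
        total_gap=float(total_gap),
    )


def split_by_cause(
    decomp: LexisDecomposition, cause_rates_f: dict, cause_rates_m: dict
) -> LexisDecomposition:
    """Fill per-cause contributions proportional to cause rate differences."""
    if set(cause_rates_f) != set(cause_rates_m):
        raise ValueError(
            "cause sets differ between sexes: "
            f"{sorted(set(cause_rates_f) ^ set(cause_rates_m))}"
        )
    causes = list(cause_rates_f)
    ref = cause_rates_f[causes[0]]
    y0 = int(ref.years[0])
    j0 = decomp.window_start - y0
    sl_a = slice(0, decomp.ages.size)
    sl_y = slice(j0, j0 + decomp.years.size)
    if j0 < 0 or j0 + decomp.years.size > ref.years.size:
        raise ValueError("cause rate surfaces do not cover the decomposition window")

    m_f = sum(cause_rates_f[c].rates[sl_a, sl_y] for c in causes)
    m_m = sum(cause_rates_m[c].rates[sl_a, sl_y] for c in causes)
    dm = m_m - m_f
    guard = np.abs(dm) < 1e-12
    denom = np.where(guard, 1.0, dm)
    per_cause = {}
    for c in causes:
        dmi = cause_rates_m[c].rates[sl_a, sl_y] - cause_rates_f[c].rates[sl_a, sl_y]
        share = np.where(guard, 0.0, dmi / denom)
        per_cause[c] = decomp.cells * share
    return replace(decomp, per_cause=per_cause)


def cause_contribution_table(decomp: LexisDecomposition) -> pd.DataFrame:
    """Signed per-cause totals in years; causes sum to the total gap."""
    if decomp.per_cause is None:
        raise ValueError("decomposition has no per-cause split; run split_by_cause first")
    rows = [
        {"cause": c, "contribution_years": float(arr.sum())}
        for c, arr in decomp.per_cause.items()
    ]
    df = pd.DataFrame(rows)
    df.loc[len(df)] = {"cause": "total", "contribution_years": float(decomp.cells.sum())}
    return df


def elimination_gap_change(
    surface_f: MortalitySurface,
    surface_m: MortalitySurface,
    cause_rates_f: dict,
    cause_rates_m: dict,
    delete,
    T: int,
    t0: int,
) -> tuple[float, float]:
    """Sex gap before and after deleting a cause set from both sexes.

    Returns ``(gap_before, gap_after)``; the scenario's effect is
    ``gap_after - gap_before`` (positive = the deleted causes were
    holding the female advantage back, as with female reproductive
    cancers).
    """
    gap_before = compute_tcal(surface_f, T, t0).value - compute_tcal(surface_m, T, t0).value
    del_f = cause_deleted_surface(surface_f, cause_rates_f, delete)
    del_m = cause_deleted_surface(surface_m, cause_rates_m, delete)
    gap_after = compute_tcal(del_f, T, t0).value - compute_tcal(del_m, T, t0).value
    return float(gap_before), float(gap_after)


def _deleted_cause_rates(cause_rates: dict, all_cause: MortalitySurface, delete) -> tuple:
    """Cause surfaces and all-cause surface after removing a cause set."""
    deleted_surface = cause_deleted_surface(all_cause, cause_rates, delete)
    new_rates = {
        c: (surf.with_rates(np.zeros_like(surf.rates)) if c in delete else surf)
        for c, surf in cause_rates.items()
    }
    return deleted_surface, new_rates


def neoplasm_gap_scenarios(
    surface_f: MortalitySurface,
    surface_m: MortalitySurface,
    cause_rates_f: dict,
    cause_rates_m: dict,
    T: int,
    t0: int,
    neoplasm_causes=None,
) -> pd.DataFrame:
    """Neoplasm contribution to the gap under elimination scenarios.

    Four rows — observed, minus breast, minus gynecological, minus both
    — each recomputing the decomposition on cause-deleted surfaces and
    summing the remaining neoplasm categories' contributions.
    """
    from .mortality_io import NEOPLASM_CATEGORIES

    if neoplasm_causes is None:
        neoplasm_causes = [c for c in NEOPLASM_CATEGORIES if c in cause_rates_f]
    scenarios = [
        ("observed", ()),
        ("minus_breast", ("breast",)),
        ("minus_gynecological", ("gynecological",)),
        ("minus_both", ("breast", "gynecological")),
    ]
    rows = []
    for name, delete in scenarios:
        delete = tuple(c for c in delete if c in cause_rates_f)
        sf, crf = _deleted_cause_rates(cause_rates_f, surface_f, delete)
        sm, crm = _deleted_cause_rates(cause_rates_m, surface_m, delete)
        decomp = split_by_cause(decompose_gap(sf, sm, T, t0), crf, crm)
        neo = sum(float(decomp.per_cause[c].sum()) for c in neoplasm_causes)
        rows.append(
            {
                "scenario": name,
                "deleted": "+".join(delete) if delete else "none",
                "neoplasm_contribution_years": neo,
                "total_gap_years": float(decomp.total_gap),
            }
        )
    return pd.DataFrame(rows)


def plot_lexis(decomp: LexisDecomposition, cause: str | None = None, ax=None,
               cohort_lines: int = 20):
    """Heat map of a contribution surface (diverging palette, cohort diagonals).

    Blue marks female survival advantage, red male advantage; dashed
    diagonals trace birth cohorts every ``cohort_lines`` years.
    Requires matplotlib (optional dependency).
    """
    import matplotlib.pyplot as plt

    if cause is None:
        values = decomp.cells
        title = "all causes"
    else:
        if decomp.per_cause is None or cause not in decomp.per_cause:
            raise ValueError(f"no per-cause surface for {cause!r}")
        values = decomp.per_cause[cause]
        title = cause
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    vmax = np.abs(values).max() or 1.0
    extent = (decomp.years[0], decomp.years[-1] + 1, decomp.ages[0], decomp.ages[-1] + 1)
    im = ax.imshow(
        values, origin="lower", aspect="auto", cmap="RdBu",
        vmin=-vmax, vmax=vmax, extent=extent,
    )
    first_cohort = int(decomp.years[0]) - int(decomp.ages[-1])
    for cohort in range(first_cohort, int(decomp.years[-1]) + 1, cohort_lines):
        ax.axline((cohort, 0), slope=1, ls="--", lw=0.5, color="0.4")
    ax.set_xlabel("calendar year")
    ax.set_ylabel("age")
    ax.set_title(f"TCAL gap contributions: {title}")
    ax.figure.colorbar(im, ax=ax, label="years per Lexis cell")
    return ax
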
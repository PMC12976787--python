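"""Period life tables.

Standard single-age life table built from central death rates m(x), used
as the period comparator for TCAL (life expectancy at birth in the
terminal year) and as the stationary-case oracle in tests.

Conversion uses q(x) = m(x) / (1 + (1 - a(x)) m(x)) with the mid-interval
assumption a(x) = 0.5 at every age, including age 0.  The package's
substantive quantities are between-sex differences, which are insensitive
to infant-a(x) refinements; ``ax`` is an override point for users who
want a different assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surfaces import MortalitySurface

__all__ = ["LifeTable", "period_life_table", "life_expectancy_at_birth"]


@dataclass(frozen=True)
class LifeTable:
    """Columns of a period life table with radix l(0) = 1."""

    ages: np.ndarray
    m: np.ndarray  # central death rate
    q: np.ndarray  # probability of death in [x, x+1)
    l: np.ndarray  # survivors at exact age x
    L: np.ndarray  # person-years lived in [x, x+1)
    e: np.ndarray  # remaining life expectancy at exact age x

    @property
    def e0(self) -> float:
        """Life expectancy at birth, years."""
        return float(self.e[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "mx": self.m, "qx": self.q,
             "lx": self.l, "Lx": self.L, "ex": self.e}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def period_life_table(m, ax: float = 0.5) -> LifeTable:
    """Build a period life table from a vector of central death rates.

    Parameters
    ----------
    m : array-like
        Central death rates by single age ``0..omega``; the last entry
        is the open age interval.
    ax : float
        Average fraction of the interval lived by those dying in it,
        applied at every age (default 0.5).

    Returns
    -------
    LifeTable
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 1 or m.size < 2:
        raise ValueError("m must be a 1-d vector with at least two ages")
    if np.any(m < 0) or not np.all(np.isfinite(m)):
        raise ValueError("death rates must be finite and >= 0")
    if not 0.0 <= ax <= 1.0:
        raise ValueError("ax must lie in [0, 1]")

    n = m.size
    ages = np.arange(n)
    q = m / (1.0 + (1.0 - ax) * m)
    q = np.minimum(q, 1.0)
    q[-1] = 1.0  # everyone dies in the open interval

    l = np.empty(n)
    l[0] = 1.0
    l[1:] = np.cumprod(1.0 - q[:-1])

    d = l * q
    L = np.empty(n)
    L[:-1] = l[1:] + ax * d[:-1]
    # open interval: stationary occupancy l / m; empty if nobody reaches it
    L[-1] = l[-1] / m[-1] if m[-1] > 0 else 0.0

    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)
    return LifeTable(ages=ages, m=m, q=q, l=l, L=L, e=e)


def life_expectancy_at_birth(surface: MortalitySurface, year: int, ax: float = 0.5) -> float:
    """Period life expectancy at birth from one year's rate column."""
    return period_life_table(surface.rate_column(year), ax=ax).e0
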
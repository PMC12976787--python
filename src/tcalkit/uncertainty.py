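"""Stratified bootstrap confidence intervals.

Resampling is stratified by (age, calendar year): within each cell the
cause composition of deaths is redrawn from a multinomial distribution
conditional on the cell's death count.  Two modes are provided:

* ``poisson`` (default): the cell's total is first redrawn as
  ``D* ~ Poisson(D)`` and the multinomial split applied conditional on
  ``D*``.  All-cause rates for a replicate are rescaled by ``D*/D``.
  This layer makes the all-cause quantities (TCAL, the sex gap) carry
  genuine sampling variability rather than collapsing to a point.
* ``conditional``: pure conditional multinomial — totals (and hence
  all-cause rates) are held fixed and only the cause composition varies.
  Useful for fidelity experiments where the count total is treated as
  design-fixed.

Intervals are percentile intervals at the stated level; the point
estimate is always computed from the unresampled data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._sampling import multinomial_split, rng_for
from .surfaces import CauseDeathSurface, MortalitySurface

__all__ = ["BootstrapResult", "resample_counts", "bootstrap_ci", "scaled_rates"]

_MODES = ("poisson", "conditional")


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate with percentile bootstrap interval(s).

    ``estimate``, ``ci_low`` and ``ci_high`` are scalars for scalar
    statistics and aligned arrays for vector-valued statistics;
    ``replicates`` has shape (n_iter,) or (n_iter, p).
    """

    estimate: float | np.ndarray
    replicates: np.ndarray
    ci_low: float | np.ndarray
    ci_high: float | np.ndarray
    n_iter: int
    seed: int
    level: float = 0.95
    mode: str = "poisson"


def resample_counts(
    counts: CauseDeathSurface,
    seed: int | np.random.Generator,
    mode: str = "poisson",
) -> CauseDeathSurface:
    """One stratified redraw of a cause-count surface.

    Identical seeds give identical output; cells with ``D = 0`` stay
    all-zero.  Per-cell cause sums equal the per-cell totals exactly.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if not counts.integer_valued:
        raise ValueError("resampling needs integer death counts")
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed)
    D = np.round(counts.total).astype(np.int64)
    new_total = rng.poisson(D) if mode == "poisson" else D.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        probs = np.where(D > 0, counts.counts / np.where(D > 0, D, 1.0), 0.0)
    new_counts = multinomial_split(rng, new_total, probs)
    return counts.with_counts(new_counts)


def scaled_rates(
    all_cause: MortalitySurface,
    original: CauseDeathSurface,
    resampled: CauseDeathSurface,
    mode: str = "poisson",
) -> MortalitySurface:
    """All-cause rate surface implied by a resampled count table.

    In ``poisson`` mode the rates are rescaled by ``D*/D`` (cells with
    ``D = 0`` keep their original rate); in ``conditional`` mode totals
    are fixed by design and the rates are returned unchanged.
    """
    if mode == "conditional":
        return all_cause
    D = original.total
    Dstar = resampled.total
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(D > 0, Dstar / np.where(D > 0, D, 1.0), 1.0)
    return all_cause.with_rates(all_cause.rates * factor)


def bootstrap_ci(
    statistic,
    counts,
    n_iter: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    mode: str = "poisson",
) -> BootstrapResult:
    """Percentile bootstrap interval for a statistic of count data.

    Parameters
    ----------
    statistic : callable
        Maps a count table — a single :class:`CauseDeathSurface` or a
        dict of them (e.g. per sex) mirroring ``counts`` — to a scalar
        or 1-d vector.  Must be deterministic given its input.
    counts : CauseDeathSurface or dict
        The observed counts; the point estimate comes from these.
    n_iter : int
        Number of bootstrap iterations (>= 2).
    seed : int
        Base seed; iteration sub-streams are derived from it, so the
        replicate set is independent of evaluation order and a given
        (seed, i) pair always produces the same replicate.
    level : float
        Coverage level of the percentile interval.
    mode : {'poisson', 'conditional'}
        Resampling mode, see the module docstring.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")

    is_mapping = isinstance(counts, dict)
    estimate = np.asarray(statistic(counts), dtype=float)
    replicates = np.empty((n_iter,) + estimate.shape)
    keys = sorted(counts) if is_mapping else None
    for i in range(n_iter):
        if is_mapping:
            redraw = {
                k: resample_counts(counts[k], rng_for(seed, i, j), mode=mode)
                for j, k in enumerate(keys)
            }
        else:
            redraw = resample_counts(counts, rng_for(seed, i, 0), mode=mode)
        replicates[i] = np.asarray(statistic(redraw), dtype=float)

    alpha = 1.0 - level
    ci_low, ci_high = np.quantile(replicates, [alpha / 2, 1 - alpha / 2], axis=0)
    squeeze = estimate.ndim == 0
    return BootstrapResult(
        estimate=float(estimate) if squeeze else estimate,
        replicates=replicates,
        ci_low=float(ci_low) if squeeze else ci_low,
        ci_high=float(ci_high) if squeeze else ci_high,
        n_iter=int(n_iter),
        seed=int(seed),
        level=float(level),
        mode=mode,
    )
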
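"""Vectorised count sampling shared by the generator and the bootstrap."""

from __future__ import annotations

import numpy as np

__all__ = ["multinomial_split", "rng_for"]


def rng_for(seed: int, *stream) -> np.random.Generator:
    """Generator for a named sub-stream of one base seed.

    Sub-streams are derived through :class:`numpy.random.SeedSequence`
    with the stream labels appended to the entropy, so each (purpose,
    sex, iteration, ...) combination gets an independent, reproducible
    stream regardless of evaluation order.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def multinomial_split(rng: np.random.Generator, totals: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Split per-cell totals over causes by a multinomial draw.

    Parameters
    ----------
    rng : numpy Generator
    totals : int ndarray, any shape S
        Number of deaths per cell.
    probs : ndarray, shape (K,) + S or (K, S[0]) broadcastable to (K,) + S
        Cause probabilities per cell; must sum to 1 over axis 0 wherever
        the total is positive.

    Returns
    -------
    int ndarray, shape (K,) + S with exact per-cell sums equal to totals.

    Implemented as a chain of vectorised conditional binomials
    (cause k given not 1..k-1), which is the standard sequential
    factorisation of the multinomial and keeps every cell's split exact.
    """
    totals = np.asarray(totals)
    if np.any(totals < 0):
        raise ValueError("totals must be >= 0")
    probs = np.broadcast_to(probs, probs.shape[:1] + totals.shape).astype(float)
    K = probs.shape[0]
    out = np.zeros((K,) + totals.shape, dtype=np.int64)
    remaining = totals.astype(np.int64).copy()
    prob_left = np.ones_like(probs[0])
    for k in range(K - 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(prob_left > 0, probs[k] / prob_left, 0.0)
        p = np.clip(p, 0.0, 1.0)
        draw = rng.binomial(remaining, p)
        out[k] = draw
        remaining -= draw
        prob_left = np.maximum(prob_left - probs[k], 0.0)
    out[K - 1] = remaining
    return out
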
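"""Firing-rate patterns and the population statistics used throughout the package.

A :class:`RatePattern` is the universal currency between processing stages: a
nonnegative firing-rate vector over a named neuronal population.  The statistics
here quantify the properties the memory theory turns on: population sparseness
(what fraction of the population is effectively active), overlap between
patterns (how similar two representations are), pattern separation (how much
less correlated two representations are after a transformation), and completion
(how much of a stored pattern was recalled beyond the cue itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class UndefinedStatisticError(ValueError):
    """Raised when a pattern statistic is mathematically undefined (0/0)."""


@dataclass(frozen=True)
class RatePattern:
    """A nonnegative firing-rate vector over a named population.

    Parameters
    ----------
    rates
        Firing rates, one entry per neuron (arbitrary rate units, e.g. spikes/s).
        Must be finite and nonnegative.
    population_id
        Label for the population the vector lives on (e.g. ``"CA3"``).
    """

    rates: np.ndarray
    population_id: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.ndim != 1 or r.size < 1:
            raise ValueError("rates must be a 1-D vector with at least one entry")
        if not np.all(np.isfinite(r)):
            raise ValueError("rates must be finite")
        if np.any(r < 0):
            raise ValueError("rates must be nonnegative")
        object.__setattr__(self, "rates", r)

    @property
    def N(self) -> int:
        return self.rates.size

    def active_indices(self, threshold: float = 0.0) -> np.ndarray:
        return np.flatnonzero(self.rates > threshold)


@dataclass(frozen=True)
class SparsenessResult:
    """Population sparseness ``a`` of a rate pattern, in ``[1/N, 1]``."""

    a: float
    N: int


def _as_rates(p: "RatePattern | np.ndarray | Sequence[float]") -> np.ndarray:
    if isinstance(p, RatePattern):
        return p.rates
    return np.asarray(p, dtype=float)


def population_sparseness(p: "RatePattern | np.ndarray") -> SparsenessResult:
    """Population sparseness a = (mean r)^2 / mean(r^2).

    For a binary pattern this equals the active fraction; it ranges from 1/N
    (a single responsive neuron) to 1.0 (all neurons responding equally).

    Raises
    ------
    UndefinedStatisticError
        For an all-zero pattern, where the measure is 0/0.
    """
    r = _as_rates(p)
    s1 = r.mean()
    s2 = np.mean(r * r)
    if s2 == 0.0:
        raise UndefinedStatisticError("sparseness undefined for an all-zero pattern")
    return SparsenessResult(a=float(s1 * s1 / s2), N=r.size)


def pattern_overlap(
    p: "RatePattern | np.ndarray",
    q: "RatePattern | np.ndarray",
    *,
    method: str = "pearson",
) -> float:
    """Similarity of two rate patterns on the same population.

    The default is the Pearson correlation of the two rate vectors, which is
    insensitive to a uniform baseline shift (as produced by global inhibition
    models).  ``method="cosine"`` gives the cosine similarity instead.

    Raises
    ------
    UndefinedStatisticError
        If either vector has zero variance (Pearson) or zero norm (cosine).
    """
    x = _as_rates(p)
    y = _as_rates(q)
    if x.size != y.size:
        raise ValueError(f"pattern lengths differ: {x.size} != {y.size}")
    if method == "pearson":
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            raise UndefinedStatisticError("overlap undefined for constant pattern")
        xc = x - x.mean()
        yc = y - y.mean()
        return float(np.dot(xc, yc) / (np.linalg.norm(xc) * np.linalg.norm(yc)))
    if method == "cosine":
        nx = np.linalg.norm(x)
        ny = np.linalg.norm(y)
        if nx == 0.0 or ny == 0.0:
            raise UndefinedStatisticError("cosine overlap undefined for zero pattern")
        return float(np.dot(x, y) / (nx * ny))
    raise ValueError(f"unknown overlap method: {method!r}")


def separation_index(in_corr: float, out_corr: float) -> float:
    """Pattern-separation index: input correlation minus output correlation.

    Positive values mean the transformation made the pair of representations
    less correlated (orthogonalization); zero means no separation.
    """
    for name, v in (("in_corr", in_corr), ("out_corr", out_corr)):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [-1, 1], got {v}")
    return float(in_corr - out_corr)


def completion_score(
    recalled: "RatePattern | np.ndarray",
    stored: "RatePattern | np.ndarray",
    cue_support: Iterable[int],
) -> float:
    """Recall quality on the units the cue did *not* specify.

    Measures completion of the whole memory from a part: the Pearson overlap of
    the recalled and stored patterns restricted to the indices outside
    ``cue_support``, so that the cue units themselves earn no credit.  If the
    recalled pattern is constant (e.g. all zero) outside the cue, no completion
    occurred and the score is 0.0.

    Raises
    ------
    UndefinedStatisticError
        If the cue support covers every unit, or the stored pattern is constant
        outside the cue.
    """
    x = _as_rates(recalled)
    y = _as_rates(stored)
    if x.size != y.size:
        raise ValueError("recalled and stored patterns must have equal length")
    cue = np.zeros(x.size, dtype=bool)
    cue[np.fromiter(cue_support, dtype=int)] = True
    rest = ~cue
    if not rest.any():
        raise UndefinedStatisticError("cue covers all units; completion undefined")
    xs, ys = x[rest], y[rest]
    if np.ptp(ys) == 0.0:
        raise UndefinedStatisticError("stored pattern constant outside cue")
    if np.ptp(xs) == 0.0:
        return 0.0
    return pattern_overlap(xs, ys)
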
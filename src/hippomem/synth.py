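"""Seeded generators for the synthetic rate patterns and events all stages use.

The theory assumes sparse, unstructured firing-rate patterns — binary subsets
of active neurons, or graded rates with an (approximately) exponential
distribution across the active population, as observed for hippocampal and
neocortical representations.  These generators realize exactly that
statistical structure, reproducibly from a seed, including pairs of patterns
at a controlled correlation for pattern-separation experiments, and
object-at-place event specifications for the one-trial recall task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patterns import RatePattern

# Graded rates are unit-mean exponential truncated at 5x mean (avoids weight
# blow-up).  The squared-mean/mean-square ratio of that truncated law enters
# the sparseness calibration below.
_TRUNC = 5.0


def _truncated_exp_sparseness_factor() -> float:
    # (E X)^2 / E X^2 for Exp(1) truncated to [0, 5]
    z = 1.0 - np.exp(-_TRUNC)
    ex = (1.0 - (1.0 + _TRUNC) * np.exp(-_TRUNC)) / z
    ex2 = (2.0 - (_TRUNC**2 + 2 * _TRUNC + 2.0) * np.exp(-_TRUNC)) / z
    return ex**2 / ex2


@dataclass(frozen=True)
class PatternEnsembleSpec:
    """Specification of an ensemble of random rate patterns.

    ``rate_distribution`` is ``"binary"`` (exactly ceil(a*N) units at rate 1)
    or ``"exponential"`` (graded truncated-exponential rates on an active
    subset sized so the population sparseness comes out at ``a``).
    ``pairwise_target_corr`` requests consecutive pattern pairs built around a
    shared active core so their Pearson correlation is near the target.
    """

    N: int
    p: int
    a: float
    rate_distribution: str = "binary"
    pairwise_target_corr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.a < 1.0:
            raise ValueError("sparseness a must be in (0, 1)")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.rate_distribution not in ("binary", "exponential"):
            raise ValueError(f"unknown rate_distribution {self.rate_distribution!r}")


def _active_count(spec: PatternEnsembleSpec) -> int:
    if spec.rate_distribution == "binary":
        return int(np.ceil(spec.a * spec.N))
    f = spec.a / _truncated_exp_sparseness_factor()
    if f > 1.0:
        raise ValueError(f"sparseness {spec.a} infeasible for graded rates")
    return max(1, int(round(f * spec.N)))


def _fill_rates(idx: np.ndarray, spec: PatternEnsembleSpec, rng: np.random.Generator) -> np.ndarray:
    r = np.zeros(spec.N)
    if spec.rate_distribution == "binary":
        r[idx] = 1.0
    else:
        r[idx] = np.minimum(rng.exponential(1.0, size=idx.size), _TRUNC)
    return r


def generate_patterns(spec: PatternEnsembleSpec) -> list[RatePattern]:
    """Generate p random patterns per the spec, reproducibly under its seed.

    With a pairwise correlation target, patterns are produced in pairs that
    share a common core of active units; the core size is chosen from the
    closed-form Pearson correlation of two binary patterns as a function of
    their overlap count.
    """
    rng = np.random.default_rng(spec.seed)
    m = _active_count(spec)
    patterns: list[RatePattern] = []
    if spec.pairwise_target_corr is None:
        for _ in range(spec.p):
            idx = rng.choice(spec.N, size=m, replace=False)
            patterns.append(RatePattern(rates=_fill_rates(idx, spec, rng)))
        return patterns
    c = spec.pairwise_target_corr
    f = m / spec.N
    # Pearson corr of two binary patterns with m active each and s shared:
    # corr = (s/N - f^2) / (f (1 - f))  ->  s = N (c f (1-f) + f^2)
    s = int(round(spec.N * (c * f * (1.0 - f) + f * f)))
    if not 0 <= s <= m:
        raise ValueError(f"correlation target {c} infeasible at a={spec.a}")
    while len(patterns) < spec.p:
        core = rng.choice(spec.N, size=s, replace=False)
        rest = np.setdiff1d(np.arange(spec.N), core, assume_unique=False)
        for _ in range(2):
            extra = rng.choice(rest, size=m - s, replace=False)
            idx = np.concatenate([core, extra])
            patterns.append(RatePattern(rates=_fill_rates(idx, spec, rng)))
            if len(patterns) == spec.p:
                break
    return patterns


@dataclass(frozen=True)
class EventSpec:
    """One event: an object at a place (optionally with valence and time)."""

    object_id: int
    place: int
    valence: str | None = None
    time_slot: int | None = None


def generate_events(
    n_events: int,
    n_places: int,
    n_object_units: int = 200,
    n_place_units: int = 200,
    object_sparseness: float = 0.1,
    seed: int = 0,
) -> tuple[list[EventSpec], list[RatePattern]]:
    """Distinct object patterns at distinct places, with their EC rate patterns.

    Each event's entorhinal representation is the concatenation of a binary
    object pattern (over ``n_object_units``) and a binary place pattern (over
    ``n_place_units``), both at ``object_sparseness``.  Deterministic under
    ``seed``; more events than distinct places is an error.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if n_events > n_places:
        raise ValueError(f"cannot place {n_events} events in {n_places} distinct places")
    rng = np.random.default_rng(seed)
    places = rng.choice(n_places, size=n_events, replace=False)
    k_obj = max(1, int(round(object_sparseness * n_object_units)))
    k_pl = max(1, int(round(object_sparseness * n_place_units)))
    place_codes = {int(pl): rng.choice(n_place_units, size=k_pl, replace=False) for pl in places}
    events, patterns = [], []
    for e, pl in enumerate(places):
        obj_idx = rng.choice(n_object_units, size=k_obj, replace=False)
        r = np.zeros(n_object_units + n_place_units)
        r[obj_idx] = 1.0
        r[n_object_units + place_codes[int(pl)]] = 1.0
        events.append(EventSpec(object_id=e, place=int(pl)))
        patterns.append(RatePattern(rates=r, population_id="EC"))
    return events, patterns
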
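"""Temporal-order memory from slowly drifting attractor states.

Time within a trial can be encoded by "time cells": successive populations of
neurons firing at successive epochs.  This module implements a rate-level
model of how such sequential activation can arise from attractor dynamics:

* several attractor pools with strong within-pool recurrence;
* firing-rate adaptation (a subtractive current with first-order kinetics)
  that slowly weakens the currently active pool;
* noise that triggers the transition once the active pool has adapted; and
* optionally a weak *forward bias* — slightly stronger synaptic weights from
  each pool to the next than in the reverse direction — which makes the pools
  activate reliably in a fixed order (the default, ``forward-bias`` mode).

Without the bias (``adaptation-only`` mode), the next pool to emerge is
simply the least-recently-active (least adapted) one, which replays whatever
order occurred before.  A third mode (``multi-tau``) gives each pool its own
adaptation time constant with a common start, so pools drop out at staggered
times.  Associating one item with each pool and replaying the pool sequence
reads the items out in presentation order — a candidate mechanism for the
recency/order structure of short-term and episodic memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .patterns import RatePattern


@dataclass(frozen=True)
class SequenceNetParams:
    """Pools of rate units with adaptation and (optionally) forward-biased weights.

    Units: ``w_intra`` and ``forward_bias`` are dimensionless synaptic
    efficacies (forward_bias must stay below w_intra so single-pool states are
    stable); ``adaptation_strength`` is the asymptotic adaptation current for
    a unit firing at rate 1; ``adaptation_tau`` its time constant in the same
    time units as ``dt`` and ``duration``; ``noise_sd`` the per-unit
    per-step Gaussian input noise.
    """

    n_pools: int = 4
    pool_size: int = 20
    w_intra: float = 1.0
    forward_bias: float = 0.15
    adaptation_strength: float = 1.3
    adaptation_tau: float = 2.0
    adaptation_taus: tuple[float, ...] | None = None  # per-pool, multi-tau mode
    noise_sd: float = 0.05
    dt: float = 0.02
    duration: float = 24.0
    mode: str = "forward-bias"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("forward-bias", "adaptation-only", "multi-tau"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.forward_bias >= self.w_intra:
            raise ValueError("forward_bias must be smaller than w_intra")
        if self.adaptation_tau <= 0 or self.dt <= 0 or self.duration <= 0:
            raise ValueError("time constants must be positive")
        if self.mode == "multi-tau" and (
            self.adaptation_taus is None or len(self.adaptation_taus) != self.n_pools
        ):
            raise ValueError("multi-tau mode needs one adaptation_tau per pool")


@dataclass
class SequenceTrace:
    """Result of a sequence-network run."""

    dominant_pool: np.ndarray  # pool index per time step
    times: np.ndarray
    pool_rates: np.ndarray  # (n_steps, n_pools) mean rate per pool
    transitions: list[tuple[float, int]]  # (time, new dominant pool)
    dwell_times: list[float]

    def pool_order(self, min_dwell: float = 0.1) -> list[int]:
        """Dominant pools in dwell order, ignoring flickers shorter than ``min_dwell``.

        Attractor transitions in this model are slow (set by the adaptation
        time constant), so dominance runs much shorter than a dwell are noise
        flickers, not states.
        """
        dt = float(self.times[1] - self.times[0]) if self.times.size > 1 else 1.0
        min_steps = max(1, int(round(min_dwell / dt)))
        order: list[int] = []
        i = 0
        d = self.dominant_pool
        while i < d.size:
            j = i
            while j < d.size and d[j] == d[i]:
                j += 1
            if j - i >= min_steps and (not order or order[-1] != int(d[i])):
                order.append(int(d[i]))
            i = j
        return order


def _weight_matrix(params: SequenceNetParams) -> np.ndarray:
    n = params.n_pools * params.pool_size
    W = np.zeros((n, n))
    for p in range(params.n_pools):
        sl = slice(p * params.pool_size, (p + 1) * params.pool_size)
        W[sl, sl] = params.w_intra
        if params.mode == "forward-bias" and p + 1 < params.n_pools:
            nxt = slice((p + 1) * params.pool_size, (p + 2) * params.pool_size)
            W[nxt, sl] = params.forward_bias  # pool p drives pool p+1
    return W


def run_sequence(params: SequenceNetParams, initial_pool: int = 0) -> SequenceTrace:
    """Integrate the pool dynamics and report the dominant-pool trajectory.

    Euler integration: each unit receives recurrent drive W r / pool_size
    minus its adaptation current plus noise; a global k-winners-take-all
    (keeping pool_size units) stands in for inhibition.  Adaptation relaxes
    toward ``adaptation_strength * r`` with time constant ``adaptation_tau``.
    In ``multi-tau`` mode all pools are launched together at t=0 and each
    adapts at its own rate.  Diverging rates raise a diagnostic error.
    """
    if not 0 <= initial_pool < params.n_pools:
        raise ValueError("initial_pool out of range")
    rng = np.random.default_rng(params.seed)
    n = params.n_pools * params.pool_size
    W = _weight_matrix(params)
    r = np.zeros(n)
    if params.mode == "multi-tau":
        r[:] = 1.0  # common start: all pools launched together
        taus = np.repeat(np.asarray(params.adaptation_taus, float), params.pool_size)
    else:
        r[initial_pool * params.pool_size : (initial_pool + 1) * params.pool_size] = 1.0
        taus = np.full(n, params.adaptation_tau)
    adapt = np.zeros(n)
    n_steps = int(round(params.duration / params.dt))
    k = params.pool_size
    dominant = np.empty(n_steps, dtype=int)
    pool_rates = np.empty((n_steps, params.n_pools))
    for t in range(n_steps):
        noise = rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd > 0 else 0.0
        h = W @ r / params.pool_size - adapt + noise
        if not np.all(np.isfinite(h)) or np.abs(h).max() > 1e6:
            raise FloatingPointError(
                f"sequence integration diverged at step {t}: |h|max={np.abs(h).max():.3g}"
            )
        r_new = np.zeros(n)
        if params.mode == "multi-tau":
            r_new[h > 0.0] = 1.0  # pools stay up until adaptation kills them
        else:
            winners = np.argsort(-h, kind="stable")[:k]
            r_new[winners] = 1.0
        adapt += params.dt * (params.adaptation_strength * r_new - adapt) / taus
        r = r_new
        pr = r.reshape(params.n_pools, params.pool_size).mean(axis=1)
        pool_rates[t] = pr
        dominant[t] = int(np.argmax(pr))
    times = np.arange(n_steps) * params.dt
    transitions = [
        (float(times[t]), int(dominant[t]))
        for t in range(1, n_steps)
        if dominant[t] != dominant[t - 1]
    ]
    bounds = [0.0] + [tt for tt, _ in transitions] + [float(params.duration)]
    dwell = [b - a for a, b in zip(bounds[:-1], bounds[1:])]
    return SequenceTrace(
        dominant_pool=dominant,
        times=times,
        pool_rates=pool_rates,
        transitions=transitions,
        dwell_times=dwell,
    )


# ---------------------------------------------------------------------------
# Item-time association and ordered recall


@dataclass
class TimeItemAssociation:
    """Hebbian associations between item patterns and time-encoding pools."""

    item_patterns: np.ndarray  # (n_items, item_dim)
    pool_item_w: np.ndarray  # (n_items, n_pools)
    pool_schedule: list[int]


def associate_items(
    item_patterns: np.ndarray, pool_schedule: list[int], params: SequenceNetParams
) -> TimeItemAssociation:
    """Associate one item with the pool active at its presentation slot.

    The association is a symmetric Hebbian weight between each item's pattern
    and the units of its scheduled pool, summarized at pool resolution.
    Duplicate item patterns make the readout ambiguous and raise a warning.
    """
    items = np.atleast_2d(np.asarray(item_patterns, dtype=float))
    if items.shape[0] != len(pool_schedule):
        raise ValueError("need exactly one item per pool slot")
    for i in range(items.shape[0]):
        for j in range(i + 1, items.shape[0]):
            if np.array_equal(items[i], items[j]):
                warnings.warn("duplicate item patterns: ordered readout is ambiguous")
    w = np.zeros((items.shape[0], params.n_pools))
    for i, pool in enumerate(pool_schedule):
        w[i, pool] = float(items[i].sum())  # Hebbian strength ~ total item activity
    return TimeItemAssociation(item_patterns=items, pool_item_w=w, pool_schedule=list(pool_schedule))


def recall_order(assoc: TimeItemAssociation, params: SequenceNetParams) -> list[int]:
    """Replay the time-encoding sequence and read out one item per dwell.

    The time-encoding pools cycle through their normal sequence (starting at
    pool 0) regardless of how items were assigned to them; during each dwell
    the most strongly associated item is read out; consecutive duplicates are
    collapsed.  Returns item indices in recalled order.
    """
    trace = run_sequence(params, initial_pool=0)
    order: list[int] = []
    visited: set[int] = set()
    for pool in trace.pool_order():
        if pool in visited:
            break  # one full replay cycle is the recalled sequence
        visited.add(pool)
        strengths = assoc.pool_item_w[:, pool]
        if strengths.max() <= 0:
            continue  # pool with no associated item
        item = int(np.argmax(strengths))
        if not order or order[-1] != item:
            order.append(item)
    return order
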
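"""The CA3 autoassociation (attractor) network.

A recurrent network with diluted connectivity stores firing-rate patterns in
its recurrent-collateral synapses by an associative (Hebbian or covariance)
rule, and retrieves a complete stored pattern when cued with part of it.  The
module provides:

* randomly diluted connectivity with or without duplicated contacts between
  the same pair of neurons;
* one-shot associative storage (plain Hebb ``dw = alpha * r_post * r_pre`` or
  the covariance variant with heterosynaptic depression, which is required for
  high capacity with sparse patterns);
* cued recall under synchronous dynamics with a global-inhibition surrogate
  (k-winners-take-all at a target sparseness, binary or graded);
* empirical capacity measurement (largest stored load p with a criterion
  fraction of patterns retrievable from partial cues) and the proportionality
  factor k it implies;
* the duplicated-contact experiment showing why dilution matters: multiple
  synapses between a pair of neurons distort the attractor landscape and
  reduce capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .patterns import RatePattern, pattern_overlap


# ---------------------------------------------------------------------------
# Connectivity


@dataclass
class DilutedConnectivity:
    """Random diluted contacts onto each neuron of a recurrent population.

    ``contacts[i]`` lists the C presynaptic indices contacting neuron i; the
    same presynaptic index may appear more than once only if ``allow_multiple``
    (duplicated contacts sum their weights).  Self-contacts never occur.
    """

    N: int
    contacts: np.ndarray  # (N, C) int array of presynaptic indices
    allow_multiple: bool
    seed: int

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=np.int64)
        if self.contacts.ndim != 2 or self.contacts.shape[0] != self.N:
            raise ValueError("contacts must be an (N, C) index array")
        if np.any(self.contacts == np.arange(self.N)[:, None]):
            raise ValueError("self-contacts are not allowed")

    @property
    def C(self) -> int:
        return self.contacts.shape[1]

    @property
    def dilution(self) -> float:
        """Realized contact probability C / (N - 1) per ordered pair."""
        return self.C / (self.N - 1)

    def count_matrix(self) -> np.ndarray:
        """Dense (N, N) matrix of contact multiplicities (post, pre)."""
        counts = np.zeros((self.N, self.N), dtype=np.int16)
        rows = np.repeat(np.arange(self.N), self.C)
        np.add.at(counts, (rows, self.contacts.ravel()), 1)
        return counts

    def max_multiplicity(self) -> int:
        m = 0
        for i in range(self.N):
            _, c = np.unique(self.contacts[i], return_counts=True)
            m = max(m, int(c.max()))
        return m


def build_diluted_connectivity(
    N: int, C: int, allow_multiple: bool = False, seed: int = 0
) -> DilutedConnectivity:
    """Sample C presynaptic contacts per neuron, uniformly among the other N-1.

    Without replacement if ``allow_multiple`` is false (so every pair has at
    most one contact), with replacement otherwise.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    if not allow_multiple and C >= N:
        raise ValueError("C must be < N for connectivity without duplicates")
    rng = np.random.default_rng(seed)
    contacts = np.empty((N, C), dtype=np.int64)
    for i in range(N):
        others = np.concatenate([np.arange(i), np.arange(i + 1, N)])
        contacts[i] = rng.choice(others, size=C, replace=allow_multiple)
    return DilutedConnectivity(N=N, contacts=contacts, allow_multiple=allow_multiple, seed=seed)


def build_symmetric_connectivity(N: int, C: int, seed: int = 0) -> DilutedConnectivity:
    """Symmetric diluted connectivity: if i contacts j then j contacts i.

    Constructed as a random circulant graph — each neuron contacts ``i +/- o``
    for C/2 random shared offsets ``o`` — so every neuron has exactly C
    contacts and the contact relation is exactly symmetric.  With a symmetric
    learning rule the weight matrix is then symmetric too, which guarantees
    energy minima for the attractor states (the classical fully-symmetric
    stability argument); the default asymmetric sampling is the
    anatomically realistic choice.
    """
    if C % 2 != 0:
        raise ValueError("symmetric connectivity needs an even C")
    max_offset = (N - 1) // 2
    if C // 2 > max_offset:
        raise ValueError("C too large for a symmetric circulant on N neurons")
    rng = np.random.default_rng(seed)
    offsets = rng.choice(np.arange(1, max_offset + 1), size=C // 2, replace=False)
    i = np.arange(N)[:, None]
    contacts = np.concatenate([(i + offsets) % N, (i - offsets) % N], axis=1)
    return DilutedConnectivity(N=N, contacts=contacts, allow_multiple=False, seed=seed)


def build_duplicated_connectivity(
    N: int, C: int, duplicate_fraction: float, seed: int = 0
) -> DilutedConnectivity:
    """Connectivity where a fraction of contact slots form duplicated pairs.

    Each neuron still receives exactly C contacts, but ``duplicate_fraction``
    of those slots are consumed by second contacts onto already-contacted
    presynaptic partners (multiplicity 2), so the number of distinct partners
    shrinks while total synapse count is matched to the baseline.
    """
    if not 0.0 <= duplicate_fraction <= 1.0:
        raise ValueError("duplicate_fraction must be in [0, 1]")
    n_dup = int(round(duplicate_fraction * C / 2.0))
    n_distinct = C - n_dup
    if n_distinct >= N:
        raise ValueError("C too large for N")
    rng = np.random.default_rng(seed)
    contacts = np.empty((N, C), dtype=np.int64)
    for i in range(N):
        others = np.concatenate([np.arange(i), np.arange(i + 1, N)])
        partners = rng.choice(others, size=n_distinct, replace=False)
        doubled = partners[:n_dup]
        contacts[i] = np.concatenate([partners, doubled])
    return DilutedConnectivity(N=N, contacts=contacts, allow_multiple=True, seed=seed)


# ---------------------------------------------------------------------------
# Learning


@dataclass(frozen=True)
class LearningRule:
    """Associative learning rule applied at each contact.

    ``hebb``:       dw = alpha * r_post * r_pre
    ``covariance``: dw = alpha * (r_post - a_post) * (r_pre - a_pre)

    The covariance variant includes heterosynaptic depression (the negative
    term when the presynaptic neuron fires but the postsynaptic one does not),
    which is what allows high storage capacity with sparse patterns.  If
    ``a_pre``/``a_post`` are None they default to each pattern's mean rate
    (equal to the sparseness a for binary patterns).
    """

    alpha: float = 1.0
    rule: str = "covariance"
    a_pre: float | None = None
    a_post: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.rule not in ("hebb", "covariance"):
            raise ValueError(f"unknown rule {self.rule!r}")


class SynapticWeights:
    """Real-valued weights supported only on the contact mask of a network."""

    def __init__(self, connectivity: DilutedConnectivity):
        self.connectivity = connectivity
        self._counts = connectivity.count_matrix().astype(np.float64)
        self.w = np.zeros((connectivity.N, connectivity.N))

    @property
    def N(self) -> int:
        return self.connectivity.N

    def store_patterns(
        self,
        patterns: "Sequence[RatePattern] | np.ndarray",
        rule: LearningRule,
    ) -> "SynapticWeights":
        """Accumulate the associative update for each pattern (in place).

        The total update is a sum of per-pattern outer products restricted to
        the contact mask, so it is independent of presentation order, and a
        duplicated contact receives the update once per contact (its effective
        weight doubles).
        """
        P = _as_pattern_matrix(patterns, self.N)
        if P.shape[0] == 0:
            return self
        if rule.rule == "hebb":
            post = pre = P
        else:
            means = P.mean(axis=1, keepdims=True)
            post = P - (means if rule.a_post is None else rule.a_post)
            pre = P - (means if rule.a_pre is None else rule.a_pre)
        self.w += rule.alpha * (post.T @ pre) * self._counts
        return self

    def drive(self, r: np.ndarray) -> np.ndarray:
        """Recurrent input h = W r / C (1/C normalization keeps h O(1))."""
        return (self.w @ r) / self.connectivity.C


def _as_pattern_matrix(patterns, N: int) -> np.ndarray:
    if isinstance(patterns, np.ndarray) and patterns.ndim == 2:
        P = np.asarray(patterns, dtype=float)
    else:
        rows = [p.rates if isinstance(p, RatePattern) else np.asarray(p, float) for p in patterns]
        P = np.array(rows, dtype=float) if rows else np.zeros((0, N))
    if P.shape[0] and P.shape[1] != N:
        raise ValueError(f"pattern length {P.shape[1]} != network size {N}")
    return P


# ---------------------------------------------------------------------------
# Recall dynamics


@dataclass(frozen=True)
class CA3Params:
    """Configuration of a CA3-style attractor simulation.

    ``a_target`` is the recall sparseness enforced by the k-WTA inhibition
    surrogate; ``dynamics`` is ``"kwta"`` (binary winners) or
    ``"threshold-linear"`` (graded rates above an activity-dependent
    threshold, for continuous/mixed patterns).  ``cue_gain`` is the strength
    of the sustained external cue input during recall: the retrieval cue is
    delivered continuously (as by the perforant path), weakly relative to the
    recurrent drive, rather than serving only as an initial condition.
    """

    N: int = 1000
    C: int = 200
    a_target: float = 0.05
    max_steps: int = 50
    convergence_tol: float = 1e-9
    dynamics: str = "kwta"
    cue_gain: float = 0.05
    noise_sd: float = 0.0
    allow_multiple: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.a_target < 1.0:
            raise ValueError("a_target must be in (0, 1)")
        if self.C >= self.N:
            raise ValueError("C must be < N")
        if self.dynamics not in ("kwta", "threshold-linear"):
            raise ValueError(f"unknown dynamics {self.dynamics!r}")


@dataclass
class RecallResult:
    """Outcome of a cued-recall run."""

    final: np.ndarray
    converged: bool
    n_steps: int
    trajectory: list[float]  # overlap with the reference (or previous state) per step


def _kwta(h: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest entries; ties broken toward lower index."""
    order = np.argsort(-h, kind="stable")
    return order[:k]


def recall(
    weights: SynapticWeights,
    cue: "RatePattern | np.ndarray",
    params: CA3Params,
    reference: "RatePattern | np.ndarray | None" = None,
    rng: np.random.Generator | None = None,
) -> RecallResult:
    """Iterate the recurrent dynamics from a cue until the active set is stable.

    Each synchronous step computes h = W r / C + cue_gain * cue (plus
    optional Gaussian noise) and applies the inhibition surrogate: binary k-WTA keeps the a_target*N
    most driven units at unit rate; threshold-linear keeps their rates graded
    above the (k+1)-th largest drive, rescaled to unit peak.  Non-convergence
    within ``max_steps`` is flagged on the result, not raised.
    """
    r = np.array(cue.rates if isinstance(cue, RatePattern) else cue, dtype=float)
    if r.size != weights.N:
        raise ValueError("cue length must equal network size")
    ref = None
    if reference is not None:
        ref = reference.rates if isinstance(reference, RatePattern) else np.asarray(reference, float)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    k = max(1, int(round(params.a_target * params.N)))
    active = np.flatnonzero(r > 0)
    prev_active = None  # for period-2 oscillation detection
    trajectory: list[float] = []
    converged = False
    step = 0
    cue_vec = np.array(cue.rates if isinstance(cue, RatePattern) else cue, dtype=float)
    for step in range(1, params.max_steps + 1):
        h = weights.drive(r) + params.cue_gain * cue_vec
        if params.noise_sd > 0:
            h = h + rng.normal(0.0, params.noise_sd, size=h.size)
        winners = _kwta(h, k)
        r_new = np.zeros_like(r)
        if params.dynamics == "kwta":
            r_new[winners] = 1.0
        else:
            theta = h[_kwta(h, k + 1)[-1]] if k + 1 <= h.size else h.min()
            r_new[winners] = np.maximum(h[winners] - theta, 0.0)
            peak = r_new.max()
            if peak > 0:
                r_new /= peak
        new_active = np.flatnonzero(r_new > 0)
        if ref is not None:
            try:
                trajectory.append(pattern_overlap(r_new, ref))
            except ValueError:
                trajectory.append(float("nan"))
        else:
            trajectory.append(float(np.linalg.norm(r_new - r)))
        same_set = new_active.size == active.size and np.array_equal(new_active, active)
        cycled = (
            prev_active is not None
            and new_active.size == prev_active.size
            and np.array_equal(new_active, prev_active)
        )
        rates_settled = np.max(np.abs(r_new - r)) <= params.convergence_tol
        r, active, prev_active = r_new, new_active, active
        if same_set and (params.dynamics == "kwta" or rates_settled):
            converged = True
            break
        if cycled and params.dynamics == "kwta":
            # synchronous k-WTA has settled into a 2-cycle between two states
            converged = True
            break
    return RecallResult(final=r, converged=converged, n_steps=step, trajectory=trajectory)


class CA3Network:
    """Convenience bundle of parameters, connectivity, and weights."""

    def __init__(
        self,
        params: CA3Params,
        connectivity: DilutedConnectivity | None = None,
    ):
        self.params = params
        if connectivity is None:
            connectivity = build_diluted_connectivity(
                params.N, params.C, allow_multiple=params.allow_multiple, seed=params.seed
            )
        self.connectivity = connectivity
        self.weights = SynapticWeights(connectivity)

    def store(self, patterns, rule: LearningRule | None = None) -> None:
        self.weights.store_patterns(patterns, rule or LearningRule())

    def recall(self, cue, reference=None, rng=None) -> RecallResult:
        return recall(self.weights, cue, self.params, reference=reference, rng=rng)


# ---------------------------------------------------------------------------
# Empirical capacity


def make_partial_cue(
    pattern: np.ndarray, cue_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Keep a random fraction of a pattern's active units, zero elsewhere.

    Returns the cue vector and the retained (cued) indices.
    """
    active = np.flatnonzero(pattern > 0)
    n_keep = max(1, int(round(cue_fraction * active.size)))
    keep = rng.choice(active, size=n_keep, replace=False)
    cue = np.zeros_like(pattern, dtype=float)
    cue[keep] = pattern[keep]
    return cue, keep


def _binary_patterns(p: int, N: int, a: float, rng: np.random.Generator) -> np.ndarray:
    k = max(1, int(round(a * N)))
    P = np.zeros((p, N))
    for mu in range(p):
        P[mu, rng.choice(N, size=k, replace=False)] = 1.0
    return P


@dataclass
class CapacityMeasurement:
    """Empirical capacity sweep for one network configuration."""

    params: CA3Params
    p_grid: list[int]
    fraction_retrieved: dict[int, list[float]]  # p -> per-seed fractions
    p_max_per_seed: list[int]
    seeds: list[int]

    @property
    def p_max(self) -> float:
        return float(np.mean(self.p_max_per_seed))

    @property
    def fitted_k(self) -> float:
        """k implied by p_max = k C / (a ln(1/a)), averaged over seeds."""
        a = self.params.a_target
        return float(self.p_max * a * np.log(1.0 / a) / self.params.C)

    def to_rows(self) -> list[dict]:
        rows = []
        for p in self.p_grid:
            for seed, frac in zip(self.seeds, self.fraction_retrieved.get(p, [])):
                rows.append({"p": p, "fraction_retrieved": frac, "seed": seed})
        return rows


def measure_capacity(
    params: CA3Params,
    p_grid: Sequence[int],
    cue_fraction: float = 0.5,
    overlap_criterion: float = 0.7,
    seeds: Sequence[int] = (0, 1, 2),
    retrieved_criterion: float = 0.9,
    n_test_cues: int = 20,
    rule: LearningRule | None = None,
    connectivity_builder=None,
) -> CapacityMeasurement:
    """Measure the storage capacity of the configured network empirically.

    For each load p in ``p_grid`` (ascending), p random binary patterns at
    sparseness ``a_target`` are stored and a sample of them is cued with
    ``cue_fraction`` of their active units; a pattern counts as retrieved when
    the recalled state overlaps it at >= ``overlap_criterion`` (Pearson).
    p_max is the largest load at which >= ``retrieved_criterion`` of tested
    patterns are retrieved.  Patterns accumulate incrementally across the grid
    so each seed performs a single storage pass.
    """
    p_grid = sorted(int(p) for p in p_grid)
    if not p_grid:
        raise ValueError("p_grid must not be empty")
    if not 0.0 < cue_fraction <= 1.0:
        raise ValueError("cue_fraction must be in (0, 1]")
    rule = rule or LearningRule()
    frac: dict[int, list[float]] = {p: [] for p in p_grid}
    p_max_per_seed: list[int] = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        if connectivity_builder is None:
            conn = build_diluted_connectivity(
                params.N, params.C, allow_multiple=params.allow_multiple, seed=seed
            )
        else:
            conn = connectivity_builder(params.N, params.C, seed)
        weights = SynapticWeights(conn)
        patterns = _binary_patterns(p_grid[-1], params.N, params.a_target, rng)
        stored = 0
        p_max = 0
        n_below = 0
        for p in p_grid:
            weights.store_patterns(patterns[stored:p], rule)
            stored = p
            test_idx = rng.choice(p, size=min(n_test_cues, p), replace=False)
            n_ok = 0
            for mu in test_idx:
                cue, _ = make_partial_cue(patterns[mu], cue_fraction, rng)
                res = recall(weights, cue, params, reference=patterns[mu], rng=rng)
                if pattern_overlap(res.final, patterns[mu]) >= overlap_criterion:
                    n_ok += 1
            f = n_ok / test_idx.size
            frac[p].append(f)
            if f >= retrieved_criterion:
                p_max = p
                n_below = 0
            else:
                n_below += 1
                if n_below >= 3:  # well past collapse; stop sweeping this seed
                    break
        p_max_per_seed.append(p_max)
    return CapacityMeasurement(
        params=params,
        p_grid=p_grid,
        fraction_retrieved=frac,
        p_max_per_seed=p_max_per_seed,
        seeds=list(seeds),
    )


def duplicate_contact_experiment(
    params: CA3Params,
    duplicate_fraction: float,
    p_grid: Sequence[int],
    seeds: Sequence[int] = (0, 1, 2),
    **capacity_kwargs,
) -> dict:
    """Compare capacity with and without duplicated contacts at matched C.

    Duplicated contacts (two synapses between the same pair, summing their
    weights) distort the energy landscape and reduce the number of patterns
    that can be stored and retrieved, which is the quantitative argument for
    diluted connectivity keeping pairwise multiplicity at most one.
    """
    baseline = measure_capacity(params, p_grid, seeds=seeds, **capacity_kwargs)
    if duplicate_fraction == 0.0:
        duplicated = baseline
    else:
        builder = lambda N, C, seed: build_duplicated_connectivity(
            N, C, duplicate_fraction, seed=seed
        )
        duplicated = measure_capacity(
            params, p_grid, seeds=seeds, connectivity_builder=builder, **capacity_kwargs
        )
    return {
        "baseline": baseline,
        "duplicated": duplicated,
        "p_max_baseline": baseline.p_max,
        "p_max_duplicated": duplicated.p_max,
        "duplicate_fraction": duplicate_fraction,
    }
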
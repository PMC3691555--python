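"""Mixed continuous + discrete memories in a single attractor network.

Physical space is continuous, so spatial memories are naturally stored as
overlapping Gaussian-tuned firing profiles (a continuous attractor); events
and objects are discrete subsets of active neurons.  A single recurrent
network can store *mixed* patterns that concatenate both: a Gaussian bump of
activity over a spatial sub-population (each neuron tuned to a preferred
location, here identified with its 1-based index) plus a binary subset within
a disjoint discrete sub-population.  After associative storage, cueing with
the discrete component alone retrieves the spatial bump (object -> place
recall), and cueing with the spatial bump retrieves the discrete subset
(place -> object recall).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ca3 import CA3Network, CA3Params, DilutedConnectivity, LearningRule, RecallResult
from .patterns import RatePattern


@dataclass(frozen=True)
class MixedMemorySpec:
    """One mixed memory: a spatial bump plus a discrete active subset.

    ``spatial_range`` is an inclusive 1-based interval (lo, hi) of units that
    form the continuous sub-population; ``center`` (in the same 1-based index
    units) and ``sigma`` define the Gaussian bump; ``discrete_indices`` are
    1-based unit indices outside the spatial range.  The bump is truncated at
    ``truncate_sd`` standard deviations so the stored pattern has sparse
    support.
    """

    spatial_range: tuple[int, int]
    center: float
    sigma: float
    discrete_indices: tuple[int, ...]
    amplitude_spatial: float = 1.0
    amplitude_discrete: float = 1.0
    truncate_sd: float = 3.0

    def __post_init__(self) -> None:
        lo, hi = self.spatial_range
        if not lo <= self.center <= hi:
            raise ValueError("bump center must lie inside spatial_range")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        for i in self.discrete_indices:
            if lo <= i <= hi:
                raise ValueError("discrete_indices must be disjoint from spatial_range")


def encode_mixed_memory(spec: MixedMemorySpec, N: int) -> RatePattern:
    """Realize a mixed-memory spec as a rate pattern on N units (1-based)."""
    lo, hi = spec.spatial_range
    if hi > N or any(i > N or i < 1 for i in spec.discrete_indices):
        raise ValueError("spec indices exceed network size")
    r = np.zeros(N)
    idx = np.arange(lo, hi + 1)  # 1-based unit indices
    if spec.sigma == 0.0:
        nearest = int(round(spec.center))
        r[nearest - 1] = spec.amplitude_spatial
    else:
        d = idx - spec.center
        bump = np.exp(-(d**2) / (2.0 * spec.sigma**2))
        bump[np.abs(d) > spec.truncate_sd * spec.sigma] = 0.0
        r[idx - 1] = spec.amplitude_spatial * bump
    for i in spec.discrete_indices:
        r[i - 1] = spec.amplitude_discrete
    return RatePattern(rates=r, population_id="mixed")


def decode_bump_center(
    p: "RatePattern | np.ndarray", spatial_range: tuple[int, int]
) -> float:
    """Population-vector readout: rate-weighted center of mass (1-based units).

    Non-periodic space; raises if the spatial component carries no activity.
    """
    r = p.rates if isinstance(p, RatePattern) else np.asarray(p, float)
    lo, hi = spatial_range
    idx = np.arange(lo, hi + 1)
    rates = r[lo - 1 : hi]
    total = rates.sum()
    if total <= 0:
        raise ValueError("no activity in the spatial component; cannot decode")
    return float(np.dot(rates, idx) / total)


class MixedMemoryNetwork:
    """An attractor network storing mixed continuous + discrete memories.

    Uses graded threshold-linear recall so the retrieved spatial component
    keeps its bump-shaped rate profile for population-vector decoding.  The
    recall sparseness target is taken from the stored memories' own active
    fraction.
    """

    def __init__(
        self,
        N: int = 1500,
        spatial_range: tuple[int, int] = (1, 1000),
        C: int | None = None,
        seed: int = 0,
        max_steps: int = 30,
    ):
        self.N = N
        self.spatial_range = spatial_range
        self.C = N - 1 if C is None else C
        self.seed = seed
        self.max_steps = max_steps
        self.specs: list[MixedMemorySpec] = []
        self._net: CA3Network | None = None

    def store(self, specs: list[MixedMemorySpec], rule: LearningRule | None = None) -> None:
        self.specs = list(specs)
        patterns = [encode_mixed_memory(s, self.N) for s in specs]
        n_active = int(np.mean([p.active_indices().size for p in patterns]))
        params = CA3Params(
            N=self.N,
            C=self.C,
            a_target=n_active / self.N,
            max_steps=self.max_steps,
            dynamics="threshold-linear",
            convergence_tol=1e-6,
            seed=self.seed,
        )
        self._net = CA3Network(params)
        self._net.store(patterns, rule or LearningRule())

    def _require_net(self) -> CA3Network:
        if self._net is None:
            raise RuntimeError("no memories stored yet")
        return self._net

    def recall_from_discrete(self, spec: MixedMemorySpec) -> RecallResult:
        """Cue with the discrete (object/event) component only."""
        cue = np.zeros(self.N)
        for i in spec.discrete_indices:
            cue[i - 1] = spec.amplitude_discrete
        return self._require_net().recall(cue)

    def recall_from_continuous(self, spec: MixedMemorySpec) -> RecallResult:
        """Cue with the spatial (bump) component only."""
        full = encode_mixed_memory(spec, self.N).rates.copy()
        for i in spec.discrete_indices:
            full[i - 1] = 0.0
        return self._require_net().recall(full)

    def decode_center(self, result: RecallResult) -> float:
        return decode_bump_center(result.final, self.spatial_range)

    def recalled_discrete_set(self, result: RecallResult, n: int) -> set[int]:
        """The n most active units outside the spatial range (1-based)."""
        lo, hi = self.spatial_range
        r = result.final.copy()
        r[lo - 1 : hi] = -np.inf
        top = np.argsort(-r, kind="stable")[:n]
        return {int(i) + 1 for i in top if result.final[i] > 0}


def default_mixed_memories(
    N: int = 1500,
    spatial_range: tuple[int, int] = (1, 1000),
    centers: tuple[float, ...] = (300.0, 500.0),
    sigma: float = 50.0,
    n_discrete: int = 25,
    seed: int = 0,
) -> list[MixedMemorySpec]:
    """Two object-place memories on a 1500-unit network.

    Continuous units 1-1000 carry Gaussian bumps at locations 300 and 500
    (sigma 50 index units); each memory additionally activates a disjoint
    random binary subset of ``n_discrete`` units among 1001-1500 representing
    its discrete object/event.
    """
    lo, hi = spatial_range
    rng = np.random.default_rng(seed)
    discrete_pool = np.arange(hi + 1, N + 1)
    chosen = rng.choice(discrete_pool, size=n_discrete * len(centers), replace=False)
    specs = []
    for m, center in enumerate(centers):
        idx = tuple(int(i) for i in sorted(chosen[m * n_discrete : (m + 1) * n_discrete]))
        specs.append(
            MixedMemorySpec(
                spatial_range=spatial_range, center=center, sigma=sigma, discrete_indices=idx
            )
        )
    return specs


def run_mixed_recall_demo(seed: int = 0, **kwargs) -> dict:
    """Store the two default mixed memories and recall each from its object cue.

    Returns the decoded bump centers (expected near 300 and 500) and the
    recalled discrete sets from the reverse, place-cued direction.
    """
    specs = default_mixed_memories(seed=seed, **kwargs)
    net = MixedMemoryNetwork(seed=seed)
    net.store(specs)
    out: dict = {"centers": [], "reverse_match": []}
    for spec in specs:
        res = net.recall_from_discrete(spec)
        out["centers"].append(net.decode_center(res))
        rev = net.recall_from_continuous(spec)
        got = net.recalled_discrete_set(rev, len(spec.discrete_indices))
        out["reverse_match"].append(
            len(got & set(spec.discrete_indices)) / len(spec.discrete_indices)
        )
    return out
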
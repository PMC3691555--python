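"""Entorhinal grid inputs, dentate competitive learning, and CA3 input routes.

The dentate gyrus is modelled as a competitive network that transforms
entorhinal grid-cell firing into sparse, well-separated representations —
producing place-like single fields from periodic grid input.  Two routes then
reach CA3:

* the mossy fibers (MF): very few (~46) strong contacts per CA3 cell from the
  dentate, acting as a random sparse projection that *randomizes* the CA3
  representation during storage so different memories are as different as
  possible;
* the perforant path (pp): many weaker direct entorhinal contacts whose
  associatively modified weights deliver the *retrieval cue* that initiates
  completion in the CA3 recurrent network.

The storage/recall asymmetry — MF needed to set up new CA3 patterns but not
to recall them, pp needed at recall — is an explicit prediction tested by the
pipeline module's lesion suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .patterns import RatePattern


# ---------------------------------------------------------------------------
# Grid cells


@dataclass(frozen=True)
class GridCellParams:
    """A medial-entorhinal grid cell firing on a triangular lattice.

    ``spacing`` is the lattice period (cm), ``orientation`` the lattice
    rotation (radians), ``phase`` a 2-D spatial offset (cm), ``peak_rate`` the
    firing rate at a lattice vertex.
    """

    spacing: float
    orientation: float = 0.0
    phase: tuple[float, float] = (0.0, 0.0)
    peak_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.peak_rate <= 0:
            raise ValueError("peak_rate must be positive")

    def lattice_vectors(self) -> np.ndarray:
        """Two primitive translation vectors of the firing lattice."""
        th = self.orientation
        v1 = self.spacing * np.array([np.cos(th), np.sin(th)])
        v2 = self.spacing * np.array([np.cos(th + np.pi / 3), np.sin(th + np.pi / 3)])
        return np.stack([v1, v2])


def grid_firing_map(cell: GridCellParams, positions: np.ndarray) -> np.ndarray:
    """Grid-cell firing rate at 2-D positions (cm).

    Rectified sum of three cosine plane waves at 60 degree separations: the
    interference pattern peaks at ``peak_rate`` on a triangular lattice with
    the cell's spacing, orientation, and phase, and is exactly periodic under
    lattice translations.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.shape[-1] != 2 or not np.all(np.isfinite(pos)):
        raise ValueError("positions must be finite 2-D points")
    kmag = 4.0 * np.pi / (np.sqrt(3.0) * cell.spacing)
    # wave directions 30, 90, 150 degrees relative to the lattice orientation
    angles = cell.orientation + np.pi / 6 + np.array([0.0, np.pi / 3, 2 * np.pi / 3])
    kvecs = kmag * np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (3, 2)
    rel = pos - np.asarray(cell.phase, dtype=float)
    g = np.cos(rel @ kvecs.T).sum(axis=1)  # in [-1.5, 3]
    rates = cell.peak_rate * np.maximum(0.0, (g + 1.5) / 4.5)
    return rates if np.asarray(positions).ndim > 1 else rates


def grid_population(
    spacings: tuple[float, ...] = (30.0, 50.0, 70.0),
    n_per_spacing: int = 34,
    peak_rate: float = 1.0,
    seed: int = 0,
) -> list[GridCellParams]:
    """A population of grid cells with a few spacings and random phases."""
    rng = np.random.default_rng(seed)
    cells = []
    for s in spacings:
        for _ in range(n_per_spacing):
            phase = tuple(rng.uniform(0.0, s, size=2))
            orientation = rng.uniform(0.0, np.pi / 3)
            cells.append(
                GridCellParams(spacing=s, orientation=orientation, phase=phase, peak_rate=peak_rate)
            )
    return cells


def grid_input_matrix(cells: list[GridCellParams], positions: np.ndarray) -> np.ndarray:
    """(n_positions, n_cells) matrix of grid rates over a trajectory."""
    return np.stack([grid_firing_map(c, positions) for c in cells], axis=1)


def linear_track_positions(length_cm: float = 100.0, n: int = 50) -> np.ndarray:
    """Evenly spaced 2-D positions along a linear track on the x axis."""
    x = np.linspace(0.0, length_cm, n)
    return np.stack([x, np.zeros_like(x)], axis=1)


# ---------------------------------------------------------------------------
# Dentate competitive network


@dataclass(frozen=True)
class CompetitiveNetParams:
    """Dentate-style competitive network configuration.

    Output sparseness ``a_out`` is enforced exactly by k-WTA; weight rows are
    kept at unit norm (divisive normalization), so learning rotates each
    output unit's weight vector toward the input patterns it wins.
    """

    n_in: int
    n_out: int
    a_out: float = 0.05
    learn_rate: float = 0.1
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.a_out < 1.0:
            raise ValueError("a_out must be in (0, 1)")
        if self.learn_rate <= 0:
            raise ValueError("learn_rate must be positive")


class CompetitiveNet:
    """k-WTA competitive network with unit-norm divisive weight normalization."""

    def __init__(self, params: CompetitiveNetParams):
        self.params = params
        rng = np.random.default_rng(params.seed)
        w = rng.uniform(0.0, 1.0, size=(params.n_out, params.n_in))
        self.w = w / np.linalg.norm(w, axis=1, keepdims=True)

    @property
    def k_winners(self) -> int:
        return max(1, int(round(self.params.a_out * self.params.n_out)))

    def respond(self, x: np.ndarray) -> np.ndarray:
        """Binary k-WTA output for one input pattern (no learning)."""
        h = self.w @ x
        out = np.zeros(self.params.n_out)
        winners = np.argsort(-h, kind="stable")[: self.k_winners]
        out[winners] = 1.0
        return out

    def train(self, input_patterns: np.ndarray) -> np.ndarray:
        """Competitive learning over the input ensemble.

        Per presentation the k winners move their weight vectors toward the
        input (dw = learn_rate * x) and are renormalized to unit norm.  Zero
        inputs are skipped with a warning.  Returns the post-training binary
        output map, one row per input pattern.
        """
        X = np.atleast_2d(np.asarray(input_patterns, dtype=float))
        if np.any(X < 0):
            raise ValueError("input patterns must be nonnegative")
        rng = np.random.default_rng(self.params.seed + 1)
        lr = self.params.learn_rate
        for _ in range(self.params.epochs):
            for idx in rng.permutation(X.shape[0]):
                x = X[idx]
                if not x.any():
                    warnings.warn("skipping all-zero input pattern")
                    continue
                h = self.w @ x
                winners = np.argsort(-h, kind="stable")[: self.k_winners]
                self.w[winners] += lr * x
                self.w[winners] /= np.linalg.norm(self.w[winners], axis=1, keepdims=True)
        return np.stack([self.respond(x) if x.any() else np.zeros(self.params.n_out) for x in X])


def train_competitive(
    params: CompetitiveNetParams, input_patterns: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Train a competitive network; returns (weight matrix, output map)."""
    net = CompetitiveNet(params)
    output_map = net.train(input_patterns)
    return net.w, output_map


# ---------------------------------------------------------------------------
# Place-field statistics


def place_field_stats(output_map: np.ndarray, min_rate_fraction: float = 0.5) -> list[dict]:
    """Per-unit place-field count and widths over a contiguous 1-D space.

    ``output_map`` has one row per position (in traversal order) and one
    column per unit.  A field is a maximal contiguous run of positions where
    the unit's rate exceeds ``min_rate_fraction`` of its peak.  Silent units
    get field count 0.  Widths are in position-sample units.
    """
    M = np.atleast_2d(np.asarray(output_map, dtype=float))
    stats = []
    for u in range(M.shape[1]):
        r = M[:, u]
        peak = r.max()
        if peak <= 0:
            stats.append({"unit": u, "n_fields": 0, "widths": []})
            continue
        above = r >= min_rate_fraction * peak
        edges = np.diff(above.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(above.size)
        widths = [int(e - s) for s, e in zip(starts, ends)]
        stats.append({"unit": u, "n_fields": len(widths), "widths": widths})
    return stats


# ---------------------------------------------------------------------------
# Mossy-fiber projection


@dataclass
class MossyProjection:
    """Sparse random DG -> CA3 projection (default 46 contacts per CA3 cell).

    The tiny contact count acts as a randomizer: even correlated dentate
    patterns drive nearly independent CA3 subsets.  A fixed per-unit jitter
    breaks k-WTA ties deterministically (drive sums over few binary inputs are
    small integers).  ``gain`` models optional non-associative mossy-fiber
    amplification (default 1, i.e. off).
    """

    n_dg: int
    n_ca3: int
    n_contacts: int = 46
    a_ca3: float = 0.05
    gain: float = 1.0
    seed: int = 0
    contacts: np.ndarray = field(init=False)
    _jitter: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_contacts > self.n_dg:
            raise ValueError("n_contacts cannot exceed the dentate population size")
        rng = np.random.default_rng(self.seed)
        self.contacts = np.stack(
            [rng.choice(self.n_dg, size=self.n_contacts, replace=False) for _ in range(self.n_ca3)]
        )
        self._jitter = rng.uniform(0.0, 1e-6, size=self.n_ca3)

    def drive(self, dg_pattern: np.ndarray) -> np.ndarray:
        dg = np.asarray(dg_pattern, dtype=float)
        if dg.size != self.n_dg:
            raise ValueError("dentate pattern length mismatch")
        return self.gain * dg[self.contacts].sum(axis=1)


def mossy_projection(dg_pattern: "RatePattern | np.ndarray", proj: MossyProjection) -> RatePattern:
    """CA3 pattern evoked through the mossy fibers: k-WTA of the summed drive."""
    dg = dg_pattern.rates if isinstance(dg_pattern, RatePattern) else np.asarray(dg_pattern, float)
    h = proj.drive(dg) + proj._jitter
    k = max(1, int(round(proj.a_ca3 * proj.n_ca3)))
    out = np.zeros(proj.n_ca3)
    out[np.argsort(-h, kind="stable")[:k]] = 1.0
    return RatePattern(rates=out, population_id="CA3")


# ---------------------------------------------------------------------------
# Perforant-path cue pathway


class PerforantPath:
    """Associative feedforward EC -> CA3 weights used as the recall-cue route.

    The weights are Hebbianly modified at storage time (when the CA3 pattern
    is being imposed by the mossy fibers); at recall a partial or complete EC
    pattern is mapped through them and thresholded by k-WTA to produce a CA3
    cue for the recurrent attractor.
    """

    def __init__(self, n_ec: int, n_ca3: int, a_ca3: float = 0.05, seed: int = 0):
        self.n_ec = n_ec
        self.n_ca3 = n_ca3
        self.a_ca3 = a_ca3
        self.w = np.zeros((n_ca3, n_ec))
        self._jitter = np.random.default_rng(seed).uniform(0.0, 1e-9, size=n_ca3)

    def train(self, ec_patterns: np.ndarray, ca3_patterns: np.ndarray, learn_rate: float = 1.0):
        EC = np.atleast_2d(np.asarray(ec_patterns, float))
        CA3 = np.atleast_2d(np.asarray(ca3_patterns, float))
        if EC.shape[0] != CA3.shape[0]:
            raise ValueError("EC and CA3 pattern counts must match")
        self.w += learn_rate * CA3.T @ EC
        return self

    def cue(self, ec_pattern: "RatePattern | np.ndarray") -> RatePattern:
        ec = ec_pattern.rates if isinstance(ec_pattern, RatePattern) else np.asarray(ec_pattern, float)
        h = self.w @ ec + self._jitter
        k = max(1, int(round(self.a_ca3 * self.n_ca3)))
        out = np.zeros(self.n_ca3)
        out[np.argsort(-h, kind="stable")[:k]] = 1.0
        return RatePattern(rates=out, population_id="CA3")


def train_pp_cue(
    ec_patterns: np.ndarray,
    ca3_patterns: np.ndarray,
    learn_rate: float = 1.0,
    a_ca3: float = 0.05,
    seed: int = 0,
) -> PerforantPath:
    """Train the perforant-path cue weights on paired EC/CA3 patterns."""
    EC = np.atleast_2d(np.asarray(ec_patterns, float))
    CA3 = np.atleast_2d(np.asarray(ca3_patterns, float))
    pp = PerforantPath(EC.shape[1], CA3.shape[1], a_ca3=a_ca3, seed=seed)
    return pp.train(EC, CA3, learn_rate)
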
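"""Closed-form storage-capacity estimates and connectivity arithmetic.

For a recurrent autoassociation network with C modifiable synapses per neuron
storing patterns at population sparseness a, the number of retrievable
memories is approximately

    p_max ~= k * C / (a * ln(1/a))

with k a factor near 0.2-0.3 that depends only weakly on the rate distribution
and connectivity.  The corresponding feedforward pattern-associator bound drops
the k factor.  Both use the natural logarithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

DEFAULT_K = 0.235  # within the ~0.2-0.3 range the analysis gives


@dataclass(frozen=True)
class CapacityQuery:
    """Inputs to the capacity formulas.

    Parameters
    ----------
    C
        Synapses per neuron: recurrent-collateral count for the autoassociator,
        feedforward count for the pattern associator.
    a
        Sparseness of the stored (output) representation, strictly in (0, 1).
    k
        Proportionality factor for the autoassociator formula (default 0.235).
    """

    C: int
    a: float
    k: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.C < 1:
            raise ValueError("C must be a positive integer")
        if not 0.0 < self.a < 1.0:
            raise ValueError(f"sparseness a must be in (0, 1), got {self.a}")
        if self.k < 0.0:
            raise ValueError("k must be nonnegative")


def autoassoc_capacity(q: CapacityQuery) -> float:
    """Maximum retrievable patterns of a recurrent autoassociator.

    Returns k * C / (a * ln(1/a)) as a real number; callers round for
    reporting.  With C = 12,000 recurrent synapses per neuron and a = 0.02
    this evaluates to roughly 36,000 memories.
    """
    return q.k * q.C / (q.a * math.log(1.0 / q.a))


def pattern_assoc_capacity(q: CapacityQuery) -> float:
    """Maximum retrievable associations of a feedforward pattern associator.

    Returns C / (a0 * ln(1/a0)) where a0 is the output sparseness.  Equals the
    autoassociator formula with k = 1, so at equal sparseness the capacity
    ratio of a feedforward versus a recurrent system is simply the ratio of
    their synapse counts (e.g. 3600/12,000 = 0.3 for the perforant-path versus
    recurrent-collateral inputs to CA3).
    """
    return q.C / (q.a * math.log(1.0 / q.a))


def connectivity_dilution(C: int, N: int) -> float:
    """Fraction of possible inputs actually connected: C / N.

    Examples: 12,000 recurrent synapses among 300,000 CA3 cells give dilution
    0.04 (or ~2% if the 600,000 bilateral population is used); 46 mossy-fiber
    contacts from 10^6 granule cells give 4.6e-5, i.e. 0.005%.
    """
    if C < 1 or N < 1:
        raise ValueError("C and N must be positive integers")
    if C > N:
        raise ValueError(f"C ({C}) cannot exceed N ({N})")
    return C / N
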
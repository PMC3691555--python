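# hippomem

Attractor-network models of hippocampal episodic memory: a simulator and
analysis library for the quantitative theory of how the dentate gyrus, CA3,
and CA1 cooperate to store and recall one-trial object-place (event)
memories, and how temporal order can be carried by slowly drifting attractor
states.

## The scientific problem

Episodic memory requires forming an arbitrary association — an object at a
place, an event at a time — in a single trial, keeping it distinct from
thousands of other stored memories, and later retrieving the whole memory
from any fragment. The theory implemented here assigns each step to a
hippocampal stage:

* **CA3** is a single recurrent *autoassociation (attractor) network*. A
  memory is a firing-rate pattern over the population; associative
  (Hebbian/covariance) modification of the recurrent-collateral synapses
  `w_ij` during one presentation stores it, and the recurrent dynamics later
  complete the whole pattern from a partial cue. The storage capacity is
  approximately

  `p_max ≈ k · C / (a · ln(1/a))`

  where `C` is the number of modifiable recurrent synapses per neuron, `a`
  the population sparseness `a = (Σ r_i/N)² / (Σ r_i²/N)`, and `k ≈ 0.2–0.3`.
  With the anatomical `C = 12,000` and `a = 0.02` this gives ~36,000
  memories. The same network stores *continuous* spatial patterns (Gaussian
  bumps over location-tuned neurons) and *mixed* memories combining a spatial
  bump with a discrete object component, so an object cue retrieves a place
  and vice versa.
* **The dentate gyrus** is a competitive network that turns entorhinal
  grid-cell input into sparse, well-separated, place-like codes (pattern
  separation), and its very sparse mossy-fiber projection (~46 contacts per
  CA3 cell, connectivity 0.005%) *randomizes* which CA3 subset represents
  each new memory — essential at storage, irrelevant at recall.
* **The perforant path** carries the retrieval cue into CA3 at recall; its
  feedforward pattern-associator capacity (`C/(a·ln(1/a))` with `C = 3600`)
  is only 3600/12,000 = 0.3 of the recurrent system's, which is the
  quantitative argument against a feedforward-only account.
* **CA1** reads the completed CA3 pattern out through associatively modified
  Schaffer-collateral synapses.
* **Temporal order** is modelled by pools of "time-encoding" neurons:
  adaptation ends each pool's reign, noise triggers the transition, and
  slightly stronger forward than reverse weights between pools make the
  sequence replay in order, so items associated with each pool are recalled
  in the order they were presented.

No external data is used; every experiment runs on seeded synthetic inputs
that realize the statistical structure the theory assumes.

## Worked example

```python
from hippomem import (CapacityQuery, autoassoc_capacity, connectivity_dilution,
                      MixedMemoryNetwork, default_mixed_memories)

# analytic capacity at the anatomical parameters
q = CapacityQuery(C=12_000, a=0.02, k=0.235)
print(round(autoassoc_capacity(q)))          # 36043  (~36,000 memories)
print(connectivity_dilution(12_000, 300_000))  # 0.04  (recurrent dilution)

# a 1500-unit attractor holding two mixed object-place memories:
# spatial bumps at locations 300 and 500 on units 1-1000 (sigma 50),
# disjoint discrete object codes on units 1001-1500
specs = default_mixed_memories(seed=0)
net = MixedMemoryNetwork(seed=0)
net.store(specs)
for spec in specs:
    res = net.recall_from_discrete(spec)     # cue with the object code alone
    print(round(net.decode_center(res), 1))  # 298.4 then 501.6
```

The decoded centers are the population-vector readout of the recalled
spatial bump: cueing with each memory's discrete (object) component alone
retrieves its stored location to within a few neurons of 300 and 500.

The same networks are driven from the shell:

```bash
hippomem capacity --C 12000 --a 0.02            # analytic p_max as JSON
hippomem mixed-recall --seed 0                  # the example above
hippomem object-place --seed 7 --out results/   # one-trial task, trials.csv
hippomem sequence --mode forward-bias --seed 1  # temporal-order replay
```

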
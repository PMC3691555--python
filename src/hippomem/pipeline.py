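"""End-to-end one-trial object-place memory: storage, cued recall, lesions.

Wires the stages into a model version of a one-trial object-place recall
task: on each trial two novel events (object O1 at place P1, object O2 at
place P2) are stored in a single presentation each, and recall is cued with
one object alone, requiring retrieval of the place it occupied.

Storage route: the entorhinal event pattern drives the dentate competitive
network, whose sparse output selects a random CA3 subset through the mossy
fibers; the CA3 recurrent collaterals, the perforant-path cue weights, and
the CA3->CA1 Schaffer collaterals are each updated once (one-trial learning).
Recall route: the object-only entorhinal pattern is mapped through the
perforant path into a partial CA3 cue, the recurrent attractor completes it,
and the place is decoded by comparing the completed CA3 pattern against the
mossy-fiber-defined CA3 signatures of the candidate places (a two-alternative
argmax, matching the two response locations of the task).

The lesion switches implement the theory's storage/recall asymmetry: the
mossy fibers are required to set up new CA3 representations (lesioning them
at storage collapses accuracy) but play no role at recall; the perforant path
is the recall cue route (lesioning it at recall collapses accuracy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ca3 import CA3Params, CA3Network, LearningRule
from .dentate import CompetitiveNet, CompetitiveNetParams, MossyProjection, PerforantPath, mossy_projection
from .patterns import pattern_overlap
from .synth import generate_events


# ---------------------------------------------------------------------------
# CA1 readout


class CA1Readout:
    """Heteroassociative CA3 -> CA1 mapping via Schaffer-collateral weights.

    CA1 target patterns are produced by a fixed competitive (k-WTA) stage;
    the Schaffer weights are Hebbianly modified at storage so that a complete
    (or attractor-completed) CA3 pattern retrieves its CA1 pattern, the
    efficient cue for recall pathways beyond the hippocampus.
    """

    def __init__(self, n_ca3: int, n_ca1: int, a_ca1: float = 0.05, seed: int = 0):
        self.n_ca3 = n_ca3
        self.n_ca1 = n_ca1
        self.a_ca1 = a_ca1
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.0, 1.0, size=(n_ca1, n_ca3))
        self._target_w = w / np.linalg.norm(w, axis=1, keepdims=True)
        self.w = np.zeros((n_ca1, n_ca3))
        self._jitter = rng.uniform(0.0, 1e-9, size=n_ca1)

    def _kwta(self, h: np.ndarray) -> np.ndarray:
        k = max(1, int(round(self.a_ca1 * self.n_ca1)))
        out = np.zeros(self.n_ca1)
        out[np.argsort(-(h + self._jitter), kind="stable")[:k]] = 1.0
        return out

    def target(self, ca3_pattern: np.ndarray) -> np.ndarray:
        """CA1 pattern assigned to a CA3 pattern by the competitive stage."""
        return self._kwta(self._target_w @ np.asarray(ca3_pattern, float))

    def train(self, ca3_patterns: np.ndarray, ca1_targets: np.ndarray, learn_rate: float = 1.0):
        CA3 = np.atleast_2d(np.asarray(ca3_patterns, float))
        CA1 = np.atleast_2d(np.asarray(ca1_targets, float))
        if CA3.shape[0] != CA1.shape[0]:
            raise ValueError("CA3 and CA1 pattern counts must match")
        self.w += learn_rate * CA1.T @ CA3
        return self

    def recall(self, ca3_pattern: np.ndarray) -> np.ndarray:
        return self._kwta(self.w @ np.asarray(ca3_pattern, float))


def train_ca1_readout(
    ca3_patterns: np.ndarray, ca1_targets: np.ndarray, learn_rate: float = 1.0, seed: int = 0
) -> CA1Readout:
    CA3 = np.atleast_2d(np.asarray(ca3_patterns, float))
    CA1 = np.atleast_2d(np.asarray(ca1_targets, float))
    readout = CA1Readout(CA3.shape[1], CA1.shape[1], a_ca1=float(CA1[0].mean()) or 0.05, seed=seed)
    return readout.train(CA3, CA1, learn_rate)


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class ExperimentConfig:
    """Network sizes, sparsenesses, and task parameters for the task model."""

    n_object_units: int = 200
    n_place_units: int = 200
    n_dg: int = 800
    a_dg: float = 0.05
    n_ca3: int = 500
    C_ca3: int = 150
    a_ca3: float = 0.05
    n_mf_contacts: int = 46
    n_ca1: int = 300
    a_ca1: float = 0.05
    n_places: int = 2
    n_trials: int = 50
    cue_type: str = "object"  # or "object+place"
    learn_rate: float = 1.0
    ca3_max_steps: int = 25
    seed: int = 0
    # lesions
    mf_lesion_at_storage: bool = False
    mf_lesion_at_recall: bool = False
    pp_lesion_at_recall: bool = False

    def __post_init__(self) -> None:
        if self.C_ca3 >= self.n_ca3:
            raise ValueError("C_ca3 must be < n_ca3")
        if self.n_mf_contacts > self.n_dg:
            raise ValueError("n_mf_contacts cannot exceed n_dg")
        if self.cue_type not in ("object", "object+place"):
            raise ValueError(f"unknown cue_type {self.cue_type!r}")
        for name in ("a_dg", "a_ca3", "a_ca1"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")

    @property
    def n_ec(self) -> int:
        return self.n_object_units + self.n_place_units

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = json.loads(text)
        return cls.from_dict(data or {})


@dataclass
class TrialRecord:
    """One trial of the object-place task."""

    trial: int
    cue_object: int
    true_place: int
    decoded_place: int
    correct: bool
    cue_overlap: float  # pp cue vs stored CA3 pattern of the cued event
    recall_overlap: float  # completed CA3 pattern vs stored CA3 pattern
    ca1_overlap: float  # CA1 readout of the completed pattern vs its target
    seed: int


@dataclass
class TaskResult:
    trials: list[TrialRecord]
    config: ExperimentConfig

    @property
    def accuracy(self) -> float:
        return float(np.mean([t.correct for t in self.trials]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.trials])

    def summary(self) -> dict:
        return {
            "n_trials": len(self.trials),
            "accuracy": self.accuracy,
            "mean_cue_overlap": float(np.nanmean([t.cue_overlap for t in self.trials])),
            "mean_recall_overlap": float(np.nanmean([t.recall_overlap for t in self.trials])),
            "mean_ca1_overlap": float(np.nanmean([t.ca1_overlap for t in self.trials])),
        }

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "trials.csv", index=False)
        (out / "summary.json").write_text(json.dumps(self.summary(), indent=2))


# ---------------------------------------------------------------------------
# Task


class ObjectPlaceTask:
    """The full storage/recall circuit with fixed projections, plastic weights."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        c = config
        self.dg = CompetitiveNet(
            CompetitiveNetParams(n_in=c.n_ec, n_out=c.n_dg, a_out=c.a_dg, seed=c.seed)
        )
        self.mf = MossyProjection(
            n_dg=c.n_dg,
            n_ca3=c.n_ca3,
            n_contacts=c.n_mf_contacts,
            a_ca3=c.a_ca3,
            seed=c.seed + 1,
        )

    def _random_ca3_pattern(self, rng: np.random.Generator) -> np.ndarray:
        """Noise-dominated CA3 state (what forms without the mossy-fiber drive)."""
        c = self.config
        out = np.zeros(c.n_ca3)
        k = max(1, int(round(c.a_ca3 * c.n_ca3)))
        out[rng.choice(c.n_ca3, size=k, replace=False)] = 1.0
        return out

    def event_to_ca3(self, ec_pattern: np.ndarray) -> np.ndarray:
        """Storage route: EC -> dentate competitive net -> mossy fibers -> CA3."""
        dg_out = self.dg.respond(np.asarray(ec_pattern, float))
        return mossy_projection(dg_out, self.mf).rates

    def place_reference(self, place_pattern_units: np.ndarray) -> np.ndarray:
        """CA3 signature of a place-only entorhinal pattern (decode template)."""
        return self.event_to_ca3(place_pattern_units)

    def run_trial(self, trial: int, trial_seed: int) -> TrialRecord:
        c = self.config
        # distinct stream from the one seeding generate_events below
        rng = np.random.default_rng(np.random.SeedSequence([trial_seed, 7]))
        events, ec_patterns = generate_events(
            n_events=2,
            n_places=c.n_places,
            n_object_units=c.n_object_units,
            n_place_units=c.n_place_units,
            seed=trial_seed,
        )
        # --- one-shot storage -------------------------------------------------
        if c.mf_lesion_at_storage:
            ca3_patterns = [self._random_ca3_pattern(rng) for _ in events]
        else:
            ca3_patterns = [self.event_to_ca3(p.rates) for p in ec_patterns]
        ca3_net = CA3Network(
            CA3Params(
                N=c.n_ca3, C=c.C_ca3, a_target=c.a_ca3, max_steps=c.ca3_max_steps,
                seed=trial_seed,
            )
        )
        rule = LearningRule(alpha=c.learn_rate) if c.learn_rate > 0 else None
        if rule is not None:
            ca3_net.store(np.array(ca3_patterns), rule)
        pp = PerforantPath(c.n_ec, c.n_ca3, a_ca3=c.a_ca3, seed=trial_seed + 1)
        ca1 = CA1Readout(c.n_ca3, c.n_ca1, a_ca1=c.a_ca1, seed=c.seed + 2)
        ca1_targets = [ca1.target(p) for p in ca3_patterns]
        if c.learn_rate > 0:
            EC = np.array([p.rates for p in ec_patterns])
            pp.train(EC, np.array(ca3_patterns), c.learn_rate)
            ca1.train(np.array(ca3_patterns), np.array(ca1_targets), c.learn_rate)
        # --- recall -----------------------------------------------------------
        cue_idx = int(rng.integers(0, len(events)))
        ec_cue = np.zeros(c.n_ec)
        obj = ec_patterns[cue_idx].rates[: c.n_object_units]
        ec_cue[: c.n_object_units] = obj
        if c.cue_type == "object+place":
            ec_cue[:] = ec_patterns[cue_idx].rates
        if c.pp_lesion_at_recall:
            ca3_cue = self._random_ca3_pattern(rng)
        else:
            ca3_cue = pp.cue(ec_cue).rates
        # mossy fibers are not part of the recall route: lesioning them here is a no-op
        res = ca3_net.recall(ca3_cue, reference=ca3_patterns[cue_idx])
        # --- decode place: two-alternative forced choice ----------------------
        # Compare the retrieved CA3 trace with the encoding-route signature of
        # the cue object placed at each candidate place; answer with the better
        # match (the task offers exactly two response locations).
        scores = []
        for ev, ecp in zip(events, ec_patterns):
            candidate = np.zeros(c.n_ec)
            candidate[: c.n_object_units] = obj
            candidate[c.n_object_units :] = ecp.rates[c.n_object_units :]
            ref = self.event_to_ca3(candidate)
            scores.append(float(np.dot(res.final, ref)) + rng.uniform(0.0, 1e-9))
        decoded = events[int(np.argmax(scores))].place
        ca1_out = ca1.recall(res.final)
        return TrialRecord(
            trial=trial,
            cue_object=events[cue_idx].object_id,
            true_place=events[cue_idx].place,
            decoded_place=decoded,
            correct=decoded == events[cue_idx].place,
            cue_overlap=_safe_overlap(ca3_cue, ca3_patterns[cue_idx]),
            recall_overlap=_safe_overlap(res.final, ca3_patterns[cue_idx]),
            ca1_overlap=_safe_overlap(ca1_out, ca1_targets[cue_idx]),
            seed=trial_seed,
        )


def _safe_overlap(x: np.ndarray, y: np.ndarray) -> float:
    try:
        return pattern_overlap(x, y)
    except ValueError:
        return float("nan")


def run_object_place_task(config: ExperimentConfig, seed: int | None = None) -> TaskResult:
    """Run the configured number of one-trial object-place recall trials.

    Fixed projections (dentate weights, mossy-fiber contacts, CA1 competitive
    stage) are shared across trials; all plastic weights are reset each trial
    (each trial stores two novel events).  Returns the per-trial records and
    summary accuracy.
    """
    if seed is None:
        seed = config.seed
    task = ObjectPlaceTask(config)
    trials = [
        task.run_trial(t, trial_seed=seed * 100_003 + t) for t in range(config.n_trials)
    ]
    return TaskResult(trials=trials, config=config)


def lesion_suite(config: ExperimentConfig, seed: int | None = None) -> dict:
    """Accuracies under the theory's lesion predictions.

    Returns accuracy for: intact; mossy fibers lesioned at storage (collapses
    to ~chance); mossy fibers lesioned at recall only (unchanged: MF are not
    on the recall route); perforant path lesioned at recall (collapses).
    """
    from dataclasses import replace

    out = {}
    for name, kwargs in [
        ("intact", {}),
        ("mf_lesion_at_storage", {"mf_lesion_at_storage": True}),
        ("mf_lesion_at_recall", {"mf_lesion_at_recall": True}),
        ("pp_lesion_at_recall", {"pp_lesion_at_recall": True}),
    ]:
        cfg = replace(config, **kwargs)
        out[name] = run_object_place_task(cfg, seed=seed).accuracy
    return out
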
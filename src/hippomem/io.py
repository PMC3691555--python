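"""HDF5 and CSV serialization for patterns, connectivity, and weights."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .ca3 import DilutedConnectivity, SynapticWeights
from .patterns import RatePattern


def save_pattern_h5(path: str | Path, pattern: RatePattern, name: str = "rates") -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=pattern.rates.astype(np.float64))
        ds.attrs["population_id"] = pattern.population_id


def load_pattern_h5(path: str | Path, name: str = "rates") -> RatePattern:
    with h5py.File(path, "r") as f:
        ds = f[name]
        return RatePattern(rates=ds[...], population_id=str(ds.attrs.get("population_id", "")))


def save_patterns_csv(path: str | Path, patterns: list[RatePattern]) -> None:
    """One row per pattern, one column per unit."""
    df = pd.DataFrame([p.rates for p in patterns])
    df.columns = [f"unit_{i}" for i in range(df.shape[1])]
    df.to_csv(path, index=False)


def load_patterns_csv(path: str | Path, population_id: str = "") -> list[RatePattern]:
    df = pd.read_csv(path)
    return [RatePattern(rates=row.to_numpy(float), population_id=population_id) for _, row in df.iterrows()]


def save_weights_h5(path: str | Path, weights: SynapticWeights) -> None:
    conn = weights.connectivity
    with h5py.File(path, "w") as f:
        f.create_dataset("contacts", data=conn.contacts)
        f.create_dataset("w", data=weights.w)
        f.attrs["N"] = conn.N
        f.attrs["C"] = conn.C
        f.attrs["seed"] = conn.seed
        f.attrs["allow_multiple"] = conn.allow_multiple


def load_weights_h5(path: str | Path) -> SynapticWeights:
    with h5py.File(path, "r") as f:
        conn = DilutedConnectivity(
            N=int(f.attrs["N"]),
            contacts=f["contacts"][...],
            allow_multiple=bool(f.attrs["allow_multiple"]),
            seed=int(f.attrs["seed"]),
        )
        w = f["w"][...]
    weights = SynapticWeights(conn)
    weights.w = w
    return weights
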
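"""Synchronized hierarchy traces: one named column per signal, common time grid.

A :class:`HierarchyTrace` holds the eight hierarchy levels of one simulation
run -- from the central timing signal down to the joint angles (plus the rod
position for oscillation runs) -- sampled on a single uniform grid.  Traces
round-trip through CSV and HDF5 with metadata preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .config import MUSCLE_NAMES

#: hierarchy levels ordered top (most central) to bottom (closest to the body)
LEVELS = ("u_central", "u_topdown", "u", "a", "F_CE", "F_MTU", "T")

#: observable world level below every control cut
WORLD_LEVEL = "q"


def level_channels(level: str, with_rod: bool = False) -> list[str]:
    """Column names belonging to one hierarchy level."""
    if level == "u_central":
        return ["u_central"]
    if level == "u_topdown":
        return [f"u_open_{m}" for m in MUSCLE_NAMES] + [f"lambda_{m}" for m in MUSCLE_NAMES]
    if level in ("u", "a", "F_CE", "F_MTU"):
        return [f"{level}_{m}" for m in MUSCLE_NAMES]
    if level == "T":
        return ["T_elbow", "T_shoulder"]
    if level == WORLD_LEVEL:
        cols = ["q_elbow", "q_shoulder"]
        if with_rod:
            cols.append("rod_x")
        return cols
    raise KeyError(f"unknown hierarchy level {level!r}")


@dataclass
class HierarchyTrace:
    """All hierarchy signals of one run on a common uniform time grid."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "time" not in self.data.columns:
            raise ValueError("trace needs a 'time' column in seconds")
        if self.data.isna().any().any():
            raise ValueError("trace contains NaNs")

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def with_rod(self) -> bool:
        return "rod_x" in self.data.columns

    def channels(self, level: str) -> list[str]:
        return level_channels(level, with_rod=self.with_rod)

    def values(self, columns: list[str]) -> np.ndarray:
        return self.data[columns].to_numpy()

    def window(self, t0: float, t1: float) -> "HierarchyTrace":
        """Sub-trace with t0 <= time < t1 (metadata carried over)."""
        mask = (self.time >= t0) & (self.time < t1)
        sub = self.data.loc[mask].reset_index(drop=True)
        meta = dict(self.meta, window=(float(t0), float(t1)))
        return HierarchyTrace(sub, meta)

    # ---------------------------------------------------------------- storage
    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(self.meta, default=str) + "\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "HierarchyTrace":
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first[1:].strip()) if first.startswith("#") else {}
            if not first.startswith("#"):
                fh.seek(0)
            df = pd.read_csv(fh)
        return cls(df, meta)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            for col in self.data.columns:
                f.create_dataset(col, data=self.data[col].to_numpy())
            f.attrs["meta"] = json.dumps(self.meta, default=str)
            f.attrs["columns"] = json.dumps(list(self.data.columns))

    @classmethod
    def from_hdf5(cls, path) -> "HierarchyTrace":
        with h5py.File(path, "r") as f:
            cols = json.loads(f.attrs["columns"])
            df = pd.DataFrame({c: f[c][:] for c in cols})
            meta = json.loads(f.attrs["meta"])
        return cls(df, meta)
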
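"""Trajectory-table and configuration I/O.

The on-disk trajectory format is a UTF-8 comma-separated table with a header
``cell_id, experiment, replicate, time_h, log_intensity`` (times in hours as
decimals).  Raw-intensity input (``intensity`` column, values > 0) is a
convenience dialect and is log-transformed on load — the analysis operates on
log-transformed data throughout.  Run configuration is JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CellData, Dataset
from .models import get_model

__all__ = ["read_trajectories", "write_trajectories", "load_config", "RunConfig", "config_hash"]

_COLUMNS = ["cell_id", "experiment", "replicate", "time_h"]


def read_trajectories(path) -> Dataset:
    """Read a trajectory table into a :class:`Dataset`.

    Requires the header columns ``cell_id, experiment, replicate, time_h``
    plus either ``log_intensity`` or ``intensity`` (the latter must be
    positive and is log-transformed).  Duplicate (cell, time) rows and
    non-numeric fields are rejected with the offending row numbers.
    """
    df = pd.read_csv(
        path,
        dtype={"cell_id": str, "experiment": str, "replicate": str},
        float_precision="round_trip",
    )
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if "log_intensity" in df.columns:
        value_col = "log_intensity"
    elif "intensity" in df.columns:
        value_col = "intensity"
    else:
        raise ValueError(f"{path}: need a log_intensity or intensity column")

    for col in ("time_h", value_col):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] + 2  # header + 1-based
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col} at file row(s) {list(bad[:10])}")
        if coerced.isna().any():
            rows = list(df.index[coerced.isna()] + 2)
            raise ValueError(f"{path}: missing {col} at file row(s) {rows[:10]}")
        df[col] = coerced

    dup = df.duplicated(subset=["cell_id", "time_h"], keep=False)
    if dup.any():
        rows = list(df.index[dup][:10] + 2)
        raise ValueError(f"{path}: duplicate (cell_id, time_h) rows at file row(s) {rows}")

    if value_col == "intensity":
        if (df[value_col] <= 0).any():
            rows = list(df.index[df[value_col] <= 0][:10] + 2)
            raise ValueError(f"{path}: non-positive intensity at file row(s) {rows}")
        df["log_intensity"] = np.log(df[value_col])

    cells = []
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("time_h")
        exps = g["experiment"].unique()
        reps = g["replicate"].unique()
        if len(exps) != 1 or len(reps) != 1:
            raise ValueError(f"{path}: cell {cid!r} has inconsistent experiment/replicate labels")
        cells.append(
            CellData(
                cell_id=str(cid),
                experiment=str(exps[0]),
                replicate=str(reps[0]),
                times=g["time_h"].to_numpy(),
                y_obs=g["log_intensity"].to_numpy(),
            )
        )
    return Dataset(cells=cells)


def write_trajectories(dataset: Dataset, path) -> None:
    """Write a :class:`Dataset` as a deterministic, loss-free CSV table.

    Rows are ordered by cell id then time; floats carry 17 significant
    digits so a read/write round trip is byte-stable and loss-free.
    """
    rows = []
    for cell in sorted(dataset.cells, key=lambda c: c.cell_id):
        for t, y in zip(cell.times, cell.y_obs):
            rows.append((cell.cell_id, cell.experiment, cell.replicate, t, y))
    df = pd.DataFrame(rows, columns=_COLUMNS + ["log_intensity"])
    df.to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """Validated run configuration for the command-line pipeline."""

    model: str = "i"
    data: str | None = None
    specific: list[str] = field(default_factory=lambda: ["gamma"])
    random_effects: list[str] | None = None
    n_starts: int = 5
    seed: int = 0
    maxiter: int = 200
    n_cells: int = 50
    sigma: float = 0.05
    analyses: list[str] = field(default_factory=lambda: ["sts", "nlme"])

    def __post_init__(self):
        model = get_model(self.model)
        for p in self.specific:
            if p not in model.parameter_names:
                raise ValueError(f"config: parameter {p!r} not in model {self.model}")
        if self.random_effects is not None:
            for p in self.random_effects:
                if p not in model.parameter_names:
                    raise ValueError(f"config: parameter {p!r} not in model {self.model}")


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration; unknown keys are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a JSON object")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {unknown}; known keys: {sorted(known)}")
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    """Stable hash of a configuration, recorded in every artifact."""
    canon = json.dumps(
        {k: getattr(config, k) for k in sorted(RunConfig.__dataclass_fields__)},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
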
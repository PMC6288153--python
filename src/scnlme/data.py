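"""Core data containers for single-cell trajectory analysis.

A :class:`CellData` holds one cell's observed log-fluorescence time course
together with its experiment (mRNA construct) and replicate (batch) labels.
A :class:`Dataset` is a validated collection of cells.  A
:class:`CellParameters` holds the strictly positive kinetic/observation
parameters of one cell in a model's identifiable parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CellData", "CellParameters", "Dataset", "Trajectory"]


@dataclass
class CellData:
    """Observed log-fluorescence time series of a single cell.

    Parameters
    ----------
    cell_id : str
        Unique identifier of the cell.
    experiment : str
        Construct label, e.g. ``"eGFP"`` or ``"d2eGFP"``.  A cell belongs to
        exactly one experiment.
    replicate : str
        Batch label of the experimental replicate the cell was recorded in.
    times : ndarray
        Strictly increasing observation times in hours.
    y_obs : ndarray
        Log-fluorescence values, one per time point.
    """

    cell_id: str
    experiment: str
    replicate: str
    times: np.ndarray
    y_obs: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y_obs = np.asarray(self.y_obs, dtype=float)
        if self.times.ndim != 1 or self.y_obs.shape != self.times.shape:
            raise ValueError(
                f"cell {self.cell_id}: times and y_obs must be 1-d arrays of "
                f"equal length, got {self.times.shape} and {self.y_obs.shape}"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"cell {self.cell_id}: times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.y_obs))):
            raise ValueError(f"cell {self.cell_id}: missing or non-finite values")

    @property
    def n_t(self) -> int:
        return self.times.size


@dataclass
class CellParameters:
    """Strictly positive parameters of one cell in an identifiable parameterization.

    ``values`` maps parameter names of a model (see
    :mod:`scnlme.models`) to positive reals: rates in 1/h, ``t0`` in h,
    amplitude-like combinations (``kappa``, ``k2m0scale``, ``offset``) in
    arbitrary fluorescence units, ``r0m0``/``e0m0`` dimensionless.
    """

    values: dict[str, float]

    def __post_init__(self) -> None:
        self.values = {k: float(v) for k, v in self.values.items()}
        for name, v in self.values.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {v}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def vector(self, parameter_names) -> np.ndarray:
        """Parameter values as an array in the order given by ``parameter_names``."""
        missing = [p for p in parameter_names if p not in self.values]
        if missing:
            raise ValueError(f"missing parameter(s): {missing}")
        return np.array([self.values[p] for p in parameter_names], dtype=float)


@dataclass
class Trajectory:
    """Simulated model states and the log-fluorescence observable on a time grid."""

    times: np.ndarray
    states: dict[str, np.ndarray]
    observable: np.ndarray


@dataclass
class Dataset:
    """A collection of cells with unique ids and experiment/replicate labels."""

    cells: list[CellData] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate cell ids: {dupes}")

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    @property
    def experiments(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cells:
            seen.setdefault(c.experiment, None)
        return list(seen)

    @property
    def replicates(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cells:
            seen.setdefault(c.replicate, None)
        return list(seen)

    def by_experiment(self) -> dict[str, list[CellData]]:
        groups: dict[str, list[CellData]] = {}
        for c in self.cells:
            groups.setdefault(c.experiment, []).append(c)
        return groups

    def by_replicate(self) -> dict[str, list[CellData]]:
        groups: dict[str, list[CellData]] = {}
        for c in self.cells:
            groups.setdefault(c.replicate, []).append(c)
        return groups


def as_cell_list(X) -> list[CellData]:
    """Normalize estimator input to a plain list of :class:`CellData`."""
    if isinstance(X, Dataset):
        return list(X.cells)
    cells = list(X)
    for c in cells:
        if not isinstance(c, CellData):
            raise TypeError(f"expected CellData instances, got {type(c).__name__}")
    return cells
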
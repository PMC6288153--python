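"""Synthetic single-cell trajectory datasets with known ground truth.

The generator reproduces the statistical structure the analysis assumes:
lognormal cell-to-cell parameter variability (``phi_i = exp(beta + b_i)``,
``b_i ~ N(0, diag(exp(d_log)))``), a common time grid (every 10 min over
30 h by default, 181 points), additive Gaussian noise on the log-fluorescence
observable (the log of multiplicative intensity noise), a constant background
offset inside the observable, and replicate-level batch effects entering as a
common multiplicative shift of the transfected mRNA amount m0 — applied,
exponent-aware, to every m0-containing fixed effect.

The default numeric values in :func:`paper_like_design` are invented desk-
scale test constants chosen to qualitatively mimic a stable eGFP plateau
versus a declining d2eGFP signal; they are not fitted estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import CellData, CellParameters, Dataset
from .models import M0_EXPONENTS, get_model, simulate_observable
from .nlme import EffectSharingMap, PopulationParameters, expand_effects

__all__ = [
    "PopulationDesign",
    "ExperimentDesign",
    "sample_single_cell_parameters",
    "simulate_dataset",
    "paper_like_design",
    "default_grid",
]


def default_grid(start: float = 0.0, end: float = 30.0, step_minutes: float = 10.0) -> np.ndarray:
    """Observation grid in hours; the default is 0..30 h every 10 min (181 points)."""
    n = int(round((end - start) * 60.0 / step_minutes)) + 1
    return start + np.arange(n) * step_minutes / 60.0


@dataclass
class PopulationDesign:
    """Generating population: model, sharing map, true effects, noise, grid."""

    map: EffectSharingMap
    population: PopulationParameters
    grid: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.population.beta.size != self.map.n_beta or self.population.d_log.size != self.map.n_d:
            raise ValueError("population vector sizes inconsistent with the sharing map")
        if self.population.log_sigma.size != len(self.map.experiments):
            raise ValueError("need one noise effect per experiment")

    @property
    def model_id(self) -> str:
        return self.map.model_id


@dataclass
class ExperimentDesign:
    """Cell counts per experiment and multiplicative m0 batch factor per replicate."""

    experiments: dict[str, int]
    replicates: dict[str, float] = field(default_factory=lambda: {"r1": 1.0})

    def __post_init__(self):
        for e, n in self.experiments.items():
            if n < 0:
                raise ValueError(f"negative cell count for experiment {e!r}")
        for r, f in self.replicates.items():
            if f <= 0:
                raise ValueError(f"batch factor for replicate {r!r} must be positive")


def _batch_shifted(design: PopulationDesign, factor: float) -> PopulationParameters:
    """Apply a multiplicative m0 batch factor to the m0-containing fixed effects."""
    beta = design.population.beta.copy()
    exponents = M0_EXPONENTS[design.model_id]
    for p, s_p in exponents.items():
        for e in design.map.experiments:
            beta[design.map.beta_index(p, e)] = (
                design.population.beta[design.map.beta_index(p, e)] + s_p * math.log(factor)
            )
    return PopulationParameters(beta=beta, d_log=design.population.d_log, log_sigma=design.population.log_sigma)


def sample_single_cell_parameters(design: PopulationDesign, experiment: str, n_cells: int, seed: int) -> list[CellParameters]:
    """Draw lognormal single-cell parameters for one experiment, deterministically."""
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    d = np.exp(design.population.d_log[design.map.d_indices(experiment)])
    out = []
    for _ in range(n_cells):
        b = rng.normal(scale=np.sqrt(d))
        out.append(expand_effects(design.map, design.population, experiment, b))
    return out


def simulate_dataset(pop: PopulationDesign, exp: ExperimentDesign, seed: int = 0):
    """Simulate a full dataset and return ``(Dataset, truth)``.

    Cells of each experiment are split evenly (round-robin) over the
    replicates; each replicate's batch factor shifts the m0-containing fixed
    effects before cells are drawn.  i.i.d. Gaussian noise with the
    experiment's sigma is added to the log observable.  ``truth`` records the
    per-replicate beta vectors and every cell's random effects for recovery
    tests.
    """
    model = get_model(pop.model_id)
    rng = np.random.default_rng(seed)
    rep_labels = list(exp.replicates)
    cells: list[CellData] = []
    truth = {
        "model": pop.model_id,
        "beta_names": list(pop.map.beta_names),
        "d_names": list(pop.map.d_names),
        "beta": pop.population.beta.tolist(),
        "d_log": pop.population.d_log.tolist(),
        "log_sigma": pop.population.log_sigma.tolist(),
        "beta_by_replicate": {},
        "cells": {},
    }
    shifted = {r: _batch_shifted(pop, f) for r, f in exp.replicates.items()}
    for r in rep_labels:
        truth["beta_by_replicate"][r] = dict(zip(pop.map.beta_names, shifted[r].beta.tolist()))
    for e, n_cells in exp.experiments.items():
        sigma = math.exp(float(pop.population.log_sigma[pop.map.experiments.index(e)]))
        d = np.exp(pop.population.d_log[pop.map.d_indices(e)])
        for i in range(n_cells):
            r = rep_labels[i % len(rep_labels)]
            b = rng.normal(scale=np.sqrt(d))
            phi = expand_effects(pop.map, shifted[r], e, b)
            try:
                y = simulate_observable(model, phi, pop.grid)
            except (RuntimeError, ValueError) as err:
                raise RuntimeError(f"simulation failed for cell parameters {phi.values}: {err}") from err
            noise = rng.normal(scale=sigma, size=pop.grid.size) if sigma > 0 else 0.0
            cid = f"{e}_{r}_{i:04d}"
            cells.append(CellData(cell_id=cid, experiment=e, replicate=r, times=pop.grid.copy(), y_obs=y + noise))
            truth["cells"][cid] = {"b": np.atleast_1d(b).tolist(), "phi": phi.values}
    return Dataset(cells=cells), truth


def paper_like_design(
    n_cells_per_experiment: int = 50,
    sigma: float = 0.05,
    random_effect_sd: float = 0.3,
    n_replicates: int = 3,
) -> tuple[PopulationDesign, ExperimentDesign]:
    """Desk-scale default study design for the standard translation model.

    Two experiments (eGFP, d2eGFP) share all effects except the protein
    degradation rate gamma; three replicates carry multiplicative m0 batch
    factors (1, 1.5, 0.7).  Median true values (invented test constants):
    delta 0.2/h, gamma_eGFP 0.03/h << gamma_d2eGFP 0.3/h, kappa 100 a.u.,
    t0 1 h, offset 10 a.u.; log-scale random-effect s.d. 0.3 on every
    parameter and observation noise s.d. 0.05.
    """
    map_ = EffectSharingMap("i", ("eGFP", "d2eGFP"), specific=("gamma",))
    medians = {
        "delta": 0.2,
        "gamma[eGFP]": 0.03,
        "gamma[d2eGFP]": 0.3,
        "kappa": 100.0,
        "t0": 1.0,
        "offset": 10.0,
    }
    beta = np.array([math.log(medians[name]) for name in map_.beta_names])
    d_log = np.full(map_.n_d, 2.0 * math.log(random_effect_sd))
    log_sigma = np.full(2, math.log(sigma))
    pop = PopulationDesign(
        map=map_,
        population=PopulationParameters(beta=beta, d_log=d_log, log_sigma=log_sigma),
    )
    factors = [1.0, 1.5, 0.7][: max(1, n_replicates)]
    exp = ExperimentDesign(
        experiments={"eGFP": n_cells_per_experiment, "d2eGFP": n_cells_per_experiment},
        replicates={f"r{i + 1}": f for i, f in enumerate(factors)},
    )
    return pop, exp
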
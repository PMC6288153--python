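"""Standard two-stage (STS) estimation.

Stage 1 fits each cell independently by maximum likelihood with additive
Gaussian noise on the log-fluorescence scale; the noise variance is profiled
out analytically (a single cell has no replicates, so the model-based
estimate sigma2 = mean squared residual is used).  Stage 2 reconstructs the
population distribution of each log-parameter with a Gaussian kernel density
estimate per experiment.

The STS approach cannot share parameters across experiments; it serves as the
baseline against which the multi-experiment NLME approach is compared, and on
the standard translation model its per-cell estimates suffer the exact
delta <-> gamma exchange symmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import gaussian_kde, qmc
from sklearn.base import BaseEstimator

from .data import CellData, CellParameters, as_cell_list
from .models import get_model, model_i_observable, simulate_observable

__all__ = [
    "sigma2_hat",
    "concentrated_cell_nll",
    "fit_cell_mle",
    "fit_sts_population",
    "kde_log_density",
    "CellFitResult",
    "PopulationDensity",
    "STS",
]

#: Floor on the profiled noise variance; prevents a -inf objective on
#: degenerate perfect fits.
SIGMA2_FLOOR = 1e-12

#: Default positive box per parameter (optimization runs in log space).
DEFAULT_BOUNDS = (1e-4, 1e4)
T0_BOUNDS = (0.05, 5.0)

#: Bandwidth floor for zero-variance samples in the KDE.
BANDWIDTH_FLOOR = 1e-3


def sigma2_hat(y_obs, y_model) -> float:
    """Model-based noise-variance estimate: mean squared residual (divisor n_t)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_model = np.asarray(y_model, dtype=float)
    if y_obs.size == 0:
        raise ValueError("empty input")
    if y_obs.shape != y_model.shape:
        raise ValueError(f"shape mismatch: {y_obs.shape} vs {y_model.shape}")
    return float(np.mean((y_obs - y_model) ** 2))


def _concentrated_nll(residuals: np.ndarray) -> tuple[float, float, bool]:
    """(nll, sigma2, clamped) for the concentrated Gaussian likelihood."""
    n = residuals.size
    s2 = float(np.mean(residuals**2))
    clamped = s2 < SIGMA2_FLOOR
    s2c = max(s2, SIGMA2_FLOOR)
    return 0.5 * n * (math.log(2.0 * math.pi * s2c) + 1.0), s2c, clamped


def concentrated_cell_nll(model, params, data: CellData) -> float:
    """Negative log-likelihood with the noise variance at its conditional optimum.

    Equals ``(n_t/2) * (log(2*pi*sigma2_hat) + 1)`` where ``sigma2_hat`` is the
    mean squared residual of the simulated observable against the data.
    """
    y_model = simulate_observable(model, params, data.times)
    nll, _, _ = _concentrated_nll(data.y_obs - y_model)
    return nll


@dataclass
class CellFitResult:
    """Stage-1 maximum-likelihood fit of a single cell."""

    cell_id: str
    params: CellParameters
    sigma2_hat: float
    nll: float
    starts: list[float]
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class PopulationDensity:
    """Kernel density estimate of one log-parameter across cells."""

    parameter: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    flags: list[str] = field(default_factory=list)


def _resolve_bounds(model, data: CellData, bounds) -> list[tuple[float, float]]:
    model = get_model(model)
    out = []
    for p in model.parameter_names:
        if bounds is not None and p in bounds:
            lo, hi = bounds[p]
        elif p == "t0":
            lo, hi = T0_BOUNDS
            hi = min(hi, float(data.times[-1]))
        else:
            lo, hi = DEFAULT_BOUNDS
        if lo <= 0 or hi <= lo:
            raise ValueError(f"bounds for {p} must be a positive box, got ({lo}, {hi})")
        out.append((lo, hi))
    return out


def _make_objective(model, data: CellData):
    """Concentrated NLL (and gradient, model i) over log-parameters."""
    model = get_model(model)
    if model.model_id == "i":

        def obj(x):
            theta = np.exp(x)
            y, jac = model_i_observable(theta, data.times, with_jac=True)
            r = data.y_obs - y
            nll, s2, _ = _concentrated_nll(r)
            grad_theta = -(jac.T @ r) / s2
            return nll, grad_theta * theta

        return obj, True

    def obj_numeric(x):
        params = dict(zip(model.parameter_names, np.exp(x)))
        try:
            y = simulate_observable(model, params, data.times)
        except (RuntimeError, ValueError):
            return 1e12
        nll, _, _ = _concentrated_nll(data.y_obs - y)
        return nll if np.isfinite(nll) else 1e12

    return obj_numeric, False


def fit_cell_mle(
    model,
    data: CellData,
    n_starts: int = 20,
    seed: int = 0,
    bounds: dict | None = None,
) -> CellFitResult:
    """Multi-start local MLE of one cell's parameters in log space.

    Starts are Latin-hypercube samples in the log-parameter box; each start is
    refined with L-BFGS-B.  Ties are broken by the lowest final objective,
    then the lowest start index, so results are deterministic given the seed.
    """
    model = get_model(model)
    box = _resolve_bounds(model, data, bounds)
    if data.n_t < model.n_parameters + 1:
        raise ValueError(
            f"cell {data.cell_id}: needs at least {model.n_parameters + 1} time points"
        )
    log_lo = np.log([b[0] for b in box])
    log_hi = np.log([b[1] for b in box])
    sampler = qmc.LatinHypercube(d=model.n_parameters, seed=np.random.default_rng(seed))
    x0s = log_lo + sampler.random(n_starts) * (log_hi - log_lo)

    obj, has_jac = _make_objective(model, data)
    results = []
    for i, x0 in enumerate(x0s):
        try:
            res = optimize.minimize(
                obj,
                x0,
                jac=has_jac if has_jac else None,
                method="L-BFGS-B",
                bounds=list(zip(log_lo, log_hi)),
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
            )
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            continue
        if np.isfinite(res.fun):
            results.append((float(res.fun), i, res))
    if not results:
        raise RuntimeError(
            f"cell {data.cell_id}: all {n_starts} starts failed; "
            f"box={dict(zip(model.parameter_names, box))}"
        )
    results.sort(key=lambda t: (t[0], t[1]))
    best = results[0][2]
    theta = np.exp(best.x)
    params = CellParameters(dict(zip(model.parameter_names, theta)))
    y = simulate_observable(model, params, data.times)
    s2 = sigma2_hat(data.y_obs, y)
    nll, s2c, clamped = _concentrated_nll(data.y_obs - y)

    flags = []
    at_bound = (best.x - log_lo < 1e-6) | (log_hi - best.x < 1e-6)
    if np.any(at_bound):
        names = [model.parameter_names[j] for j in np.flatnonzero(at_bound)]
        flags.append(f"boundary:{','.join(names)}")
    if clamped:
        flags.append("sigma2_floor")
    converged = bool(best.success) and not flags
    return CellFitResult(
        cell_id=data.cell_id,
        params=params,
        sigma2_hat=s2,
        nll=nll,
        starts=sorted(r[0] for r in results),
        converged=converged,
        flags=flags,
    )


def kde_log_density(samples, grid=None, parameter: str = "") -> PopulationDensity:
    """Gaussian KDE with Silverman bandwidth on log-parameter estimates.

    The default grid spans the samples +/- 3 bandwidths; the trapezoid
    integral of the density over that grid is ~1.  Zero-variance samples get
    a floor bandwidth and a flag.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2 or not np.all(np.isfinite(samples)):
        raise ValueError("need >= 2 finite samples")
    flags = []
    std = samples.std(ddof=1)
    kde = None
    if std > BANDWIDTH_FLOOR:
        try:
            kde = gaussian_kde(samples, bw_method="silverman")
        except np.linalg.LinAlgError:
            kde = None
    if kde is not None:
        bw = float(np.sqrt(kde.covariance[0, 0]))
        evaluate = kde
    else:
        bw = BANDWIDTH_FLOOR
        flags.append("bandwidth_floor")

        def evaluate(g):
            z = (g[None, :] - samples[:, None]) / bw
            return np.exp(-0.5 * z**2).sum(axis=0) / (samples.size * bw * np.sqrt(2 * np.pi))

    if grid is None:
        grid = np.linspace(samples.min() - 3 * bw, samples.max() + 3 * bw, 512)
    else:
        grid = np.asarray(grid, dtype=float)
    density = np.asarray(evaluate(grid), dtype=float)
    return PopulationDensity(parameter=parameter, grid=grid, density=density, bandwidth=bw, flags=flags)


class STS(BaseEstimator):
    """Standard two-stage estimator.

    Parameters
    ----------
    model : str
        Model id ('i', 'ii', 'iii' or 'iv').
    n_starts : int
        Local-optimization starts per cell.
    seed : int
        Base seed; each cell gets an independent child seed.
    bounds : dict or None
        Optional per-parameter positive boxes overriding the defaults.

    Attributes
    ----------
    cell_results_ : list of CellFitResult
        Stage-1 fits of the cells that could be fitted.
    excluded_ : list of (cell_id, reason)
        Cells whose fit failed.
    densities_ : dict[(experiment, parameter)] -> PopulationDensity
        Stage-2 kernel density estimates on the log scale, per experiment
        (experiments are never pooled).
    """

    def __init__(self, model: str = "i", n_starts: int = 20, seed: int = 0, bounds=None):
        self.model = model
        self.n_starts = n_starts
        self.seed = seed
        self.bounds = bounds

    def fit(self, X, y=None):
        cells = as_cell_list(X)
        if len(cells) < 2:
            raise ValueError("STS needs at least 2 cells")
        model = get_model(self.model)
        self.cell_results_ = []
        self.excluded_ = []
        fitted_cells = []
        # one shared start design for every cell: identical data then yields
        # identical estimates (and the same branch of the swap symmetry)
        for cell in cells:
            try:
                res = fit_cell_mle(
                    model, cell, n_starts=self.n_starts, seed=self.seed, bounds=self.bounds
                )
            except (RuntimeError, ValueError) as err:
                self.excluded_.append((cell.cell_id, str(err)))
                continue
            self.cell_results_.append(res)
            fitted_cells.append(cell)
        self._fitted_cells = fitted_cells

        self.densities_ = {}
        by_exp: dict[str, list[CellFitResult]] = {}
        for cell, res in zip(fitted_cells, self.cell_results_):
            by_exp.setdefault(cell.experiment, []).append(res)
        for exp, results in by_exp.items():
            if len(results) < 2:
                continue
            for p in model.parameter_names:
                logs = np.log([r.params[p] for r in results])
                self.densities_[(exp, p)] = kde_log_density(logs, parameter=p)
        return self

    def predict(self, X=None):
        """Fitted observable arrays, one per fitted cell (or for new cells X)."""
        if not hasattr(self, "cell_results_"):
            raise RuntimeError("estimator is not fitted")
        if X is not None:
            raise ValueError("STS has no out-of-sample prediction; call predict() after fit")
        model = get_model(self.model)
        return [
            simulate_observable(model, r.params, c.times)
            for c, r in zip(self._fitted_cells, self.cell_results_)
        ]


def fit_sts_population(model, cells, n_starts: int = 20, seed: int = 0, bounds=None) -> STS:
    """Fit the STS estimator to a cell collection and return the fitted object."""
    return STS(model=getattr(model, "model_id", model), n_starts=n_starts, seed=seed, bounds=bounds).fit(cells)
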
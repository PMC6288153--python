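"""Multi-experiment nonlinear mixed-effect (NLME) estimation.

Each cell's parameter vector is ``phi_i = exp(beta^e + b_i)`` with a fixed
effect ``beta^e`` for the cell's experiment and a Gaussian random effect
``b_i ~ N(0, D^e)`` — a lognormal cell-to-cell variability model that keeps
all kinetic parameters positive.  The random-effect covariance ``D`` is
diagonal and parameterized through the matrix logarithm (``D = diag(exp(
d_log))``), which keeps it positive definite without constraints.  The
marginal likelihood integral over ``b_i`` is evaluated with the Laplace
approximation: minimize the negative joint log-density psi over ``b``, then

    nll_i = psi(b_hat) - (n_b/2) log(2 pi) + (1/2) log det H psi(b_hat).

An effect-sharing map ties selected population effects (fixed effects and
random-effect variances) together across experiments — the mechanism that
lets a second mRNA construct break the delta <-> gamma exchange symmetry of
the standard translation model.  The outer problem (over beta, d_log and one
log-noise effect per experiment) is solved by seeded multi-start local
optimization, the inner problems (one per cell) by damped Newton /
quasi-Newton with warm starts across outer iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .data import CellData, CellParameters, as_cell_list
from .models import get_model, model_i_observable, simulate_observable

__all__ = [
    "EffectSharingMap",
    "PopulationParameters",
    "LaplaceCellResult",
    "NLMEFitResult",
    "expand_effects",
    "joint_neg_log_density",
    "inner_mode",
    "laplace_cell_nll",
    "laplace_marginal",
    "multi_experiment_nll",
    "fit_nlme",
    "empirical_bayes_parameters",
    "NLME",
]

#: Finite penalty returned when the simulation fails at phi(b); keeps the
#: inner optimizer alive instead of propagating an exception.
SIM_FAILURE_PENALTY = 1e10

#: Diagonal jitter ladder applied to non-positive-definite inner Hessians.
JITTER_LADDER = (1e-8, 1e-6, 1e-4, 1e-2, 1.0)

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Effect sharing and population parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectSharingMap:
    """Assignment of model parameters to global population-effect indices.

    Shared parameters point to one global fixed-effect (and variance) index
    in every experiment; experiment-specific parameters (the study default:
    the protein degradation rate gamma) get one index per experiment.
    ``random_effects`` lists the parameters that carry a random effect (all
    of them by default).
    """

    model_id: str
    experiments: tuple[str, ...]
    specific: tuple[str, ...] = ("gamma",)
    random_effects: tuple[str, ...] | None = None

    def __post_init__(self):
        model = get_model(self.model_id)
        object.__setattr__(self, "experiments", tuple(self.experiments))
        object.__setattr__(self, "specific", tuple(self.specific))
        if len(set(self.experiments)) != len(self.experiments) or not self.experiments:
            raise ValueError("experiments must be non-empty and unique")
        for p in self.specific:
            if p not in model.parameter_names:
                raise ValueError(f"unknown experiment-specific parameter {p!r}")
        re = self.random_effects
        re = model.parameter_names if re is None else tuple(re)
        for p in re:
            if p not in model.parameter_names:
                raise ValueError(f"unknown random-effect parameter {p!r}")
        object.__setattr__(self, "random_effects", re)

        beta_names: list[str] = []
        beta_index: dict[tuple[str, str], int] = {}
        d_names: list[str] = []
        d_index: dict[tuple[str, str], int] = {}
        for p in model.parameter_names:
            if p in self.specific:
                for e in self.experiments:
                    beta_index[(p, e)] = len(beta_names)
                    beta_names.append(f"{p}[{e}]")
            else:
                idx = len(beta_names)
                beta_names.append(p)
                for e in self.experiments:
                    beta_index[(p, e)] = idx
        for p in re:
            if p in self.specific:
                for e in self.experiments:
                    d_index[(p, e)] = len(d_names)
                    d_names.append(f"{p}[{e}]")
            else:
                idx = len(d_names)
                d_names.append(p)
                for e in self.experiments:
                    d_index[(p, e)] = idx
        object.__setattr__(self, "beta_names", tuple(beta_names))
        object.__setattr__(self, "_beta_index", beta_index)
        object.__setattr__(self, "d_names", tuple(d_names))
        object.__setattr__(self, "_d_index", d_index)

    @property
    def n_beta(self) -> int:
        return len(self.beta_names)

    @property
    def n_d(self) -> int:
        return len(self.d_names)

    @property
    def n_random(self) -> int:
        return len(self.random_effects)

    def beta_index(self, parameter: str, experiment: str) -> int:
        self._check_experiment(experiment)
        return self._beta_index[(parameter, experiment)]

    def d_index(self, parameter: str, experiment: str) -> int:
        self._check_experiment(experiment)
        return self._d_index[(parameter, experiment)]

    def _check_experiment(self, experiment: str) -> None:
        if experiment not in self.experiments:
            raise ValueError(f"unknown experiment {experiment!r}; known: {self.experiments}")

    def beta_indices(self, experiment: str) -> np.ndarray:
        """Global beta index for every model parameter, in model order."""
        model = get_model(self.model_id)
        return np.array([self.beta_index(p, experiment) for p in model.parameter_names])

    def d_indices(self, experiment: str) -> np.ndarray:
        """Global d_log index for every random-effect parameter, in order."""
        return np.array([self.d_index(p, experiment) for p in self.random_effects])

    def random_positions(self) -> np.ndarray:
        """Positions of the random-effect parameters within the model's vector."""
        model = get_model(self.model_id)
        return np.array([model.parameter_names.index(p) for p in self.random_effects])


@dataclass
class PopulationParameters:
    """Global fixed effects, log random-effect variances and noise effects.

    ``beta`` and ``d_log`` are indexed by an :class:`EffectSharingMap`;
    ``log_sigma`` holds one log measurement-noise s.d. per experiment, in the
    map's experiment order.
    """

    beta: np.ndarray
    d_log: np.ndarray
    log_sigma: np.ndarray

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.d_log = np.atleast_1d(np.asarray(self.d_log, dtype=float))
        self.log_sigma = np.atleast_1d(np.asarray(self.log_sigma, dtype=float))
        for name, v in (("beta", self.beta), ("d_log", self.d_log), ("log_sigma", self.log_sigma)):
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be finite, got {v}")

    def pack(self) -> np.ndarray:
        return np.concatenate([self.beta, self.d_log, self.log_sigma])

    @classmethod
    def unpack(cls, x: np.ndarray, map_: EffectSharingMap) -> "PopulationParameters":
        nb, nd = map_.n_beta, map_.n_d
        ne = len(map_.experiments)
        if x.size != nb + nd + ne:
            raise ValueError(f"expected vector of length {nb + nd + ne}, got {x.size}")
        return cls(beta=x[:nb], d_log=x[nb : nb + nd], log_sigma=x[nb + nd :])


@dataclass
class LaplaceCellResult:
    """Per-cell random-effect mode, curvature and Laplace NLL contribution."""

    cell_id: str
    b_hat: np.ndarray
    hessian: np.ndarray
    nll: float
    inner_converged: bool
    jitter_added: float = 0.0


@dataclass
class NLMEFitResult:
    population: PopulationParameters
    map: EffectSharingMap
    cell_results: list[LaplaceCellResult]
    nll: float
    starts: list[dict]
    converged: bool


# ---------------------------------------------------------------------------
# Per-cell joint density and Laplace machinery
# ---------------------------------------------------------------------------


def expand_effects(map_: EffectSharingMap, population: PopulationParameters, experiment: str, b) -> CellParameters:
    """Single-cell parameters ``phi = exp(beta^e + b)`` for one experiment.

    ``b`` is ordered like ``map_.random_effects``; parameters without a
    random effect take ``phi = exp(beta)`` exactly.
    """
    model = get_model(map_.model_id)
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if b.size != map_.n_random:
        raise ValueError(f"expected {map_.n_random} random effects, got {b.size}")
    log_phi = population.beta[map_.beta_indices(experiment)].copy()
    log_phi[map_.random_positions()] += b
    return CellParameters(dict(zip(model.parameter_names, np.exp(log_phi))))


def _prior_terms(map_: EffectSharingMap, population: PopulationParameters, experiment: str):
    # clip so outer line searches probing extreme iterates cannot overflow;
    # the objective plateaus there and backtracking recovers
    d = np.exp(np.clip(population.d_log[map_.d_indices(experiment)], -60.0, 60.0))
    e_idx = map_.experiments.index(experiment)
    sigma2 = math.exp(2.0 * float(np.clip(population.log_sigma[e_idx], -30.0, 30.0)))
    return d, sigma2


def joint_neg_log_density(model, data: CellData, map_: EffectSharingMap, population: PopulationParameters, b) -> float:
    """Negative log of (trajectory likelihood x random-effect prior) at ``b``.

    A simulation failure at ``phi(b)`` yields a large-but-finite penalty so
    the inner optimizer can recover.
    """
    model = get_model(model)
    b = np.atleast_1d(np.asarray(b, dtype=float))
    d, sigma2 = _prior_terms(map_, population, data.experiment)
    try:
        phi = expand_effects(map_, population, data.experiment, b)
        y = simulate_observable(model, phi, data.times)
    except (RuntimeError, ValueError, OverflowError):
        return SIM_FAILURE_PENALTY + float(np.sum(b**2))
    r = data.y_obs - y
    nll_data = 0.5 * float(np.sum(r**2)) / sigma2 + 0.5 * data.n_t * math.log(2.0 * math.pi * sigma2)
    nll_prior = 0.5 * float(np.sum(b**2 / d)) + 0.5 * float(np.sum(np.log(2.0 * math.pi * d)))
    value = nll_data + nll_prior
    return value if np.isfinite(value) else SIM_FAILURE_PENALTY + float(np.sum(b**2))


def _joint_grad_model_i(data: CellData, map_: EffectSharingMap, population: PopulationParameters):
    """Analytic gradient of the joint negative log-density for model (i)."""
    d, sigma2 = _prior_terms(map_, population, data.experiment)
    beta_full = population.beta[map_.beta_indices(data.experiment)]
    pos = map_.random_positions()

    def grad(b):
        log_phi = beta_full.copy()
        log_phi[pos] += b
        theta = np.exp(np.clip(log_phi, -60.0, 60.0))  # guard overflow at wild b
        y, jac = model_i_observable(theta, data.times, with_jac=True)
        r = data.y_obs - y
        g_theta = -(jac.T @ r) / sigma2
        return np.nan_to_num(g_theta[pos] * theta[pos], nan=0.0, posinf=1e10, neginf=-1e10) + b / d

    return grad


def _fd_hessian(f, x: np.ndarray, grad=None) -> np.ndarray:
    """Central finite-difference Hessian, from the gradient when available."""
    n = x.size
    steps = 1e-4 * (1.0 + np.abs(x))
    H = np.empty((n, n))
    if grad is not None:
        for k in range(n):
            e = np.zeros(n)
            e[k] = steps[k]
            H[:, k] = (grad(x + e) - grad(x - e)) / (2.0 * steps[k])
    else:
        f0 = f(x)
        for k in range(n):
            for j in range(k, n):
                ek = np.zeros(n)
                ej = np.zeros(n)
                ek[k] = steps[k]
                ej[j] = steps[j]
                if j == k:
                    H[k, k] = (f(x + ek) - 2.0 * f0 + f(x - ek)) / steps[k] ** 2
                else:
                    H[k, j] = H[j, k] = (
                        f(x + ek + ej) - f(x + ek - ej) - f(x - ek + ej) + f(x - ek - ej)
                    ) / (4.0 * steps[k] * steps[j])
    return 0.5 * (H + H.T)


def _make_pd(H: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest ladder jitter making H positive definite (Cholesky test).

    The ladder is scaled by the magnitude of H; if even the largest jitter
    fails, the eigenvalues are clipped from below (recorded as the jitter).
    """
    scale = max(1.0, float(np.max(np.abs(H))))
    eye = np.eye(H.shape[0])
    for jitter in (0.0,) + tuple(j * scale for j in JITTER_LADDER):
        try:
            np.linalg.cholesky(H + jitter * eye)
            return H + jitter * eye, jitter
        except np.linalg.LinAlgError:
            continue
    w, V = np.linalg.eigh(H)
    floor = 1e-8 * scale
    w_clip = np.clip(w, floor, None)
    return (V * w_clip) @ V.T, float(np.max(w_clip - w))


def laplace_marginal(f, b0, grad=None, cell_id: str = "") -> LaplaceCellResult:
    """Laplace-approximate marginal NLL of a generic negative log-joint ``f(b)``.

    Minimizes ``f`` from ``b0`` (with up to 3 perturbed retries), computes the
    central-finite-difference Hessian at the mode, regularizes it to positive
    definite if needed, and returns

        nll = f(b_hat) - (n_b/2) log(2 pi) + (1/2) log det H.

    Exact when ``f`` is quadratic in ``b`` (Gaussian case).
    """
    b0 = np.atleast_1d(np.asarray(b0, dtype=float))
    n_b = b0.size
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(4):
        start = b0 if attempt == 0 else b0 + rng.normal(scale=0.5, size=n_b)
        res = optimize.minimize(f, start, jac=grad, method="BFGS", options={"gtol": 1e-9, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
        if res.fun < SIM_FAILURE_PENALTY and (res.success or np.linalg.norm(res.jac) < 1e-5):
            best = res if res.fun <= best.fun else best
            break
    converged = best.fun < SIM_FAILURE_PENALTY and (
        bool(best.success) or float(np.linalg.norm(best.jac)) < 1e-5
    )
    b_hat = np.asarray(best.x, dtype=float)
    H = _fd_hessian(f, b_hat, grad=grad)
    H_pd, jitter = _make_pd(H)
    sign, logdet = np.linalg.slogdet(H_pd)
    nll = float(best.fun) - 0.5 * n_b * _LOG2PI + 0.5 * logdet
    return LaplaceCellResult(
        cell_id=cell_id,
        b_hat=b_hat,
        hessian=H_pd,
        nll=float(nll),
        inner_converged=converged and sign > 0,
        jitter_added=jitter,
    )


def _cell_f_and_grad(model, data, map_, population):
    model = get_model(model)
    f = lambda b: joint_neg_log_density(model, data, map_, population, b)
    grad = _joint_grad_model_i(data, map_, population) if model.model_id == "i" else None
    return f, grad


def inner_mode(model, data: CellData, map_: EffectSharingMap, population: PopulationParameters, b_init=None) -> LaplaceCellResult:
    """Random-effect mode and Hessian for one cell (inner problem)."""
    b0 = np.zeros(map_.n_random) if b_init is None else np.asarray(b_init, dtype=float)
    f, grad = _cell_f_and_grad(model, data, map_, population)
    return laplace_marginal(f, b0, grad=grad, cell_id=data.cell_id)


def laplace_cell_nll(model, data: CellData, map_: EffectSharingMap, population: PopulationParameters, warm_start=None) -> LaplaceCellResult:
    """Laplace marginal NLL contribution of one cell."""
    return inner_mode(model, data, map_, population, b_init=warm_start)


def multi_experiment_nll(model, cells, map_: EffectSharingMap, population: PopulationParameters, warm_starts=None) -> float:
    """Total Laplace NLL, summed per experiment over that experiment's cells."""
    cells = as_cell_list(cells)
    if not cells:
        raise ValueError("empty cell set")
    for c in cells:
        if c.experiment not in map_.experiments:
            raise ValueError(f"cell {c.cell_id}: experiment {c.experiment!r} not in sharing map")
    total = 0.0
    for i, c in enumerate(cells):
        ws = None if warm_starts is None else warm_starts[i]
        total += laplace_cell_nll(model, c, map_, population, warm_start=ws).nll
    return total


# ---------------------------------------------------------------------------
# Vectorized engine for model (i) on a common time grid
# ---------------------------------------------------------------------------


class _VectorizedModelI:
    """Laplace objective for model (i), vectorized across cells.

    All cells of one experiment must share a time grid (the study design:
    every 10 min over 30 h).  Inner problems are solved jointly by a damped
    Newton iteration with the Gauss-Newton Hessian and analytic gradients;
    the Laplace curvature is then the central-finite-difference Hessian of
    the analytic gradient, per cell.
    """

    def __init__(self, cells: list[CellData], map_: EffectSharingMap):
        self.map = map_
        self.cells = cells
        self.groups = []  # (experiment, cell indices, times, Y_obs)
        by_exp: dict[str, list[int]] = {}
        for i, c in enumerate(cells):
            if c.experiment not in map_.experiments:
                raise ValueError(f"cell {c.cell_id}: experiment {c.experiment!r} not in sharing map")
            by_exp.setdefault(c.experiment, []).append(i)
        for e, idx in by_exp.items():
            times = cells[idx[0]].times
            for i in idx[1:]:
                if cells[i].times.shape != times.shape or not np.allclose(cells[i].times, times):
                    raise ValueError("vectorized engine requires a common grid per experiment")
            Y = np.stack([cells[i].y_obs for i in idx])
            self.groups.append((e, np.array(idx), times, Y))
        self.n_random = map_.n_random
        self.pos = map_.random_positions()
        self.warm = np.zeros((len(cells), self.n_random))

    # -- per-experiment pieces -------------------------------------------

    def _theta(self, beta_full, B):
        log_phi = np.broadcast_to(beta_full, (B.shape[0], beta_full.size)).copy()
        log_phi[:, self.pos] += B
        # clip so exp never under/overflows to 0/inf at wild outer iterates
        return np.exp(np.clip(log_phi, -60.0, 60.0))

    def _psi_grad(self, times, Y, beta_full, d, sigma2, B, want_grad=True):
        theta = self._theta(beta_full, B)
        n_t = times.size
        if want_grad:
            y, jac = model_i_observable(theta, times, with_jac=True)
        else:
            y = model_i_observable(theta, times)
        r = Y - y
        psi = (
            0.5 * np.sum(r**2, axis=1) / sigma2
            + 0.5 * n_t * math.log(2.0 * math.pi * sigma2)
            + 0.5 * np.sum(B**2 / d, axis=1)
            + 0.5 * np.sum(np.log(2.0 * math.pi * d))
        )
        if not want_grad:
            return psi
        J = jac[:, :, self.pos] * theta[:, None, self.pos]  # d y / d b
        G = -np.einsum("ctb,ct->cb", J, r) / sigma2 + B / d
        H_gn = np.einsum("ctb,ctk->cbk", J, J) / sigma2 + np.eye(self.n_random) / d[None, :]
        return psi, G, H_gn

    def _solve_inner(self, times, Y, beta_full, d, sigma2, B0, max_newton=40, gtol=1e-8):
        """Damped Gauss-Newton on all cells at once.

        Far from the mode, steps are backtracked on the objective; once a
        cell's gradient is small, full Newton steps are taken (quadratic
        convergence, no objective comparison — near the mode psi differences
        fall below floating-point resolution).  The best visited point per
        cell is returned, which also handles the measure-zero kinks the
        transfection-onset parameter introduces at sample times.
        """
        B = B0.copy()
        n_c = B.shape[0]
        psi, G, H = self._psi_grad(times, Y, beta_full, d, sigma2, B)
        best_B, best_psi = B.copy(), psi.copy()
        active_idx = np.arange(n_c)
        for _ in range(max_newton):
            gnorm = np.max(np.abs(G), axis=1)
            keep = gnorm > gtol
            active_idx = active_idx[keep]
            if active_idx.size == 0:
                break
            G, H, psi = G[keep], H[keep], psi[keep]
            gnorm = gnorm[keep]
            Ba = B[active_idx]
            ridge = 1e-12
            eye_r = np.eye(self.n_random)
            while True:
                try:
                    step = np.linalg.solve(H + ridge * eye_r, G[..., None])[..., 0]
                    break
                except np.linalg.LinAlgError:
                    # GN Hessian is PSD; escalate the ridge until invertible
                    ridge = max(ridge * 1e4, 1e-8 * float(np.max(np.abs(H))) + 1e-12)
            norm = np.linalg.norm(step, axis=1, keepdims=True)
            step *= np.minimum(1.0, 5.0 / np.maximum(norm, 1e-300))
            near = gnorm < 1e-4
            alpha = np.ones(active_idx.size)
            Ya = Y[active_idx]
            for _ in range(15):
                B_try = Ba - alpha[:, None] * step
                psi_try = self._psi_grad(times, Ya, beta_full, d, sigma2, B_try, want_grad=False)
                worse = ~near & (psi_try > psi + 1e-12)
                if not worse.any():
                    break
                alpha = np.where(worse, 0.5 * alpha, alpha)
            B[active_idx] = B_try
            psi, G, H = self._psi_grad(times, Ya, beta_full, d, sigma2, B_try)
            better = psi < best_psi[active_idx]
            upd = active_idx[better]
            best_B[upd] = B_try[better]
            best_psi[upd] = psi[better]
        # evaluate convergence at the best visited points
        _, G_fin, _ = self._psi_grad(times, Y, beta_full, d, sigma2, best_B)
        gnorm = np.max(np.abs(G_fin), axis=1)
        # the transfection-onset parameter makes psi piecewise smooth in b;
        # cells whose mode sits at a sample-time kink retain a small residual
        # gradient, which is structural rather than a solver failure
        return best_B, best_psi, gnorm <= 1e-3

    def _fd_hessians(self, times, Y, beta_full, d, sigma2, B):
        n_c = B.shape[0]
        H = np.empty((n_c, self.n_random, self.n_random))
        steps = 1e-4 * (1.0 + np.abs(B))
        for k in range(self.n_random):
            Ep = B.copy()
            Em = B.copy()
            Ep[:, k] += steps[:, k]
            Em[:, k] -= steps[:, k]
            _, Gp, _ = self._psi_grad(times, Y, beta_full, d, sigma2, Ep)
            _, Gm, _ = self._psi_grad(times, Y, beta_full, d, sigma2, Em)
            H[:, :, k] = (Gp - Gm) / (2.0 * steps[:, k][:, None])
        return 0.5 * (H + np.transpose(H, (0, 2, 1)))

    # -- public objective -------------------------------------------------

    def nll(self, population: PopulationParameters, detailed: bool = False, curvature: str = "fd"):
        """Total Laplace NLL at the given population parameters.

        ``curvature`` selects the Hessian behind the Laplace log-determinant:
        ``"fd"`` is the central-finite-difference Hessian of the analytic
        gradient (the reference definition), ``"gn"`` its Gauss-Newton
        approximation (cheaper; used while the outer optimizer explores — the
        two coincide as residuals vanish).  Returns the scalar total, or
        (total, per-cell LaplaceCellResult list in the original cell order)
        when ``detailed``.
        """
        total = 0.0
        results: list[LaplaceCellResult | None] = [None] * len(self.cells)
        n_fail = 0
        for e, idx, times, Y in self.groups:
            beta_full = population.beta[self.map.beta_indices(e)]
            d, sigma2 = _prior_terms(self.map, population, e)
            B0 = self.warm[idx]
            B, psi, ok = self._solve_inner(times, Y, beta_full, d, sigma2, B0)
            self.warm[idx] = B
            if curvature == "gn":
                _, _, H = self._psi_grad(times, Y, beta_full, d, sigma2, B)
            else:
                H = self._fd_hessians(times, Y, beta_full, d, sigma2, B)
            jitters = np.zeros(len(idx))
            eig = np.linalg.eigvalsh(H)
            bad = eig[:, 0] <= 0
            for j in np.flatnonzero(bad):
                H[j], jitters[j] = _make_pd(H[j])
            sign, logdet = np.linalg.slogdet(H)
            nll_cells = psi - 0.5 * self.n_random * _LOG2PI + 0.5 * logdet
            total += float(np.sum(nll_cells))
            n_fail += int(np.sum(~ok))
            if detailed:
                for j, ci in enumerate(idx):
                    results[ci] = LaplaceCellResult(
                        cell_id=self.cells[ci].cell_id,
                        b_hat=B[j].copy(),
                        hessian=H[j].copy(),
                        nll=float(nll_cells[j]),
                        inner_converged=bool(ok[j]),
                        jitter_added=float(jitters[j]),
                    )
        self.last_fail_fraction = n_fail / len(self.cells)
        if detailed:
            return total, results
        return total

    def nll_and_grad(self, population: PopulationParameters, curvature: str = "gn"):
        """Total Laplace NLL (GN curvature) and its approximate analytic gradient.

        Uses the envelope theorem at the inner modes for the psi terms and
        the exact prior/noise derivatives of the Gauss-Newton
        log-determinant; the dependence of the data curvature J on the fixed
        effects is neglected (a small, smooth bias that the final
        finite-difference polish removes).  One evaluation costs about the
        same as the objective alone, which is what makes exploration with
        hundreds of outer iterations affordable.
        """
        n_beta = population.beta.size
        n_d = population.d_log.size
        grad = np.zeros(n_beta + n_d + population.log_sigma.size)
        total = 0.0
        n_fail = 0
        eye = np.eye(self.n_random)
        for e, idx, times, Y in self.groups:
            beta_idx = self.map.beta_indices(e)
            d_idx = self.map.d_indices(e)
            e_pos = self.map.experiments.index(e)
            beta_full = population.beta[beta_idx]
            d, sigma2 = _prior_terms(self.map, population, e)
            B0 = self.warm[idx]
            B, psi, ok = self._solve_inner(times, Y, beta_full, d, sigma2, B0)
            self.warm[idx] = B
            n_fail += int(np.sum(~ok))

            theta = self._theta(beta_full, B)
            y, jac = model_i_observable(theta, times, with_jac=True)
            r = Y - y
            J_full = jac * theta[:, None, :]  # d y / d (beta_full + b) per param
            H = (
                np.einsum("ctb,ctk->cbk", J_full[:, :, self.pos], J_full[:, :, self.pos]) / sigma2
                + eye / d[None, :]
            )
            if curvature == "fd":
                H = self._fd_hessians(times, Y, beta_full, d, sigma2, B)
            sign, logdet = np.linalg.slogdet(H)
            bad = sign <= 0
            for j in np.flatnonzero(bad):
                Hj, _ = _make_pd(H[j])
                H[j] = Hj
                sign[j], logdet[j] = np.linalg.slogdet(Hj)
            nll_cells = psi - 0.5 * self.n_random * _LOG2PI + 0.5 * logdet
            total += float(np.sum(nll_cells))

            Hinv = np.linalg.inv(H)
            hdiag = np.einsum("ckk->ck", Hinv)

            dpsi_dbeta = -np.einsum("ctj,ct->cj", J_full, r) / sigma2
            np.add.at(grad, beta_idx, dpsi_dbeta.sum(axis=0))

            dd = (-0.5 * B**2 / d) + 0.5 - 0.5 * hdiag / d
            np.add.at(grad, n_beta + d_idx, dd.sum(axis=0))

            rss = np.sum(r**2, axis=1)
            dls = (-rss / sigma2 + times.size) - (self.n_random - np.sum(hdiag / d, axis=1))
            grad[n_beta + n_d + e_pos] += float(np.sum(dls))
        self.last_fail_fraction = n_fail / len(self.cells)
        return total, grad

    def reset_warm(self):
        self.warm[:] = 0.0


def _make_total_objective(model, cells, map_, curvature: str = "fd", reset: bool = True):
    """Total-NLL callable over the packed population vector.

    With ``reset`` (the default) every call cold-starts the inner problems so
    the callable is a pure function of x; profiles pass ``reset=False`` to
    warm-start the inner modes along their continuation.
    """
    model = get_model(model)
    use_fast = model.model_id == "i"
    engine = None
    if use_fast:
        try:
            engine = _VectorizedModelI(cells, map_)
        except ValueError:
            engine = None
    if engine is not None:
        def objective(x):
            if reset:
                # cold-start the inner problems so the objective is a pure,
                # deterministic function of x (finite differences stay clean)
                engine.reset_warm()
            pop = PopulationParameters.unpack(np.asarray(x, dtype=float), map_)
            return engine.nll(pop, curvature=curvature)
        return objective, engine

    warm = [np.zeros(map_.n_random) for _ in cells]

    def objective(x):
        pop = PopulationParameters.unpack(np.asarray(x, dtype=float), map_)
        total = 0.0
        n_fail = 0
        for i, c in enumerate(cells):
            res = laplace_cell_nll(model, c, map_, pop, warm_start=warm[i])
            warm[i] = res.b_hat
            total += res.nll
            n_fail += not res.inner_converged
        objective.last_fail_fraction = n_fail / len(cells)
        return total

    objective.last_fail_fraction = 0.0
    return objective, None


def _sts_informed_centers(model, cells, map_: EffectSharingMap, seed: int) -> list[np.ndarray]:
    """Data-driven outer starting points from a quick STS on a subsample.

    Per-cell STS estimates of the standard model come in unordered
    (delta, gamma) pairs because of the exchange symmetry, so for model (i)
    two centers are returned — one for each assignment of the first
    experiment's low/high rate cluster to delta — and the multi-start ranking
    decides between the basins.
    """
    from .sts import fit_cell_mle  # local import to avoid a cycle

    model = get_model(model)
    rng = np.random.default_rng(seed)
    beta = np.zeros(map_.n_beta)
    beta_counts = np.zeros(map_.n_beta)
    d_samples: dict[int, list[float]] = {i: [] for i in range(map_.n_d)}
    s2_by_exp: dict[str, list[float]] = {}
    logs_by_exp: dict[str, np.ndarray] = {}
    by_exp: dict[str, list[CellData]] = {}
    for c in cells:
        by_exp.setdefault(c.experiment, []).append(c)
    for e, group in by_exp.items():
        take = min(12, len(group))
        chosen = list(rng.choice(len(group), size=take, replace=False))
        logs = []
        for j in chosen:
            try:
                res = fit_cell_mle(model, group[j], n_starts=6, seed=int(rng.integers(2**31)))
            except (RuntimeError, ValueError):
                continue
            logs.append(np.log(res.params.vector(model.parameter_names)))
            s2_by_exp.setdefault(e, []).append(res.sigma2_hat)
        if not logs:
            continue
        L = np.stack(logs)
        logs_by_exp[e] = L
        med = np.median(L, axis=0)
        var = L.var(axis=0) if len(logs) > 1 else np.full(model.n_parameters, 0.09)
        b_idx = map_.beta_indices(e)
        for k, gi in enumerate(b_idx):
            beta[gi] += med[k]
            beta_counts[gi] += 1
        for p, gi in zip(map_.random_effects, map_.d_indices(e)):
            k = model.parameter_names.index(p)
            d_samples[gi].append(float(var[k]))
    beta = np.where(beta_counts > 0, beta / np.maximum(beta_counts, 1), 0.0)
    d_log = np.array(
        [
            math.log(np.clip(np.mean(v) if v else 0.09, 0.02, 0.25))
            for v in (d_samples[i] for i in range(map_.n_d))
        ]
    )
    log_sigma = np.array(
        [
            0.5 * math.log(max(np.median(s2_by_exp.get(e, [0.01])), 1e-6))
            for e in map_.experiments
        ]
    )
    center = np.concatenate([beta, d_log, log_sigma])
    if model.model_id != "i" or not logs_by_exp:
        return [center]

    # model (i): resolve the delta/gamma cluster assignment two ways
    names = list(model.parameter_names)
    i_d, i_g = names.index("delta"), names.index("gamma")
    centers = []
    e0 = map_.experiments[0]
    L0 = logs_by_exp.get(e0)
    if L0 is None:
        return [center]
    lo = float(np.median(np.minimum(L0[:, i_d], L0[:, i_g])))
    hi = float(np.median(np.maximum(L0[:, i_d], L0[:, i_g])))
    for delta_c, gamma_c in ((hi, lo), (lo, hi)):
        x = center.copy()
        x[map_.beta_index("delta", e0)] = delta_c
        x[map_.beta_index("gamma", e0)] = gamma_c
        centers.append(x)
    return centers


def fit_nlme(
    model,
    cells,
    map_: EffectSharingMap | None = None,
    n_starts: int = 10,
    seed: int = 0,
    maxiter: int = 300,
    x0: np.ndarray | None = None,
) -> NLMEFitResult:
    """Multi-start hierarchical NLME fit.

    The outer problem is solved with L-BFGS-B and finite-difference gradients
    over (beta, d_log, log_sigma); inner problems are warm-started across
    outer iterations.  The first start is a data-driven center (quick STS on
    a subsample); the remaining starts are seeded random perturbations of it.
    Starts whose inner problems fail for more than 20% of cells are marked
    crashed and excluded from ranking.
    """
    model = get_model(model)
    cells = as_cell_list(cells)
    if map_ is None:
        specific = ("gamma",) if "gamma" in model.parameter_names else ()
        experiments = []
        for c in cells:
            if c.experiment not in experiments:
                experiments.append(c.experiment)
        map_ = EffectSharingMap(model.model_id, tuple(experiments), specific=specific)
    counts: dict[str, int] = {}
    for c in cells:
        counts[c.experiment] = counts.get(c.experiment, 0) + 1
    for e in map_.experiments:
        if counts.get(e, 0) < 2:
            raise ValueError(f"experiment {e!r} needs at least 2 cells, got {counts.get(e, 0)}")

    rng = np.random.default_rng(seed)
    centers = [x0] if x0 is not None else _sts_informed_centers(model, cells, map_, seed)
    n_x = centers[0].size
    starts_x = list(centers[:n_starts])
    k = 0
    while len(starts_x) < n_starts:
        starts_x.append(centers[k % len(centers)] + rng.uniform(-1.0, 1.0, size=n_x))
        k += 1

    # exploration uses the cheap Gauss-Newton Laplace curvature with the
    # approximate analytic outer gradient; the winner is polished and
    # reported with the central-difference curvature
    objective_gn, engine = _make_total_objective(model, cells, map_, curvature="gn")
    objective_fd, _ = (objective_gn, engine) if engine is None else _make_total_objective(model, cells, map_, curvature="fd")
    if engine is None:
        objective_fd = objective_gn  # generic path always uses fd Hessians
        explore_fun, explore_jac = objective_gn, None
    else:
        def explore_fun(x):
            engine.reset_warm()
            pop = PopulationParameters.unpack(np.asarray(x, dtype=float), map_)
            return engine.nll_and_grad(pop)

        explore_jac = True
    start_table = []
    candidates = []
    for i, xs in enumerate(starts_x):
        if engine is not None:
            engine.reset_warm()
        try:
            res = optimize.minimize(
                explore_fun,
                xs,
                method="L-BFGS-B",
                jac=explore_jac,
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-4, "eps": 1e-6},
            )
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as err:
            start_table.append({"start": i, "nll": math.inf, "crashed": True, "message": str(err)})
            continue
        fail_frac = (
            engine.last_fail_fraction if engine is not None else getattr(objective_gn, "last_fail_fraction", 0.0)
        )
        crashed = (not np.isfinite(res.fun)) or fail_frac > 0.2
        start_table.append(
            {
                "start": i,
                "nll": float(res.fun),
                "crashed": bool(crashed),
                "inner_fail_fraction": float(fail_frac),
                "message": str(res.message),
            }
        )
        if not crashed:
            candidates.append((float(res.fun), i, res))
    if not candidates:
        raise RuntimeError(f"all {len(starts_x)} NLME starts failed or crashed: {start_table}")
    candidates.sort(key=lambda t: (t[0], t[1]))
    _, _, best = candidates[0]
    if engine is not None:
        def polish_fun(x):
            engine.reset_warm()
            pop = PopulationParameters.unpack(np.asarray(x, dtype=float), map_)
            return engine.nll_and_grad(pop, curvature="fd")

        best = optimize.minimize(
            polish_fun,
            best.x,
            method="L-BFGS-B",
            jac=True,
            options={"maxiter": max(40, maxiter // 5), "ftol": 1e-10, "gtol": 1e-5},
        )
    population = PopulationParameters.unpack(np.asarray(best.x, dtype=float), map_)

    if engine is not None:
        engine.reset_warm()
        total, cell_results = engine.nll(population, detailed=True)
    else:
        cell_results = []
        total = 0.0
        for c in cells:
            r = laplace_cell_nll(model, c, map_, population)
            cell_results.append(r)
            total += r.nll
    start_table_sorted = sorted(start_table, key=lambda r: (r["nll"], r["start"]))
    return NLMEFitResult(
        population=population,
        map=map_,
        cell_results=cell_results,
        nll=float(total),
        starts=start_table_sorted,
        converged=bool(best.success),
    )


def empirical_bayes_parameters(fit: NLMEFitResult, cells=None, map_: EffectSharingMap | None = None) -> list[CellParameters]:
    """Empirical-Bayes single-cell parameters ``phi_i = exp(beta^e + b_hat_i)``.

    Requires the cells the fit was computed on (for their experiment labels);
    cells with a non-converged inner problem still get a value, flagged in
    ``fit.cell_results``.
    """
    map_ = map_ or fit.map
    if cells is None:
        raise ValueError("pass the cells the model was fitted on")
    cells = as_cell_list(cells)
    if len(cells) != len(fit.cell_results):
        raise ValueError("cells do not match the fit")
    return [
        expand_effects(map_, fit.population, c.experiment, r.b_hat)
        for c, r in zip(cells, fit.cell_results)
    ]


class NLME(BaseEstimator):
    """Multi-experiment nonlinear mixed-effect estimator.

    Parameters mirror :func:`fit_nlme`; ``specific`` names the
    experiment-specific parameters (default: the protein degradation rate
    ``gamma``) and ``random_effects`` restricts which parameters carry a
    random effect (default: all).

    Attributes
    ----------
    population_ : PopulationParameters
    map_ : EffectSharingMap
    cell_results_ : list of LaplaceCellResult
    nll_ : float
    result_ : NLMEFitResult
    """

    def __init__(
        self,
        model: str = "i",
        specific=("gamma",),
        random_effects=None,
        n_starts: int = 10,
        seed: int = 0,
        maxiter: int = 300,
    ):
        self.model = model
        self.specific = specific
        self.random_effects = random_effects
        self.n_starts = n_starts
        self.seed = seed
        self.maxiter = maxiter

    def fit(self, X, y=None):
        cells = as_cell_list(X)
        model = get_model(self.model)
        experiments = []
        for c in cells:
            if c.experiment not in experiments:
                experiments.append(c.experiment)
        specific = tuple(p for p in self.specific if p in model.parameter_names)
        map_ = EffectSharingMap(
            model.model_id, tuple(experiments), specific=specific, random_effects=self.random_effects
        )
        self.result_ = fit_nlme(
            model, cells, map_, n_starts=self.n_starts, seed=self.seed, maxiter=self.maxiter
        )
        self.map_ = self.result_.map
        self.population_ = self.result_.population
        self.cell_results_ = self.result_.cell_results
        self.nll_ = self.result_.nll
        self._fitted_cells = cells
        return self

    def predict(self, X=None):
        """Empirical-Bayes fitted observables for the training cells."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        if X is not None:
            raise ValueError("NLME predicts for the fitted cells; call predict() after fit")
        model = get_model(self.model)
        phis = empirical_bayes_parameters(self.result_, cells=self._fitted_cells)
        return [simulate_observable(model, phi, c.times) for c, phi in zip(self._fitted_cells, phis)]

    def empirical_bayes_parameters(self):
        return empirical_bayes_parameters(self.result_, cells=self._fitted_cells)
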
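"""Profile likelihoods, symmetry checks, residual analysis and model selection.

Profile likelihoods re-optimize all nuisance parameters at each fixed value
of one parameter; bimodality of a degradation-rate profile diagnoses the
delta <-> gamma exchange symmetry of the standard translation model, and its
disappearance under a joint two-construct fit demonstrates that the symmetry
has been broken.  Model comparison uses AIC/BIC plus a replicate-based
significance test: log-likelihood standard deviations estimated on data
subsets are extrapolated to the full experiment by dividing by the square
root of the subset fraction.  Batch effects are interpreted mechanistically
through per-replicate correction factors for the transfected mRNA amount m0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import CellData, as_cell_list
from .models import get_model, simulate_observable
from .nlme import EffectSharingMap, PopulationParameters, _make_total_objective
from .sts import _make_objective, _resolve_bounds

__all__ = [
    "ProfileResult",
    "ResidualProfile",
    "ModelComparison",
    "profile_parameter",
    "sts_parameter_profile",
    "nlme_beta_profile",
    "count_profile_minima",
    "swap_symmetry_check",
    "residual_time_profile",
    "information_criteria",
    "extrapolate_ll_sd",
    "compare_models_across_replicates",
    "m0_correction_factors",
]

#: A profile local minimum is only counted if it sits at least this many
#: objective units below both flanking barriers (noise-robust modality).
MODALITY_DROP = 2.0


@dataclass
class ProfileResult:
    parameter: str
    grid: np.ndarray
    objective: np.ndarray
    nuisances: list[np.ndarray]
    n_minima: int
    failed_points: list[int] = field(default_factory=list)


@dataclass
class ResidualProfile:
    experiment: str
    model_id: str
    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_cells: int
    flags: list[str] = field(default_factory=list)


@dataclass
class ModelComparison:
    models: list[str]
    nll: dict[str, float]
    k_params: dict[str, int]
    aic: dict[str, float]
    bic: dict[str, float]
    ll_sd: dict[str, float]
    pairwise_z: dict[tuple[str, str], float]
    pairwise_p: dict[tuple[str, str], float]


def count_profile_minima(values, drop: float = MODALITY_DROP) -> int:
    """Number of well-separated local minima of a profile curve.

    A local minimum counts when the barrier separating it from its neighbors
    (or the curve endpoints) rises at least ``drop`` objective units above it
    on both sides.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return 1 if v.size else 0
    minima = [
        i
        for i in range(v.size)
        if (i == 0 or v[i] <= v[i - 1]) and (i == v.size - 1 or v[i] <= v[i + 1])
    ]
    # collapse plateaus
    dedup = []
    for i in minima:
        if dedup and i - dedup[-1] == 1 and v[i] == v[dedup[-1]]:
            continue
        dedup.append(i)
    count = 0
    for j, i in enumerate(dedup):
        left = v[dedup[j - 1] : i + 1].max() if j > 0 else v[: i + 1].max()
        right = v[i : dedup[j + 1] + 1].max() if j < len(dedup) - 1 else v[i:].max()
        if left - v[i] >= drop and right - v[i] >= drop:
            count += 1
    # a unimodal curve has one minimum even if the barriers are shallow
    return max(count, 1)


def profile_parameter(objective, x_opt, index: int, grid, extra_starts=None, minimize_options=None, continuation_only: bool = False, has_grad: bool = False) -> ProfileResult:
    """Profile one coordinate of an objective over the full parameter vector.

    At each grid value the ``index``-th coordinate is fixed and the others are
    re-optimized, warm-started from the previous grid point (continuation) and
    from the global optimum; ``extra_starts(value)`` may supply additional
    nuisance starts.  Failed re-optimizations are flagged and skipped over.
    """
    x_opt = np.asarray(x_opt, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    free = [j for j in range(x_opt.size) if j != index]
    opts = {"maxiter": 200, "ftol": 1e-11, "gtol": 1e-7}
    if minimize_options:
        opts.update(minimize_options)

    def reduced(nu, v):
        x = x_opt.copy()
        x[index] = v
        x[free] = nu
        if has_grad:
            f, g = objective(x)
            return f, np.asarray(g)[free]
        return objective(x)

    values = np.full(grid.size, np.nan)
    nuisances: list[np.ndarray] = [None] * grid.size
    failed = []
    # start from the grid point nearest the optimum and sweep outward
    i0 = int(np.argmin(np.abs(grid - x_opt[index])))
    order = list(range(i0, grid.size)) + list(range(i0 - 1, -1, -1))
    prev: dict[str, np.ndarray] = {"up": x_opt[free].copy(), "down": x_opt[free].copy()}
    for i in order:
        direction = "up" if i >= i0 else "down"
        if continuation_only and i not in (i0,):
            starts = [prev[direction]]
        else:
            starts = [prev[direction], x_opt[free].copy()]
        if extra_starts is not None:
            starts.extend(np.asarray(s, dtype=float) for s in extra_starts(grid[i]))
        best = None
        for s in starts:
            try:
                res = optimize.minimize(reduced, s, args=(grid[i],), jac=has_grad, method="L-BFGS-B", options=opts)
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                continue
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            failed.append(i)
            continue
        values[i] = best.fun
        nuisances[i] = best.x.copy()
        prev[direction] = best.x.copy()
    # refinement sweeps: a continuation can lag behind the true profile
    # (hysteresis); re-polish each point from any better neighbor's nuisance
    # optimum until no point improves
    for _ in range(3):
        improved = False
        for i in list(range(grid.size)) + list(range(grid.size - 1, -1, -1)):
            for j in (i - 1, i + 1):
                if j < 0 or j >= grid.size or nuisances[j] is None:
                    continue
                if not np.isfinite(values[i]) or values[j] < values[i]:
                    try:
                        res = optimize.minimize(
                            reduced, nuisances[j], args=(grid[i],), jac=has_grad,
                            method="L-BFGS-B", options=opts,
                        )
                    except (RuntimeError, ValueError, np.linalg.LinAlgError):
                        continue
                    if np.isfinite(res.fun) and (not np.isfinite(values[i]) or res.fun < values[i] - 1e-6):
                        values[i] = res.fun
                        nuisances[i] = res.x.copy()
                        improved = True
        if not improved:
            break
    failed = [i for i in range(grid.size) if not np.isfinite(values[i])]
    ok = np.isfinite(values)
    n_minima = count_profile_minima(values[ok]) if ok.any() else 0
    return ProfileResult(
        parameter=f"x[{index}]",
        grid=grid,
        objective=values,
        nuisances=nuisances,
        n_minima=n_minima,
        failed_points=failed,
    )


def sts_parameter_profile(model, data: CellData, params_opt, parameter: str, grid, bounds=None) -> ProfileResult:
    """STS profile of one cell parameter (grid on the natural scale).

    For model (i) the delta <-> gamma swap of the optimum is added as an
    extra re-optimization start so the mirror branch of the symmetry is
    found reliably.
    """
    model = get_model(model)
    obj, has_jac = _make_objective(model, data)
    names = list(model.parameter_names)
    index = names.index(parameter)
    x_opt = np.log(params_opt.vector(names))
    box = _resolve_bounds(model, data, bounds)
    log_box = np.log(np.asarray(box))
    free = [j for j in range(len(names)) if j != index]

    def clipped(x):
        return obj(np.clip(x, log_box[:, 0], log_box[:, 1]))

    extra = None
    if model.model_id == "i" and parameter in ("delta", "gamma"):
        other = "gamma" if parameter == "delta" else "delta"
        oi = names.index(other)

        def extra(value):
            swap = x_opt.copy()
            swap[oi] = x_opt[index]  # nuisance rate takes the profiled rate's optimum
            return [swap[free]]

    res = profile_parameter(
        clipped, x_opt, index, np.log(np.asarray(grid, dtype=float)), extra_starts=extra, has_grad=has_jac
    )
    res.parameter = parameter
    res.grid = np.exp(res.grid)
    return res


def nlme_beta_profile(model, cells, map_: EffectSharingMap, population: PopulationParameters, beta_name: str, grid_log, maxiter: int = 60) -> ProfileResult:
    """Profile of one fixed effect of the NLME objective (grid on the log scale).

    All remaining population parameters are re-optimized at each grid point;
    the per-cell inner modes are warm-started along the continuation.
    """
    model = get_model(model)
    cells = as_cell_list(cells)
    index = list(map_.beta_names).index(beta_name)
    # the Gauss-Newton Laplace curvature keeps the profile affordable; the
    # modality conclusion is unaffected (gn and fd curvatures coincide as
    # residuals vanish).  Inner modes warm-start along the continuation and
    # the approximate analytic outer gradient drives the re-optimization.
    objective, engine = _make_total_objective(model, cells, map_, curvature="gn", reset=False)
    if engine is not None:
        def objective(x):
            pop = PopulationParameters.unpack(np.asarray(x, dtype=float), map_)
            return engine.nll_and_grad(pop)

        has_grad = True
    else:
        has_grad = False
    x_opt = population.pack()
    res = profile_parameter(
        objective,
        x_opt,
        index,
        np.asarray(grid_log, dtype=float),
        minimize_options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-3},
        continuation_only=True,
        has_grad=has_grad,
    )
    res.parameter = beta_name
    return res


def swap_symmetry_check(model, params, times, tol: float = 1e-8):
    """Max observable deviation under exchanging delta and gamma (model i).

    Returns ``(symmetric, max_abs_deviation)``.  For the standard model the
    deviation is zero up to floating-point error; extended models need not be
    symmetric and the deviation is simply reported.
    """
    model = get_model(model)
    values = dict(params.values if hasattr(params, "values") else params)
    swapped = dict(values)
    swapped["delta"], swapped["gamma"] = values["gamma"], values["delta"]
    y1 = simulate_observable(model, values, times)
    y2 = simulate_observable(model, swapped, times)
    dev = float(np.max(np.abs(y1 - y2)))
    return dev < tol, dev


def residual_time_profile(cells, fitted, model_id: str = "") -> list[ResidualProfile]:
    """Cross-cell mean and standard deviation of residuals per time point.

    ``fitted`` holds one fitted observable array per cell; cells are grouped
    by experiment and must share a common time grid within each group.  The
    population formula (divisor n) is used for the standard deviation.
    """
    cells = as_cell_list(cells)
    if len(cells) != len(fitted):
        raise ValueError("one fitted trajectory per cell required")
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(cells):
        groups.setdefault(c.experiment, []).append(i)
    out = []
    for e, idx in groups.items():
        times = cells[idx[0]].times
        for i in idx[1:]:
            if not np.array_equal(cells[i].times, times):
                raise ValueError(f"experiment {e}: cells must share a common time grid")
        R = np.stack([cells[i].y_obs - np.asarray(fitted[i], dtype=float) for i in idx])
        flags = []
        if len(idx) < 2:
            flags.append("sd_undefined")
            sd = np.full(times.size, np.nan)
        else:
            sd = R.std(axis=0, ddof=0)
        out.append(
            ResidualProfile(
                experiment=e,
                model_id=model_id,
                times=times,
                mean=R.mean(axis=0),
                sd=sd,
                n_cells=len(idx),
                flags=flags,
            )
        )
    return out


def information_criteria(nll: float, k_params: int, n_obs: int) -> tuple[float, float]:
    """AIC and BIC from a total negative log-likelihood.

    ``k_params`` counts estimated population-level quantities (fixed effects,
    random-effect variances, noise effects); ``n_obs`` is the total number of
    scalar observations (cells x time points).
    """
    if n_obs <= 0:
        raise ValueError(f"n_obs must be positive, got {n_obs}")
    aic = 2.0 * nll + 2.0 * k_params
    bic = 2.0 * nll + k_params * math.log(n_obs)
    return aic, bic


def extrapolate_ll_sd(subset_lls, fraction: float) -> float:
    """Full-experiment log-likelihood s.d. extrapolated from data subsets.

    The log-likelihood is a sum of independent per-cell terms, so its
    variance scales with the number of cells; the subset standard deviation
    (sample formula, divisor n-1) is divided by ``sqrt(fraction)`` — e.g. a
    factor ``1/sqrt(1/3) = 1.732`` for thirds.
    """
    lls = np.asarray(subset_lls, dtype=float)
    if lls.size < 2:
        raise ValueError("need at least 2 subset log-likelihoods")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return float(lls.std(ddof=1) / math.sqrt(fraction))


def compare_models_across_replicates(full_nll, subset_lls, fraction, k_params, n_obs) -> ModelComparison:
    """AIC/BIC table plus replicate-based significance of log-likelihood gaps.

    For each model pair the difference of full-data log-likelihoods is
    compared against the extrapolated standard deviations (combined in
    quadrature, assuming independence); a two-sided normal p-value is
    reported.  The same subsets must underlie every model's ``subset_lls``.
    """
    models = list(full_nll)
    n_subsets = {m: len(subset_lls[m]) for m in models}
    if len(set(n_subsets.values())) != 1:
        raise ValueError(f"mismatched subset counts: {n_subsets}")
    sd = {m: extrapolate_ll_sd(subset_lls[m], fraction) for m in models}
    aic, bic = {}, {}
    for m in models:
        aic[m], bic[m] = information_criteria(full_nll[m], k_params[m], n_obs)
    z, p = {}, {}
    for a in models:
        for b in models:
            if a >= b:
                continue
            delta_ll = -(full_nll[a] - full_nll[b])  # log-likelihood difference
            sd_d = math.hypot(sd[a], sd[b])
            zz = delta_ll / sd_d if sd_d > 0 else (0.0 if delta_ll == 0 else math.inf)
            z[(a, b)] = zz
            p[(a, b)] = float(2.0 * stats.norm.sf(abs(zz))) if np.isfinite(zz) else 0.0
    return ModelComparison(
        models=models,
        nll=dict(full_nll),
        k_params=dict(k_params),
        aic=aic,
        bic=bic,
        ll_sd=sd,
        pairwise_z=z,
        pairwise_p=p,
    )


def m0_correction_factors(beta_by_replicate, reference: str, m0_exponents):
    """Per-replicate multiplicative m0 correction factors and their consistency.

    For each m0-containing parameter combination ``p`` with m0 exponent
    ``s_p`` and replicate ``r``, the factor ``exp(s_p * (beta_{r,p} -
    beta_{ref,p}))`` estimates the batch's fold change in transfected mRNA.
    If the batch effect is a pure m0 shift, all parameters agree; the
    consistency score is the largest coefficient of variation of the factors
    across parameters within a replicate (0 for a pure shift).
    """
    if reference not in beta_by_replicate:
        raise ValueError(f"reference replicate {reference!r} missing")
    ref = beta_by_replicate[reference]
    factors: dict[str, dict[str, float]] = {}
    score = 0.0
    for r, betas in beta_by_replicate.items():
        row = {}
        for p, s_p in m0_exponents.items():
            if p not in betas or p not in ref:
                raise ValueError(f"missing beta entry for {p!r} in replicate {r!r} or reference")
            row[p] = math.exp(s_p * (betas[p] - ref[p]))
        factors[r] = row
        vals = np.array(list(row.values()))
        cv = float(vals.std(ddof=0) / vals.mean()) if vals.mean() != 0 else math.inf
        score = max(score, cv)
    return factors, score
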
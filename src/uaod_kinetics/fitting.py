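"""Least-squares fitting of thin-layer models and goodness-of-fit selection.

Each model is fitted to an MR-versus-time curve by bounded nonlinear least
squares (scipy's trust-region reflective solver) from a deterministic grid
of starting points; the best start by SSE wins.  Goodness of fit is reported
as SSE, RMSE = sqrt(SSE/N) and R^2 = 1 - SSE/SStot, and the best model is
the one with the highest R^2, ties broken by lower RMSE, then fewer
parameters, then registry order.

RMSE deliberately uses N (not N - p) in its denominator: with 8-9 points per
curve the plain definition is the one consistent with the reference fit
statistics, and it keeps RMSE monotone in SSE across models of different
size.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InvalidInputError, SelectionError
from .models import ModelSpec, model_registry, registry_index
from .records import OsmoticTrajectory, condition_key

log = logging.getLogger(__name__)

#: soft parameter bounds used by the fitter, by parameter name
PARAMETER_BOUNDS: dict[str, tuple[float, float]] = {
    "k": (0.0, 10.0),
    "k0": (0.0, 10.0),
    "k1": (0.0, 10.0),
    "g": (0.0, 10.0),
    "n": (1e-6, 3.0),
    "a": (-2.0, 2.0),
    "b": (-2.0, 2.0),
    "c": (-2.0, 2.0),
}

_K_START_GRID = (0.001, 0.01, 0.1)
_N_START_GRID = (0.5, 1.0)
# residual assigned to non-finite model evaluations during optimisation
_PENALTY = 1e6


@dataclass(frozen=True)
class FitResult:
    """One model fitted to one MR curve."""

    model: str
    parameters: dict[str, float]
    sse: float
    rmse: float
    r2: float
    converged: bool
    n_points: int
    best: bool = field(default=False, compare=False)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)


def goodness_of_fit(observed, predicted) -> tuple[float, float, float]:
    """SSE, RMSE and R^2 between observed and predicted MR series.

    R^2 is computed against the mean of the observations; constant
    observations make it undefined and raise.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise InvalidInputError("observed and predicted must be equal-length 1-D series")
    if obs.size < 2:
        raise InvalidInputError("need at least 2 points for goodness of fit")
    sse = float(np.sum((obs - pred) ** 2))
    rmse = math.sqrt(sse / obs.size)
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0.0:
        raise InvalidInputError("R^2 undefined: observations are constant")
    r2 = 1.0 - sse / sstot
    return sse, rmse, r2


def _starting_points(model: ModelSpec) -> list[dict[str, float]]:
    """Deterministic multi-start grid.

    k-type constants sweep a log grid; n sweeps {0.5, 1}; a = 1 and b = c = 0
    with g = k/2.  Models with >= 3 parameters but no n (Logarithmic, Verma)
    sweep a second value of their secondary shape parameter instead, so every
    such model gets at least 5 starts.
    """
    names = model.parameter_names
    k_name = "k0" if "k0" in names else "k"
    n_grid = _N_START_GRID if "n" in names else (math.nan,)
    if model.n_parameters >= 3 and "n" not in names:
        # Logarithmic sweeps c, Verma sweeps the g/k ratio, for >= 5 starts
        secondary_grid = ((("c", 0.0), ("c", 0.1)) if "c" in names
                          else (("g_ratio", 0.5), ("g_ratio", 2.0)))
    else:
        secondary_grid = ((None, None),)
    starts: list[dict[str, float]] = []
    for k, n, (sec_name, sec_val) in itertools.product(
        _K_START_GRID, n_grid, secondary_grid
    ):
        theta: dict[str, float] = {k_name: k, "n": n, "a": 1.0, "b": 0.0,
                                   "c": 0.0, "g": 0.5 * k, "k1": 0.5 * k}
        if sec_name == "c":
            theta["c"] = sec_val
        elif sec_name == "g_ratio":
            theta["g"] = sec_val * k
        start = {p: theta[p] for p in names}
        if start not in starts:  # n-grid collapses for n-free models
            starts.append(start)
    return starts


def fit_model(
    model: ModelSpec,
    times,
    mr,
    *,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FitResult:
    """Fit one thin-layer model to an MR curve.

    Requires at least max(3, p + 1) points.  Never raises on optimisation
    failure: if every start fails, the result carries ``converged=False``
    and infinite SSE so model selection can skip it.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(mr, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise InvalidInputError("times and mr must be equal-length 1-D series")
    min_points = max(3, model.n_parameters + 1)
    if t.size < min_points:
        raise InvalidInputError(
            f"{model.name} needs >= {min_points} points, got {t.size}"
        )
    all_bounds = dict(PARAMETER_BOUNDS)
    if bounds:
        all_bounds.update(bounds)
    lower = np.array([all_bounds[p][0] for p in model.parameter_names])
    upper = np.array([all_bounds[p][1] for p in model.parameter_names])

    def residuals(theta: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore"):
            pred = model(t, *theta)
        res = pred - y
        return np.where(np.isfinite(res), res, _PENALTY)

    best_theta: np.ndarray | None = None
    best_sse = math.inf
    for start in _starting_points(model):
        x0 = np.clip(
            np.array([start[p] for p in model.parameter_names]),
            lower + 1e-12,
            upper - 1e-12,
        )
        try:
            sol = least_squares(
                residuals,
                x0,
                bounds=(lower, upper),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=5000,
            )
        except Exception:  # singular Jacobian etc.: this start is abandoned
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        sse = float(np.sum(residuals(sol.x) ** 2))
        if sse < best_sse:
            best_sse = sse
            best_theta = sol.x
    if best_theta is None or not math.isfinite(best_sse):
        return FitResult(
            model=model.name,
            parameters={p: math.nan for p in model.parameter_names},
            sse=math.inf,
            rmse=math.inf,
            r2=-math.inf,
            converged=False,
            n_points=int(t.size),
        )
    pred = model(t, *best_theta)
    sse, rmse, r2 = goodness_of_fit(y, pred)
    return FitResult(
        model=model.name,
        parameters=dict(zip(model.parameter_names, map(float, best_theta))),
        sse=sse,
        rmse=rmse,
        r2=r2,
        converged=True,
        n_points=int(t.size),
    )


def select_best(fits: list[FitResult], *, tie_tol: float = 1e-6) -> FitResult:
    """The winning fit: highest R^2; near-ties (within ``tie_tol``) resolved
    by lower RMSE, then fewer parameters, then registry order.

    Permutation-invariant in the input list.
    """
    usable = [f for f in fits if f.converged and math.isfinite(f.sse)]
    if not usable:
        raise SelectionError("no converged fit to select from")
    r2_max = max(f.r2 for f in usable)
    contenders = [f for f in usable if f.r2 >= r2_max - tie_tol]
    # RMSE ties within the same tolerance (e.g. every nested model at SSE ~ 0
    # on noiseless data) fall through to parsimony, then registry order
    rmse_min = min(f.rmse for f in contenders)
    contenders = [f for f in contenders if f.rmse <= rmse_min + tie_tol]
    return min(contenders, key=lambda f: (f.n_parameters, registry_index(f.model)))


def averaged_mr_curve(
    trajectories: list[OsmoticTrajectory], *, include_t0: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Point-wise replicate-mean MR curve for one condition.

    All replicates must share the same time grid.  With ``include_t0`` the
    t = 0 point (MR = 1 by definition) anchors the fit.
    """
    if not trajectories:
        raise InvalidInputError("no trajectories supplied")
    t0 = trajectories[0].times_min
    for traj in trajectories[1:]:
        if not np.array_equal(traj.times_min, t0):
            raise InvalidInputError("replicates must share one time grid")
    mr = np.mean([traj.moisture_ratio_series() for traj in trajectories], axis=0)
    if include_t0:
        return t0.copy(), mr
    return t0[1:].copy(), mr[1:]


def fit_all_conditions(
    dataset: list[OsmoticTrajectory],
    *,
    models: list[ModelSpec] | None = None,
    include_t0: bool = True,
    tie_tol: float = 1e-6,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Fit every model to every condition and flag the best per condition.

    Replicate MR curves are averaged point-wise before fitting (one parameter
    set per condition, as in the reference report layout); ``per_replicate``
    fits each replicate curve separately instead.

    Returns a long-format table: one row per (condition[, replicate], model),
    flattened parameter columns, SSE/RMSE/R2 and a ``best`` flag.
    """
    models = list(models) if models is not None else model_registry()
    groups: dict[tuple, dict[int, list[OsmoticTrajectory]]] = {}
    for traj in dataset:
        key = condition_key(traj.condition.power_w, traj.condition.concentration_pct)
        rep = traj.replicate_id if per_replicate else 0
        groups.setdefault(key, {}).setdefault(rep, []).append(traj)

    param_columns = sorted({p for m in models for p in m.parameter_names})
    rows: list[dict] = []
    for (power, conc), reps in sorted(groups.items()):
        for rep_id, trajs in sorted(reps.items()):
            try:
                t, mr = averaged_mr_curve(trajs, include_t0=include_t0)
            except InvalidInputError as exc:
                log.warning("skipping condition (%s W, %s%%): %s", power, conc, exc)
                continue
            if t.size < 4:
                log.warning(
                    "skipping condition (%s W, %s%%): only %d MR points", power, conc, t.size
                )
                continue
            fits = [fit_model(m, t, mr) for m in models]
            try:
                winner = select_best(fits, tie_tol=tie_tol)
            except SelectionError as exc:
                log.warning("no converged fit for (%s W, %s%%): %s", power, conc, exc)
                continue
            for fit in fits:
                row = {
                    "power_W": power,
                    "concentration_pct": conc,
                    "model": fit.model,
                    **{p: fit.parameters.get(p, math.nan) for p in param_columns},
                    "SSE": fit.sse,
                    "RMSE": fit.rmse,
                    "R2": fit.r2,
                    "best": fit is winner,
                }
                if per_replicate:
                    row["replicate_id"] = rep_id
                rows.append(row)
    columns = ["power_W", "concentration_pct"]
    if per_replicate:
        columns.append("replicate_id")
    columns += ["model", *param_columns, "SSE", "RMSE", "R2", "best"]
    return pd.DataFrame(rows, columns=columns)
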
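"""Effective moisture diffusivity from the ln(MR)-versus-time slope.

For a slab of half-thickness L dried from both faces, the first term of the
Fickian series solution gives ln MR approximately linear in time, with slope
proportional to the effective diffusivity:

    D_eff = slope_per_second * 4 * L^2 / pi^2      [m^2/s]

Slopes are regressed in per-minute units (treatment time is recorded in
minutes) and converted internally by 1/60.  ln MR slopes are negative during
dehydration; this module stores and reports the slope *magnitude*, matching
the sign convention of the reference report, and rejects negative inputs
with guidance rather than silently flipping them.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError
from .fitting import averaged_mr_curve
from .records import OsmoticTrajectory, TreatmentCondition, condition_key

log = logging.getLogger(__name__)

#: default half-thickness: half of the 5 mm slice, in metres
DEFAULT_HALF_THICKNESS_M = 0.0025


@dataclass(frozen=True)
class DiffusivityResult:
    """Slope, correlation and effective diffusivity for one condition."""

    condition: TreatmentCondition
    slope_per_min: float  # magnitude of the ln MR slope
    r: float  # magnitude of the regression correlation
    half_thickness_m: float
    deff_m2_per_s: float


def ln_mr_slope(times, mr) -> tuple[float, float]:
    """Magnitude of the OLS slope of ln(MR) on time, and |r|.

    Points with MR <= 0 carry no usable log signal; they are dropped with a
    warning.  At least 3 usable points are required.  Times are minutes, so
    the slope is per minute.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(mr, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise InvalidInputError("times and mr must be equal-length 1-D series")
    usable = y > 0
    if not np.all(usable):
        warnings.warn(
            f"dropping {int(np.sum(~usable))} point(s) with MR <= 0 from the "
            "ln MR regression",
            stacklevel=2,
        )
    t, y = t[usable], y[usable]
    if t.size < 3:
        raise InsufficientDataError(
            f"need >= 3 points with MR > 0 for the ln MR regression, got {t.size}"
        )
    log_mr = np.log(y)
    if np.allclose(log_mr, log_mr[0]):
        return 0.0, 0.0  # no drying signal; correlation undefined, reported as 0
    fit = stats.linregress(t, log_mr)
    return abs(float(fit.slope)), abs(float(fit.rvalue))


def deff_from_slope(slope_per_min: float, half_thickness_m: float) -> float:
    """Effective moisture diffusivity (m^2/s) from a per-minute slope magnitude."""
    slope_per_min = float(slope_per_min)
    half_thickness_m = float(half_thickness_m)
    if slope_per_min < 0:
        raise InvalidInputError(
            "slope must be the magnitude of the ln MR slope (>= 0); pass "
            "abs(slope) — the dehydration sign convention is handled internally"
        )
    if half_thickness_m <= 0:
        raise InvalidInputError("half-thickness must be > 0 m")
    slope_per_s = slope_per_min / 60.0
    return slope_per_s * 4.0 * half_thickness_m**2 / math.pi**2


def diffusivity_result(
    trajectories: list[OsmoticTrajectory],
    *,
    half_thickness_m: float = DEFAULT_HALF_THICKNESS_M,
) -> DiffusivityResult:
    """Slope, r and D_eff for one condition's replicate set."""
    t, mr = averaged_mr_curve(trajectories, include_t0=True)
    slope, r = ln_mr_slope(t, mr)
    return DiffusivityResult(
        condition=trajectories[0].condition,
        slope_per_min=slope,
        r=r,
        half_thickness_m=half_thickness_m,
        deff_m2_per_s=deff_from_slope(slope, half_thickness_m),
    )


def diffusivity_table(
    dataset: list[OsmoticTrajectory],
    *,
    half_thickness_m: float = DEFAULT_HALF_THICKNESS_M,
) -> pd.DataFrame:
    """One row per (power, concentration): slope, D_eff and r.

    Conditions whose regression fails (too few usable points) are skipped
    with a logged warning.
    """
    groups: dict[tuple, list[OsmoticTrajectory]] = {}
    for traj in dataset:
        key = condition_key(traj.condition.power_w, traj.condition.concentration_pct)
        groups.setdefault(key, []).append(traj)
    rows = []
    for (power, conc), trajs in sorted(groups.items()):
        try:
            res = diffusivity_result(trajs, half_thickness_m=half_thickness_m)
        except (InsufficientDataError, InvalidInputError) as exc:
            log.warning("skipping condition (%s W, %s%%): %s", power, conc, exc)
            continue
        rows.append((power, conc, res.slope_per_min, res.deff_m2_per_s, res.r))
    return pd.DataFrame(
        rows, columns=["power_W", "concentration_pct", "slope_per_min",
                       "Deff_m2_per_s", "r"]
    )


def aggregate_deff(table: pd.DataFrame, by: str) -> pd.Series:
    """Arithmetic mean of D_eff per level of concentration or power.

    ``by`` is ``"concentration"`` or ``"power"``.  Empty groups cannot arise
    from a groupby; missing D_eff values drop their row with a warning.
    """
    columns = {"concentration": "concentration_pct", "power": "power_W"}
    if by not in columns:
        raise InvalidInputError(f"group by 'concentration' or 'power', not {by!r}")
    frame = table[[columns[by], "Deff_m2_per_s"]].dropna()
    if len(frame) < len(table):
        log.warning("dropped %d row(s) without D_eff", len(table) - len(frame))
    means = frame.groupby(columns[by])["Deff_m2_per_s"].mean()
    means.name = "mean_Deff_m2_per_s"
    return means
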
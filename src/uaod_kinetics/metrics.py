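"""Mass-transfer indices for osmotic dehydration.

All indices are percentages of the *initial* slice mass A0 of the same
replicate:

* mass reduction   MRe = 100 (A0 - At) / A0
* solids gain      SG  = 100 (St - S0) / A0
* water loss       WL  = 100 (W0 - (At - St)) / A0

Because water mass is total mass minus solids mass at both endpoints, the
three indices satisfy WL = MRe + SG identically; ``trajectory_metrics``
asserts that conservation row-wise.  The moisture ratio MR = Mt / M0 (water
mass now over water mass initially) is the dimensionless variable of the
thin-layer kinetics, and the rehydration ratio RR = 100 Mr / M0 compares a
rehydrated dried slice with its oven-dry mass.

Negative MRe/SG/WL values are returned as-is (replicate scatter can produce
them); MR > 1 is allowed but flagged with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import InconsistentRecordError, InvalidInputError
from .records import OsmoticTrajectory, RehydrationPair


def mass_reduction(a0: float, at: float) -> float:
    """Percent loss of total slice mass relative to the initial mass.

    Negative when the slice gained mass (solids uptake outrunning water loss).
    """
    a0 = float(a0)
    at = float(at)
    if a0 <= 0:
        raise InvalidInputError(f"initial mass A0 must be > 0 g, got {a0}")
    if at < 0:
        raise InvalidInputError(f"treated mass At must be >= 0 g, got {at}")
    return 100.0 * (a0 - at) / a0


def solids_gain(a0: float, s0: float, st: float) -> float:
    """Soluble-solids uptake as a percent of the initial slice mass."""
    a0, s0, st = float(a0), float(s0), float(st)
    if a0 <= 0:
        raise InvalidInputError(f"initial mass A0 must be > 0 g, got {a0}")
    if s0 < 0 or st < 0:
        raise InvalidInputError("solids masses must be >= 0 g")
    value = 100.0 * (st - s0) / a0
    if value < 0:
        warnings.warn(
            f"negative solids gain ({value:.3g}%): solids decreased", stacklevel=2
        )
    return value


def water_loss(a0: float, w0: float, at: float, st: float) -> float:
    """Water removed as a percent of the initial slice mass.

    Uses the substitution W_t = A_t - S_t, so only the treated slice's total
    and solids masses are needed.
    """
    a0, w0, at, st = float(a0), float(w0), float(at), float(st)
    if a0 <= 0:
        raise InvalidInputError(f"initial mass A0 must be > 0 g, got {a0}")
    if w0 < 0:
        raise InvalidInputError("initial water mass must be >= 0 g")
    if st > at:
        raise InconsistentRecordError(
            f"solids mass ({st} g) exceeds total mass ({at} g)"
        )
    value = 100.0 * (w0 - (at - st)) / a0
    if value < 0:
        warnings.warn(
            f"negative water loss ({value:.3g}%): water content increased", stacklevel=2
        )
    return value


def rehydration_ratio(pair: RehydrationPair) -> float:
    """Rehydrated mass over oven-dry mass, in percent (values > 100 expected)."""
    return 100.0 * pair.rehydrated_mass_g / pair.dried_mass_g


def moisture_ratio(mt, m0: float):
    """Water mass at time t over initial water mass (dimensionless).

    Accepts a scalar or array ``mt``.  Values above 1 are physically odd
    (water uptake during dehydration) and trigger a warning but are not
    clipped.
    """
    m0 = float(m0)
    if m0 <= 0:
        raise InvalidInputError(f"initial water mass M0 must be > 0 g, got {m0}")
    mt_arr = np.asarray(mt, dtype=float)
    if np.any(mt_arr < 0):
        raise InvalidInputError("water mass Mt must be >= 0 g")
    mr = mt_arr / m0
    if np.any(mr > 1):
        warnings.warn("moisture ratio above 1: water content exceeds initial", stacklevel=2)
    return float(mr) if np.isscalar(mt) else mr


def trajectory_metrics(traj: OsmoticTrajectory) -> pd.DataFrame:
    """All four indices at every post-treatment time of one trajectory.

    Returns one row per time point t > 0 with columns
    ``time_min, MRe_pct, SG_pct, WL_pct, MR``, keyed by the trajectory's
    condition and replicate.  The conservation identity WL = MRe + SG is
    asserted to 1e-9 on every row.
    """
    a0 = float(traj.total_mass_g[0])
    s0 = float(traj.solids_mass_g[0])
    w0 = float(traj.water_mass_g[0])
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-row negatives surface in the summary
        for i in range(1, traj.n_times):
            t = float(traj.times_min[i])
            try:
                mre = mass_reduction(a0, traj.total_mass_g[i])
                sg = solids_gain(a0, s0, traj.solids_mass_g[i])
                wl = water_loss(a0, w0, traj.total_mass_g[i], traj.solids_mass_g[i])
                mr = moisture_ratio(float(traj.water_mass_g[i]), w0)
            except (InvalidInputError, InconsistentRecordError) as exc:
                raise type(exc)(f"at t = {t} min: {exc}") from exc
            rows.append((t, mre, sg, wl, mr))
    frame = pd.DataFrame(rows, columns=["time_min", "MRe_pct", "SG_pct", "WL_pct", "MR"])
    residual = (frame["WL_pct"] - frame["MRe_pct"] - frame["SG_pct"]).abs()
    if not residual.empty and residual.max() > 1e-9:
        raise InconsistentRecordError(
            f"conservation WL = MRe + SG violated (max residual {residual.max():.3g})"
        )
    frame.insert(0, "replicate_id", traj.replicate_id)
    frame.insert(0, "concentration_pct", traj.condition.concentration_pct)
    frame.insert(0, "power_W", traj.condition.power_w)
    return frame


def dataset_metrics(dataset) -> pd.DataFrame:
    """Concatenated ``trajectory_metrics`` over an iterable of trajectories."""
    frames = [trajectory_metrics(traj) for traj in dataset]
    if not frames:
        return pd.DataFrame(
            columns=["power_W", "concentration_pct", "replicate_id",
                     "time_min", "MRe_pct", "SG_pct", "WL_pct", "MR"]
        )
    return pd.concat(frames, ignore_index=True)


def metrics_summary(metric_table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of each index over replicates.

    The study design leaves open whether indices are reported per replicate
    or pooled; this package computes per replicate and summarises as
    mean +/- sd per (power, concentration, time).
    """
    grouped = metric_table.groupby(["power_W", "concentration_pct", "time_min"])
    agg = grouped[["MRe_pct", "SG_pct", "WL_pct", "MR"]].agg(["mean", "std"])
    agg.columns = [f"{col}_{stat}" for col, stat in agg.columns]
    return agg.reset_index()
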
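"""Reading and writing trajectory tables and analysis reports.

The interchange format is plain CSV with header
``replicate_id,power_W,concentration_pct,time_min,mass_g,solids_g,water_g``
(decimal point, UTF-8).  Numeric round-trips are lossless to 12 significant
digits.  D_eff values are rendered in E-notation at 3 significant figures
(e.g. ``1.39E-10``) in the diffusivity report.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .records import OsmoticTrajectory, TreatmentCondition

TRAJECTORY_COLUMNS = [
    "replicate_id",
    "power_W",
    "concentration_pct",
    "time_min",
    "mass_g",
    "solids_g",
    "water_g",
]

_FLOAT_FORMAT = "%.12g"


def format_deff(value: float) -> str:
    """Scientific E-notation at 3 significant figures: 1.3932e-10 -> '1.39E-10'."""
    return f"{float(value):.2E}"


def trajectories_to_frame(dataset: list[OsmoticTrajectory]) -> pd.DataFrame:
    """Flatten trajectories into the interchange schema."""
    rows = []
    for traj in dataset:
        for i in range(traj.n_times):
            rows.append(
                (
                    traj.replicate_id,
                    traj.condition.power_w,
                    traj.condition.concentration_pct,
                    traj.times_min[i],
                    traj.total_mass_g[i],
                    traj.solids_mass_g[i],
                    traj.water_mass_g[i],
                )
            )
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def frame_to_trajectories(frame: pd.DataFrame) -> list[OsmoticTrajectory]:
    """Group an interchange-schema frame back into trajectory records."""
    missing = [c for c in TRAJECTORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    keys = ["power_W", "concentration_pct", "replicate_id", "time_min"]
    duplicated = frame.duplicated(subset=keys, keep=False)
    if duplicated.any():
        dupes = frame.loc[duplicated, keys].drop_duplicates().to_dict("records")
        raise SchemaError(f"duplicate (condition, replicate, time) keys: {dupes}")
    dataset = []
    group_keys = ["power_W", "concentration_pct", "replicate_id"]
    for (power, conc, rep), group in frame.groupby(group_keys, sort=True):
        group = group.sort_values("time_min")
        dataset.append(
            OsmoticTrajectory(
                condition=TreatmentCondition(
                    power_w=float(power), concentration_pct=float(conc)
                ),
                times_min=group["time_min"].to_numpy(float),
                total_mass_g=group["mass_g"].to_numpy(float),
                solids_mass_g=group["solids_g"].to_numpy(float),
                water_mass_g=group["water_g"].to_numpy(float),
                replicate_id=int(rep),
            )
        )
    return dataset


def write_trajectories(dataset: list[OsmoticTrajectory], path) -> None:
    trajectories_to_frame(dataset).to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_trajectories(path) -> list[OsmoticTrajectory]:
    """Parse a trajectory CSV; schema violations raise ``SchemaError``."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(
            f"{path}: empty file, expected header {','.join(TRAJECTORY_COLUMNS)}"
        ) from exc
    if frame.empty:
        raise SchemaError(f"{path}: no data rows")
    try:
        return frame_to_trajectories(frame)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_diffusivity_report(table: pd.DataFrame, path) -> None:
    """Diffusivity CSV with D_eff in 3-s.f. E-notation."""
    out = table.copy()
    out["Deff_m2_per_s"] = out["Deff_m2_per_s"].map(format_deff)
    out.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_report_bundle(bundle: dict[str, pd.DataFrame], outdir, *, as_json: bool = False) -> dict[str, Path]:
    """Write every report table in a bundle to ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in bundle.items():
        if name == "diffusivity":
            path = outdir / f"{name}.csv"
            write_diffusivity_report(table, path)
        else:
            path = outdir / f"{name}.csv"
            table.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
        paths[name] = path
        if as_json:
            jpath = outdir / f"{name}.json"
            jpath.write_text(
                json.dumps(
                    json.loads(table.to_json(orient="records")), indent=2
                )
                + "\n"
            )
            paths[f"{name}_json"] = jpath
    return paths


__all__ = [
    "TRAJECTORY_COLUMNS",
    "format_deff",
    "trajectories_to_frame",
    "frame_to_trajectories",
    "write_trajectories",
    "read_trajectories",
    "write_diffusivity_report",
    "write_report_bundle",
]
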
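"""Reference constants for kiwifruit-slice UAOD (40 kHz bath, 50 deg C, 5 mm slices).

Two measured tables for the 3 x 3 (ultrasound power x sucrose concentration)
design are kept here as plain data:

* ``PAGE_CONSTANTS`` — the Page-model constants (k per minute, n) that best
  described the moisture-ratio kinetics in each cell, with their fit
  statistics.  They parameterize the default synthetic study, so simulated
  kinetics carry realistic curvature and ordering.
* ``DIFFUSIVITY_ROWS`` — the ln(MR)-versus-time slope (per minute), the
  effective moisture diffusivity (m^2/s) and the regression correlation per
  cell.  The slope column is an exactly recomputable arithmetic surface for
  the Fickian slab formula; note the printed slopes were rounded to 2
  significant figures after D_eff was computed, so recomputed D_eff can
  differ from the printed value by up to ~3%.

Solids-gain anchors are the measured uptake percentages at 80 min for the
four cells where they were reported; the synthetic generator interpolates
the rest (monotone in power and concentration).
"""

from __future__ import annotations

import pandas as pd

# (power_W, concentration_pct) -> (k per min, n)
PAGE_CONSTANTS: dict[tuple[int, int], tuple[float, float]] = {
    (0, 20): (0.0130, 0.6127),
    (75, 20): (0.0294, 0.4866),
    (150, 20): (0.0484, 0.3778),
    (0, 30): (0.0335, 0.5018),
    (75, 30): (0.0495, 0.4225),
    (150, 30): (0.0539, 0.4322),
    (0, 40): (0.1184, 0.3241),
    (75, 40): (0.1189, 0.3381),
    (150, 40): (0.1390, 0.3604),
}

# (power_W, concentration_pct) -> (R2, SSE, RMSE) of the Page fit
PAGE_FIT_STATS: dict[tuple[int, int], tuple[float, float, float]] = {
    (0, 20): (0.988, 0.0003, 0.0065),
    (75, 20): (0.996, 0.0001, 0.0047),
    (150, 20): (0.991, 0.0004, 0.0072),
    (0, 30): (0.992, 0.0004, 0.0079),
    (75, 30): (0.989, 0.0007, 0.0097),
    (150, 30): (0.994, 0.0004, 0.0080),
    (0, 40): (0.982, 0.0021, 0.0171),
    (75, 40): (0.975, 0.0032, 0.0216),
    (150, 40): (0.991, 0.0017, 0.0158),
}

# power_W, concentration_pct, slope (per min, magnitude), Deff (m^2/s), r
DIFFUSIVITY_ROWS: list[tuple[int, int, float, float, float]] = [
    (0, 20, 0.0022, 9.05e-11, 0.965),
    (75, 20, 0.0028, 1.17e-10, 0.957),
    (150, 20, 0.0028, 1.15e-10, 0.934),
    (0, 30, 0.0033, 1.39e-10, 0.951),
    (75, 30, 0.0033, 1.39e-10, 0.920),
    (150, 30, 0.0038, 1.59e-10, 0.920),
    (0, 40, 0.0050, 2.10e-10, 0.902),
    (75, 40, 0.0054, 2.26e-10, 0.903),
    (150, 40, 0.0070, 2.93e-10, 0.914),
]

# (power_W, concentration_pct) -> measured soluble-solids gain (%) at 80 min
SOLIDS_GAIN_80MIN_ANCHORS: dict[tuple[int, int], float] = {
    (0, 20): 3.28,
    (75, 20): 6.76,
    (150, 20): 9.11,
    (75, 40): 13.53,
}

# Study geometry and composition
SLICE_THICKNESS_MM = 5.0
HALF_THICKNESS_M = 0.0025
INITIAL_MOISTURE_FRACTION_WB = 0.84
SAMPLING_TIMES_MIN = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)


def diffusivity_frame() -> pd.DataFrame:
    """The reference diffusivity table as a DataFrame (report schema)."""
    return pd.DataFrame(
        DIFFUSIVITY_ROWS,
        columns=["power_W", "concentration_pct", "slope_per_min", "Deff_m2_per_s", "r"],
    )


def page_constants_frame() -> pd.DataFrame:
    """Reference Page constants and fit statistics as a DataFrame."""
    rows = [
        (p, c, k, n, *PAGE_FIT_STATS[(p, c)])
        for (p, c), (k, n) in PAGE_CONSTANTS.items()
    ]
    return pd.DataFrame(
        rows, columns=["power_W", "concentration_pct", "k", "n", "R2", "SSE", "RMSE"]
    )
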
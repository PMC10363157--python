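"""Synthetic UAOD study generator.

Emulates the 3 powers x 3 sucrose concentrations x 8 sampling times x 3
replicates factorial design on kiwifruit slices: moisture kinetics follow
the Page form MR = exp(-k t^n) with the reference (k, n) constants per cell,
and soluble-solids gain follows a saturating first-order uptake
SG(t) = SG_inf (1 - exp(-beta t)).  Water, solids and total mass are then
reconstructed so that W + S = A holds exactly, which makes the conservation
identity WL = MRe + SG structural in every generated record.

Replicate scatter is additive Gaussian noise on MR (clipped to (0, 1.05])
and on SG (clipped at 0), drawn from a generator seeded hierarchically by
(seed, power, concentration, replicate) so each cell's noise stream is
independent of the rest of the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import reference
from .errors import ConfigurationError
from .records import OsmoticTrajectory, TreatmentCondition

#: first-order solids-uptake rate (per minute): ~91% of the asymptote by 80 min
DEFAULT_SG_RATE_PER_MIN = 0.03

#: measured 80-min solids-gain anchors, completed monotonically in power and
#: concentration for the cells without a reported value
SG_80MIN_PCT: dict[tuple[int, int], float] = {
    (0, 20): 3.28,
    (75, 20): 6.76,
    (150, 20): 9.11,
    (0, 30): 4.90,
    (75, 30): 10.10,
    (150, 30): 12.00,
    (0, 40): 6.80,
    (75, 40): 13.53,
    (150, 40): 15.00,
}


@dataclass(frozen=True)
class CellKinetics:
    """Forward-model parameters for one (power, concentration) cell."""

    page_k: float  # per minute
    page_n: float
    sg_asymptote_pct: float  # SG_inf, percent of initial mass
    sg_rate_per_min: float  # beta

    def __post_init__(self) -> None:
        if self.page_k <= 0 or self.page_n <= 0:
            raise ConfigurationError("Page k and n must be > 0")
        if self.sg_rate_per_min <= 0:
            raise ConfigurationError("solids-uptake rate beta must be > 0")
        if not 0 < self.sg_asymptote_pct <= 20:
            raise ConfigurationError("SG asymptote must be in (0, 20] percent")


@dataclass(frozen=True)
class StudyDesign:
    """The factorial grid, slice composition and noise model of one study."""

    powers_w: tuple[float, ...] = (0.0, 75.0, 150.0)
    concentrations_pct: tuple[float, ...] = (20.0, 30.0, 40.0)
    times_min: tuple[float, ...] = reference.SAMPLING_TIMES_MIN
    replicates: int = 3
    initial_mass_g: float = 10.0
    initial_moisture_fraction: float = reference.INITIAL_MOISTURE_FRACTION_WB
    noise_sd: float = 0.005  # MR units
    sg_noise_sd_pct: float = 0.25  # absolute percent on SG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigurationError("need at least 1 replicate")
        if not 0 < self.initial_moisture_fraction < 1:
            raise ConfigurationError("moisture fraction must be in (0, 1)")
        if not self.times_min or self.times_min[0] != 0:
            raise ConfigurationError("sampling times must start at 0 min")
        if self.noise_sd < 0 or self.sg_noise_sd_pct < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")

    @property
    def grid(self) -> list[tuple[float, float]]:
        return [(p, c) for p in self.powers_w for c in self.concentrations_pct]


KineticParameterMap = dict[tuple[float, float], CellKinetics]


def default_parameter_map(
    *, sg_rate_per_min: float = DEFAULT_SG_RATE_PER_MIN
) -> KineticParameterMap:
    """Reference-calibrated kinetics for the default 3 x 3 grid.

    Page (k, n) are the measured constants per cell; the solids asymptote is
    back-computed from the 80-min anchor so the noiseless trajectory hits the
    anchored uptake at the end of treatment.
    """
    saturation_80 = 1.0 - math.exp(-sg_rate_per_min * 80.0)
    out: KineticParameterMap = {}
    for (power, conc), (k, n) in reference.PAGE_CONSTANTS.items():
        sg80 = SG_80MIN_PCT[(power, conc)]
        out[(float(power), float(conc))] = CellKinetics(
            page_k=k,
            page_n=n,
            sg_asymptote_pct=sg80 / saturation_80,
            sg_rate_per_min=sg_rate_per_min,
        )
    return out


def _cell_rng(design: StudyDesign, power: float, conc: float, replicate: int):
    # hierarchical seeding: independent stream per (cell, replicate)
    return np.random.default_rng(
        [int(design.seed), int(round(power)), int(round(10 * conc)), int(replicate)]
    )


def simulate_condition(
    design: StudyDesign,
    params: CellKinetics,
    condition: TreatmentCondition,
    replicate: int,
) -> OsmoticTrajectory:
    """One replicate trajectory for one treatment cell.

    The t = 0 record is the untreated slice (MR = 1, SG = 0) and carries no
    noise: it *defines* the initial masses every index is computed against.
    """
    t = np.asarray(design.times_min, dtype=float)
    rng = _cell_rng(design, condition.power_w, condition.concentration_pct, replicate)

    mr = np.exp(-params.page_k * np.power(t, params.page_n))
    sg = params.sg_asymptote_pct * (1.0 - np.exp(-params.sg_rate_per_min * t))
    if design.noise_sd > 0:
        mr[1:] += rng.normal(0.0, design.noise_sd, size=t.size - 1)
    if design.sg_noise_sd_pct > 0:
        sg[1:] += rng.normal(0.0, design.sg_noise_sd_pct, size=t.size - 1)
    mr = np.clip(mr, 1e-6, 1.05)
    sg = np.clip(sg, 0.0, None)

    a0 = design.initial_mass_g
    w0 = design.initial_moisture_fraction * a0
    s0 = a0 - w0
    water = mr * w0
    solids = s0 + sg * a0 / 100.0
    total = water + solids
    return OsmoticTrajectory(
        condition=condition,
        times_min=t,
        total_mass_g=total,
        solids_mass_g=solids,
        water_mass_g=water,
        replicate_id=replicate,
        initial_moisture_fraction=design.initial_moisture_fraction,
    )


def simulate_study(
    design: StudyDesign,
    params: KineticParameterMap | None = None,
) -> list[OsmoticTrajectory]:
    """Full factorial dataset: |powers| x |concentrations| x replicates
    trajectories, deterministic given ``design.seed``.
    """
    if params is None:
        params = default_parameter_map()
    missing = [cell for cell in design.grid if (cell[0], cell[1]) not in params]
    if missing:
        raise ConfigurationError(
            "parameter map missing cells: "
            + ", ".join(f"({p} W, {c}%)" for p, c in missing)
        )
    dataset = []
    for power, conc in design.grid:
        condition = TreatmentCondition(power_w=power, concentration_pct=conc)
        cell = params[(power, conc)]
        for rep in range(design.replicates):
            dataset.append(simulate_condition(design, cell, condition, rep))
    return dataset


__all__ = [
    "CellKinetics",
    "StudyDesign",
    "KineticParameterMap",
    "default_parameter_map",
    "simulate_condition",
    "simulate_study",
    "DEFAULT_SG_RATE_PER_MIN",
    "SG_80MIN_PCT",
]
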
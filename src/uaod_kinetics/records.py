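"""Core record types: treatment conditions and slice mass trajectories.

An osmotic-dehydration trajectory tracks one fruit slice (one replicate of one
treatment) through time: total mass A, soluble-solids mass S, and water mass
W, all in grams, with W + S = A at every sampling time.  These three series
are the substrate of every mass-transfer index and of the moisture-ratio
kinetics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InconsistentRecordError, InvalidInputError

# absolute tolerance (grams) for the water + solids = total identity
MASS_BALANCE_ATOL = 1e-6
# tolerance on the declared initial wet-basis moisture fraction
MOISTURE_FRACTION_ATOL = 0.01


@dataclass(frozen=True)
class TreatmentCondition:
    """One cell of the factorial design.

    Parameters
    ----------
    power_w : float
        Ultrasound power in watts; 0 means plain osmotic dehydration.
    concentration_pct : float
        Sucrose solution concentration, % w/w, in (0, 100).
    frequency_khz : float
        Ultrasonic bath frequency (kHz).
    temperature_c : float
        Solution temperature (deg C), held constant in the study design.
    """

    power_w: float
    concentration_pct: float
    frequency_khz: float = 40.0
    temperature_c: float = 50.0

    def __post_init__(self) -> None:
        if self.power_w < 0:
            raise InvalidInputError(f"ultrasound power must be >= 0 W, got {self.power_w}")
        if not 0 < self.concentration_pct < 100:
            raise InvalidInputError(
                f"sucrose concentration must be in (0, 100) % w/w, got {self.concentration_pct}"
            )

    @property
    def key(self) -> tuple[float, float]:
        return (self.power_w, self.concentration_pct)


@dataclass(frozen=True)
class RehydrationPair:
    """Dried/rehydrated mass pair for the rehydration ratio.

    ``dried_mass_g`` is the slice mass after oven drying (the denominator of
    the rehydration ratio); it is distinct from the initial *water* mass used
    by the moisture ratio.
    """

    dried_mass_g: float
    rehydrated_mass_g: float

    def __post_init__(self) -> None:
        if self.dried_mass_g <= 0:
            raise InvalidInputError(f"dried mass must be > 0 g, got {self.dried_mass_g}")
        if self.rehydrated_mass_g <= 0:
            raise InvalidInputError(
                f"rehydrated mass must be > 0 g, got {self.rehydrated_mass_g}"
            )


@dataclass(frozen=True)
class OsmoticTrajectory:
    """Time-indexed (total, solids, water) masses for one slice.

    Invariants enforced at construction:

    * times are in minutes, non-negative, strictly increasing, first entry 0;
    * all masses are non-negative and water + solids = total at every time;
    * if ``initial_moisture_fraction`` is declared, W_0 / A_0 matches it.
    """

    condition: TreatmentCondition
    times_min: np.ndarray
    total_mass_g: np.ndarray
    solids_mass_g: np.ndarray
    water_mass_g: np.ndarray
    replicate_id: int = 0
    initial_moisture_fraction: float | None = None

    def __post_init__(self) -> None:
        for name in ("times_min", "total_mass_g", "solids_mass_g", "water_mass_g"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        t, a, s, w = self.times_min, self.total_mass_g, self.solids_mass_g, self.water_mass_g
        if not (t.shape == a.shape == s.shape == w.shape) or t.ndim != 1:
            raise InvalidInputError("times and mass series must be 1-D and equal length")
        if t.size < 1 or t[0] != 0:
            raise InvalidInputError("trajectory must start at t = 0 min")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(a < 0) or np.any(s < 0) or np.any(w < 0):
            raise InvalidInputError("masses must be non-negative")
        if np.any(np.abs(w + s - a) > MASS_BALANCE_ATOL):
            worst = float(np.max(np.abs(w + s - a)))
            raise InconsistentRecordError(
                f"water + solids != total mass (max |residual| = {worst:.3g} g)"
            )
        if self.initial_moisture_fraction is not None:
            if a[0] <= 0:
                raise InvalidInputError("initial total mass must be > 0 g")
            frac = w[0] / a[0]
            if abs(frac - self.initial_moisture_fraction) > MOISTURE_FRACTION_ATOL:
                raise InconsistentRecordError(
                    f"W0/A0 = {frac:.4f} differs from declared moisture fraction "
                    f"{self.initial_moisture_fraction:.4f}"
                )

    @property
    def n_times(self) -> int:
        return int(self.times_min.size)

    def moisture_ratio_series(self) -> np.ndarray:
        """Water mass at each time over the initial water mass."""
        w0 = float(self.water_mass_g[0])
        if w0 <= 0:
            raise InvalidInputError("initial water mass must be > 0 g for a moisture ratio")
        return self.water_mass_g / w0


def condition_key(power_w: float, concentration_pct: float) -> tuple[float, float]:
    """Canonical (power, concentration) grouping key."""
    return (float(power_w), float(concentration_pct))


__all__ = [
    "TreatmentCondition",
    "RehydrationPair",
    "OsmoticTrajectory",
    "condition_key",
    "MASS_BALANCE_ATOL",
]
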
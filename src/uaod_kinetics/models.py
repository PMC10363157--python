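"""The six thin-layer dehydration model forms.

Each model expresses the moisture ratio MR(t) as an empirical function of
treatment time t (minutes).  The registry is closed: Page, Newton, Midilli,
Logarithmic, Verma and Two-term, in that order.

Note on the Two-term form: it is implemented with an exponent n on the first
term, MR = a exp(-k0 t^n) + b exp(-k1 t).  The conventional two-term model
has no such exponent; with the exponent, Two-term nests Page (a=1, b=0) and
the two-term exponential (n=1).
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigurationError, InvalidInputError


@dataclass(frozen=True)
class ModelSpec:
    """One thin-layer model: a name, ordered parameter names, and MR(t; theta)."""

    name: str
    parameter_names: tuple[str, ...]
    _formula: Callable[..., np.ndarray]

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def __call__(self, t, *theta):
        """Raw formula evaluation; no validation (used by the fitter)."""
        return self._formula(np.asarray(t, dtype=float), *theta)


def _page(t, k, n):
    return np.exp(-k * np.power(t, n))


def _newton(t, k):
    return np.exp(-k * t)


def _midilli(t, a, k, n, b):
    return a * np.exp(-k * np.power(t, n)) + b * t


def _logarithmic(t, a, k, c):
    return a * np.exp(-k * t) + c


def _verma(t, a, k, g):
    return a * np.exp(-k * t) + (1.0 - a) * np.exp(-g * t)


def _two_term(t, a, k0, n, b, k1):
    return a * np.exp(-k0 * np.power(t, n)) + b * np.exp(-k1 * t)


PAGE = ModelSpec("Page", ("k", "n"), _page)
NEWTON = ModelSpec("Newton", ("k",), _newton)
MIDILLI = ModelSpec("Midilli", ("a", "k", "n", "b"), _midilli)
LOGARITHMIC = ModelSpec("Logarithmic", ("a", "k", "c"), _logarithmic)
VERMA = ModelSpec("Verma", ("a", "k", "g"), _verma)
TWO_TERM = ModelSpec("TwoTerm", ("a", "k0", "n", "b", "k1"), _two_term)

_REGISTRY: tuple[ModelSpec, ...] = (PAGE, NEWTON, MIDILLI, LOGARITHMIC, VERMA, TWO_TERM)


def model_registry() -> list[ModelSpec]:
    """The six models, in canonical report order."""
    return list(_REGISTRY)


def registry_index(name: str) -> int:
    """Position of a model in the canonical order (selection tie-break)."""
    for i, spec in enumerate(_REGISTRY):
        if spec.name == name:
            return i
    raise ConfigurationError(f"unknown model {name!r}")


def get_model(name: str) -> ModelSpec:
    return _REGISTRY[registry_index(name)]


def evaluate(model: ModelSpec, theta: Mapping[str, float], t):
    """Evaluate MR(t; theta) with validation.

    ``theta`` must supply every parameter of ``model``; ``t`` is minutes,
    scalar or array, non-negative.
    """
    missing = [p for p in model.parameter_names if p not in theta]
    if missing:
        raise ConfigurationError(
            f"model {model.name} missing parameter(s): {', '.join(missing)}"
        )
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidInputError("time must be >= 0 min")
    values = model(t_arr, *(float(theta[p]) for p in model.parameter_names))
    return float(values) if np.isscalar(t) else values


__all__ = [
    "ModelSpec",
    "PAGE",
    "NEWTON",
    "MIDILLI",
    "LOGARITHMIC",
    "VERMA",
    "TWO_TERM",
    "model_registry",
    "registry_index",
    "get_model",
    "evaluate",
]
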
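"""Compartment models of blast-cell death and ctDNA transport.

Three nested linear models of increasing mechanistic detail:

* ``ONE_STEP`` — exponential decay of ctDNA in peripheral blood only.
* ``TWO_STEP`` — blast cells in bone marrow release ctDNA directly into
  peripheral blood, where it degrades.
* ``THREE_STEP`` — blast cells die in the marrow, releasing ctDNA into a
  marrow compartment that subsequently transits to peripheral blood.

The canonical parameter ordering used throughout the package is

    (B0, c0pb, gamma_d, s_c, alpha, gamma_t)

restricted per model to the parameters the model actually uses.  The
degradation rate ``gamma_deg`` is a fixed physiological constant (default
33/day, the rate implied by a ~30 minute ctDNA half-life) and is never part
of the estimated parameter vector.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelKind",
    "KineticModel",
    "EffectVector",
    "GAMMA_DEG_DEFAULT",
    "one_step",
    "two_step",
    "three_step",
    "get_model",
    "rhs",
    "initial_state",
    "count_parameters",
    "decay_rate_from_half_life",
]

#: Fixed ctDNA degradation rate in peripheral blood (1/day).
GAMMA_DEG_DEFAULT = 33.0

#: Minutes per day, used by the half-life conversion helper.
_MINUTES_PER_DAY = 1440.0


class ModelKind(str, enum.Enum):
    ONE_STEP = "one_step"
    TWO_STEP = "two_step"
    THREE_STEP = "three_step"


class InvalidModelError(ValueError):
    """Raised for unknown or inconsistent model kinds."""


@dataclass(frozen=True)
class KineticModel:
    """Structural description of one compartment model.

    Attributes
    ----------
    kind
        Which of the three nested models this is.
    state_names
        Ordered state labels, a subset of ``("B", "cbm", "cpb")``.
    parameter_names
        Ordered free-parameter labels in canonical order; ``gamma_deg`` is
        deliberately absent (fixed constant).
    observable_names
        Ordered observable labels, subset of ``("y_ctdna", "y_blast")``.
    """

    kind: ModelKind
    state_names: tuple[str, ...]
    parameter_names: tuple[str, ...]
    observable_names: tuple[str, ...]

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    @property
    def n_observables(self) -> int:
        return len(self.observable_names)


_MODELS: dict[ModelKind, KineticModel] = {
    ModelKind.ONE_STEP: KineticModel(
        kind=ModelKind.ONE_STEP,
        state_names=("cpb",),
        parameter_names=("c0pb", "alpha"),
        observable_names=("y_ctdna",),
    ),
    ModelKind.TWO_STEP: KineticModel(
        kind=ModelKind.TWO_STEP,
        state_names=("B", "cpb"),
        parameter_names=("B0", "c0pb", "alpha", "gamma_t"),
        observable_names=("y_ctdna", "y_blast"),
    ),
    ModelKind.THREE_STEP: KineticModel(
        kind=ModelKind.THREE_STEP,
        state_names=("B", "cbm", "cpb"),
        parameter_names=("B0", "c0pb", "gamma_d", "s_c", "alpha", "gamma_t"),
        observable_names=("y_ctdna", "y_blast"),
    ),
}


def one_step() -> KineticModel:
    return _MODELS[ModelKind.ONE_STEP]


def two_step() -> KineticModel:
    return _MODELS[ModelKind.TWO_STEP]


def three_step() -> KineticModel:
    return _MODELS[ModelKind.THREE_STEP]


def get_model(kind: ModelKind | str) -> KineticModel:
    """Look up the canonical :class:`KineticModel` for ``kind``."""
    try:
        kind = ModelKind(kind)
    except ValueError as exc:
        raise InvalidModelError(f"unknown model kind: {kind!r}") from exc
    return _MODELS[kind]


@dataclass(frozen=True)
class EffectVector:
    """Natural-scale per-patient kinetic parameters.

    All entries are strictly positive.  ``s_c >= 1`` guarantees the
    peripheral-blood ctDNA gradient at treatment start is non-negative;
    ``alpha <= 1`` because it is a fraction of total ctDNA.
    """

    B0: float = 1.0
    c0pb: float = 1.0
    gamma_d: float = 1.0
    s_c: float = 1.0
    alpha: float = 1.0
    gamma_t: float = 1.0
    gamma_deg: float = GAMMA_DEG_DEFAULT

    def __post_init__(self) -> None:
        for name in ("B0", "c0pb", "gamma_d", "s_c", "alpha", "gamma_t", "gamma_deg"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        if self.alpha > 1.0:
            raise ValueError(f"alpha must be <= 1, got {self.alpha!r}")
        if self.s_c < 1.0:
            raise ValueError(f"s_c must be >= 1, got {self.s_c!r}")

    @property
    def c0bm(self) -> float:
        """Implied initial marrow ctDNA, ``(gamma_deg/gamma_t) * c0pb * s_c``."""
        return self.gamma_deg / self.gamma_t * self.c0pb * self.s_c

    def with_(self, **kwargs) -> "EffectVector":
        return replace(self, **kwargs)

    def values(self, model: KineticModel) -> np.ndarray:
        """Free-parameter values in the model's canonical order."""
        return np.array([getattr(self, n) for n in model.parameter_names])


def rhs(model: KineticModel, state, params: EffectVector) -> np.ndarray:
    """Time derivative of the state vector (1/day units).

    Pure function of its inputs; raises on negative states or a state vector
    of the wrong length.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_states,):
        raise ValueError(
            f"state must have shape ({model.n_states},), got {state.shape}"
        )
    if np.any(state < 0):
        raise ValueError("state values must be non-negative")
    if model.kind is ModelKind.ONE_STEP:
        (cpb,) = state
        return np.array([-params.gamma_deg * cpb])
    if model.kind is ModelKind.TWO_STEP:
        B, cpb = state
        return np.array([-params.gamma_t * B, params.gamma_t * B - params.gamma_deg * cpb])
    if model.kind is ModelKind.THREE_STEP:
        B, cbm, cpb = state
        return np.array(
            [
                -params.gamma_d * B,
                params.gamma_d * B - params.gamma_t * cbm,
                params.gamma_t * cbm - params.gamma_deg * cpb,
            ]
        )
    raise InvalidModelError(f"unknown model kind: {model.kind!r}")


def initial_state(model: KineticModel, params: EffectVector) -> np.ndarray:
    """State vector at treatment start (t = 0).

    For the three-step model the marrow ctDNA pool is initialised at
    ``c0bm = (gamma_deg/gamma_t) * c0pb * s_c`` which, for ``s_c >= 1``,
    makes the t=0 gradient of peripheral-blood ctDNA non-negative.
    """
    if params.s_c < 1.0:
        raise ValueError(
            f"s_c must be >= 1 (non-negative initial ctDNA gradient), got {params.s_c!r}"
        )
    if model.kind is ModelKind.ONE_STEP:
        return np.array([params.c0pb])
    if model.kind is ModelKind.TWO_STEP:
        return np.array([params.B0, params.c0pb])
    if model.kind is ModelKind.THREE_STEP:
        return np.array([params.B0, params.c0bm, params.c0pb])
    raise InvalidModelError(f"unknown model kind: {model.kind!r}")


def observe(model: KineticModel, states: np.ndarray, params: EffectVector) -> np.ndarray:
    """Map a (time x state) array to the model's observables.

    ``y_ctdna = alpha * cpb`` and, where blasts are modeled, ``y_blast = B``.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    cols = {name: states[:, i] for i, name in enumerate(model.state_names)}
    out = []
    for obs in model.observable_names:
        if obs == "y_ctdna":
            out.append(params.alpha * cols["cpb"])
        elif obs == "y_blast":
            out.append(cols["B"])
        else:  # pragma: no cover - defensive
            raise InvalidModelError(f"unknown observable {obs!r}")
    return np.column_stack(out)


def count_parameters(model: KineticModel) -> tuple[int, int]:
    """Return ``(population_count, patient_specific_count)``.

    The population count is: one mean per mixed effect, one log-variance per
    mixed effect, the shared transition rate where present, plus the ctDNA
    noise standard deviation.  The patient-specific count is the number of
    mixed (random) effects.
    """
    mixed = {
        ModelKind.ONE_STEP: 2,   # c0pb, alpha
        ModelKind.TWO_STEP: 3,   # B0, c0pb, alpha
        ModelKind.THREE_STEP: 5,  # B0, c0pb, gamma_d, s_c, alpha
    }[model.kind]
    shared = 0 if model.kind is ModelKind.ONE_STEP else 1  # gamma_t
    population = 2 * mixed + shared + 1  # means + variances + gamma_t + sigma_c
    return population, mixed


def decay_rate_from_half_life(half_life_minutes: float) -> float:
    """Exponential decay rate (1/day) implied by a half-life in minutes.

    ``decay_rate_from_half_life(30)`` gives ~33.27/day; the package uses the
    rounded constant :data:`GAMMA_DEG_DEFAULT` = 33/day as the fixed default.
    """
    if not half_life_minutes > 0:
        raise ValueError(f"half-life must be > 0, got {half_life_minutes!r}")
    return math.log(2.0) * _MINUTES_PER_DAY / half_life_minutes
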
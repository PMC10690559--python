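"""Closed-form trajectories and parameter sensitivities.

The three models are linear rate cascades, so every state is a linear
combination of cascade kernels ``E[k1, ..., kn]`` — confluent divided
differences of ``exp(l t)`` over ``l_i = -k_i``:

    cpb(t) = gd*gt*B0 * E[gd, gt, gdeg]
           + gdeg*s_c*c0pb * E[gt, gdeg]
           + c0pb * E[gdeg]                       (three-step)

Repeated rates — the degenerate branches where two or three of (gamma_d,
gamma_t, gamma_deg) coincide — are the confluent cases
``E[k, k] = t exp(-k t)``, ``E[k, k, k] = t^2/2 exp(-k t)``, so one
evaluator covers every branch.  Parameter sensitivities follow from the
node-doubling identity

    d/dk E[..., k, ...] = -m * E[..., k, k, ...]

with m the multiplicity of k, again valid uniformly across branches.  Two
rates are merged into one confluent node when their relative gap is below
``BRANCH_RTOL``; the divided-difference forms lose precision as 1/gap near
degeneracy, and the merge bound keeps that error below the documented
tolerances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .models import EffectVector, KineticModel, ModelKind, initial_state, observe, rhs

__all__ = [
    "BRANCH_RTOL",
    "Trajectory",
    "SensitivityTensor",
    "cascade_kernel",
    "solve_analytic",
    "solve_numeric",
    "sensitivities_analytic",
]

#: Relative gap below which two decay rates are treated as equal.
BRANCH_RTOL = 1e-8


@dataclass(frozen=True)
class Trajectory:
    """Time grid plus state and observable matrices (time-major)."""

    model: KineticModel
    times: np.ndarray            # (n_t,)
    states: np.ndarray           # (n_t, n_states)
    observables: np.ndarray      # (n_t, n_observables)

    def state(self, name: str) -> np.ndarray:
        return self.states[:, self.model.state_names.index(name)]

    def observable(self, name: str) -> np.ndarray:
        return self.observables[:, self.model.observable_names.index(name)]


@dataclass(frozen=True)
class SensitivityTensor:
    """d(observable)/d(parameter) on the natural scale.

    ``values`` has shape (n_t, n_observables, n_parameters) with the model's
    canonical observable and parameter ordering.
    """

    model: KineticModel
    times: np.ndarray
    values: np.ndarray

    def of(self, observable: str, parameter: str) -> np.ndarray:
        i = self.model.observable_names.index(observable)
        j = self.model.parameter_names.index(parameter)
        return self.values[:, i, j]


def _merge_nodes(nodes: tuple[float, ...]) -> tuple[float, ...]:
    """Sort rates and snap nearly-equal ones onto a common confluent node."""
    ns = sorted(nodes)
    out: list[float] = []
    for x in ns:
        if out and abs(x - out[-1]) <= BRANCH_RTOL * max(abs(x), abs(out[-1])):
            # extend the current cluster; all members take the cluster mean
            cluster = [v for v in out if v == out[-1]] + [x]
            mean = sum(cluster) / len(cluster)
            for _ in cluster[:-1]:
                out.pop()
            out.extend([mean] * len(cluster))
        else:
            out.append(x)
    return tuple(out)


def _dd(nodes: tuple[float, ...], t: np.ndarray) -> np.ndarray:
    """Confluent divided difference of exp(l t) over l = -k, sorted/merged k."""
    first, last = nodes[0], nodes[-1]
    if first == last:
        n = len(nodes)
        return t ** (n - 1) * np.exp(-first * t) / math.factorial(n - 1)
    # divided difference over l_i = -k_i: denominator l_hi - l_lo = first - last
    return (_dd(nodes[:-1], t) - _dd(nodes[1:], t)) / (last - first)


def cascade_kernel(nodes, t) -> np.ndarray:
    """Confluent divided difference of ``exp(l t)`` over ``l_i = -k_i``.

    This is the impulse-response kernel of a linear decay cascade: the state
    fed through compartments with decay rates ``k_1 .. k_n`` (unit transfer
    coefficients) is exactly this kernel.  It is non-negative for t >= 0 and
    reduces to ``t^{n-1} exp(-k t)/(n-1)!`` when all rates coincide.
    """
    return _dd(_merge_nodes(tuple(float(x) for x in nodes)), np.asarray(t, dtype=float))


def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if t[0] < 0:
        raise ValueError("times must start at t >= 0")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending")
    return t


def _states_analytic(model: KineticModel, p: EffectVector, t: np.ndarray) -> np.ndarray:
    gd, gt, gg = p.gamma_d, p.gamma_t, p.gamma_deg
    E = cascade_kernel
    if model.kind is ModelKind.ONE_STEP:
        cpb = p.c0pb * E((gg,), t)
        return cpb[:, None]
    if model.kind is ModelKind.TWO_STEP:
        B = p.B0 * E((gt,), t)
        cpb = gt * p.B0 * E((gt, gg), t) + p.c0pb * E((gg,), t)
        return np.column_stack([B, cpb])
    if model.kind is ModelKind.THREE_STEP:
        B = p.B0 * E((gd,), t)
        cbm = gd * p.B0 * E((gd, gt), t) + p.c0bm * E((gt,), t)
        cpb = (
            gd * gt * p.B0 * E((gd, gt, gg), t)
            + gg * p.s_c * p.c0pb * E((gt, gg), t)
            + p.c0pb * E((gg,), t)
        )
        return np.column_stack([B, cbm, cpb])
    raise ValueError(f"unknown model kind: {model.kind!r}")


def solve_analytic(model: KineticModel, params: EffectVector, times) -> Trajectory:
    """Evaluate the closed-form solution on a time grid (days)."""
    t = _check_times(times)
    if params.s_c < 1.0:
        raise ValueError(f"s_c must be >= 1, got {params.s_c!r}")
    states = _states_analytic(model, params, t)
    return Trajectory(model, t, states, observe(model, states, params))


def solve_numeric(
    model: KineticModel,
    params: EffectVector,
    times,
    rtol: float = 1e-10,
    atol_scale: float = 1e-14,
) -> Trajectory:
    """Adaptive ODE integration of :func:`rhs` — the validation oracle."""
    t = _check_times(times)
    x0 = initial_state(model, params)
    atol = atol_scale * max(float(np.max(x0)), 1.0)
    t0, t1 = float(t[0]), float(t[-1])
    if t1 == t0:
        states = np.tile(x0, (t.size, 1))
    else:
        sol = solve_ivp(
            lambda _, x: rhs(model, np.maximum(x, 0.0), params),
            (t0, t1),
            x0,
            t_eval=t,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        states = sol.y.T
    return Trajectory(model, t, states, observe(model, states, params))


def _cpb_and_grads(p: EffectVector, t: np.ndarray, kind: ModelKind):
    """cpb(t) and its partials w.r.t. the model's free parameters.

    Rate derivatives use the node-doubling identity
    ``d/dk E(nodes) = -m E(nodes + [k])`` with m the multiplicity of k.
    """
    gd, gt, gg = p.gamma_d, p.gamma_t, p.gamma_deg
    E = cascade_kernel
    e_gg = E((gg,), t)
    if kind is ModelKind.ONE_STEP:
        cpb = p.c0pb * e_gg
        return cpb, {"c0pb": e_gg}
    if kind is ModelKind.TWO_STEP:
        d2 = E((gt, gg), t)
        cpb = gt * p.B0 * d2 + p.c0pb * e_gg
        return cpb, {
            "B0": gt * d2,
            "c0pb": e_gg,
            "gamma_t": p.B0 * d2 - gt * p.B0 * E((gt, gt, gg), t),
        }
    # three-step: cpb = gd*gt*B0*E[gd,gt,gg] + gg*sc*c0pb*E[gt,gg] + c0pb*E[gg]
    d3 = E((gd, gt, gg), t)
    d2 = E((gt, gg), t)
    cpb = gd * gt * p.B0 * d3 + gg * p.s_c * p.c0pb * d2 + p.c0pb * e_gg
    grads = {
        "B0": gd * gt * d3,
        "c0pb": gg * p.s_c * d2 + e_gg,
        "gamma_d": gt * p.B0 * d3 - gd * gt * p.B0 * E((gd, gd, gt, gg), t),
        "s_c": gg * p.c0pb * d2,
        "gamma_t": (
            gd * p.B0 * d3
            - gd * gt * p.B0 * E((gd, gt, gt, gg), t)
            - gg * p.s_c * p.c0pb * E((gt, gt, gg), t)
        ),
    }
    return cpb, grads


def sensitivities_analytic(
    model: KineticModel, params: EffectVector, times
) -> SensitivityTensor:
    """Analytic d(observable)/d(parameter), natural scale, all branches.

    The coupling of the implied marrow initial condition
    ``c0bm = (gamma_deg/gamma_t) c0pb s_c`` to c0pb, s_c and gamma_t is
    already folded into the closed form, so the chain rule is exact.
    """
    t = _check_times(times)
    p = params
    cpb, cpb_grads = _cpb_and_grads(p, t, model.kind)
    zeros = np.zeros_like(t)

    # blast decay rate: gamma_t in the two-step model, gamma_d in the three-step
    if model.kind is ModelKind.TWO_STEP:
        blast_rate_name = "gamma_t"
        blast_rate = p.gamma_t
    else:
        blast_rate_name = "gamma_d"
        blast_rate = p.gamma_d
    e_blast = np.exp(-blast_rate * t)

    out = np.zeros((t.size, model.n_observables, model.n_parameters))
    for j, name in enumerate(model.parameter_names):
        for i, obs in enumerate(model.observable_names):
            if obs == "y_ctdna":
                if name == "alpha":
                    out[:, i, j] = cpb
                else:
                    out[:, i, j] = p.alpha * cpb_grads.get(name, zeros)
            else:  # y_blast = B
                if name == "B0":
                    out[:, i, j] = e_blast
                elif name == blast_rate_name:
                    out[:, i, j] = -p.B0 * t * e_blast
                else:
                    out[:, i, j] = 0.0
    return SensitivityTensor(model, t, out)
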
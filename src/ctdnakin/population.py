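"""Nonlinear mixed-effects estimation for the kinetic models.

Per-patient natural-scale parameters are composed as ``phi = A beta + B b``
on a transformed scale — every effect is exponentially transformed for
positivity, except the marrow scaling factor which uses ``s_c = 1 + exp``
to respect its lower bound of 1 — with random effects
``b ~ N(0, D)``, ``D = exp(diag(delta))`` diagonal.  The population
likelihood marginalizes the random effects per patient with a first-order
conditional (Laplace) approximation around the conditional mode, using a
Gauss-Newton curvature built from the analytic model sensitivities.  The
outer problem is maximized by multi-start local optimization (Latin
hypercube start points, bounded quasi-Newton steps).

The ctDNA observation noise scale is configurable: additive Gaussian on
log10 counts (default; the data span several decades) or on the linear
count scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .cohort import PreparedPatient
from .kinetics.models import (
    GAMMA_DEG_DEFAULT,
    EffectVector,
    KineticModel,
    ModelKind,
    count_parameters,
)
from .kinetics.solutions import cascade_kernel

__all__ = [
    "EffectStructure",
    "FitConfig",
    "PopulationEstimate",
    "ConditionalFit",
    "build_effect_structure",
    "compose_effects",
    "extract_random_effects",
    "patient_loglik",
    "conditional_mode",
    "marginal_loglik_foce",
    "fit_population",
    "laplace_marginal",
    "gauss_newton_mode",
]

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)
_LN10 = math.log(10.0)

#: Default transformed-scale (log) bounds per effect, spanning the
#: physiologic decades of the measured data.
DEFAULT_BETA_BOUNDS = {
    "B0": (math.log(1e10), math.log(1.2e12)),
    "c0pb": (math.log(1e3), math.log(1e9)),
    "gamma_d": (math.log(1e-2), math.log(1e2)),
    "s_c": (math.log(1e-3), math.log(1e2)),   # bound on s_c - 1
    "alpha": (math.log(1e-6), 0.0),
    "gamma_t": (math.log(1e-2), math.log(1e2)),
}
#: Bounds for random-effect log-variances delta.
DEFAULT_DELTA_BOUNDS = (math.log(1e-4), math.log(4.0))
#: Bounds for log(sigma_c) per noise scale.
DEFAULT_LOG_SIGMA_BOUNDS = {"log10": (math.log(1e-3), math.log(2.0)),
                            "linear": (math.log(1.0), math.log(1e12))}


@dataclass(frozen=True)
class EffectStructure:
    """Design of the mixed-effects composition for one model.

    ``beta_names`` lists the fixed-effect vector entries: the mean of every
    mixed effect (canonical parameter order) followed by the shared
    transition rate where the model has one.  ``random_names`` lists the
    mixed effects, which are exactly the entries receiving a random
    contribution.
    """

    model: KineticModel
    beta_names: tuple[str, ...]
    random_names: tuple[str, ...]
    gamma_deg: float = GAMMA_DEG_DEFAULT

    @property
    def n_beta(self) -> int:
        return len(self.beta_names)

    @property
    def n_random(self) -> int:
        return len(self.random_names)

    @property
    def n_population(self) -> int:
        """Total estimated population parameters (beta + delta + sigma_c)."""
        return self.n_beta + self.n_random + 1


_MIXED = {
    ModelKind.ONE_STEP: ("c0pb", "alpha"),
    ModelKind.TWO_STEP: ("B0", "c0pb", "alpha"),
    ModelKind.THREE_STEP: ("B0", "c0pb", "gamma_d", "s_c", "alpha"),
}


def build_effect_structure(model: KineticModel, gamma_deg: float = GAMMA_DEG_DEFAULT) -> EffectStructure:
    """Mixed/fixed-effect partition for a model."""
    mixed = _MIXED[model.kind]
    shared = () if model.kind is ModelKind.ONE_STEP else ("gamma_t",)
    structure = EffectStructure(model, mixed + shared, mixed, gamma_deg)
    expected_pop, expected_rand = count_parameters(model)
    assert structure.n_population == expected_pop and structure.n_random == expected_rand
    return structure


def _inverse_link(name: str, value: float) -> float:
    """Transformed scale -> natural scale."""
    if name == "s_c":
        return 1.0 + math.exp(value)
    return math.exp(value)


def link(name: str, natural: float) -> float:
    """Natural scale -> transformed scale."""
    if name == "s_c":
        if natural <= 1.0:
            raise ValueError(f"s_c must be > 1 on the transformed scale, got {natural!r}")
        return math.log(natural - 1.0)
    return math.log(natural)


def compose_effects(structure: EffectStructure, beta, b=None) -> EffectVector:
    """Assemble natural-scale effects from fixed effects and one patient's b."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (structure.n_beta,):
        raise ValueError(f"beta must have shape ({structure.n_beta},), got {beta.shape}")
    if b is None:
        b = np.zeros(structure.n_random)
    b = np.asarray(b, dtype=float)
    if b.shape != (structure.n_random,):
        raise ValueError(f"b must have shape ({structure.n_random},), got {b.shape}")
    values = {}
    for i, name in enumerate(structure.beta_names):
        phi = beta[i]
        if name in structure.random_names:
            phi = phi + b[structure.random_names.index(name)]
        values[name] = _inverse_link(name, phi)
    return EffectVector(gamma_deg=structure.gamma_deg, **values)


def extract_random_effects(structure: EffectStructure, beta, effects: EffectVector) -> np.ndarray:
    """Invert :func:`compose_effects` for the random-effect entries."""
    beta = np.asarray(beta, dtype=float)
    out = np.empty(structure.n_random)
    for j, name in enumerate(structure.random_names):
        i = structure.beta_names.index(name)
        out[j] = link(name, getattr(effects, name)) - beta[i]
    return out


# ---------------------------------------------------------------------------
# observation model

@dataclass
class _PatientArrays:
    """Cached numpy views of one prepared patient's observations."""

    t_blast: np.ndarray
    blast: np.ndarray
    blast_sd: np.ndarray
    t_ctdna: np.ndarray
    ctdna: np.ndarray
    log10_ctdna: np.ndarray

    @classmethod
    def from_patient(cls, p: PreparedPatient) -> "_PatientArrays":
        if p.blast_sds is None:
            raise ValueError(f"patient {p.patient_id}: blast noise sds not attached")
        ct = np.asarray(p.ctdna_counts, dtype=float)
        with np.errstate(divide="ignore"):
            log10 = np.log10(ct)
        return cls(
            np.asarray(p.blast_times, dtype=float),
            np.asarray(p.blast_counts, dtype=float),
            np.asarray(p.blast_sds, dtype=float),
            np.asarray(p.ctdna_times, dtype=float),
            ct,
            log10,
        )


def _nat_from_effects(structure: EffectStructure, effects: EffectVector) -> np.ndarray:
    """Natural-scale effect array in ``structure.beta_names`` order."""
    return np.array([getattr(effects, n) for n in structure.beta_names])


def _nat_from_beta_b(structure: EffectStructure, beta: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Compose natural-scale effects directly on arrays (fitting hot path)."""
    phi = beta.copy()
    phi[: structure.n_random] += b
    nat = np.exp(phi)
    if structure.model.kind is ModelKind.THREE_STEP:
        nat[3] += 1.0  # s_c = 1 + exp(phi_sc)
    return nat


def _kernels_three_step(gd: float, gt: float, gg: float, t: np.ndarray):
    """e_gd, e_gg, E2(gt,gg), E3(gd,gt,gg), E4(gd,gd,gt,gg).

    Inline distinct-rate formulas; falls back to the branch-aware
    :func:`cascade_kernel` near rate degeneracies.
    """
    gap = min(abs(gt - gd), abs(gg - gd), abs(gg - gt)) / max(gd, gt, gg)
    e_d = np.exp(-gd * t)
    e_g = np.exp(-gg * t)
    if gap < 1e-6:
        return (
            e_d,
            e_g,
            cascade_kernel((gt, gg), t),
            cascade_kernel((gd, gt, gg), t),
            cascade_kernel((gd, gd, gt, gg), t),
        )
    e_t = np.exp(-gt * t)
    E2_tg = (e_t - e_g) / (gg - gt)
    E2_dt = (e_d - e_t) / (gt - gd)
    E2_dd = t * e_d
    E3 = (E2_dt - E2_tg) / (gg - gd)
    E3_ddt = (E2_dd - E2_dt) / (gt - gd)
    E4 = (E3_ddt - E3) / (gg - gd)
    return e_d, e_g, E2_tg, E3, E4


def _residuals(
    structure: EffectStructure,
    arrays: _PatientArrays,
    nat: np.ndarray,
    sigma_c: float,
    noise_scale: str,
    use_blasts: bool,
    use_ctdna: bool,
    with_jac: bool,
):
    """Weighted residual vector (and Jacobian w.r.t. b) plus the log-density
    normalization constant of the used observations.

    ``nat`` holds the natural-scale effects in ``structure.beta_names``
    order.  Jacobian columns are w.r.t. the random effects b (chain rule
    through the links: d nat/d b = nat, except s_c where it is nat - 1).
    """
    kind = structure.model.kind
    if kind is ModelKind.ONE_STEP:
        use_blasts = False  # the model has no blast observable
    gg = structure.gamma_deg
    nr = structure.n_random
    n_c = arrays.t_ctdna.size if use_ctdna else 0
    n_b = arrays.t_blast.size if use_blasts else 0
    r = np.empty(n_c + n_b)
    J = np.zeros((n_c + n_b, nr)) if with_jac else None
    norm_const = 0.0

    # d(natural)/d(b_j) for each random effect
    link_scale = nat[:nr].copy()
    if kind is ModelKind.THREE_STEP:
        link_scale[3] = nat[3] - 1.0

    if use_ctdna:
        t = arrays.t_ctdna
        if kind is ModelKind.ONE_STEP:
            c0pb, alpha = nat
            e_g = np.exp(-gg * t)
            cpb = c0pb * e_g
            dcpb = (e_g, None)
        elif kind is ModelKind.TWO_STEP:
            B0, c0pb, alpha, gt = nat
            E2 = cascade_kernel((gt, gg), t)
            e_g = np.exp(-gg * t)
            cpb = gt * B0 * E2 + c0pb * e_g
            dcpb = (gt * E2, e_g, None)
        else:
            B0, c0pb, gd, sc, alpha, gt = nat
            e_d, e_g, E2, E3, E4 = _kernels_three_step(gd, gt, gg, t)
            cpb = gd * gt * B0 * E3 + gg * sc * c0pb * E2 + c0pb * e_g
            dcpb = (
                gd * gt * E3,                      # B0
                gg * sc * E2 + e_g,                # c0pb
                gt * B0 * E3 - gd * gt * B0 * E4,  # gamma_d
                gg * c0pb * E2,                    # s_c
                None,                              # alpha (handled below)
            )
        y = alpha * cpb
        if noise_scale == "log10":
            r[:n_c] = (np.log10(y) - arrays.log10_ctdna) / sigma_c
            w = 1.0 / (y * _LN10 * sigma_c)  # d r / d y
        elif noise_scale == "linear":
            r[:n_c] = (y - arrays.ctdna) / sigma_c
            w = 1.0 / sigma_c
        else:
            raise ValueError(f"unknown ctdna noise scale {noise_scale!r}")
        norm_const += -n_c * (0.5 * _LOG2PI + math.log(sigma_c))
        if with_jac:
            for j, name in enumerate(structure.random_names):
                if name == "alpha":
                    J[:n_c, j] = w * cpb * link_scale[j]
                else:
                    g = dcpb[j]
                    if g is not None:
                        J[:n_c, j] = w * alpha * g * link_scale[j]
    if use_blasts and n_b:
        t = arrays.t_blast
        if kind is ModelKind.TWO_STEP:
            B0, rate = nat[0], nat[3]
            rate_j = None  # gamma_t carries no random effect
        else:
            B0, rate = nat[0], nat[2]
            rate_j = 2  # gamma_d
        e = np.exp(-rate * t)
        yb = B0 * e
        r[n_c:] = (yb - arrays.blast) / arrays.blast_sd
        norm_const += float(-np.sum(0.5 * _LOG2PI + np.log(arrays.blast_sd)))
        if with_jac:
            J[n_c:, 0] = e / arrays.blast_sd * link_scale[0]
            if rate_j is not None:
                J[n_c:, rate_j] = -B0 * t * e / arrays.blast_sd * link_scale[rate_j]
    return r, J, norm_const


def patient_loglik(
    patient: PreparedPatient,
    effects: EffectVector,
    sigma_c: float,
    noise_scale: str = "log10",
    use_blasts: bool = True,
    use_ctdna: bool = True,
    structure: EffectStructure | None = None,
) -> float:
    """Gaussian observation log-likelihood of one patient.

    Blast counts enter on the linear scale with their attached sds; ctDNA
    counts on the configured noise scale with sd ``sigma_c``.  Returns -inf
    (with a log record) if the model output is non-finite.
    """
    if structure is None:
        raise ValueError("structure is required")
    arrays = _PatientArrays.from_patient(patient)
    nat = _nat_from_effects(structure, effects)
    r, _, norm = _residuals(
        structure, arrays, nat, sigma_c, noise_scale, use_blasts, use_ctdna, False
    )
    if not np.all(np.isfinite(r)):
        logger.warning("non-finite model output for patient %s", patient.patient_id)
        return -np.inf
    return float(-0.5 * np.sum(r**2) + norm)


# ---------------------------------------------------------------------------
# generic Gauss-Newton conditional mode + Laplace marginal

@dataclass
class ConditionalFit:
    """Result of a conditional random-effect optimization."""

    b_hat: np.ndarray
    curvature: np.ndarray        # negative Hessian (Gauss-Newton) of the joint
    joint_loglik: float          # observation loglik + random-effect prior at b_hat
    converged: bool
    n_iter: int


def gauss_newton_mode(
    residual_fn,
    d_diag: np.ndarray,
    b0: np.ndarray | None = None,
    max_iter: int = 100,
    gtol: float = 1e-10,
) -> ConditionalFit:
    """Maximize ``-0.5 ||r(b)||^2 - 0.5 b' D^-1 b`` by damped Gauss-Newton.

    ``residual_fn(b) -> (r, J, norm_const)`` supplies the weighted residual
    vector, its Jacobian w.r.t. b, and the Gaussian normalization constant
    of the observation density.  The returned curvature is the
    positive-semidefinite Gauss-Newton matrix ``J'J + D^-1``.
    """
    d_diag = np.asarray(d_diag, dtype=float)
    n = d_diag.size
    d_inv = 1.0 / d_diag
    b = np.zeros(n) if b0 is None else np.array(b0, dtype=float)

    def objective(bv):
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                r, J, norm = residual_fn(bv)
        except (ValueError, OverflowError, FloatingPointError):
            return np.inf, None, None, None
        if not np.all(np.isfinite(r)):
            return np.inf, None, None, None
        f = 0.5 * float(r @ r) + 0.5 * float(bv * d_inv @ bv)
        return f, r, J, norm

    f, r, J, norm = objective(b)
    if not np.isfinite(f) and b0 is not None:
        b = np.zeros(n)
        f, r, J, norm = objective(b)
    if not np.isfinite(f):
        raise RuntimeError("conditional objective is non-finite at b = 0")
    lam = 1e-4
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = J.T @ r + d_inv * b
        H = J.T @ J
        H[np.diag_indices(n)] += d_inv
        if float(np.max(np.abs(g))) < gtol * max(1.0, abs(f)):
            converged = True
            break
        # Levenberg damping on the GN system
        accepted = False
        for _ in range(25):
            Hd = H.copy()
            Hd[np.diag_indices(n)] *= 1.0 + lam
            try:
                step = np.linalg.solve(Hd, -g)
            except np.linalg.LinAlgError:
                lam = max(lam, 1e-8) * 10
                continue
            predicted = -(g @ step) - 0.5 * float(step @ (H @ step))
            if predicted <= 1e-12 * max(1.0, abs(f)):
                # no float-resolvable improvement left
                converged = True
                break
            f_new, r_new, J_new, norm_new = objective(b + step)
            if np.isfinite(f_new) and f_new < f:
                b = b + step
                f, r, J, norm = f_new, r_new, J_new, norm_new
                lam = max(lam / 5, 1e-10)
                accepted = True
                break
            lam = max(lam, 1e-8) * 10
        if not accepted:
            break
    curvature = J.T @ J + np.diag(d_inv)
    prior = -0.5 * float(b * d_inv @ b) - 0.5 * float(np.sum(np.log(d_diag))) - 0.5 * n * _LOG2PI
    joint = -0.5 * float(r @ r) + norm + prior
    if not converged and it == max_iter:
        logger.debug("conditional mode: no convergence after %d iterations", max_iter)
    return ConditionalFit(b, curvature, joint, converged, it)


def laplace_marginal(residual_fn, d_diag, b0=None) -> tuple[float, ConditionalFit]:
    """Laplace (first-order conditional) approximation of the marginal loglik.

    ``log p(y) ~= joint(b_hat) + (n/2) log 2pi - 0.5 log det(curvature)``.
    Exact when the residuals are linear in b.  A singular curvature is
    ridge-regularized with a warning.
    """
    fit = gauss_newton_mode(residual_fn, d_diag, b0=b0)
    H = fit.curvature
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0 or not np.isfinite(logdet):
        logger.warning("singular conditional curvature; applying ridge")
        H = H + 1e-8 * np.eye(H.shape[0]) * max(1.0, float(np.max(np.abs(H))))
        _, logdet = np.linalg.slogdet(H)
    ll = fit.joint_loglik + 0.5 * H.shape[0] * _LOG2PI - 0.5 * logdet
    return float(ll), fit


# ---------------------------------------------------------------------------
# batched cohort objective (vectorized across patients; used by fit_population)

class _BatchedCohort:
    """All patients' observations concatenated for vectorized inner solves.

    Computes the same per-patient Laplace terms as :func:`laplace_marginal`
    over :func:`_make_residual_fn`, but runs the damped Gauss-Newton inner
    iterations for every patient simultaneously (batched 5x5 solves and
    segment reductions), which makes the outer multi-start optimization
    tractable on one CPU.
    """

    def __init__(self, structure: EffectStructure, arrays: list[_PatientArrays], noise_scale: str):
        self.structure = structure
        self.noise_scale = noise_scale
        kind = structure.model.kind
        self.kind = kind
        self.K = len(arrays)
        self.nr = structure.n_random
        self.nb = structure.n_beta
        self.alpha_idx = structure.beta_names.index("alpha")
        self.use_blasts = kind is not ModelKind.ONE_STEP

        self.t_c = np.concatenate([a.t_ctdna for a in arrays])
        self.idx_c = np.concatenate(
            [np.full(a.t_ctdna.size, k) for k, a in enumerate(arrays)]
        ).astype(np.intp)
        self.log10_c = np.concatenate([a.log10_ctdna for a in arrays])
        self.obs_c = np.concatenate([a.ctdna for a in arrays])
        self.n_c = np.array([a.t_ctdna.size for a in arrays])

        if self.use_blasts:
            self.t_b = np.concatenate([a.t_blast for a in arrays])
            self.idx_b = np.concatenate(
                [np.full(a.t_blast.size, k) for k, a in enumerate(arrays)]
            ).astype(np.intp)
            self.obs_b = np.concatenate([a.blast for a in arrays])
            self.sd_b = np.concatenate([a.blast_sd for a in arrays])
            self.norm_b = np.array(
                [float(-np.sum(0.5 * _LOG2PI + np.log(a.blast_sd))) for a in arrays]
            )
        else:
            self.norm_b = np.zeros(self.K)

    # -- model evaluation ---------------------------------------------------
    def _nat(self, beta: np.ndarray, b: np.ndarray) -> np.ndarray:
        phi = np.broadcast_to(beta, (self.K, self.nb)).copy()
        phi[:, : self.nr] += b
        with np.errstate(over="ignore"):
            nat = np.exp(phi)
        if self.kind is ModelKind.THREE_STEP:
            nat[:, 3] += 1.0
        return nat

    def _eval(self, beta: np.ndarray, b: np.ndarray, sigma_c: float):
        """Per-patient objective f, gradient g and GN Hessian H (w.r.t. b)."""
        K, nr = self.K, self.nr
        gg = self.structure.gamma_deg
        nat = self._nat(beta, b)
        feasible = nat[:, self.alpha_idx] <= 1.0
        feasible &= np.all(np.isfinite(nat), axis=1)

        t = self.t_c
        idx = self.idx_c
        e_g = np.exp(-gg * t)
        dcol = {}
        if self.kind is ModelKind.ONE_STEP:
            c0pb, alpha = nat[idx, 0], nat[idx, 1]
            cpb = c0pb * e_g
            dcol[0] = e_g
        elif self.kind is ModelKind.TWO_STEP:
            B0, c0pb, alpha = nat[idx, 0], nat[idx, 1], nat[idx, 2]
            gt = nat[idx, 3]
            E2 = (np.exp(-gt * t) - e_g) / (gg - gt)
            cpb = gt * B0 * E2 + c0pb * e_g
            dcol[0] = gt * E2
            dcol[1] = e_g
        else:
            B0, c0pb, gd, sc, alpha = (nat[idx, j] for j in range(5))
            gt = nat[idx, 5]
            e_d = np.exp(-gd * t)
            e_t = np.exp(-gt * t)
            E2_tg = (e_t - e_g) / (gg - gt)
            E2_dt = (e_d - e_t) / (gt - gd)
            E3 = (E2_dt - E2_tg) / (gg - gd)
            E3_ddt = (t * e_d - E2_dt) / (gt - gd)
            E4 = (E3_ddt - E3) / (gg - gd)
            cpb = gd * gt * B0 * E3 + gg * sc * c0pb * E2_tg + c0pb * e_g
            dcol[0] = gd * gt * E3
            dcol[1] = gg * sc * E2_tg + e_g
            dcol[2] = gt * B0 * E3 - gd * gt * B0 * E4
            dcol[3] = gg * c0pb * E2_tg
            # patients whose rates sit near a degeneracy branch: redo exactly
            gd_k, gt_k = nat[:, 2], nat[:, 5]
            gaps = np.minimum(np.abs(gt_k - gd_k), np.abs(gg - gd_k))
            gaps = np.minimum(gaps, np.abs(gg - gt_k))
            gaps /= np.maximum(np.maximum(gd_k, gt_k), gg)
            for k in np.nonzero(gaps < 1e-6)[0]:
                m = idx == k
                tk = t[m]
                gdk, gtk, sck, B0k, c0k = nat[k, 2], nat[k, 5], nat[k, 3], nat[k, 0], nat[k, 1]
                e_dk, e_gk, E2k, E3k, E4k = _kernels_three_step(gdk, gtk, gg, tk)
                cpb[m] = gdk * gtk * B0k * E3k + gg * sck * c0k * E2k + c0k * e_gk
                dcol[0][m] = gdk * gtk * E3k
                dcol[1][m] = gg * sck * E2k + e_gk
                dcol[2][m] = gtk * B0k * E3k - gdk * gtk * B0k * E4k
                dcol[3][m] = gg * c0k * E2k

        y = alpha * cpb
        if self.noise_scale == "log10":
            with np.errstate(divide="ignore", invalid="ignore"):
                r_c = (np.log10(y) - self.log10_c) / sigma_c
                w = 1.0 / (y * _LN10 * sigma_c)
        else:
            r_c = (y - self.obs_c) / sigma_c
            w = np.full_like(y, 1.0 / sigma_c)

        link = nat[:, :nr].copy()
        if self.kind is ModelKind.THREE_STEP:
            link[:, 3] = nat[:, 3] - 1.0
        link_e = link[idx]

        J_c = np.empty((t.size, nr))
        for j, name in enumerate(self.structure.random_names):
            if name == "alpha":
                J_c[:, j] = w * cpb * link_e[:, j]
            elif j in dcol:
                J_c[:, j] = w * alpha * dcol[j] * link_e[:, j]
            else:  # pragma: no cover - no such effect in current structures
                J_c[:, j] = 0.0

        parts_r = [(r_c, J_c, idx)]
        if self.use_blasts:
            tb = self.t_b
            idxb = self.idx_b
            if self.kind is ModelKind.TWO_STEP:
                B0b, rate = nat[idxb, 0], nat[idxb, 3]
                rate_j = None
            else:
                B0b, rate = nat[idxb, 0], nat[idxb, 2]
                rate_j = 2
            e_b = np.exp(-rate * tb)
            yb = B0b * e_b
            r_b = (yb - self.obs_b) / self.sd_b
            J_b = np.zeros((tb.size, nr))
            J_b[:, 0] = e_b / self.sd_b * link[idxb, 0]
            if rate_j is not None:
                J_b[:, rate_j] = -B0b * tb * e_b / self.sd_b * link[idxb, rate_j]
            parts_r.append((r_b, J_b, idxb))

        f = np.zeros(K)
        g = np.zeros((K, nr))
        H = np.zeros((K, nr, nr))
        ok = np.ones(K, dtype=bool)
        for r, J, ix in parts_r:
            finite = np.isfinite(r)
            if not finite.all():
                bad = np.unique(ix[~finite])
                ok[bad] = False
                r = np.where(finite, r, 0.0)
                J = np.where(finite[:, None], J, 0.0)
            f += 0.5 * np.bincount(ix, weights=r * r, minlength=K)
            for j in range(nr):
                g[:, j] += np.bincount(ix, weights=J[:, j] * r, minlength=K)
                for l in range(j, nr):
                    h = np.bincount(ix, weights=J[:, j] * J[:, l], minlength=K)
                    H[:, j, l] += h
                    if l != j:
                        H[:, l, j] += h
        ok &= feasible
        f[~ok] = np.inf
        return f, g, H

    # -- batched inner optimization -----------------------------------------
    def neg_marginal(self, beta, delta, sigma_c, warm_b=None, max_iter=100, gtol=1e-10):
        """-sum_k Laplace marginal loglik; returns (value, b_hat matrix)."""
        K, nr = self.K, self.nr
        d_diag = np.exp(np.asarray(delta, dtype=float))
        d_inv = 1.0 / d_diag
        b = np.zeros((K, nr)) if warm_b is None else np.array(warm_b, dtype=float)

        def full_eval(bmat):
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                f, g, H = self._eval(beta, bmat, sigma_c)
            f = f + 0.5 * np.sum(bmat**2 * d_inv, axis=1)
            g = g + bmat * d_inv
            H = H + np.diag(d_inv)
            return f, g, H

        f, g, H = full_eval(b)
        if not np.all(np.isfinite(f)):
            bad = ~np.isfinite(f)
            b[bad] = 0.0
            f, g, H = full_eval(b)
        lam = np.full(K, 1e-4)
        active = np.ones(K, dtype=bool)
        for _ in range(max_iter):
            gmax = np.max(np.abs(g), axis=1)
            active &= gmax >= gtol * np.maximum(1.0, np.abs(f))
            if not active.any():
                break
            Hd = H.copy()
            di = np.diag_indices(nr)
            Hd[:, di[0], di[1]] *= (1.0 + lam)[:, None]
            try:
                step = np.linalg.solve(Hd, -g[..., None])[..., 0]
            except np.linalg.LinAlgError:
                jitter = 1e-10 * np.eye(nr)
                step = np.linalg.solve(Hd + jitter, -g[..., None])[..., 0]
            predicted = -np.einsum("kj,kj->k", g, step) - 0.5 * np.einsum(
                "kj,kjl,kl->k", step, H, step
            )
            resolvable = predicted > 1e-12 * np.maximum(1.0, np.abs(f))
            active &= resolvable
            if not active.any():
                break
            b_try = np.where(active[:, None], b + step, b)
            f_new, g_new, H_new = full_eval(b_try)
            accept = active & np.isfinite(f_new) & (f_new < f)
            b = np.where(accept[:, None], b_try, b)
            f = np.where(accept, f_new, f)
            g = np.where(accept[:, None], g_new, g)
            H = np.where(accept[:, None, None], H_new, H)
            lam = np.where(accept, np.maximum(lam / 5, 1e-10), np.maximum(lam, 1e-8) * 10)
            # patients whose damping exploded make no further progress
            active &= lam < 1e12

        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):  # pragma: no cover - PSD by construction
            H = H + 1e-8 * np.eye(nr)
            sign, logdet = np.linalg.slogdet(H)
        norm_c = -self.n_c * (0.5 * _LOG2PI + math.log(sigma_c))
        ll = -f + norm_c + self.norm_b - 0.5 * float(np.sum(delta)) - 0.5 * logdet
        return -float(np.sum(ll)), b


# ---------------------------------------------------------------------------
# kinetic-model specialization

def _make_residual_fn(
    structure: EffectStructure,
    arrays: _PatientArrays,
    beta: np.ndarray,
    sigma_c: float,
    noise_scale: str,
    use_blasts: bool,
    use_ctdna: bool,
):
    alpha_idx = structure.beta_names.index("alpha")

    def fn(b):
        nat = _nat_from_beta_b(structure, beta, b)
        if nat[alpha_idx] > 1.0:
            raise ValueError("alpha > 1 is infeasible")
        return _residuals(
            structure, arrays, nat, sigma_c, noise_scale, use_blasts, use_ctdna, True
        )

    return fn


def conditional_mode(
    patient: PreparedPatient,
    structure: EffectStructure,
    beta,
    delta,
    sigma_c: float,
    noise_scale: str = "log10",
    use_blasts: bool = True,
    use_ctdna: bool = True,
    b0=None,
) -> ConditionalFit:
    """Conditional mode of one patient's random effects given the population.

    Maximizes ``patient_loglik(phi(beta, b)) + log N(b; 0, D)`` over b and
    returns the mode with its Gauss-Newton curvature.
    """
    if not use_blasts and not use_ctdna:
        raise ValueError("at least one observable must be used")
    arrays = _PatientArrays.from_patient(patient)
    d_diag = np.exp(np.asarray(delta, dtype=float))
    fn = _make_residual_fn(
        structure, arrays, np.asarray(beta, float), sigma_c, noise_scale, use_blasts, use_ctdna
    )
    return gauss_newton_mode(fn, d_diag, b0=b0)


def marginal_loglik_foce(
    patients: list[PreparedPatient],
    structure: EffectStructure,
    beta,
    delta,
    sigma_c: float,
    noise_scale: str = "log10",
    warm_starts: dict | None = None,
) -> float:
    """Population marginal log-likelihood (sum of per-patient Laplace terms)."""
    beta = np.asarray(beta, dtype=float)
    d_diag = np.exp(np.asarray(delta, dtype=float))
    total = 0.0
    for p in patients:
        arrays = _PatientArrays.from_patient(p)
        fn = _make_residual_fn(structure, arrays, beta, sigma_c, noise_scale, True, True)
        b0 = warm_starts.get(p.patient_id) if warm_starts is not None else None
        ll, fit = laplace_marginal(fn, d_diag, b0=b0)
        if warm_starts is not None:
            warm_starts[p.patient_id] = fit.b_hat
        total += ll
    return total


# ---------------------------------------------------------------------------
# population fitting

@dataclass
class FitConfig:
    """Configuration of the multi-start population fit."""

    n_starts: int = 300
    seed: int = 1
    ctdna_noise_scale: str = "log10"
    beta_bounds: dict = field(default_factory=lambda: dict(DEFAULT_BETA_BOUNDS))
    delta_bounds: tuple = DEFAULT_DELTA_BOUNDS
    maxiter: int = 500

    @classmethod
    def fast(cls, **kwargs) -> "FitConfig":
        """Reduced profile (30 starts, capped iterations) for tests/smoke runs."""
        kwargs.setdefault("n_starts", 30)
        kwargs.setdefault("maxiter", 200)
        return cls(**kwargs)


@dataclass
class PopulationEstimate:
    """Population-level estimate with multi-start metadata."""

    structure: EffectStructure
    beta: np.ndarray             # transformed scale
    delta: np.ndarray            # log variances of random effects
    sigma_c: float
    loglik: float
    multistart_table: list      # dicts: start, objective (loglik), converged
    seed: int
    noise_scale: str = "log10"

    @property
    def d_diag(self) -> np.ndarray:
        return np.exp(self.delta)

    def typical_effects(self) -> EffectVector:
        """Natural-scale effects of the typical patient (b = 0)."""
        return compose_effects(self.structure, self.beta)

    def waterfall(self) -> np.ndarray:
        """Final log-likelihoods sorted best-first (failed starts as -inf)."""
        vals = [
            row["loglik"] if row["loglik"] is not None else -np.inf
            for row in self.multistart_table
        ]
        return np.sort(np.asarray(vals, dtype=float))[::-1]

    def to_dict(self) -> dict:
        typ = self.typical_effects()
        return {
            "model": self.structure.model.kind.value,
            "beta_names": list(self.structure.beta_names),
            "random_names": list(self.structure.random_names),
            "beta_transformed": [float(x) for x in self.beta],
            "typical_values_natural": {
                n: float(getattr(typ, n)) for n in self.structure.beta_names
            },
            "delta_log_variance": [float(x) for x in self.delta],
            "sigma_c": float(self.sigma_c),
            "noise_scale": self.noise_scale,
            "loglik": float(self.loglik),
            "seed": self.seed,
            "n_population_parameters": self.structure.n_population,
            "multistart_table": self.multistart_table,
        }


class EstimationFailure(RuntimeError):
    """No start converged; carries the multistart table."""

    def __init__(self, message: str, table: list):
        super().__init__(message)
        self.table = table


def _pack_bounds(structure: EffectStructure, config: FitConfig) -> list[tuple[float, float]]:
    bounds = [config.beta_bounds[name] for name in structure.beta_names]
    bounds += [config.delta_bounds] * structure.n_random
    bounds.append(DEFAULT_LOG_SIGMA_BOUNDS[config.ctdna_noise_scale])
    return bounds


def fit_population(
    patients: list[PreparedPatient],
    model_or_structure,
    config: FitConfig | None = None,
) -> PopulationEstimate:
    """Multi-start maximum (approximate marginal) likelihood estimation.

    Start points are Latin-hypercube samples within the transformed-scale
    bounds; each start runs a bounded quasi-Newton local maximization of the
    Laplace objective.  Deterministic given ``config.seed``.
    """
    if len(patients) < 2:
        raise ValueError("population fitting needs >= 2 patients")
    config = config or FitConfig()
    structure = (
        model_or_structure
        if isinstance(model_or_structure, EffectStructure)
        else build_effect_structure(model_or_structure)
    )
    bounds = _pack_bounds(structure, config)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    n_dim = lo.size
    nb, nr = structure.n_beta, structure.n_random

    arrays = [_PatientArrays.from_patient(p) for p in patients]
    batch = _BatchedCohort(structure, arrays, config.ctdna_noise_scale)

    warm = {"b": None}

    def negloglik(x):
        beta = x[:nb]
        delta = x[nb:nb + nr]
        sigma_c = math.exp(x[-1])
        val, b_hat = batch.neg_marginal(beta, delta, sigma_c, warm_b=warm["b"])
        warm["b"] = b_hat
        if not np.isfinite(val):
            return 1e100
        return val

    sampler = qmc.LatinHypercube(d=n_dim, seed=config.seed)
    starts = lo + sampler.random(config.n_starts) * (hi - lo)

    table = []
    best_x, best_f = None, np.inf
    for i, x0 in enumerate(starts):
        warm["b"] = None
        try:
            res = optimize.minimize(
                negloglik,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": config.maxiter, "eps": 1e-6, "ftol": 1e-11},
            )
            f, x, ok = float(res.fun), res.x, bool(res.success)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("start %d failed: %s", i, exc)
            f, x, ok = np.inf, None, False
        table.append(
            {
                "start_index": i,
                "start_point": [float(v) for v in x0],
                "loglik": (-f if np.isfinite(f) else None),
                "converged": ok,
            }
        )
        if ok and f < best_f:
            best_f, best_x = f, x
    if best_x is None:
        raise EstimationFailure("no multi-start run converged", table)
    return PopulationEstimate(
        structure=structure,
        beta=best_x[:nb].copy(),
        delta=best_x[nb:nb + nr].copy(),
        sigma_c=math.exp(best_x[-1]),
        loglik=-best_f,
        multistart_table=table,
        seed=config.seed,
        noise_scale=config.ctdna_noise_scale,
    )
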
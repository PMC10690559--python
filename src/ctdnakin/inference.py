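"""Single-patient estimation, leave-one-out blast prediction, and the
alpha-based relapse stratification report.

A fitted (or otherwise supplied) population estimate acts as the prior for
one patient's random effects; the conditional mode given any subset of the
observables yields patient-specific parameters and predicted trajectories
for *all* observables — in particular, bone-marrow blast kinetics predicted
from peripheral-blood ctDNA alone.  Prediction uncertainty comes from
linearizing the observable map around the mode (sensitivity x inverse
curvature x sensitivity').
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import PreparedPatient
from .kinetics.models import EffectVector
from .kinetics.solutions import Trajectory, sensitivities_analytic, solve_analytic
from .population import (
    ConditionalFit,
    FitConfig,
    PopulationEstimate,
    compose_effects,
    conditional_mode,
    fit_population,
)

__all__ = [
    "PatientEstimate",
    "LooPrediction",
    "LooReport",
    "AlphaReport",
    "estimate_single_patient",
    "loo_predict_blasts",
    "alpha_relapse_report",
]

logger = logging.getLogger(__name__)

OBSERVABLE_SET = ("y_ctdna", "y_blast")


@dataclass
class PatientEstimate:
    """Conditional estimate of one patient against a population prior."""

    patient_id: str
    b_hat: np.ndarray
    phi_hat: EffectVector
    alpha_hat: float
    predicted: Trajectory
    uncertainty: np.ndarray      # (n_t, n_observables) linearized sd
    conditional: ConditionalFit
    used_observables: tuple


def _prediction_uncertainty(
    population: PopulationEstimate,
    effects: EffectVector,
    fit: ConditionalFit,
    times: np.ndarray,
) -> np.ndarray:
    """Per-time sd of each observable from curvature-based linearization."""
    structure = population.structure
    sens = sensitivities_analytic(structure.model, effects, times)
    n_t, n_obs = times.size, structure.model.n_observables
    # d(observable)/d(b_j): chain through the inverse links
    cols = []
    for name in structure.random_names:
        j = structure.model.parameter_names.index(name)
        scale = getattr(effects, name) - (1.0 if name == "s_c" else 0.0)
        cols.append(sens.values[:, :, j] * scale)
    S = np.stack(cols, axis=-1)          # (n_t, n_obs, n_random)
    cov = np.linalg.inv(fit.curvature)
    var = np.einsum("tij,jk,tik->ti", S, cov, S)
    return np.sqrt(np.maximum(var, 0.0))


def estimate_single_patient(
    patient: PreparedPatient,
    population: PopulationEstimate,
    use_observables: tuple = OBSERVABLE_SET,
    prediction_times=None,
) -> PatientEstimate:
    """Conditional mode of one patient's random effects under the population
    prior, restricted to the selected observables.

    Returns natural-scale effects and predicted trajectories (with
    linearized uncertainty bands) for every observable of the model,
    including the ones not conditioned on.
    """
    bad = set(use_observables) - set(OBSERVABLE_SET)
    if bad:
        raise ValueError(f"unknown observables: {sorted(bad)}")
    if not use_observables:
        raise ValueError("use_observables must be non-empty")
    structure = population.structure
    fit = conditional_mode(
        patient,
        structure,
        population.beta,
        population.delta,
        population.sigma_c,
        noise_scale=population.noise_scale,
        use_blasts="y_blast" in use_observables,
        use_ctdna="y_ctdna" in use_observables,
    )
    effects = compose_effects(structure, population.beta, fit.b_hat)
    if prediction_times is None:
        t_max = max(
            [21.0]
            + list(np.atleast_1d(patient.blast_times))
            + list(np.atleast_1d(patient.ctdna_times))
        )
        prediction_times = np.linspace(0.0, t_max, 106)
    prediction_times = np.asarray(prediction_times, dtype=float)
    traj = solve_analytic(structure.model, effects, prediction_times)
    sd = _prediction_uncertainty(population, effects, fit, prediction_times)
    return PatientEstimate(
        patient_id=patient.patient_id,
        b_hat=fit.b_hat,
        phi_hat=effects,
        alpha_hat=effects.alpha,
        predicted=traj,
        uncertainty=sd,
        conditional=fit,
        used_observables=tuple(use_observables),
    )


@dataclass
class LooPrediction:
    """Blast predictions for one held-out patient."""

    patient_id: str
    status: str                  # "ok" | "failed: <reason>"
    times: np.ndarray
    measured: np.ndarray
    predicted: np.ndarray
    rel_error: np.ndarray        # |pred - meas| / meas, nan for meas == 0
    within_10pct: np.ndarray     # bool per measurement
    alpha_hat: float | None = None


@dataclass
class LooReport:
    predictions: list
    n_ok: int
    n_failed: int

    def fraction_within(self, time_filter=None) -> float:
        """Fraction of patients whose (filtered) measurements are all hit."""
        hits, total = 0, 0
        for p in self.predictions:
            if p.status != "ok":
                total += 1
                continue
            mask = np.ones(p.times.size, dtype=bool)
            if time_filter is not None:
                mask = time_filter(p.times)
            if mask.any():
                total += 1
                hits += bool(np.all(p.within_10pct[mask]))
        return hits / total if total else float("nan")


def loo_predict_blasts(
    patients: list[PreparedPatient],
    model,
    config: FitConfig | None = None,
) -> LooReport:
    """Leave-one-out validation of ctDNA-only blast prediction.

    For each patient: the population is fitted on the remaining patients,
    the held-out patient's random effects are estimated from ctDNA alone
    with that population as prior, and the predicted blast counts at the
    held-out blast measurement times are scored against the measurements —
    a hit is a prediction within 10% of the measured count (within the
    substituted sd band for zero-valued measurements).
    """
    if len(patients) < 3:
        raise ValueError("leave-one-out validation needs >= 3 patients")
    config = config or FitConfig.fast()
    out = []
    for k, held in enumerate(patients):
        rest = patients[:k] + patients[k + 1 :]
        try:
            population = fit_population(rest, model, config)
            est = estimate_single_patient(held, population, use_observables=("y_ctdna",))
        except Exception as exc:
            logger.warning("LOO fold for %s failed: %s", held.patient_id, exc)
            out.append(
                LooPrediction(
                    held.patient_id,
                    f"failed: {exc}",
                    np.asarray(held.blast_times),
                    np.asarray(held.blast_counts),
                    np.full(len(held.blast_times), np.nan),
                    np.full(len(held.blast_times), np.nan),
                    np.zeros(len(held.blast_times), dtype=bool),
                )
            )
            continue
        pred_traj = solve_analytic(
            population.structure.model, est.phi_hat, np.asarray(held.blast_times)
        )
        pred = pred_traj.observable("y_blast")
        meas = np.asarray(held.blast_counts, dtype=float)
        sds = np.asarray(held.blast_sds, dtype=float)
        rel = np.where(meas > 0, np.abs(pred - meas) / np.where(meas > 0, meas, 1.0), np.nan)
        within = np.where(meas > 0, np.abs(pred - meas) <= 0.10 * meas, np.abs(pred) <= sds)
        out.append(
            LooPrediction(
                held.patient_id,
                "ok",
                np.asarray(held.blast_times),
                meas,
                pred,
                rel,
                within.astype(bool),
                alpha_hat=est.alpha_hat,
            )
        )
    n_ok = sum(p.status == "ok" for p in out)
    return LooReport(out, n_ok, len(out) - n_ok)


@dataclass
class AlphaReport:
    """Descriptive alpha-vs-relapse stratification (no hypothesis test)."""

    rows: list                   # dicts: patient_id, alpha, relapse
    n_relapsed: int
    n_non_relapsed: int
    alpha_geo_mean_relapsed: float | None
    alpha_geo_mean_non_relapsed: float | None
    pair_separation: float | None   # P(alpha_relapsed < alpha_non_relapsed), ties 0.5

    def to_dict(self) -> dict:
        return {
            "patients": self.rows,
            "n_relapsed": self.n_relapsed,
            "n_non_relapsed": self.n_non_relapsed,
            "alpha_geo_mean_relapsed": self.alpha_geo_mean_relapsed,
            "alpha_geo_mean_non_relapsed": self.alpha_geo_mean_non_relapsed,
            "pair_separation": self.pair_separation,
        }


def alpha_relapse_report(estimates: list[PatientEstimate], relapse_labels: dict) -> AlphaReport:
    """Rank-based separation of alpha between relapsed and non-relapsed.

    ``pair_separation`` is the fraction of (relapsed, non-relapsed) pairs in
    which the relapsed patient has the smaller alpha; ties count one half.
    Purely descriptive — with cohorts of this size a formal test would
    overreach.
    """
    if len(estimates) < 2:
        raise ValueError("need >= 2 patient estimates")
    seen = set()
    rows = []
    for e in estimates:
        if e.patient_id in seen:
            raise ValueError(f"duplicate estimate for patient {e.patient_id}")
        seen.add(e.patient_id)
        rows.append(
            {
                "patient_id": e.patient_id,
                "alpha": float(e.alpha_hat),
                "relapse": bool(relapse_labels[e.patient_id]),
            }
        )
    rel = [r["alpha"] for r in rows if r["relapse"]]
    non = [r["alpha"] for r in rows if not r["relapse"]]

    def geo(xs):
        return float(np.exp(np.mean(np.log(xs)))) if xs else None

    if rel and non:
        wins = sum(1.0 if a < b else (0.5 if a == b else 0.0) for a in rel for b in non)
        separation = wins / (len(rel) * len(non))
    else:
        separation = None
    return AlphaReport(rows, len(rel), len(non), geo(rel), geo(non), separation)
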
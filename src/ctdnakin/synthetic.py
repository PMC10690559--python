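"""Synthetic cohort generation with retained ground truth.

Patients are drawn with log-normal variability around configurable typical
values (random effects ``b ~ N(0, diag(omega^2))`` composed through the same
links as the estimation code), observed on a clinical-style schedule — two
marrow blast measurements (day 0 and day 16-18) and 2-14 ctDNA samples in
the first 18 days — with 10% multiplicative Gaussian blast noise and
configurable ctDNA noise.  Relapse-designated patients get their mutated
ctDNA fraction alpha shrunk by a configurable factor, mirroring the higher
clonal heterogeneity observed in relapsing disease.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cohort import (
    NUCLEATED_BM_CELLS,
    BLAST_NOISE_CV,
    PatientRecord,
    blasts_count_to_fraction,
    ctdna_count_to_concentration,
    write_cohort,
)
from .kinetics.models import GAMMA_DEG_DEFAULT, EffectVector, three_step, get_model
from .kinetics.solutions import solve_analytic
from .population import EffectStructure, build_effect_structure, compose_effects, link

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "PatientTruth",
    "clinical_defaults",
    "sample_patients",
    "simulate_observations",
    "generate_cohort",
]

#: Plausible typical values at physiologic magnitudes (documented defaults,
#: not literature estimates).  c0pb is the total ctDNA pool across all
#: mutations (large), of which the assayed mutation is the small fraction
#: alpha; with these scales the initial marrow pool and the blast-release
#: flux contribute comparably to the early peripheral-blood signal.
DEFAULT_TYPICAL = {
    "B0": 5e11,
    "c0pb": 1e9,
    "gamma_d": 0.5,
    "s_c": 2.0,
    "alpha": 1e-3,
    "gamma_t": 2.0,
}

DEFAULT_OMEGA = {
    "B0": 0.4,
    "c0pb": 0.5,
    "gamma_d": 0.3,
    "s_c": 0.4,
    "alpha": 0.3,
}


@dataclass
class CohortConfig:
    """Generative configuration of a synthetic cohort."""

    n_patients: int = 10
    mutation_split: dict = field(default_factory=lambda: {"NPM1": 0.7, "IDH2": 0.3})
    typical_values: dict = field(default_factory=lambda: dict(DEFAULT_TYPICAL))
    omega: dict = field(default_factory=lambda: dict(DEFAULT_OMEGA))
    sigma_c: float = 0.1
    ctdna_noise_scale: str = "log10"
    blast_noise_cv: float = BLAST_NOISE_CV
    relapse_fraction: float = 0.3
    relapse_alpha_factor: float = 0.1
    ctdna_n_range: tuple = (2, 14)
    ctdna_t_max: float = 18.0
    blast_second_days: tuple = (16, 17, 18)
    blood_volume_range: tuple = (3.5, 6.0)
    gamma_deg: float = GAMMA_DEG_DEFAULT
    model: str = "three_step"
    seed: int = 1

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.mutation_split.values()) - 1.0) > 1e-9:
            raise ValueError("mutation_split fractions must sum to 1")
        tv = self.typical_values
        if any(v <= 0 for v in tv.values()):
            raise ValueError("typical values must be positive")
        if tv["s_c"] < 1.0:
            raise ValueError("typical s_c must be >= 1")
        if not (0.0 < tv["alpha"] <= 1.0):
            raise ValueError("typical alpha must be in (0, 1]")
        if not (0.0 <= self.relapse_fraction <= 1.0):
            raise ValueError("relapse_fraction must be in [0, 1]")
        lo, hi = self.ctdna_n_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid ctdna_n_range")

    def to_dict(self) -> dict:
        return asdict(self)


def clinical_defaults(**overrides) -> CohortConfig:
    """Ten patients, 7:3 NPM1/IDH2, 3 relapsed, clinical-style schedule."""
    cfg = CohortConfig(**overrides)
    cfg.validate()
    return cfg


@dataclass
class PatientTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    mutation: str
    relapse: bool
    blood_volume: float
    b_true: np.ndarray
    effects: EffectVector


@dataclass
class SyntheticTruth:
    """Generating parameters of a simulated cohort."""

    config: CohortConfig
    structure: EffectStructure
    beta: np.ndarray
    delta: np.ndarray
    patients: list

    def effects_of(self, patient_id: str) -> EffectVector:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p.effects
        raise KeyError(patient_id)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "beta_names": list(self.structure.beta_names),
            "random_names": list(self.structure.random_names),
            "beta": [float(x) for x in self.beta],
            "delta": [float(x) for x in self.delta],
            "patients": [
                {
                    "patient_id": p.patient_id,
                    "mutation": p.mutation,
                    "relapse": p.relapse,
                    "blood_volume": p.blood_volume,
                    "b_true": [float(x) for x in p.b_true],
                    "effects": {
                        n: float(getattr(p.effects, n))
                        for n in ("B0", "c0pb", "gamma_d", "s_c", "alpha", "gamma_t", "gamma_deg")
                    },
                }
                for p in self.patients
            ],
        }


def _truth_beta(structure: EffectStructure, config: CohortConfig) -> np.ndarray:
    return np.array([link(n, config.typical_values[n]) for n in structure.beta_names])


def sample_patients(config: CohortConfig) -> SyntheticTruth:
    """Draw per-patient true effects; deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    model = get_model(config.model)
    structure = build_effect_structure(model, gamma_deg=config.gamma_deg)
    beta = _truth_beta(structure, config)
    omega = np.array([config.omega.get(n, 0.0) for n in structure.random_names])
    # delta is the log of the random-effect variances
    with np.errstate(divide="ignore"):
        delta = np.log(np.maximum(omega, 1e-300) ** 2)

    n = config.n_patients
    n_relapse = int(round(config.relapse_fraction * n))
    relapse_idx = set(rng.choice(n, size=n_relapse, replace=False).tolist())

    mut_names = sorted(config.mutation_split)
    mut_counts = {m: int(round(config.mutation_split[m] * n)) for m in mut_names}
    while sum(mut_counts.values()) > n:
        mut_counts[mut_names[-1]] -= 1
    while sum(mut_counts.values()) < n:
        mut_counts[mut_names[0]] += 1
    mutations = [m for m in mut_names for _ in range(mut_counts[m])]
    rng.shuffle(mutations)

    patients = []
    for k in range(n):
        b = rng.normal(0.0, 1.0, size=structure.n_random) * omega
        relapse = k in relapse_idx
        if relapse and "alpha" in structure.random_names:
            j = structure.random_names.index("alpha")
            b = b.copy()
            b[j] += np.log(config.relapse_alpha_factor)
        effects = compose_effects(structure, beta, b)
        volume = rng.uniform(*config.blood_volume_range)
        patients.append(
            PatientTruth(
                patient_id=f"S{k + 1:02d}",
                mutation=mutations[k],
                relapse=relapse,
                blood_volume=float(volume),
                b_true=b,
                effects=effects,
            )
        )
    return SyntheticTruth(config, structure, beta, delta, patients)


def _positive_noisy(
    rng: np.random.Generator,
    value: float,
    sd: float,
    upper: float = np.inf,
    max_tries: int = 100,
) -> float:
    """Additive Gaussian perturbation, redrawn (not clipped) outside (0, upper]."""
    if sd == 0.0:
        return min(value, upper)
    for _ in range(max_tries):
        v = value + rng.normal(0.0, sd)
        if 0 < v <= upper:
            return v
    return min(value, upper)  # pathological sd; fall back to the noiseless value


def simulate_observations(
    truth: SyntheticTruth, rng: np.random.Generator | None = None
) -> list[PatientRecord]:
    """Simulate the clinical measurement process for every truth patient.

    Blast counts get multiplicative Gaussian noise (cv = config.blast_noise_cv)
    and are reported as marrow fractions; ctDNA counts are perturbed on the
    configured noise scale and reported as concentrations (copies/L).
    """
    config = truth.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0C0]))
    model = get_model(config.model)
    records = []
    for p in truth.patients:
        second_day = float(rng.choice(config.blast_second_days))
        blast_times = np.array([0.0, second_day])
        n_ctdna = int(rng.integers(config.ctdna_n_range[0], config.ctdna_n_range[1] + 1))
        # baseline draw at treatment start plus uniform follow-up sampling
        ctdna_times = np.concatenate(
            [[0.0], np.sort(rng.uniform(0.0, config.ctdna_t_max, size=n_ctdna - 1))]
        )

        grid = np.unique(np.concatenate([blast_times, ctdna_times]))
        traj = solve_analytic(model, p.effects, grid)
        blast_true = np.interp(blast_times, grid, traj.observable("y_blast"))
        ctdna_true = np.interp(ctdna_times, grid, traj.observable("y_ctdna"))

        blast_obs = []
        for t, y in zip(blast_times, blast_true):
            noisy = _positive_noisy(rng, y, config.blast_noise_cv * y, upper=NUCLEATED_BM_CELLS)
            blast_obs.append((float(t), float(blasts_count_to_fraction(noisy))))
        ctdna_obs = []
        for t, y in zip(ctdna_times, ctdna_true):
            if config.ctdna_noise_scale == "log10":
                noisy = 10 ** (np.log10(y) + rng.normal(0.0, config.sigma_c)) if config.sigma_c else y
            elif config.ctdna_noise_scale == "linear":
                noisy = _positive_noisy(rng, y, config.sigma_c)
            else:
                raise ValueError(f"unknown ctdna noise scale {config.ctdna_noise_scale!r}")
            conc = ctdna_count_to_concentration(float(noisy), p.blood_volume)
            ctdna_obs.append((float(t), float(conc)))
        records.append(
            PatientRecord(
                patient_id=p.patient_id,
                mutation=p.mutation,
                relapse=p.relapse,
                blast_obs=blast_obs,
                ctdna_obs=ctdna_obs,
                blood_volume=p.blood_volume,
            )
        )
    return records


def generate_cohort(config: CohortConfig) -> tuple[SyntheticTruth, list[PatientRecord]]:
    """Sample truth and simulate its observations in one call."""
    truth = sample_patients(config)
    return truth, simulate_observations(truth)


def write_truth(truth: SyntheticTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2) + "\n")


def write_synthetic_cohort(config: CohortConfig, out_dir) -> SyntheticTruth:
    """Generate and write cohort files + truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth, records = generate_cohort(config)
    write_cohort(records, out / "observations.csv", out / "covariates.json")
    write_truth(truth, out / "truth.json")
    return truth
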
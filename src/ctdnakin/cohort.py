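"""Cohort data model, file IO, and preprocessing.

Clinical inputs are per-patient longitudinal series: bone-marrow blast
percentage (a fraction of nucleated marrow cells) and mutation-specific
ctDNA concentration in copies per liter of blood.  Preprocessing converts
both to absolute whole-body counts — blasts via a fixed nucleated marrow
cell number, ctDNA via the patient's blood volume (given directly, or
computed from sex/height/weight with the Nadler formula) — aligns
pre-treatment sampling times to t=0, and attaches measurement-noise
standard deviations (10% multiplicative for blasts, with a cohort-level
substitution rule for zero-valued measurements).

File format: a tidy observations CSV
``patient_id, compartment, time_days, value, unit`` with compartment in
{blast_bm, ctdna_pb}, plus a covariates JSON (one record per patient).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NUCLEATED_BM_CELLS",
    "BLAST_NOISE_CV",
    "PatientRecord",
    "PreparedPatient",
    "CohortSummary",
    "nadler_blood_volume",
    "blasts_fraction_to_count",
    "blasts_count_to_fraction",
    "ctdna_concentration_to_count",
    "ctdna_count_to_concentration",
    "align_times",
    "prepare_patient",
    "attach_noise",
    "prepare_cohort",
    "summarize_cohort",
    "read_cohort",
    "write_cohort",
]

logger = logging.getLogger(__name__)

#: Assumed number of nucleated cells in the bone marrow.
NUCLEATED_BM_CELLS = 1.2e12

#: Multiplicative measurement noise of blast counts.
BLAST_NOISE_CV = 0.10

#: Matching window (days) when substituting the noise of zero measurements.
ZERO_SD_MATCH_WINDOW = 1.0

_MUTATIONS = ("NPM1", "IDH2")
_COMPARTMENTS = ("blast_bm", "ctdna_pb")


@dataclass
class PatientRecord:
    """Raw clinical record for one patient.

    ``blast_obs`` holds (time_days, blast fraction in [0, 1]) pairs and
    ``ctdna_obs`` holds (time_days, concentration in copies/L) pairs, with
    times relative to treatment start (negative = pre-treatment sampling).
    """

    patient_id: str
    mutation: str
    relapse: bool
    blast_obs: list[tuple[float, float]]
    ctdna_obs: list[tuple[float, float]]
    sex: str | None = None
    height: float | None = None       # meters
    weight: float | None = None       # kg
    blood_volume: float | None = None  # liters, overrides height/weight

    def __post_init__(self) -> None:
        if self.mutation not in _MUTATIONS:
            raise ValueError(f"mutation must be one of {_MUTATIONS}, got {self.mutation!r}")
        has_anthro = self.sex is not None and self.height is not None and self.weight is not None
        if self.blood_volume is None and not has_anthro:
            raise ValueError(
                f"patient {self.patient_id}: need blood_volume or (sex, height, weight)"
            )
        if len(self.blast_obs) < 1:
            raise ValueError(f"patient {self.patient_id}: need >= 1 blast observation")
        if len(self.ctdna_obs) < 2:
            raise ValueError(f"patient {self.patient_id}: need >= 2 ctDNA observations")
        for t, v in self.blast_obs:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"blast fraction must be in [0, 1], got {v!r}")
            _check_raw_time(t, self.patient_id)
        for t, v in self.ctdna_obs:
            if v < 0:
                raise ValueError(f"ctDNA concentration must be >= 0, got {v!r}")
            _check_raw_time(t, self.patient_id)

    def resolved_blood_volume(self) -> float:
        if self.blood_volume is not None:
            return float(self.blood_volume)
        return nadler_blood_volume(self.sex, self.height, self.weight)


def _check_raw_time(t: float, pid: str) -> None:
    if not (-6.0 <= t <= 30.0):
        raise ValueError(f"patient {pid}: observation time {t!r} outside [-6, 30] days")


@dataclass
class PreparedPatient:
    """Preprocessed patient: whole-body counts on an aligned day axis.

    Blast standard deviations are populated by :func:`attach_noise`; ctDNA
    standard deviations stay ``None`` because the ctDNA noise level is a
    model parameter estimated during fitting.
    """

    patient_id: str
    mutation: str
    relapse: bool
    blood_volume: float
    blast_times: np.ndarray
    blast_counts: np.ndarray
    ctdna_times: np.ndarray
    ctdna_counts: np.ndarray
    blast_sds: np.ndarray | None = None
    ctdna_sds: np.ndarray | None = None


def nadler_blood_volume(sex: str, height_m: float, weight_kg: float) -> float:
    """Total blood volume in liters from sex, height (m) and weight (kg).

    Nadler's regression: males ``0.3669 h^3 + 0.03219 w + 0.6041``,
    females ``0.3561 h^3 + 0.03308 w + 0.1833``.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if not (0.5 < height_m < 2.5) or not (20.0 < weight_kg < 250.0):
        warnings.warn(
            f"anthropometrics out of the usual range (h={height_m} m, w={weight_kg} kg); "
            "blood volume computed anyway",
            stacklevel=2,
        )
    if sex == "male":
        return 0.3669 * height_m**3 + 0.03219 * weight_kg + 0.6041
    return 0.3561 * height_m**3 + 0.03308 * weight_kg + 0.1833


def blasts_fraction_to_count(fraction: float) -> float:
    """Blast fraction of nucleated marrow cells -> absolute blast count."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction!r}")
    return NUCLEATED_BM_CELLS * fraction


def blasts_count_to_fraction(count: float) -> float:
    return count / NUCLEATED_BM_CELLS


def ctdna_concentration_to_count(concentration_per_l: float, blood_volume_l: float) -> float:
    """ctDNA concentration (copies/L) times blood volume (L) -> total copies."""
    if concentration_per_l < 0 or blood_volume_l < 0:
        raise ValueError("concentration and blood volume must be >= 0")
    return concentration_per_l * blood_volume_l


def ctdna_count_to_concentration(count: float, blood_volume_l: float) -> float:
    return count / blood_volume_l


def align_times(record: PatientRecord) -> PatientRecord:
    """Map pre-treatment sampling times onto the treatment start t=0.

    A single pre-treatment time is moved to 0 (no blast proliferation is
    assumed between sampling and treatment start).  With several distinct
    pre-treatment times, the earliest moves to 0 and their relative spacing
    is preserved; this situation is flagged with a warning.  Post-treatment
    times are never changed.  Idempotent on already-aligned records.
    """
    all_times = [t for t, _ in record.blast_obs] + [t for t, _ in record.ctdna_obs]
    if not all_times:
        raise ValueError(f"patient {record.patient_id}: no measurements")
    neg = sorted({t for t in all_times if t < 0})
    if not neg:
        return record
    t_min = neg[0]
    if len(neg) > 1:
        warnings.warn(
            f"patient {record.patient_id}: {len(neg)} distinct pre-treatment times; "
            "earliest mapped to 0, relative spacing preserved",
            stacklevel=2,
        )

    def shift(series):
        return [((t - t_min) if t < 0 else t, v) for t, v in series]

    return replace(record, blast_obs=shift(record.blast_obs), ctdna_obs=shift(record.ctdna_obs))


def prepare_patient(record: PatientRecord) -> PreparedPatient:
    """Align times and convert measurements to whole-body counts."""
    record = align_times(record)
    volume = record.resolved_blood_volume()
    bt = np.array([t for t, _ in record.blast_obs], dtype=float)
    bc = np.array([blasts_fraction_to_count(v) for _, v in record.blast_obs])
    ct = np.array([t for t, _ in record.ctdna_obs], dtype=float)
    cc = np.array([ctdna_concentration_to_count(v, volume) for _, v in record.ctdna_obs])
    b_order = np.argsort(bt, kind="stable")
    c_order = np.argsort(ct, kind="stable")
    return PreparedPatient(
        patient_id=record.patient_id,
        mutation=record.mutation,
        relapse=record.relapse,
        blood_volume=volume,
        blast_times=bt[b_order],
        blast_counts=bc[b_order],
        ctdna_times=ct[c_order],
        ctdna_counts=cc[c_order],
    )


def attach_noise(patients: list[PreparedPatient]) -> list[PreparedPatient]:
    """Attach blast-count noise standard deviations across the cohort.

    sd = 10% of the measured count.  Zero-valued measurements get the mean
    sd of the cohort's non-zero measurements within +-1 day of the same time
    point; if no such measurement exists anywhere in that window, the
    fallback is 10% of the smallest non-zero blast count in the cohort
    (logged).
    """
    nonzero: list[tuple[float, float]] = []  # (time, sd)
    for p in patients:
        for t, c in zip(p.blast_times, p.blast_counts):
            if c > 0:
                nonzero.append((float(t), BLAST_NOISE_CV * float(c)))
    smallest_nonzero = min((c for p in patients for c in p.blast_counts if c > 0), default=None)

    out = []
    for p in patients:
        sds = np.empty_like(p.blast_counts)
        for i, (t, c) in enumerate(zip(p.blast_times, p.blast_counts)):
            if c > 0:
                sds[i] = BLAST_NOISE_CV * c
                continue
            matched = [sd for tt, sd in nonzero if abs(tt - t) <= ZERO_SD_MATCH_WINDOW]
            if matched:
                sds[i] = float(np.mean(matched))
            elif smallest_nonzero is not None:
                sds[i] = BLAST_NOISE_CV * smallest_nonzero
                logger.warning(
                    "patient %s: no non-zero blast measurement within +-%g day of t=%g; "
                    "fallback sd from smallest non-zero cohort count",
                    p.patient_id, ZERO_SD_MATCH_WINDOW, t,
                )
            else:
                raise ValueError("cohort has no non-zero blast measurement at all")
        out.append(replace(p, blast_sds=sds))
    return out


def prepare_cohort(records: list[PatientRecord]) -> list[PreparedPatient]:
    """Full preprocessing: align, convert to counts, attach noise sds."""
    return attach_noise([prepare_patient(r) for r in records])


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    n_by_mutation: dict
    n_relapsed: int
    ctdna_n_mean: float
    ctdna_n_sd: float | None    # sample sd (n-1); None for a single patient
    ctdna_n_min: int
    ctdna_n_max: int
    blast_n_mean: float


def summarize_cohort(cohort) -> CohortSummary:
    """Descriptive summary; accepts raw records or prepared patients."""
    if len(cohort) == 0:
        raise ValueError("cohort must contain at least one patient")

    def n_ctdna(p):
        return len(p.ctdna_obs) if hasattr(p, "ctdna_obs") else len(p.ctdna_times)

    def n_blast(p):
        return len(p.blast_obs) if hasattr(p, "blast_obs") else len(p.blast_times)

    counts = np.array([n_ctdna(p) for p in cohort])
    by_mut: dict[str, int] = {}
    for p in cohort:
        by_mut[p.mutation] = by_mut.get(p.mutation, 0) + 1
    return CohortSummary(
        n_patients=len(cohort),
        n_by_mutation=by_mut,
        n_relapsed=sum(bool(p.relapse) for p in cohort),
        ctdna_n_mean=float(np.mean(counts)),
        ctdna_n_sd=float(np.std(counts, ddof=1)) if len(counts) > 1 else None,
        ctdna_n_min=int(np.min(counts)),
        ctdna_n_max=int(np.max(counts)),
        blast_n_mean=float(np.mean([n_blast(p) for p in cohort])),
    )


# ---------------------------------------------------------------------------
# file IO

def write_cohort(records: list[PatientRecord], obs_csv, covariates_json) -> None:
    """Write a cohort in the canonical tidy format (deterministic ordering)."""
    rows = []
    for r in sorted(records, key=lambda r: r.patient_id):
        for t, v in sorted(r.blast_obs):
            rows.append((r.patient_id, "blast_bm", repr(float(t)), repr(float(v)), "fraction"))
        for t, v in sorted(r.ctdna_obs):
            rows.append((r.patient_id, "ctdna_pb", repr(float(t)), repr(float(v)), "copies_per_L"))
    lines = ["patient_id,compartment,time_days,value,unit"]
    lines += [",".join(row) for row in rows]
    Path(obs_csv).write_text("\n".join(lines) + "\n")

    cov = []
    for r in sorted(records, key=lambda r: r.patient_id):
        cov.append(
            {
                "patient_id": r.patient_id,
                "mutation": r.mutation,
                "relapse": bool(r.relapse),
                "sex": r.sex,
                "height": r.height,
                "weight": r.weight,
                "blood_volume": r.blood_volume,
            }
        )
    Path(covariates_json).write_text(json.dumps(cov, indent=2, sort_keys=True) + "\n")


def read_cohort(obs_csv, covariates_json) -> list[PatientRecord]:
    """Read a cohort written by :func:`write_cohort` (or hand-authored)."""
    obs = pd.read_csv(obs_csv)
    missing = {"patient_id", "compartment", "time_days", "value"} - set(obs.columns)
    if missing:
        raise ValueError(f"observations CSV is missing columns: {sorted(missing)}")
    bad = set(obs["compartment"]) - set(_COMPARTMENTS)
    if bad:
        raise ValueError(f"unknown compartments in observations CSV: {sorted(bad)}")
    cov = json.loads(Path(covariates_json).read_text())

    records = []
    for c in cov:
        pid = c["patient_id"]
        sub = obs[obs["patient_id"].astype(str) == str(pid)]
        blast = [
            (float(t), float(v))
            for t, v in sub[sub["compartment"] == "blast_bm"][["time_days", "value"]].values
        ]
        ctdna = [
            (float(t), float(v))
            for t, v in sub[sub["compartment"] == "ctdna_pb"][["time_days", "value"]].values
        ]
        records.append(
            PatientRecord(
                patient_id=str(pid),
                mutation=c["mutation"],
                relapse=bool(c["relapse"]),
                blast_obs=sorted(blast),
                ctdna_obs=sorted(ctdna),
                sex=c.get("sex"),
                height=c.get("height"),
                weight=c.get("weight"),
                blood_volume=c.get("blood_volume"),
            )
        )
    return records
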
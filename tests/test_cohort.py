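import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdnakin.cohort import (
    NUCLEATED_BM_CELLS,
    CohortSummary,
    PatientRecord,
    align_times,
    attach_noise,
    blasts_count_to_fraction,
    blasts_fraction_to_count,
    ctdna_concentration_to_count,
    ctdna_count_to_concentration,
    nadler_blood_volume,
    prepare_cohort,
    prepare_patient,
    read_cohort,
    summarize_cohort,
    write_cohort,
)

from .conftest import tiny_records

# per-patient ctDNA measurement counts of the clinical cohort
CLINICAL_CTDNA_COUNTS = (9, 2, 9, 7, 5, 12, 12, 14, 6, 11)


class TestNadler:
    def test_male_example(self):
        assert nadler_blood_volume("male", 1.80, 80.0) == pytest.approx(5.319, abs=5e-4)

    def test_female_example(self):
        assert nadler_blood_volume("female", 1.60, 60.0) == pytest.approx(3.627, abs=5e-4)

    @given(h=st.floats(1.4, 2.1), w1=st.floats(40, 150), w2=st.floats(40, 150))
    @settings(max_examples=50, deadline=None)
    def test_weight_monotonicity(self, h, w1, w2):
        if abs(w1 - w2) < 1e-6:
            return
        lo, hi = sorted((w1, w2))
        for sex in ("male", "female"):
            assert nadler_blood_volume(sex, h, lo) < nadler_blood_volume(sex, h, hi)

    def test_unknown_sex(self):
        with pytest.raises(ValueError, match="sex"):
            nadler_blood_volume("other", 1.8, 80.0)

    def test_out_of_range_warns_but_computes(self):
        with pytest.warns(UserWarning, match="range"):
            v = nadler_blood_volume("male", 2.6, 80.0)
        assert v > 0


class TestUnitConversions:
    def test_full_marrow(self):
        assert blasts_fraction_to_count(1.0) == 1.2e12

    def test_zero(self):
        assert blasts_fraction_to_count(0.0) == 0.0

    def test_thirty_percent(self):
        assert blasts_fraction_to_count(0.30) == pytest.approx(3.6e11)

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            blasts_fraction_to_count(1.2)

    def test_ctdna_product(self):
        assert ctdna_concentration_to_count(2.5e4, 4.0) == pytest.approx(1e5)
        assert ctdna_concentration_to_count(0.0, 4.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ctdna_concentration_to_count(-1.0, 4.0)

    @given(st.floats(1e-9, 1.0), st.floats(0.5, 8.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trips(self, frac, volume):
        assert blasts_count_to_fraction(blasts_fraction_to_count(frac)) == pytest.approx(
            frac, rel=1e-12
        )
        conc = frac * 1e6
        count = ctdna_concentration_to_count(conc, volume)
        assert ctdna_count_to_concentration(count, volume) == pytest.approx(conc, rel=1e-12)


class TestAlignTimes:
    def _record(self, blast_obs, ctdna_obs=None):
        return PatientRecord(
            patient_id="X",
            mutation="NPM1",
            relapse=False,
            blast_obs=blast_obs,
            ctdna_obs=ctdna_obs or [(0.0, 1e4), (2.0, 5e3)],
            blood_volume=4.0,
        )

    def test_single_pretreatment_to_zero(self):
        rec = align_times(self._record([(-4.0, 0.5), (16.0, 0.0)]))
        assert [t for t, _ in rec.blast_obs] == [0.0, 16.0]

    def test_idempotent_when_aligned(self):
        rec = self._record([(0.0, 0.5), (16.0, 0.0)])
        assert align_times(rec) == rec

    def test_two_pretreatment_points_keep_spacing(self):
        with pytest.warns(UserWarning, match="pre-treatment"):
            rec = align_times(
                self._record([(16.0, 0.0)], [(-5.0, 1e4), (-2.0, 9e3), (3.0, 1e3)])
            )
        assert [t for t, _ in rec.ctdna_obs] == [0.0, 3.0, 3.0]

    def test_out_of_window_time_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            self._record([(-7.0, 0.5)])


class TestAttachNoise:
    def test_ten_percent_sd(self):
        prep = prepare_cohort(tiny_records())
        for p in prep:
            nz = p.blast_counts > 0
            assert np.allclose(p.blast_sds[nz], 0.10 * p.blast_counts[nz])
            assert np.all(p.blast_sds > 0)

    def test_zero_measurement_substitution(self):
        # cohort of three: two non-zero at day 16 (counts 1e10/1.2e12 and
        # 3e10/1.2e12 scaled), one zero at day 16 -> sd = mean of the others'
        def rec(pid, frac16):
            return PatientRecord(
                patient_id=pid, mutation="NPM1", relapse=False,
                blast_obs=[(0.0, 0.5), (16.0, frac16)],
                ctdna_obs=[(0.0, 1e4), (2.0, 5e3)], blood_volume=4.0,
            )

        f1 = 1e10 / NUCLEATED_BM_CELLS
        f2 = 3e10 / NUCLEATED_BM_CELLS
        prep = prepare_cohort([rec("A", f1), rec("B", f2), rec("C", 0.0)])
        c = next(p for p in prep if p.patient_id == "C")
        assert c.blast_sds[1] == pytest.approx(np.mean([1e9, 3e9]))

    def test_all_positive_cohort_no_substitution(self):
        prep = prepare_cohort(tiny_records())
        # patient P1 has a zero at day 16; rebuild with strictly positive values
        recs = tiny_records()
        for r in recs:
            r.blast_obs = [(t, max(v, 0.01)) for t, v in r.blast_obs]
        prep = prepare_cohort(recs)
        for p in prep:
            assert np.allclose(p.blast_sds, 0.10 * p.blast_counts)

    def test_fallback_when_no_match_in_window(self):
        def rec(pid, frac16, day):
            return PatientRecord(
                patient_id=pid, mutation="NPM1", relapse=False,
                blast_obs=[(0.0, 0.5), (day, frac16)],
                ctdna_obs=[(0.0, 1e4), (2.0, 5e3)], blood_volume=4.0,
            )

        # zero at day 16 with the only non-zero second measurements at day 18
        prep = prepare_cohort([rec("A", 0.02, 18.0), rec("B", 0.0, 16.0)])
        b = next(p for p in prep if p.patient_id == "B")
        smallest_nonzero = 0.02 * NUCLEATED_BM_CELLS
        assert b.blast_sds[1] == pytest.approx(0.10 * smallest_nonzero)


class TestSummarize:
    def _cohort_with_counts(self, counts):
        out = []
        for i, n in enumerate(counts):
            out.append(
                PatientRecord(
                    patient_id=f"P{i}", mutation="NPM1" if i < 7 else "IDH2",
                    relapse=i in (6, 8, 9),
                    blast_obs=[(0.0, 0.5)],
                    ctdna_obs=[(float(j), 1e4) for j in range(n)],
                    blood_volume=4.0,
                )
            )
        return out

    def test_clinical_mean(self):
        s = summarize_cohort(self._cohort_with_counts(CLINICAL_CTDNA_COUNTS))
        assert s.ctdna_n_mean == pytest.approx(8.7)

    def test_clinical_sample_sd(self):
        s = summarize_cohort(self._cohort_with_counts(CLINICAL_CTDNA_COUNTS))
        assert round(s.ctdna_n_sd, 1) == 3.7

    def test_single_patient_sd_missing(self):
        s = summarize_cohort(self._cohort_with_counts([5]))
        assert s.ctdna_n_sd is None

    def test_counts_and_split(self):
        s = summarize_cohort(self._cohort_with_counts(CLINICAL_CTDNA_COUNTS))
        assert s.n_patients == 10
        assert s.n_by_mutation == {"NPM1": 7, "IDH2": 3}
        assert s.n_relapsed == 3
        assert (s.ctdna_n_min, s.ctdna_n_max) == (2, 14)


class TestIO:
    def test_round_trip_values(self, tmp_path):
        records = tiny_records()
        write_cohort(records, tmp_path / "obs.csv", tmp_path / "cov.json")
        back = read_cohort(tmp_path / "obs.csv", tmp_path / "cov.json")
        assert [r.patient_id for r in back] == [r.patient_id for r in records]
        for a, b in zip(records, back):
            assert sorted(a.blast_obs) == sorted(b.blast_obs)
            assert sorted(a.ctdna_obs) == sorted(b.ctdna_obs)
            assert a.blood_volume == b.blood_volume
            assert a.relapse == b.relapse

    def test_write_is_byte_stable(self, tmp_path):
        records = tiny_records()
        write_cohort(records, tmp_path / "a.csv", tmp_path / "a.json")
        back = read_cohort(tmp_path / "a.csv", tmp_path / "a.json")
        write_cohort(back, tmp_path / "b.csv", tmp_path / "b.json")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_missing_column_rejected(self, tmp_path):
        (tmp_path / "obs.csv").write_text("patient_id,value\nP1,1.0\n")
        (tmp_path / "cov.json").write_text('[{"patient_id": "P1", "mutation": "NPM1", "relapse": false}]')
        with pytest.raises(ValueError, match="missing columns"):
            read_cohort(tmp_path / "obs.csv", tmp_path / "cov.json")


class TestRecordValidation:
    def test_needs_volume_or_anthropometrics(self):
        with pytest.raises(ValueError, match="blood_volume"):
            PatientRecord(
                patient_id="X", mutation="NPM1", relapse=False,
                blast_obs=[(0.0, 0.5)], ctdna_obs=[(0.0, 1e4), (1.0, 1e3)],
            )

    def test_nadler_used_when_no_volume(self):
        rec = PatientRecord(
            patient_id="X", mutation="NPM1", relapse=False,
            blast_obs=[(0.0, 0.5)], ctdna_obs=[(0.0, 1e4), (1.0, 1e3)],
            sex="male", height=1.80, weight=80.0,
        )
        assert rec.resolved_blood_volume() == pytest.approx(5.319, abs=5e-4)

    def test_explicit_volume_beats_nadler(self):
        rec = PatientRecord(
            patient_id="X", mutation="NPM1", relapse=False,
            blast_obs=[(0.0, 0.5)], ctdna_obs=[(0.0, 1e4), (1.0, 1e3)],
            sex="male", height=1.80, weight=80.0, blood_volume=6.0,
        )
        assert rec.resolved_blood_volume() == 6.0

    def test_needs_two_ctdna_points(self):
        with pytest.raises(ValueError, match="ctDNA"):
            PatientRecord(
                patient_id="X", mutation="NPM1", relapse=False,
                blast_obs=[(0.0, 0.5)], ctdna_obs=[(0.0, 1e4)], blood_volume=4.0,
            )

    def test_prepared_patient_sorted_times(self):
        rec = PatientRecord(
            patient_id="X", mutation="NPM1", relapse=False,
            blast_obs=[(16.0, 0.1), (-2.0, 0.5)],
            ctdna_obs=[(3.0, 1e3), (0.0, 1e4)], blood_volume=4.0,
        )
        prep = prepare_patient(rec)
        assert list(prep.blast_times) == [0.0, 16.0]
        assert list(prep.ctdna_times) == [0.0, 3.0]
        assert prep.blast_counts[0] == pytest.approx(0.5 * NUCLEATED_BM_CELLS)
        assert prep.ctdna_counts[0] == pytest.approx(4e4)
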
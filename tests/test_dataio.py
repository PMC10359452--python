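"""Dataset model, unit conversion, exclusion rules, cross-validation
truncation and the NONMEM-flavoured CSV round trip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maintpkpd.datasets import (
    Dataset,
    DoseEvent,
    Observation,
    ParseError,
    PatientRecord,
    apply_exclusions,
    crossval_truncate,
    read_dataset,
    write_dataset,
)
from maintpkpd.units import convert_ery_concentration
from maintpkpd.variants import FINAL_VARIANT


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "raw, expected",
    [
        (0.0, 0.0),
        (100.0, 0.511956),  # 100 * 330 / 64458 / 1000
        (1350.0, 6.911415),
    ],
)
def test_ery_concentration_conversion(raw, expected):
    assert convert_ery_concentration(raw) == pytest.approx(expected, rel=1e-4)


def test_ery_concentration_rejects_negative():
    with pytest.raises(ValueError):
        convert_ery_concentration(-1.0)


@given(st.floats(0, 1e4), st.floats(0, 1e4))
@settings(max_examples=50, deadline=None)
def test_ery_concentration_is_linear(a, b):
    f = convert_ery_concentration
    assert f(a + b) == pytest.approx(f(a) + f(b), abs=1e-12)


# ---------------------------------------------------------------------------
# exclusion filter
# ---------------------------------------------------------------------------

def _full_obs():
    return [
        Observation(0.0, "E-MTX", 0.02), Observation(0.0, "E-TGN", 0.8),
        Observation(28.0, "E-MTX", 0.03), Observation(28.0, "E-TGN", 0.9),
        Observation(14.0, "ANC", 1.5),
    ]


def _doses():
    return [DoseEvent(0.0, "6MP", 75.0), DoseEvent(0.0, "MTX", 20.0)]


def test_exclusion_rules_and_log():
    ok = PatientRecord("ok", 6, 110, 20, _doses(), _full_obs())
    one_tgn = PatientRecord(
        "one_tgn", 6, 110, 20, _doses(),
        [o for o in _full_obs() if not (o.kind == "E-TGN" and o.time > 0)],
    )
    no_dose = PatientRecord("no_dose", 6, 110, 20,
                            [DoseEvent(0.0, "6MP", 75.0)], _full_obs())
    no_anc = PatientRecord("no_anc", 6, 110, 20, _doses(),
                           [o for o in _full_obs() if o.kind != "ANC"])
    ds = Dataset([ok, one_tgn, no_dose, no_anc])
    kept, log = apply_exclusions(ds, FINAL_VARIANT)
    assert [p.id for p in kept.patients] == ["ok"]
    assert dict(log.entries) == {
        "one_tgn": "lt2_metabolite_obs",
        "no_dose": "no_dose",
        "no_anc": "missing_covariate_or_anc",
    }


def test_exclusions_reanchor_to_first_joint_measurement():
    obs = [
        Observation(5.0, "E-MTX", 0.02), Observation(10.0, "E-TGN", 0.8),
        Observation(40.0, "E-MTX", 0.03), Observation(40.0, "E-TGN", 0.9),
        Observation(2.0, "ANC", 2.0), Observation(12.0, "ANC", 1.5),
    ]
    doses = [DoseEvent(t, "6MP", 75.0) for t in (1.0, 11.0, 20.0)]
    doses += [DoseEvent(11.0, "MTX", 20.0)]
    p = PatientRecord("p", 6, 110, 20, doses, obs)
    with pytest.raises(ValueError):
        # after anchoring at t=10, only one E-MTX observation remains
        apply_exclusions(Dataset([p]), FINAL_VARIANT)
    # give it a second E-MTX measurement at the anchor
    obs.append(Observation(10.0, "E-MTX", 0.021))
    p2 = PatientRecord("p2", 6, 110, 20, doses, obs)
    kept, log = apply_exclusions(Dataset([p2]), FINAL_VARIANT)
    q = kept.patients[0]
    assert len(log) == 0
    # anchor = max(first E-MTX at 5, first E-TGN at 10) = 10; earlier rows drop
    assert q.times("E-MTX").tolist() == [0.0, 30.0]
    assert q.times("E-TGN").tolist() == [0.0, 30.0]
    assert q.times("ANC").tolist() == [2.0]
    assert [d.time for d in q.doses] == [1.0, 1.0, 10.0]


def test_exclusions_idempotent(small_cohort):
    _, dataset, _ = small_cohort
    once, log1 = apply_exclusions(dataset, FINAL_VARIANT)
    twice, log2 = apply_exclusions(once, FINAL_VARIANT)
    assert len(log1) == 0 and len(log2) == 0
    assert [p.id for p in once.patients] == [p.id for p in twice.patients]
    for a, b in zip(once.patients, twice.patients):
        assert a.observations == b.observations
        assert a.doses == b.doses


def test_exclusions_empty_result_names_dominant_rule():
    p = PatientRecord("p", 6, 110, 20, [], _full_obs())
    with pytest.raises(ValueError, match="no_dose"):
        apply_exclusions(Dataset([p]), FINAL_VARIANT)


# ---------------------------------------------------------------------------
# cross-validation truncation
# ---------------------------------------------------------------------------

def _cv_patient(anc_times, met_times, pid="p"):
    obs = []
    for t in met_times:
        obs.append(Observation(t, "E-MTX", 0.02))
        obs.append(Observation(t, "E-TGN", 0.8))
    for t in anc_times:
        obs.append(Observation(t, "ANC", 1.5))
    return PatientRecord(pid, 6, 110, 20, _doses(), obs)


def test_crossval_cutoff_keeps_strictly_earlier_observations():
    p = _cv_patient([10.0, 20.0, 30.0, 40.0], [0.0, 5.0, 25.0, 35.0])
    kept, _ = crossval_truncate(Dataset([p]), FINAL_VARIANT)
    q = kept.patients[0]
    # cutoff is the 3rd ANC time (30): half the ANC observations lie before
    assert q.times("ANC").tolist() == [10.0, 20.0]
    assert q.times("E-MTX").tolist() == [0.0, 5.0, 25.0]


@pytest.mark.parametrize("anc_times", [[12.0], [7.0, 7.0, 7.0]])
def test_crossval_degenerate_patients_are_excluded(anc_times):
    # a single ANC observation (or all at the cutoff time) leaves nothing
    p = _cv_patient(anc_times, [0.0, 5.0])
    with pytest.raises(ValueError):
        crossval_truncate(Dataset([p]), FINAL_VARIANT)


def test_crossval_retains_a_time_prefix(small_cohort):
    _, dataset, _ = small_cohort
    kept, _ = crossval_truncate(dataset, FINAL_VARIANT)
    for q in kept.patients:
        p = dataset.get(q.id)
        for kind in ("E-MTX", "E-TGN", "ANC"):
            before = p.times(kind)
            after = q.times(kind)
            assert after.size <= before.size
            assert np.array_equal(after, before[: after.size])


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def test_csv_round_trip_is_lossless(small_cohort, tmp_path):
    _, dataset, _ = small_cohort
    path = tmp_path / "cohort.csv"
    write_dataset(dataset, path)
    back = read_dataset(path)
    assert len(back.patients) == len(dataset.patients)
    for a, b in zip(dataset.patients, back.patients):
        assert a.id == b.id
        assert (a.age, a.height, a.weight) == (b.age, b.height, b.weight)
        assert a.observations == b.observations
        assert a.doses == b.doses


def test_csv_parse_errors_name_the_row(tmp_path):
    header = "ID,TIME,EVID,DVID,DV,AMT,DRUG,HT,WT,AGE\n"
    bad_dvid = header + "p1,0,0,1,0.02,,,110,20,6\np1,1,0,7,0.5,,,110,20,6\n"
    f = tmp_path / "bad.csv"
    f.write_text(bad_dvid)
    with pytest.raises(ParseError, match="row 3"):
        read_dataset(f)
    f.write_text(header + "p1,0,0,1,abc,,,110,20,6\n")
    with pytest.raises(ParseError, match="DV"):
        read_dataset(f)
    f.write_text(header + "p1,5,0,1,0.02,,,110,20,6\np1,3,0,2,0.5,,,110,20,6\n")
    with pytest.raises(ParseError, match="unsorted"):
        read_dataset(f)
    f.write_text("ID,TIME,EVID\np1,0,0\n")
    with pytest.raises(ParseError, match="missing mandatory column"):
        read_dataset(f)


def test_csv_unit_flag_converts_metabolite_rows(tmp_path):
    header = "ID,TIME,EVID,DVID,DV,AMT,DRUG,HT,WT,AGE,UNIT\n"
    rows = (
        "p1,0,0,2,100,,,110,20,6,nmol_mmolHb\n"
        "p1,1,0,2,0.5,,,110,20,6,umolL\n"
        "p1,2,0,3,1.5,,,110,20,6,\n"
    )
    f = tmp_path / "units.csv"
    f.write_text(header + rows)
    ds = read_dataset(f)
    vals = ds.patients[0].values("E-TGN")
    assert vals[0] == pytest.approx(convert_ery_concentration(100.0))
    assert vals[1] == 0.5
    assert ds.patients[0].values("ANC")[0] == 1.5
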
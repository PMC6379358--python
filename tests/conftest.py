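import pytest

from lacest.datamodel import (CWRTestRecord, Dataset, Intensity, Sex,
                              SubjectRecord, write_dataset)
from lacest.synth import SynthConfig, generate_cohort


def make_subject(**kw):
    base = dict(subject_id="S01", age=33.0, sex=Sex.FEMALE, height_cm=165.0,
                weight_kg=62.7, bmi=23.0, resting_hr=70.0)
    base.update(kw)
    return SubjectRecord(**base)


def make_test(**kw):
    base = dict(subject_id="S01", intensity=Intensity.LC,
                percent_peak_wr=0.35, work_rate_w=66.0, duration_min=15.0,
                ex_hr=110.0, bf=22.0, vt_l=1.3, lactate_mmol_l=3.7)
    base.update(kw)
    return CWRTestRecord(**base)


@pytest.fixture
def trio_dataset():
    """One subject with the full LC/MC/HC trio of tests."""
    return Dataset(
        subjects=[make_subject()],
        tests=[
            make_test(intensity=Intensity.LC, ex_hr=110.0, bf=22.0,
                      vt_l=1.3, lactate_mmol_l=3.7),
            make_test(intensity=Intensity.MC, ex_hr=140.0, bf=27.0,
                      vt_l=1.8, work_rate_w=107.0, percent_peak_wr=0.60,
                      duration_min=10.0, lactate_mmol_l=6.9),
            make_test(intensity=Intensity.HC, ex_hr=165.0, bf=35.0,
                      vt_l=2.3, work_rate_w=146.0, percent_peak_wr=0.90,
                      duration_min=4.0, lactate_mmol_l=10.4),
        ],
    )


@pytest.fixture
def trio_files(trio_dataset, tmp_path):
    sp, tp = tmp_path / "subjects.csv", tmp_path / "tests.csv"
    write_dataset(trio_dataset, sp, tp)
    return sp, tp


@pytest.fixture(scope="session")
def cohort31():
    """Default-size synthetic cohort: 31 subjects, 93 tests."""
    return generate_cohort(SynthConfig(seed=123))
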
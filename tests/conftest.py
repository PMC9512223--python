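import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def calib():
    from hipforce import default_calibration

    return default_calibration()


@pytest.fixture()
def subjects_csv(tmp_path):
    path = tmp_path / "subjects.csv"
    path.write_text(
        "subject_id,gender,age_years,height_cm,body_mass_kg\n"
        "S1,male,24,178,70\n"
        "S2,female,22,163,58\n"
    )
    return path
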
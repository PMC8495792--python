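import numpy as np
import pytest
from hypothesis import settings

from strigasurvey.survey_io import FieldRecord, QuadratRecord, SurveyDataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_field(
    field_id="F1",
    year=2019,
    densities=(2, 3),
    crop="rice",
    rice_variety="B22",
    companion_crop=None,
    prev_crop_1="maize",
    prev_crop_2=None,
    lat=-19.6,
    lon=46.0,
    transect=1,
    altitude_m=850.0,
    monthly_precip_mm=None,
    mean_temp_C=22.0,
    no3_ppm=None,
):
    if monthly_precip_mm is None:
        monthly_precip_mm = tuple([120.0] * 12)
    quadrats = [
        QuadratRecord(
            field_id=field_id,
            quadrat_index=i + 1,
            density=d,
            crop_height_cm=90.0,
            crop_cover_pct=60.0,
            other_weed_cover_pct=15.0,
        )
        for i, d in enumerate(densities)
    ]
    return FieldRecord(
        field_id=field_id,
        year=year,
        transect=transect,
        lat=lat,
        lon=lon,
        altitude_m=altitude_m,
        crop=crop,
        rice_variety=rice_variety,
        companion_crop=companion_crop,
        prev_crop_1=prev_crop_1,
        prev_crop_2=prev_crop_2,
        quadrats=quadrats,
        monthly_precip_mm=monthly_precip_mm,
        mean_temp_C=mean_temp_C,
        no3_ppm=no3_ppm,
    )


@pytest.fixture
def two_year_dataset():
    """Three fields: one paired cereal, one unmatched, one turned non-cereal."""
    f1a = make_field("F1", 2019, (1, 2))
    f1b = make_field("F1", 2020, (2, 2), prev_crop_1="rice", prev_crop_2="maize")
    f2 = make_field("F2", 2019, (0, 0))
    f3a = make_field("F3", 2019, (3, 4))
    f3b = make_field(
        "F3", 2020, (0, 0), crop="manioc", rice_variety=None,
        prev_crop_1="rice", prev_crop_2="maize",
    )
    d19 = SurveyDataset([f1a, f2, f3a])
    d20 = SurveyDataset([f1b, f3b])
    return d19, d20


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
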
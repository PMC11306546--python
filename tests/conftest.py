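import pytest

from chwpay import (
    GeographyInputs,
    OverheadLedger,
    ServiceModel,
    StaffingPlan,
    WageDistribution,
    fixture_national,
)


@pytest.fixture
def national_geo() -> GeographyInputs:
    """Synthetic national-composite geography with the base-case means."""
    return fixture_national()


@pytest.fixture
def rn_plan() -> StaffingPlan:
    return StaffingPlan.rn()


@pytest.fixture
def service() -> ServiceModel:
    return ServiceModel()


def make_geo(
    geo_id="T1",
    chw=(20.0, 0.0),
    rn=(30.0, 0.0),
    msw=(25.0, 0.0),
    overhead=(1.0, 1.0, 5.0, 1.0, 2.0),
    oh_sds=None,
    travel=0.5,
    metro=True,
    weight=1.0,
) -> GeographyInputs:
    """Small deterministic geography for unit tests (sds default to zero)."""
    eq, sw, tr, sp, be = overhead
    return GeographyInputs(
        geo_id=geo_id,
        state="XX",
        area_name=f"test area {geo_id}",
        metro=metro,
        chw_wage=WageDistribution(*chw),
        supervisor_wages={
            "RN": WageDistribution(*rn),
            "MSW": WageDistribution(*msw),
        },
        overhead=OverheadLedger(
            equipment=eq, software=sw, transportation=tr, space=sp, benefits=be,
            sds=oh_sds or {},
        ),
        travel_time_per_inperson_visit=travel,
        employment_weight=weight,
    )
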
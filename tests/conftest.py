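import pytest

from figgcba import (
    CrimeCategoryParams,
    DistributionSpec,
    MurderParams,
    Scenario,
    paper_scenario,
)


@pytest.fixture(scope="session")
def scenario() -> Scenario:
    return paper_scenario()


@pytest.fixture(scope="session")
def db(scenario):
    return scenario.database


def as_point(dist: DistributionSpec) -> DistributionSpec:
    return DistributionSpec.point(dist.base, proportion=dist.proportion)


def point_category(params: CrimeCategoryParams) -> CrimeCategoryParams:
    """Collapse every distribution of a category to its base-case point."""
    fields = params.model_dump()
    out = {}
    for name, value in fields.items():
        attr = getattr(params, name)
        if isinstance(attr, DistributionSpec):
            out[name] = as_point(attr)
        else:
            out[name] = value
    return CrimeCategoryParams.model_validate(
        {k: (v.model_dump() if isinstance(v, DistributionSpec) else v) for k, v in out.items()}
    )


def point_murder(mp: MurderParams) -> MurderParams:
    return MurderParams(
        reported_murders=mp.reported_murders,
        clearance_rate=mp.clearance_rate,
        profile_yield=as_point(mp.profile_yield),
        horizon_years=mp.horizon_years,
        serial_reduction=as_point(mp.serial_reduction),
    )


def assert_rel(actual: float, expected: float, tol: float = 1e-3) -> None:
    """Relative-error assertion with a readable failure message."""
    err = abs(actual - expected) / abs(expected) if expected else abs(actual)
    assert err <= tol, f"{actual} differs from {expected} by {err:.2e} (> {tol})"
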
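"""Deterministic bounding model against the published arithmetic."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from figgcba import (
    category_annual,
    category_lifetime,
    grand_totals,
    investigation_cost,
    leads,
    lifetime_pools,
    murder_pipeline,
    no_hit_pool,
    overall_success_rate,
    ratio_stat,
    savings,
    table5,
    victims_prevented,
)
from conftest import assert_rel


# ---------------------------------------------------------------------------
# elementary rate and count arithmetic
# ---------------------------------------------------------------------------


def test_published_rate_arithmetic():
    assert round(100 * ratio_stat(33_398, 80_325), 1) == 41.6
    assert round(100 * ratio_stat(15_784, 33_398), 1) == 47.3
    assert round(100 * ratio_stat(10_550, 15_784), 1) == 66.8
    assert round(100 * overall_success_rate(0.416, 0.473), 1) == 19.7
    assert overall_success_rate(0.45, 0.80) == pytest.approx(0.36)
    assert overall_success_rate(1.0, 0.3) == 0.3


def test_rate_input_validation():
    with pytest.raises(ValueError):
        overall_success_rate(1.2, 0.5)
    with pytest.raises(ValueError):
        ratio_stat(1, 0)


def test_no_hit_pool(db):
    assert no_hit_pool(db) == 556_482
    zero_hits = db.model_copy(update={"lifetime_hits": 0})
    assert no_hit_pool(zero_hits) == db.total_forensic_profiles
    all_hits = db.model_copy(update={"lifetime_hits": db.total_forensic_profiles})
    assert no_hit_pool(all_hits) == 0


@pytest.mark.parametrize(
    "pool, u, p, h, expected",
    [
        (556_482, 0.05, 0.135, 0.59, 46_540),  # sexual assault, lifetime low
        (556_482, 0.20, 0.865, 0.88, 508_313),  # other crimes, lifetime high
        (114_426, 0.20, 0.20, 0.88, 24_167),  # sexual assault, annual high
        (114_426, 0.05, 0.135, 0.59, 9_570),  # sexual assault, annual low
    ],
)
def test_leads_matches_published_counts(pool, u, p, h, expected):
    assert round(leads(pool, u, p, h)) == expected


def test_leads_identity_and_validation():
    assert leads(1234.5, 0.0, 1.0, 1.0) == 1234.5
    with pytest.raises(ValueError):
        leads(100, 0.1, 1.2, 0.5)
    with pytest.raises(ValueError):
        leads(-1, 0.1, 0.5, 0.5)


def test_victims_prevented():
    assert round(victims_prevented(46_540, 0.30)) == 13_962
    assert round(victims_prevented(117_528, 0.67)) == 78_744
    assert victims_prevented(1000, 0.0) == 0.0


def test_savings_products():
    tangible, intangible = savings(1, 7419, 133_021)
    assert (tangible, intangible) == (7419, 133_021)
    assert savings(0, 7419, 133_021) == (0, 0)
    # unrounded chain value, within the published figures' rounding slack
    victims = leads(556_482, 0.05, 0.135, 0.59) * 0.30
    tangible, intangible = savings(victims, 7419, 133_021)
    assert_rel(tangible, 103_583_611)
    assert_rel(intangible, 1_857_230_822)


def test_investigation_cost():
    assert investigation_cost(1000, 50, 46) == 2_300_000
    assert investigation_cost(1, 10, 24) == 240
    assert investigation_cost(0, 50, 46) == 0


# ---------------------------------------------------------------------------
# per-category chains
# ---------------------------------------------------------------------------


def test_sexual_assault_lifetime_bounds(db, scenario):
    sa = scenario.sexual_assault
    assert_rel(category_lifetime(db, sa, "low").tangible_savings, 212_991_099)
    assert_rel(category_lifetime(db, sa, "high").tangible_savings, 1_201_258_822)
    assert_rel(category_lifetime(db, sa, "low").intangible_savings, 3_818_882_463)
    assert_rel(category_lifetime(db, sa, "high").intangible_savings, 21_538_300_280)
    no_hit, hit = lifetime_pools(db, sa, "high")
    assert round(hit.victims_prevented) == pytest.approx(83_173, abs=1)
    assert round(no_hit.leads) == pytest.approx(117_528, abs=1)
    no_hit_low, hit_low = lifetime_pools(db, sa, "low")
    assert round(hit_low.victims_prevented) == pytest.approx(14_747, abs=1)


def test_other_crimes_lifetime_bounds(db, scenario):
    oc = scenario.other_crimes
    assert_rel(category_lifetime(db, oc, "low").tangible_savings, 1_376_848_971)
    assert_rel(category_lifetime(db, oc, "high").tangible_savings, 5_243_008_983)
    assert_rel(category_lifetime(db, oc, "low").intangible_savings, 5_157_058_570)
    assert_rel(category_lifetime(db, oc, "high").intangible_savings, 19_637_959_564)
    no_hit_low, hit_low = lifetime_pools(db, oc, "low")
    assert round(no_hit_low.leads) == pytest.approx(275_792, abs=1)
    # the hit pool's upload increase is allocated with the sexual-assault
    # share, as in the published workbook
    assert_rel(hit_low.tangible_savings, 693_352_469)
    assert_rel(lifetime_pools(db, oc, "high")[1].tangible_savings, 2_513_546_523)


def test_sexual_assault_annual(db, scenario):
    sa = scenario.sexual_assault
    low = category_annual(db, sa, "low")
    high = category_annual(db, sa, "high")
    assert round(low.leads) == 9_570
    assert round(high.leads) == 24_167
    assert_rel(low.tangible_savings, 21_299_354)
    assert_rel(high.tangible_savings, 120_126_495)
    assert_rel(low.intangible_savings, 381_892_614)
    assert_rel(high.intangible_savings, 2_153_841_008)


def test_other_crimes_annual(db, scenario):
    oc = scenario.other_crimes
    low = category_annual(db, oc, "low")
    high = category_annual(db, oc, "high")
    # the published narrative prints 17,103 low victims, but its own dollar
    # figure ($140,543,217 = victims x $8,261) pins the value at 17,013 — a
    # digit transposition in print
    assert round(low.victims_prevented) == 17_013
    assert_rel(low.tangible_savings, 140_543_217)
    assert round(high.victims_prevented) == pytest.approx(67_939, abs=1)
    assert_rel(high.tangible_savings, 561_242_720)
    assert_rel(high.intangible_savings, 2_102_163_449)


def test_murder_pipeline(scenario):
    mp, cat = scenario.murder, scenario.murder_category
    horizon_low, annual_low = murder_pipeline(mp, cat, "low")
    horizon_high, annual_high = murder_pipeline(mp, cat, "high")
    assert round(mp.unsolved_per_year) == 6_672
    assert round(mp.unsolved_per_year * mp.profile_yield.low * mp.horizon_years) == 20_015
    assert round(mp.unsolved_per_year * mp.profile_yield.high * mp.horizon_years) == 33_358
    assert round(horizon_low.leads) == 12_399
    assert round(horizon_high.leads) == 35_226
    assert round(horizon_low.victims_prevented) == 620
    assert round(horizon_high.victims_prevented) == 5_284
    assert_rel(horizon_low.tangible_savings, 1_648_053_202)
    assert_rel(horizon_high.tangible_savings, 14_046_361_433)
    assert_rel(horizon_low.intangible_savings, 3_193_315_687)
    assert_rel(horizon_high.intangible_savings, 27_216_637_334)
    assert_rel(annual_low.tangible_savings, 164_805_320)
    assert_rel(annual_high.intangible_savings, 2_721_663_733)


def test_murder_zero_yield_zeroes_downstream(scenario):
    from figgcba import DistributionSpec

    mp = scenario.murder.model_copy(update={"profile_yield": DistributionSpec.point(0.0, proportion=True)})
    horizon, annual = murder_pipeline(mp, scenario.murder_category, "high")
    assert horizon.leads == horizon.victims_prevented == horizon.tangible_savings == 0
    assert annual.total_savings == 0


def test_murder_scope_consistency(scenario):
    """Annual x horizon years equals the horizon totals exactly."""
    horizon, annual = murder_pipeline(scenario.murder, scenario.murder_category, "high")
    years = scenario.murder.horizon_years
    for field in ("leads", "victims_prevented", "tangible_savings", "intangible_savings"):
        assert math.isclose(getattr(annual, field) * years, getattr(horizon, field), rel_tol=1e-12)


# ---------------------------------------------------------------------------
# totals
# ---------------------------------------------------------------------------


def test_table5_grand_totals(scenario):
    df = table5(scenario)
    totals = df[df.category == "total"].set_index(["scope", "bound"])
    assert_rel(totals.loc[("lifetime", "lowest"), "total_savings"], 15_407_149_992)
    assert_rel(totals.loc[("lifetime", "highest"), "total_savings"], 88_883_526_416)
    assert_rel(totals.loc[("annual", "lowest"), "total_savings"], 1_554_283_916)
    assert_rel(totals.loc[("annual", "highest"), "total_savings"], 9_063_673_549)
    assert_rel(totals.loc[("lifetime", "lowest"), "tangible_savings"], 3_237_893_272)
    assert_rel(totals.loc[("annual", "highest"), "intangible_savings"], 6_977_668_191)


def test_grand_totals_contract(db, scenario):
    assert grand_totals([]) == {
        "tangible_savings": 0.0,
        "intangible_savings": 0.0,
        "total_savings": 0.0,
    }
    lifetime = category_lifetime(db, scenario.sexual_assault, "low")
    annual = category_annual(db, scenario.sexual_assault, "low")
    with pytest.raises(ValueError, match="mixed scopes"):
        grand_totals([lifetime, annual])
    with pytest.raises(ValueError, match="scopes"):
        lifetime + annual


# ---------------------------------------------------------------------------
# structural properties
# ---------------------------------------------------------------------------

_frac = st.floats(min_value=0.0, max_value=1.0)
_pool = st.floats(min_value=0.0, max_value=2e6)
_delta = st.floats(min_value=0.0, max_value=0.5)


@settings(max_examples=100, database=None, deadline=None)
@given(pool=_pool, u=_frac, p=_frac, h=_frac, r=_frac, d=_delta)
def test_chain_monotone_in_each_rate(pool, u, p, h, r, d):
    base_leads = leads(pool, u, p, h)
    assert leads(pool, min(u + d, 1.0), p, h) >= base_leads
    assert leads(pool, u, min(p + d, 1.0), h) >= base_leads
    assert leads(pool, u, p, min(h + d, 1.0)) >= base_leads
    assert victims_prevented(base_leads, min(r + d, 1.0)) >= victims_prevented(base_leads, r)


def test_endpoint_containment(db, scenario):
    """The base-case evaluation lies inside the low/high bounds everywhere."""
    for params in (scenario.sexual_assault, scenario.other_crimes):
        for fn in (category_annual, category_lifetime):
            low, base, high = (fn(db, params, s) for s in ("low", "base", "high"))
            for field in ("leads", "victims_prevented", "tangible_savings", "intangible_savings"):
                assert getattr(low, field) <= getattr(base, field) <= getattr(high, field)


def test_lifetime_combined_is_componentwise_sum(db, scenario):
    no_hit, hit = lifetime_pools(db, scenario.sexual_assault, "high")
    combined = category_lifetime(db, scenario.sexual_assault, "high")
    for field in ("leads", "victims_prevented", "tangible_savings",
                  "intangible_savings", "investigation_cost"):
        assert getattr(combined, field) == getattr(no_hit, field) + getattr(hit, field)
    assert combined.victims_prevented <= combined.leads


def test_brute_force_oracle_equivalence(db, scenario):
    """Term-by-term recomputation of the full chain matches the composed ops."""
    sa = scenario.sexual_assault
    for setting in ("low", "high"):
        u = sa.upload_increase.at(setting)
        p = sa.category_share.at(setting)
        h = sa.lead_rate.at(setting)
        r = sa.reduction_rate.at(setting)
        expected = {}
        for pool in (556_482, 587_773):
            increased_pool = pool * p + pool * u * p
            lead_count = increased_pool * h
            victims = lead_count * r
            expected[pool] = (
                lead_count,
                victims,
                victims * sa.tangible_cost.base,
                victims * sa.intangible_cost.base,
            )
        no_hit, hit = lifetime_pools(db, sa, setting)
        for pool, result in ((556_482, no_hit), (587_773, hit)):
            lead_count, victims, tangible, intangible = expected[pool]
            assert math.isclose(result.leads, lead_count, rel_tol=1e-9)
            assert math.isclose(result.victims_prevented, victims, rel_tol=1e-9)
            assert math.isclose(result.tangible_savings, tangible, rel_tol=1e-9)
            assert math.isclose(result.intangible_savings, intangible, rel_tol=1e-9)
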
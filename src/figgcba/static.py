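"""Deterministic bounding model for FIGG adoption benefits.

The model is a multiplicative chain evaluated at its lowest and highest
plausible input brackets:

    pool -> leads -> victims prevented -> tangible / intangible savings

* ``pool`` is a stock of searchable forensic profiles: profiles that never
  hit in the STR database (lifetime, no-hit), profiles that did hit
  (lifetime, hit), annual uploads (annual scope), or unsolved-murder
  profiles accumulated over a horizon.
* ``leads = pool x lead_rate x (share + upload_increase x increase_share)``
  — the kinship-search lead rate applied to the category's profiles plus
  the additional profiles a more sensitive assay would make uploadable.
  With ``increase_share == share`` this is the familiar
  ``pool x (1 + u) x p x h``.
* ``victims = leads x reduction_rate`` converts leads into prevented
  victims via earlier identification of serial offenders.
* savings are victims times per-case tangible and intangible crime costs.

The ``low``/``high`` settings sweep the rate inputs (upload increase,
profile share, lead rate, reduction rate, murder profile yield) to their
endpoints simultaneously; per-case costs and investigation labor stay at
their base-case values, which is how the published bounds are constructed.
Intermediates are never rounded — rounding happens only at display.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

import pandas as pd

from .params import (
    CrimeCategoryParams,
    DatabaseState,
    MurderParams,
    Scenario,
    Setting,
)

__all__ = [
    "SavingsResult",
    "overall_success_rate",
    "ratio_stat",
    "no_hit_pool",
    "leads",
    "victims_prevented",
    "savings",
    "investigation_cost",
    "chain",
    "category_lifetime",
    "lifetime_pools",
    "category_annual",
    "murder_pipeline",
    "grand_totals",
    "table5",
]

Scope = Literal["lifetime", "annual", "horizon"]
Pool = Literal["no_hit", "hit", "combined"]


@dataclass(frozen=True)
class SavingsResult:
    """Outcome of one chain evaluation for one category, scope and pool."""

    scope: Scope
    pool: Pool
    category: str
    leads: float
    victims_prevented: float
    tangible_savings: float
    intangible_savings: float
    investigation_cost: float

    @property
    def total_savings(self) -> float:
        return self.tangible_savings + self.intangible_savings

    def __add__(self, other: "SavingsResult") -> "SavingsResult":
        if self.scope != other.scope:
            raise ValueError(f"cannot combine scopes {self.scope!r} and {other.scope!r}")
        if self.category != other.category:
            raise ValueError("cannot combine different categories")
        return SavingsResult(
            scope=self.scope,
            pool="combined",
            category=self.category,
            leads=self.leads + other.leads,
            victims_prevented=self.victims_prevented + other.victims_prevented,
            tangible_savings=self.tangible_savings + other.tangible_savings,
            intangible_savings=self.intangible_savings + other.intangible_savings,
            investigation_cost=self.investigation_cost + other.investigation_cost,
        )

    def scaled(self, factor: float, scope: Scope | None = None) -> "SavingsResult":
        return replace(
            self,
            scope=scope or self.scope,
            leads=self.leads * factor,
            victims_prevented=self.victims_prevented * factor,
            tangible_savings=self.tangible_savings * factor,
            intangible_savings=self.intangible_savings * factor,
            investigation_cost=self.investigation_cost * factor,
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def overall_success_rate(upload_rate: float, hit_rate: float) -> float:
    """Fraction of completed kits that yield a database hit/lead.

    The product of the upload rate (profiles per completed kit) and the hit
    rate (hits per uploaded profile); e.g. 0.416 x 0.473 ~= 19.7%.
    """
    for name, value in (("upload_rate", upload_rate), ("hit_rate", hit_rate)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    return upload_rate * hit_rate


def ratio_stat(numerator: float, denominator: float) -> float:
    """Plain ratio of two tallies (e.g. uploads / completed kits)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return numerator / denominator


def no_hit_pool(db: DatabaseState) -> int:
    """Forensic profiles that have never hit: total minus lifetime hits."""
    return db.total_forensic_profiles - db.lifetime_hits


def leads(
    pool: float,
    upload_increase: float,
    category_share: float,
    lead_rate: float,
    increase_share: float | None = None,
) -> float:
    """Investigative leads from a profile pool.

    ``pool x lead_rate x (category_share + upload_increase x increase_share)``,
    where ``increase_share`` defaults to ``category_share`` (giving
    ``pool x (1+u) x p x h``).  The separate share for the upload-increase
    term mirrors how the published hit-pool figures allocate the newly
    uploadable profiles.
    """
    if pool < 0:
        raise ValueError("pool must be non-negative")
    if upload_increase < 0:
        raise ValueError("upload_increase must be non-negative")
    for name, value in (("category_share", category_share), ("lead_rate", lead_rate)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    inc = category_share if increase_share is None else increase_share
    return pool * lead_rate * (category_share + upload_increase * inc)


def victims_prevented(leads_count: float, reduction_rate: float) -> float:
    """Prevented victims: leads times the recidivism/victim-reduction rate."""
    if not 0.0 <= reduction_rate <= 1.0:
        raise ValueError(f"reduction_rate must be in [0, 1], got {reduction_rate}")
    return leads_count * reduction_rate


def savings(victims: float, tangible_cost: float, intangible_cost: float) -> tuple[float, float]:
    """(tangible, intangible) savings from prevented victims, per-case costs."""
    if min(victims, tangible_cost, intangible_cost) < 0:
        raise ValueError("victims and per-case costs must be non-negative")
    return victims * tangible_cost, victims * intangible_cost


def investigation_cost(leads_count: float, extra_hours: float, hourly_rate: float) -> float:
    """Added police labor: leads x extra investigation hours x hourly rate.

    Reported as its own line, not netted from savings.
    """
    if min(leads_count, extra_hours, hourly_rate) < 0:
        raise ValueError("inputs must be non-negative")
    return leads_count * extra_hours * hourly_rate


# ---------------------------------------------------------------------------
# chain evaluation per category
# ---------------------------------------------------------------------------

# inputs swept to their endpoints by the low/high settings; everything else
# (per-case costs, labor hours/rate) is held at base case
_SWEPT_FIELDS = ("upload_increase", "category_share", "lead_rate", "reduction_rate")


def _rate(params: CrimeCategoryParams, field: str, setting: Setting) -> float:
    return getattr(params, field).at(setting)


def chain(
    pool: float,
    params: CrimeCategoryParams,
    setting: Setting,
    *,
    scope: Scope,
    pool_name: Pool,
    use_hit_increase_share: bool = False,
) -> SavingsResult:
    """Evaluate the full leads -> victims -> savings chain on one pool."""
    inc_share = None
    if use_hit_increase_share and params.hit_increase_share is not None:
        inc_share = params.hit_increase_share.at(setting)
    n_leads = leads(
        pool,
        _rate(params, "upload_increase", setting),
        _rate(params, "category_share", setting),
        _rate(params, "lead_rate", setting),
        increase_share=inc_share,
    )
    victims = victims_prevented(n_leads, _rate(params, "reduction_rate", setting))
    tangible, intangible = savings(victims, params.tangible_cost.base, params.intangible_cost.base)
    labor = investigation_cost(n_leads, params.extra_hours.base, params.police_hourly_rate.base)
    return SavingsResult(
        scope=scope,
        pool=pool_name,
        category=params.name,
        leads=n_leads,
        victims_prevented=victims,
        tangible_savings=tangible,
        intangible_savings=intangible,
        investigation_cost=labor,
    )


def lifetime_pools(
    db: DatabaseState, params: CrimeCategoryParams, setting: Setting
) -> tuple[SavingsResult, SavingsResult]:
    """(no-hit, hit) chain results over the lifetime of the STR database."""
    no_hit = chain(no_hit_pool(db), params, setting, scope="lifetime", pool_name="no_hit")
    hit = chain(
        db.lifetime_hits,
        params,
        setting,
        scope="lifetime",
        pool_name="hit",
        use_hit_increase_share=True,
    )
    return no_hit, hit


def category_lifetime(
    db: DatabaseState, params: CrimeCategoryParams, setting: Setting
) -> SavingsResult:
    """Combined (no-hit + hit) lifetime savings for one crime category."""
    no_hit, hit = lifetime_pools(db, params, setting)
    return no_hit + hit


def category_annual(
    db: DatabaseState, params: CrimeCategoryParams, setting: Setting
) -> SavingsResult:
    """Annual savings: the chain applied to one year of database uploads.

    The annual scope applies the chain to all uploads with no hit/no-hit
    split (the split is a property of the accumulated stock, not the flow).
    """
    result = chain(db.annual_uploads, params, setting, scope="annual", pool_name="combined")
    return result


def murder_pipeline(
    mp: MurderParams, params: CrimeCategoryParams, setting: Setting
) -> tuple[SavingsResult, SavingsResult]:
    """(horizon, annual) savings for murder.

    Murders have their own front end: unsolved cases per year (reported x
    non-clearance) accumulate profiles over ``horizon_years`` at the assumed
    DNA-profile yield; leads then follow the upload-increase and lead-rate
    chain (no within-database share), and prevented victims use the
    serial-murder reduction range.  Annual figures are horizon totals
    divided by the horizon, exactly.
    """
    unsolved = mp.unsolved_per_year  # carried unrounded
    profiles = unsolved * mp.profile_yield.at(setting) * mp.horizon_years
    n_leads = profiles * (1.0 + _rate(params, "upload_increase", setting)) * _rate(
        params, "lead_rate", setting
    )
    victims = n_leads * mp.serial_reduction.at(setting)
    tangible, intangible = savings(victims, params.tangible_cost.base, params.intangible_cost.base)
    labor = investigation_cost(n_leads, params.extra_hours.base, params.police_hourly_rate.base)
    horizon = SavingsResult(
        scope="horizon",
        pool="no_hit",
        category=params.name,
        leads=n_leads,
        victims_prevented=victims,
        tangible_savings=tangible,
        intangible_savings=intangible,
        investigation_cost=labor,
    )
    annual = horizon.scaled(1.0 / mp.horizon_years, scope="annual")
    return horizon, annual


def grand_totals(results: Iterable[SavingsResult]) -> dict[str, float]:
    """Sum tangible, intangible and combined savings across categories.

    All results must share one scope; mixing lifetime and annual figures in
    one total is refused.
    """
    results = list(results)
    if not results:
        return {"tangible_savings": 0.0, "intangible_savings": 0.0, "total_savings": 0.0}
    scopes = {r.scope for r in results}
    # horizon totals are the lifetime-equivalent presentation for murder
    if scopes - {"lifetime", "horizon"} and scopes != {"annual"}:
        raise ValueError(f"mixed scopes in one total: {sorted(scopes)}")
    return {
        "tangible_savings": sum(r.tangible_savings for r in results),
        "intangible_savings": sum(r.intangible_savings for r in results),
        "total_savings": sum(r.total_savings for r in results),
    }


def table5(scenario: Scenario) -> pd.DataFrame:
    """Projected cost savings per category and in total, lifetime and annual.

    Rows are (scope, category, bound); columns are tangible, intangible and
    total savings in nominal USD, full precision (round at display).
    """
    db = scenario.database
    rows = []
    for setting in ("low", "high"):
        bound = "lowest" if setting == "low" else "highest"
        lifetime = [
            category_lifetime(db, scenario.sexual_assault, setting),
            category_lifetime(db, scenario.other_crimes, setting),
            murder_pipeline(scenario.murder, scenario.murder_category, setting)[0],
        ]
        annual = [
            category_annual(db, scenario.sexual_assault, setting),
            category_annual(db, scenario.other_crimes, setting),
            murder_pipeline(scenario.murder, scenario.murder_category, setting)[1],
        ]
        for scope_label, results in (("lifetime", lifetime), ("annual", annual)):
            for r in results:
                rows.append(
                    {
                        "scope": scope_label,
                        "category": r.category,
                        "bound": bound,
                        "tangible_savings": r.tangible_savings,
                        "intangible_savings": r.intangible_savings,
                        "total_savings": r.total_savings,
                    }
                )
            totals = grand_totals(results)
            rows.append({"scope": scope_label, "category": "total", "bound": bound, **totals})
    return pd.DataFrame(rows)
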
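"""Sequencing-economics side of the analysis.

Per-sample reagent costs for a targeted large-SNP panel (library
preparation kit split across its libraries plus the sequencing run kit
split across the run's plexity), scaled up to national caseload and
reference-database budgets, instrument amortization, cost per
investigative lead, the historical STR-database cost per hit, and a
microarray alternative for database population.

Display conventions follow the published tables: per-sample prices to the
cent, per-lead and per-hit costs to whole dollars, aggregate budgets in
whole dollars.  Internally everything except the per-sample price (a
catalog price, quoted to the cent) is carried at full precision.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .params import BudgetLine, CostInputs, ReagentSpec

__all__ = [
    "per_sample_cost",
    "caseload_cost",
    "database_population_cost",
    "annual_budget",
    "budget_lines",
    "cost_per_lead",
    "historical_cost_per_hit",
    "microarray_alternative",
    "missing_persons_comparison",
    "table6",
    "table7",
]


def per_sample_cost(spec: ReagentSpec) -> float:
    """Reagent cost per sample, in USD to the cent.

    Library preparation price per sample (kit cost / kit size, or the flat
    per-library price) plus the sequencing run kit cost divided by the
    number of libraries pooled per run.
    """
    return round(spec.per_library_cost + spec.run_kit_cost / spec.plexity, 2)


def caseload_cost(requests_per_year: float, samples_per_request: float, per_sample: float) -> float:
    """Annual national casework reagent cost: requests x samples/request x price."""
    if min(requests_per_year, samples_per_request, per_sample) < 0:
        raise ValueError("inputs must be non-negative")
    return requests_per_year * samples_per_request * per_sample


def database_population_cost(samples_per_year: float, per_sample: float) -> float:
    """Annual reference-database build-out reagent cost."""
    if min(samples_per_year, per_sample) < 0:
        raise ValueError("inputs must be non-negative")
    return samples_per_year * per_sample


def annual_budget(lines: Iterable[BudgetLine]) -> float:
    """Total annual cost: sum of each line's amortized annual cost."""
    return sum(line.annual_cost for line in lines)


def budget_lines(
    costs: CostInputs,
    price_scenario: str,
    *,
    database_per_sample: float | None = None,
) -> list[BudgetLine]:
    """Assemble the annual budget for one per-sample price scenario.

    ``price_scenario`` is ``"high"`` (current kit pricing) or ``"low"``
    (optimistic high-volume pricing).  Both scenarios cost the full
    projected casework volume (``requests_high`` x samples per request).
    ``database_per_sample`` overrides the database-population price (used
    for the microarray alternative).
    """
    if price_scenario not in ("low", "high"):
        raise ValueError(f"price_scenario must be 'low' or 'high', got {price_scenario!r}")
    case_price = getattr(costs.caseload, f"per_sample_{price_scenario}")
    db_price = getattr(costs.database_population, f"per_sample_{price_scenario}")
    if database_per_sample is not None:
        db_price = database_per_sample
    casework = caseload_cost(
        costs.caseload.requests_high, costs.caseload.samples_per_request, case_price
    )
    database = database_population_cost(costs.database_population.samples_per_year, db_price)
    lines = [
        BudgetLine(name="Casework", total_cost=casework),
        BudgetLine(name="Database work", total_cost=database),
    ]
    lines.extend(costs.infrastructure)
    return lines


def cost_per_lead(
    budget: float, annual_uploads: float, upload_increase: float, lead_rate: float
) -> float:
    """Annual budget divided by projected annual investigative leads.

    Leads are ``annual_uploads x (1 + upload_increase) x lead_rate``.
    Returned at full precision; round to whole dollars for display.
    """
    if budget < 0:
        raise ValueError("budget must be non-negative")
    n_leads = annual_uploads * (1.0 + upload_increase) * lead_rate
    if n_leads <= 0:
        raise ValueError("projected leads must be positive")
    return budget / n_leads


def historical_cost_per_hit(funding: float, hits: float) -> int:
    """Historical STR-database cost per hit, rounded to whole dollars."""
    if hits <= 0:
        raise ValueError("hits must be positive")
    if funding < 0:
        raise ValueError("funding must be non-negative")
    return round(funding / hits)


def microarray_alternative(
    costs: CostInputs,
    annual_uploads: float,
    lead_rate_bounds: tuple[float, float] = (0.59, 0.88),
    upload_increase_bounds: tuple[float, float] = (0.05, 0.20),
    array_per_sample: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Budget and cost-per-lead ranges when microarrays populate the database.

    Only the database-population per-sample price is substituted (default:
    the fixture's microarray price); casework still uses the sequencing
    panel.  Returns (low, high) budget and (low, high) cost per lead, the
    latter pairing the cheap budget with the most leads and the expensive
    budget with the fewest, as in the published comparison.
    """
    price = (
        costs.database_population.microarray_per_sample
        if array_per_sample is None
        else array_per_sample
    )
    budgets = {
        scenario: annual_budget(budget_lines(costs, scenario, database_per_sample=price))
        for scenario in ("low", "high")
    }
    u_low, u_high = upload_increase_bounds
    h_low, h_high = lead_rate_bounds
    cpl_low = cost_per_lead(budgets["low"], annual_uploads, u_high, h_high)
    cpl_high = cost_per_lead(budgets["high"], annual_uploads, u_low, h_low)
    return {
        "annual_budget": (budgets["low"], budgets["high"]),
        "cost_per_lead": (cpl_low, cpl_high),
    }


def missing_persons_comparison(
    current: Sequence[ReagentSpec], figg: Sequence[ReagentSpec]
) -> pd.DataFrame:
    """Side-by-side per-sample reagent costs, current typing vs the SNP panel."""
    rows = []
    for approach, specs in (("current", current), ("figg", figg)):
        for spec in specs:
            rows.append(
                {"approach": approach, "configuration": spec.name, "per_sample_cost": per_sample_cost(spec)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published-table renderers
# ---------------------------------------------------------------------------


def table6(costs: CostInputs) -> pd.DataFrame:
    """Projected additional annual costs under the two per-sample price scenarios."""
    columns = {}
    for scenario in ("high", "low"):
        lines = budget_lines(costs, scenario)
        col = {line.name: line.annual_cost for line in lines}
        col["Total cost/year"] = annual_budget(lines)
        label = f"${getattr(costs.caseload, f'per_sample_{scenario}'):.2f}/sample"
        columns[label] = col
    return pd.DataFrame(columns)


def table7(
    costs: CostInputs,
    annual_uploads: float,
    upload_increase_bounds: tuple[float, float] = (0.05, 0.20),
    lead_rate_bounds: tuple[float, float] = (0.59, 0.88),
) -> pd.DataFrame:
    """Projected cost per investigative lead for the SNP-panel approach.

    Pairs the expensive budget with the pessimistic upload/lead rates and
    the cheap budget with the optimistic ones — the two extremes of cost
    per lead.
    """
    rows = []
    pairings = (
        ("high", upload_increase_bounds[0], lead_rate_bounds[0]),
        ("low", upload_increase_bounds[1], lead_rate_bounds[1]),
    )
    for scenario, u, h in pairings:
        budget = annual_budget(budget_lines(costs, scenario))
        uploads_with_increase = annual_uploads * (1.0 + u)
        n_leads = uploads_with_increase * h
        rows.append(
            {
                "samples_per_year_uploaded": annual_uploads,
                "increased_upload_rate": u,
                "samples_per_year": uploads_with_increase,
                "investigative_lead_rate": h,
                "investigative_leads_per_year": n_leads,
                "cost_per_year": budget,
                "cost_per_lead": round(cost_per_lead(budget, annual_uploads, u, h)),
            }
        )
    return pd.DataFrame(rows)
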
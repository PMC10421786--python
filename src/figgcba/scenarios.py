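"""Synthetic scenario generation and independent oracles.

The analysis has no unit-level data — every input is an independent
triangular/uniform/point distribution feeding a multiplicative chain — so
testability comes from generating random, internally consistent parameter
sets with exactly that structure, plus two independent oracles:

* :func:`oracle_expectation` — the closed-form mean of the chain
  (expectation of a product of independent inputs is the product of their
  means), used to cross-check simulated means.
* :func:`oracle_enumeration` — exhaustive enumeration of the outcome
  distribution when every input has a small finite support, used to check
  the sampler's empirical distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .params import (
    BudgetLine,
    CaseloadInputs,
    CostInputs,
    CrimeCategoryParams,
    DatabasePopulationInputs,
    DatabaseState,
    DistributionSpec,
    InstrumentPurchase,
    MurderParams,
    ReagentSpec,
    Scenario,
)

__all__ = [
    "ScenarioSpec",
    "generate_scenario",
    "oracle_expectation",
    "oracle_enumeration",
    "DiscreteSpec",
]


class ScenarioSpec(BaseModel):
    """Bounds and switches for random scenario generation."""

    model_config = ConfigDict(frozen=True)

    seed: int
    n_categories: int = Field(default=2, ge=0)
    pool_bounds: tuple[int, int] = (100_000, 2_000_000)
    tangible_cost_bounds: tuple[float, float] = (1_000.0, 50_000.0)
    intangible_cost_bounds: tuple[float, float] = (10_000.0, 500_000.0)
    upload_increase_bounds: tuple[float, float] = (0.0, 0.30)
    rate_bounds: tuple[float, float] = (0.05, 0.95)
    hours_bounds: tuple[float, float] = (5.0, 80.0)
    hourly_rate_bounds: tuple[float, float] = (15.0, 100.0)
    # probability that a generated triangular mode collapses onto the max,
    # exercising the right-degenerate edge present in the published tables
    degenerate_mode_prob: float = Field(default=0.1, ge=0.0, le=1.0)
    uniform_prob: float = Field(default=0.25, ge=0.0, le=1.0)


def _spec(
    rng: np.random.Generator,
    lo: float,
    hi: float,
    *,
    proportion: bool = False,
    uniform_prob: float = 0.25,
    degenerate_mode_prob: float = 0.1,
) -> DistributionSpec:
    a, b = np.sort(rng.uniform(lo, hi, size=2))
    a, b = float(a), float(b)
    if rng.random() < uniform_prob:
        return DistributionSpec.uniform(a, b, proportion=proportion)
    if rng.random() < degenerate_mode_prob:
        mode = b
    else:
        mode = float(a + rng.random() * (b - a))
    return DistributionSpec.triangular(a, mode, b, proportion=proportion)


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Random, internally consistent full parameter set; deterministic by seed."""
    rng = np.random.default_rng(spec.seed)

    def dist(lo, hi, proportion=False):
        return _spec(
            rng,
            lo,
            hi,
            proportion=proportion,
            uniform_prob=spec.uniform_prob,
            degenerate_mode_prob=spec.degenerate_mode_prob,
        )

    total = int(rng.integers(*spec.pool_bounds))
    hits = int(total * rng.uniform(0.2, 0.8))
    completed = int(rng.integers(10_000, 100_000))
    uploaded = int(completed * rng.uniform(0.2, 0.8))
    saki_hits = int(uploaded * rng.uniform(0.2, 0.8))
    funding = np.sort(rng.uniform(1e8, 5e9, size=2))
    db = DatabaseState(
        total_forensic_profiles=total,
        lifetime_hits=hits,
        annual_uploads=max(1, int(total * rng.uniform(0.05, 0.15))),
        saki_completed_kits=completed,
        saki_uploaded=uploaded,
        saki_hits=saki_hits,
        saki_serial_hits=int(saki_hits * rng.uniform(0.2, 0.9)),
        funding_low=float(funding[0]),
        funding_high=float(funding[1]),
    )

    r_lo, r_hi = spec.rate_bounds
    # shares across categories drawn inside disjoint windows so their ranges
    # stay plausible fractions of one database
    def category(name: str) -> CrimeCategoryParams:
        share_width = rng.uniform(0.02, 0.25)
        share_lo = rng.uniform(0.0, 1.0 - share_width)
        return CrimeCategoryParams(
            name=name,
            tangible_cost=dist(*spec.tangible_cost_bounds),
            intangible_cost=dist(*spec.intangible_cost_bounds),
            upload_increase=dist(*spec.upload_increase_bounds, proportion=True),
            upload_ratio=dist(r_lo, r_hi, proportion=True),
            category_share=dist(share_lo, share_lo + share_width, proportion=True),
            total_cases=dist(10_000, 500_000),
            lead_rate=dist(r_lo, r_hi, proportion=True),
            reduction_rate=dist(r_lo, r_hi, proportion=True),
            extra_hours=dist(*spec.hours_bounds),
            police_hourly_rate=dist(*spec.hourly_rate_bounds),
        )

    categories = [category(f"category_{i:02d}") for i in range(spec.n_categories)]

    murder = MurderParams(
        reported_murders=int(rng.integers(1_000, 50_000)),
        clearance_rate=float(rng.uniform(0.3, 0.9)),
        profile_yield=dist(0.1, 0.9, proportion=True),
        horizon_years=int(rng.integers(1, 15)),
        serial_reduction=dist(0.01, 0.3, proportion=True),
    )

    kit_cost = float(rng.uniform(5_000, 30_000))
    kit_size = int(rng.integers(8, 97))
    costs = CostInputs(
        reagents={
            "panel_run": ReagentSpec(
                name="panel_run",
                library_kit_cost=kit_cost,
                library_kit_size=kit_size,
                run_kit_cost=float(rng.uniform(500, 3_000)),
                plexity=int(rng.integers(1, 301)),
            ),
            "flat_run": ReagentSpec(
                name="flat_run",
                per_library_override=float(rng.uniform(50, 500)),
                run_kit_cost=float(rng.uniform(0, 3_000)),
                plexity=int(rng.integers(1, 301)),
            ),
        },
        caseload=CaseloadInputs(
            requests_low=int(rng.integers(50_000, 300_000)),
            requests_high=int(rng.integers(300_000, 600_000)),
            samples_per_request=int(rng.integers(1, 10)),
            per_sample_high=float(rng.uniform(200, 400)),
            per_sample_low=float(rng.uniform(50, 200)),
        ),
        database_population=DatabasePopulationInputs(
            samples_per_year=int(rng.integers(100_000, 2_000_000)),
            per_sample_high=float(rng.uniform(200, 400)),
            per_sample_low=float(rng.uniform(50, 200)),
            microarray_per_sample=float(rng.uniform(20, 100)),
        ),
        instruments=[
            InstrumentPurchase(
                name="sequencers",
                count=int(rng.integers(10, 300)),
                unit_cost=float(rng.uniform(100_000, 500_000)),
            )
        ],
        infrastructure=[
            BudgetLine(
                name="capital",
                total_cost=float(rng.uniform(1e7, 1e8)),
                amortization_years=int(rng.integers(1, 20)),
            ),
            BudgetLine(name="recurring", total_cost=float(rng.uniform(1e6, 1e8))),
        ],
    )

    # a generated run needs at least one category for the chain; reuse the
    # murder-style front end as its own category parameters when present
    sa = categories[0] if categories else category("sexual_assault")
    other = categories[1] if len(categories) > 1 else category("other_crimes")
    murder_cat = category("murder")
    return Scenario(
        database=db,
        sexual_assault=sa,
        other_crimes=other,
        murder_category=murder_cat,
        murder=murder,
        costs=costs,
    )


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def oracle_expectation(
    params: CrimeCategoryParams,
    db: DatabaseState,
    model_variant: str = "annual_uploads",
    mp: MurderParams | None = None,
) -> dict[str, float]:
    """Closed-form expected outcomes of the annual chain for one category.

    All inputs are independent, so each expected outcome is the product of
    the analytic means of its factors: triangular mean is
    ``(low + mode + high) / 3``, uniform mean is the midpoint.
    """
    mean = lambda d: d.mean  # noqa: E731
    if model_variant == "annual_uploads":
        if params.name == "murder":
            if mp is None:
                raise ValueError("murder oracle requires MurderParams")
            e_leads = (
                mp.unsolved_per_year
                * mean(mp.profile_yield)
                * (1.0 + mean(params.upload_increase))
                * mean(params.lead_rate)
            )
            e_victims = e_leads * mean(mp.serial_reduction)
        else:
            e_leads = (
                db.annual_uploads
                * (1.0 + mean(params.upload_increase))
                * mean(params.category_share)
                * mean(params.lead_rate)
            )
            e_victims = e_leads * mean(params.reduction_rate)
    elif model_variant == "total_cases":
        e_leads = (
            mean(params.total_cases)
            * mean(params.category_share)
            * mean(params.upload_ratio)
            * (1.0 + mean(params.upload_increase))
            * mean(params.lead_rate)
        )
        e_victims = e_leads * mean(params.reduction_rate)
    else:
        raise ValueError(f"unknown model variant {model_variant!r}")
    return {
        "leads": e_leads,
        "victims_prevented": e_victims,
        "tangible": e_victims * mean(params.tangible_cost),
        "intangible": e_victims * mean(params.intangible_cost),
        "investigation_cost": e_leads * mean(params.extra_hours) * mean(params.police_hourly_rate),
    }


@dataclass(frozen=True)
class DiscreteSpec:
    """Finite-support input distribution for the enumeration oracle."""

    values: tuple[float, ...]
    probs: tuple[float, ...]
    kind: str = field(default="discrete", init=False)

    def __post_init__(self):
        if len(self.values) != len(self.probs):
            raise ValueError("values and probs must have equal length")
        if not self.probs or min(self.probs) < 0:
            raise ValueError("probs must be non-negative and non-empty")
        if not math.isclose(sum(self.probs), 1.0, abs_tol=1e-9):
            raise ValueError("probs must sum to 1")

    @property
    def low(self) -> float:
        return min(self.values)

    @property
    def high(self) -> float:
        return max(self.values)


def oracle_enumeration(
    inputs: Mapping[str, DiscreteSpec],
    fn: Callable[[Mapping[str, float]], float],
    max_points: int = 5,
    max_inputs: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact outcome distribution by exhaustive enumeration.

    ``fn`` maps a full assignment of input values to a scalar outcome.
    Returns sorted unique outcome values with their total probabilities
    (outcomes coinciding to 9 decimals are merged).  Refuses supports
    larger than ``max_points`` per input or more than ``max_inputs`` inputs.
    """
    if len(inputs) > max_inputs:
        raise ValueError(f"too many inputs for enumeration: {len(inputs)} > {max_inputs}")
    for name, d in inputs.items():
        if len(d.values) > max_points:
            raise ValueError(f"support of {name!r} too large: {len(d.values)} > {max_points}")
    names = list(inputs)
    acc: dict[float, float] = {}
    for combo in itertools.product(*(zip(inputs[n].values, inputs[n].probs) for n in names)):
        values = {n: vp[0] for n, vp in zip(names, combo)}
        prob = math.prod(vp[1] for vp in combo)
        key = round(float(fn(values)), 9)
        acc[key] = acc.get(key, 0.0) + prob
    outcomes = np.array(sorted(acc))
    probs = np.array([acc[o] for o in outcomes])
    return outcomes, probs
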
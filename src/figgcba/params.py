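"""Typed parameter model for the FIGG cost-benefit analysis.

Every quantity the analysis consumes is a printed statistic or a judgmental
range, so the whole input surface is a set of validated, serializable
parameter objects rather than raw data files:

* :class:`DistributionSpec` — one uncertain input, modelled as a triangular
  (min, base case, max), uniform (min, max) or point distribution.
* :class:`CrimeCategoryParams` — the per-crime-category input rows
  (tangible/intangible cost per case, upload increase, upload ratio,
  share of database profiles, caseload, investigative-lead rate,
  recidivism/victim-reduction rate, extra investigation labor).
* :class:`DatabaseState` — national DNA index (NDIS) and Sexual Assault Kit
  Initiative (SAKI) tallies that anchor the deterministic model.
* :class:`MurderParams` — the unsolved-murder front end (reported murders,
  clearance rate, profile yield, horizon, serial-offender reduction).
* :class:`ReagentSpec` / :class:`BudgetLine` / :class:`CostInputs` — the
  sequencing-economics side (per-sample reagents, instruments, annual
  infrastructure budget lines).

Config files are single JSON documents; the packaged fixtures
``paper_tables_2_4``, ``paper_database_state`` and ``paper_costs`` encode
the published input tables and are the defaults throughout the package.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_serializer, model_validator

__all__ = [
    "DistributionSpec",
    "CrimeCategoryParams",
    "DatabaseState",
    "MurderParams",
    "ReagentSpec",
    "BudgetLine",
    "InstrumentPurchase",
    "CaseloadInputs",
    "DatabasePopulationInputs",
    "CostInputs",
    "Scenario",
    "load_config",
    "save_config",
    "load_fixture",
    "paper_scenario",
    "FIXTURE_NAMES",
]

Setting = Literal["low", "base", "high"]


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class DistributionSpec(_Frozen):
    """One uncertain model input.

    ``kind`` is ``triangular`` (low, mode, high), ``uniform`` (low, high) or
    ``point`` (a known constant, ``low == mode == high``).  Inputs flagged
    ``proportion=True`` are rates/fractions and must have support in [0, 1].

    The *base case* of a spec is the value the deterministic model uses when
    the input is held fixed: the mode for triangular, the midpoint for
    uniform, the value itself for point.
    """

    kind: Literal["triangular", "uniform", "point"]
    low: float
    high: float
    mode: Optional[float] = None
    proportion: bool = False

    @model_validator(mode="before")
    @classmethod
    def _accept_point_value(cls, data):
        # point specs may be written compactly as {"kind": "point", "value": v}
        if isinstance(data, dict) and data.get("kind") == "point" and "value" in data:
            data = dict(data)
            v = data.pop("value")
            data.update(low=v, high=v, mode=v)
        return data

    @model_serializer(mode="plain")
    def _serialize(self) -> dict:
        if self.kind == "point":
            out: dict = {"kind": "point", "value": self.low}
        else:
            out = {"kind": self.kind, "low": self.low, "high": self.high}
            if self.kind == "triangular":
                out["mode"] = self.mode
        if self.proportion:
            out["proportion"] = True
        return out

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        for name in ("low", "high"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.low > self.high:
            raise ValueError(f"low ({self.low}) must be <= high ({self.high})")
        if self.kind == "triangular":
            if self.mode is None:
                raise ValueError("triangular distribution requires a mode")
            if not math.isfinite(self.mode):
                raise ValueError("mode must be finite")
            if not (self.low <= self.mode <= self.high):
                raise ValueError(
                    f"triangular requires low <= mode <= high, got "
                    f"({self.low}, {self.mode}, {self.high})"
                )
        elif self.kind == "point":
            if not (self.low == self.high and (self.mode is None or self.mode == self.low)):
                raise ValueError("point distribution requires low == mode == high")
            object.__setattr__(self, "mode", self.low)
        elif self.mode is not None:
            raise ValueError("uniform distribution takes no mode")
        if self.proportion and not (0.0 <= self.low and self.high <= 1.0):
            raise ValueError(
                f"proportion support must lie in [0, 1], got [{self.low}, {self.high}]"
            )
        return self

    # -- constructors ------------------------------------------------------

    @classmethod
    def triangular(
        cls, low: float, mode: float, high: float, proportion: bool = False
    ) -> "DistributionSpec":
        return cls(kind="triangular", low=low, mode=mode, high=high, proportion=proportion)

    @classmethod
    def uniform(cls, low: float, high: float, proportion: bool = False) -> "DistributionSpec":
        return cls(kind="uniform", low=low, high=high, proportion=proportion)

    @classmethod
    def point(cls, value: float, proportion: bool = False) -> "DistributionSpec":
        return cls(kind="point", low=value, high=value, mode=value, proportion=proportion)

    # -- summaries ---------------------------------------------------------

    @property
    def is_point(self) -> bool:
        return self.kind == "point" or self.low == self.high

    @property
    def base(self) -> float:
        """Base-case value: mode (triangular/point) or midpoint (uniform)."""
        if self.kind == "uniform":
            return 0.5 * (self.low + self.high)
        return float(self.mode)  # type: ignore[arg-type]

    @property
    def mean(self) -> float:
        """Analytic mean: (low + mode + high)/3 for triangular, midpoint for uniform."""
        if self.kind == "triangular":
            return (self.low + self.mode + self.high) / 3.0  # type: ignore[operator]
        return 0.5 * (self.low + self.high)

    def at(self, setting: Setting) -> float:
        """Endpoint or base-case value for a deterministic evaluation."""
        if setting == "low":
            return self.low
        if setting == "high":
            return self.high
        if setting == "base":
            return self.base
        raise ValueError(f"unknown setting {setting!r}")


def _require_proportion(spec: DistributionSpec, field: str) -> None:
    if not (0.0 <= spec.low and spec.high <= 1.0):
        raise ValueError(f"{field}: support [{spec.low}, {spec.high}] must lie in [0, 1]")


def _require_nonnegative(spec: DistributionSpec, field: str) -> None:
    if spec.low < 0:
        raise ValueError(f"{field}: support must be non-negative, got low={spec.low}")


class CrimeCategoryParams(_Frozen):
    """The input rows for one crime category.

    ``hit_increase_share`` is the profile share used for the upload-increase
    term when the lifetime *hit* pool is evaluated; it defaults to
    ``category_share``.  The published workbook computed the hit-pool upload
    increment for the combined other-crimes category with the sexual-assault
    share, and the fixture mirrors that wiring so the printed totals
    reproduce.
    """

    name: str
    tangible_cost: DistributionSpec
    intangible_cost: DistributionSpec
    upload_increase: DistributionSpec
    upload_ratio: DistributionSpec
    category_share: DistributionSpec
    total_cases: DistributionSpec
    lead_rate: DistributionSpec
    reduction_rate: DistributionSpec
    extra_hours: DistributionSpec
    police_hourly_rate: DistributionSpec
    hit_increase_share: Optional[DistributionSpec] = None

    _FRACTIONS = ("upload_increase", "upload_ratio", "category_share", "lead_rate", "reduction_rate")
    _NONNEG = ("tangible_cost", "intangible_cost", "total_cases", "extra_hours", "police_hourly_rate")

    @model_validator(mode="after")
    def _check(self) -> "CrimeCategoryParams":
        for field in self._FRACTIONS:
            _require_proportion(getattr(self, field), f"{self.name}.{field}")
        for field in self._NONNEG:
            _require_nonnegative(getattr(self, field), f"{self.name}.{field}")
        if self.hit_increase_share is not None:
            _require_proportion(self.hit_increase_share, f"{self.name}.hit_increase_share")
        return self


class DatabaseState(_Frozen):
    """NDIS/SAKI database tallies anchoring the deterministic model."""

    total_forensic_profiles: int = Field(gt=0)
    lifetime_hits: int = Field(ge=0)
    annual_uploads: int = Field(gt=0)
    saki_completed_kits: int = Field(gt=0)
    saki_uploaded: int = Field(ge=0)
    saki_hits: int = Field(ge=0)
    saki_serial_hits: int = Field(ge=0)
    funding_low: float = Field(ge=0)
    funding_high: float = Field(ge=0)

    @model_validator(mode="after")
    def _check(self) -> "DatabaseState":
        if self.lifetime_hits > self.total_forensic_profiles:
            raise ValueError("lifetime_hits cannot exceed total_forensic_profiles")
        if not (self.saki_serial_hits <= self.saki_hits <= self.saki_uploaded <= self.saki_completed_kits):
            raise ValueError(
                "SAKI counts must satisfy serial_hits <= hits <= uploaded <= completed_kits"
            )
        if self.funding_low > self.funding_high:
            raise ValueError("funding_low cannot exceed funding_high")
        return self


class MurderParams(_Frozen):
    """Front end for the murder category: unsolved cases feed the chain."""

    reported_murders: int = Field(gt=0)
    clearance_rate: float = Field(ge=0.0, le=1.0)
    profile_yield: DistributionSpec
    horizon_years: int = Field(ge=1)
    serial_reduction: DistributionSpec

    @model_validator(mode="after")
    def _check(self) -> "MurderParams":
        _require_proportion(self.profile_yield, "murder.profile_yield")
        _require_proportion(self.serial_reduction, "murder.serial_reduction")
        return self

    @property
    def unsolved_per_year(self) -> float:
        """Murders without clearance in a year (carried unrounded)."""
        return self.reported_murders * (1.0 - self.clearance_rate)


class ReagentSpec(_Frozen):
    """Per-sample sequencing reagent economics for one run configuration.

    Library cost per sample comes either from a kit (``library_kit_cost`` /
    ``library_kit_size``) or from a flat ``per_library_override`` price;
    exactly one of the two must be given.  The run kit cost is split across
    ``plexity`` libraries pooled per sequencing run.
    """

    name: str
    library_kit_cost: Optional[float] = None
    library_kit_size: Optional[int] = None
    per_library_override: Optional[float] = None
    run_kit_cost: float = Field(ge=0)
    plexity: int = Field(ge=1)

    @model_validator(mode="after")
    def _check(self) -> "ReagentSpec":
        kit = self.library_kit_cost is not None or self.library_kit_size is not None
        override = self.per_library_override is not None
        if kit and override:
            raise ValueError(f"{self.name}: give a library kit or a per-library price, not both")
        if kit:
            if self.library_kit_cost is None or self.library_kit_size is None:
                raise ValueError(f"{self.name}: library kit needs both cost and size")
            if self.library_kit_cost < 0 or self.library_kit_size < 1:
                raise ValueError(f"{self.name}: invalid library kit cost/size")
        elif not override:
            raise ValueError(f"{self.name}: no library cost supplied")
        elif self.per_library_override < 0:  # type: ignore[operator]
            raise ValueError(f"{self.name}: per-library price must be non-negative")
        return self

    @property
    def per_library_cost(self) -> float:
        """Library preparation price per sample, rounded to the cent."""
        if self.per_library_override is not None:
            return round(self.per_library_override, 2)
        return round(self.library_kit_cost / self.library_kit_size, 2)  # type: ignore[operator]


class BudgetLine(_Frozen):
    """One annualized infrastructure line (capital spread over 10 years, or recurring)."""

    name: str
    total_cost: float = Field(ge=0)
    amortization_years: int = Field(ge=1, default=1)

    @property
    def annual_cost(self) -> float:
        return self.total_cost / self.amortization_years


class InstrumentPurchase(_Frozen):
    """Instrument line item; ``printed_total`` overrides count x unit_cost."""

    name: str
    count: int = Field(ge=0)
    unit_cost: float = Field(ge=0)
    printed_total: Optional[float] = None

    @property
    def total(self) -> float:
        return self.printed_total if self.printed_total is not None else self.count * self.unit_cost


class CaseloadInputs(_Frozen):
    """National casework volume and per-sample price scenarios."""

    requests_low: int = Field(ge=0)
    requests_high: int = Field(ge=0)
    samples_per_request: int = Field(ge=1)
    per_sample_high: float = Field(ge=0)
    per_sample_low: float = Field(ge=0)


class DatabasePopulationInputs(_Frozen):
    """Reference-database build-out volume and per-sample price scenarios."""

    samples_per_year: int = Field(ge=0)
    per_sample_high: float = Field(ge=0)
    per_sample_high_text: Optional[float] = None
    per_sample_low: float = Field(ge=0)
    microarray_per_sample: float = Field(ge=0)
    note: Optional[str] = None


class CostInputs(_Frozen):
    """All cost-model inputs: reagent run configurations, volumes, capital lines."""

    reagents: dict[str, ReagentSpec]
    caseload: CaseloadInputs
    database_population: DatabasePopulationInputs
    instruments: list[InstrumentPurchase]
    infrastructure: list[BudgetLine]


class Scenario(_Frozen):
    """A complete parameter set for one analysis run."""

    database: DatabaseState
    sexual_assault: CrimeCategoryParams
    other_crimes: CrimeCategoryParams
    murder_category: CrimeCategoryParams
    murder: MurderParams
    costs: CostInputs

    @property
    def categories(self) -> dict[str, CrimeCategoryParams]:
        return {
            "sexual_assault": self.sexual_assault,
            "other_crimes": self.other_crimes,
            "murder": self.murder_category,
        }


# ---------------------------------------------------------------------------
# config I/O and packaged fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("paper_tables_2_4", "paper_database_state", "paper_costs")

_FIXTURE_TYPES = {
    "paper_database_state": DatabaseState,
    "paper_costs": CostInputs,
}


def load_config(path: str | Path) -> Scenario:
    """Load and validate a full scenario from a JSON config file.

    Raises ``FileNotFoundError`` for a missing file, ``ValueError`` on parse
    failure, and ``pydantic.ValidationError`` (naming the offending field
    path and bound) on invariant violations.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    return Scenario.model_validate(payload)


def save_config(scenario: Scenario, path: str | Path) -> Path:
    """Serialize a scenario to JSON such that ``load_config`` round-trips it."""
    path = Path(path)
    path.write_text(json.dumps(scenario.model_dump(), indent=2) + "\n")
    return path


def _fixture_payload(name: str) -> dict:
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    text = resources.files("figgcba.data").joinpath(f"{name}.json").read_text()
    return json.loads(text)


def load_fixture(name: str):
    """Load one packaged fixture.

    ``paper_database_state`` -> :class:`DatabaseState`;
    ``paper_costs`` -> :class:`CostInputs`;
    ``paper_tables_2_4`` -> dict with the three crime-category parameter sets
    plus the murder front end.
    """
    payload = _fixture_payload(name)
    if name in _FIXTURE_TYPES:
        return _FIXTURE_TYPES[name].model_validate(payload)
    return {
        "sexual_assault": CrimeCategoryParams.model_validate(payload["sexual_assault"]),
        "other_crimes": CrimeCategoryParams.model_validate(payload["other_crimes"]),
        "murder_category": CrimeCategoryParams.model_validate(payload["murder_category"]),
        "murder": MurderParams.model_validate(payload["murder"]),
    }


def paper_scenario() -> Scenario:
    """The packaged published-input scenario (Tables 2-4, database state, costs)."""
    tables = load_fixture("paper_tables_2_4")
    return Scenario(
        database=load_fixture("paper_database_state"),
        sexual_assault=tables["sexual_assault"],
        other_crimes=tables["other_crimes"],
        murder_category=tables["murder_category"],
        murder=tables["murder"],
        costs=load_fixture("paper_costs"),
    )
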
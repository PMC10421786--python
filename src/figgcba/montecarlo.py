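"""Monte Carlo uncertainty propagation and tornado sensitivity analysis.

Every uncertain input is an independent triangular/uniform/point
distribution; each trial samples all of them and pushes the values through
the annual multiplicative chain per crime category.  Two model variants are
provided because the published workbook's wiring is ambiguous:

* ``annual_uploads`` (default) — the chain used by the published static
  annual arithmetic: ``annual uploads x (1+u) x share x lead rate x
  reduction``, with the murder category driven by its unsolved-case front
  end (unsolved/yr x profile yield x (1+u) x lead rate x serial reduction).
* ``total_cases`` — the input tables read verbatim: ``total cases x share
  x upload ratio x (1+u) x lead rate x reduction``.

Sampling is reproducible and reordering-safe: each named input draws from
its own substream derived from the run seed and a stable hash of the input
name, so adding or reordering inputs does not disturb the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import (
    CrimeCategoryParams,
    DatabaseState,
    DistributionSpec,
    MurderParams,
)

__all__ = [
    "sample",
    "model_inputs",
    "evaluate",
    "run_trials",
    "TrialRecord",
    "TrialSet",
    "SimulationSummary",
    "summarize",
    "SensitivityRow",
    "tornado",
    "envelope",
]

MODEL_VARIANTS = ("annual_uploads", "total_cases")

_OUTCOME_FIELDS = ("leads", "victims_prevented", "tangible", "intangible", "investigation_cost")


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample(dist, rng: np.random.Generator, size: int | None = None):
    """Draw from a distribution spec with a seeded generator.

    Triangular draws use the generator's two-branch inverse-CDF sampler;
    uniform draws are an affine transform of unit uniforms; point specs
    return the constant.  Objects with ``kind == "discrete"`` (finite
    support with probabilities, used by the enumeration oracle) are also
    accepted.
    """
    kind = getattr(dist, "kind", None)
    if kind == "discrete":
        return rng.choice(np.asarray(dist.values, dtype=float), size=size, p=dist.probs)
    if kind == "point" or dist.low == dist.high:
        value = float(dist.low)
        return value if size is None else np.full(size, value)
    if kind == "triangular":
        return rng.triangular(dist.low, dist.mode, dist.high, size=size)
    if kind == "uniform":
        return rng.uniform(dist.low, dist.high, size=size)
    raise ValueError(f"cannot sample from distribution kind {kind!r}")


def _input_rng(seed: int, name: str) -> np.random.Generator:
    """Independent, deterministic substream for one named input."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# model wiring
# ---------------------------------------------------------------------------


def _variant_fields(variant: str) -> tuple[str, ...]:
    if variant == "annual_uploads":
        return (
            "upload_increase",
            "category_share",
            "lead_rate",
            "reduction_rate",
            "tangible_cost",
            "intangible_cost",
            "extra_hours",
            "police_hourly_rate",
        )
    if variant == "total_cases":
        return (
            "total_cases",
            "category_share",
            "upload_ratio",
            "upload_increase",
            "lead_rate",
            "reduction_rate",
            "tangible_cost",
            "intangible_cost",
            "extra_hours",
            "police_hourly_rate",
        )
    raise ValueError(f"unknown model variant {variant!r}; choose from {MODEL_VARIANTS}")


def model_inputs(
    categories: Sequence[CrimeCategoryParams],
    mp: MurderParams | None,
    model_variant: str = "annual_uploads",
) -> dict[str, DistributionSpec]:
    """Named distribution set the simulation samples, in a stable order.

    Under the default variant the category named ``murder`` contributes the
    unsolved-case front end's profile-yield and serial-reduction
    distributions instead of share/reduction rows.
    """
    fields = _variant_fields(model_variant)
    inputs: dict[str, DistributionSpec] = {}
    for params in categories:
        is_murder = params.name == "murder" and model_variant == "annual_uploads"
        for f in fields:
            if is_murder and f in ("category_share", "reduction_rate"):
                continue
            inputs[f"{params.name}.{f}"] = getattr(params, f)
        if is_murder:
            if mp is None:
                raise ValueError("murder category requires MurderParams under the default variant")
            inputs["murder.profile_yield"] = mp.profile_yield
            inputs["murder.serial_reduction"] = mp.serial_reduction
    return inputs


def evaluate(
    values: Mapping[str, float | np.ndarray],
    db: DatabaseState,
    categories: Sequence[CrimeCategoryParams],
    mp: MurderParams | None,
    model_variant: str = "annual_uploads",
) -> dict[str, float | np.ndarray]:
    """Deterministic annual chain on concrete input values (scalars or arrays).

    Returns per-category and combined outcomes keyed
    ``"<category>.<outcome>"`` with outcomes ``leads``,
    ``victims_prevented``, ``tangible``, ``intangible`` and
    ``investigation_cost``.
    """
    outcomes: dict[str, float | np.ndarray] = {}
    combined: dict[str, float | np.ndarray] = {f: 0.0 for f in _OUTCOME_FIELDS}
    for params in categories:
        c = params.name
        v = lambda f: values[f"{c}.{f}"]  # noqa: E731
        if model_variant == "annual_uploads":
            if c == "murder":
                if mp is None:
                    raise ValueError("murder category requires MurderParams")
                pool = mp.unsolved_per_year * values["murder.profile_yield"]
                leads = pool * (1.0 + v("upload_increase")) * v("lead_rate")
                victims = leads * values["murder.serial_reduction"]
            else:
                leads = db.annual_uploads * (1.0 + v("upload_increase")) * v("category_share") * v("lead_rate")
                victims = leads * v("reduction_rate")
        elif model_variant == "total_cases":
            leads = (
                v("total_cases")
                * v("category_share")
                * v("upload_ratio")
                * (1.0 + v("upload_increase"))
                * v("lead_rate")
            )
            victims = leads * v("reduction_rate")
        else:
            raise ValueError(f"unknown model variant {model_variant!r}")
        cat_out = {
            "leads": leads,
            "victims_prevented": victims,
            "tangible": victims * v("tangible_cost"),
            "intangible": victims * v("intangible_cost"),
            "investigation_cost": leads * v("extra_hours") * v("police_hourly_rate"),
        }
        for f, value in cat_out.items():
            outcomes[f"{c}.{f}"] = value
            combined[f] = combined[f] + value
    for f, value in combined.items():
        outcomes[f"combined.{f}"] = value
    return outcomes


# ---------------------------------------------------------------------------
# trial runner
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialRecord:
    """One simulation trial: the sampled inputs and the resulting outcomes."""

    trial_index: int
    sampled_inputs: dict[str, float]
    outcomes: dict[str, float]


@dataclass(frozen=True)
class TrialSet:
    """Columnar container for a simulation run; iterates as TrialRecords."""

    seed: int
    model_variant: str
    inputs: pd.DataFrame
    outcomes: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.inputs)

    def __len__(self) -> int:
        return self.n_trials

    def __getitem__(self, i: int) -> TrialRecord:
        return TrialRecord(
            trial_index=int(self.inputs.index[i]),
            sampled_inputs=self.inputs.iloc[i].to_dict(),
            outcomes=self.outcomes.iloc[i].to_dict(),
        )

    def __iter__(self) -> Iterator[TrialRecord]:
        for i in range(self.n_trials):
            yield self[i]


def run_trials(
    db: DatabaseState,
    categories: Sequence[CrimeCategoryParams],
    mp: MurderParams | None,
    n_trials: int = 1000,
    seed: int = 0,
    model_variant: str = "annual_uploads",
) -> TrialSet:
    """Run the Monte Carlo simulation; deterministic given the seed."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    inputs = model_inputs(categories, mp, model_variant)
    sampled = {
        name: np.asarray(sample(dist, _input_rng(seed, name), size=n_trials))
        for name, dist in inputs.items()
    }
    outcomes = evaluate(sampled, db, categories, mp, model_variant)
    return TrialSet(
        seed=seed,
        model_variant=model_variant,
        inputs=pd.DataFrame(sampled),
        outcomes=pd.DataFrame(outcomes),
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

_QUANTILES = (0.025, 0.25, 0.50, 0.75, 0.975)


@dataclass(frozen=True)
class SimulationSummary:
    """Descriptive statistics and histograms for every simulated outcome."""

    n_trials: int
    seed: int
    model_variant: str
    outcomes: dict[str, dict] = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "seed": self.seed,
            "model_variant": self.model_variant,
            "outcomes": self.outcomes,
        }


def summarize(trials: TrialSet, bins: int = 30) -> SimulationSummary:
    """Exact descriptive statistics of the trial set.

    Histograms are equal-width over [min, max] with ``bins`` bins.
    """
    if trials.n_trials < 1:
        raise ValueError("need at least one trial")
    stats: dict[str, dict] = {}
    for name, series in trials.outcomes.items():
        x = series.to_numpy(dtype=float)
        counts, edges = np.histogram(x, bins=bins)
        stats[name] = {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
            "min": float(x.min()),
            "max": float(x.max()),
            "quantiles": {str(q): float(np.quantile(x, q)) for q in _QUANTILES},
            "histogram": {"edges": edges.tolist(), "counts": counts.tolist()},
        }
    return SimulationSummary(
        n_trials=trials.n_trials,
        seed=trials.seed,
        model_variant=trials.model_variant,
        outcomes=stats,
    )


# ---------------------------------------------------------------------------
# one-at-a-time (tornado) sensitivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityRow:
    """Outcome swing when one input moves low -> high, all else at base."""

    input_name: str
    outcome_at_low: float
    outcome_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def tornado(
    db: DatabaseState,
    categories: Sequence[CrimeCategoryParams],
    mp: MurderParams | None,
    outcome: str,
    model_variant: str = "annual_uploads",
) -> list[SensitivityRow]:
    """One-at-a-time sensitivity of one outcome, rows sorted by descending swing.

    For every uncertain input the deterministic model is evaluated with
    that input at its low and at its high endpoint while every other input
    sits at its base case.
    """
    inputs = model_inputs(categories, mp, model_variant)
    base = {name: dist.base for name, dist in inputs.items()}
    probe = evaluate(base, db, categories, mp, model_variant)
    if outcome not in probe:
        raise KeyError(f"unknown outcome {outcome!r}; available: {sorted(probe)}")
    rows = []
    for name, dist in inputs.items():
        values = []
        for endpoint in (dist.low, dist.high):
            point = dict(base)
            point[name] = endpoint
            values.append(float(evaluate(point, db, categories, mp, model_variant)[outcome]))
        rows.append(SensitivityRow(input_name=name, outcome_at_low=values[0], outcome_at_high=values[1]))
    return sorted(rows, key=lambda r: r.swing, reverse=True)


def envelope(
    db: DatabaseState,
    categories: Sequence[CrimeCategoryParams],
    mp: MurderParams | None,
    model_variant: str = "annual_uploads",
) -> tuple[dict[str, float], dict[str, float]]:
    """All-low and all-high deterministic outcome bounds.

    The chain is non-decreasing in every input, so every trial outcome lies
    inside this envelope.
    """
    inputs = model_inputs(categories, mp, model_variant)
    bounds = []
    for attr in ("low", "high"):
        values = {name: getattr(dist, attr) for name, dist in inputs.items()}
        out = evaluate(values, db, categories, mp, model_variant)
        bounds.append({k: float(v) for k, v in out.items()})
    return bounds[0], bounds[1]
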
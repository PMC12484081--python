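"""Scenario suite: the baseline estimate and six named sensitivity variants.

Each scenario is a declarative transformation of the inputs or assumptions
feeding the exposure-distribution and dose-response stages:

baseline
    point mass at the country mean BLL (dose-response evaluated at the mean);
log-normal
    full distributional integration, with the log-normal fitted from the
    country mean and the share above 5 µg/dL (falling back to the
    two-exceedance fit when the mean-based fit is infeasible);
lower_bound
    a conservative dose-response variant: no-effect threshold plus a lower
    slope, both configurable;
lower_ci / upper_ci
    point mass at the lower / upper interval bound of the mean BLL;
increase_5 / increase_10
    BLL location multiplied by 1.05 / 1.10 before the distribution is
    built — an exposure increase, not a cost rescaling, which matters under
    a nonlinear dose-response.

Running a suite over a country table yields the scenario-by-region matrix
(six continent means of the relative cost, plus a global dollar total per
scenario).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .bll_distribution import (
    ExposureDistribution,
    fit_lognormal_mean_exceedance,
    fit_lognormal_two_exceedances,
    make_degenerate,
)
from .cost_model import CountryResult, SummaryTable, absolute_cost, relative_iq_cost, summarize
from .country_data import CONTINENTS, CountryRecord, EconomicParams, QuadratureSettings
from .dose_response import DoseResponseSpec, expected_iq_loss
from .errors import FeasibilityError, ScenarioError


@dataclass(frozen=True)
class ScenarioSpec:
    """A named transformation of pipeline inputs and assumptions."""

    name: str
    family: str = "degenerate"  # distribution family to construct
    mean_source: str = "bll_mean"  # which BLL field supplies the location
    bll_multiplier: float = 1.0
    dr_variant: DoseResponseSpec | None = None

    def __post_init__(self):
        if self.bll_multiplier < 0:
            raise ValueError("bll_multiplier must be non-negative")
        if self.family not in ("degenerate", "lognormal", "normal"):
            raise ValueError(f"unknown scenario family {self.family!r}")
        if self.mean_source not in ("bll_mean", "bll_lo", "bll_hi"):
            raise ValueError(f"unknown mean_source {self.mean_source!r}")

    @staticmethod
    def named(name: str) -> "ScenarioSpec":
        """The built-in definition of one of the seven named scenarios."""
        try:
            return _NAMED[name]
        except KeyError:
            raise ValueError(
                f"unknown scenario name {name!r}; known: {sorted(_NAMED)}"
            ) from None


#: Conservative dose-response used by the "lower_bound" scenario: a
#: 2 µg/dL no-effect threshold and roughly half the default log-slope.
LOWER_BOUND_DR = DoseResponseSpec(
    form="loglinear", coefficients=(1.4,), threshold=2.0
)

_NAMED = {
    "baseline": ScenarioSpec("baseline"),
    "log-normal": ScenarioSpec("log-normal", family="lognormal"),
    "lower_bound": ScenarioSpec("lower_bound", dr_variant=LOWER_BOUND_DR),
    "lower_ci": ScenarioSpec("lower_ci", mean_source="bll_lo"),
    "upper_ci": ScenarioSpec("upper_ci", mean_source="bll_hi"),
    "increase_5": ScenarioSpec("increase_5", bll_multiplier=1.05),
    "increase_10": ScenarioSpec("increase_10", bll_multiplier=1.10),
}


def default_suite() -> tuple[ScenarioSpec, ...]:
    """The seven named scenarios, baseline first."""
    return tuple(_NAMED.values())


def _shift_location(
    dist: ExposureDistribution, mult: float
) -> ExposureDistribution:
    if mult == 1.0:
        return dist
    if dist.family == "degenerate":
        return make_degenerate(dist.params[0] * mult)
    if dist.family == "normal":
        loc, scale = dist.params
        return ExposureDistribution("normal", (loc * mult, scale))
    mu, sigma = dist.params
    if mult == 0.0:
        return make_degenerate(0.0)
    return ExposureDistribution("lognormal", (mu + math.log(mult), sigma))


def apply_scenario(
    record: CountryRecord,
    spec: ScenarioSpec,
    dr: DoseResponseSpec,
    root_policy: str = "smaller_sigma",
) -> tuple[ExposureDistribution, DoseResponseSpec]:
    """Build the effective exposure distribution and dose-response for a country.

    Raises :class:`ScenarioError` when a log-normal scenario has no
    exceedance data to fit from; an infeasible fit propagates with the
    country id attached.
    """
    effective_dr = spec.dr_variant if spec.dr_variant is not None else dr
    loc = float(getattr(record, spec.mean_source))

    if spec.family == "degenerate":
        dist = make_degenerate(loc)
    elif spec.family == "lognormal":
        if record.p_gt5 is None and record.p_gt10 is None:
            raise ScenarioError(
                f"country {record.iso3}: log-normal scenario requires at "
                "least one exceedance share (p_gt5 or p_gt10)"
            )
        if (record.p_gt5 == 0.0 and loc < 5.0) or loc == 0.0:
            # degenerate limit: no dispersion is representable when no mass
            # lies above the threshold (or there is no exposure at all)
            return _shift_location(make_degenerate(loc), spec.bll_multiplier), effective_dr
        dist = None
        if record.p_gt5 is not None and 0.0 < record.p_gt5 < 1.0:
            try:
                dist = fit_lognormal_mean_exceedance(
                    loc,
                    record.p_gt5,
                    threshold=5.0,
                    root_policy=root_policy,
                    second_p=record.p_gt10,
                    second_threshold=10.0,
                )
            except FeasibilityError:
                dist = None  # fall through to the two-exceedance fit
        if dist is None:
            if (
                record.p_gt5 is None
                or record.p_gt10 is None
                or not 0.0 < record.p_gt10 < record.p_gt5 < 1.0
            ):
                raise ScenarioError(
                    f"country {record.iso3}: mean+exceedance log-normal fit "
                    "infeasible and two-exceedance fallback unavailable"
                )
            dist = fit_lognormal_two_exceedances(record.p_gt5, record.p_gt10)
    else:  # normal: scale set from the interval half-width, floored
        half_width = max((record.bll_hi - record.bll_lo) / 2.0, 1e-6)
        dist = ExposureDistribution("normal", (loc, half_width))

    return _shift_location(dist, spec.bll_multiplier), effective_dr


def run_scenario(
    records: Sequence[CountryRecord],
    spec: ScenarioSpec,
    dr: DoseResponseSpec,
    econ: EconomicParams,
    quad: QuadratureSettings | None = None,
    root_policy: str = "smaller_sigma",
) -> list[CountryResult]:
    """Run one scenario over all countries; deterministic for fixed inputs.

    Per-country failures are collected and raised together as a single
    :class:`ScenarioError` listing every failing country.
    """
    results: list[CountryResult] = []
    failures: dict[str, Exception] = {}
    for rec in records:
        try:
            dist, eff_dr = apply_scenario(rec, spec, dr, root_policy)
            loss = expected_iq_loss(dist, eff_dr, quad)
            rel = relative_iq_cost(loss, econ, rec.ret_edu)
            results.append(
                CountryResult(
                    iso3=rec.iso3,
                    mean_iq_loss=loss,
                    relative_cost_pct=rel,
                    absolute_cost=absolute_cost(rel, rec.gdp_pc, rec.pop_0_19),
                )
            )
        except Exception as exc:  # noqa: BLE001 - aggregated and re-raised
            failures[rec.iso3] = exc
    if failures:
        details = "; ".join(f"{k}: {v}" for k, v in failures.items())
        raise ScenarioError(
            f"scenario {spec.name!r} failed for {len(failures)} "
            f"country(ies): {details}",
            failures=failures,
        )
    return results


def run_sensitivity_suite(
    records: Sequence[CountryRecord],
    suite: Sequence[ScenarioSpec],
    dr: DoseResponseSpec,
    econ: EconomicParams,
    quad: QuadratureSettings | None = None,
    weighting: str = "population",
    root_policy: str = "smaller_sigma",
) -> tuple[pd.DataFrame, dict[str, SummaryTable], dict[str, list[CountryResult]]]:
    """Run every scenario and assemble the region-by-scenario matrix.

    Returns
    -------
    matrix
        DataFrame with one column per scenario; the six continent rows hold
        mean relative costs in percent, the final ``Global`` row the total
        annual cost in 2021 international dollars.
    summaries
        scenario name -> :class:`SummaryTable`.
    results
        scenario name -> per-country result list.
    """
    names = [s.name for s in suite]
    if len(names) != len(set(names)):
        raise ValueError("scenario names must be unique within a suite")
    summaries: dict[str, SummaryTable] = {}
    all_results: dict[str, list[CountryResult]] = {}
    for spec in suite:
        res = run_scenario(records, spec, dr, econ, quad, root_policy)
        all_results[spec.name] = res
        summaries[spec.name] = summarize(res, records, weighting)

    rows = [c for c in CONTINENTS if any(r.continent == c for r in records)]
    data = {}
    for name, summ in summaries.items():
        col = [summ.continent_mean_pct.get(c, float("nan")) for c in rows]
        col.append(summ.global_total)
        data[name] = col
    matrix = pd.DataFrame(data, index=[*rows, "Global"])
    return matrix, summaries, all_results
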
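"""Monetize IQ loss as foregone lifetime earnings, and aggregate.

The relative IQ cost of country i is

    rel_i = min(cap, 100 * L_i * e_US * (r_i / r_US))            [percent]

where L_i is the mean IQ points lost per 0-19-year-old, e_US the fractional
lifetime-earnings loss per IQ point in the US reference economy, and
r_i / r_US rescales by the country's returns to education relative to the
US — a proxy for the relative economic return to cognitive skill.  The
absolute cost converts the percentage to an annual dollar flow:

    abs_i = rel_i / 100 * gdp_pc_i * pop_0_19_i    [2021 international $/yr]

Summing abs_i over countries gives the global total; continent summaries
report the (population-weighted or simple) mean of rel_i.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

import numpy as np

from .country_data import CountryRecord, EconomicParams


@dataclass(frozen=True)
class CountryResult:
    """Per-country pipeline output."""

    iso3: str
    mean_iq_loss: float
    relative_cost_pct: float
    absolute_cost: float


@dataclass(frozen=True)
class SummaryTable:
    """Continent means, global total and distributional statistics."""

    continent_mean_pct: Mapping[str, float]
    global_total: float
    weighting: str
    median_pct: float
    min_pct: float
    max_pct: float

    def to_dict(self) -> dict:
        return {
            "continent_mean_pct": dict(self.continent_mean_pct),
            "global_total": self.global_total,
            "weighting": self.weighting,
            "median_pct": self.median_pct,
            "min_pct": self.min_pct,
            "max_pct": self.max_pct,
        }


def relative_iq_cost(
    mean_iq_loss: float, econ: EconomicParams, ret_edu: float
) -> float:
    """Percent of lifetime earnings foregone, capped at ``econ.cap_pct``."""
    if mean_iq_loss < 0:
        raise ValueError("mean IQ loss must be non-negative")
    if ret_edu < 0:
        raise ValueError("returns to education must be non-negative")
    econ.validate()
    raw = 100.0 * mean_iq_loss * econ.e_us * (ret_edu / econ.r_us)
    return min(econ.cap_pct, raw)


def absolute_cost(relative_cost_pct: float, gdp_pc: float, pop_0_19: float) -> float:
    """Annual dollar cost: percentage of earnings times GDP pc times cohort size."""
    if relative_cost_pct < 0 or gdp_pc < 0 or pop_0_19 < 0:
        raise ValueError("cost inputs must be non-negative")
    return relative_cost_pct / 100.0 * gdp_pc * pop_0_19


def summarize(
    results: Sequence[CountryResult],
    records: Sequence[CountryRecord],
    weighting: str = "population",
) -> SummaryTable:
    """Aggregate per-country results to continent means and a global total.

    ``results`` and ``records`` must be keyed by the same iso3 set.
    Continent means average ``relative_cost_pct`` either weighted by the
    0-19 population or unweighted, per the ``weighting`` flag.
    """
    if weighting not in ("population", "unweighted"):
        raise ValueError(f"unknown weighting mode {weighting!r}")
    if not results:
        raise ValueError("cannot summarize an empty result list")
    rec_by_iso = {r.iso3: r for r in records}
    res_isos = {r.iso3 for r in results}
    if res_isos != set(rec_by_iso):
        missing = res_isos.symmetric_difference(rec_by_iso)
        raise KeyError(f"results and records keyed differently: {sorted(missing)}")

    by_continent: dict[str, list[CountryResult]] = {}
    for res in results:
        cont = rec_by_iso[res.iso3].continent
        by_continent.setdefault(cont, []).append(res)

    means: dict[str, float] = {}
    for cont, group in by_continent.items():
        if not group:
            raise ValueError(f"empty continent group {cont!r}")
        pcts = np.array([g.relative_cost_pct for g in group])
        if weighting == "population":
            w = np.array([float(rec_by_iso[g.iso3].pop_0_19) for g in group])
            if w.sum() == 0:
                raise ValueError(
                    f"continent {cont!r} has zero total population; "
                    "population weighting undefined"
                )
            means[cont] = float(np.average(pcts, weights=w))
        else:
            means[cont] = float(pcts.mean())

    all_pcts = [r.relative_cost_pct for r in results]
    return SummaryTable(
        continent_mean_pct=means,
        global_total=float(sum(r.absolute_cost for r in results)),
        weighting=weighting,
        median_pct=float(median(all_pcts)),
        min_pct=float(min(all_pcts)),
        max_pct=float(max(all_pcts)),
    )
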
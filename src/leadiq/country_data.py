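"""Domain types, validation and tabular IO for the per-country input data.

The pipeline's atomic input is one country's blood-lead-level (BLL) summary
statistics for ages 0-19 together with the economic covariates needed to
monetize cognitive damage: GDP per capita at purchasing power parity
(constant 2021 international dollars), the population aged 0-19, and the
country's returns to education (fractional earnings gain per year of
schooling, used as a proxy for the returns to cognitive skill).

Tables are plain CSV, UTF-8, "." decimal, header required.  Optional
exceedance shares (fraction of children above 5 / 10 µg/dL) are encoded as
empty cells when absent — never as sentinel numbers, since 0 is a meaningful
exceedance value.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, RowValidationError, SchemaError

#: The six aggregation regions used for continent-level reporting.
CONTINENTS = (
    "Africa",
    "Asia",
    "Europe",
    "North America",
    "Oceania",
    "South/Central America",
)

#: Canonical CSV column order for country input tables.
INPUT_COLUMNS = (
    "iso3",
    "name",
    "continent",
    "bll_mean",
    "bll_lo",
    "bll_hi",
    "p_gt5",
    "p_gt10",
    "gdp_pc",
    "pop0_19",
    "ret_edu",
)

#: Canonical CSV column order for per-country result tables.
RESULT_COLUMNS = ("iso3", "mean_iq_loss", "relative_cost_pct", "absolute_cost")


@dataclass(frozen=True)
class CountryRecord:
    """One country's exposure summaries plus economic covariates.

    BLL fields are µg/dL; ``bll_lo``/``bll_hi`` bound the mean estimate
    (interval bounds, not population quantiles).  ``p_gt5``/``p_gt10`` are
    the shares of 0-19-year-olds above 5 and 10 µg/dL, or ``None`` when the
    source does not report them.
    """

    iso3: str
    name: str
    continent: str
    bll_mean: float
    bll_lo: float
    bll_hi: float
    p_gt5: float | None
    p_gt10: float | None
    gdp_pc: float
    pop_0_19: int
    ret_edu: float

    def validate(self) -> None:
        """Raise :class:`RowValidationError` on any invariant violation."""
        if len(self.iso3) != 3:
            raise RowValidationError(self.iso3, "iso3", "must be a 3-letter code")
        if self.continent not in CONTINENTS:
            raise RowValidationError(
                self.iso3,
                "continent",
                f"{self.continent!r} is not one of {CONTINENTS}",
            )
        if not 0 <= self.bll_lo <= self.bll_mean <= self.bll_hi:
            raise RowValidationError(
                self.iso3,
                "bll_mean",
                f"interval ordering 0 <= lo <= mean <= hi violated: "
                f"lo={self.bll_lo}, mean={self.bll_mean}, hi={self.bll_hi}",
            )
        for fname in ("p_gt5", "p_gt10"):
            val = getattr(self, fname)
            if val is not None and not 0.0 <= val <= 1.0:
                raise RowValidationError(self.iso3, fname, f"{val} not in [0, 1]")
        if self.p_gt5 is not None and self.p_gt10 is not None:
            if self.p_gt10 > self.p_gt5:
                raise RowValidationError(
                    self.iso3,
                    "p_gt10",
                    f"p_gt10={self.p_gt10} exceeds p_gt5={self.p_gt5}",
                )
        if not self.gdp_pc > 0:
            raise RowValidationError(self.iso3, "gdp_pc", "must be positive")
        if self.pop_0_19 < 0:
            raise RowValidationError(self.iso3, "pop0_19", "must be non-negative")
        if not self.ret_edu > 0:
            raise RowValidationError(self.iso3, "ret_edu", "must be positive")


@dataclass(frozen=True)
class EconomicParams:
    """Monetization parameters.

    ``e_us`` is the fractional lifetime-earnings loss per IQ point in the US
    reference economy; ``r_us`` the US returns to education; ``cap_pct`` the
    maximum relative cost (foregone earnings cannot exceed earnings).
    """

    e_us: float = 0.02
    r_us: float = 0.10
    cap_pct: float = 100.0

    def validate(self) -> None:
        if not self.e_us > 0:
            raise ConfigError("e_us must be positive")
        if not self.r_us > 0:
            raise ConfigError("r_us must be positive")
        if not 0 < self.cap_pct <= 100:
            raise ConfigError("cap_pct must be in (0, 100]")


# ---------------------------------------------------------------------------
# Table IO


def _parse_optional(value: Any) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def read_country_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[CountryRecord]:
    """Read and validate a per-country CSV input table.

    Parameters
    ----------
    path
        CSV file with a header row and the columns in :data:`INPUT_COLUMNS`.
    schema
        Optional mapping from canonical column names to the names used in
        the file, for tables exported under different conventions.

    Returns
    -------
    list of CountryRecord, in file row order, every record validated.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype={"iso3": str, "name": str, "continent": str})
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in INPUT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[CountryRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        rec = CountryRecord(
            iso3=str(row.iso3),
            name=str(row.name),
            continent=str(row.continent),
            bll_mean=float(row.bll_mean),
            bll_lo=float(row.bll_lo),
            bll_hi=float(row.bll_hi),
            p_gt5=_parse_optional(row.p_gt5),
            p_gt10=_parse_optional(row.p_gt10),
            gdp_pc=float(row.gdp_pc),
            pop_0_19=int(row.pop0_19),
            ret_edu=float(row.ret_edu),
        )
        if rec.iso3 in seen:
            raise SchemaError(f"duplicate iso3 code: {rec.iso3}")
        seen.add(rec.iso3)
        rec.validate()
        records.append(rec)
    return records


def write_country_table(records: Sequence[CountryRecord], path: str | Path) -> None:
    """Write country records back to the canonical CSV schema."""
    if not records:
        raise ValueError("cannot write an empty country table")
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["pop0_19"] = d.pop("pop_0_19")
        rows.append(d)
    df = pd.DataFrame(rows, columns=INPUT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def write_results(results: Sequence["CountryResult"], path: str | Path) -> None:
    """Write per-country results as CSV with >= 10 significant digits."""
    if not results:
        raise ValueError("cannot write an empty result table")
    df = pd.DataFrame([dataclasses.asdict(r) for r in results], columns=RESULT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_results(path: str | Path) -> list["CountryResult"]:
    """Read back a result table written by :func:`write_results`."""
    from .cost_model import CountryResult

    df = pd.read_csv(path, dtype={"iso3": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing result column(s): {', '.join(missing)}")
    return [
        CountryResult(
            iso3=str(row.iso3),
            mean_iq_loss=float(row.mean_iq_loss),
            relative_cost_pct=float(row.relative_cost_pct),
            absolute_cost=float(row.absolute_cost),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class QuadratureSettings:
    """Settings for distributional expectations (see dose_response)."""

    nodes: int = 128
    rel_tol: float = 1e-8

    def validate(self) -> None:
        if self.nodes < 2:
            raise ConfigError("quadrature nodes must be >= 2")
        if not 0 < self.rel_tol < 1:
            raise ConfigError("quadrature rel_tol must be in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """Full run configuration: economics, dose-response, scenarios, numerics."""

    econ: EconomicParams
    dose_response: "DoseResponseSpec"
    scenarios: tuple["ScenarioSpec", ...]
    quadrature: QuadratureSettings
    seed: int = 0
    weighting: str = "population"
    root_policy: str = "smaller_sigma"

    def validate(self) -> None:
        self.econ.validate()
        self.dose_response.validate()
        self.quadrature.validate()
        if self.weighting not in ("population", "unweighted"):
            raise ConfigError(f"unknown weighting mode {self.weighting!r}")
        if self.root_policy not in (
            "smaller_sigma",
            "larger_sigma",
            "match_second_exceedance",
        ):
            raise ConfigError(f"unknown root_policy {self.root_policy!r}")
        names = [s.name for s in self.scenarios]
        if len(names) != len(set(names)):
            raise ConfigError("scenario names must be unique within a suite")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = [dataclasses.asdict(s) for s in self.scenarios]
        return d


_TOP_KEYS = {
    "econ",
    "dose_response",
    "scenarios",
    "quadrature",
    "seed",
    "weighting",
    "root_policy",
}


def _build_section(cls, data: Mapping[str, Any], section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in {section}: {', '.join(sorted(unknown))}")
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration, filling defaults.

    Unknown keys are rejected so that typos fail loudly rather than
    silently falling back to defaults.
    """
    from .dose_response import DoseResponseSpec
    from .scenarios import ScenarioSpec, default_suite

    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")

    econ = _build_section(EconomicParams, raw.get("econ", {}), "econ")
    dr_raw = dict(raw.get("dose_response", {}))
    for key in ("coefficients", "knots"):
        if key in dr_raw and isinstance(dr_raw[key], list):
            dr_raw[key] = tuple(dr_raw[key])
    if dr_raw:
        dr = _build_section(DoseResponseSpec, dr_raw, "dose_response")
    else:
        dr = DoseResponseSpec.default()
    if "scenarios" in raw:
        scen = []
        for i, s in enumerate(raw["scenarios"]):
            if isinstance(s, str):
                scen.append(ScenarioSpec.named(s))
            else:
                s = dict(s)
                if "dr_variant" in s and isinstance(s["dr_variant"], Mapping):
                    dv = dict(s["dr_variant"])
                    for key in ("coefficients", "knots"):
                        if key in dv and isinstance(dv[key], list):
                            dv[key] = tuple(dv[key])
                    s["dr_variant"] = _build_section(
                        DoseResponseSpec, dv, f"scenarios[{i}].dr_variant"
                    )
                scen.append(_build_section(ScenarioSpec, s, f"scenarios[{i}]"))
        scenarios = tuple(scen)
    else:
        scenarios = default_suite()
    quad = _build_section(QuadratureSettings, raw.get("quadrature", {}), "quadrature")

    cfg = RunConfig(
        econ=econ,
        dose_response=dr,
        scenarios=scenarios,
        quadrature=quad,
        seed=int(raw.get("seed", 0)),
        weighting=str(raw.get("weighting", "population")),
        root_policy=str(raw.get("root_policy", "smaller_sigma")),
    )
    cfg.validate()
    return cfg


def default_config() -> RunConfig:
    """The package's default run configuration."""
    from .dose_response import DoseResponseSpec
    from .scenarios import default_suite

    cfg = RunConfig(
        econ=EconomicParams(),
        dose_response=DoseResponseSpec.default(),
        scenarios=default_suite(),
        quadrature=QuadratureSettings(),
    )
    cfg.validate()
    return cfg
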
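"""Input-table parsing, validation and run-configuration loading."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from leadiq import (
    CountryRecord,
    CountryResult,
    default_config,
    load_config,
    read_country_table,
    read_results,
    write_country_table,
    write_results,
)
from leadiq.country_data import CONTINENTS
from leadiq.errors import ConfigError, RowValidationError, SchemaError

HEADER = "iso3,name,continent,bll_mean,bll_lo,bll_hi,p_gt5,p_gt10,gdp_pc,pop0_19,ret_edu"


def write_csv(tmp_path, rows, header=HEADER):
    path = tmp_path / "countries.csv"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


class TestReadCountryTable:
    def test_identity_parse(self, tmp_path):
        path = write_csv(
            tmp_path,
            [
                "NGA,Nigeria,Africa,7.5,6.0,9.0,0.6,0.25,5000,90000000,0.12",
                "DEU,Germany,Europe,1.2,1.0,1.5,,,55000,15000000,0.08",
            ],
        )
        recs = read_country_table(path)
        assert len(recs) == 2
        assert recs[0].iso3 == "NGA" and recs[0].bll_mean == 7.5
        assert recs[0].p_gt10 == 0.25
        assert recs[1].p_gt5 is None and recs[1].p_gt10 is None
        assert recs[1].pop_0_19 == 15_000_000

    def test_exceedance_ordering_violation(self, tmp_path):
        path = write_csv(
            tmp_path, ["NGA,Nigeria,Africa,7.5,6.0,9.0,0.1,0.3,5000,90000000,0.12"]
        )
        with pytest.raises(RowValidationError, match="p_gt10"):
            read_country_table(path)

    def test_interval_ordering_violation_names_country(self, tmp_path):
        path = write_csv(
            tmp_path, ["NGA,Nigeria,Africa,7.5,8.0,9.0,,,5000,90000000,0.12"]
        )
        with pytest.raises(RowValidationError, match="NGA"):
            read_country_table(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("iso3,name,continent\nNGA,Nigeria,Africa\n")
        with pytest.raises(SchemaError, match="bll_mean"):
            read_country_table(path)

    def test_duplicate_iso3_rejected(self, tmp_path):
        row = "NGA,Nigeria,Africa,7.5,6.0,9.0,,,5000,90000000,0.12"
        path = write_csv(tmp_path, [row, row])
        with pytest.raises(SchemaError, match="duplicate"):
            read_country_table(path)

    def test_country_table_round_trip(self, tmp_path, toy_records):
        path = tmp_path / "rt.csv"
        write_country_table(toy_records, path)
        assert read_country_table(path) == toy_records


class TestResultsIO:
    def test_round_trip(self, tmp_path):
        results = [
            CountryResult("AAA", 2.0, 6.0, 6.0e8),
            CountryResult("BBB", 0.123456789012, 0.369, 1.23456789012e9),
        ]
        path = tmp_path / "results.csv"
        write_results(results, path)
        back = read_results(path)
        for a, b in zip(results, back):
            assert a.iso3 == b.iso3
            assert b.mean_iq_loss == pytest.approx(a.mean_iq_loss, rel=1e-10)
            assert b.absolute_cost == pytest.approx(a.absolute_cost, rel=1e-10)

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_results([], tmp_path / "x.csv")


class TestConfig:
    def test_minimal_config_fills_defaults(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("seed: 7\n")
        cfg = load_config(path)
        assert cfg.seed == 7
        assert cfg.econ.cap_pct == 100.0
        assert cfg.dose_response.form == "loglinear"
        assert len(cfg.scenarios) == 7
        assert cfg.quadrature.nodes == 128

    def test_out_of_range_cap_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("econ:\n  cap_pct: 150\n")
        with pytest.raises(ConfigError):
            load_config(path)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("eon:\n  cap_pct: 50\n")
        with pytest.raises(ConfigError, match="eon"):
            load_config(path)

    def test_config_echo_round_trip(self, tmp_path):
        import yaml

        cfg = default_config()
        path = tmp_path / "echo.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert load_config(path).to_dict() == cfg.to_dict()

    def test_json_config_supported(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text('{"econ": {"e_us": 0.03}}')
        assert load_config(path).econ.e_us == 0.03


valid_records = st.builds(
    CountryRecord,
    iso3=st.text("ABCDEFGHIJKLMNOPQRSTUVWXYZ", min_size=3, max_size=3),
    name=st.just("X"),
    continent=st.sampled_from(CONTINENTS),
    bll_mean=st.floats(0.5, 20.0),
    bll_lo=st.just(0.0),
    bll_hi=st.just(25.0),
    p_gt5=st.one_of(st.none(), st.floats(0.3, 1.0)),
    p_gt10=st.one_of(st.none(), st.floats(0.0, 0.3)),
    gdp_pc=st.floats(100.0, 1e5),
    pop_0_19=st.integers(0, 10**9),
    ret_edu=st.floats(0.01, 0.3),
)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(rec=valid_records)
def test_validation_accepts_every_valid_record(rec):
    rec.validate()


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    rec=valid_records,
    corruption=st.sampled_from(
        [
            ("continent", "Antarctica"),
            ("bll_lo", 30.0),
            ("gdp_pc", 0.0),
            ("pop_0_19", -1),
            ("ret_edu", 0.0),
            ("p_gt5", 1.5),
        ]
    ),
)
def test_validation_rejects_every_corrupted_record(rec, corruption):
    field, bad = corruption
    broken = dataclasses.replace(rec, **{field: bad})
    with pytest.raises(RowValidationError) as exc:
        broken.validate()
    assert exc.value.iso3 == rec.iso3
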
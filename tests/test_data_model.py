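"""Specimen-table parsing, date resolution and reference-table validation."""

import io

import pytest
from hypothesis import given, strategies as st

from isocline.data_model import (
    RegionParams,
    RowError,
    SpecimenRecord,
    TableError,
    YearSpec,
    load_aliases,
    load_pom_registry,
    load_regions,
    load_sources,
    load_reference_specimens,
    parse_year_spec,
    read_specimen_table,
    resolve_pom,
    resolve_region_code,
    resolve_year,
    validate_cn,
    write_specimen_table,
)


# ---------------------------------------------------------------- year specs


@pytest.mark.parametrize(
    "text, kind, resolved",
    [
        ("1843", "exact", 1843),
        ("04/01/1876", "exact", 1876),
        ("March 1879", "exact", 1879),
        ("1878-1880", "range", 1879),
        ("1878–1880", "range", 1879),  # en dash, as printed
        ("before 1850", "before", 1850),
        ("1925-1951", "range", 1938),
        ("1901-1904", "range", 1902),
    ],
)
def test_year_spec_parsing_and_resolution(text, kind, resolved):
    spec = parse_year_spec(text)
    assert spec.kind == kind
    assert resolve_year(spec) == resolved


def test_unparseable_year_raises():
    with pytest.raises(ValueError):
        parse_year_spec("sometime in the past")
    with pytest.raises(ValueError):
        parse_year_spec("1880-1878")


@given(
    y1=st.integers(1800, 1950),
    span1=st.integers(0, 30),
    gap=st.integers(0, 50),
    span2=st.integers(0, 30),
)
def test_resolve_year_monotone(y1, span1, gap, span2):
    """A range wholly after another never resolves to an earlier year."""
    a = YearSpec("range", y1, y1 + span1) if span1 else YearSpec("exact", y1)
    b_start = y1 + span1 + gap
    b = (
        YearSpec("range", b_start, b_start + span2)
        if span2
        else YearSpec("exact", b_start)
    )
    assert resolve_year(b) >= resolve_year(a)
    # idempotence: resolving twice is resolving once
    assert resolve_year(a) == resolve_year(a)


# ---------------------------------------------------------------- C:N flags


@pytest.mark.parametrize(
    "cn, expected",
    [(3.1, "in-range"), (3.29, "in-range"), (4.3, "lipid-suspect"), (2.5, "lipid-suspect")],
)
def test_validate_cn(cn, expected):
    rec = SpecimenRecord(
        "X", "sp", "Ross Sea", YearSpec("exact", 1900), d15n=10.0, cn_ratio=cn
    )
    assert validate_cn(rec, window=(2.9, 3.3)) == expected


def test_validate_cn_requires_positive():
    rec = SpecimenRecord(
        "X", "sp", "Ross Sea", YearSpec("exact", 1900), d15n=10.0
    )
    with pytest.raises(ValueError):
        validate_cn(rec)


def test_cn_must_be_positive_at_construction():
    with pytest.raises(ValueError):
        SpecimenRecord(
            "X", "sp", "RS", YearSpec("exact", 1900), d15n=10.0, cn_ratio=-1.0
        )


def test_lipid_suspect_threshold():
    rec = SpecimenRecord(
        "X", "sp", "RS", YearSpec("exact", 1900), d15n=10.0, cn_ratio=3.4
    )
    assert rec.lipid_suspect


# ---------------------------------------------------------------- table I/O

CSV_OK = """NHMUK ID,species,location,year,d13C,C:N,d15N
ZE.1950.11.14.3,A. australis,Patagonian west coast,04/01/1876,−12.06,3.30,19.84
ZD.1879.8.21.5,A. australis,Strait of Magellan,1878–1880,−11.90,3.1,17.50
"""


def test_read_specimen_table_with_aliases_and_unicode_minus():
    records, errors = read_specimen_table(io.StringIO(CSV_OK))
    assert not errors
    assert len(records) == 2
    r = records[0]
    assert r.specimen_id == "ZE.1950.11.14.3"
    assert r.d13c_raw == pytest.approx(-12.06)
    assert r.year_spec.kind == "exact" and resolve_year(r.year_spec) == 1876
    assert records[1].year_spec.kind == "range"


def test_read_missing_mandatory_column():
    with pytest.raises(TableError, match="d15n"):
        read_specimen_table(io.StringIO("id,species,location,year\na,b,c,1900\n"))


def test_read_collects_malformed_rows():
    bad = CSV_OK + "BAD.1,sp,Ross Sea,not-a-year,-20.0,3.2,9.0\n"
    records, errors = read_specimen_table(io.StringIO(bad))
    assert len(records) == 2
    assert len(errors) == 1 and isinstance(errors[0], RowError)
    assert "not-a-year" in errors[0].message


def test_empty_table_with_header_gives_empty_list():
    records, errors = read_specimen_table(
        io.StringIO("id,species,location,year,d15n\n")
    )
    assert records == [] and errors == []


def test_round_trip_is_exact():
    records, _ = read_specimen_table(io.StringIO(CSV_OK))
    buf = io.StringIO()
    write_specimen_table(records, buf)
    again, errors = read_specimen_table(io.StringIO(buf.getvalue()))
    assert not errors
    for a, b in zip(records, again):
        assert a == b


# ------------------------------------------------------- packaged reference


def test_packaged_regions_satisfy_invariants(regions):
    assert set(regions) == {"MS", "FI", "SG", "SS", "RS"}
    for rp in regions.values():
        assert rp.total_cse <= 0 and rp.a_value <= 0
        assert rp.pom_d15n is not None


def test_packaged_sources_valid():
    blue = load_sources("blue_whale")
    seal = load_sources("fur_seal")
    assert len(blue) == 7 and len(seal) == 4
    for s in blue + seal:
        assert s.n >= 1 and s.sd_d13c >= 0 and s.sd_d15n >= 0


def test_packaged_reference_dataset_loads(reference_records):
    assert len(reference_records) == 19
    assert all(r.d13c_normalized is not None for r in reference_records)


def test_region_and_pom_resolution():
    assert resolve_region_code("Patagonian west coast") == "MS"
    assert resolve_region_code("Antarctic seas") == "RS"
    assert resolve_region_code("South Atlantic") == "SG"
    # POM keyed on label, not Suess region: Patagonian west coast uses 9.4
    assert resolve_pom("Patagonian west coast")[0] == 9.4
    assert resolve_pom("Strait of Magellan")[0] == 8.1
    assert resolve_pom("Ross Sea") == (0.6, None)
    assert resolve_pom("South Georgia") == (3.6, (2.0, 5.4))
    with pytest.raises(KeyError, match="MS, FI, SG, SS, RS"):
        resolve_region_code("Mare Incognitum")


def test_region_params_consistency_enforced():
    with pytest.raises(ValueError, match="inconsistent"):
        RegionParams("XX", total_cse=-0.91, a_value=-0.01)
    with pytest.raises(ValueError):
        RegionParams("XX", total_cse=0.5, a_value=-0.005)


def test_sanity_window_violation_warns_not_errors():
    with pytest.warns(UserWarning, match="sanity window"):
        SpecimenRecord("X", "sp", "RS", YearSpec("exact", 1900), d15n=45.0)
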
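"""Domain types, tabular readers/writers and validation for specimen, region,
POM and prey-source tables.

The central object is the :class:`SpecimenRecord` — one museum specimen with
its raw isotope measurements (δ13C vs V-PDB, δ15N vs AIR, C:N ratio) and the
derived fields added by the correction pipeline (lipid-normalized δ13C and
Suess-corrected δ13C).  Collection dates of historical specimens are messy
(exact days, bare years, closed ranges, "before Y"); they are parsed into a
:class:`YearSpec` and resolved to a single calendar year by
:func:`resolve_year` only when a correction needs one.

Reference tables shipped with the package: the five-region Suess-correction
constants, the particulate-organic-matter (POM) δ15N baseline registry, the
prey-source isotope table used for mixing models, and the 19-specimen
pre-industrial-whaling reference dataset.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "YearSpec",
    "SpecimenRecord",
    "RegionParams",
    "TEFScheme",
    "SourceDistribution",
    "AnalyticalUncertainty",
    "TableError",
    "RowError",
    "parse_year_spec",
    "resolve_year",
    "validate_cn",
    "read_specimen_table",
    "write_specimen_table",
    "load_aliases",
    "load_regions",
    "load_pom_registry",
    "load_sources",
    "load_reference_specimens",
    "load_reference_printed_se",
    "resolve_region_code",
    "resolve_pom",
]

#: Sanity windows for isotope values (‰); violations warn, never error.
D13C_WINDOW = (-40.0, 0.0)
D15N_WINDOW = (-5.0, 30.0)

#: C:N above this value flags a record as lipid-suspect (configurable).
CN_LIPID_THRESHOLD = 3.3

_UNICODE_MINUS = {"−": "-", "–": "-", "—": "-"}


class TableError(ValueError):
    """A structural problem with an input table (e.g. a missing column)."""


@dataclass(frozen=True)
class RowError:
    """A malformed row, collected rather than silently dropped."""

    line: int
    message: str
    raw: str = ""


# --------------------------------------------------------------------------
# collection-date specifiers


@dataclass(frozen=True)
class YearSpec:
    """Parsed collection-date specifier.

    ``kind`` is one of ``"exact"`` (single year, optionally with day/month),
    ``"range"`` (closed year range) or ``"before"`` (terminus ante quem).
    """

    kind: str
    year: int | None = None
    year_end: int | None = None
    text: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("exact", "range", "before"):
            raise ValueError(f"unknown year-spec kind {self.kind!r}")
        if self.kind == "range" and (self.year is None or self.year_end is None):
            raise ValueError("range year-spec needs both endpoints")
        if self.kind != "range" and self.year is None:
            raise ValueError("year-spec needs a year")


_MONTHS = {
    m.lower(): i + 1
    for i, m in enumerate(
        "January February March April May June July August September "
        "October November December".split()
    )
}

_RE_RANGE = re.compile(r"^(\d{4})\s*-\s*(\d{4})$")
_RE_BEFORE = re.compile(r"^before\s+(\d{4})$", re.IGNORECASE)
_RE_DMY = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{4})$")
_RE_MONTH_YEAR = re.compile(r"^([A-Za-z]+)\s+(\d{4})$")
_RE_YEAR = re.compile(r"^(\d{4})$")


def _normalize_minus(s: str) -> str:
    for u, a in _UNICODE_MINUS.items():
        s = s.replace(u, a)
    return s


def parse_year_spec(text: str) -> YearSpec:
    """Parse a collection-date string into a :class:`YearSpec`.

    Accepted forms: ``"1843"``, ``"04/01/1876"`` (day/month/year),
    ``"March 1879"``, ``"1878-1880"`` (hyphen, en- or em-dash), and
    ``"before 1850"``.
    """
    s = _normalize_minus(str(text)).strip()
    if m := _RE_YEAR.match(s):
        return YearSpec("exact", int(m.group(1)), text=s)
    if m := _RE_RANGE.match(s):
        y1, y2 = int(m.group(1)), int(m.group(2))
        if y2 < y1:
            raise ValueError(f"inverted year range {s!r}")
        return YearSpec("range", y1, y2, text=s)
    if m := _RE_BEFORE.match(s):
        return YearSpec("before", int(m.group(1)), text=s)
    if m := _RE_DMY.match(s):
        return YearSpec("exact", int(m.group(3)), text=s)
    if m := _RE_MONTH_YEAR.match(s):
        if m.group(1).lower() in _MONTHS:
            return YearSpec("exact", int(m.group(2)), text=s)
    raise ValueError(f"unparseable collection date {text!r}")


def resolve_year(spec: YearSpec) -> int:
    """Resolve a date specifier to a single calendar year.

    Exact dates resolve to their year; closed ranges to the floor of the
    midpoint (``1878-1880`` → 1879); ``before Y`` to ``Y`` itself.
    Monotone: a range wholly after another resolves no earlier.
    """
    if spec.kind == "exact" or spec.kind == "before":
        return int(spec.year)  # type: ignore[arg-type]
    return (int(spec.year) + int(spec.year_end)) // 2  # type: ignore[arg-type]


# --------------------------------------------------------------------------
# domain types


@dataclass
class SpecimenRecord:
    """One museum specimen with raw and derived isotope values.

    Derived fields (``d13c_normalized``, ``d13c_se``) stay ``None`` until the
    corresponding correction has run.  ``d13c_se`` is the Suess-corrected
    value (SE = Suess effect), directly comparable across collection eras.
    """

    specimen_id: str
    species: str
    region: str
    year_spec: YearSpec
    d15n: float
    d13c_raw: float | None = None
    cn_ratio: float | None = None
    d13c_normalized: float | None = None
    d13c_se: float | None = None
    year_resolution: str | None = None

    def __post_init__(self) -> None:
        if self.cn_ratio is not None and not self.cn_ratio > 0:
            raise ValueError(
                f"{self.specimen_id}: C:N ratio must be positive, got {self.cn_ratio}"
            )
        for name, val, window in (
            ("d13c_raw", self.d13c_raw, D13C_WINDOW),
            ("d13c_normalized", self.d13c_normalized, D13C_WINDOW),
            ("d15n", self.d15n, D15N_WINDOW),
        ):
            if val is not None and not (window[0] <= val <= window[1]):
                warnings.warn(
                    f"{self.specimen_id}: {name}={val}‰ outside sanity window {window}",
                    stacklevel=2,
                )

    @property
    def lipid_suspect(self) -> bool:
        """True iff C:N exceeds the lipid-contamination threshold (3.3)."""
        return self.cn_ratio is not None and self.cn_ratio > CN_LIPID_THRESHOLD

    def resolved_year(self) -> int:
        return resolve_year(self.year_spec)


@dataclass(frozen=True)
class RegionParams:
    """Per-region Suess-correction constants and POM baseline.

    ``total_cse`` is the accumulated surface-water Suess effect (‰, ≤ 0) and
    ``a_value`` the per-year δ13C decline constant derived from it by dividing
    by the 140-year industrial-era span.
    """

    region_code: str
    total_cse: float
    a_value: float
    pom_d15n: float | None = None
    pom_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.total_cse > 0:
            raise ValueError(f"{self.region_code}: total CSE must be ≤ 0")
        if self.a_value > 0:
            raise ValueError(f"{self.region_code}: a-value must be ≤ 0")
        expected = _round_half_away(self.total_cse / 140.0, 4)
        if abs(self.a_value - expected) > 5e-5:
            raise ValueError(
                f"{self.region_code}: a_value {self.a_value} inconsistent with "
                f"total_cse/140 = {expected}"
            )
        if self.pom_range is not None and self.pom_d15n is not None:
            lo, hi = self.pom_range
            if not (lo <= self.pom_d15n <= hi):
                raise ValueError(f"{self.region_code}: POM range must bracket POM value")


@dataclass(frozen=True)
class TEFScheme:
    """A named trophic-enrichment-factor parameterization for δ15N.

    ``tef`` is the per-trophic-level enrichment (‰).  Schemes using the
    tissue-corrected equation carry ``tef_mmt``, the marine-mammal-tissue
    offset subtracted from the sample before dividing by ``tef``.
    """

    name: str
    tef: float
    tef_mmt: float | None = None
    tef_mmt_sd: float | None = None

    #: plausible band for marine-mammal δ15N TEF (‰); outside warns.
    PLAUSIBLE = (2.0, 3.4)

    def __post_init__(self) -> None:
        if not self.tef > 0:
            raise ValueError("TEF must be positive")
        lo, hi = self.PLAUSIBLE
        if not (lo <= self.tef <= hi):
            warnings.warn(
                f"TEF {self.tef}‰ outside plausible band [{lo}, {hi}]", stacklevel=2
            )

    @property
    def tissue_corrected(self) -> bool:
        return self.tef_mmt is not None


@dataclass(frozen=True)
class SourceDistribution:
    """A prey source's tracer summary statistics (mean/s.d. per tracer, n)."""

    source_id: str
    region_label: str
    n: int
    mu_d13c: float
    sd_d13c: float
    mu_d15n: float
    sd_d15n: float
    region_code: str | None = None
    consumer: str | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"{self.source_id}: n must be ≥ 1")
        if self.sd_d13c < 0 or self.sd_d15n < 0:
            raise ValueError(f"{self.source_id}: s.d. must be non-negative")


@dataclass(frozen=True)
class AnalyticalUncertainty:
    """Total analytical standard uncertainty of the mass-spectrometry (‰).

    Defaults are the propagated totals for bone collagen measured in
    duplicate: 0.188‰ for δ13C and 0.204‰ for δ15N.
    """

    u_d13c: float = 0.188
    u_d15n: float = 0.204

    def __post_init__(self) -> None:
        if not (self.u_d13c > 0 and self.u_d15n > 0):
            raise ValueError("analytical uncertainties must be positive")


def _round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (report convention; Python's round is banker's)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# C:N validation


def validate_cn(
    record: SpecimenRecord, window: tuple[float, float] = (2.9, 3.3)
) -> str:
    """Classify a record's C:N ratio against the accepted collagen window.

    Returns ``"in-range"`` or ``"lipid-suspect"``.  Out-of-range specimens are
    never removed — lipid contamination is corrected mathematically downstream.
    """
    if record.cn_ratio is None:
        raise ValueError(f"{record.specimen_id}: C:N ratio absent")
    if record.cn_ratio <= 0:
        raise ValueError(f"{record.specimen_id}: non-positive C:N")
    lo, hi = window
    return "in-range" if lo <= record.cn_ratio <= hi else "lipid-suspect"


# --------------------------------------------------------------------------
# tabular I/O

# Documented header alias table: each canonical field accepts these spellings
# (lower-cased, punctuation stripped).
_HEADER_ALIASES: dict[str, tuple[str, ...]] = {
    "specimen_id": ("specimen_id", "id", "nhmuk_id", "accession"),
    "species": ("species", "taxon"),
    "region": ("region", "location", "locality"),
    "year": ("year", "date", "year_spec", "collection_year"),
    "d13c_raw": ("d13c_raw", "raw_d13c", "d13c"),
    "cn_ratio": ("cn_ratio", "cn", "c_n", "c_n_ratio"),
    "d15n": ("d15n",),
    "d13c_normalized": ("d13c_normalized", "d13c_norm"),
    "d13c_se": ("d13c_se", "d13c_suess", "d13c_corrected"),
}

_MANDATORY = ("specimen_id", "species", "region", "year", "d15n")


def _canon(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.strip().lower()).strip("_")


def _map_header(header: Sequence[str]) -> dict[str, int]:
    mapping: dict[str, int] = {}
    for idx, raw in enumerate(header):
        c = _canon(raw)
        for canonical, aliases in _HEADER_ALIASES.items():
            if c in aliases and canonical not in mapping:
                mapping[canonical] = idx
    missing = [m for m in _MANDATORY if m not in mapping]
    if missing:
        raise TableError(f"missing mandatory column(s): {', '.join(missing)}")
    return mapping


def _parse_float(s: str) -> float | None:
    s = _normalize_minus(s).strip()
    if not s:
        return None
    return float(s)


def read_specimen_table(
    path: str | Path | io.TextIOBase, delimiter: str = ","
) -> tuple[list[SpecimenRecord], list[RowError]]:
    """Read a delimited specimen table.

    Header names are mapped onto :class:`SpecimenRecord` fields through a
    documented alias table; Unicode minus signs are normalized on read.
    Malformed rows are collected into the returned error list, never silently
    dropped.

    Returns
    -------
    (records, errors)
    """
    if isinstance(path, (str, Path)):
        fh: io.TextIOBase = open(path, newline="", encoding="utf-8")
        close = True
    else:
        fh, close = path, False
    records: list[SpecimenRecord] = []
    errors: list[RowError] = []
    try:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise TableError("empty file: no header row")
        cols = _map_header(header)

        def get(row: Sequence[str], key: str) -> str:
            i = cols.get(key)
            return row[i] if i is not None and i < len(row) else ""

        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            try:
                yspec = parse_year_spec(get(row, "year"))
                rec = SpecimenRecord(
                    specimen_id=get(row, "specimen_id").strip(),
                    species=get(row, "species").strip(),
                    region=get(row, "region").strip(),
                    year_spec=yspec,
                    d15n=_require_float(get(row, "d15n"), "d15n"),
                    d13c_raw=_parse_float(get(row, "d13c_raw")),
                    cn_ratio=_parse_float(get(row, "cn_ratio")),
                    d13c_normalized=_parse_float(get(row, "d13c_normalized")),
                    d13c_se=_parse_float(get(row, "d13c_se")),
                )
                records.append(rec)
            except (ValueError, TypeError) as exc:
                errors.append(RowError(lineno, str(exc), ",".join(row)))
    finally:
        if close:
            fh.close()
    return records, errors


def _require_float(s: str, name: str) -> float:
    v = _parse_float(s)
    if v is None:
        raise ValueError(f"missing value for {name}")
    return v


_WRITE_COLUMNS = (
    "specimen_id",
    "species",
    "region",
    "year",
    "d13c_raw",
    "cn_ratio",
    "d15n",
    "d13c_normalized",
    "d13c_se",
)


def write_specimen_table(
    records: Iterable[SpecimenRecord], path: str | Path | io.TextIOBase
) -> None:
    """Write records back to CSV; round-trips bit-exactly with the reader."""
    if isinstance(path, (str, Path)):
        fh: io.TextIOBase = open(path, "w", newline="", encoding="utf-8")
        close = True
    else:
        fh, close = path, False
    try:
        w = csv.writer(fh)
        w.writerow(_WRITE_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.specimen_id,
                    r.species,
                    r.region,
                    r.year_spec.text,
                    _fmt(r.d13c_raw),
                    _fmt(r.cn_ratio),
                    _fmt(r.d15n),
                    _fmt(r.d13c_normalized),
                    _fmt(r.d13c_se),
                ]
            )
    finally:
        if close:
            fh.close()


def _fmt(v: float | None) -> str:
    return "" if v is None else repr(v)


# --------------------------------------------------------------------------
# packaged reference tables


def _data_path(name: str):
    return resources.files("isocline.data").joinpath(name)


def load_aliases(path: str | Path | None = None) -> dict:
    """Load the region/POM alias configuration (packaged default or a file)."""
    if path is None:
        text = _data_path("aliases.yaml").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    return yaml.safe_load(text)


def load_regions(path: str | Path | None = None) -> dict[str, RegionParams]:
    """Load the five-region Suess-constant table, keyed by region code.

    POM defaults from the packaged registry are attached to each region.
    """
    rows = _read_csv_resource("regions.csv" if path is None else path)
    pom = load_pom_registry()
    aliases = load_aliases()
    defaults = aliases["pom_region_defaults"]
    out: dict[str, RegionParams] = {}
    for row in rows:
        code = row["region_code"]
        label = defaults.get(code)
        p = pom.get(label, (None, None)) if label else (None, None)
        out[code] = RegionParams(
            region_code=code,
            total_cse=float(row["total_cse"]),
            a_value=float(row["a_value"]),
            pom_d15n=p[0],
            pom_range=p[1],
        )
    return out


def load_pom_registry(
    path: str | Path | None = None,
) -> dict[str, tuple[float, tuple[float, float] | None]]:
    """POM δ15N baselines keyed by location label → (value, optional range)."""
    rows = _read_csv_resource("pom.csv" if path is None else path)
    out: dict[str, tuple[float, tuple[float, float] | None]] = {}
    for row in rows:
        rng = None
        if row.get("pom_low") and row.get("pom_high"):
            rng = (float(row["pom_low"]), float(row["pom_high"]))
        out[row["label"]] = (float(row["pom_d15n"]), rng)
    return out


def load_sources(
    consumer: str | None = None, path: str | Path | None = None
) -> list[SourceDistribution]:
    """Load the packaged prey-source isotope table.

    ``consumer`` filters to the source set assembled for one consumer species
    (``"blue_whale"`` krill panel or ``"fur_seal"`` fish/squid panel).
    """
    rows = _read_csv_resource("sources.csv" if path is None else path)
    out = []
    for row in rows:
        if consumer is not None and row.get("consumer") != consumer:
            continue
        out.append(
            SourceDistribution(
                source_id=row["source_id"],
                region_label=row["region_label"],
                n=int(row["n"]),
                mu_d13c=float(row["mu_d13c"]),
                sd_d13c=float(row["sd_d13c"]),
                mu_d15n=float(row["mu_d15n"]),
                sd_d15n=float(row["sd_d15n"]),
                region_code=row.get("region_code") or None,
                consumer=row.get("consumer") or None,
            )
        )
    return out


def load_reference_specimens() -> list[SpecimenRecord]:
    """The packaged 19-specimen pre-industrial-whaling reference dataset.

    These specimens enter the pipeline at the lipid-normalized stage (raw δ13C
    and C:N per specimen are not part of the packaged table).
    """
    rows = _read_csv_resource("specimens_pre1904.csv")
    recs = []
    for row in rows:
        recs.append(
            SpecimenRecord(
                specimen_id=row["specimen_id"],
                species=row["species"],
                region=row["location"],
                year_spec=parse_year_spec(row["year"]),
                d15n=float(row["d15n"]),
                d13c_normalized=float(row["d13c_normalized"]),
            )
        )
    return recs


def load_reference_printed_se() -> dict[str, float]:
    """Printed Suess-corrected δ13C values of the reference dataset (2 d.p.)."""
    rows = _read_csv_resource("specimens_pre1904.csv")
    return {row["specimen_id"]: float(row["d13c_se_printed"]) for row in rows}


def _read_csv_resource(name_or_path) -> list[dict[str, str]]:
    if isinstance(name_or_path, (str, Path)) and Path(str(name_or_path)).exists():
        text = Path(name_or_path).read_text(encoding="utf-8")
    else:
        text = _data_path(str(name_or_path)).read_text(encoding="utf-8")
    text = _normalize_minus(text)
    return list(csv.DictReader(io.StringIO(text)))


def resolve_region_code(location: str, aliases: Mapping | None = None) -> str:
    """Map a free-text location to one of the five Suess regions.

    Raises ``KeyError`` listing the known codes when unmapped.
    """
    amap = (aliases or load_aliases())["region_aliases"]
    loc = location.strip()
    if loc in amap:
        return amap[loc]
    lowered = {k.lower(): v for k, v in amap.items()}
    if loc.lower() in lowered:
        return lowered[loc.lower()]
    raise KeyError(
        f"unmapped region {location!r}; known codes: MS, FI, SG, SS, RS "
        "(extend the alias map to add localities)"
    )


def resolve_pom(
    location: str, aliases: Mapping | None = None
) -> tuple[float, tuple[float, float] | None]:
    """Resolve the POM δ15N baseline for a location label.

    Looks up the label (through POM aliases) first, then falls back to the
    default baseline of the resolved Suess region.
    """
    cfg = aliases or load_aliases()
    registry = load_pom_registry()
    loc = location.strip()
    label = cfg.get("pom_aliases", {}).get(loc, loc)
    if label in registry:
        return registry[label]
    code = resolve_region_code(loc, cfg)
    default_label = cfg["pom_region_defaults"][code]
    return registry[default_label]
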
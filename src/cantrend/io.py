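"""Readers and writers: tidy incidence/RSVI tables, Google Trends
multiTimeline exports, packaged reference tables, and report output.

All formats are plain text (CSV/JSON).  Tidy tables carry one
(region, year, value) observation per row.  The multiTimeline dialect is
the Google Trends time-series export: a title line, a blank line, a
``Month,<topic>: (<region>)`` header, then ``YYYY-MM,<int>`` rows where
``<1`` marks a sub-unit value.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Any, Iterable, Mapping

import pandas as pd

from ._regions import normalize_region
from .core import (
    ACTUAL,
    IncidenceSeries,
    RSVISeries,
    display_percent,
    display_ratio,
)

__all__ = [
    "FixtureSet",
    "FIXTURE_NAMES",
    "read_incidence_csv",
    "read_trends_csv",
    "load_fixture",
    "table1_inputs",
    "write_report",
    "write_incidence_csv",
    "write_rsvi_csv",
]

log = logging.getLogger(__name__)

# "<1" in a Trends export means a positive value below 1; the midpoint of
# (0, 1) is used so the cell stays distinguishable from true 0
# (insufficient data).
LESS_THAN_ONE = 0.5


# --------------------------------------------------------------------------
# tidy readers
# --------------------------------------------------------------------------

def _read_frame(source: str | Path | IO[str]) -> pd.DataFrame:
    return pd.read_csv(source, skip_blank_lines=True, comment=None)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"{what}: missing column(s) {missing}; found {list(df.columns)}"
        )


def _numeric(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad][:5]]  # +2: header + 1-based
        raise ValueError(
            f"{what}: non-numeric {col!r} value(s) at file row(s) {rows}"
        )
    if out.isna().any():
        rows = [int(i) + 2 for i in df.index[out.isna()][:5]]
        raise ValueError(f"{what}: empty {col!r} value(s) at file row(s) {rows}")
    return out


def read_incidence_csv(
    source: str | Path | IO[str],
    *,
    region_col: str = "region",
    year_col: str = "year",
    cases_col: str = "cases",
) -> dict[str, IncidenceSeries]:
    """Read a tidy incidence CSV into one series per region.

    Every row is treated as an observed (``actual``) count.  Duplicate
    (region, year) pairs and non-numeric cells are errors that name the
    offenders.
    """
    df = _read_frame(source)
    _require_columns(df, (region_col, year_col, cases_col), "incidence CSV")
    years = _numeric(df, year_col, "incidence CSV").astype(int)
    cases = _numeric(df, cases_col, "incidence CSV")
    regions = df[region_col].astype(str).map(normalize_region)
    dup = pd.DataFrame({"region": regions, "year": years}).duplicated(keep=False)
    if dup.any():
        offenders = sorted(
            {(r, int(y)) for r, y in zip(regions[dup], years[dup])}
        )
        raise ValueError(f"incidence CSV: duplicate (region, year): {offenders}")
    out: dict[str, IncidenceSeries] = {}
    for region, grp in pd.DataFrame(
        {"region": regions, "year": years, "cases": cases}
    ).groupby("region", sort=True):
        out[str(region)] = IncidenceSeries(
            region=str(region),
            values=dict(zip(grp["year"], grp["cases"])),
            provenance={int(y): ACTUAL for y in grp["year"]},
        )
    return out


_MT_HEADER = re.compile(r"^Month,(?P<topic>.*?):\s*\((?P<region>.*?)\)\s*$")
_MT_ROW = re.compile(r"^(?P<year>\d{4})-(?P<month>\d{2}),(?P<value><1|\d+(?:\.\d+)?)$")


def _parse_multitimeline(text: str, min_months: int) -> RSVISeries:
    lines = text.splitlines()
    header_idx = next(
        (i for i, ln in enumerate(lines) if _MT_HEADER.match(ln.strip())), None
    )
    if header_idx is None:
        raise ValueError(
            "multiTimeline CSV: no 'Month,<topic>: (<region>)' header found"
        )
    m = _MT_HEADER.match(lines[header_idx].strip())
    assert m is not None
    topic, region_name = m.group("topic"), m.group("region")
    monthly: dict[int, list[float]] = {}
    for lineno, raw in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        ln = raw.strip()
        if not ln:
            continue
        row = _MT_ROW.match(ln)
        if row is None:
            raise ValueError(
                f"multiTimeline CSV: unparseable month row at line {lineno}: {ln!r}"
            )
        tok = row.group("value")
        value = LESS_THAN_ONE if tok == "<1" else float(tok)
        if not (0.0 <= value <= 100.0):
            raise ValueError(
                f"multiTimeline CSV: RSVI {value} outside [0, 100] at line {lineno}"
            )
        monthly.setdefault(int(row.group("year")), []).append(value)
    yearly: dict[int, float] = {}
    for year, vals in sorted(monthly.items()):
        if len(vals) < min_months:
            log.warning(
                "multiTimeline: excluding partial year %d (%d of %d months)",
                year, len(vals), min_months,
            )
            continue
        # yearly index = arithmetic mean of the monthly values, full precision
        yearly[year] = sum(vals) / len(vals)
    return RSVISeries(
        region=normalize_region(region_name), values=yearly, topic=topic
    )


def read_trends_csv(
    source: str | Path | IO[str],
    mode: str = "tidy",
    *,
    region_col: str = "region",
    year_col: str = "year",
    rsvi_col: str = "rsvi",
    topic: str = "cancer",
    min_months: int = 12,
) -> dict[str, RSVISeries]:
    """Read search-interest data into RSVI series.

    ``mode="tidy"`` expects (region, year, rsvi) columns with yearly
    values already on the 0-100 scale.  ``mode="multitimeline"`` parses
    a Google Trends export and aggregates months to a yearly arithmetic
    mean; years with fewer than ``min_months`` months are excluded with
    a warning (no imputation).
    """
    if mode == "multitimeline":
        if isinstance(source, (str, Path)):
            text = Path(source).read_text(encoding="utf-8-sig")
        else:
            text = source.read()
        series = _parse_multitimeline(text, min_months)
        return {series.region: series}
    if mode != "tidy":
        raise ValueError(f"unknown mode {mode!r}; expected 'tidy' or 'multitimeline'")
    df = _read_frame(source)
    _require_columns(df, (region_col, year_col, rsvi_col), "RSVI CSV")
    years = _numeric(df, year_col, "RSVI CSV").astype(int)
    rsvi = _numeric(df, rsvi_col, "RSVI CSV")
    regions = df[region_col].astype(str).map(normalize_region)
    dup = pd.DataFrame({"region": regions, "year": years}).duplicated(keep=False)
    if dup.any():
        offenders = sorted({(r, int(y)) for r, y in zip(regions[dup], years[dup])})
        raise ValueError(f"RSVI CSV: duplicate (region, year): {offenders}")
    out: dict[str, RSVISeries] = {}
    for region, grp in pd.DataFrame(
        {"region": regions, "year": years, "rsvi": rsvi}
    ).groupby("region", sort=True):
        out[str(region)] = RSVISeries(
            region=str(region),
            values=dict(zip(grp["year"], grp["rsvi"])),
            topic=topic,
        )
    return out


# --------------------------------------------------------------------------
# packaged reference tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSet:
    """A packaged validation/projection table, one row per region (-year)."""

    name: str
    data: pd.DataFrame
    description: str


_FIXTURES: dict[str, str] = {
    "table1_2017": (
        "US-state one-step validation for 2017: actual 2016 counts, RSVI "
        "2016/2017, display ratio, predicted and actual 2017 counts, %error"
    ),
    "table2_2018_2020": (
        "US-state validation 2018-2020: predicted count, actual count and "
        "%error per region-year"
    ),
    "table3_us_projections": (
        "US-state chained projections for 2021-2023 (inputs unpublished; "
        "reference values only)"
    ),
    "table4_world_projections": (
        "Country-level chained projections for 2021-2023 (inputs "
        "unpublished; reference values only)"
    ),
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def load_fixture(name: str) -> FixtureSet:
    """Load one of the packaged reference tables by name."""
    if name not in _FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; valid names: {list(FIXTURE_NAMES)}"
        )
    ref = resources.files("cantrend").joinpath(f"fixtures/{name}.csv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    return FixtureSet(name=name, data=df, description=_FIXTURES[name])


def table1_inputs(
    fixture: FixtureSet | None = None,
) -> tuple[dict[str, IncidenceSeries], dict[str, RSVISeries]]:
    """Model inputs (incidence + RSVI collections) from the 2017 validation table.

    The table prints every input the one-step model needs — the actual
    2016 and 2017 counts and the RSVI values for both years — so the
    whole validation run can be reconstructed from it.
    """
    fx = fixture if fixture is not None else load_fixture("table1_2017")
    incidence: dict[str, IncidenceSeries] = {}
    rsvi: dict[str, RSVISeries] = {}
    for row in fx.data.itertuples(index=False):
        incidence[row.region] = IncidenceSeries(
            region=row.region,
            values={2016: row.actual_2016, 2017: row.actual_2017},
        )
        rsvi[row.region] = RSVISeries(
            region=row.region,
            values={2016: row.rsvi_2016, 2017: row.rsvi_2017},
        )
    return incidence, rsvi


# --------------------------------------------------------------------------
# report output
# --------------------------------------------------------------------------

def _records_frame(records) -> pd.DataFrame:
    rows = [
        {
            "region": r.region,
            "base_year": r.base_year,
            "target_year": r.target_year,
            "base_count": r.base_count,
            "base_provenance": r.base_provenance,
            "rsvi_base": r.rsvi_base,
            "rsvi_target": r.rsvi_target,
            "ratio": display_ratio(r.ratio),
            "predicted_raw": r.predicted_raw,
            "predicted": r.predicted,
            "actual": r.actual,
            "pct_error": None
            if r.percent_error is None
            else display_percent(r.percent_error),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def _as_frame(data: Any) -> pd.DataFrame:
    from .validation import ValidationTable  # local import avoids a cycle

    if isinstance(data, ValidationTable):
        return _records_frame(data.records)
    if isinstance(data, pd.DataFrame):
        df = data
    elif isinstance(data, Mapping):
        df = pd.DataFrame(
            {"region": list(data.keys()), "value": list(data.values())}
        )
    elif isinstance(data, Iterable):
        seq = list(data)
        if seq and hasattr(seq[0], "predicted_raw"):
            return _records_frame(seq)
        df = pd.DataFrame(seq)
    else:
        raise TypeError(f"cannot serialize {type(data).__name__} as a report")
    if df.empty:
        raise ValueError("refusing to write an empty report")
    return df


def write_report(data: Any, path: str | Path, format: str = "csv") -> None:
    """Write a report deterministically (stable column and row order).

    ``data`` may be a ValidationTable, a list of PredictionRecords, a
    region -> value mapping, or a DataFrame.  Rows are sorted by region
    code (then year when present) so the same input always produces a
    byte-identical file; JSON uses one record object per row.
    """
    df = _as_frame(data)
    sort_cols = [c for c in ("region", "year", "target_year") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    path = Path(path)
    if format == "csv":
        path.write_text(df.to_csv(index=False, lineterminator="\n"), encoding="utf-8")
    elif format == "json":
        records = json.loads(df.to_json(orient="records"))
        path.write_text(
            json.dumps(records, indent=2, allow_nan=False) + "\n", encoding="utf-8"
        )
    else:
        raise ValueError(f"unknown report format {format!r}; expected csv or json")


def write_incidence_csv(
    series: Mapping[str, IncidenceSeries], path: str | Path
) -> None:
    """Write an incidence collection as a tidy (region, year, cases, provenance) CSV."""
    rows = [
        {
            "region": s.region,
            "year": year,
            "cases": s.values[year],
            "provenance": s.provenance[year],
        }
        for _, s in sorted(series.items())
        for year in s.years
    ]
    write_report(pd.DataFrame(rows), path, "csv")


def write_rsvi_csv(series: Mapping[str, RSVISeries], path: str | Path) -> None:
    """Write an RSVI collection as a tidy (region, year, rsvi) CSV."""
    rows = [
        {"region": s.region, "year": year, "rsvi": s.values[year]}
        for _, s in sorted(series.items())
        for year in s.years
    ]
    write_report(pd.DataFrame(rows), path, "csv")
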
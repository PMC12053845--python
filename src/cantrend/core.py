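"""Core prediction model: RSVI-ratio nowcasting of yearly incidence.

The model predicts next year's case count for a region by scaling this
year's count with the year-over-year change in public search interest:

    predicted(t+1) = cases(t) * RSVI(t+1) / RSVI(t)

where RSVI is the 0-100 relative search volume index for the disease
topic in that region.  Validation uses the signed percentage error

    %error = (predicted - actual) / actual * 100.

All arithmetic is carried at full floating precision; rounding (counts
to integers, ratios to 3 decimals, %errors to 1 decimal) is a display
concern handled by the ``round_count`` / ``display_ratio`` /
``display_percent`` helpers.  Within a prediction record the %error is
computed from the *unrounded* prediction, which is the convention the
reference validation tables follow.
"""

from __future__ import annotations

import math
import statistics
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

__all__ = [
    "InsufficientSearchDataError",
    "RSVISeries",
    "IncidenceSeries",
    "PredictionRecord",
    "ErrorSummary",
    "ErrorComparison",
    "rsvi_ratio",
    "predict_one_step",
    "percent_error",
    "chain_forecast",
    "error_summary",
    "compare_error_vectors",
    "round_count",
    "display_ratio",
    "display_percent",
]

ACTUAL = "actual"
PREDICTED = "predicted"


class InsufficientSearchDataError(ValueError):
    """Raised when an RSVI value is 0 or missing.

    An index value of 0 designates insufficient search data for the
    topic in that region/year, not zero interest, so the ratio model is
    undefined there.
    """


# --------------------------------------------------------------------------
# rounding helpers (display conventions)
# --------------------------------------------------------------------------

def round_count(x: float) -> int:
    """Round a predicted count to the nearest integer, halves away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _round_dp(x: float, dp: int) -> float:
    # Decimal(repr(x)) avoids binary-representation surprises like
    # round(2.675, 2) -> 2.67
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def display_ratio(ratio: float) -> float:
    """RSVI ratio at the 3-decimal reporting precision (half away from zero)."""
    return _round_dp(ratio, 3)


def display_percent(error: float) -> float:
    """%error at the 1-decimal reporting precision (half away from zero)."""
    return _round_dp(error, 1)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RSVISeries:
    """Per-region yearly relative search volume index on the 0-100 scale.

    Parameters
    ----------
    region:
        Region code used as join key (e.g. ``"AL"``, ``"DE"``).
    values:
        Mapping year -> index value, each in [0, 100].
    topic:
        Search topic the index was collected for.
    """

    region: str
    values: Mapping[int, float]
    topic: str = "cancer"

    def __post_init__(self) -> None:
        clean: dict[int, float] = {}
        for year, v in self.values.items():
            year = int(year)
            if year in clean:
                raise ValueError(f"{self.region}: duplicate year {year}")
            v = float(v)
            if not (0.0 <= v <= 100.0) or math.isnan(v):
                raise ValueError(
                    f"{self.region}/{year}: RSVI {v!r} outside [0, 100]"
                )
            clean[year] = v
        object.__setattr__(self, "values", clean)

    @property
    def years(self) -> list[int]:
        return sorted(self.values)

    def value(self, year: int) -> float:
        """Index value for ``year``; 0 or absent raises InsufficientSearchDataError."""
        v = self.values.get(year)
        if v is None:
            raise InsufficientSearchDataError(
                f"no RSVI value for {self.region} in {year}"
            )
        if v == 0:
            raise InsufficientSearchDataError(
                f"RSVI is 0 for {self.region} in {year}: "
                "insufficient search data for this topic"
            )
        return v


@dataclass
class IncidenceSeries:
    """Per-region yearly case counts with actual/predicted provenance.

    A year marked ``actual`` can never be overwritten by a predicted
    value; observed registry data always wins over model output.
    """

    region: str
    values: dict[int, float] = field(default_factory=dict)
    provenance: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = {int(y): float(v) for y, v in self.values.items()}
        prov = {int(y): p for y, p in self.provenance.items()}
        for year, v in values.items():
            if v < 0 or math.isnan(v):
                raise ValueError(f"{self.region}/{year}: negative count {v!r}")
            prov.setdefault(year, ACTUAL)
        for year, p in prov.items():
            if p not in (ACTUAL, PREDICTED):
                raise ValueError(f"{self.region}/{year}: bad provenance {p!r}")
        self.values = values
        self.provenance = prov

    @property
    def years(self) -> list[int]:
        return sorted(self.values)

    def actual_years(self) -> list[int]:
        return sorted(y for y, p in self.provenance.items() if p == ACTUAL)

    def set_value(self, year: int, count: float, provenance: str) -> None:
        year = int(year)
        if count < 0:
            raise ValueError(f"{self.region}/{year}: negative count {count!r}")
        if provenance not in (ACTUAL, PREDICTED):
            raise ValueError(f"bad provenance {provenance!r}")
        if self.provenance.get(year) == ACTUAL and provenance == PREDICTED:
            raise ValueError(
                f"{self.region}/{year}: refusing to overwrite an actual "
                "count with a predicted value"
            )
        self.values[year] = float(count)
        self.provenance[year] = provenance


@dataclass(frozen=True)
class PredictionRecord:
    """One one-step prediction, with the validation fields when known.

    ``predicted_raw`` is the exact product ``base_count * ratio``;
    ``predicted`` is its integer rounding for reporting.  ``percent_error``
    is present iff ``actual`` is, and is computed from ``predicted_raw``.
    ``base_provenance`` records whether the base count was an observed
    figure or itself a model prediction (chained forecasting).
    """

    region: str
    base_year: int
    target_year: int
    base_count: float
    rsvi_base: float
    rsvi_target: float
    ratio: float
    predicted_raw: float
    predicted: int
    actual: float | None = None
    percent_error: float | None = None
    base_provenance: str = ACTUAL

    def __post_init__(self) -> None:
        if self.target_year != self.base_year + 1:
            raise ValueError(
                f"{self.region}: target year {self.target_year} is not "
                f"base year {self.base_year} + 1"
            )
        expected = self.base_count * self.rsvi_target / self.rsvi_base
        if not math.isclose(self.predicted_raw, expected, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError(
                f"{self.region}: predicted_raw {self.predicted_raw!r} "
                f"inconsistent with base_count * ratio = {expected!r}"
            )
        if (self.actual is None) != (self.percent_error is None):
            raise ValueError(
                f"{self.region}: percent_error must be present exactly "
                "when actual is"
            )
        if self.base_provenance not in (ACTUAL, PREDICTED):
            raise ValueError(f"bad base_provenance {self.base_provenance!r}")


@dataclass(frozen=True)
class ErrorSummary:
    """Summary of a vector of signed %errors.

    Both the arithmetic mean and the (midpoint-convention) median are
    always reported; the two can differ materially on skewed error
    vectors, so neither is allowed to stand in for the other.
    ``prop_within_threshold`` is the fraction of records with
    ``|error| <= threshold`` (threshold in percentage points, default 6).
    """

    n: int
    mean: float
    median: float
    min: float
    max: float
    prop_within_threshold: float
    threshold: float = 6.0

    def __post_init__(self) -> None:
        # 1-ulp slack: a float mean of identical values can exceed max
        tol = 1e-12 * max(1.0, abs(self.min), abs(self.max))
        if not (self.min - tol <= self.median <= self.max + tol):
            raise ValueError("median outside [min, max]")
        if not (self.min - tol <= self.mean <= self.max + tol):
            raise ValueError("mean outside [min, max]")
        if not (0.0 <= self.prop_within_threshold <= 1.0):
            raise ValueError("prop_within_threshold outside [0, 1]")


@dataclass(frozen=True)
class ErrorComparison:
    """Paired comparison of two %error vectors over a common region set.

    ``abs_diff`` holds |a| - |b| per region (negative means model A was
    closer to the actuals there); ``n_a_better`` / ``n_b_better`` /
    ``n_ties`` count regions by the sign of that difference.
    """

    regions: tuple[str, ...]
    abs_diff: Mapping[str, float]
    mae_a: float
    mae_b: float
    n_a_better: int
    n_b_better: int
    n_ties: int
    dropped_a: tuple[str, ...] = ()
    dropped_b: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def rsvi_ratio(
    rsvi_target: float,
    rsvi_base: float,
    *,
    region: str | None = None,
    year: int | None = None,
) -> float:
    """Year-over-year search-interest ratio ``rsvi_target / rsvi_base``.

    Returned at full precision; use :func:`display_ratio` for the
    3-decimal reporting form.  A base value of 0 means insufficient
    search data and raises :class:`InsufficientSearchDataError`
    (``region``/``year`` only decorate the message).
    """
    where = ""
    if region is not None or year is not None:
        where = f" ({region or '?'}/{year if year is not None else '?'})"
    for name, v in (("base", rsvi_base), ("target", rsvi_target)):
        if v is None or math.isnan(v):
            raise InsufficientSearchDataError(f"missing {name} RSVI{where}")
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} RSVI {v!r} outside [0, 100]{where}")
    if rsvi_base == 0:
        raise InsufficientSearchDataError(
            f"base RSVI is 0{where}: insufficient search data"
        )
    return rsvi_target / rsvi_base


def predict_one_step(
    base_count: float,
    rsvi_base: float,
    rsvi_target: float,
    *,
    region: str = "",
    base_year: int = 0,
    actual: float | None = None,
    base_provenance: str = ACTUAL,
) -> PredictionRecord:
    """Predict next year's count from this year's count and the RSVI pair.

    ``predicted_raw = base_count * rsvi_target / rsvi_base`` using the
    full-precision ratio (never the 3-decimal display form — the two
    differ by whole counts at registry scale).  When ``actual`` is given
    the record carries the full-precision %error of ``predicted_raw``.
    """
    if base_count < 0 or math.isnan(base_count):
        raise ValueError(f"negative base count {base_count!r}")
    ratio = rsvi_ratio(rsvi_target, rsvi_base, region=region or None, year=base_year)
    raw = base_count * ratio
    err = percent_error(raw, actual) if actual is not None else None
    return PredictionRecord(
        region=region,
        base_year=base_year,
        target_year=base_year + 1,
        base_count=float(base_count),
        rsvi_base=float(rsvi_base),
        rsvi_target=float(rsvi_target),
        ratio=ratio,
        predicted_raw=raw,
        predicted=round_count(raw),
        actual=None if actual is None else float(actual),
        percent_error=err,
        base_provenance=base_provenance,
    )


def percent_error(predicted: float, actual: float) -> float:
    """Signed percentage error ``(predicted - actual) / actual * 100``.

    Full precision; use :func:`display_percent` for 1-decimal reporting.
    Undefined (raises) for ``actual <= 0``.
    """
    if actual is None or math.isnan(actual) or actual <= 0:
        raise ValueError(
            f"percent error undefined for actual={actual!r} (must be > 0)"
        )
    return (predicted - actual) / actual * 100.0


def chain_forecast(
    base_count: float,
    base_year: int,
    rsvi: RSVISeries,
    horizon: int,
    *,
    base_provenance: str = ACTUAL,
) -> list[PredictionRecord]:
    """Multi-year forecast where each step's base is the previous prediction.

    Step k (k = 1..horizon) predicts year ``base_year + k`` from the
    *unrounded* prediction for year ``base_year + k - 1`` (rounding only
    at reporting), so the k-step raw forecast telescopes to
    ``base_count * rsvi(base_year + k) / rsvi(base_year)``.  Records
    beyond the first carry ``base_provenance="predicted"`` — error is
    expected to compound with horizon because each base drifts further
    from observed data.

    Every year in ``base_year .. base_year + horizon`` must have a
    positive RSVI value; the first missing/zero year is named in the
    error (no interpolation).
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    if base_count < 0:
        raise ValueError(f"negative base count {base_count!r}")
    for year in range(base_year, base_year + horizon + 1):
        rsvi.value(year)  # raises naming the first offending year
    records: list[PredictionRecord] = []
    carry = float(base_count)
    prov = base_provenance
    for k in range(horizon):
        year = base_year + k
        rec = predict_one_step(
            carry,
            rsvi.value(year),
            rsvi.value(year + 1),
            region=rsvi.region,
            base_year=year,
            base_provenance=prov,
        )
        records.append(rec)
        carry = rec.predicted_raw
        prov = PREDICTED
    return records


def error_summary(
    errors: Sequence[float] | Iterable[float],
    threshold: float = 6.0,
) -> ErrorSummary:
    """Mean, median (midpoint for even n), range and within-threshold share."""
    errs = [float(e) for e in errors]
    if not errs:
        raise ValueError("error_summary requires a non-empty error vector")
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    return ErrorSummary(
        n=len(errs),
        mean=statistics.fmean(errs),
        median=float(statistics.median(errs)),
        min=min(errs),
        max=max(errs),
        prop_within_threshold=sum(abs(e) <= threshold for e in errs) / len(errs),
        threshold=float(threshold),
    )


def compare_error_vectors(
    errors_a: Mapping[str, float],
    errors_b: Mapping[str, float],
) -> ErrorComparison:
    """Paired region-by-region comparison of two models' %error vectors.

    Regions present in only one vector are inner-joined away with a
    warning listing the drops; an empty intersection raises.  A model
    "wins" a region when its absolute error is strictly smaller there.
    """
    common = sorted(set(errors_a) & set(errors_b))
    if not common:
        raise ValueError("error vectors share no region")
    dropped_a = tuple(sorted(set(errors_a) - set(errors_b)))
    dropped_b = tuple(sorted(set(errors_b) - set(errors_a)))
    if dropped_a or dropped_b:
        warnings.warn(
            "compare_error_vectors: inner join dropped regions "
            f"only in A: {list(dropped_a)}, only in B: {list(dropped_b)}",
            stacklevel=2,
        )
    diff = {r: abs(errors_a[r]) - abs(errors_b[r]) for r in common}
    return ErrorComparison(
        regions=tuple(common),
        abs_diff=diff,
        mae_a=statistics.fmean(abs(errors_a[r]) for r in common),
        mae_b=statistics.fmean(abs(errors_b[r]) for r in common),
        n_a_better=sum(d < 0 for d in diff.values()),
        n_b_better=sum(d > 0 for d in diff.values()),
        n_ties=sum(d == 0 for d in diff.values()),
        dropped_a=dropped_a,
        dropped_b=dropped_b,
    )
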
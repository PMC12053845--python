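"""Validation runs: rebuild year-by-year prediction tables from raw
inputs, summarize their %errors, and project beyond the observed years.

``validate_year`` re-creates the one-step validation table for a target
year: for every region with an actual count in the base year, an actual
in the target year, and RSVI values for both, it produces a
:class:`~cantrend.core.PredictionRecord` and summarizes the %errors.
Regions missing any input are reported in a ``skipped`` mapping with the
reason — never silently dropped.

``project_unobserved`` chains forecasts past the last observed year;
each step's base is the previous (unrounded) prediction, so deviation
from reality accumulates with horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import (
    ACTUAL,
    PREDICTED,
    ErrorSummary,
    IncidenceSeries,
    InsufficientSearchDataError,
    PredictionRecord,
    RSVISeries,
    chain_forecast,
    error_summary,
    predict_one_step,
)

__all__ = ["ValidationTable", "predict_year", "validate_year",
           "validate_multi_year", "project_unobserved"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationTable:
    """One-step predictions for a single target year plus their %error summary."""

    target_year: int
    records: tuple[PredictionRecord, ...]
    skipped: Mapping[str, str]
    summary: ErrorSummary | None

    def errors_by_region(self) -> dict[str, float]:
        return {
            r.region: r.percent_error
            for r in self.records
            if r.percent_error is not None
        }


def _one_region(
    inc: IncidenceSeries,
    rsvi: RSVISeries | None,
    target_year: int,
    require_actual: bool,
) -> PredictionRecord | str:
    base_year = target_year - 1
    if inc.provenance.get(base_year) != ACTUAL:
        return f"no actual count for base year {base_year}"
    actual = inc.values.get(target_year)
    if inc.provenance.get(target_year) != ACTUAL:
        actual = None
    if require_actual and actual is None:
        return f"no actual count for target year {target_year}"
    if rsvi is None:
        return "no RSVI series"
    try:
        rsvi_base = rsvi.value(base_year)
        rsvi_target = rsvi.value(target_year)
    except InsufficientSearchDataError as exc:
        return str(exc)
    return predict_one_step(
        inc.values[base_year],
        rsvi_base,
        rsvi_target,
        region=inc.region,
        base_year=base_year,
        actual=actual,
        base_provenance=ACTUAL,
    )


def predict_year(
    incidence: Mapping[str, IncidenceSeries],
    rsvi: Mapping[str, RSVISeries],
    target_year: int,
    *,
    require_actual: bool = False,
    threshold: float = 6.0,
) -> ValidationTable:
    """One-step predictions of ``target_year`` from the previous year's actuals.

    With ``require_actual=False`` regions without a target-year actual
    still get a (unvalidated) prediction; the summary covers only the
    records that do carry a %error.
    """
    records: list[PredictionRecord] = []
    skipped: dict[str, str] = {}
    for region in sorted(incidence):
        out = _one_region(
            incidence[region], rsvi.get(region), target_year, require_actual
        )
        if isinstance(out, str):
            skipped[region] = out
        else:
            records.append(out)
    if not records:
        raise ValueError(
            f"no qualifying region for target year {target_year}; "
            f"skipped: {skipped}"
        )
    errors = [r.percent_error for r in records if r.percent_error is not None]
    summary = error_summary(errors, threshold=threshold) if errors else None
    for region, reason in skipped.items():
        log.info("validate %d: skipped %s (%s)", target_year, region, reason)
    return ValidationTable(
        target_year=target_year,
        records=tuple(records),
        skipped=skipped,
        summary=summary,
    )


def validate_year(
    incidence: Mapping[str, IncidenceSeries],
    rsvi: Mapping[str, RSVISeries],
    target_year: int,
    *,
    threshold: float = 6.0,
) -> ValidationTable:
    """Predict ``target_year`` for every region with complete inputs and
    score each prediction against the target-year actual."""
    return predict_year(
        incidence, rsvi, target_year, require_actual=True, threshold=threshold
    )


def validate_multi_year(
    incidence: Mapping[str, IncidenceSeries],
    rsvi: Mapping[str, RSVISeries],
    years: Sequence[int],
    *,
    threshold: float = 6.0,
) -> list[ValidationTable]:
    """Run :func:`validate_year` for each target year.

    Each year is predicted from the *previous year's actual* count (not
    chained through earlier predictions): when actuals exist they are
    always the better base.
    """
    return [
        validate_year(incidence, rsvi, year, threshold=threshold)
        for year in years
    ]


def project_unobserved(
    incidence: Mapping[str, IncidenceSeries],
    rsvi: Mapping[str, RSVISeries],
    last_actual_year: int,
    horizon: int,
) -> dict[str, IncidenceSeries]:
    """Chained projections for years with no actuals yet.

    Starting from each region's actual count in ``last_actual_year``,
    forecasts ``horizon`` further years with each step based on the
    previous (unrounded) prediction.  Output years carry
    ``provenance="predicted"``.  %error is expected to increase with
    horizon due to the cumulative deviation of predicted bases from
    reality; a run-log warning records this caveat.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    log.warning(
        "projecting %d year(s) beyond %d from predicted bases: %%error is "
        "expected to increase due to the cumulative deviation from reality "
        "from year to year",
        horizon, last_actual_year,
    )
    out: dict[str, IncidenceSeries] = {}
    for region in sorted(incidence):
        inc = incidence[region]
        if inc.provenance.get(last_actual_year) != ACTUAL:
            raise ValueError(
                f"{region}: no actual count for {last_actual_year}"
            )
        if region not in rsvi:
            raise InsufficientSearchDataError(f"{region}: no RSVI series")
        records = chain_forecast(
            inc.values[last_actual_year], last_actual_year, rsvi[region], horizon
        )
        series = IncidenceSeries(region=region)
        for rec in records:
            series.set_value(rec.target_year, rec.predicted_raw, PREDICTED)
            log.info(
                "forecast %s %d: %d (base %d, provenance=%s)",
                region, rec.target_year, rec.predicted, rec.base_year,
                rec.base_provenance,
            )
        out[region] = series
    return out
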
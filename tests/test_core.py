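"""Unit and property tests for the ratio model, error statistic,
chained forecasting, summaries and paired comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cantrend.core import (
    ErrorSummary,
    IncidenceSeries,
    InsufficientSearchDataError,
    PredictionRecord,
    RSVISeries,
    chain_forecast,
    compare_error_vectors,
    display_percent,
    display_ratio,
    error_summary,
    percent_error,
    predict_one_step,
    round_count,
    rsvi_ratio,
)

rsvi_values = st.floats(min_value=1.0, max_value=100.0, allow_nan=False)
counts = st.floats(min_value=0.0, max_value=1e7, allow_nan=False)


# --------------------------------------------------------------------------
# rsvi_ratio
# --------------------------------------------------------------------------

class TestRsviRatio:
    @pytest.mark.parametrize(
        "target, base, shown",
        [
            (86, 89, 0.966),   # falling interest
            (98, 90, 1.089),   # 1.0889: display rounds to nearest, not truncates
            (85, 88, 0.966),
            (70, 67, 1.045),
        ],
    )
    def test_display_rounding(self, target, base, shown):
        assert display_ratio(rsvi_ratio(target, base)) == shown

    @given(x=rsvi_values)
    def test_identity_ratio(self, x):
        assert rsvi_ratio(x, x) == 1.0

    def test_full_precision_returned(self):
        assert rsvi_ratio(86, 89) == 86 / 89

    def test_zero_base_is_insufficient_data(self):
        with pytest.raises(InsufficientSearchDataError, match="insufficient"):
            rsvi_ratio(50, 0, region="AL", year=2016)

    def test_error_names_region_and_year(self):
        with pytest.raises(InsufficientSearchDataError, match="AL/2016"):
            rsvi_ratio(50, 0, region="AL", year=2016)

    @pytest.mark.parametrize("target, base", [(101, 50), (50, -1), (150, 90)])
    def test_out_of_scale_rejected(self, target, base):
        with pytest.raises(ValueError):
            rsvi_ratio(target, base)


# --------------------------------------------------------------------------
# predict_one_step
# --------------------------------------------------------------------------

class TestPredictOneStep:
    @pytest.mark.parametrize(
        "base_count, rsvi_base, rsvi_target, predicted",
        [
            (27550, 89, 86, 26621),
            (3008, 67, 70, 3143),
            (1000, 80, 40, 500),
            (115030, 90, 98, 125255),
        ],
    )
    def test_known_predictions(self, base_count, rsvi_base, rsvi_target, predicted):
        assert predict_one_step(base_count, rsvi_base, rsvi_target).predicted == predicted

    def test_uses_full_precision_ratio_not_display(self):
        # 27550 * 0.966 = 26613.3 — the display ratio would be wrong by 8 cases
        rec = predict_one_step(27550, 89, 86)
        assert rec.predicted == 26621 != round_count(27550 * 0.966)

    @given(n=counts, r=rsvi_values)
    def test_identity_ratio_returns_base(self, n, r):
        rec = predict_one_step(n, r, r)
        assert rec.predicted_raw == n
        assert rec.predicted == round_count(n)

    @given(n=counts, a=rsvi_values, b=rsvi_values, k=st.floats(0.1, 1000))
    def test_scale_equivariance(self, n, a, b, k):
        one = predict_one_step(n, a, b).predicted_raw
        scaled = predict_one_step(k * n, a, b).predicted_raw
        assert scaled == pytest.approx(k * one, rel=1e-12)

    @given(n=st.floats(1.0, 1e7), a=rsvi_values, b=rsvi_values)
    def test_ratio_inversion_recovers_base(self, n, a, b):
        fwd = predict_one_step(n, a, b).predicted_raw
        back = predict_one_step(fwd, b, a).predicted_raw
        assert back == pytest.approx(n, rel=1e-9)

    def test_negative_base_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            predict_one_step(-1, 80, 80)

    def test_record_fields(self):
        rec = predict_one_step(
            27550, 89, 86, region="AL", base_year=2016, actual=27409
        )
        assert (rec.region, rec.base_year, rec.target_year) == ("AL", 2016, 2017)
        assert rec.base_provenance == "actual"
        # %error computed from the unrounded prediction
        assert rec.percent_error == percent_error(rec.predicted_raw, 27409)
        assert display_percent(rec.percent_error) == -2.9

    def test_error_absent_without_actual(self):
        assert predict_one_step(100, 50, 50).percent_error is None


# --------------------------------------------------------------------------
# percent_error
# --------------------------------------------------------------------------

class TestPercentError:
    @pytest.mark.parametrize(
        "predicted, actual, shown",
        [
            (26621, 27409, -2.9),
            (30915, 27463, 12.6),
            (3921.272727272727, 3987, -1.6),  # raw prediction, not its rounding
        ],
    )
    def test_display_values(self, predicted, actual, shown):
        assert display_percent(percent_error(predicted, actual)) == shown

    def test_full_precision(self):
        assert percent_error(26621, 27409) == (26621 - 27409) / 27409 * 100

    @given(x=st.floats(0.001, 1e9))
    def test_zero_iff_equal(self, x):
        assert percent_error(x, x) == 0.0

    @given(p=st.floats(0, 1e9), a=st.floats(0.001, 1e9))
    def test_sign_matches_difference(self, p, a):
        e = percent_error(p, a)
        assert math.copysign(1, e) == math.copysign(1, p - a) or e == 0 == p - a

    @pytest.mark.parametrize("actual", [0, -5])
    def test_nonpositive_actual_rejected(self, actual):
        with pytest.raises(ValueError):
            percent_error(100, actual)


# --------------------------------------------------------------------------
# chain_forecast
# --------------------------------------------------------------------------

def _series(values, region="XX"):
    return RSVISeries(region=region, values=values)


class TestChainForecast:
    def test_two_step_hand_computed(self):
        rsvi = _series({0: 80, 1: 88, 2: 66})
        recs = chain_forecast(10000, 0, rsvi, 2)
        assert [r.predicted_raw for r in recs] == [
            pytest.approx(11000.0), pytest.approx(8250.0)
        ]
        # telescoped form: base * rsvi(end)/rsvi(start)
        assert recs[-1].predicted_raw == pytest.approx(10000 * 66 / 80, rel=1e-12)

    def test_constant_rsvi_keeps_base(self):
        recs = chain_forecast(5432, 2016, _series({y: 70 for y in range(2016, 2021)}), 4)
        assert all(r.predicted_raw == 5432 for r in recs)

    def test_provenance_actual_then_predicted(self):
        recs = chain_forecast(100, 0, _series({0: 50, 1: 60, 2: 70}), 2)
        assert [r.base_provenance for r in recs] == ["actual", "predicted"]

    def test_carries_unrounded_base(self):
        rsvi = _series({0: 89, 1: 86, 2: 86})
        recs = chain_forecast(27550, 0, rsvi, 2)
        assert recs[1].base_count == recs[0].predicted_raw  # 26621.348..., not 26621

    @given(
        base=st.floats(1, 1e6),
        vals=st.lists(st.integers(1, 100), min_size=3, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_telescoping_identity(self, base, vals):
        years = dict(enumerate(vals))
        rsvi = _series(years)
        recs = chain_forecast(base, 0, rsvi, len(vals) - 1)
        for k, rec in enumerate(recs, start=1):
            assert rec.predicted_raw == pytest.approx(
                base * vals[k] / vals[0], rel=1e-9
            )

    def test_missing_year_names_first_offender(self):
        rsvi = _series({2016: 80, 2018: 70})
        with pytest.raises(InsufficientSearchDataError, match="2017"):
            chain_forecast(1000, 2016, rsvi, 2)

    def test_zero_rsvi_names_year(self):
        rsvi = _series({2016: 80, 2017: 0, 2018: 70})
        with pytest.raises(InsufficientSearchDataError, match="2017"):
            chain_forecast(1000, 2016, rsvi, 2)

    @pytest.mark.parametrize("horizon", [0, -1])
    def test_bad_horizon(self, horizon):
        with pytest.raises(ValueError, match="horizon"):
            chain_forecast(1000, 2016, _series({2016: 80}), horizon)


# --------------------------------------------------------------------------
# error_summary
# --------------------------------------------------------------------------

class TestErrorSummary:
    def test_single_element(self):
        s = error_summary([3.5])
        assert (s.mean, s.median, s.min, s.max, s.n) == (3.5, 3.5, 3.5, 3.5, 1)

    def test_even_n_median_is_midpoint(self):
        assert error_summary([-1.6, -1.5, 4.0, -9.0]).median == -1.55

    def test_threshold_share(self):
        s = error_summary([0.0, 5.9, -6.0, 6.1, -12.0], threshold=6)
        assert s.prop_within_threshold == 3 / 5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            error_summary([])

    @given(
        errs=st.lists(st.floats(-50, 50), min_size=1, max_size=40),
        threshold=st.floats(0.5, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_against_sort_based_oracle(self, errs, threshold):
        s = error_summary(errs, threshold=threshold)
        arr = np.sort(np.asarray(errs))
        n = len(arr)
        med = arr[n // 2] if n % 2 else (arr[n // 2 - 1] + arr[n // 2]) / 2
        assert s.mean == pytest.approx(arr.mean(), rel=1e-12, abs=1e-12)
        assert s.median == pytest.approx(med, rel=1e-12, abs=1e-12)
        assert (s.min, s.max) == (arr[0], arr[-1])
        assert s.prop_within_threshold == np.mean(np.abs(arr) <= threshold)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ErrorSummary(n=2, mean=5.0, median=0.0, min=-1.0, max=1.0,
                         prop_within_threshold=0.5)


# --------------------------------------------------------------------------
# compare_error_vectors
# --------------------------------------------------------------------------

class TestCompareErrorVectors:
    def test_identical_vectors_all_ties(self):
        v = {"AL": -2.0, "AK": 3.0, "AZ": 0.0}
        cmp = compare_error_vectors(v, dict(v))
        assert cmp.n_ties == 3 and cmp.n_a_better == cmp.n_b_better == 0
        assert all(d == 0 for d in cmp.abs_diff.values())

    def test_hand_example(self):
        cmp = compare_error_vectors({"r1": -2, "r2": 4}, {"r1": 3, "r2": 4})
        assert cmp.mae_a == 3.0 and cmp.mae_b == 3.5
        assert cmp.n_a_better == 1 and cmp.n_ties == 1 and cmp.n_b_better == 0

    def test_inner_join_warns_and_lists_drops(self):
        with pytest.warns(UserWarning, match="KS"):
            cmp = compare_error_vectors({"AL": 1, "KS": 2}, {"AL": 3, "VT": 4})
        assert cmp.regions == ("AL",)
        assert cmp.dropped_a == ("KS",) and cmp.dropped_b == ("VT",)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            compare_error_vectors({"AL": 1}, {"VT": 2})

    @given(
        data=st.dictionaries(
            st.sampled_from([f"R{i}" for i in range(12)]),
            st.tuples(st.floats(-20, 20), st.floats(-20, 20)),
            min_size=1,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_win_counts_against_recount_oracle(self, data):
        a = {r: ab[0] for r, ab in data.items()}
        b = {r: ab[1] for r, ab in data.items()}
        cmp = compare_error_vectors(a, b)
        wins_a = sum(abs(a[r]) < abs(b[r]) for r in data)
        wins_b = sum(abs(a[r]) > abs(b[r]) for r in data)
        assert (cmp.n_a_better, cmp.n_b_better) == (wins_a, wins_b)
        assert cmp.n_ties == len(data) - wins_a - wins_b


# --------------------------------------------------------------------------
# rounding helpers and domain-type invariants
# --------------------------------------------------------------------------

class TestRoundingAndTypes:
    @pytest.mark.parametrize(
        "x, expected",
        [(2.5, 3), (-2.5, -3), (2.4, 2), (-2.4, -2), (0.0, 0), (26621.35, 26621)],
    )
    def test_count_rounds_half_away_from_zero(self, x, expected):
        assert round_count(x) == expected

    @pytest.mark.parametrize(
        "x, expected", [(1.0889, 1.089), (0.9663, 0.966), (1.0005, 1.001)]
    )
    def test_ratio_display(self, x, expected):
        assert display_ratio(x) == expected

    @pytest.mark.parametrize(
        "x, expected", [(-2.875, -2.9), (12.569, 12.6), (-1.6485, -1.6), (0.05, 0.1)]
    )
    def test_percent_display(self, x, expected):
        assert display_percent(x) == expected

    def test_rsvi_series_rejects_out_of_scale(self):
        with pytest.raises(ValueError):
            RSVISeries(region="AL", values={2016: 101})

    def test_incidence_rejects_negative(self):
        with pytest.raises(ValueError):
            IncidenceSeries(region="AL", values={2016: -1})

    def test_actual_never_overwritten_by_prediction(self):
        s = IncidenceSeries(region="AL", values={2016: 100})
        with pytest.raises(ValueError, match="refusing to overwrite"):
            s.set_value(2016, 90, "predicted")
        s.set_value(2017, 90, "predicted")
        s.set_value(2017, 95, "actual")  # actual replacing predicted is fine
        assert s.provenance[2017] == "actual"

    def test_record_invariants(self):
        with pytest.raises(ValueError, match="target year"):
            PredictionRecord(
                region="AL", base_year=2016, target_year=2018, base_count=1,
                rsvi_base=50, rsvi_target=50, ratio=1.0, predicted_raw=1.0,
                predicted=1,
            )
        with pytest.raises(ValueError, match="percent_error"):
            PredictionRecord(
                region="AL", base_year=2016, target_year=2017, base_count=1,
                rsvi_base=50, rsvi_target=50, ratio=1.0, predicted_raw=1.0,
                predicted=1, actual=1.0,
            )
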
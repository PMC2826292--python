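"""Unit and property tests for the dosing advisory algorithm."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gripk.advisor import (
    DEFAULT_CONFIG,
    HIGH_INFUSION_RATE,
    MARKED_ABNORMAL_POTASSIUM,
    AdvisoryContext,
    ContractViolationError,
    InvalidInputError,
    KalemicState,
    TargetRange,
    advise,
    check_alerts,
    classify,
    clearance_fraction,
    cockcroft_gault,
    is_renal_impaired,
    mean_recent_rate,
    next_interval,
    sliding_scale_rate,
    target_range,
    within_range_rate,
)


class TestCockcroftGault:
    @pytest.mark.parametrize("age,weight,sex,creat,expected", [
        (60, 70, "male", 88.4, 5600 / 72),          # creatinine exactly 1 mg/dL
        (60, 70, "female", 88.4, 5600 / 72 * 0.85),
        (140, 70, "male", 100.0, 0.0),               # age factor vanishes
    ])
    def test_examples(self, age, weight, sex, creat, expected):
        assert cockcroft_gault(age, weight, sex, creat) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("kwargs", [
        dict(age=60, weight=70, sex="male", creatinine=0.0),
        dict(age=60, weight=70, sex="male", creatinine=-5.0),
        dict(age=60, weight=0, sex="male", creatinine=90.0),
        dict(age=-1, weight=70, sex="male", creatinine=90.0),
        dict(age=60, weight=70, sex="other", creatinine=90.0),
    ])
    def test_invalid_inputs(self, kwargs):
        with pytest.raises(InvalidInputError):
            cockcroft_gault(**kwargs)


class TestClearanceFraction:
    @pytest.mark.parametrize("gfr,diuresis,rrt,expected", [
        (120.0, 6.0, False, 0.1),    # oliguria dominates
        (120.0, 90.0, False, 1.0),   # both components at cap
        (0.0, 0.0, True, 0.5),       # anuric on hemofiltration
        (50.0, 90.0, False, 0.5),    # GFR component dominates
        (120.0, 90.0, True, 1.5),    # RRT adds on top of a normal fraction
    ])
    def test_examples(self, gfr, diuresis, rrt, expected):
        assert clearance_fraction(gfr, diuresis, rrt) == pytest.approx(expected)

    def test_missing_inputs_fall_back(self):
        assert clearance_fraction(None, 30.0, False) == pytest.approx(0.5)
        assert clearance_fraction(50.0, None, False) == pytest.approx(0.5)
        assert clearance_fraction(None, None, False) == 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            clearance_fraction(-1.0, 60.0, False)
        with pytest.raises(InvalidInputError):
            clearance_fraction(100.0, -1.0, False)


@pytest.mark.parametrize("gfr,diuresis,expected", [
    (25.0, 50.0, True),    # low GFR alone
    (80.0, 20.0, True),    # oliguria alone
    (30.0, 30.0, False),   # cutoffs are strict
    (100.0, 100.0, False),
    (None, 20.0, True),    # diuresis-only assessment
    (None, None, False),   # no renal data: assume normal
])
def test_renal_impairment_cutoffs(gfr, diuresis, expected):
    assert is_renal_impaired(gfr, diuresis) is expected


def test_target_range_lowering():
    normal = target_range(False)
    impaired = target_range(True)
    assert (normal.low, normal.high) == (3.8, 4.5)
    assert (impaired.low, impaired.high) == (pytest.approx(3.6), pytest.approx(4.3))
    assert normal.low - impaired.low == pytest.approx(0.2)
    assert normal.high - impaired.high == pytest.approx(0.2)


@pytest.mark.parametrize("potassium,expected", [
    (3.7, KalemicState.HYPOKALEMIA),
    (4.6, KalemicState.HYPERKALEMIA),
    (3.8, KalemicState.NORMOKALEMIA),  # bounds inclusive
    (4.5, KalemicState.NORMOKALEMIA),
    (4.0, KalemicState.NORMOKALEMIA),
])
def test_classification_boundaries(potassium, expected):
    assert classify(potassium, TargetRange(3.8, 4.5)) is expected


class TestSlidingScale:
    @pytest.mark.parametrize("potassium,expected", [
        (2.0, 20.0),   # anchor
        (3.5, 6.0),    # anchor
        (2.75, 13.0),  # midpoint of the linear scale
        (1.4, 20.0),   # clamped below the low anchor
    ])
    def test_scale_values(self, potassium, expected):
        assert sliding_scale_rate(potassium, target_range(False)) == expected

    def test_extends_linearly_between_high_anchor_and_target(self):
        # slope -14/1.5 continues past K=3.5 up to the target lower bound
        expected = 20.0 - (14.0 / 1.5) * (3.7 - 2.0)
        got = sliding_scale_rate(3.7, target_range(False))
        assert abs(got - expected) <= DEFAULT_CONFIG.rate_resolution / 2

    def test_rejects_non_hypokalemic_call(self):
        with pytest.raises(ContractViolationError):
            sliding_scale_rate(3.8, target_range(False))

    @given(st.tuples(st.floats(0.5, 3.79), st.floats(0.5, 3.79)))
    def test_monotone_non_increasing(self, pair):
        k1, k2 = sorted(pair)
        target = target_range(False)
        assert sliding_scale_rate(k1, target) >= sliding_scale_rate(k2, target)

    def test_never_negative(self):
        for k in np.arange(0.5, 3.8, 0.05):
            assert sliding_scale_rate(float(k), target_range(False)) >= 0.0


class TestMeanRecentRate:
    def test_constant_rate_over_full_window(self):
        assert mean_recent_rate([(0.0, 8.0, 2.0)], 0.0, 8.0) == pytest.approx(2.0)

    def test_time_weighted_mean(self):
        log = [(0.0, 4.0, 0.0), (4.0, 8.0, 4.0)]
        assert mean_recent_rate(log, 0.0, 8.0) == pytest.approx(2.0)

    def test_shorter_span_since_admission(self):
        # admitted 2 h ago: average over 2 h, not 8
        assert mean_recent_rate([(0.0, 2.0, 3.0)], 0.0, 2.0) == pytest.approx(3.0)

    def test_gaps_count_as_zero(self):
        assert mean_recent_rate([(6.0, 8.0, 4.0)], 0.0, 8.0) == pytest.approx(1.0)

    def test_empty_span_returns_zero(self):
        assert mean_recent_rate([], 0.0, 0.0) == 0.0

    def test_interval_outside_stay_rejected(self):
        with pytest.raises(InvalidInputError):
            mean_recent_rate([(0.0, 9.0, 2.0)], 0.0, 8.0)
        with pytest.raises(InvalidInputError):
            mean_recent_rate([(-1.0, 2.0, 2.0)], 0.0, 8.0)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(InvalidInputError):
            mean_recent_rate([(0.0, 4.0, 2.0), (3.0, 6.0, 1.0)], 0.0, 8.0)

    @given(st.data())
    def test_matches_dense_sampling_oracle(self, data):
        # interval endpoints on whole seconds so the 1 s oracle is exact
        now_s = data.draw(st.integers(3600, 12 * 3600))
        n_breaks = data.draw(st.integers(2, 8))
        breaks = sorted(data.draw(st.lists(
            st.integers(0, now_s), min_size=n_breaks, max_size=n_breaks, unique=True)))
        log = []
        for s, e in zip(breaks[:-1], breaks[1:]):
            rate = data.draw(st.floats(0.0, 20.0))
            if data.draw(st.booleans()):
                log.append((s / 3600.0, e / 3600.0, rate))
        now = now_s / 3600.0
        expected = mean_recent_rate(log, 0.0, now)
        # brute force: sample the step function at every 1-second cell midpoint
        span_start_s = max(now_s - 8 * 3600, 0)
        mids = (np.arange(span_start_s, now_s) + 0.5) / 3600.0
        values = np.zeros_like(mids)
        for s, e, rate in log:
            values[(mids >= s) & (mids < e)] = rate
        assert expected == pytest.approx(float(values.mean()), abs=1e-6)


class TestWithinRangeRate:
    @pytest.mark.parametrize("mean_8h,clearance,expected", [
        (4.0, 1.0, 4.0),    # exact fixed point at clearance 1
        (1.0, 0.25, 1.0),   # exact fixed point at clearance 0.25
        (8.0, 1.0, 7.0),    # one smoothing step: 0.75*8 + 0.25*4
    ])
    def test_examples(self, mean_8h, clearance, expected):
        assert within_range_rate(mean_8h, clearance) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            within_range_rate(-1.0, 1.0)
        with pytest.raises(InvalidInputError):
            within_range_rate(1.0, -0.1)

    @given(st.floats(0.0, 25.0), st.floats(0.0, 1.5), st.integers(1, 40))
    def test_geometric_convergence_to_clearance_rate(self, m0, clearance, n):
        lam = DEFAULT_CONFIG.convergence_weight
        limit = DEFAULT_CONFIG.pump_rate_per_clearance * clearance
        rate = m0
        for _ in range(n):
            rate = within_range_rate(rate, clearance)
        assert abs(rate - limit) <= (1 - lam) ** n * abs(m0 - limit) + 1e-9


class TestAlerts:
    @pytest.mark.parametrize("potassium,impaired,rate,expected", [
        (2.7, False, 11.0, (MARKED_ABNORMAL_POTASSIUM,)),
        (2.7, True, 11.0, ()),          # renal window is wider at the bottom
        (2.5, False, 14.0, (MARKED_ABNORMAL_POTASSIUM, HIGH_INFUSION_RATE)),
        (5.9, False, 0.0, ()),
        (5.9, True, 0.0, (MARKED_ABNORMAL_POTASSIUM,)),
        (4.0, False, 12.0, ()),          # threshold is strict (> 12)
        (4.0, False, 12.5, (HIGH_INFUSION_RATE,)),
    ])
    def test_examples(self, potassium, impaired, rate, expected):
        assert check_alerts(potassium, impaired, rate) == expected

    def test_alert_window_partition_on_fine_grid(self):
        for impaired, low, high in ((False, 2.8, 6.0), (True, 2.6, 5.8)):
            for k in np.round(np.arange(1.0, 7.01, 0.01), 2):
                alerts = check_alerts(float(k), impaired, 0.0)
                outside = k < low or k > high
                assert (MARKED_ABNORMAL_POTASSIUM in alerts) == outside, (k, impaired)


@pytest.mark.parametrize("state,alerts,expected", [
    (KalemicState.NORMOKALEMIA, (), 4.0),
    (KalemicState.HYPOKALEMIA, (), 2.0),
    (KalemicState.HYPERKALEMIA, (), 2.0),
    (KalemicState.HYPERKALEMIA, (MARKED_ABNORMAL_POTASSIUM,), 1.0),
    (KalemicState.HYPOKALEMIA, (HIGH_INFUSION_RATE,), 2.0),
])
def test_next_interval_table(state, alerts, expected):
    assert next_interval(state, alerts) == expected


def _ctx(potassium, **kwargs):
    defaults = dict(creatinine=88.4, age=40.0, weight=90.0, sex="male",
                    diuresis_6h=600.0, on_rrt=False, infusion_log=(),
                    admission_time=0.0, now=8.0)
    defaults.update(kwargs)
    return AdvisoryContext(potassium=potassium, **defaults)


class TestAdvise:
    def test_severe_hypokalemia_full_composition(self):
        advice = advise(_ctx(2.0))
        assert advice.rate == 20.0
        assert MARKED_ABNORMAL_POTASSIUM in advice.alerts
        assert HIGH_INFUSION_RATE in advice.alerts
        assert advice.next_interval == 1.0
        assert advice.state is KalemicState.HYPOKALEMIA

    def test_within_range_fixed_point(self):
        advice = advise(_ctx(4.0, infusion_log=((0.0, 8.0, 4.0),)))
        assert advice.rate == 4.0
        assert advice.alerts == ()
        assert advice.next_interval == 4.0
        assert advice.clearance_fraction == pytest.approx(1.0)

    def test_hyperkalemia_stops_infusion(self):
        advice = advise(_ctx(5.2, infusion_log=((0.0, 8.0, 6.0),)))
        assert advice.rate == 0.0
        assert advice.state is KalemicState.HYPERKALEMIA

    def test_renal_impairment_lowers_target_and_widens_alerts(self):
        # anuric, not on RRT: impaired, target (3.6, 4.3)
        advice = advise(_ctx(4.4, diuresis_6h=30.0))
        assert advice.state is KalemicState.HYPERKALEMIA
        assert advice.target.low == pytest.approx(3.6)
        assert advice.target.high == pytest.approx(4.3)
        assert advice.rate == 0.0

    def test_deterministic(self):
        a = advise(_ctx(3.2, infusion_log=((0.0, 5.0, 2.0),)))
        b = advise(_ctx(3.2, infusion_log=((0.0, 5.0, 2.0),)))
        assert a == b

    @given(st.floats(0.6, 8.0))
    def test_rate_nonnegative_finite_and_hyper_implies_zero(self, potassium):
        advice = advise(_ctx(round(potassium, 2)))
        assert advice.rate >= 0.0 and math.isfinite(advice.rate)
        if advice.state is KalemicState.HYPERKALEMIA:
            assert advice.rate == 0.0
        if advice.rate > 12.0:
            assert HIGH_INFUSION_RATE in advice.alerts

    def test_invalid_potassium_rejected_not_clipped(self):
        with pytest.raises(InvalidInputError):
            _ctx(0.0)
        with pytest.raises(InvalidInputError):
            _ctx(-3.5)
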
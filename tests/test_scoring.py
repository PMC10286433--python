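"""Change-score rules: preprocessing, ternary scoring, weighted sum."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crowdstress.errors import ConfigError, FormatError
from crowdstress.scoring import (
    PhysioStream,
    RuleScores,
    ScoringParams,
    change_score,
    evaluate_rules,
    preprocess,
    score_session,
)
from crowdstress.synthetic import ScrEvent, simulate_physio

from conftest import flat_streams, make_window


class TestPreprocess:
    def test_clean_constant_stream_unchanged(self):
        stream = PhysioStream("GSR", 0.0, 4.0, np.full(40, 5.0))
        (out,) = preprocess(stream, 4.0)
        np.testing.assert_allclose(out.samples, 5.0)
        assert out.fs == 4.0 and out.start_epoch == 0.0

    def test_out_of_range_sample_removed_and_interpolated(self):
        x = np.full(10, 5.0)
        x[4] = 150.0  # implausible skin conductance
        (out,) = preprocess(PhysioStream("GSR", 0.0, 4.0, x), 4.0)
        np.testing.assert_allclose(out.samples, 5.0)

    def test_long_dropout_splits_into_segments(self):
        x = np.full(10 * 4, 5.0)
        x[16:28] = np.nan  # 3 s dropout at 4 Hz
        segs = preprocess(PhysioStream("GSR", 100.0, 4.0, x), 4.0)
        assert len(segs) == 2
        assert segs[0].start_epoch == 100.0
        assert segs[1].start_epoch == pytest.approx(100.0 + 28 / 4)

    def test_short_gap_interpolated_single_segment(self):
        x = np.full(10 * 4, 5.0)
        x[16:24] = np.nan  # exactly 2 s: interpolated, not split
        segs = preprocess(PhysioStream("GSR", 0.0, 4.0, x), 4.0)
        assert len(segs) == 1
        assert not np.isnan(segs[0].samples).any()

    def test_entirely_out_of_range_raises(self):
        with pytest.raises(FormatError, match="out of range"):
            preprocess(PhysioStream("ST", 0.0, 4.0, np.full(20, 99.0)), 4.0)

    def test_irrational_resample_raises(self):
        stream = PhysioStream("GSR", 0.0, np.pi, np.full(20, 5.0))
        with pytest.raises(FormatError, match="resample"):
            preprocess(stream, 4.0)

    def test_downsampling_preserves_level(self):
        (out,) = preprocess(PhysioStream("GSR", 0.0, 8.0, np.full(80, 5.0)), 4.0)
        assert out.fs == 4.0
        np.testing.assert_allclose(out.samples[2:-2], 5.0, rtol=1e-6)


class TestEvaluateRules:
    def test_flat_window_scores_zero(self, params):
        gsr, st = make_window()
        rs = evaluate_rules(gsr, st, params)
        assert (rs.s1, rs.s2, rs.s3, rs.s4) == (0.0, 0.0, 0.0, 0.0)

    def test_complete_fulfilment(self, params):
        # 0.12 µS rise over 3 s with a −0.006 °C/s temperature drop meets
        # every complete criterion; slope ratio 0.04 µS/s is also complete
        gsr, st = make_window(amplitude=0.12, rise_s=3.0, st_slope=-0.006)
        rs = evaluate_rules(gsr, st, params)
        assert (rs.s1, rs.s2, rs.s3, rs.s4) == (1.0, 1.0, 1.0, 1.0)

    def test_partial_fulfilment(self, params):
        # 0.07 µS over 6 s: amplitude and rise time partial, ratio
        # 0.0117 µS/s partial, flat temperature scores zero
        gsr, st = make_window(amplitude=0.07, rise_s=6.0, trough_at_s=1.0)
        rs = evaluate_rules(gsr, st, params)
        assert (rs.s1, rs.s2, rs.s3, rs.s4) == (0.5, 0.0, 0.5, 0.5)

    def test_window_too_short_raises(self, params):
        with pytest.raises(ConfigError, match="window"):
            evaluate_rules(np.zeros(10), np.zeros(10), params)

    def test_temperature_rule_only_fires_on_decrease(self, params):
        gsr, st = make_window(st_slope=+0.01)
        assert evaluate_rules(gsr, st, params).s2 == 0.0


class TestChangeScore:
    def test_oracle_all_81_ternary_combinations(self, params):
        """Brute-force Σ wn·sn over the full ternary grid matches exactly."""
        weights = [params.w1, params.w2, params.w3, params.w4]
        for combo in itertools.product((0.0, 0.5, 1.0), repeat=4):
            expected = sum(w * s for w, s in zip(weights, combo))
            rs = RuleScores(0.0, *combo)
            assert change_score(rs, params) == expected

    def test_extremes(self, params):
        assert change_score(RuleScores(0, 1, 1, 1, 1), params) == 80.0
        assert change_score(RuleScores(0, 0, 0, 0, 0), params) == 0.0
        assert change_score(RuleScores(0, 1, 1, 0.5, 0.5), params) == 60.0

    def test_invalid_score_value_rejected(self):
        with pytest.raises(ConfigError):
            RuleScores(0.0, 0.3, 0, 0, 0)


class TestScoreSession:
    def test_record_count_and_flat_scores(self, params):
        gsr, st = flat_streams(seconds=60)
        df = score_session(gsr, st, params)
        assert len(df) == 53  # 60 − 8 + 1
        assert (df["CS"] == 0).all()

    def test_no_overlap_raises(self, params):
        gsr, _ = flat_streams(seconds=30, start=0.0)
        _, st = flat_streams(seconds=30, start=1000.0)
        with pytest.raises(ConfigError, match="overlap"):
            score_session(gsr, st, params)

    def test_strong_event_produces_high_score(self, params):
        ev = ScrEvent(onset=30.0, amplitude=0.4, rise_time=3.0, decay_tau=5.0, st_dip=0.3)
        gsr, st = simulate_physio([ev], duration_s=60, fs=4.0)
        df = score_session(gsr, st, params)
        peak_region = df[(df["t"] >= 30) & (df["t"] <= 40)]
        assert peak_region["CS"].max() >= 40.0

    def test_determinism(self, params):
        gsr, st = flat_streams(seconds=30)
        a = score_session(gsr, st, params)
        b = score_session(gsr, st, params)
        assert a.equals(b)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_cs_bounds_and_granularity_property(seed):
    """Any input window yields CS ∈ [0, 80], a multiple of 10 under default
    weights (ternary scores × 20)."""
    rng = np.random.default_rng(seed)
    params = ScoringParams()
    gsr = np.abs(rng.normal(2.0, 0.5, 32).cumsum() / 10 + 1)
    stt = 33.0 + rng.normal(0, 0.05, 32).cumsum()
    rs = evaluate_rules(gsr, stt, params)
    cs = change_score(rs, params)
    assert 0.0 <= cs <= 80.0
    assert cs % 10 == 0


def test_amplitude_monotonicity(params):
    """Raising the trough-to-peak amplitude (all else fixed) never lowers
    the amplitude rule score or the change score."""
    prev_s1, prev_cs = -1.0, -1.0
    for amp in np.linspace(0.0, 0.3, 31)[1:]:
        gsr, stw = make_window(amplitude=float(amp), rise_s=3.0)
        rs = evaluate_rules(gsr, stw, params)
        cs = change_score(rs, params)
        assert rs.s1 >= prev_s1
        assert cs >= prev_cs
        prev_s1, prev_cs = rs.s1, cs
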
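import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from marchphys.energetics import (
    EnergySummary,
    KCAL_PER_KJ,
    classify_intensity,
    energy_balance,
    paee_minute,
    paee_series,
    ree_daily,
    round_half_up,
    total_energy,
)
from marchphys.segmentation import BREAK, MARCH, MISSING, classify_states
from .conftest import make_minutes


class TestMifflin:
    @pytest.mark.parametrize(
        "w, h, a, expected",
        [
            (74.8, 178.5, 20.3, 1767.125),   # cohort mean soldier
            (0.0, 0.0, 0.0, 5.0),            # constant term
            (110.0, 191.9, 23.0, 2189.375),  # cohort extremes
        ],
    )
    def test_mens_equation(self, w, h, a, expected):
        assert ree_daily(w, h, a) == pytest.approx(expected, abs=1e-9)

    def test_missing_anthropometrics_rejected(self):
        with pytest.raises(ValueError):
            ree_daily(float("nan"), 178.5, 20.3)


class TestPaeeMinute:
    def test_march_equation(self):
        # HRaR 60: (60*0.7810 - 15.9337)/4.1868
        assert paee_minute(130.0, 70.0, 0.0, MARCH) == pytest.approx(7.3866, abs=1e-4)

    def test_march_root_is_zero(self):
        hrar_root = 15.9337 / 0.7810
        assert paee_minute(60.0 + hrar_root, 60.0, 0.0, MARCH) == pytest.approx(0.0, abs=1e-12)

    def test_break_equation(self):
        # HRaR 30, 1000 cpm: (14.52 + 1.0 - 4.7964)/4.1868
        assert paee_minute(90.0, 60.0, 1000.0, BREAK) == pytest.approx(2.5613, abs=1e-4)

    def test_negative_clamped_unless_disabled(self):
        assert paee_minute(62.0, 60.0, 0.0, MARCH) == 0.0
        assert paee_minute(62.0, 60.0, 0.0, MARCH, clamp=False) < 0.0

    def test_resting_hr_required(self):
        with pytest.raises(ValueError):
            paee_minute(130.0, float("nan"), 0.0, MARCH)

    def test_kj_divisor_recovers_kilojoules(self):
        kcal = paee_minute(130.0, 70.0, 0.0, MARCH)
        assert kcal * KCAL_PER_KJ == pytest.approx(60 * 0.7810 - 15.9337)

    @given(st.floats(min_value=80, max_value=200), st.floats(min_value=0.1, max_value=20),
           st.sampled_from([MARCH, BREAK]))
    @settings(max_examples=50, derandomize=True)
    def test_nondecreasing_in_heart_rate(self, hr, dhr, state):
        assert paee_minute(hr + dhr, 60.0, 500.0, state) >= paee_minute(hr, 60.0, 500.0, state)


def _march_minutes_at_rate(rate_kcal_min, n, resting_hr=60.0):
    hrar = (KCAL_PER_KJ * rate_kcal_min + 15.9337) / 0.7810
    return classify_states(make_minutes([1.8] * n, hr=resting_hr + hrar))


class TestTotalEnergy:
    def test_constant_march_rate_sums(self):
        mins = _march_minutes_at_rate(8.79, 475)
        summary = total_energy(mins, "S001", 74.8, 178.5, 20.3, 60.0)
        assert summary.paee_total == pytest.approx(8.79 * 475, rel=1e-9)
        assert summary.tee == pytest.approx(summary.paee_total + summary.ree_march, rel=1e-12)

    def test_ree_prorated_over_protocol(self):
        mins = _march_minutes_at_rate(8.79, 475)
        summary = total_energy(mins, "S001", 74.8, 178.5, 20.3, 60.0)
        assert summary.ree_march == pytest.approx(1767.125 * 475 / 1440, rel=1e-12)
        assert summary.ree_march == pytest.approx(582.9, abs=0.05)

    def test_resting_break_clamps_to_zero(self):
        mins = classify_states(make_minutes([0.5] * 30, hr=60.0, hacc=0.0))
        summary = total_energy(mins, "S001", 74.8, 178.5, 20.3, 60.0)
        assert summary.paee_total == 0.0

    def test_missing_minutes_excluded_from_proration(self):
        mins = classify_states(make_minutes([1.8] * 50 + [np.nan] * 10))
        summary = total_energy(mins, "S001", 74.8, 178.5, 20.3, 60.0)
        assert summary.protocol_minutes == 50
        assert summary.ree_march == pytest.approx(1767.125 * 50 / 1440)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            total_energy(make_minutes([]).assign(state=None), "S", 74.8, 178.5, 20.3, 60.0)

    @given(st.integers(1, 99), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_additivity_under_splitting(self, cut, seed):
        rng = np.random.default_rng(seed)
        n = 100
        mins = classify_states(make_minutes(
            rng.choice([1.8, 0.5], n), hr=rng.uniform(70, 180, n), hacc=rng.uniform(0, 8000, n)))
        whole = np.nansum(paee_series(mins, 60.0))
        left = np.nansum(paee_series(mins.iloc[:cut].reset_index(drop=True), 60.0))
        right = np.nansum(paee_series(mins.iloc[cut:].reset_index(drop=True), 60.0))
        assert left + right == pytest.approx(whole, rel=1e-12)

    def test_vectorized_matches_per_minute_loop(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(10, 120))
            mins = classify_states(make_minutes(
                rng.choice([1.8, 0.5], n), hr=rng.uniform(50, 200, n), hacc=rng.uniform(0, 9000, n)))
            vec = paee_series(mins, 62.0)
            loop = np.array([
                paee_minute(r.hr, 62.0, r.hacc, r.state) for r in mins.itertuples()])
            np.testing.assert_array_equal(vec, loop)


class TestEnergyBalance:
    @pytest.mark.parametrize(
        "intake, tee, pct",
        [(1042.0, 4803.0, 22), (1212.0, 4684.0, 26), (1718.0, 4732.0, 36)],
    )
    def test_percent_replaced_matches_printed_medians(self, intake, tee, pct):
        summary = EnergySummary("S", 0, 0, 0, tee, 0, "", 475)
        out = energy_balance(summary, [intake])
        assert out.pct_replaced == pct
        assert out.deficit == pytest.approx(intake - tee)

    def test_zero_intake(self):
        summary = energy_balance(EnergySummary("S", 0, 0, 0, 4000.0, 0, "", 475), [])
        assert summary.intake == 0.0
        assert summary.deficit == -4000.0
        assert summary.pct_replaced == 0

    def test_negative_diary_item_rejected(self):
        with pytest.raises(ValueError):
            energy_balance(EnergySummary("S", 0, 0, 0, 4000.0, 0, "", 475), [100.0, -5.0])


class TestIntensity:
    @pytest.mark.parametrize(
        "rate, label",
        [(4177 / 475, "very heavy"), (7.5, "heavy"), (6.0, "heavy"),
         (3.0, "moderate"), (0.0, "light")],
    )
    def test_howley_classes(self, rate, label):
        assert classify_intensity(rate) == label


def test_round_half_up_breaks_ties_upward():
    assert round_half_up(0.5) == 1
    assert round_half_up(2.5) == 3      # not banker's rounding
    assert round_half_up(21.69) == 22
    assert round_half_up(36.31) == 36
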
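"""Tests for ischemic-burden statistics: curves, correction, tertiles, agreement."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fermiperf as fp
from fermiperf.burden import (
    DEFAULT_THRESHOLDS,
    BurdenCurve,
    tertile_assign,
)
from fermiperf.fermi import MPRMap


def _map_from_values(values, valid=None):
    values = np.asarray(values, dtype=float).reshape(1, -1)
    valid = (
        np.ones_like(values, bool)
        if valid is None
        else np.asarray(valid, bool).reshape(1, -1)
    )
    return MPRMap(values=values, valid=valid)


def brute_force_burden(values, valid, scar, theta):
    """Independent pixel-counting oracle."""
    num = den = 0
    for v, ok, sc in zip(values, valid, scar):
        if not ok or sc:
            continue
        den += 1
        if v < theta:
            num += 1
    return 100.0 * num / den if den else None


class TestBurdenCurve:
    def test_counting_arithmetic(self):
        values = np.r_[np.full(30, 1.0), np.full(70, 2.0)]
        curve = fp.burden_curve(_map_from_values(values), [1.5])
        assert curve.burden[0] == pytest.approx(30.0)

    def test_bounds(self):
        values = np.linspace(1.0, 2.0, 50)
        curve = fp.burden_curve(_map_from_values(values), [0.5, 2.5])
        assert curve.burden[0] == 0.0
        assert curve.burden[-1] == 100.0

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = rng.integers(20, 200)
            values = rng.uniform(0.2, 3.5, n)
            valid = rng.random(n) > 0.1
            if not valid.any():
                continue
            theta = float(rng.uniform(0.5, 3.0))
            got = fp.burden_curve(_map_from_values(values, valid), [theta])
            expected = brute_force_burden(values, valid, np.zeros(n, bool), theta)
            assert got.burden[0] == pytest.approx(expected)

    def test_no_valid_units_rejected(self):
        with pytest.raises(ValueError):
            fp.burden_curve(_map_from_values([1.0], valid=[False]))

    @given(st.integers(0, 2**31 - 1))
    def test_non_decreasing_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.0, 4.0, 60)
        curve = fp.burden_curve(_map_from_values(values), DEFAULT_THRESHOLDS)
        assert np.all(np.diff(curve.burden) >= 0)
        assert np.all((curve.burden >= 0) & (curve.burden <= 100))


class TestCorrectedBurden:
    def test_hand_count_example(self):
        # 100 pixels, 30 below theta; scar covers 15 of which 12 below theta
        values = np.r_[
            np.full(12, 1.0),   # scar, below
            np.full(3, 2.0),    # scar, above
            np.full(18, 1.0),   # non-scar, below
            np.full(67, 2.0),   # non-scar, above
        ]
        scar = np.r_[np.ones(15, bool), np.zeros(85, bool)]
        unc = fp.burden_curve(_map_from_values(values), [1.5])
        corr = fp.corrected_burden(_map_from_values(values), scar.reshape(1, -1), [1.5])
        assert unc.burden[0] == pytest.approx(30.0)
        assert corr.burden[0] == pytest.approx(100 * 18 / 85)

    def test_empty_scar_is_identity(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0.5, 3.0, 80)
        m = _map_from_values(values)
        unc = fp.burden_curve(m)
        corr = fp.corrected_burden(m, np.zeros((1, 80), bool))
        np.testing.assert_allclose(corr.burden, unc.burden)

    def test_scar_above_threshold_can_raise_burden(self):
        # scar pixels all above theta: exclusion shrinks only the denominator
        values = np.r_[np.full(10, 1.0), np.full(90, 3.0)]
        scar = np.r_[np.zeros(50, bool), np.ones(50, bool)]
        unc = fp.burden_curve(_map_from_values(values), [2.0])
        corr = fp.corrected_burden(_map_from_values(values), scar.reshape(1, -1), [2.0])
        expected = brute_force_burden(values, np.ones(100, bool), scar, 2.0)
        assert corr.burden[0] == pytest.approx(expected)
        assert corr.burden[0] > unc.burden[0]

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = rng.integers(20, 200)
            values = rng.uniform(0.2, 3.5, n)
            valid = rng.random(n) > 0.1
            scar = rng.random(n) > 0.8
            theta = float(rng.uniform(0.5, 3.0))
            expected = brute_force_burden(values, valid, scar, theta)
            if expected is None:
                continue
            got = fp.corrected_burden(
                _map_from_values(values, valid), scar.reshape(1, -1), [theta]
            )
            assert got.burden[0] == pytest.approx(expected)

    def test_scar_covering_everything_rejected(self):
        with pytest.raises(ValueError):
            fp.corrected_burden(
                _map_from_values([1.0, 2.0]), np.ones((1, 2), bool), [1.5]
            )


class TestRelativeError:
    def test_arithmetic(self):
        unc = BurdenCurve(thresholds=[1.5], burden=[25.0])
        corr = BurdenCurve(thresholds=[1.5], burden=[18.0], corrected=True)
        _, err, defined = fp.relative_error(unc, corr)
        assert err[0] == pytest.approx(28.0)
        assert defined.all()

    def test_identity_gives_zero(self):
        unc = BurdenCurve(thresholds=[1.0, 1.5], burden=[10.0, 20.0])
        _, err, _ = fp.relative_error(unc, unc)
        np.testing.assert_allclose(err, 0.0)

    def test_zero_uncorrected_flagged_not_raised(self):
        unc = BurdenCurve(thresholds=[0.5, 1.5], burden=[0.0, 20.0])
        corr = BurdenCurve(thresholds=[0.5, 1.5], burden=[0.0, 15.0], corrected=True)
        _, err, defined = fp.relative_error(unc, corr)
        assert not defined[0] and np.isnan(err[0])
        assert defined[1]

    def test_grid_mismatch_rejected(self):
        a = BurdenCurve(thresholds=[1.0], burden=[10.0])
        b = BurdenCurve(thresholds=[1.5], burden=[10.0])
        with pytest.raises(ValueError):
            fp.relative_error(a, b)


class TestTertiles:
    def test_equal_count_split(self):
        labels = tertile_assign([1, 2, 3, 4, 5, 6])
        np.testing.assert_array_equal(labels, [0, 0, 1, 1, 2, 2])

    def test_unsorted_input(self):
        labels = tertile_assign([6, 1, 4, 2, 5, 3])
        np.testing.assert_array_equal(labels, [2, 0, 1, 0, 2, 1])

    def test_no_change_when_corrected_equals_uncorrected(self):
        burdens = np.array([5.0, 1.0, 9.0, 3.0, 7.0, 2.0])
        out = fp.tertile_recategorization(burdens, burdens.copy())
        assert out["n_recategorized"] == 0
        np.testing.assert_array_equal(out["labels_before"], out["labels_after"])

    def test_known_recategorization_matches_brute_force(self):
        unc = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        corr = unc.copy()
        corr[3] = 2.5   # mid -> low
        corr[8] = 5.5   # high -> mid
        out = fp.tertile_recategorization(unc, corr)
        # independent re-scoring
        b_low, b_mid = 3.0, 6.0
        moved = 0
        for before, c in zip(out["labels_before"], corr):
            after = 0 if c <= b_low else (1 if c <= b_mid else 2)
            moved += after < before
        assert out["boundaries"] == (b_low, b_mid)
        assert out["n_recategorized"] == moved == 2
        assert out["moved_down"] == {0: 7, 1: 2, 2: 0}

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            fp.tertile_recategorization([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_identical_series(self):
        a = np.array([1.0, 2.0, 3.0])
        out = fp.bland_altman(a, a.copy())
        assert out.bias == 0 and out.loa_lower == 0 and out.loa_upper == 0
        assert out.r_defined and out.pearson_r == pytest.approx(1.0)

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0])
        out = fp.bland_altman(a + 1, a)
        assert out.bias == pytest.approx(1.0)
        assert out.sd_diff == 0.0

    def test_constant_series_correlation_flagged(self):
        out = fp.bland_altman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not out.r_defined and math.isnan(out.pearson_r)

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(21)
        a = rng.normal(10, 2, 40)
        b = a + rng.normal(0.5, 1.0, 40)
        out = fp.bland_altman(a, b)
        d = a - b
        bias = sum(d) / len(d)
        sd = math.sqrt(sum((x - bias) ** 2 for x in d) / (len(d) - 1))
        am, bm = sum(a) / len(a), sum(b) / len(b)
        r = sum((x - am) * (y - bm) for x, y in zip(a, b)) / math.sqrt(
            sum((x - am) ** 2 for x in a) * sum((y - bm) ** 2 for y in b)
        )
        assert out.bias == pytest.approx(bias, rel=1e-12)
        assert out.loa_lower == pytest.approx(bias - 1.96 * sd, rel=1e-12)
        assert out.loa_upper == pytest.approx(bias + 1.96 * sd, rel=1e-12)
        assert out.pearson_r == pytest.approx(r, rel=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fp.bland_altman([1.0], [2.0])
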
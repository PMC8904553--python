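"""Feature mapping: threshold filter, maxima, amplitude factor, distortion,
axial shift, RMSE and the assembled 18-slot row."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fpscreen import (
    CavityModel,
    DegenerateInputError,
    IncompatibleDomainError,
    Interferogram,
    amplitude_factor,
    axial_shift,
    distortion,
    extract_features,
    filter_by_threshold,
    find_local_maxima,
    maxima_distance_stats,
    rmse,
    theoretical_interferogram,
)
from fpscreen.features import FEATURE_NAMES


def make(power, lo=1530.0, hi=None):
    power = np.asarray(power, dtype=float)
    hi = lo + len(power) - 1 if hi is None else hi
    return Interferogram(wavelength=np.linspace(lo, hi, len(power)), power=power)


def oracle_maxima(power):
    """Independent run-based scan: an interior run of equal values is a
    maximum iff both adjacent runs are lower; report its leftmost index."""
    idx = []
    i = 0
    n = len(power)
    while i < n:
        j = i
        while j + 1 < n and power[j + 1] == power[i]:
            j += 1
        if i > 0 and j < n - 1 and power[i - 1] < power[i] and power[j + 1] < power[i]:
            idx.append(i)
        i = j + 1
    return idx


class TestThresholdFilter:
    def test_zero_threshold_keeps_everything(self):
        s = make([0.2, 1.0, -0.1, 0.5])
        f = filter_by_threshold(s, 0.0)
        assert f.retained.all()
        assert f.global_max == 1.0

    def test_five_percent_of_peak_two(self):
        s = make([0.05, 2.0, 0.11, 0.09, 1.5])
        f = filter_by_threshold(s, 0.05)  # cutoff 0.1
        assert list(f.retained) == [False, True, True, False, True]
        assert f.global_max == 2.0  # global maximum unchanged

    def test_two_level_signal(self):
        f = filter_by_threshold(make([0.2, 1.0, 0.2, 1.0]), 0.5)
        assert list(f.retained) == [False, True, False, True]

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            filter_by_threshold(make([0.0, 0.0, 0.0]), 0.05)

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            filter_by_threshold(make([1.0, 2.0]), 1.0)


class TestLocalMaxima:
    def test_monotone_signal_has_none(self):
        assert find_local_maxima(make([1.0, 2.0, 3.0, 4.0])) == []

    def test_hand_enumeration(self):
        s = make([0.0, 1.0, 0.0, 2.0, 0.0])
        maxima = find_local_maxima(s)
        assert [p for _, p in maxima] == [1.0, 2.0]
        assert maxima[0][0] == s.wavelength[1] and maxima[1][0] == s.wavelength[3]

    def test_plateau_reported_once_leftmost(self):
        s = make([0.0, 1.0, 1.0, 1.0, 0.0])
        maxima = find_local_maxima(s)
        assert len(maxima) == 1
        assert maxima[0][0] == s.wavelength[1]

    def test_fewer_than_three_samples(self):
        assert find_local_maxima(make([1.0, 2.0])) == []

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 5), min_size=1, max_size=50))
    def test_matches_exhaustive_scan(self, values):
        power = np.asarray(values, dtype=float)
        s = make(power + 1.0)  # keep strictly positive so nothing is filtered
        detected = [w for w, _ in find_local_maxima(s)]
        expected = [s.wavelength[i] for i in oracle_maxima(power)]
        assert detected == expected


class TestDistanceStats:
    def test_hand_arithmetic(self):
        stats = maxima_distance_stats([(1540.0, 1.0), (1543.0, 1.0), (1549.0, 1.0)])
        assert stats == (4.5, 6.0, 3.0, 4.5)

    def test_sentinel_for_single_maximum(self):
        assert maxima_distance_stats([(1550.0, 2.0)]) == (0.0, 0.0, 0.0, 0.0)
        assert maxima_distance_stats([]) == (0.0, 0.0, 0.0, 0.0)

    def test_noiseless_fringe_spacing(self, noiseless_model):
        t = theoretical_interferogram(noiseless_model)
        maxima = find_local_maxima(filter_by_threshold(t, 0.05))
        f5 = maxima_distance_stats(maxima)[0]
        assert f5 == pytest.approx(3.30, abs=0.02)  # adjacent orders 2nl/m


class TestAmplitudeFactor:
    def test_identical_signals(self):
        s = make([0.5, 2.0, 0.5])
        assert amplitude_factor(s, s) == 1.0

    def test_forced_arithmetic(self):
        exp = make([0.001, 0.004])
        sim = make([1.0, 2.0])
        assert amplitude_factor(exp, sim) == pytest.approx(500.0)

    def test_half_scale(self):
        sim = make([0.5, 2.0, 0.5])
        exp = make(0.5 * sim.power)
        assert amplitude_factor(exp, sim) == pytest.approx(2.0)

    def test_zero_maximum_rejected(self):
        with pytest.raises(DegenerateInputError):
            amplitude_factor(make([0.0, -1.0]), make([1.0, 2.0]))


class TestDistortion:
    def test_zero_numerator_case(self):
        # constant exp of area 2 with f = 0.5 -> area_exp * f = 1 -> D = 0
        exp = make([0.5, 0.5, 0.5], lo=1530.0, hi=1534.0)
        sim = make([1.0, 1.0, 1.0], lo=1530.0, hi=1534.0)
        assert distortion(exp, sim, f=0.5) == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic(self):
        # area_exp = 2, f = 0.25, area_sym = 4 -> D = |1 - 0.5| / 4 = 0.125
        exp = make([0.5, 0.5, 0.5], lo=1530.0, hi=1534.0)
        sim = make([1.0, 1.0, 1.0], lo=1530.0, hi=1534.0)
        assert distortion(exp, sim, f=0.25) == pytest.approx(0.125)

    def test_simpson_area_of_fringes_over_whole_periods(self):
        # window spanning fringe orders 475..465 of 2nl = 728000 nm: ten whole
        # periods, closed-form area = window width (adaptive-quadrature oracle
        # deviates by 7e-7 relative)
        lo, hi = 728000.0 / 475, 728000.0 / 465
        grid = np.linspace(lo, hi, 2001)
        model = CavityModel(
            refractive_index=1.30, center_wavelength_nm=(lo + hi) / 2,
            wavelength_grid=grid,
        )
        t = theoretical_interferogram(model)
        width = hi - lo
        sim = Interferogram(wavelength=grid, power=np.ones_like(grid))
        # D = |1 - area_T / width| / width isolates the Simpson area of T
        d = distortion(t, sim, f=1.0 / width)
        assert d * width == pytest.approx(0.0, abs=1e-4)

    def test_disjoint_windows_rejected(self):
        with pytest.raises(IncompatibleDomainError):
            distortion(make([1.0, 1.0], lo=1530, hi=1531),
                       make([1.0, 1.0], lo=1540, hi=1541), f=1.0)


class TestAxialShift:
    def test_identical_signals(self):
        s = make([0.0, 1.0, 0.0])
        assert axial_shift(s, s) == 0.0

    def test_constructed_shift(self):
        grid = np.arange(1530.0, 1540.0, 0.5)
        sim = Interferogram(wavelength=grid, power=np.exp(-((grid - 1534.0) ** 2)))
        exp = Interferogram(wavelength=grid, power=np.exp(-((grid - 1535.5) ** 2)))
        assert axial_shift(exp, sim) == pytest.approx(1.5)
        assert axial_shift(sim, exp) == pytest.approx(-1.5)

    def test_tie_broken_to_lowest_wavelength(self):
        s = make([0.0, 2.0, 0.0, 2.0, 0.0])
        ref = make([2.0, 0.0, 0.0, 0.0, 0.0])
        assert axial_shift(s, ref) == s.wavelength[1] - ref.wavelength[0]


class TestRMSE:
    def test_identical(self):
        s = make([0.3, 1.7, 0.5])
        assert rmse(s, s, f=1.0) == 0.0

    def test_constant_offset(self):
        a = make([1.0, 1.0, 1.0, 1.0, 1.0])
        b = make([1.3, 1.3, 1.3, 1.3, 1.3])
        assert rmse(a, b, f=1.0) == pytest.approx(0.3)

    def test_alternating_sequences(self):
        a = make([0.0, 1.0, 0.0, 1.0])
        b = make([1.0, 0.0, 1.0, 0.0])
        assert rmse(a, b, f=1.0) == pytest.approx(1.0)


class TestExtractFeatures:
    def test_self_comparison(self, noiseless_model):
        t = theoretical_interferogram(noiseless_model)
        row = extract_features(t, noiseless_model)
        assert row["F4"] == pytest.approx(1.0)
        assert row["F10"] == 0.0
        assert row["F11"] == pytest.approx(0.0, abs=1e-9)
        # literal printed distortion of a self-comparison: |1 - A| / A with A
        # the Simpson area of the fringe signal (trapezoid oracle)
        area = np.trapezoid(t.power, t.wavelength)
        assert row["F9"] == pytest.approx(abs(1 - area) / area, rel=1e-3)

    def test_row_has_18_slots(self, noiseless_model):
        t = theoretical_interferogram(noiseless_model)
        row = extract_features(t, noiseless_model)
        assert tuple(row) == FEATURE_NAMES
        assert np.isnan(row["F18"])  # target unset at extraction time

    def test_default_grid_window(self, noiseless_model):
        t = theoretical_interferogram(noiseless_model)
        row = extract_features(t, noiseless_model)
        assert (row["F13"], row["F14"]) == (1530.0, 1570.0)
        assert row["F14"] - row["F13"] == 40.0
        assert row["F13"] <= row["F16"] <= row["F14"]

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_scale_invariance(self, noiseless_model, c):
        """Rescaling the experimental power leaves the geometry features
        unchanged, scales F2/F15 by c and F4 by 1/c."""
        from fpscreen import synthetic_interferogram

        model = CavityModel(refractive_index=1.42, noise_sd=0.0)
        s = synthetic_interferogram(model, seed=0)
        scaled = Interferogram(wavelength=s.wavelength, power=c * s.power)
        r1 = extract_features(s, model)
        r2 = extract_features(scaled, model)
        for key in ("F1", "F5", "F6", "F7", "F8", "F10", "F13", "F14", "F16", "F17"):
            assert r2[key] == pytest.approx(r1[key]), key
        assert r2["F2"] == pytest.approx(c * r1["F2"])
        assert r2["F15"] == pytest.approx(c * r1["F15"])
        assert r2["F4"] == pytest.approx(r1["F4"] / c)
        # f times the global maximum recovers ssmax (the reference grid
        # maximum, marginally below the analytic peak of 2) exactly
        ssmax = theoretical_interferogram(model).power.max()
        assert r2["F4"] * r2["F2"] == pytest.approx(ssmax, rel=1e-12)

    def test_pure_function(self, noiseless_model):
        t = theoretical_interferogram(noiseless_model)
        r1 = extract_features(t, noiseless_model)
        r2 = extract_features(t, noiseless_model)
        assert np.isnan(r1.pop("F18")) and np.isnan(r2.pop("F18"))
        assert r1 == r2

    def test_fringe_count_matches_analytic_for_panel(self):
        from fpscreen import analytic_maxima

        for n in (1.30, 1.38, 1.44, 1.50):
            model = CavityModel(refractive_index=n, noise_sd=0.0)
            t = theoretical_interferogram(model)
            row = extract_features(t, model)
            assert row["F1"] == len(analytic_maxima(model, 1530.0, 1570.0))
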
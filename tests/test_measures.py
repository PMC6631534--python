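"""Fold-change, moment-based duration/timing measures, AUC and peak detection."""

import numpy as np
import pytest

import nfkb_btrcp as nb
from nfkb_btrcp.measures import MeasureError, signal_duration_variance
from nfkb_btrcp.synthetic import SyntheticSignalSpec, generate_signal


def erf_step(center=200.0, width=30.0, amplitude=50.0, offset=1.0, dt=0.1):
    """Signal whose |derivative| is a Gaussian bump: duration/timing known."""
    return generate_signal(SyntheticSignalSpec(
        family="gaussian-bump-derivative", t_final=630.0, dt=dt,
        amplitude=amplitude, offset=offset, center=center, width=width))


class TestFoldChange:
    def test_constant_signal_gives_one(self):
        t, y = generate_signal(SyntheticSignalSpec(family="constant", offset=3.0))
        assert nb.fold_change(t, y) == 1.0

    def test_equals_brute_force_scan(self):
        t, y = erf_step()
        window = nb.MeasureWindow(0.0, 630.0)
        assert nb.fold_change(t, y, window) == pytest.approx(
            max(y) / y[0], rel=0, abs=0)

    def test_nonpositive_initial_value_rejected(self):
        t, y = generate_signal(SyntheticSignalSpec(family="sinusoid",
                                                   offset=0.0))
        assert y[0] == 0.0
        with pytest.raises(MeasureError, match="initial value"):
            nb.fold_change(t, y)

    def test_window_restricts_the_maximum(self):
        t, y = erf_step(center=200.0)
        early = nb.fold_change(t, y, nb.MeasureWindow(0.0, 50.0))
        # only the far Gaussian tail grows inside [0, 50] min
        assert early == pytest.approx(1.0, rel=1e-4)
        assert early < nb.fold_change(t, y)


class TestSignalDuration:
    def test_gaussian_weight_recovers_width(self):
        """|derivative| Gaussian with σ = 30 min ⇒ duration 30 min (±1%)."""
        t, y = erf_step(width=30.0)
        assert nb.signal_duration(t, y) == pytest.approx(30.0, rel=1e-2)

    def test_variance_form_is_square_of_duration(self):
        t, y = erf_step()
        assert signal_duration_variance(t, y) == pytest.approx(
            nb.signal_duration(t, y) ** 2, rel=1e-12)

    def test_time_shift_invariance(self):
        t, y = erf_step(center=150.0)
        t2, y2 = erf_step(center=350.0)
        d1 = nb.signal_duration(t, y)
        d2 = nb.signal_duration(t2, y2)
        assert d2 == pytest.approx(d1, rel=1e-4)

    def test_constant_signal_is_undefined_not_zero(self):
        t, y = generate_signal(SyntheticSignalSpec(family="constant", offset=2.0))
        with pytest.raises(MeasureError, match="zero total variation"):
            nb.signal_duration(t, y)

    def test_discrete_moment_oracle_equivalence(self, traj_b001):
        """Pipeline moments equal direct discrete sums on the same samples."""
        t, y = traj_b001.t_min, traj_b001.nuclear_nfkb()
        w = np.abs(np.gradient(y, t))
        m0 = np.trapezoid(w, t)
        m1 = np.trapezoid(w * t, t) / m0
        m2 = np.trapezoid(w * t ** 2, t) / m0
        assert nb.signaling_time(t, y) == pytest.approx(m1, rel=1e-4)
        assert nb.signal_duration(t, y) == pytest.approx(
            np.sqrt(m2 - m1 ** 2), rel=1e-4)


class TestSignalingTime:
    def test_gaussian_weight_recovers_center(self):
        t, y = erf_step(center=200.0)
        assert nb.signaling_time(t, y) == pytest.approx(200.0, rel=1e-2)

    def test_step_like_rise_localizes_weight(self):
        """A sharp rise at ~45 min carries essentially all the weight."""
        t, y = erf_step(center=45.0, width=1.0)
        assert nb.signaling_time(t, y) == pytest.approx(45.0, abs=0.5)

    def test_shift_equivariance(self):
        t1, y1 = erf_step(center=150.0)
        t2, y2 = erf_step(center=250.0)
        shift = nb.signaling_time(t2, y2) - nb.signaling_time(t1, y1)
        assert shift == pytest.approx(100.0, abs=1e-3)


class TestAreaUnderCurve:
    def test_constant_signal_baselines(self):
        t, y = generate_signal(SyntheticSignalSpec(
            family="constant", offset=3.0, t_final=100.0))
        assert nb.area_under_curve(t, y, baseline="initial") == 0.0
        assert nb.area_under_curve(t, y, baseline="zero") == pytest.approx(300.0)

    def test_matches_analytic_oracle_on_smooth_signal(self):
        """Trapezoid vs the closed-form integral of the erf step (zero base).

        ∫ offset + A·Φ((t−µ)/σ) dt has an exact expression; at dt = 0.1 min
        the trapezoid rule must agree to 1e-6 relative.
        """
        from scipy.special import erf as sp_erf

        A, mu, sig, off, T = 50.0, 200.0, 30.0, 1.0, 630.0
        t, y = erf_step(center=mu, width=sig, amplitude=A, offset=off, dt=0.1)

        def antideriv(x):
            z = (x - mu) / (sig * np.sqrt(2.0))
            return off * x + A * 0.5 * (
                x + (x - mu) * sp_erf(z)
                + sig * np.sqrt(2.0 / np.pi) * np.exp(-z * z))

        exact = antideriv(T) - antideriv(0.0)
        got = nb.area_under_curve(t, y, baseline="zero")
        assert got == pytest.approx(exact, rel=1e-6)

    def test_refinement_consistency_on_trajectory(self, params, traj_b001):
        """Trapezoid on the 0.5-min grid vs a 10× finer re-integration."""
        coarse = nb.area_under_curve(traj_b001.t_min, traj_b001.nuclear_nfkb())
        fine_traj = nb.stimulated_response(
            params, nb.Stimulus(tnf=1, btrcp_nM=1e-2), dt_out_min=0.05)
        fine = nb.area_under_curve(fine_traj.t_min, fine_traj.nuclear_nfkb())
        assert coarse == pytest.approx(fine, rel=1e-4)


class TestDetectPeaks:
    def test_sine_peak_count_equals_periods(self):
        t, y = generate_signal(SyntheticSignalSpec(
            family="sinusoid", period=100.0, t_final=500.0, dt=0.1, offset=2.0))
        peaks = nb.detect_peaks(t, y)
        assert len(peaks) == 5

    def test_prominence_sweep_isolates_principal_peak(self, traj_b1):
        t, y = traj_b1.t_min, traj_b1.nuclear_nfkb()
        all_peaks = nb.detect_peaks(t, y)
        minor = [h for _, h in all_peaks[1:]]
        high = nb.detect_peaks(t, y, min_prominence=max(minor) + 1.0)
        assert len(high) == 1
        assert high[0][1] == pytest.approx(all_peaks[0][1])

    def test_peaks_ordered_by_time_with_decreasing_heights(self, traj_b1):
        peaks = nb.detect_peaks(traj_b1.t_min, traj_b1.nuclear_nfkb())
        times = [p[0] for p in peaks]
        heights = [p[1] for p in peaks]
        assert times == sorted(times)
        assert all(a > b for a, b in zip(heights, heights[1:]))


class TestMeasureReport:
    def test_resampling_half_grid_consistency(self, traj_b001):
        """All measures agree within 0.5% on the full and half-density grids."""
        full = nb.measure_report(traj_b001)
        half = nb.Trajectory(traj_b001.t_min[::2], traj_b001.data.iloc[::2],
                             traj_b001.stimulus, traj_b001.params)
        coarse = nb.measure_report(half)
        for name in ("fold_change", "signal_duration", "signaling_time",
                     "auc", "first_peak_height", "first_peak_time"):
            assert getattr(coarse, name) == pytest.approx(
                getattr(full, name), rel=5e-3)
        assert coarse.n_peaks == full.n_peaks

    def test_amplitude_conventions_both_reported(self, traj_b1):
        rep = nb.measure_report(traj_b1)
        assert rep.first_peak_amplitude == pytest.approx(
            rep.first_peak_height - traj_b1.nuclear_nfkb()[0])


@pytest.fixture(scope="module")
def scan(params):
    grid = np.logspace(np.log10(5e-5), np.log10(2.0), 16)
    long = nb.btrcp_scan(params, grid)
    return long.pivot(index="btrcp_nM", columns="measure", values="value")


class TestBtrcpScan:

    def test_fold_change_monotone_nondecreasing(self, scan):
        assert np.all(np.diff(scan["fold_change"].to_numpy()) >= -1e-9)

    def test_signal_duration_biphasic_with_interior_maximum(self, scan):
        dur = scan["signal_duration"].to_numpy()
        k = int(np.argmax(dur))
        assert 0 < k < dur.size - 1
        assert np.all(np.diff(dur[: k + 1]) > 0)
        assert np.all(np.diff(dur[k:]) < 0)
        assert scan.index[k] == pytest.approx(1e-2, rel=0.7)

    def test_signaling_time_biphasic_like_duration(self, scan):
        st = scan["signaling_time"].to_numpy()
        k = int(np.argmax(st))
        assert 0 < k < st.size - 1

    def test_auc_and_amplitude_increase_with_btrcp(self, scan):
        assert scan["auc"].iloc[-1] > scan["auc"].iloc[0]
        amp = scan["first_peak_amplitude"].to_numpy()
        assert np.all(np.diff(amp) >= -1e-9)
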
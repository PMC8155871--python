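"""Force-distance parsing, smoothing, event detection and parameter extraction."""

import numpy as np
import pandas as pd
import pytest

from seedstage.texture import (
    CurveError,
    ForceDistanceCurve,
    NoBreakError,
    detect_break,
    detect_peaks,
    elasticity,
    integrate_energy,
    read_curve,
    smooth_curve,
    texture_profile,
)


def _curve(d, f, **kw):
    return ForceDistanceCurve(np.asarray(d, float), np.asarray(f, float), **kw)


class TestReadCurve:
    def test_distance_force_columns_preserved(self, tmp_path):
        p = tmp_path / "c.csv"
        d = np.arange(12) * 0.01
        f = np.linspace(1, 12, 12)
        pd.DataFrame({"distance_mm": d, "force_N": f}).to_csv(p, index=False)
        curve = read_curve(p)
        assert len(curve) == 12
        np.testing.assert_allclose(np.diff(curve.distance), 0.01)

    def test_time_mode_spacing_at_acquisition_settings(self, tmp_path):
        p = tmp_path / "t.csv"
        t = np.arange(20) / 500.0  # 500 samples/s
        f = np.linspace(1, 20, 20)
        pd.DataFrame({"time_s": t, "force_N": f}).to_csv(p, index=False)
        curve = read_curve(p, probe_speed=1.0)
        np.testing.assert_allclose(np.diff(curve.distance), 0.002, atol=1e-12)

    def test_trigger_trimming_rezeroes_distance(self, tmp_path):
        p = tmp_path / "trig.csv"
        d = np.arange(20) * 0.002
        f = np.concatenate([np.full(5, 0.01), np.linspace(0.06, 30, 15)])
        pd.DataFrame({"distance_mm": d, "force_N": f}).to_csv(p, index=False)
        curve = read_curve(p)
        assert curve.distance[0] == 0.0
        assert len(curve) == 15
        assert curve.force[0] >= curve.activation_force

    def test_retract_tail_truncated(self, tmp_path):
        p = tmp_path / "r.csv"
        d = np.concatenate([np.arange(15) * 0.002, np.arange(14, 0, -1) * 0.002])
        f = np.concatenate([np.linspace(1, 15, 15), np.zeros(14)])
        pd.DataFrame({"distance_mm": d, "force_N": f}).to_csv(p, index=False)
        assert len(read_curve(p)) == 15

    def test_single_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"force_N": [1, 2, 3]}).to_csv(p, index=False)
        with pytest.raises(CurveError):
            read_curve(p)

    def test_too_short_after_trimming_rejected(self, tmp_path):
        p = tmp_path / "short.csv"
        pd.DataFrame({"distance_mm": [0, 0.1, 0.2], "force_N": [1.0, 2.0, 3.0]}).to_csv(
            p, index=False
        )
        with pytest.raises(CurveError):
            read_curve(p)


class TestSmoothCurve:
    def test_window_one_is_identity(self):
        c = _curve(np.arange(20) * 0.01, np.sin(np.arange(20)))
        np.testing.assert_array_equal(smooth_curve(c, 1).force, c.force)

    def test_constant_force_unchanged(self):
        c = _curve(np.arange(30) * 0.01, np.full(30, 7.0))
        np.testing.assert_allclose(smooth_curve(c, 7).force, 7.0)

    def test_spike_attenuated_by_window_factor(self):
        n, w = 101, 5
        f = np.zeros(n)
        f[50] = 10.0
        c = _curve(np.arange(n) * 0.01, f)
        sm = smooth_curve(c, w).force
        # closed form: an isolated unit impulse becomes a w-wide plateau at 1/w
        assert sm.max() == pytest.approx(10.0 / w)

    def test_oversized_window_rejected(self):
        c = _curve(np.arange(5) * 0.01, np.ones(5))
        with pytest.raises(CurveError):
            smooth_curve(c, 7)
        with pytest.raises(CurveError):
            smooth_curve(c, 4)  # even


def _bumpy_curve(n_bumps=4, prominence=10.0):
    """Flat baseline at 20 N with triangular bumps of the given prominence."""
    d = np.arange(0, 2.0, 0.002)
    f = np.full(d.size, 20.0)
    centers = np.linspace(0.3, 1.7, n_bumps)
    for c in centers:
        tri = prominence * np.clip(1 - np.abs(d - c) / 0.05, 0, 1)
        f = np.maximum(f, 20.0 + tri)
    return _curve(d, f)


class TestDetectPeaks:
    def test_monotone_curve_has_no_interior_peaks(self):
        c = _curve(np.arange(50) * 0.002, np.linspace(1, 60, 50))
        assert detect_peaks(c, 1.0).size == 0

    def test_bumps_counted_at_low_threshold(self):
        assert detect_peaks(_bumpy_curve(4, 10.0), 1.0).size == 4

    def test_high_threshold_prunes_peaks(self):
        assert detect_peaks(_bumpy_curve(4, 10.0), 20.0).size < 4

    def test_threshold_monotonicity(self):
        c = _bumpy_curve(5, 12.0)
        counts = [detect_peaks(c, p).size for p in (0.5, 2, 5, 11, 13, 30)]
        assert counts == sorted(counts, reverse=True)


def _break_curve():
    """Rise to 60 N at 0.55 mm, collapse to 38 N, then climb to 1.6 mm."""
    knots_d = [0.0, 0.55, 0.59, 0.70, 1.6]
    knots_f = [0.5, 60.0, 38.0, 39.0, 65.0]
    d = np.arange(0, 1.6 + 1e-9, 0.002)
    return _curve(d, np.interp(d, knots_d, knots_f))


class TestDetectBreak:
    def test_monotone_increasing_curve_has_no_break(self):
        c = _curve(np.arange(100) * 0.002, np.linspace(0.5, 80, 100))
        with pytest.raises(NoBreakError):
            detect_break(c, detect_peaks(c, 1.0))

    def test_break_located_at_generated_drop(self):
        c = _break_curve()
        ev = detect_break(c, detect_peaks(c, 1.0))
        assert ev.distance == pytest.approx(0.55, abs=0.002)
        assert ev.force_before == pytest.approx(60.0, abs=0.5)
        assert ev.drop == pytest.approx(22.0, abs=0.5)

    def test_small_dip_skipped_for_major_drop(self):
        # 5% dip at 0.3 mm, then a 50% collapse at 0.6 mm
        knots_d = [0.0, 0.30, 0.34, 0.60, 0.66, 0.80, 1.2]
        knots_f = [0.5, 40.0, 38.0, 62.0, 31.0, 33.0, 70.0]
        d = np.arange(0, 1.2 + 1e-9, 0.002)
        c = _curve(d, np.interp(d, knots_d, knots_f))
        ev = detect_break(c, detect_peaks(c, 1.0), drop_fraction=0.2)
        assert ev.distance == pytest.approx(0.60, abs=0.004)


class TestElasticity:
    def test_exact_line_through_origin(self):
        d = np.arange(0, 0.5 + 1e-9, 0.002)
        c = _curve(d, 100.0 * d)
        ev_idx = len(d) - 1
        from seedstage.texture import BreakEvent

        ev = BreakEvent(ev_idx, d[-1], float(c.force[-1]), 0.0)
        assert elasticity(c, ev) == pytest.approx(100.0)

    def test_intercept_absorbed(self):
        d = np.arange(0, 0.5 + 1e-9, 0.002)
        c = _curve(d, 100.0 * d + 5.0)
        from seedstage.texture import BreakEvent

        ev = BreakEvent(len(d) - 1, d[-1], float(c.force[-1]), 0.0)
        assert elasticity(c, ev) == pytest.approx(100.0)

    def test_noisy_slope_recovered_within_two_percent(self):
        rng = np.random.default_rng(5)
        d = np.arange(0, 0.6 + 1e-9, 0.002)
        c = _curve(d, 98.0 * d + rng.normal(0, 1.0, d.size))
        from seedstage.texture import BreakEvent

        ev = BreakEvent(len(d) - 1, d[-1], float(c.force[-1]), 0.0)
        assert elasticity(c, ev) == pytest.approx(98.0, rel=0.02)

    def test_break_below_floor_rejected(self):
        d = np.arange(0, 0.1 + 1e-9, 0.002)
        c = _curve(d, 50.0 * d)  # peaks at 5 N < 10 N floor
        from seedstage.texture import BreakEvent

        ev = BreakEvent(len(d) - 1, d[-1], float(c.force[-1]), 0.0)
        with pytest.raises(CurveError):
            elasticity(c, ev)


class TestIntegrateEnergy:
    def test_triangle_area(self):
        d = np.arange(0, 0.5 + 1e-9, 0.002)
        c = _curve(d, 120.0 * d)  # rises to 60 N at 0.5 mm
        assert integrate_energy(c, 0, len(d) - 1) == pytest.approx(15.0, abs=1e-9)

    def test_zero_force(self):
        c = _curve(np.arange(20) * 0.002, np.zeros(20))
        assert integrate_energy(c, 0, 19) == 0.0

    def test_piecewise_linear_matches_closed_form(self):
        kd = np.array([0.0, 0.4, 0.5, 1.0])
        kf = np.array([0.0, 50.0, 30.0, 80.0])
        d = np.arange(0, 1.0 + 1e-9, 0.002)
        c = _curve(d, np.interp(d, kd, kf))
        want = np.trapezoid(kf, kd)
        assert integrate_energy(c, 0, len(d) - 1) == pytest.approx(want, abs=1e-9)

    def test_reversed_indices_rejected(self):
        c = _curve(np.arange(20) * 0.002, np.ones(20))
        with pytest.raises(CurveError):
            integrate_energy(c, 10, 3)


class TestTextureProfile:
    def test_handmade_curve_recovers_known_parameters(self):
        # Np=4, Bf=60 at Bd=0.55, Th=3.2 (travel 1.6 mm)
        knots_d = [0.0, 0.55, 0.59, 0.70, 0.90, 1.00, 1.20, 1.30, 1.50, 1.6]
        knots_f = [0.5, 60.0, 38.0, 39.0, 50.0, 42.0, 53.0, 45.0, 57.0, 52.0]
        d = np.arange(0, 1.6 + 1e-9, 0.002)
        c = _curve(d, np.interp(d, knots_d, knots_f))
        p = texture_profile(c)
        assert p.Np == 4
        assert p.Bf == pytest.approx(60.0, abs=0.25)
        assert p.Bd == pytest.approx(0.55, abs=0.002)
        assert p.Th == pytest.approx(3.2)
        assert p.Si == pytest.approx(0.55 / 3.2, abs=1e-3)
        assert p.Si == pytest.approx(0.171875, abs=1e-3)

    def test_identities_and_bounds_on_generated_cohort(self, default_spec):
        from seedstage.synth import generate_curve

        rng = np.random.default_rng(12)
        for i in range(20):
            curve, _ = generate_curve(default_spec, i % 5 + 1, rng=rng)
            p = texture_profile(curve)
            assert p.Si == pytest.approx(p.Bd / p.Th, abs=1e-9)
            assert p.Ar == pytest.approx(p.Be / p.De, abs=1e-9)
            assert p.Bd <= p.Th / 2
            assert 0 < p.Ar <= 1 and p.Be <= p.De
            assert p.Bdc <= p.Bf
            assert p.Np >= 1

    def test_monotone_curve_yields_no_profile(self):
        d = np.arange(0, 1.0 + 1e-9, 0.002)
        c = _curve(d, 80.0 * d + 0.5)
        with pytest.raises(NoBreakError):
            texture_profile(c)
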
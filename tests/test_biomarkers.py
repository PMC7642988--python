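"""Biomarker extraction and proarrhythmia event detection, validated on
waveforms with analytically known geometry and labels."""

import numpy as np
import pytest

from cardiopop import biomarkers as bm
from cardiopop.synthetic import SyntheticAPSpec, gen_ap_trace


def _beat(**kw):
    spec = SyntheticAPSpec(n_beats=1, **kw)
    t, v, cai, labels = gen_ap_trace(spec)
    return t, v[0], cai[0], labels, spec


class TestAPD:
    def test_analytic_value_on_piecewise_linear_wave(self):
        # closed form: the plateau sags 15% of the amplitude, then a linear
        # ramp of ramp_ms returns to rest; APD90 follows from similar triangles
        t, v, _, _, spec = _beat(rest_mV=-85.0, peak_mV=40.0, plateau_ms=200.0,
                                 ramp_ms=100.0, dt_ms=0.1)
        amp = spec.peak_mV - spec.rest_mV
        v_end_plateau = spec.peak_mV - 0.15 * amp
        v90 = spec.peak_mV - 0.9 * amp
        t_cross = spec.plateau_ms + spec.ramp_ms * (v_end_plateau - v90) / (
            v_end_plateau - spec.rest_mV)
        apd = bm.apd(t, v)
        assert apd == pytest.approx(t_cross, abs=1.5)  # minus upstroke time

    def test_levels_are_ordered(self):
        t, v, _, _, _ = _beat()
        assert bm.apd(t, v, level=50.0) < bm.apd(t, v, level=90.0)

    def test_missing_crossing_returns_nan(self):
        t, v, _, _, _ = _beat(rf=True)
        assert np.isnan(bm.apd(t, v))

    def test_no_upstroke_raises(self):
        t = np.arange(0, 500, 0.5)
        with pytest.raises(ValueError, match="upstroke"):
            bm.apd(t, np.full_like(t, -85.0))

    def test_level_bounds(self):
        t, v, _, _, _ = _beat()
        with pytest.raises(ValueError):
            bm.apd(t, v, level=120.0)


def test_rmp_is_prestimulus_sample():
    t = np.arange(0, 100, 0.5)
    assert bm.rmp(t, np.full_like(t, -87.0)) == -87.0


class TestEAD:
    def test_injected_bump_detected_with_amplitude(self):
        t, v, _, _, _ = _beat(ead_bump=(180.0, 15.0, 30.0))
        flag, when, amp = bm.detect_ead(t, v)
        assert flag
        # the bump rides on the sagging plateau, so the measured rise is a
        # little below the injected 15 mV
        assert 8.0 < amp <= 16.0
        assert 150.0 < when < 250.0

    def test_amplitude_exact_on_flat_plateau(self):
        # spike to +40, flat plateau at 0 mV, 15 mV bump at 200 ms
        t = np.arange(0.0, 500.0, 0.25)
        v = np.where(t < 1.0, -85.0 + 125.0 * t, 40.0)
        v = np.where(t >= 10.0, 0.0, v)
        v = np.where(t >= 300.0, -85.0, v)
        v = v + 15.0 * np.exp(-0.5 * ((t - 200.0) / 12.0) ** 2)
        flag, when, amp = bm.detect_ead(t, v)
        assert flag
        assert amp == pytest.approx(15.0, abs=0.2)
        assert when == pytest.approx(200.0, abs=2.0)

    def test_monotone_repolarization_is_negative(self):
        t, v, _, _, _ = _beat()
        assert not bm.detect_ead(t, v)[0]

    def test_phase1_notch_and_dome_not_flagged(self):
        # a legitimate early notch/dome within the search blanking window
        t, v, _, _, _ = _beat()
        notch = 12.0 * np.exp(-0.5 * ((t - 30.0) / 8.0) ** 2)
        assert not bm.detect_ead(t, v - notch)[0]


class TestRF:
    def test_clamped_plateau_flagged(self):
        t, v, _, _, _ = _beat(rf=True)
        assert bm.detect_rf(t, v)

    def test_normal_beat_not_flagged(self):
        t, v, _, _, _ = _beat()
        assert not bm.detect_rf(t, v)

    def test_degenerate_threshold_always_true(self):
        t, v, _, _, _ = _beat()
        assert bm.detect_rf(t, v, v_threshold=-200.0)


class TestAlternans:
    @pytest.mark.parametrize(
        "apds, expected",
        [
            ([200, 240, 201, 239], True),
            ([220, 221, 220, 221], False),
            ([200, 240, 238, 200], False),
        ],
    )
    def test_examples(self, apds, expected):
        assert bm.detect_alternans(apds, tol_ms=5.0) is expected

    def test_needs_four_beats(self):
        with pytest.raises(ValueError, match=">= 4"):
            bm.detect_alternans([200, 240, 200])


class TestPercentChange:
    def test_arithmetic(self):
        assert bm.percent_change(333.0, 233.0) == pytest.approx(42.9, abs=0.05)
        assert bm.percent_change(5.0, 5.0) == 0.0

    def test_paper_style_consistency(self):
        # a 164 ms reduction on a 410 ms baseline is a 40% change
        assert bm.percent_change(410.0 - 164.0, 410.0) == pytest.approx(-40.0, abs=0.1)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            bm.percent_change(1.0, 0.0)


def test_detectors_perfect_on_labeled_corpus():
    """Sensitivity and specificity are both 1.0 over 1,000 seeded parametric
    traces whose event amplitudes are at least twice the detector
    thresholds (EAD bumps 15 mV vs 2 mV rise; alternans 30 ms vs 5 ms)."""
    rng = np.random.default_rng(7)
    results = {"ead": [[0, 0], [0, 0]], "rf": [[0, 0], [0, 0]], "alternans": [[0, 0], [0, 0]]}
    for i in range(1000):
        kind = i % 4
        kw = dict(noise_sd_mV=0.15, seed=int(rng.integers(2**31)), n_beats=4)
        if kind == 1:
            # bumps on the plateau (the steep final ramp masks slow bumps)
            kw["ead_bump"] = (float(rng.uniform(130, 190)), 15.0, 30.0)
        elif kind == 2:
            kw["rf"] = True
        elif kind == 3:
            kw["alternans_d_apd_ms"] = 30.0
        spec = SyntheticAPSpec(**kw)
        t, v, cai, labels = gen_ap_trace(spec)
        apds = [bm.apd(t, v[b]) for b in range(4)]
        out = bm.from_beat(t, v[-1], cai[-1], spec.cycle_length_ms, apd_history=apds)
        for key in results:
            truth = labels[key]
            pred = getattr(out, key)
            results[key][int(truth)][int(pred)] += 1
    for key, ((tn, fp), (fn, tp)) in results.items():
        assert fp == 0, f"{key}: {fp} false positives"
        assert fn == 0, f"{key}: {fn} false negatives"
        assert tp > 0 and tn > 0


def test_rf_forces_apd_undefined_and_flags_are_consistent():
    spec = SyntheticAPSpec(rf=True, n_beats=2)
    t, v, cai, _ = gen_ap_trace(spec)
    out = bm.from_beat(t, v[-1], cai[-1], spec.cycle_length_ms)
    assert out.rf
    assert not out.apd_defined
    assert out.apd90_ms == spec.cycle_length_ms  # reported as cycle length


def test_apd_stable_under_grid_refinement(base, yss):
    """Halving the uniform output step changes APD90 by no more than the
    interpolation error."""
    from cardiopop.model import SolverSettings
    from cardiopop.protocols import PacingProtocol, run_paced

    apds = []
    for dt_out in (0.5, 0.25):
        proto = PacingProtocol(frequency_hz=1.0, n_prepace=1, n_record=2, min_prepace=1,
                               solver=SolverSettings(dt_output_ms=dt_out))
        trace = run_paced(base, proto, y0=yss)
        t, v, _ = trace.beat(1)
        apds.append(bm.apd(t, v))
    assert abs(apds[0] - apds[1]) < 0.1
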
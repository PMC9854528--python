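"""Sinusoid evaluation, canonicalization, fitting, phase categories, sweeps."""

import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avprosody import errors
from avprosody.measurements_io import POSITIONS
from avprosody.peak_windows import SegmentWindow
from avprosody.sine_model import (
    SineParams,
    fit_region,
    fit_sine,
    normalize_params,
    phase_category,
    r_squared,
    sine_value,
    sweep_window_sizes,
    window_duration_ms,
)
from avprosody.synthetic import SyntheticConfig, generate_pitch_window


def _wrap_dist(a, b):
    d = abs(a - b) % 2.0
    return min(d, 2.0 - d)


def _param_err(est: SineParams, true: SineParams) -> float:
    return max(
        abs(est.I - true.I),
        abs(est.A - true.A),
        abs(est.f - true.f),
        _wrap_dist(est.phi, true.phi),
    )


class TestSineValue:
    def test_quarter_cycle(self):
        p = SineParams(I=0, A=1, f=0.25, phi=0)
        assert sine_value(p, 1.0) == pytest.approx(1.0)

    def test_phase_shift_by_one_negates(self):
        t = np.linspace(0, 3, 50)
        p = SineParams(I=0, A=1.3, f=0.7, phi=0.4)
        q = SineParams(I=0, A=1.3, f=0.7, phi=1.4)
        np.testing.assert_allclose(sine_value(q, t), -sine_value(p, t), atol=1e-12)

    def test_zero_amplitude_is_constant_baseline(self):
        p = SineParams(I=2.0, A=0.0, f=1.0, phi=0.3)
        t = np.linspace(0, 5, 20)
        np.testing.assert_allclose(sine_value(p, t), 2.0)


class TestNormalize:
    def test_negative_amplitude_flips_phase(self):
        p = normalize_params(0, -1, 0.5, 0.2)
        assert (p.A, p.phi) == pytest.approx((1.0, 1.2))

    def test_phase_wraps_mod_two(self):
        p = normalize_params(0, 1, 0.5, 2.5)
        assert p.phi == pytest.approx(0.5)

    def test_zero_frequency_rejected(self):
        with pytest.raises(errors.UnidentifiableFrequencyError):
            normalize_params(0, 1, 0.0, 0.5)

    @given(
        st.floats(-5, 5),
        st.floats(-4, 4),
        st.floats(0.05, 5).filter(lambda f: f > 0.05),
        st.floats(-6, 6),
    )
    @settings(max_examples=200, deadline=None)
    def test_curve_pointwise_unchanged(self, I, A, f, phi):
        """Canonicalization never moves the curve (1e-10 on a 100-point grid)."""
        t = np.linspace(0.0, 2.0, 100)
        raw = I + A * np.sin(2 * np.pi * f * t + phi * np.pi)
        p = normalize_params(I, A, f, phi)
        assert 0 <= p.phi < 2 and p.A >= 0 and p.f > 0
        np.testing.assert_allclose(sine_value(p, t), raw, atol=1e-10)

    def test_negative_frequency_canonicalized(self):
        t = np.linspace(0, 2, 60)
        # I + A sin(2 pi f t + phi pi) at (A, f) = (-1.2, -0.8) equals
        # 0.3 + 1.2 sin(2 pi 0.8 t - 0.7 pi) by the double sign flip
        raw = 0.3 + 1.2 * np.sin(2 * np.pi * 0.8 * t - 0.7 * np.pi)
        p = normalize_params(0.3, -1.2, -0.8, 0.7)
        np.testing.assert_allclose(sine_value(p, t), raw, atol=1e-12)


class TestPhaseCategory:
    @pytest.mark.parametrize(
        "phi,label",
        [
            (0.24, "high_rising"),
            (1.04, "low_falling"),
            (0.0, "high_rising"),
            (0.5, "high_falling"),
            (1.0, "low_falling"),
            (1.5, "low_rising"),
            (1.999, "low_rising"),
        ],
    )
    def test_quadrants_half_open(self, phi, label):
        assert phase_category(phi) == label

    @pytest.mark.parametrize("phi", [-0.1, 2.0, 5.0])
    def test_out_of_range_rejected(self, phi):
        with pytest.raises(errors.PhaseRangeError):
            phase_category(phi)


class TestRSquared:
    def test_perfect_fit_is_one(self):
        y = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        assert r_squared(np.full(5, y.mean()), y) == pytest.approx(0.0)

    def test_hand_computed_case(self):
        """SSE = 2, SST = 8 -> r2 = 0.75."""
        y = np.array([-2.0, 0.0, 0.0, 2.0])  # mean 0, SST 8
        pred = y + np.array([1.0, 0.0, -1.0, 0.0])  # SSE 2
        assert r_squared(pred, y) == pytest.approx(0.75)

    def test_constant_data_rejected(self):
        with pytest.raises(errors.UndefinedRSquaredError):
            r_squared(np.zeros(5), np.ones(5))


class TestFitSine:
    def test_exact_recovery_on_model_data(self):
        t = np.arange(19) / 30.0
        true = SineParams(I=0.4, A=1.7, f=0.9, phi=1.3)
        est, sse, converged = fit_sine(t, sine_value(true, t))
        assert converged
        assert sse == pytest.approx(0.0, abs=1e-12)
        assert _param_err(est, true) < 1e-6

    @given(
        st.floats(-1, 1),
        st.floats(0.2, 3.0),
        st.floats(0.2, 1.2),
        st.floats(0, 2).filter(lambda p: p < 2),
    )
    @settings(max_examples=120, deadline=None)
    def test_recovery_property_over_generator_ranges(self, I, A, f, phi):
        t = np.arange(19) / 30.0
        true = SineParams(I=I, A=A, f=f, phi=phi)
        est, _, _ = fit_sine(t, sine_value(true, t))
        assert _param_err(est, true) < 1e-6

    def test_constant_input_returns_zero_amplitude(self):
        t = np.arange(10) / 30.0
        est, sse, converged = fit_sine(t, np.full(10, 3.5))
        assert converged
        assert est.A == 0.0 and est.I == pytest.approx(3.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(errors.InsufficientDataError):
            fit_sine(np.arange(4) / 30.0, np.zeros(4))

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            fit_sine(np.array([0.0, 0.1, 0.1, 0.2, 0.3]), np.zeros(5))

    def test_amplitude_bounded_on_noisy_near_linear_data(self, rng):
        """Interpolation-style distortions must not yield runaway amplitudes."""
        t = np.arange(17) / 30.0
        y = 0.8 * t + rng.normal(0, 0.05, size=17)
        est, _, _ = fit_sine(t, y)
        assert est.A <= 5.0 * np.ptp(y) + 1e-9

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_sse_not_worse_than_r_nls_oracle(self, tmp_path, rng):
        """Independent oracle: R's nls (Levenberg-Marquardt, 40 random starts)
        on one noisy contour must not find a lower SSE than the fit."""
        t = np.arange(17) / 30.0
        true = SineParams(I=0.2, A=1.4, f=0.8, phi=0.6)
        y = sine_value(true, t) + rng.normal(0, 0.3, size=17)
        est, sse, _ = fit_sine(t, y)
        data = tmp_path / "xy.tsv"
        np.savetxt(data, np.column_stack([t, y]), delimiter="\t", header="t\ty", comments="")
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(minpack.lm))
            d <- read.delim(commandArgs(TRUE)[1])
            set.seed(1)
            best <- Inf
            for (i in 1:40) {
              st <- list(I=runif(1,-1,1), A=runif(1,0,3), f=runif(1,0.05,3), p=runif(1,0,2))
              m <- try(nlsLM(y ~ I + A*sin(2*pi*f*t + p*pi), data=d, start=st,
                             lower=c(-Inf,0,0.05,-Inf), upper=c(Inf,Inf,5,Inf),
                             control=nls.lm.control(maxiter=200)), silent=TRUE)
              if (!inherits(m, "try-error")) best <- min(best, sum(residuals(m)^2))
            }
            cat(sprintf("%.12f", best))
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(data)], capture_output=True, text=True, check=True
        )
        r_sse = float(out.stdout.strip())
        assert sse <= r_sse * (1 + 1e-8) + 1e-10


class TestFitRegion:
    def _window(self, cfg=None, seed=7):
        cfg = cfg or SyntheticConfig(seed=seed).noiseless()
        rng = np.random.default_rng(seed)
        pre = SineParams(I=0.1, A=1.2, f=0.8, phi=0.7)
        post = SineParams(I=-0.2, A=2.0, f=0.5, phi=1.6)
        series, post_used = generate_pitch_window(pre, post, cfg, rng, apply_missing=False)
        w = SegmentWindow("0001-0001", "a", 0, 1.0, np.zeros(121), series)
        return w, pre, post_used

    def test_pre_region_spans_peak_inclusive(self):
        w, pre, _ = self._window()
        fit = fit_region(w, "pre", 17)
        assert not fit.skipped
        # positions -16..0 lie inside the generated 19-frame pre sine
        assert fit.sse == pytest.approx(0.0, abs=1e-10)

    def test_generator_truth_recovered_both_regions(self):
        w, pre, post_used = self._window()
        fpre = fit_region(w, "pre", 19)
        fpost = fit_region(w, "post", 17)
        assert _param_err(fpre.params, pre) < 1e-6
        assert _param_err(fpost.params, post_used) < 1e-6

    def test_insufficient_coverage_skips_with_reason(self):
        w, _, _ = self._window()
        pitch = w.pitch.copy()
        pitch[54:61] = np.nan  # 7 of 17 pre positions missing -> < 75% coverage
        w2 = SegmentWindow(w.segment_id, w.speaker, 0, 1.0, w.eyebrow, pitch)
        fit = fit_region(w2, "pre", 17)
        assert fit.skipped and "coverage" in fit.skip_reason

    def test_unknown_region_rejected(self):
        w, _, _ = self._window()
        with pytest.raises(ValueError):
            fit_region(w, "mid", 17)


class TestSweep:
    def test_cardinality_and_determinism(self):
        windows = [TestFitRegion()._window(seed=s)[0] for s in (1, 2, 3)]
        t1 = sweep_window_sizes(windows, "post", sizes=(10, 15, 20))
        t2 = sweep_window_sizes(windows, "post", sizes=(10, 15, 20))
        assert len(t1) == 9
        assert t1.equals(t2)

    def test_mean_r2_incremental_equals_batch(self, small_bundle):
        bundle, _ = small_bundle
        ok = bundle.fits_post[~bundle.fits_post["skipped"].astype(bool)]
        ok = ok[ok["window_size"] == 17]
        batch = ok["r2"].mean()
        incremental = np.mean([v for v in ok["r2"]])
        assert batch == pytest.approx(incremental, abs=1e-12)

    def test_sizes_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            sweep_window_sizes([], "pre", sizes=(4,))


def test_window_durations_at_30fps():
    assert window_duration_ms(19) == pytest.approx(633.3333, abs=0.01)
    assert window_duration_ms(17) == pytest.approx(566.6667, abs=0.01)
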
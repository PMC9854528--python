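"""Positional smooths, peak split, and mixed models for brow-peak magnitude."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from avprosody import errors
from avprosody.measurements_io import POSITIONS
from avprosody.peak_windows import SegmentWindow
from avprosody.prominence_stats import (
    combined_model,
    fit_peak_model,
    positional_summary,
    select_best_window,
    split_by_peak,
)


def _windows_from_matrix(mat, peaks=None, speaker="a"):
    out = []
    for i, row in enumerate(mat):
        peak = peaks[i] if peaks is not None else float(row[60])
        out.append(
            SegmentWindow(f"0001-{i:04d}", speaker, 0, peak, np.asarray(row), np.asarray(row))
        )
    return out


class TestPositionalSummary:
    def test_constant_signal_flat_with_band_containing_it(self):
        mat = np.full((8, 121), 2.5) + np.random.default_rng(0).normal(0, 1e-9, (8, 121))
        summ = positional_summary(_windows_from_matrix(mat), signal="eyebrow", k=10)
        np.testing.assert_allclose(summ.mean, 2.5, atol=1e-6)
        assert np.all(summ.lower <= 2.5 + 1e-6) and np.all(summ.upper >= 2.5 - 1e-6)

    def test_duplication_leaves_mean_curve_unchanged(self, rng):
        mat = rng.normal(size=(12, 121)) + np.linspace(-1, 1, 121)
        w = _windows_from_matrix(mat)
        s1 = positional_summary(w, k=15)
        s2 = positional_summary(w + w, k=15)
        np.testing.assert_allclose(s1.mean, s2.mean, atol=1e-8)

    def test_interpolates_per_position_means_at_full_basis(self, rng):
        """k equal to the number of positions: the smoother passes through the
        per-position arithmetic means."""
        mat = rng.normal(size=(15, 121)) + np.sin(np.linspace(0, 3, 121))
        summ = positional_summary(_windows_from_matrix(mat), k=121)
        np.testing.assert_allclose(summ.mean, mat.mean(axis=0), atol=1e-6)

    def test_band_ordering_invariant(self, rng):
        mat = rng.normal(size=(10, 121))
        summ = positional_summary(_windows_from_matrix(mat), k=30)
        assert np.all(summ.lower <= summ.mean) and np.all(summ.mean <= summ.upper)

    def test_oversized_basis_rejected(self, rng):
        mat = rng.normal(size=(5, 121))
        with pytest.raises(errors.BasisError):
            positional_summary(_windows_from_matrix(mat), k=122)


class TestSplitByPeak:
    def test_partition_and_boundary_to_high(self):
        mat = np.zeros((3, 121))
        w = _windows_from_matrix(mat, peaks=[0.2, 1.6, 1.5])
        low, high = split_by_peak(w, threshold=1.5)
        assert [x.peak_height for x in low] == [0.2]
        assert sorted(x.peak_height for x in high) == [1.5, 1.6]

    def test_standard_normal_tail_fraction(self, rng):
        peaks = rng.standard_normal(1000)
        w = _windows_from_matrix(np.zeros((1000, 121)), peaks=peaks)
        _, high = split_by_peak(w, 1.5)
        expected = stats.norm.sf(1.5)
        assert len(high) / 1000 == pytest.approx(expected, abs=0.02)


def _lmm_data(rng, n_per=40, n_groups=5, tau_sd=0.4, sigma=0.5, beta=(0.5, 0.3, 0.25)):
    n = n_per * n_groups
    speaker = np.repeat([f"S{i}" for i in range(n_groups)], n_per)
    x1 = rng.normal(size=n)
    x2 = rng.uniform(0, 2, size=n)
    u = rng.normal(0, tau_sd, size=n_groups)
    y = (
        beta[0]
        + beta[1] * x1
        + beta[2] * x2
        + np.repeat(u, n_per)
        + rng.normal(0, sigma, size=n)
    )
    return pd.DataFrame({"speaker": speaker, "x1": x1, "x2": x2, "peak_height": y})


class TestFitPeakModel:
    def test_noiseless_zero_variance_beta_exact(self, rng):
        df = _lmm_data(rng, tau_sd=0.0, sigma=0.0)
        res = fit_peak_model(df, predictors=("x1", "x2"), random_intercept=False)
        np.testing.assert_allclose(
            res.fixed_effects["estimate"], [0.5, 0.3, 0.25], atol=1e-6
        )

    def test_reduces_to_ols_without_random_intercept(self, rng):
        df = _lmm_data(rng)
        ols = fit_peak_model(df, predictors=("x1", "x2"), random_intercept=False)
        import statsmodels.api as sm

        X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
        ref = sm.OLS(df["peak_height"], X).fit()
        np.testing.assert_allclose(ols.fixed_effects["estimate"], ref.params, atol=1e-8)
        assert ols.random_intercept_variance == 0.0

    def test_recovers_generative_coefficients_within_3se(self, rng):
        df = _lmm_data(rng, n_per=150)
        res = fit_peak_model(df, predictors=("x1", "x2"))
        for term, truth in zip(("Intercept", "x1", "x2"), (0.5, 0.3, 0.25)):
            est = res.fixed_effects.loc[term, "estimate"]
            se = res.fixed_effects.loc[term, "std_error"]
            assert abs(est - truth) < 3 * se

    def test_single_speaker_rejected(self, rng):
        df = _lmm_data(rng, n_groups=1)
        with pytest.raises(errors.DegenerateGroupingError):
            fit_peak_model(df, predictors=("x1", "x2"))

    def test_collinear_predictors_rejected(self, rng):
        df = _lmm_data(rng)
        df["x3"] = 2 * df["x1"]
        with pytest.raises(errors.CollinearityError):
            fit_peak_model(df, predictors=("x1", "x2", "x3"))

    def test_too_few_observations_rejected(self, rng):
        df = _lmm_data(rng, n_per=1)
        with pytest.raises(errors.InsufficientDataError):
            fit_peak_model(df, predictors=("x1", "x2"))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_matches_lmerTest_estimates_and_satterthwaite_df(self, tmp_path, rng):
        """Independent oracle: lme4/lmerTest agree on estimates, SEs,
        Satterthwaite df and p-values."""
        df = _lmm_data(rng, n_per=24)
        res = fit_peak_model(df, predictors=("x1", "x2"))
        data = tmp_path / "d.tsv"
        df.to_csv(data, sep="\t", index=False)
        script = tmp_path / "m.R"
        script.write_text(
            """
            suppressMessages(library(lmerTest))
            d <- read.delim(commandArgs(TRUE)[1])
            m <- lmer(peak_height ~ x1 + x2 + (1|speaker), data=d)
            co <- coef(summary(m))
            write.table(co, stdout(), sep="\\t", col.names=FALSE)
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(data)], capture_output=True, text=True, check=True
        )
        r_rows = [line.split("\t") for line in out.stdout.strip().splitlines()]
        r_tab = {row[0].strip('"'): [float(v) for v in row[1:]] for row in r_rows}
        for ours, theirs in (("Intercept", "(Intercept)"), ("x1", "x1"), ("x2", "x2")):
            est, se, dof, t, p = res.fixed_effects.loc[ours]
            r_est, r_se, r_df, r_t, r_p = r_tab[theirs]
            assert est == pytest.approx(r_est, abs=1e-4)
            assert se == pytest.approx(r_se, rel=1e-3)
            assert dof == pytest.approx(r_df, rel=0.01)
            assert p == pytest.approx(r_p, abs=1e-3)


class TestSelection:
    def _model(self, rng, aic):
        df = _lmm_data(rng)
        m = fit_peak_model(df, predictors=("x1", "x2"))
        m.aic_ml = aic
        return m

    def test_single_candidate_returned(self, rng):
        m = self._model(rng, 100.0)
        size, best, table = select_best_window({19: m})
        assert size == 19 and best is m and len(table) == 1

    def test_tie_breaks_to_smallest_size(self, rng):
        m1, m2 = self._model(rng, 50.0), self._model(rng, 50.0)
        size, _, _ = select_best_window({15: m1, 12: m2})
        assert size == 12

    def test_minimum_aic_wins(self, rng):
        models = {s: self._model(rng, float(100 - s)) for s in (10, 14, 19)}
        size, _, table = select_best_window(models)
        assert size == 19
        assert table.iloc[0]["window_size"] == 19

    def test_selection_prefers_windows_spanning_the_coupled_region(self):
        """The generator couples peak height to a 19-frame pre-peak sinusoid;
        across seeds the selected window is never the far-too-short candidate,
        whose fits discard most of that information."""
        from avprosody import PipelineConfig, SyntheticConfig
        from avprosody.pipeline import run_synthetic_pipeline

        for seed in (41, 42, 43):
            bundle, _ = run_synthetic_pipeline(
                SyntheticConfig(seed=seed, n_speakers=5, segments_per_speaker=80),
                PipelineConfig(sweep_sizes=(11, 15, 19)),
            )
            table = bundle.selection_table.set_index("window_size")
            assert int(bundle.selection_table.iloc[0]["window_size"]) != 11
            assert table.loc[19, "aic_ml"] < table.loc[11, "aic_ml"]


class TestCombined:
    def _fit_tables(self, rng, n=200, post_only=True):
        speakers = np.repeat(["S1", "S2", "S3", "S4"], n // 4)
        seg = [f"{(i // 50) + 1:04d}-{i:04d}" for i in range(n)]
        base = {
            "segment_id": seg,
            "speaker": speakers,
            "skipped": False,
        }
        pre = pd.DataFrame(
            {
                **base,
                "region": "pre",
                "window_size": 19,
                "I": rng.uniform(-1, 1, n),
                "A": rng.uniform(0.2, 3, n),
                "f": rng.uniform(0.2, 1.2, n),
                "phi": rng.uniform(0, 2, n),
            }
        )
        post = pd.DataFrame(
            {
                **base,
                "region": "post",
                "window_size": 17,
                "I": rng.uniform(-1, 1, n),
                "A": rng.uniform(0.2, 3, n),
                "f": rng.uniform(0.2, 1.2, n),
                "phi": rng.uniform(0, 2, n),
            }
        )
        y = 0.2 + 0.4 * post["A"] + 0.3 * post["f"] + rng.normal(0, 0.3, n)
        peaks = pd.DataFrame({"segment_id": seg, "speaker": speakers, "peak_height": y})
        return pre, post, peaks

    def test_pre_coefficients_near_zero_when_only_post_drives(self, rng):
        pre, post, peaks = self._fit_tables(rng)
        res = combined_model(pre, post, peaks)
        for term in ("A_pre", "f_pre", "phi_pre"):
            est = res.fixed_effects.loc[term, "estimate"]
            se = res.fixed_effects.loc[term, "std_error"]
            assert abs(est) < 2 * se
        assert res.fixed_effects.loc["A_post", "p"] < 0.001

    def test_duplication_shrinks_se_keeps_estimates(self, rng):
        pre, post, peaks = self._fit_tables(rng)
        r1 = combined_model(pre, post, peaks)
        pre2 = pd.concat([pre, pre.assign(segment_id=pre["segment_id"] + "b")], ignore_index=True)
        post2 = pd.concat([post, post.assign(segment_id=post["segment_id"] + "b")], ignore_index=True)
        peaks2 = pd.concat([peaks, peaks.assign(segment_id=peaks["segment_id"] + "b")], ignore_index=True)
        r2 = combined_model(pre2, post2, peaks2)
        np.testing.assert_allclose(
            r1.fixed_effects["estimate"], r2.fixed_effects["estimate"], atol=1e-3
        )
        assert (
            r2.fixed_effects["std_error"].to_numpy()
            < r1.fixed_effects["std_error"].to_numpy()
        ).all()

    def test_empty_join_rejected(self, rng):
        pre, post, peaks = self._fit_tables(rng)
        post["segment_id"] = post["segment_id"] + "_other"
        with pytest.raises(errors.NoOverlapError):
            combined_model(pre, post, peaks)
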
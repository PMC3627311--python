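"""Design construction, weighted fitting, Monte-Carlo channel inference."""

import numpy as np
import pandas as pd
import pytest

import nirschange as nc
from nirschange.glm import (
    _corr_all_shifts,
    build_design,
    condition_columns,
    fit_weighted,
    responding_channels,
)
from nirschange.schedule import ScheduleConfig

FS = 10.0


@pytest.fixture(scope="module")
def design_and_schedule():
    sched = nc.generate_infant_schedule(ScheduleConfig(n_target_blocks=8, seed=7))
    design = build_design(sched, FS)
    return sched, design


class TestBuildDesign:
    def test_six_minute_session_has_ten_detrend_columns(self, small_schedule):
        n = int(6 * 60 * FS)
        design = build_design(small_schedule, FS, n_samples=n)
        detrend = [c for c in design.columns if c.startswith("detrend")]
        assert len(detrend) == 10  # sine+cosine pairs for periods 2..6 min

    def test_two_condition_columns_and_intercept(self, design_and_schedule):
        _, design = design_and_schedule
        assert condition_columns(design) == ["cond_cluster", "cond_duration"]
        assert "intercept" in design.columns

    def test_condition_regressor_zero_before_first_target(self, design_and_schedule):
        sched, design = design_and_schedule
        first_onset = min(b.onset_s for b in sched.target_blocks)
        i0 = int(first_onset * FS)
        for col in condition_columns(design):
            assert np.allclose(design[col].to_numpy()[:i0], 0.0)

    def test_short_session_warns_and_omits_detrend(self, small_schedule):
        with pytest.warns(UserWarning, match="2 min"):
            design = build_design(small_schedule, FS, n_samples=int(90 * FS))
        assert not [c for c in design.columns if c.startswith("detrend")]

    def test_detrend_columns_are_near_orthogonal_to_intercept(self, small_schedule):
        n = int(6 * 60 * FS)
        design = build_design(small_schedule, FS, n_samples=n)
        for col in design.columns:
            if col.startswith("detrend"):
                assert abs(design[col].mean()) < 0.02


class TestFitWeighted:
    def test_noiseless_beta_recovered_exactly(self, montage):
        sched = nc.generate_infant_schedule(ScheduleConfig(n_target_blocks=8, seed=7))
        eff = nc.EffectSpec(oxy_amplitude={"cluster": 0.1, "duration": 0.1})
        rec = nc.simulate_recording(sched, montage, eff, nc.NoiseModel.silent())
        design = build_design(sched, rec.fs, rec.n_samples)
        fit = fit_weighted(
            rec.oxy[rec.channel_index("left", 4)], design, np.ones(rec.n_samples)
        )
        assert fit.betas["cond_cluster"] == pytest.approx(0.1, abs=1e-8)
        assert fit.betas["cond_duration"] == pytest.approx(0.1, abs=1e-8)

    def test_beta_recovery_within_ten_percent_under_noise(self):
        from nirschange.experiments import beta_recovery_error

        assert beta_recovery_error(amplitude=0.1, white_sd=0.01, seed=3) < 0.10

    def test_all_zero_weights_raise(self, design_and_schedule):
        _, design = design_and_schedule
        y = np.zeros(len(design))
        with pytest.raises(ValueError, match="no usable samples"):
            fit_weighted(y, design, np.zeros(len(design)))

    def test_all_ones_weights_equal_ols(self, design_and_schedule, rng):
        """Independent oracle: statsmodels OLS on the same design."""
        import statsmodels.api as sm

        _, design = design_and_schedule
        y = rng.normal(0, 1, len(design)) + 0.3 * design["cond_cluster"].to_numpy()
        fit = fit_weighted(y, design, np.ones(len(design)))
        ols = sm.OLS(y, design.to_numpy()).fit()
        assert np.allclose(list(fit.betas.values()), ols.params, atol=1e-10)
        assert np.allclose(list(fit.se.values()), ols.bse, atol=1e-10)

    def test_zero_weighted_samples_do_not_influence_fit(self, design_and_schedule, rng):
        _, design = design_and_schedule
        n = len(design)
        y = rng.normal(0, 1, n)
        w = np.ones(n)
        w[100:200] = 0.0
        fit_a = fit_weighted(y, design, w)
        y2 = y.copy()
        y2[100:200] = 1e6  # corrupt only excluded samples
        fit_b = fit_weighted(y2, design, w)
        assert fit_a.betas == pytest.approx(fit_b.betas)

    def test_rank_deficiency_names_collinear_columns(self, design_and_schedule, rng):
        sched, design = design_and_schedule
        bad = design.copy()
        bad["cond_duration"] = 0.0  # e.g. a schedule with no duration blocks
        with pytest.raises(ValueError, match="cond_duration"):
            fit_weighted(rng.normal(0, 1, len(bad)), bad, np.ones(len(bad)))


class TestMonteCarloInference:
    def test_closed_form_matches_explicit_surrogate_refit(self, design_and_schedule, rng):
        """The FFT evaluation of the surrogate statistic must agree with an
        explicit construct-surrogate-and-refit at arbitrary shifts (the
        surrogate shifts the nuisance-model residual and restores the
        nuisance fit)."""
        _, design = design_and_schedule
        n = len(design)
        X = design.to_numpy()
        cond_idx = np.array(
            [i for i, c in enumerate(design.columns) if c.startswith("cond_")]
        )
        nuis_idx = np.array([i for i in range(X.shape[1]) if i not in cond_idx])
        y = rng.normal(0, 1, n)
        w = np.ones(n)
        w[300:350] = 0.0
        r_all = _corr_all_shifts(y, X, w, cond_idx, nuis_idx)
        keep = w > 0
        beta_red, _, _, _ = np.linalg.lstsq(X[keep][:, nuis_idx], y[keep], rcond=None)
        c = X[:, nuis_idx] @ beta_red
        e = y - c
        for s in (0, 17, 400, n - 5):
            surrogate = c + np.roll(e, s)
            direct = fit_weighted(surrogate, design, w).r
            assert r_all[s] == pytest.approx(direct, abs=1e-10)

    def test_zero_shift_surrogate_is_the_observed_series(self, design_and_schedule, rng):
        _, design = design_and_schedule
        n = len(design)
        X = design.to_numpy()
        cond_idx = np.array(
            [i for i, c in enumerate(design.columns) if c.startswith("cond_")]
        )
        nuis_idx = np.array([i for i in range(X.shape[1]) if i not in cond_idx])
        y = rng.normal(0, 1, n) + 0.2 * design["cond_cluster"].to_numpy()
        w = np.ones(n)
        r_all = _corr_all_shifts(y, X, w, cond_idx, nuis_idx)
        assert r_all[0] == pytest.approx(fit_weighted(y, design, w).r, abs=1e-10)

    def test_strong_effect_is_detected(self, montage):
        sched = nc.generate_infant_schedule(ScheduleConfig(n_target_blocks=8, seed=7))
        noise = nc.NoiseModel(white_sd=0.02, drift=(), cardiac_amp=0, respiratory_amp=0)
        eff = nc.EffectSpec(oxy_amplitude={"cluster": 0.1, "duration": 0.1})
        rec = nc.simulate_recording(sched, montage, eff, noise, seed=5)
        design = build_design(sched, rec.fs, rec.n_samples)
        fits = responding_channels(
            rec, design, np.ones(rec.n_samples), n_mc=1000, seed=6
        )
        roi = [f for ch, f in zip(rec.channels, fits) if ch.roi]
        assert all(f.responding for f in roi)

    def test_corrected_p_monotone_in_observed_correlation(self, montage):
        sched = nc.generate_infant_schedule(ScheduleConfig(n_target_blocks=8, seed=7))
        rec = nc.simulate_recording(sched, montage, seed=8)
        design = build_design(sched, rec.fs, rec.n_samples)
        fits = responding_channels(
            rec, design, np.ones(rec.n_samples), n_mc=500, seed=9
        )
        by_r = sorted(fits, key=lambda f: abs(f.r), reverse=True)
        ps = [f.p_corrected for f in by_r]
        assert ps == sorted(ps)

    def test_corrected_p_never_below_raw_p(self, montage):
        sched = nc.generate_infant_schedule(ScheduleConfig(n_target_blocks=8, seed=7))
        rec = nc.simulate_recording(sched, montage, seed=10)
        design = build_design(sched, rec.fs, rec.n_samples)
        fits = responding_channels(
            rec, design, np.ones(rec.n_samples), n_mc=500, seed=11
        )
        for f in fits:
            assert f.p_corrected >= f.p_raw

    def test_session_too_short_for_shift_raises(self, montage):
        cfg = ScheduleConfig(
            n_target_blocks=2, baseline_jitter_s=(9.0, 9.0), seed=0
        )
        sched = nc.generate_infant_schedule(cfg)
        rec = nc.simulate_recording(sched, montage, seed=1)
        design = build_design(sched, rec.fs, rec.n_samples)
        with pytest.raises(ValueError, match="too short"):
            responding_channels(
                rec, design, np.ones(rec.n_samples), n_mc=10, min_shift_s=30.0
            )

    def test_default_iteration_count_is_ten_thousand(self):
        import inspect

        sig = inspect.signature(responding_channels)
        assert sig.parameters["n_mc"].default == 10_000
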
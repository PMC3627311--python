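"""FIR reconstruction, ROI peak extraction, laterality indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import nirschange as nc
from nirschange.fir import fir_design, laterality_table, reconstruct, roi_peak
from nirschange.schedule import ScheduleConfig

FS = 10.0


@pytest.fixture(scope="module")
def spaced_schedule():
    """Targets far enough apart that the 20 s FIR window fits between onsets."""
    return nc.generate_infant_schedule(
        ScheduleConfig(n_target_blocks=6, baseline_jitter_s=(21.0, 27.0), seed=3)
    )


class TestFirDesign:
    def test_twenty_regressors_per_condition_by_default(self, spaced_schedule):
        design = fir_design(spaced_schedule, FS)
        for cond in ("cluster", "duration"):
            cols = [c for c in design.columns if c.startswith(f"fir_{cond}_")]
            assert len(cols) == 20

    def test_single_onset_bin_three_covers_three_to_four_seconds(self):
        cfg = ScheduleConfig(n_target_blocks=2, baseline_jitter_s=(30.0, 30.0), seed=0)
        sched = nc.generate_infant_schedule(cfg, populate_tokens=False)
        onset = sched.condition_onsets("cluster")[0]
        design = fir_design(sched, FS)
        col = design["fir_cluster_3"].to_numpy()
        i0, i1 = int((onset + 3) * FS), int((onset + 4) * FS)
        assert np.all(col[i0:i1] == 1.0)
        assert col.sum() == pytest.approx(i1 - i0)

    def test_bins_of_one_onset_are_mutually_orthogonal(self, spaced_schedule):
        design = fir_design(spaced_schedule, FS)
        cols = [c for c in design.columns if c.startswith("fir_cluster_")]
        X = design[cols].to_numpy()
        gram = X.T @ X
        off_diag = gram - np.diag(np.diag(gram))
        assert np.all(off_diag == 0)

    def test_warns_when_window_exceeds_onset_gap(self, small_schedule):
        with pytest.warns(UserWarning, match="FIR window"):
            fir_design(small_schedule, FS, n_bins=30)


class TestReconstruct:
    def test_zero_input_gives_zero_betas(self, spaced_schedule, montage):
        rec = nc.simulate_recording(
            spaced_schedule, montage, nc.EffectSpec.null(), nc.NoiseModel.silent()
        )
        est = reconstruct(rec, fir_design(spaced_schedule, FS, rec.n_samples))
        assert np.allclose(est["total_beta"], 0.0)

    def test_noiseless_recovery_traces_the_true_waveform(self):
        from nirschange.experiments import fir_recovery_correlation

        assert fir_recovery_correlation(noise_ratio=0.0, seed=5) > 0.99

    def test_noisy_recovery_correlation_above_095(self):
        from nirschange.experiments import fir_recovery_correlation

        assert fir_recovery_correlation(noise_ratio=0.2, seed=5) > 0.95

    def test_total_beta_is_sum_of_oxy_and_deoxy(self, spaced_schedule, montage):
        rec = nc.simulate_recording(spaced_schedule, montage, seed=4)
        est = reconstruct(rec, fir_design(spaced_schedule, FS, rec.n_samples))
        assert np.allclose(
            est["total_beta"], est["oxy_beta"] + est["deoxy_beta"], atol=1e-12
        )


class TestRoiPeak:
    @staticmethod
    def _estimate(rows):
        return pd.DataFrame(rows)

    def test_max_abs_within_window(self, montage):
        rows = [
            {"subject": 0, "hemisphere": h, "channel": ch, "condition": "cluster",
             "bin": b, "oxy_beta": 0.0, "deoxy_beta": 0.0, "total_beta": v}
            for h in ("left", "right")
            for ch in (4, 6, 7)
            for b, v in enumerate([0.1, -0.4, 0.2] + [0.0] * 17)
        ]
        peaks = roi_peak(self._estimate(rows), montage)
        assert set(peaks["peak_abs"]) == {0.4}
        assert set(peaks["peak_signed"]) == {-0.4}

    def test_peak_outside_nine_second_window_is_ignored(self, montage):
        rows = [
            {"subject": 0, "hemisphere": h, "channel": 4, "condition": "cluster",
             "bin": b, "oxy_beta": 0.0, "deoxy_beta": 0.0,
             "total_beta": 5.0 if b == 12 else (0.2 if b == 3 else 0.0)}
            for h in ("left", "right") for b in range(20)
        ]
        peaks = roi_peak(self._estimate(rows), montage)
        assert set(peaks["peak_abs"]) == {0.2}

    def test_max_taken_across_roi_channels(self, montage):
        rows = [
            {"subject": 0, "hemisphere": h, "channel": ch, "condition": "cluster",
             "bin": b, "oxy_beta": 0.0, "deoxy_beta": 0.0,
             "total_beta": {4: 0.1, 6: 0.3, 7: 0.2}[ch] if b == 2 else 0.0}
            for h in ("left", "right") for ch in (4, 6, 7) for b in range(20)
        ]
        peaks = roi_peak(self._estimate(rows), montage)
        assert set(peaks["peak_abs"]) == {0.3}
        assert set(peaks["channel"]) == {6}

    def test_empty_roi_raises(self):
        montage = nc.build_montage(roi_channels=())
        with pytest.raises(ValueError, match="ROI"):
            roi_peak(pd.DataFrame({"hemisphere": [], "channel": [], "bin": []}), montage)


class TestLateralityIndex:
    @pytest.mark.parametrize(
        "L, R, expected",
        [(1.0, 1.0, 0.0), (2.0, 1.0, 1 / 3), (1.0, 0.0, 1.0), (0.0, 1.0, -1.0)],
    )
    def test_known_values(self, L, R, expected):
        assert nc.laterality_index(L, R) == pytest.approx(expected)

    def test_zero_denominator_is_missing(self):
        assert np.isnan(nc.laterality_index(0.0, 0.0))

    @given(
        L=st.floats(0.001, 100.0), R=st.floats(0.001, 100.0), c=st.floats(0.01, 50.0)
    )
    def test_antisymmetry_bounds_and_scale_invariance(self, L, R, c):
        li = nc.laterality_index(L, R)
        assert -1.0 <= li <= 1.0
        assert nc.laterality_index(R, L) == pytest.approx(-li, abs=1e-12)
        assert nc.laterality_index(c * L, c * R) == pytest.approx(li, abs=1e-9)

    def test_left_dominant_cohort_yields_positive_group_li(self):
        from nirschange.experiments import li_cohort

        li = li_cohort(n_subjects=8, seed=13)
        assert li["li"].mean() > 0
        assert (li.groupby("condition")["li"].mean() > 0).all()


class TestGroupSummary:
    def test_single_value_cell(self):
        df = pd.DataFrame({"group": ["a"], "condition": ["cluster"], "li": [0.4]})
        out = nc.group_summary(df)
        row = out.iloc[0]
        assert row["mean"] == row["q1"] == row["q3"] == row["min"] == row["max"] == 0.4

    def test_symmetric_values(self):
        df = pd.DataFrame(
            {"group": ["a"] * 3, "condition": ["cluster"] * 3, "li": [-1.0, 0.0, 1.0]}
        )
        row = nc.group_summary(df).iloc[0]
        assert row["mean"] == 0.0 and row["min"] == -1.0 and row["max"] == 1.0

    def test_quartiles_match_sort_based_oracle(self, rng):
        vals = rng.uniform(-1, 1, 37)
        df = pd.DataFrame(
            {"group": ["a"] * 37, "condition": ["duration"] * 37, "li": vals}
        )
        row = nc.group_summary(df).iloc[0]
        # linear-interpolation (type-7) quartiles from sorted order statistics
        srt = np.sort(vals)

        def q7(p):
            h = (len(srt) - 1) * p
            lo = int(np.floor(h))
            return srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])

        assert row["q1"] == pytest.approx(q7(0.25))
        assert row["q3"] == pytest.approx(q7(0.75))

    def test_empty_cell_warns_and_is_omitted(self):
        df = pd.DataFrame(
            {"group": ["a"], "condition": ["cluster"], "li": [np.nan]}
        )
        with pytest.warns(UserWarning, match="empty cell"):
            out = nc.group_summary(df)
        assert out.empty
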
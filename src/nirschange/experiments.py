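"""Simulated validation experiments for the pipeline.

Reusable routines that measure the pipeline's operating characteristics on
ground-truth-known synthetic cohorts: empirical family-wise error of the
max-statistic Monte-Carlo test on null sessions, GLM beta recovery, FIR
waveform recovery, power of the adult duration x token-variability 2x2
analysis, and recovery of a lateralised response by the LI procedure.  Each
routine is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .anova import anova_2x2_within
from .geometry import Montage, build_montage
from .glm import build_design, fit_weighted, responding_channels
from .hrf import DEFAULT_HRF, block_regressor
from .fir import fir_design, laterality_table, reconstruct, roi_peak
from .schedule import ADULT_CONDITIONS, ScheduleConfig, generate_adult_schedule, generate_infant_schedule
from .synth import EffectSpec, NoiseModel, simulate_recording

__all__ = [
    "ADULT_EFFECTS",
    "measure_fwer",
    "beta_recovery_error",
    "fir_recovery_correlation",
    "adult_cohort_zscores",
    "anova_2x2_power",
    "li_cohort",
]

#: ground-truth oxy amplitudes (mM*mm) of the duration-condition response in
#: the adult 2x2 emulation: increasing with block duration, decreasing with
#: token variability (long-single strongest, short-multi weakest)
ADULT_EFFECTS = {
    "long-single": 0.08,
    "long-multi": 0.05,
    "short-single": 0.05,
    "short-multi": 0.03,
}
#: between-subject spread of response amplitude (lognormal sigma)
SUBJECT_SIGMA = 0.25


def measure_fwer(
    n_sessions: int = 200,
    n_mc: int = 1000,
    n_target_blocks: int = 16,
    alpha: float = 0.05,
    seed: int = 0,
    montage: Montage | None = None,
) -> float:
    """Family-wise false-positive rate of the responding-channel test.

    Simulates ``n_sessions`` stimulus-free sessions (full noise model, zero
    response amplitude everywhere), runs the max-statistic Monte-Carlo test
    on each, and returns the fraction of sessions declaring at least one
    responding channel.  Should sit near ``alpha``.
    """
    montage = montage or build_montage()
    root = np.random.SeedSequence(seed)
    hits = 0
    for k, child in enumerate(root.spawn(n_sessions)):
        s1, s2, s3 = (int(c.generate_state(1, np.uint32)[0] % 2**31)
                      for c in child.spawn(3))
        sched = generate_infant_schedule(
            ScheduleConfig(n_target_blocks=n_target_blocks, seed=s1)
        )
        rec = simulate_recording(
            sched, montage, EffectSpec.null(), NoiseModel(), seed=s2
        )
        design = build_design(sched, rec.fs, rec.n_samples)
        fits = responding_channels(
            rec, design, np.ones(rec.n_samples),
            n_mc=n_mc, alpha=alpha, seed=s3,
        )
        hits += any(f.responding for f in fits)
    return hits / n_sessions


def beta_recovery_error(
    amplitude: float = 0.1,
    white_sd: float = 0.01,
    n_target_blocks: int = 8,
    seed: int = 0,
) -> float:
    """Worst relative error of recovered condition betas on a seeded session.

    Injects a known oxy amplitude into every channel of a session with white
    noise only and returns ``max |beta_hat - amplitude| / amplitude`` over
    the ROI channels and both conditions.
    """
    montage = build_montage()
    sched = generate_infant_schedule(
        ScheduleConfig(n_target_blocks=n_target_blocks, seed=seed)
    )
    eff = EffectSpec(
        oxy_amplitude={c: amplitude for c in sched.config.conditions},
        non_roi_scale=1.0,
    )
    rec = simulate_recording(
        sched, montage, eff,
        NoiseModel(white_sd=white_sd, drift=(), cardiac_amp=0.0, respiratory_amp=0.0),
        seed=seed + 1,
    )
    design = build_design(sched, rec.fs, rec.n_samples)
    w = np.ones(rec.n_samples)
    errs = []
    for i, ch in enumerate(rec.channels):
        if not ch.roi:
            continue
        fit = fit_weighted(rec.oxy[i], design, w)
        for cond in sched.config.conditions:
            errs.append(abs(fit.betas[f"cond_{cond}"] - amplitude) / amplitude)
    return float(max(errs))


def fir_recovery_correlation(
    amplitude: float = 0.1,
    noise_ratio: float = 0.0,
    seed: int = 0,
    n_target_blocks: int = 6,
) -> float:
    """Correlation between FIR-recovered and true total-Hb response waveforms.

    Simulates widely spaced target blocks (baselines long enough that the
    modelled 20 s window fits between onsets), reconstructs the FIR betas of
    one ROI channel, and correlates the recovered total-Hb bin curve with the
    ground-truth convolved response sampled at bin centres.  ``noise_ratio``
    sets the white-noise sd as a fraction of the response amplitude.
    """
    montage = build_montage()
    cfg = ScheduleConfig(
        n_target_blocks=n_target_blocks,
        baseline_jitter_s=(21.0, 27.0),
        seed=seed,
    )
    sched = generate_infant_schedule(cfg)
    eff = EffectSpec(oxy_amplitude={c: amplitude for c in cfg.conditions})
    noise = NoiseModel(
        white_sd=noise_ratio * amplitude, drift=(),
        cardiac_amp=0.0, respiratory_amp=0.0,
    )
    rec = simulate_recording(sched, montage, eff, noise, seed=seed + 1, tail_s=25.0)
    design = fir_design(sched, rec.fs, rec.n_samples)
    est = reconstruct(rec, design)

    # ground truth: the unit-peak convolved block response over one window
    fs = rec.fs
    n_win = int(20 * fs)
    true_curve = block_regressor([0.0], cfg.target_duration_s, n_win, fs)
    centers = (np.arange(20) + 0.5) * fs
    truth = amplitude * (1.0 + eff.deoxy_ratio) * true_curve[centers.astype(int)]

    ch = montage.channel("left", 4)
    sub = est[
        (est["hemisphere"] == "left")
        & (est["channel"] == ch.id)
        & (est["condition"] == "cluster")
    ].sort_values("bin")
    rec_curve = sub["total_beta"].to_numpy()
    return float(np.corrcoef(rec_curve, truth)[0, 1])


def adult_cohort_zscores(
    n_subjects: int = 8,
    seed: int = 0,
    effects: dict | None = None,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Z-scores of one simulated adult 2x2 cohort (long format).

    Each subject contributes four counterbalanced sessions (short/long x
    single/multi).  Per session only the duration condition carries a
    response, with amplitude from ``effects`` scaled by a per-subject
    lognormal factor; the z-score entering the ANOVA is the largest
    duration-condition z across the left ROI channels (the channels near
    auditory cortex), as in a peak-channel analysis.
    """
    effects = effects or ADULT_EFFECTS
    noise = noise or NoiseModel()
    montage = build_montage(spacing_mm=30.0)
    roi_left = montage.roi_channels("left")
    root = np.random.SeedSequence(seed)
    rows = []
    for subj, subj_seq in enumerate(root.spawn(n_subjects)):
        subj_rng = np.random.default_rng(subj_seq)
        gain = float(np.exp(subj_rng.normal(0.0, SUBJECT_SIGMA)))
        for ci, cond_name in enumerate(ADULT_CONDITIONS):
            s1, s2 = (int(c.generate_state(1, np.uint32)[0] % 2**31)
                      for c in subj_seq.spawn(2))
            sched = generate_adult_schedule(
                cond_name, seed=(s1 + ci) % 2**31, populate_tokens=False
            )
            eff = EffectSpec(
                oxy_amplitude={"duration": gain * effects[cond_name], "cluster": 0.0},
                non_roi_scale=0.0,
            )
            rec = simulate_recording(
                sched, montage, eff, noise,
                seed=(s2 + ci) % 2**31,
                channels=roi_left, tail_s=20.0,
            )
            design = build_design(sched, rec.fs, rec.n_samples)
            w = np.ones(rec.n_samples)
            z = max(
                fit_weighted(rec.oxy[i], design, w).z["cond_duration"]
                for i in range(len(roi_left))
            )
            dur_level, tok_level = cond_name.split("-")
            rows.append(
                {"subject": subj, "duration": dur_level, "tokens": tok_level, "z": z}
            )
    return pd.DataFrame(rows)


def anova_2x2_power(
    n_cohorts: int = 100,
    n_subjects: int = 8,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of simulated adult cohorts with both 2x2 main effects significant.

    With amplitudes increasing in block duration and decreasing in token
    variability, both the duration and the token-variability main effect of
    the within-subject ANOVA should be detected in most cohorts.
    """
    both = 0
    for k in range(n_cohorts):
        df = adult_cohort_zscores(n_subjects=n_subjects, seed=seed * 100_003 + k)
        tab = anova_2x2_within(df)
        both += (tab.loc["duration", "p"] < alpha) and (tab.loc["tokens", "p"] < alpha)
    return both / n_cohorts


def li_cohort(
    n_subjects: int = 15,
    left_amplitude: float = 0.08,
    right_amplitude: float = 0.04,
    white_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Laterality indices of a cohort with a left-dominant ground truth.

    Simulates infant sessions whose ROI responses are stronger on the left,
    runs the full FIR + ROI-peak + LI procedure per subject, and returns the
    per-subject LI table (conditions pooled via their own peaks).
    """
    montage = build_montage()
    root = np.random.SeedSequence(seed)
    frames = []
    for subj, subj_seq in enumerate(root.spawn(n_subjects)):
        s1, s2 = (int(c.generate_state(1, np.uint32)[0] % 2**31)
                  for c in subj_seq.spawn(2))
        sched = generate_infant_schedule(
            ScheduleConfig(n_target_blocks=8, seed=s1), populate_tokens=False
        )
        eff = EffectSpec(
            oxy_amplitude={"cluster": left_amplitude, "duration": left_amplitude},
            left_scale=1.0,
            right_scale=right_amplitude / left_amplitude,
            non_roi_scale=0.25,
        )
        rec = simulate_recording(
            sched, montage, eff,
            NoiseModel(white_sd=white_sd, drift=(), cardiac_amp=0.0, respiratory_amp=0.0),
            seed=s2, tail_s=20.0,
        )
        design = fir_design(sched, rec.fs, rec.n_samples)
        est = reconstruct(rec, design, subject=subj)
        peaks = roi_peak(est, montage)
        frames.append(laterality_table(peaks))
    return pd.concat(frames, ignore_index=True)
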
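"""Artifact-weighted GLM and max-statistic Monte-Carlo channel inference.

Per channel, the measured series is modelled as a weighted least-squares fit
of: two HRF-convolved condition boxcars (cluster, duration), an intercept,
slow-detrend sine/cosine pairs with periods of 2, 3, ..., n minutes up to the
session length, and optional baseline-shift steps after major artifacts.
Samples flagged as artifacts get weight zero and drop out of the fit.

A channel "responds" when the correlation between its observed series and its
fitted condition prediction exceeds chance.  Chance is calibrated with a
Westfall-Young style max-statistic Monte-Carlo procedure using a
Freedman-Lane circular-shift null: each iteration shifts every channel's
nuisance-model residual by one shared random offset of at least 30 s, adds
the (unshifted) nuisance fit back, refits the full model to the surrogate
series and records the maximum |r| across the channel family; the corrected
p of a channel is the fraction of null maxima at or above its observed |r|.
Shifting the residual rather than the raw series preserves autocorrelation
and cross-channel dependence while keeping the slow trends at their true
time positions, so their wrap-around discontinuity never enters the null;
at zero shift the surrogate equals the observed series exactly.  The
per-shift refit is evaluated in closed form via FFT circular
cross-correlations, which makes the statistic available for every possible
shift at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .hrf import CanonicalHRF, DEFAULT_HRF, block_regressor
from .recording import HbRecording
from .schedule import Schedule

__all__ = [
    "ChannelFit",
    "build_design",
    "fit_weighted",
    "responding_channels",
    "condition_columns",
]

MIN_SHIFT_S = 30.0


@dataclass
class ChannelFit:
    """Per-channel weighted-GLM result."""

    betas: dict
    se: dict
    z: dict  # beta / se, condition regressors
    #: correlation between the observed series and the fitted condition
    #: prediction, on weight-1 samples
    r: float
    residuals: np.ndarray = field(repr=False)
    n_used: int
    p_raw: float | None = None
    p_corrected: float | None = None
    responding: bool = False


def condition_columns(design: pd.DataFrame) -> list[str]:
    return [c for c in design.columns if c.startswith("cond_")]


def build_design(
    sched: Schedule,
    fs: float,
    n_samples: int | None = None,
    hrf: CanonicalHRF = DEFAULT_HRF,
    baseline_regressors: list | None = None,
) -> pd.DataFrame:
    """Assemble the session design matrix as a named-column DataFrame.

    Columns: ``intercept``; one ``cond_<name>`` HRF-convolved boxcar per
    condition; ``detrend_{sin,cos}_<p>min`` pairs for every whole-minute
    period from 2 up to the session length (none, with a warning, for
    sessions under 2 minutes); ``baseline_shift_<k>`` steps if supplied.
    """
    if n_samples is None:
        n_samples = int(round(sched.duration_s * fs))
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n_samples)}
    for cond in sched.config.conditions:
        cols[f"cond_{cond}"] = block_regressor(
            sched.condition_onsets(cond),
            sched.config.target_duration_s,
            n_samples,
            fs,
            hrf,
        )
    session_min = n_samples / fs / 60.0
    t = np.arange(n_samples) / fs
    periods = range(2, int(np.floor(session_min + 1e-9)) + 1)
    if not len(periods):
        warnings.warn("session shorter than 2 min: no detrend regressors", stacklevel=2)
    for p in periods:
        w = 2 * np.pi / (p * 60.0)
        # demeaned so the nuisance columns stay orthogonal to the intercept
        # even when the period does not divide the session length
        sin_col = np.sin(w * t)
        cos_col = np.cos(w * t)
        cols[f"detrend_sin_{p}min"] = sin_col - sin_col.mean()
        cols[f"detrend_cos_{p}min"] = cos_col - cos_col.mean()
    for k, reg in enumerate(baseline_regressors or [], start=1):
        cols[f"baseline_shift_{k}"] = np.asarray(reg, dtype=float)
    return pd.DataFrame(cols)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    from scipy import linalg

    if X.shape[0] < X.shape[1]:
        raise ValueError("fewer usable samples than regressors")
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = sorted(names[i] for i in piv[rank:])
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


def _weighted_corr(y: np.ndarray, yhat: np.ndarray) -> float:
    yc = y - y.mean()
    hc = yhat - yhat.mean()
    den = np.sqrt((yc @ yc) * (hc @ hc))
    return float(yc @ hc / den) if den > 0 else 0.0


def fit_weighted(
    y: np.ndarray, design: pd.DataFrame, weights: np.ndarray
) -> ChannelFit:
    """Weighted least squares of one channel with 0/1 sample weights.

    Artifacted samples (weight 0) are excluded outright; with all-ones
    weights this reduces to OLS.  ``r`` is the correlation between the
    observed series and the condition-regressor part of the fit, computed on
    the retained samples only.  Raises with the offending column names when
    the retained design is rank deficient, and when no samples remain.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape != y.shape or len(y) != len(design):
        raise ValueError("recording, design and weights lengths must agree")
    keep = w > 0
    if not keep.any():
        raise ValueError("no usable samples (all weights are zero)")
    names = list(design.columns)
    X = design.to_numpy()[keep]
    ys = y[keep]
    _check_rank(X, names)

    beta, _, _, _ = np.linalg.lstsq(X, ys, rcond=None)
    resid = ys - X @ beta
    dof = max(X.shape[0] - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))

    cond_idx = [i for i, c in enumerate(names) if c.startswith("cond_")]
    yhat_cond = X[:, cond_idx] @ beta[cond_idx]
    r = _weighted_corr(ys, yhat_cond)
    full_resid = np.full_like(y, np.nan)
    full_resid[keep] = resid

    betas = dict(zip(names, beta))
    ses = dict(zip(names, se))
    zs = {
        names[i]: (betas[names[i]] / ses[names[i]] if ses[names[i]] > 0 else 0.0)
        for i in cond_idx
    }
    return ChannelFit(
        betas=betas, se=ses, z=zs, r=r, residuals=full_resid, n_used=int(keep.sum())
    )


def _corr_all_shifts(
    y: np.ndarray,
    X: np.ndarray,
    w: np.ndarray,
    cond_idx: np.ndarray,
    nuis_idx: np.ndarray,
) -> np.ndarray:
    """Observed-vs-condition-prediction correlation for every surrogate shift.

    The Freedman-Lane surrogate at shift ``s`` is ``y*(s) = c + roll(e, s)``
    where ``c`` is the nuisance-only (reduced-model) weighted fit of ``y``
    and ``e = y - c`` its residual; the full design is refit to ``y*(s)``
    and r is the weighted correlation between ``y*(s)`` and the refit's
    condition prediction.  ``y*(0) = y``, so index 0 holds the observed
    statistic.  Every shift-dependent inner product (``X'W roll(e)``,
    ``sum w roll(e)``, ``sum w c roll(e)``, ``sum w roll(e)^2``) is a
    circular cross-correlation, evaluated by FFT; the Gram matrix ``X'WX``
    is shift-invariant, so all n shifts cost a handful of FFTs.
    """
    n, k = X.shape
    keep = w > 0
    beta_red, _, _, _ = np.linalg.lstsq(X[keep][:, nuis_idx], y[keep], rcond=None)
    c = X[:, nuis_idx] @ beta_red
    e = y - c

    Xw = X * w[:, None]
    G = Xw.T @ X
    A = np.linalg.inv(G)
    m = float(w.sum())
    b = w @ X  # weighted column sums of the design

    def corr_fft(g: np.ndarray, u: np.ndarray) -> np.ndarray:
        # circular cross-correlation: out[s] = sum_i g[i] * u[(i - s) mod n]
        return np.fft.irfft(np.fft.rfft(g, n) * np.conj(np.fft.rfft(u, n)), n)

    a_fix = Xw.T @ c
    a = a_fix[None, :] + np.fft.irfft(
        np.fft.rfft(Xw, n=n, axis=0) * np.conj(np.fft.rfft(e, n))[:, None], n, axis=0
    )  # (n, k): X'W y*(s)
    S1 = float(w @ c) + corr_fft(w, e)
    S2 = float(w @ (c * c)) + 2 * corr_fft(w * c, e) + corr_fft(w, e * e)

    B = a @ A.T  # full-model betas for every shift, (n, k)
    Bc = B[:, cond_idx]
    Gcc = G[np.ix_(cond_idx, cond_idx)]

    sum_yhat = Bc @ b[cond_idx]
    sum_yhat2 = np.einsum("si,ij,sj->s", Bc, Gcc, Bc)
    sum_y_yhat = np.einsum("si,si->s", a[:, cond_idx], Bc)

    num = sum_y_yhat - S1 * sum_yhat / m
    var_y = np.maximum(S2 - S1**2 / m, 0.0)
    var_h = np.maximum(sum_yhat2 - sum_yhat**2 / m, 0.0)
    den = np.sqrt(var_y * var_h)
    out = np.zeros(n)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def responding_channels(
    recording: HbRecording,
    design: pd.DataFrame,
    weights: np.ndarray | dict,
    signal: str = "oxy",
    n_mc: int = 10_000,
    alpha: float = 0.05,
    min_shift_s: float = MIN_SHIFT_S,
    seed: int = 0,
) -> list[ChannelFit]:
    """Fit every channel and decide responders by max-statistic Monte-Carlo.

    Each Monte-Carlo iteration applies one shared circular shift (uniform on
    ``[min_shift_s, session - min_shift_s]``) to every channel's
    nuisance-model residual, restores the nuisance fit, refits, and takes
    the maximum |r| over channels (Westfall-Young max statistic under a
    Freedman-Lane surrogate).  ``weights`` is either one weight vector
    shared by all channels or a ``{hemisphere: weights}`` dict (probe-level
    exclusion).  Returns the channel fits in recording order with ``p_raw``,
    ``p_corrected`` and ``responding`` filled in; the channel family for the
    correction is all channels of the recording.
    """
    Y = recording.oxy if signal == "oxy" else recording.total if signal == "total" else recording.deoxy
    n = recording.n_samples
    fs = recording.fs
    lo = int(np.ceil(min_shift_s * fs))
    hi = n - lo
    if hi < lo:
        raise ValueError("session too short for the minimum circular shift")
    rng = np.random.default_rng(seed)
    offsets = rng.integers(lo, hi + 1, size=n_mc)

    names = list(design.columns)
    cond_idx = np.array([i for i, c in enumerate(names) if c.startswith("cond_")])
    nuis_idx = np.array([i for i in range(len(names)) if i not in cond_idx])
    X = design.to_numpy()

    fits: list[ChannelFit] = []
    null_per_channel = []
    for i, ch in enumerate(recording.channels):
        w = weights[ch.hemisphere] if isinstance(weights, dict) else weights
        w = np.asarray(w, dtype=float)
        _check_rank(X[w > 0], names)
        fit = fit_weighted(Y[i], design, w)
        r_all = _corr_all_shifts(Y[i], X, w, cond_idx, nuis_idx)
        # the zero-shift surrogate is the observed series itself
        assert abs(r_all[0] - fit.r) < 1e-6
        null_per_channel.append(np.abs(r_all[offsets]))
        fits.append(fit)

    null = np.stack(null_per_channel)  # (n_ch, n_mc)
    null_max = null.max(axis=0)
    for i, fit in enumerate(fits):
        obs = abs(fit.r)
        fit.p_raw = float((1 + (null[i] >= obs).sum()) / (1 + n_mc))
        fit.p_corrected = float((1 + (null_max >= obs).sum()) / (1 + n_mc))
        fit.responding = fit.p_corrected < alpha
    return fits


def fit_report(recording: HbRecording, fits: list[ChannelFit]) -> pd.DataFrame:
    """Tidy per-channel, per-condition fit table."""
    rows = []
    for ch, fit in zip(recording.channels, fits):
        for col, z in fit.z.items():
            cond = col.removeprefix("cond_")
            rows.append(
                {
                    "hemisphere": ch.hemisphere,
                    "channel": ch.id,
                    "condition": cond,
                    "beta": fit.betas[col],
                    "se": fit.se[col],
                    "z": z,
                    "r": fit.r,
                    "p_raw": fit.p_raw,
                    "p_corrected": fit.p_corrected,
                    "responding": fit.responding,
                }
            )
    return pd.DataFrame(rows)
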
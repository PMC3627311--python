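"""FIR reconstruction of the hemodynamic response and laterality indices.

The finite-impulse-response model replaces the canonical-HRF assumption with
a bank of short time-shifted boxcars: per condition, bin *k* is 1 during
``[onset + k, onset + k + 1)`` seconds after every target-block onset of that
condition.  The fitted bin betas trace the average response waveform without
assuming its shape.  Twenty one-second bins (shifts 0-19 s) are fitted by
default.

The laterality index compares homologous left/right regions of interest:
``LI = (L - R) / (L + R)`` where L and R are the maximum absolute total-Hb
bin betas over the 0-9 s window within the ROI channels of each hemisphere.
With non-negative L and R the index lies in [-1, 1]; positive values mean
left dominance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geometry import Montage
from .recording import HbRecording
from .schedule import Schedule

__all__ = [
    "fir_design",
    "reconstruct",
    "roi_peak",
    "laterality_index",
    "laterality_table",
    "group_summary",
]

DEFAULT_N_BINS = 20
DEFAULT_BIN_S = 1.0


def fir_design(
    sched: Schedule,
    fs: float,
    n_samples: int | None = None,
    n_bins: int = DEFAULT_N_BINS,
    bin_s: float = DEFAULT_BIN_S,
    include_intercept: bool = True,
) -> pd.DataFrame:
    """Time-shifted boxcar design: ``n_bins`` columns per condition.

    Column ``fir_<condition>_<k>`` is 1 during ``[onset + k*bin_s,
    onset + (k+1)*bin_s)`` for every target onset of that condition.  Warns
    when the modelled window exceeds the shortest onset-to-onset gap (late
    bins then overlap the next block's early bins and their betas share
    variance).
    """
    if n_samples is None:
        n_samples = int(round(sched.duration_s * fs))
    onsets_all = np.sort([b.onset_s for b in sched.target_blocks])
    if onsets_all.size >= 2:
        min_gap = float(np.diff(onsets_all).min())
        if n_bins * bin_s > min_gap:
            warnings.warn(
                f"FIR window {n_bins * bin_s:.0f} s exceeds the shortest "
                f"target-onset gap ({min_gap:.1f} s)",
                stacklevel=2,
            )
    cols: dict[str, np.ndarray] = {}
    if include_intercept:
        cols["intercept"] = np.ones(n_samples)
    for cond in sched.config.conditions:
        onsets = sched.condition_onsets(cond)
        for k in range(n_bins):
            col = np.zeros(n_samples)
            for onset in onsets:
                i0 = int(round((onset + k * bin_s) * fs))
                i1 = int(round((onset + (k + 1) * bin_s) * fs))
                col[max(i0, 0) : min(i1, n_samples)] = 1.0
            cols[f"fir_{cond}_{k}"] = col
    return pd.DataFrame(cols)


def reconstruct(
    recording: HbRecording,
    design: pd.DataFrame,
    weights: np.ndarray | dict | None = None,
    subject: str | int = 0,
) -> pd.DataFrame:
    """Least-squares FIR betas per channel, condition and time bin.

    Oxy and deoxy are fitted separately against the same design; total-Hb
    betas are their bin-wise sum.  Returns a tidy frame with columns
    ``subject, hemisphere, channel, condition, bin, oxy_beta, deoxy_beta,
    total_beta``.  Raises on a rank-deficient (weighted) design.
    """
    from .glm import _check_rank

    names = list(design.columns)
    X = design.to_numpy()
    fir_cols = [(i, c) for i, c in enumerate(names) if c.startswith("fir_")]

    rows = []
    for i, ch in enumerate(recording.channels):
        if weights is None:
            w = np.ones(recording.n_samples)
        elif isinstance(weights, dict):
            w = np.asarray(weights[ch.hemisphere], dtype=float)
        else:
            w = np.asarray(weights, dtype=float)
        keep = w > 0
        if not keep.any():
            raise ValueError("no usable samples (all weights are zero)")
        Xs = X[keep]
        _check_rank(Xs, names)
        sol, _, _, _ = np.linalg.lstsq(
            Xs, np.stack([recording.oxy[i][keep], recording.deoxy[i][keep]], axis=1),
            rcond=None,
        )
        for j, col in fir_cols:
            _, cond, k = col.split("_", 2)
            rows.append(
                {
                    "subject": subject,
                    "hemisphere": ch.hemisphere,
                    "channel": ch.id,
                    "condition": cond,
                    "bin": int(k),
                    "oxy_beta": sol[j, 0],
                    "deoxy_beta": sol[j, 1],
                    "total_beta": sol[j, 0] + sol[j, 1],
                }
            )
    return pd.DataFrame(rows)


def roi_peak(
    estimate: pd.DataFrame,
    montage: Montage,
    window_s: tuple[float, float] = (0.0, 9.0),
    bin_s: float = DEFAULT_BIN_S,
    value: str = "total_beta",
) -> pd.DataFrame:
    """Peak |total-Hb| FIR beta in the ROI, per subject/condition/hemisphere.

    The maximum of ``|value|`` over the ROI channels of each hemisphere and
    the bins whose start falls inside ``window_s`` (half-open, so the default
    covers bins 0-8 of 1 s).  The signed beta at the peak is kept alongside.
    """
    lo, hi = window_s
    out = []
    for hemi in montage.hemispheres:
        roi_ids = [c.id for c in montage.roi_channels(hemi)]
        if not roi_ids:
            raise ValueError(f"empty ROI for hemisphere {hemi!r}")
        sub = estimate[
            (estimate["hemisphere"] == hemi)
            & estimate["channel"].isin(roi_ids)
            & (estimate["bin"] * bin_s >= lo)
            & (estimate["bin"] * bin_s < hi)
        ]
        if sub.empty:
            raise ValueError(f"no FIR betas in the ROI window for {hemi!r}")
        for (subj, cond), grp in sub.groupby(["subject", "condition"], observed=True):
            k = grp[value].abs().idxmax()
            out.append(
                {
                    "subject": subj,
                    "condition": cond,
                    "hemisphere": hemi,
                    "peak_abs": abs(grp.loc[k, value]),
                    "peak_signed": grp.loc[k, value],
                    "channel": grp.loc[k, "channel"],
                    "bin": grp.loc[k, "bin"],
                }
            )
    return pd.DataFrame(out)


def laterality_index(L: float, R: float) -> float:
    """``(L - R) / (L + R)``; NaN when the denominator is zero."""
    denom = L + R
    if denom == 0:
        return float("nan")
    return (L - R) / denom


def laterality_table(peaks: pd.DataFrame) -> pd.DataFrame:
    """Per subject and condition: L, R peak magnitudes and their LI."""
    wide = peaks.pivot_table(
        index=["subject", "condition"], columns="hemisphere",
        values="peak_abs", observed=True,
    ).reset_index()
    wide["li"] = [
        laterality_index(l, r) for l, r in zip(wide["left"], wide["right"])
    ]
    return wide.rename(columns={"left": "L", "right": "R"})[
        ["subject", "condition", "L", "R", "li"]
    ]


def group_summary(
    li: pd.DataFrame, group: str = "group", condition: str = "condition",
    value: str = "li",
) -> pd.DataFrame:
    """Descriptive LI statistics per group x condition cell.

    Mean, first and third quartile (linear-interpolation convention), and
    range, mirroring a box-with-whiskers summary; empty cells are omitted
    with a warning.
    """
    rows = []
    for (g, c), grp in li.groupby([group, condition], observed=True):
        vals = grp[value].dropna().to_numpy()
        if vals.size == 0:
            warnings.warn(f"empty cell ({g}, {c}) omitted", stacklevel=2)
            continue
        rows.append(
            {
                group: g,
                condition: c,
                "n": vals.size,
                "mean": vals.mean(),
                "q1": float(np.quantile(vals, 0.25)),
                "q3": float(np.quantile(vals, 0.75)),
                "min": vals.min(),
                "max": vals.max(),
            }
        )
    return pd.DataFrame(rows)
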
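"""Optical-density conversion, filtering, and motion-artifact handling.

The artifact criterion operates on band-passed (0.02-0.7 Hz) total-Hb: any
100 ms window whose excursion (max minus min) exceeds 1.5 mM*mm is flagged.
Flags are assessed at the level of probe pads, not single channels — head
movement disturbs every channel of a pad — so per-channel flags are pooled
across a pad before events are formed.  Flagged stretches are not corrected
but excluded, by zero weights in the downstream GLM; *major* artifacts
additionally spawn a step ("baseline-shift") regressor because the optical
coupling, and with it the signal baseline, may settle at a new level after a
large movement.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import signal
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ArtifactMask",
    "mbll_convert",
    "bandpass",
    "detect_artifacts",
    "artifact_weights",
    "baseline_shift_regressors",
    "DEFAULT_ARTIFACT_THRESHOLD",
    "DEFAULT_ARTIFACT_WINDOW_S",
]

DEFAULT_ARTIFACT_THRESHOLD = 1.5  # mM*mm excursion
DEFAULT_ARTIFACT_WINDOW_S = 0.1  # s
#: flagged events closer than this are merged into one
DEFAULT_MERGE_GAP_S = 0.5
#: a "major" artifact: excursion above this multiple of the threshold ...
MAJOR_EXCURSION_FACTOR = 2.0
#: ... or longer than this
MAJOR_DURATION_S = 1.0


@dataclass(frozen=True)
class MaskEvent:
    start_s: float
    end_s: float
    major: bool

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ArtifactMask:
    """Probe-level exclusion mask: one boolean series + event list per pad."""

    fs: float
    sample_mask: dict  # hemisphere -> bool array, True = artifacted
    events: dict  # hemisphere -> list[MaskEvent]

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.sample_mask.values())))

    def any_flagged(self) -> bool:
        return any(m.any() for m in self.sample_mask.values())


def mbll_convert(od_wl1, od_wl2, extinction_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Invert the modified Beer-Lambert law per sample.

    Solves ``E @ [oxy; deoxy] = [od1; od2]`` for each time point, where ``E``
    holds the two wavelengths' extinction coefficients for (oxy-Hb, deoxy-Hb).
    The optical pathlength stays folded into the result, hence units of
    mM*mm.  Raises on a singular matrix; warns when it is ill-conditioned.
    """
    od1 = np.asarray(od_wl1, dtype=float)
    od2 = np.asarray(od_wl2, dtype=float)
    E = np.asarray(extinction_matrix, dtype=float)
    if E.shape != (2, 2):
        raise ValueError("extinction matrix must be 2x2")
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValueError("extinction matrix is singular")
    if np.linalg.cond(E) > 1e3:
        warnings.warn("extinction matrix is ill-conditioned", stacklevel=2)
    hb = np.linalg.solve(E, np.stack([od1, od2]).reshape(2, -1))
    oxy = hb[0].reshape(od1.shape)
    deoxy = hb[1].reshape(od2.shape)
    return oxy, deoxy


def bandpass(series, fs: float, low: float = 0.02, high: float = 0.7, order: int = 3):
    """Zero-phase Butterworth band-pass (default 0.02-0.7 Hz).

    Applied forward-backward (``sosfiltfilt``), so the passband gain is ~1,
    DC is rejected, and no phase is introduced.  Works on 1-D series or
    ``(n_channels, n_samples)`` arrays along the last axis.
    """
    if fs <= 2 * high:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    x = np.asarray(series, dtype=float)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def _window_excursion_flags(x: np.ndarray, w: int, threshold: float) -> np.ndarray:
    """Flag every sample covered by a (w+1)-sample window with excursion > threshold."""
    n = x.shape[-1]
    if n <= w:
        return np.zeros(n, bool)
    sw = sliding_window_view(x, w + 1, axis=-1)
    exc = sw.max(-1) - sw.min(-1)
    winflag = exc > threshold
    if winflag.ndim > 1:  # pool across channels of the pad
        winflag = winflag.any(axis=0)
    delta = np.zeros(n + 1, dtype=int)
    starts = np.flatnonzero(winflag)
    np.add.at(delta, starts, 1)
    np.add.at(delta, np.minimum(starts + w + 1, n), -1)
    return np.cumsum(delta[:-1]) > 0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detect_artifacts(
    total_hb_bandpassed: np.ndarray,
    fs: float,
    hemispheres: list | None = None,
    threshold: float = DEFAULT_ARTIFACT_THRESHOLD,
    window_s: float = DEFAULT_ARTIFACT_WINDOW_S,
    merge_gap_s: float = DEFAULT_MERGE_GAP_S,
) -> ArtifactMask:
    """Flag motion artifacts on band-passed total-Hb, pooled per probe pad.

    Parameters
    ----------
    total_hb_bandpassed:
        ``(n_channels, n_samples)`` band-passed total-Hb array.
    hemispheres:
        Per-channel pad label; all channels of a pad share one mask.  Defaults
        to a single pad for all channels.
    threshold, window_s:
        A sliding window of ``window_s`` whose max-min excursion exceeds
        ``threshold`` flags all samples it covers.
    merge_gap_s:
        Events separated by less than this are merged.  Merged events are
        *major* when their pooled excursion exceeds ``2 * threshold`` or they
        last longer than 1 s.
    """
    x = np.atleast_2d(np.asarray(total_hb_bandpassed, dtype=float))
    n_ch, n = x.shape
    if hemispheres is None:
        hemispheres = ["all"] * n_ch
    if len(hemispheres) != n_ch:
        raise ValueError("need one pad label per channel")
    w = max(1, int(round(window_s * fs)))

    sample_mask: dict[str, np.ndarray] = {}
    events: dict[str, list[MaskEvent]] = {}
    for pad in dict.fromkeys(hemispheres):
        idx = [i for i, h in enumerate(hemispheres) if h == pad]
        flags = _window_excursion_flags(x[idx], w, threshold)
        # merge nearby events by closing short gaps
        gap = int(round(merge_gap_s * fs))
        merged = flags.copy()
        for a, b in _runs(~flags):
            if 0 < a and b < n and (b - a) < gap:
                merged[a:b] = True
        evs = []
        for a, b in _runs(merged):
            seg = x[idx][:, a:b]
            exc = float(seg.max() - seg.min()) if seg.size else 0.0
            dur = (b - a) / fs
            evs.append(
                MaskEvent(
                    start_s=a / fs,
                    end_s=b / fs,
                    major=exc > MAJOR_EXCURSION_FACTOR * threshold
                    or dur > MAJOR_DURATION_S,
                )
            )
        sample_mask[pad] = merged
        events[pad] = evs
    return ArtifactMask(fs=fs, sample_mask=sample_mask, events=events)


def artifact_weights(
    mask: np.ndarray | ArtifactMask,
    pad_samples: int = 1,
    hemisphere: str | None = None,
) -> np.ndarray:
    """0/1 GLM sample weights: zero over flagged stretches (plus padding).

    Accepts either a boolean sample mask or an :class:`ArtifactMask` (with
    ``hemisphere`` selecting the pad).  ``pad_samples`` extra samples on each
    side of every flagged run are also zeroed.
    """
    if isinstance(mask, ArtifactMask):
        if hemisphere is None and len(mask.sample_mask) == 1:
            hemisphere = next(iter(mask.sample_mask))
        flags = mask.sample_mask[hemisphere]
    else:
        flags = np.asarray(mask, dtype=bool)
    n = flags.size
    weights = np.ones(n)
    for a, b in _runs(flags):
        weights[max(0, a - pad_samples) : min(n, b + pad_samples)] = 0.0
    return weights


def baseline_shift_regressors(
    mask: ArtifactMask, n_samples: int, hemisphere: str | None = None
) -> list[np.ndarray]:
    """One step regressor per major artifact: 0 before its end, 1 after.

    These absorb a lasting baseline change after a large movement so it is
    not aliased into condition or detrend regressors.
    """
    if hemisphere is None and len(mask.sample_mask) == 1:
        hemisphere = next(iter(mask.sample_mask))
    regs = []
    for ev in mask.events[hemisphere]:
        if not ev.major:
            continue
        step = np.zeros(n_samples)
        step[int(round(ev.end_s * mask.fs)) :] = 1.0
        regs.append(step)
    return regs
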
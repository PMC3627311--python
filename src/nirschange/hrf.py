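"""Canonical double-gamma hemodynamic response and block regressors.

The canonical HRF is the difference of two gamma densities: a positive lobe
peaking a few seconds after stimulus onset and a delayed, smaller undershoot.
Gammas are parameterised directly by their mode (peak delay) and dispersion,
so ``peak_delay_s`` is the actual time-to-peak of the main lobe.  The curve is
normalised to unit peak amplitude; condition regressors are the convolution of
a block boxcar with this kernel, renormalised to unit peak so that a fitted
beta is directly interpretable as the response amplitude in mM*mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CanonicalHRF", "DEFAULT_HRF", "canonical_hrf", "block_regressor"]


@dataclass(frozen=True)
class CanonicalHRF:
    """Double-gamma HRF parameters (all times in seconds)."""

    peak_delay_s: float = 5.5
    undershoot_delay_s: float = 15.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    #: peak amplitude divided by undershoot amplitude
    ratio: float = 6.0
    #: kernel support; the response has decayed to ~0 by here
    duration_s: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_delay_s <= 0 or self.undershoot_delay_s <= 0:
            raise ValueError("delays must be positive")
        if self.peak_dispersion_s <= 0 or self.undershoot_dispersion_s <= 0:
            raise ValueError("dispersions must be positive")
        if self.ratio <= 0:
            raise ValueError("peak:undershoot ratio must be positive")


DEFAULT_HRF = CanonicalHRF()


def _gamma_mode(t: np.ndarray, mode: float, dispersion: float) -> np.ndarray:
    # gamma pdf with its mode at `mode`: shape a = 1 + mode/dispersion
    a = 1.0 + mode / dispersion
    return stats.gamma.pdf(t, a, scale=dispersion)


def canonical_hrf(t, params: CanonicalHRF = DEFAULT_HRF) -> np.ndarray:
    """Evaluate the canonical HRF at times ``t`` (seconds).

    Zero for ``t <= 0`` (onset convention) and normalised so the main-lobe
    peak equals 1.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    grid = np.linspace(0.0, params.duration_s, 2048)

    def raw(x: np.ndarray) -> np.ndarray:
        out = _gamma_mode(x, params.peak_delay_s, params.peak_dispersion_s)
        out = out - _gamma_mode(
            x, params.undershoot_delay_s, params.undershoot_dispersion_s
        ) / params.ratio
        return np.where(x > 0, out, 0.0)

    peak = raw(grid).max()
    vals = raw(t) / peak
    return float(vals[0]) if scalar else vals


def block_regressor(
    onsets_s,
    durations_s,
    n_samples: int,
    fs: float,
    params: CanonicalHRF = DEFAULT_HRF,
) -> np.ndarray:
    """Boxcar-convolved condition regressor, unit peak.

    Builds a 0/1 boxcar that is 1 during each ``[onset, onset+duration)``
    block, convolves it with the canonical HRF sampled at ``fs``, and rescales
    to unit maximum (an all-zero boxcar stays all-zero).
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    onsets = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    durations = np.atleast_1d(np.asarray(durations_s, dtype=float))
    if durations.size == 1:
        durations = np.full_like(onsets, durations[0])
    if onsets.shape != durations.shape:
        raise ValueError("onsets and durations must align")

    box = np.zeros(n_samples)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset * fs))
        i1 = int(round((onset + dur) * fs))
        box[max(i0, 0) : min(i1, n_samples)] = 1.0

    kernel_t = np.arange(0.0, params.duration_s, 1.0 / fs)
    kernel = canonical_hrf(kernel_t, params)
    reg = np.convolve(box, kernel)[:n_samples]
    peak = np.abs(reg).max()
    if peak > 0:
        reg = reg / peak
    return reg
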
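"""Ground-truth-known synthetic fNIRS recordings.

Simulates the block-design sessions the analysis pipeline consumes: each
channel's oxy-Hb trace is a sum of HRF-convolved condition responses
(amplitudes set per channel and condition by an :class:`EffectSpec`),
structured physiological noise (white sensor noise, slow sinusoidal drifts,
cardiac and respiratory oscillations with random phases) and optional motion
artifacts (spikes and baseline steps applied pad-wide, as real head movement
is).  Deoxy-Hb mirrors oxy-Hb with a smaller, opposite-signed amplitude, the
canonical stimulus response pattern.  The full set of injected parameters is
returned as a truth record so downstream estimates can be scored.

A forward modified-Beer-Lambert model converts Hb traces into dual-wavelength
optical-density changes for testing the inverse conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np

from .geometry import Channel, Montage
from .hrf import CanonicalHRF, DEFAULT_HRF, block_regressor
from .recording import HbRecording
from .schedule import Schedule

__all__ = [
    "EffectSpec",
    "NoiseModel",
    "ArtifactEvent",
    "EXTINCTION_COEFFS",
    "simulate_recording",
    "hb_to_optical_density",
]

#: nominal extinction coefficients [per wavelength row: (oxy-Hb, deoxy-Hb)],
#: arbitrary-but-consistent units; override via config for a calibrated setup
EXTINCTION_COEFFS: dict[str, np.ndarray] = {
    # ~780 / 830 nm continuous-wave pair
    "780_830": np.array([[0.71, 1.08], [0.97, 0.69]]),
    # ~670 / 850 nm pair
    "670_850": np.array([[0.32, 2.80], [1.06, 0.69]]),
}


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth response amplitudes (mM*mm) per condition.

    ``oxy_amplitude[condition]`` is the peak oxy-Hb response of a responding
    channel.  ROI channels respond at full amplitude scaled by their
    hemisphere factor; non-ROI channels respond at ``non_roi_scale`` of that.
    Deoxy-Hb responds at ``deoxy_ratio`` times the oxy amplitude (negative:
    the canonical oxy-up / deoxy-down pattern).
    """

    oxy_amplitude: dict = field(default_factory=lambda: {"cluster": 0.05, "duration": 0.05})
    deoxy_ratio: float = -0.3
    left_scale: float = 1.0
    right_scale: float = 1.0
    non_roi_scale: float = 0.25

    def __post_init__(self) -> None:
        for cond, amp in self.oxy_amplitude.items():
            if not np.isfinite(amp):
                raise ValueError(f"amplitude for {cond!r} must be finite")
        if not 0.0 <= abs(self.deoxy_ratio) <= 1.0:
            raise ValueError("deoxy/oxy magnitude ratio must lie in [0, 1]")

    def amplitude(self, channel: Channel, condition: str) -> float:
        base = float(self.oxy_amplitude.get(condition, 0.0))
        base *= self.left_scale if channel.hemisphere == "left" else self.right_scale
        if not channel.roi:
            base *= self.non_roi_scale
        return base

    @classmethod
    def null(cls) -> "EffectSpec":
        """No stimulus response anywhere (null-session ground truth)."""
        return cls(oxy_amplitude={})


@dataclass(frozen=True)
class NoiseModel:
    """Additive physiological + sensor noise (amplitudes in mM*mm).

    Drift terms are sinusoids with periods of at least a minute; cardiac and
    respiratory terms are fixed-frequency sinusoids with per-channel random
    phases.  Defaults are implementer-chosen magnitudes typical of
    continuous-wave recordings, kept well below the motion-artifact threshold.
    """

    white_sd: float = 0.03
    drift: tuple[tuple[float, float], ...] = ((60.0, 0.02), (180.0, 0.03))
    cardiac_hz: float = 2.5  # infant heart rate ~150 bpm
    cardiac_amp: float = 0.01
    respiratory_hz: float = 0.6
    respiratory_amp: float = 0.008

    def __post_init__(self) -> None:
        amps = [self.white_sd, self.cardiac_amp, self.respiratory_amp]
        amps += [a for _, a in self.drift]
        if any(a < 0 for a in amps):
            raise ValueError("noise amplitudes must be non-negative")
        if any(p < 60.0 for p, _ in self.drift):
            raise ValueError("drift periods must be at least 60 s")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(white_sd=0.0, drift=(), cardiac_amp=0.0, respiratory_amp=0.0)

    def sample(self, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
        t = np.arange(n) / fs
        out = rng.normal(0.0, self.white_sd, n) if self.white_sd > 0 else np.zeros(n)
        for period, amp in self.drift:
            out += amp * np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
        for hz, amp in ((self.cardiac_hz, self.cardiac_amp),
                        (self.respiratory_hz, self.respiratory_amp)):
            if amp > 0:
                out += amp * np.sin(2 * np.pi * hz * t + rng.uniform(0, 2 * np.pi))
        return out


@dataclass(frozen=True)
class ArtifactEvent:
    """One injected motion artifact.

    ``magnitude`` is the induced total-Hb excursion (split evenly between the
    oxy and deoxy traces); ``spike`` is a triangular pulse of the given width,
    ``step`` a lasting baseline offset.
    """

    time_s: float
    kind: str  # "spike" | "step"
    magnitude: float
    width_s: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in ("spike", "step"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")


def _artifact_trace(events: Sequence[ArtifactEvent], n: int, fs: float) -> np.ndarray:
    out = np.zeros(n)
    for ev in events:
        i0 = int(round(ev.time_s * fs))
        if not 0 <= i0 < n:
            raise ValueError(f"artifact at {ev.time_s} s falls outside the session")
        if ev.kind == "step":
            out[i0:] += ev.magnitude
        else:
            half = max(1, int(round(ev.width_s * fs / 2)))
            ramp = np.concatenate([np.linspace(0, 1, half + 1)[1:],
                                   np.linspace(1, 0, half + 1)[1:]])
            seg = ramp[: max(0, n - i0)]
            out[i0 : i0 + seg.size] += ev.magnitude * seg
    return out


def simulate_recording(
    sched: Schedule,
    montage: Montage,
    effects: EffectSpec | None = None,
    noise: NoiseModel | None = None,
    artifacts: Sequence[ArtifactEvent] = (),
    fs: float = 10.0,
    hrf: CanonicalHRF = DEFAULT_HRF,
    seed: int = 0,
    channels: Sequence[Channel] | None = None,
    tail_s: float = 0.0,
) -> HbRecording:
    """Simulate one session on a montage (or a channel subset).

    Per channel: ``oxy = sum_c amplitude(ch, c) * regressor_c + noise +
    artifacts`` with ``regressor_c`` the unit-peak HRF-convolved boxcar of
    condition ``c``; deoxy analogous via the effect spec's deoxy ratio.
    Identical seeds give identical output; the injected ground truth is
    attached as ``recording.truth``.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    effects = effects if effects is not None else EffectSpec()
    noise = noise if noise is not None else NoiseModel()
    if noise.cardiac_amp > 0 and fs <= 2 * noise.cardiac_hz:
        raise ValueError("sampling rate must exceed twice the cardiac frequency")
    if not sched.blocks:
        raise ValueError("schedule is empty")
    chans = tuple(channels) if channels is not None else montage.channels

    n = int(round((sched.duration_s + tail_s) * fs))
    rng = np.random.default_rng(seed)
    conditions = sched.config.conditions
    regs = {
        c: block_regressor(
            sched.condition_onsets(c), sched.config.target_duration_s, n, fs, hrf
        )
        for c in conditions
    }
    art = _artifact_trace(artifacts, n, fs)

    oxy = np.zeros((len(chans), n))
    deoxy = np.zeros((len(chans), n))
    amps: dict[str, dict[str, float]] = {}
    for i, ch in enumerate(chans):
        for c in conditions:
            a = effects.amplitude(ch, c)
            amps.setdefault(f"{ch.hemisphere}:{ch.id}", {})[c] = a
            oxy[i] += a * regs[c]
            deoxy[i] += a * effects.deoxy_ratio * regs[c]
        oxy[i] += noise.sample(n, fs, rng) + art / 2.0
        deoxy[i] += noise.sample(n, fs, rng) + art / 2.0

    truth = {
        "seed": seed,
        "fs": fs,
        "oxy_amplitudes": amps,
        "deoxy_ratio": effects.deoxy_ratio,
        "noise": {
            "white_sd": noise.white_sd,
            "drift": [list(d) for d in noise.drift],
            "cardiac_hz": noise.cardiac_hz,
            "cardiac_amp": noise.cardiac_amp,
            "respiratory_hz": noise.respiratory_hz,
            "respiratory_amp": noise.respiratory_amp,
        },
        "artifacts": [
            {"time_s": a.time_s, "kind": a.kind,
             "magnitude": a.magnitude, "width_s": a.width_s}
            for a in artifacts
        ],
        "hrf": {"peak_delay_s": hrf.peak_delay_s,
                "undershoot_delay_s": hrf.undershoot_delay_s,
                "ratio": hrf.ratio},
    }
    return HbRecording(fs=fs, channels=chans, oxy=oxy, deoxy=deoxy,
                       provenance="synthetic", truth=truth)


def hb_to_optical_density(
    recording: HbRecording,
    extinction: np.ndarray | str = "780_830",
    cond_warn_threshold: float = 1e3,
) -> np.ndarray:
    """Forward modified-Beer-Lambert model: OD changes at two wavelengths.

    ``OD[:, w, :] = E[w, 0] * oxy + E[w, 1] * deoxy`` for each channel; the
    returned array has shape ``(n_channels, 2, n_samples)``.  Raises on a
    singular extinction matrix and warns when its rows are nearly
    proportional (condition number above ``cond_warn_threshold``), since the
    inverse conversion then amplifies measurement noise.
    """
    E = EXTINCTION_COEFFS[extinction] if isinstance(extinction, str) else np.asarray(extinction, float)
    if E.shape != (2, 2):
        raise ValueError("extinction matrix must be 2x2")
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValueError("extinction matrix is singular")
    if np.linalg.cond(E) > cond_warn_threshold:
        warnings.warn(
            "extinction matrix is ill-conditioned; Hb separation will be noisy",
            stacklevel=2,
        )
    hb = np.stack([recording.oxy, recording.deoxy], axis=1)  # (ch, 2, n)
    return np.einsum("wk,ckn->cwn", E, hb)
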
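"""In-memory container for multichannel hemoglobin time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Channel

__all__ = ["HbRecording"]


@dataclass
class HbRecording:
    """Sampled oxy-/deoxy-Hb concentration-change series per channel.

    Concentration changes carry the unresolved optical pathlength and are
    expressed in mM*mm throughout.  ``oxy`` and ``deoxy`` are arrays of shape
    ``(n_channels, n_samples)`` aligned with ``channels``.
    """

    fs: float
    channels: tuple[Channel, ...]
    oxy: np.ndarray
    deoxy: np.ndarray
    provenance: str = "synthetic"  # "measured" | "converted" | "synthetic"
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.oxy = np.asarray(self.oxy, dtype=float)
        self.deoxy = np.asarray(self.deoxy, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n_ch = len(self.channels)
        if self.oxy.shape != self.deoxy.shape or self.oxy.shape[0] != n_ch:
            raise ValueError("oxy/deoxy shapes must be (n_channels, n_samples)")
        if np.isnan(self.oxy).any() or np.isnan(self.deoxy).any():
            raise ValueError("recording contains NaN samples")

    @property
    def n_samples(self) -> int:
        return self.oxy.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    @property
    def total(self) -> np.ndarray:
        """Total-Hb = oxy + deoxy, pointwise."""
        return self.oxy + self.deoxy

    def channel_index(self, hemisphere: str, channel_id: int) -> int:
        for i, ch in enumerate(self.channels):
            if ch.hemisphere == hemisphere and ch.id == channel_id:
                return i
        raise KeyError(f"channel ({hemisphere}, {channel_id}) not in recording")

    def hemisphere_indices(self, hemisphere: str) -> np.ndarray:
        idx = [i for i, ch in enumerate(self.channels) if ch.hemisphere == hemisphere]
        return np.array(idx, dtype=int)
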
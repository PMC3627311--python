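"""File formats: TSV time series, events, reports; JSON configs.

All tabular formats are UTF-8 TSV with '.' decimal separators and strict
column validation; every file the pipeline writes can be read back by this
module (round-trip property).  Validation failures raise
:class:`ValidationError` with 1-based line numbers where applicable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Channel, Montage, build_montage
from .recording import HbRecording
from .schedule import (
    Block,
    CONDITION_WORDS,
    Schedule,
    ScheduleConfig,
    Token,
)

__all__ = [
    "ValidationError",
    "write_recording",
    "read_recording",
    "write_od",
    "read_od",
    "write_events",
    "read_events",
    "write_truth",
]

RECORDING_COLUMNS = ["time_s", "channel_id", "hemisphere", "oxy", "deoxy"]
OD_COLUMNS = ["time_s", "channel_id", "hemisphere", "od_wl1", "od_wl2"]
EVENTS_COLUMNS = ["onset_s", "duration_s", "trial_type", "word", "token_index", "block_index"]


class ValidationError(ValueError):
    """A file or configuration failed validation."""


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no samples (empty file)") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValidationError(f"{path}: no samples")
    return df


def _check_numeric(df: pd.DataFrame, path, cols: list[str]) -> None:
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        bad = bad.union(df.index[df[col].isna()])
        if len(bad):
            # +2: one for the header row, one for 1-based numbering
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise ValidationError(
                f"{path}: malformed numeric value in column {col!r} at line(s) {lines}"
            )
        df[col] = vals


def write_recording(recording: HbRecording, path) -> None:
    """Long-format TSV: time_s, channel_id, hemisphere, oxy, deoxy."""
    n = recording.n_samples
    t = recording.times
    frames = []
    for i, ch in enumerate(recording.channels):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": t,
                    "channel_id": ch.id,
                    "hemisphere": ch.hemisphere,
                    "oxy": recording.oxy[i],
                    "deoxy": recording.deoxy[i],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_recording(path, montage: Montage | None = None) -> HbRecording:
    """Read a recording TSV; channel metadata comes from ``montage`` if given.

    The sampling rate is recovered from the time column and must be uniform.
    """
    df = _read_tsv(path, RECORDING_COLUMNS)
    _check_numeric(df, path, ["time_s", "oxy", "deoxy"])
    return _frame_to_recording(df, path, montage, value_cols=("oxy", "deoxy"))


def write_od(recording_channels, times, od: np.ndarray, path) -> None:
    """Dual-wavelength optical-density TSV (od shape: channels x 2 x samples)."""
    frames = []
    for i, ch in enumerate(recording_channels):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": times,
                    "channel_id": ch.id,
                    "hemisphere": ch.hemisphere,
                    "od_wl1": od[i, 0],
                    "od_wl2": od[i, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_od(path, montage: Montage | None = None):
    """Read an optical-density TSV: (channels, times, od array, fs)."""
    df = _read_tsv(path, OD_COLUMNS)
    _check_numeric(df, path, ["time_s", "od_wl1", "od_wl2"])
    rec = _frame_to_recording(df, path, montage, value_cols=("od_wl1", "od_wl2"))
    od = np.stack([rec.oxy, rec.deoxy], axis=1)
    return rec.channels, rec.times, od, rec.fs


def _frame_to_recording(df, path, montage, value_cols) -> HbRecording:
    chan_keys = list(dict.fromkeys(zip(df["hemisphere"], df["channel_id"])))
    a_list, b_list, channels = [], [], []
    fs = None
    for hemi, cid in chan_keys:
        sub = df[(df["hemisphere"] == hemi) & (df["channel_id"] == cid)]
        t = sub["time_s"].to_numpy()
        if len(t) < 2:
            raise ValidationError(f"{path}: channel ({hemi}, {cid}) has too few samples")
        dt = np.diff(t)
        if dt.min() <= 0 or (abs(dt - dt.mean()) > 1e-6 * max(dt.mean(), 1e-12)).any():
            raise ValidationError(f"{path}: non-uniform sampling for channel ({hemi}, {cid})")
        ch_fs = 1.0 / dt.mean()
        if fs is None:
            fs = ch_fs
        elif abs(ch_fs - fs) > 1e-9 * fs:
            raise ValidationError(f"{path}: sampling rate differs across channels")
        if montage is not None:
            channels.append(montage.channel(hemi, int(cid)))
        else:
            channels.append(
                Channel(id=int(cid), source=(0, 0), detector=(0, 0),
                        distance_mm=float("nan"), kind="short",
                        hemisphere=str(hemi), roi=False)
            )
        a_list.append(sub[value_cols[0]].to_numpy())
        b_list.append(sub[value_cols[1]].to_numpy())
    if len({len(a) for a in a_list}) != 1:
        raise ValidationError(f"{path}: channels have unequal lengths")
    return HbRecording(
        fs=float(fs), channels=tuple(channels),
        oxy=np.stack(a_list), deoxy=np.stack(b_list), provenance="measured",
    )


def write_events(sched: Schedule, path) -> None:
    """BIDS-style events TSV, one row per token plus its block context."""
    rows = []
    for bi, block in enumerate(sched.blocks):
        in_block = [
            tok for tok in sched.tokens
            if block.onset_s - 1e-9 <= tok.onset_s < block.end_s - 1e-9
        ]
        trial_type = block.condition if block.kind == "target" else "baseline"
        for tok in in_block:
            rows.append(
                {
                    "onset_s": tok.onset_s,
                    "duration_s": sched.config.soa_s,
                    "trial_type": trial_type,
                    "word": tok.word,
                    "token_index": tok.token_index,
                    "block_index": bi,
                }
            )
    pd.DataFrame(rows, columns=EVENTS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events(path, config: ScheduleConfig | None = None) -> Schedule:
    """Reconstruct a schedule from an events TSV.

    Block onsets/durations are recovered from token membership (tokens are
    spaced exactly one SOA apart, so a block spans ``n_tokens * soa``).
    Overlapping blocks fail validation.
    """
    df = _read_tsv(path, EVENTS_COLUMNS)
    _check_numeric(df, path, ["onset_s", "duration_s"])
    config = config or ScheduleConfig()
    blocks, tokens = [], []
    prev_end = -np.inf
    for bi, grp in df.groupby("block_index", sort=True):
        grp = grp.sort_values("onset_s")
        trial_type = grp["trial_type"].iloc[0]
        if (grp["trial_type"] != trial_type).any():
            raise ValidationError(f"{path}: mixed trial types in block {bi}")
        onset = float(grp["onset_s"].iloc[0])
        duration = len(grp) * config.soa_s
        if onset < prev_end - 1e-9:
            raise ValidationError(f"{path}: block {bi} overlaps the previous block")
        prev_end = onset + duration
        kind = "baseline" if trial_type == "baseline" else "target"
        condition = None if kind == "baseline" else str(trial_type)
        if condition is not None and condition not in CONDITION_WORDS:
            raise ValidationError(f"{path}: unknown trial type {condition!r}")
        blocks.append(Block(kind, condition, onset, duration))
        for _, row in grp.iterrows():
            tokens.append(
                Token(
                    onset_s=float(row["onset_s"]),
                    word=str(row["word"]),
                    token_index=int(row["token_index"]),
                )
            )
    return Schedule(config=config, blocks=tuple(blocks), tokens=tuple(tokens))


def write_truth(recording: HbRecording, path) -> None:
    """JSON side-car with the synthetic ground-truth record."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(recording.truth or {}, fh, indent=2)
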
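"""End-to-end pipeline: simulate -> preprocess -> fit -> FIR -> laterality.

A :class:`PipelineConfig` plus a master seed fully determines every output;
per-stage seeds are derived deterministically from the master seed so that
the simulation and the Monte-Carlo inference are independently reproducible.
Each run writes its stage outputs plus a JSON manifest with the seed, the
configuration echo, per-file SHA-256 checksums, and the headline counts
(samples flagged per pad, channels responding) so a null result is
inspectable rather than silent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import Montage, build_montage, layout_to_json
from .glm import build_design, fit_report, responding_channels
from .hrf import CanonicalHRF
from .io import ValidationError, write_events, write_recording, write_truth
from .fir import fir_design, laterality_table, reconstruct, roi_peak
from .preprocess import (
    artifact_weights,
    bandpass,
    baseline_shift_regressors,
    detect_artifacts,
)
from .schedule import ScheduleConfig, generate_infant_schedule
from .synth import ArtifactEvent, EffectSpec, NoiseModel, simulate_recording

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "fit", "hrf", "laterality", "report")


@dataclass
class PipelineConfig:
    """Fully serialisable run configuration (see JSON schema in docs)."""

    # probe geometry
    rows: int = 2
    cols: int = 4
    spacing_mm: float = 25.0
    include_long: bool = False
    roi_channels: tuple[int, ...] = (4, 6, 7)
    # schedule
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    # synthesis
    fs: float = 10.0
    effects: EffectSpec = field(default_factory=EffectSpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    artifacts: tuple[ArtifactEvent, ...] = ()
    hrf: CanonicalHRF = field(default_factory=CanonicalHRF)
    # preprocessing
    band_low_hz: float = 0.02
    band_high_hz: float = 0.7
    artifact_threshold: float = 1.5
    artifact_window_s: float = 0.1
    # inference
    n_mc: int = 10_000
    alpha: float = 0.05
    # FIR
    fir_bins: int = 20
    fir_bin_s: float = 1.0
    # master seed
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = {
            "fs": self.fs, "spacing_mm": self.spacing_mm,
            "band_low_hz": self.band_low_hz, "band_high_hz": self.band_high_hz,
            "artifact_threshold": self.artifact_threshold,
            "artifact_window_s": self.artifact_window_s,
            "alpha": self.alpha, "fir_bin_s": self.fir_bin_s,
        }
        for name, val in numeric.items():
            if not isinstance(val, (int, float)) or isinstance(val, bool) or val <= 0:
                raise ValidationError(f"{name} must be a positive number, got {val!r}")
        for name, val in (("rows", self.rows), ("cols", self.cols),
                          ("n_mc", self.n_mc), ("fir_bins", self.fir_bins),
                          ("seed", self.seed)):
            if not isinstance(val, int) or isinstance(val, bool):
                raise ValidationError(f"{name} must be an integer, got {val!r}")
        if not self.band_low_hz < self.band_high_hz:
            raise ValidationError("band_low_hz must be below band_high_hz")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed below 2**31."""
        idx = STAGES.index(stage)
        child = np.random.SeedSequence(self.seed, spawn_key=(idx,))
        return int(child.generate_state(1, np.uint32)[0] % (2**31))

    def to_json(self) -> str:
        doc = asdict(self)
        doc["effects"]["oxy_amplitude"] = dict(self.effects.oxy_amplitude)
        return json.dumps(doc, indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"config is not valid JSON: {exc}") from None
        try:
            if "schedule" in doc:
                sched = dict(doc["schedule"])
                if "baseline_jitter_s" in sched:
                    sched["baseline_jitter_s"] = tuple(sched["baseline_jitter_s"])
                if "conditions" in sched:
                    sched["conditions"] = tuple(sched["conditions"])
                doc["schedule"] = ScheduleConfig(**sched)
            if "effects" in doc:
                doc["effects"] = EffectSpec(**doc["effects"])
            if "noise" in doc:
                noise = dict(doc["noise"])
                if "drift" in noise:
                    noise["drift"] = tuple(tuple(d) for d in noise["drift"])
                doc["noise"] = NoiseModel(**noise)
            if "artifacts" in doc:
                doc["artifacts"] = tuple(ArtifactEvent(**a) for a in doc["artifacts"])
            if "hrf" in doc:
                doc["hrf"] = CanonicalHRF(**doc["hrf"])
            if "roi_channels" in doc:
                doc["roi_channels"] = tuple(doc["roi_channels"])
            return cls(**doc)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"invalid configuration: {exc}") from None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on one synthetic session and write the report bundle.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "nirschange",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.to_json()),
        "stages": {},
        "files": {},
    }

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- simulate -----------------------------------------------------------
    try:
        montage = build_montage(
            config.rows, config.cols, config.spacing_mm,
            config.include_long, config.roi_channels,
        )
        sched = generate_infant_schedule(
            config.schedule, seed=config.stage_seed("simulate"),
        )
        recording = simulate_recording(
            sched, montage, config.effects, config.noise, config.artifacts,
            fs=config.fs, hrf=config.hrf, seed=config.stage_seed("simulate"),
        )
        (out / "layout.json").write_text(layout_to_json(montage))
        write_events(sched, out / "events.tsv")
        write_recording(recording, out / "recording.tsv")
        write_truth(recording, out / "truth.json")
        manifest["stages"]["simulate"] = {
            "n_channels": len(recording.channels),
            "n_samples": recording.n_samples,
            "session_s": sched.duration_s,
        }
    except Exception as exc:  # noqa: BLE001
        fail("simulate", exc)

    # --- preprocess ---------------------------------------------------------
    try:
        total_bp = bandpass(
            recording.total, config.fs, config.band_low_hz, config.band_high_hz
        )
        mask = detect_artifacts(
            total_bp, config.fs,
            hemispheres=[c.hemisphere for c in recording.channels],
            threshold=config.artifact_threshold,
            window_s=config.artifact_window_s,
        )
        weights = {
            hemi: artifact_weights(mask, hemisphere=hemi)
            for hemi in mask.sample_mask
        }
        base_regs = []
        for hemi in mask.sample_mask:
            base_regs.extend(
                baseline_shift_regressors(mask, recording.n_samples, hemi)
            )
        ev_rows = [
            {"hemisphere": h, "start_s": e.start_s, "end_s": e.end_s, "major": e.major}
            for h, evs in mask.events.items() for e in evs
        ]
        pd.DataFrame(
            ev_rows, columns=["hemisphere", "start_s", "end_s", "major"]
        ).to_csv(out / "artifacts.tsv", sep="\t", index=False)
        manifest["stages"]["preprocess"] = {
            "samples_flagged": {h: int(m.sum()) for h, m in mask.sample_mask.items()},
            "n_major_artifacts": sum(e.major for evs in mask.events.values() for e in evs),
        }
    except Exception as exc:  # noqa: BLE001
        fail("preprocess", exc)

    # --- fit ----------------------------------------------------------------
    try:
        design = build_design(
            sched, config.fs, recording.n_samples, config.hrf, base_regs
        )
        fits = responding_channels(
            recording, design, weights,
            n_mc=config.n_mc, alpha=config.alpha,
            seed=config.stage_seed("fit"),
        )
        report = fit_report(recording, fits)
        report.to_csv(out / "fit_report.tsv", sep="\t", index=False)
        manifest["stages"]["fit"] = {
            "n_regressors": design.shape[1],
            "n_mc": config.n_mc,
            "channels_responding": int(
                report.drop_duplicates(["hemisphere", "channel"])["responding"].sum()
            ),
        }
    except Exception as exc:  # noqa: BLE001
        fail("fit", exc)

    # --- hrf (FIR) ----------------------------------------------------------
    try:
        fdesign = fir_design(
            sched, config.fs, recording.n_samples,
            n_bins=config.fir_bins, bin_s=config.fir_bin_s,
        )
        estimate = reconstruct(recording, fdesign, weights)
        estimate.to_csv(out / "hrf_estimates.tsv", sep="\t", index=False)
        manifest["stages"]["hrf"] = {"n_bins": config.fir_bins}
    except Exception as exc:  # noqa: BLE001
        fail("hrf", exc)

    # --- laterality ---------------------------------------------------------
    try:
        peaks = roi_peak(estimate, montage, bin_s=config.fir_bin_s)
        li = laterality_table(peaks)
        li.to_csv(out / "laterality.tsv", sep="\t", index=False)
        manifest["stages"]["laterality"] = {
            "li": {
                f"{row.condition}": None if pd.isna(row.li) else float(row.li)
                for row in li.itertuples()
            }
        }
    except Exception as exc:  # noqa: BLE001
        fail("laterality", exc)

    # --- report -------------------------------------------------------------
    for name in ("layout.json", "events.tsv", "recording.tsv", "truth.json",
                 "artifacts.tsv", "fit_report.tsv", "hrf_estimates.tsv",
                 "laterality.tsv"):
        manifest["files"][name] = _sha256(out / name)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
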
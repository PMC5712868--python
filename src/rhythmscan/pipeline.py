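"""Integrated arrhythmia pipeline over whole records.

Stage order follows the integrated flow: resample to 200 Hz, cut 5-min
windows, detect QRS, extract features, rule-based VPC, RR correction + AF
decision per window, optional MLP APC stage, then the raw-signal 2-s VF
pass.  AF works on the RR series and VF on the raw signal, so the two run
on disjoint representations of the same window; when the VF override is
enabled, beats falling inside a detected VF episode have any ectopic label
cleared (a fibrillating signal has no meaningful beat classes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import af_detector, beat_classifiers, qrs_beats, vf_detector
from .beat_classifiers import MlpModel
from .config import PipelineConfig
from .signal_io import Annotation, EcgRecord, resample, slice_windows

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, window: int, cause: Exception):
        super().__init__(f"stage {stage!r} failed on window {window}: {cause}")
        self.stage, self.window = stage, window


@dataclass
class PipelineResult:
    record_id: str
    fs: float
    n_samples: int
    beat_samples: list[int]
    beat_labels: list[str]
    af_decisions: list[af_detector.AfDecision]
    af_episodes: list[tuple[int, int]]        # half-open sample intervals
    vf_episodes: list[tuple[int, int]]
    vf_ratios: list[float]                    # one per 2-s segment
    overridden_beats: list[int] = field(default_factory=list)
    config_hash: str = ""
    version: str = "0.1.0"

    def to_annotation(self) -> Annotation:
        eps = [(s, e, "AF") for s, e in self.af_episodes]
        eps += [(s, e, "VF") for s, e in self.vf_episodes]
        return Annotation(list(zip(self.beat_samples, self.beat_labels)), eps)

    def to_json(self) -> str:
        d = {
            "record_id": self.record_id, "fs": self.fs,
            "n_samples": self.n_samples,
            "beat_samples": [int(s) for s in self.beat_samples],
            "beat_labels": self.beat_labels,
            "af_decisions": [
                {"window_id": a.window_id, "sampen": a.sampen,
                 "is_af": a.is_af, "n_beats": a.n_beats}
                for a in self.af_decisions
            ],
            "af_episodes": [[int(s), int(e)] for s, e in self.af_episodes],
            "vf_episodes": [[int(s), int(e)] for s, e in self.vf_episodes],
            "vf_ratios": [float(r) if np.isfinite(r) else None
                          for r in self.vf_ratios],
            "overridden_beats": [int(i) for i in self.overridden_beats],
            "config_hash": self.config_hash, "version": self.version,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineResult":
        d = json.loads(text)
        from .config import AfConfig

        return cls(
            record_id=d["record_id"], fs=d["fs"], n_samples=d["n_samples"],
            beat_samples=d["beat_samples"], beat_labels=d["beat_labels"],
            af_decisions=[
                af_detector.AfDecision(a["window_id"], a["sampen"],
                                       a["is_af"], a["n_beats"], AfConfig())
                for a in d["af_decisions"]
            ],
            af_episodes=[tuple(e) for e in d["af_episodes"]],
            vf_episodes=[tuple(e) for e in d["vf_episodes"]],
            vf_ratios=[float("nan") if r is None else r for r in d["vf_ratios"]],
            overridden_beats=d["overridden_beats"],
            config_hash=d["config_hash"], version=d["version"],
        )


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(rec: EcgRecord, cfg: PipelineConfig | None = None,
                 model: MlpModel | None = None) -> PipelineResult:
    """Run the full integrated detection flow on one record."""
    cfg = cfg or PipelineConfig()
    if cfg.apc_stage_enabled and model is None:
        raise ValueError("APC stage enabled but no model supplied")
    rec = resample(rec, cfg.target_fs)
    fs = rec.fs
    windows = slice_windows(rec, cfg.af.window_s, cfg.af.min_window_s)
    win_samples = int(round(cfg.af.window_s * fs))
    seg_samples = int(round(cfg.vf.segment_s * fs))

    all_samples: list[int] = []
    all_labels: list[str] = []
    af_decisions: list[af_detector.AfDecision] = []
    vf_flags: list[bool] = []
    vf_ratios: list[float] = []

    for w, win in enumerate(windows):
        offset = w * win_samples
        try:
            beats = qrs_beats.detect_qrs(win, cfg.qrs)
        except Exception as e:  # pragma: no cover - defensive
            raise StageError("detect_qrs", w, e) from e
        try:
            feats = qrs_beats.extract_beat_features(win, beats, cfg.features)
            beats = beat_classifiers.classify_vpc(feats, beats, cfg.vpc)
        except Exception as e:
            raise StageError("classify_vpc", w, e) from e
        try:
            af_decisions.append(
                af_detector.detect_af_window(beats, cfg.af, window_id=win.record_id)
            )
        except Exception as e:
            raise StageError("detect_af_window", w, e) from e
        if cfg.apc_stage_enabled and model is not None:
            try:
                beats = beat_classifiers.classify_apc(model, feats, beats)
            except Exception as e:
                raise StageError("classify_apc", w, e) from e
        try:
            segs = vf_detector.segment_2s(win, cfg.vf)
            for seg in segs:
                b = vf_detector.band_peaks(seg, fs, cfg.vf)
                vf_flags.append(vf_detector.classify_vf_segment(b))
                vf_ratios.append(b.ratio)
            # keep the segment grid aligned with 2-s slots across windows
            vf_flags += [False] * (win_samples // seg_samples - len(segs)) \
                if win.partial else []
        except Exception as e:
            raise StageError("vf_detector", w, e) from e
        labels = ["N" if lab == "?" else lab for lab in beats.labels]
        all_samples += [int(s) + offset for s in beats.beat_samples]
        all_labels += labels
        log.info("window %d: %d beats, af=%s", w, len(beats),
                 af_decisions[-1].is_af)

    af_eps = af_detector.af_windows_to_episodes(af_decisions, win_samples)
    af_eps = [(s, min(e, len(rec))) for s, e in af_eps]
    vf_eps = vf_detector.vf_segments_to_episodes(vf_flags, seg_samples,
                                                 cfg.vf.bridge_gaps)
    vf_eps = [(s, min(e, len(rec))) for s, e in vf_eps]

    overridden: list[int] = []
    if cfg.vf.override_beats and vf_eps:
        for i, s in enumerate(all_samples):
            if any(a <= s < b for a, b in vf_eps):
                if all_labels[i] in ("V", "S"):
                    overridden.append(i)
                    all_labels[i] = "N"

    return PipelineResult(
        record_id=rec.record_id, fs=fs, n_samples=len(rec),
        beat_samples=all_samples, beat_labels=all_labels,
        af_decisions=af_decisions, af_episodes=af_eps, vf_episodes=vf_eps,
        vf_ratios=vf_ratios, overridden_beats=overridden,
        config_hash=_config_hash(cfg),
    )
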
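"""Pipeline configuration.

Every tunable threshold used anywhere in the package lives here, with its
default, so a single YAML file can reconfigure a whole run.  Defaults are the
published constants where the underlying algorithm has them (the Hamilton
detector chain, the 3.96 spectral ratio) and documented package choices where
it does not (the VPC rule factors, the AF entropy threshold, MLP
hyperparameters).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class QrsConfig:
    """Hamilton-style QRS detector constants (all at 200 Hz)."""

    bandpass_low_hz: float = 8.0
    bandpass_high_hz: float = 16.0
    integration_ms: float = 80.0
    refractory_ms: float = 200.0
    twave_window_ms: float = 360.0
    threshold_factor: float = 0.3125  # peak/noise mixing factor
    searchback_factor: float = 1.5    # multiples of mean RR triggering search-back
    searchback_threshold: float = 0.5  # fraction of detection threshold
    peak_memory: int = 8              # running averages use this many recent peaks
    r_refine_ms: float = 80.0         # half-window for R-peak refinement on raw signal


@dataclass
class FeatureConfig:
    """Beat-feature fiducial measurement."""

    qrs_slope_fraction: float = 0.10   # onset/offset: deviation < 10% of R amplitude
    qrs_scan_ms: float = 120.0         # max scan distance from R for onset/offset
    p_search_min_ms: float = 40.0      # P-wave window before QRS onset
    p_search_max_ms: float = 240.0
    neighborhood: int = 10             # beats pooled on each side for RR stats


@dataclass
class VpcConfig:
    width_factor: float = 1.5          # QRS duration vs running-median width
    prematurity_factor: float = 0.85   # rr_prev vs rr_mean_20
    median_window: int = 50            # beats in the running QRS-width median


@dataclass
class MlpConfig:
    n_hidden: int = 10
    learning_rate: float = 0.01
    max_epochs: int = 500
    patience: int = 20
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    class_weighting: bool = True


@dataclass
class AfConfig:
    m: int = 2
    r_factor: float = 0.2              # tolerance r = r_factor * SD(word values)
    threshold: float = 1.18            # theta_AF on SampEn(wv); calibrated by
                                       # `rhythmscan calibrate-af` on the
                                       # default synthetic corpus (seed 0)
    min_beats: int = 100               # per 5-min window
    window_s: float = 300.0
    min_window_s: float = 60.0         # partial tail windows shorter than this drop


@dataclass
class VfConfig:
    segment_s: float = 2.0
    vf_band: tuple[float, float] = (2.61, 4.95)      # inclusive both ends
    nvf_band: tuple[float, float] = (0.5, 2.61)      # exclusive both ends
    nvf2_band: tuple[float, float] = (4.95, 10.0)    # exclusive low, inclusive high
    ratio_threshold: float = 3.96
    bridge_gaps: int = 1               # negative segments bridged inside an episode
    override_beats: bool = True        # VF episodes override beat labels


@dataclass
class Ec57Config:
    beat_tolerance_s: float = 0.15
    excluded_records: tuple[str, ...] = ("102", "104", "107", "217", "2202", "8205")


@dataclass
class PipelineConfig:
    target_fs: float = 200.0
    qrs: QrsConfig = field(default_factory=QrsConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    vpc: VpcConfig = field(default_factory=VpcConfig)
    mlp: MlpConfig = field(default_factory=MlpConfig)
    af: AfConfig = field(default_factory=AfConfig)
    vf: VfConfig = field(default_factory=VfConfig)
    ec57: Ec57Config = field(default_factory=Ec57Config)
    apc_stage_enabled: bool = False    # needs a trained model

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "qrs", "features", "vpc", "mlp", "af", "vf", "ec57"
            ):
                sub_cls = {
                    "qrs": QrsConfig, "features": FeatureConfig, "vpc": VpcConfig,
                    "mlp": MlpConfig, "af": AfConfig, "vf": VfConfig,
                    "ec57": Ec57Config,
                }[f.name]
                val = sub_cls(**val)
            kwargs[f.name] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
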
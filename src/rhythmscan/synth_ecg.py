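"""Seeded synthetic single-lead ECG with exact ground truth.

Records are assembled from a rhythm plan (ordered ``(rhythm, duration_s)``
segments) and rendered as sums of Gaussian waves — one P-QRS-T template per
beat — plus rhythm-specific modifications:

* sinus:  beats at the configured rate with small Gaussian RR jitter;
  atrial (APC) and ventricular (VPC) premature complexes are inserted at
  the configured events-per-minute rates.  An APC is early (~0.7x the mean
  RR) with an altered P wave; a VPC is early, wide (double QRS width, no P)
  and followed by a compensatory pause.
* AF:     RR drawn i.i.d. from the configured law (default uniform
  0.35-1.0 s), P waves suppressed, and a small irregular fibrillatory
  baseline added.
* VF:     no discrete beats; an amplitude-modulated oscillation whose
  instantaneous frequency follows an Ornstein-Uhlenbeck walk clipped to
  the configured band (default 3-5 Hz).

Ground-truth beat marks land exactly on the rendered R-peak samples and
episode boundaries exactly on the plan boundaries, so detector scores
against the returned :class:`~rhythmscan.signal_io.Annotation` measure the
detectors, not the bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .signal_io import Annotation, EcgRecord

__all__ = ["SynthConfig", "WaveSpec", "generate_record", "make_corpus",
           "template_qrs_duration"]


# Gaussian wave parameters: (time offset from R in s, amplitude mV, sigma s)
DEFAULT_WAVES = {
    "P": (-0.16, 0.12, 0.022),
    "Q": (-0.032, -0.08, 0.009),
    "R": (0.0, 1.0, 0.011),
    "S": (0.032, -0.14, 0.010),
    "T": (0.22, 0.28, 0.045),
}


@dataclass
class WaveSpec:
    """Per-beat morphology switches applied to the default template."""

    qrs_width_scale: float = 1.0
    qrs_amp_scale: float = 1.0
    p_amp_scale: float = 1.0
    p_shift_s: float = 0.0


@dataclass
class SynthConfig:
    fs: float = 200.0
    rhythm_plan: list[tuple[str, float]] = field(
        default_factory=lambda: [("SINUS", 300.0)]
    )
    sinus_rate_bpm: float = 70.0
    sinus_rr_jitter_s: float = 0.03
    apc_rate_per_min: float = 0.0
    vpc_rate_per_min: float = 0.0
    apc_prematurity: float = 0.7
    vpc_prematurity: float = 0.6
    af_rr_law: tuple[str, tuple[float, float]] = ("uniform", (0.35, 1.0))
    af_fibrillatory_mv: float = 0.05
    vf_freq_band: tuple[float, float] = (3.0, 5.0)
    vf_amp_mv: float = 0.8
    noise_snr_db: float | None = None
    baseline_wander_mv: float = 0.0
    mains_hz: float | None = None
    mains_mv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for _, d in self.rhythm_plan):
            raise ValueError("plan durations must be positive")
        lo, hi = self.vf_freq_band
        if not (0.5 < lo < hi <= 10.0):
            raise ValueError("vf_freq_band must lie within (0.5, 10] Hz")


def _add_gauss(sig: np.ndarray, fs: float, center_s: float, amp: float,
               sigma_s: float) -> None:
    half = int(math.ceil(5 * sigma_s * fs))
    c = center_s * fs
    lo = max(0, int(round(c)) - half)
    hi = min(len(sig), int(round(c)) + half + 1)
    if hi <= lo:
        return
    t = (np.arange(lo, hi) - c) / fs
    sig[lo:hi] += amp * np.exp(-0.5 * (t / sigma_s) ** 2)


def _render_beat(sig: np.ndarray, fs: float, r_sample: int,
                 spec: WaveSpec) -> None:
    r_s = r_sample / fs
    for name, (off, amp, sigma) in DEFAULT_WAVES.items():
        if name == "P":
            if spec.p_amp_scale == 0.0:
                continue
            _add_gauss(sig, fs, r_s + off + spec.p_shift_s,
                       amp * spec.p_amp_scale, sigma)
        elif name in ("Q", "R", "S"):
            _add_gauss(sig, fs, r_s + off * spec.qrs_width_scale,
                       amp * spec.qrs_amp_scale,
                       sigma * spec.qrs_width_scale)
        else:
            _add_gauss(sig, fs, r_s + off, amp, sigma)


def template_qrs_duration(width_scale: float = 1.0, fs: float = 2000.0,
                          threshold: float = 0.10,
                          hold_s: float = 0.020) -> float:
    """QRS duration of the rendered template, measured on the waveform.

    Renders an isolated Q/R/S complex on a fine grid and measures the span
    around R where the waveform deviates from baseline by more than
    ``threshold`` of the R amplitude, jumping sub-threshold gaps shorter
    than ``hold_s`` — the same fiducial convention the feature extractor
    applies to real signals, so this is the ground truth for
    ``qrs_duration`` tests.
    """
    sig = np.zeros(int(2.0 * fs))
    r = int(1.0 * fs)
    for name in ("Q", "R", "S"):
        off, amp, sigma = DEFAULT_WAVES[name]
        _add_gauss(sig, fs, r / fs + off * width_scale, amp, sigma * width_scale)
    dev = np.abs(sig) > threshold * abs(sig[r])
    hold = max(1, int(round(hold_s * fs)))

    def bound(step: int) -> int:
        j, run, last = r, 0, r
        while 0 < j < len(sig) - 1:
            j += step
            if dev[j]:
                run = 0
                last = j
            else:
                run += 1
                if run >= hold:
                    break
        return last

    return (bound(+1) - bound(-1)) / fs


def _draw_af_rr(rng: np.random.Generator, law: tuple[str, tuple]) -> float:
    name, params = law
    if name == "uniform":
        return float(rng.uniform(*params))
    if name == "lognormal":
        mu, sigma = params
        return float(rng.lognormal(mu, sigma))
    raise ValueError(f"unknown AF RR law {name!r}")


def _ou_frequency(rng: np.random.Generator, n: int, fs: float,
                  band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    f0 = 0.5 * (lo + hi)
    theta, sigma = 1.0, 0.4  # 1/s relaxation, Hz/sqrt(s) diffusion
    dt = 1.0 / fs
    f = np.empty(n)
    f[0] = f0
    shocks = rng.normal(0.0, sigma * math.sqrt(dt), size=n - 1) if n > 1 else []
    for i in range(1, n):
        f[i] = f[i - 1] + theta * (f0 - f[i - 1]) * dt + shocks[i - 1]
    return np.clip(f, lo, hi)


def generate_record(config: SynthConfig,
                    record_id: str = "synth") -> tuple[EcgRecord, Annotation]:
    """Render one record plus its exact ground-truth annotation."""
    fs = config.fs
    total_s = sum(d for _, d in config.rhythm_plan)
    n = int(round(total_s * fs))
    sig = np.zeros(n)
    rng = np.random.default_rng(config.seed)
    beats: list[tuple[int, str]] = []
    episodes: list[tuple[int, int, str]] = []

    mean_rr = 60.0 / config.sinus_rate_bpm
    if total_s * config.sinus_rate_bpm / 60.0 < 1:
        raise ValueError("infeasible plan: rate x duration < 1 beat")

    seg_start_s = 0.0
    # carry beat phase across segment boundaries
    t = 0.4 * mean_rr
    for rhythm, dur in config.rhythm_plan:
        seg_end_s = seg_start_s + dur
        s0, s1 = int(round(seg_start_s * fs)), int(round(seg_end_s * fs))
        episodes.append((s0, min(s1, n), rhythm))
        if rhythm == "VF":
            m = s1 - s0
            f_inst = _ou_frequency(rng, m, fs, config.vf_freq_band)
            phase = 2 * math.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * math.pi)
            am = 1.0 + 0.3 * np.sin(
                2 * math.pi * 0.4 * np.arange(m) / fs + rng.uniform(0, 2 * math.pi)
            )
            sig[s0:s1] += config.vf_amp_mv * am * np.sin(phase)
            t = seg_end_s + 0.4 * mean_rr  # resume beats after the VF block
            seg_start_s = seg_end_s
            continue
        if rhythm == "AF":
            # fibrillatory baseline: narrowband irregular wavelets ~6 Hz
            m = s1 - s0
            fib_f = _ou_frequency(rng, m, fs, (5.0, 7.0))
            fib_phase = 2 * math.pi * np.cumsum(fib_f) / fs
            sig[s0:s1] += config.af_fibrillatory_mv * np.sin(fib_phase)
            if t < seg_start_s:
                t = seg_start_s + _draw_af_rr(rng, config.af_rr_law)
            while t < seg_end_s:
                r = int(round(t * fs))
                if 0 <= r < n:
                    beats.append((r, "N"))
                    _render_beat(sig, fs, r, WaveSpec(p_amp_scale=0.0))
                t += _draw_af_rr(rng, config.af_rr_law)
            seg_start_s = seg_end_s
            continue
        # sinus (and OTHER): jittered beats with optional APC/VPC events
        if t < seg_start_s:
            t = seg_start_s + 0.4 * mean_rr
        p_apc = config.apc_rate_per_min * mean_rr / 60.0
        p_vpc = config.vpc_rate_per_min * mean_rr / 60.0
        last_normal = False  # premature complexes only follow a normal beat
        while t < seg_end_s:
            u = rng.uniform() if last_normal else 1.0
            last_normal = True
            jitter = rng.normal(0.0, config.sinus_rr_jitter_s)
            if u < p_vpc:
                t_ect = t - (1.0 - config.vpc_prematurity) * mean_rr
                r = int(round(t_ect * fs))
                if 0 <= r < n and t_ect < seg_end_s:
                    beats.append((r, "V"))
                    _render_beat(sig, fs, r,
                                 WaveSpec(qrs_width_scale=2.0,
                                          qrs_amp_scale=1.25, p_amp_scale=0.0))
                last_normal = False
                t += mean_rr + jitter  # compensatory: next sinus beat on schedule
            elif u < p_vpc + p_apc:
                t_ect = t - (1.0 - config.apc_prematurity) * mean_rr
                r = int(round(t_ect * fs))
                if 0 <= r < n and t_ect < seg_end_s:
                    beats.append((r, "S"))
                    _render_beat(sig, fs, r,
                                 WaveSpec(p_amp_scale=0.5, p_shift_s=0.03))
                last_normal = False
                t = t_ect + mean_rr + jitter  # non-compensatory reset
            else:
                r = int(round(t * fs))
                if 0 <= r < n:
                    beats.append((r, "N"))
                    _render_beat(sig, fs, r, WaveSpec())
                t += mean_rr + jitter
        seg_start_s = seg_end_s

    # de-duplicate / enforce strictly increasing beat marks
    beats.sort()
    dedup: list[tuple[int, str]] = []
    for s, lab in beats:
        if dedup and s <= dedup[-1][0]:
            continue
        dedup.append((s, lab))

    if config.baseline_wander_mv > 0:
        f_bw = rng.uniform(0.1, 0.4)
        sig += config.baseline_wander_mv * np.sin(
            2 * math.pi * f_bw * np.arange(n) / fs + rng.uniform(0, 2 * math.pi)
        )
    if config.mains_hz is not None and config.mains_mv > 0:
        sig += config.mains_mv * np.sin(
            2 * math.pi * config.mains_hz * np.arange(n) / fs
        )
    if config.noise_snr_db is not None:
        p_sig = float(np.mean(sig**2))
        p_noise = p_sig / (10.0 ** (config.noise_snr_db / 10.0))
        sig += rng.normal(0.0, math.sqrt(p_noise), size=n)

    rec = EcgRecord(sig, fs, record_id)
    ann = Annotation(dedup, episodes)
    return rec, ann


def make_corpus(n_records: int, template_configs: list[SynthConfig] | SynthConfig,
                seed: int = 0):
    """Generate ``n_records`` records with per-record seeds derived from ``seed``.

    Template configs are cycled when fewer than ``n_records`` are given.
    Returns ``(records, summary)`` where summary counts beats per class and
    episodes per rhythm across the corpus.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if isinstance(template_configs, SynthConfig):
        template_configs = [template_configs]
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_records)]
    out = []
    summary = {"beats": {"N": 0, "S": 0, "V": 0, "Q": 0},
               "episodes": {"SINUS": 0, "AF": 0, "VF": 0, "OTHER": 0}}
    import dataclasses as _dc

    for k in range(n_records):
        tpl = template_configs[k % len(template_configs)]
        cfg = _dc.replace(tpl, seed=child_seeds[k])
        rec, ann = generate_record(cfg, record_id=f"synth{k:03d}")
        out.append((rec, ann))
        for _, lab in ann.beat_marks:
            summary["beats"][lab] = summary["beats"].get(lab, 0) + 1
        for _, _, r in ann.rhythm_episodes:
            summary["episodes"][r] += 1
    return out, summary
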
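"""Hamilton-style QRS detection and per-beat feature extraction.

The detector follows the classic open-source recipe: band-pass 8-16 Hz,
differentiate, rectify, 80 ms moving-window integration, then adaptive
peak/noise thresholding with a 200 ms refractory period, slope-based T-wave
rejection and RR-driven search-back.  R-peak positions are refined on the
raw signal (largest absolute deviation near the detection point), so beat
sample indices land on the R wave itself rather than on the integrated
envelope.

Per-beat features are the interval/morphology set used by the downstream
beat classifiers: P-R interval, QRS duration, previous and next RR, the
mean and SD of RR over the ten beats before and after, and R amplitude.
Fields that cannot be measured (first beat's rr_prev, an absent P wave) are
NaN-flagged rather than zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import FeatureConfig, QrsConfig
from .signal_io import EcgRecord

__all__ = ["BeatSeries", "BeatFeatures", "detect_qrs", "extract_beat_features",
           "rr_intervals", "FEATURE_NAMES"]


@dataclass
class BeatSeries:
    """Detected beats: sample indices, derived RR intervals and labels."""

    beat_samples: np.ndarray     # strictly increasing, 0-based
    fs: float
    labels: list[str] = field(default_factory=list)  # N/S/V/Q/?

    def __post_init__(self):
        self.beat_samples = np.asarray(self.beat_samples, dtype=int)
        if np.any(np.diff(self.beat_samples) <= 0):
            raise ValueError("beat samples must be strictly increasing")
        if not self.labels:
            self.labels = ["?"] * len(self.beat_samples)
        if len(self.labels) != len(self.beat_samples):
            raise ValueError("labels and beat_samples must align")

    @property
    def rr(self) -> np.ndarray:
        """RR intervals in seconds; empty when fewer than 2 beats."""
        return np.diff(self.beat_samples) / self.fs

    def times(self) -> np.ndarray:
        return self.beat_samples / self.fs

    def __len__(self) -> int:
        return len(self.beat_samples)


FEATURE_NAMES = ("pr_interval", "qrs_duration", "rr_prev", "rr_next",
                 "rr_mean_20", "rr_sd_20", "r_amplitude")


@dataclass
class BeatFeatures:
    """Interval/morphology features for one beat; NaN marks undefined."""

    pr_interval: float = math.nan
    qrs_duration: float = math.nan
    rr_prev: float = math.nan
    rr_next: float = math.nan
    rr_mean_20: float = math.nan
    rr_sd_20: float = math.nan
    r_amplitude: float = math.nan

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


def rr_intervals(beats: BeatSeries) -> np.ndarray:
    """Successive R-R differences in seconds (empty when < 2 beats)."""
    return beats.rr


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _preprocess(x: np.ndarray, fs: float, cfg: QrsConfig):
    """Band-pass -> derivative -> rectify -> moving-window integrate."""
    nyq = fs / 2.0
    b, a = sps.butter(2, [cfg.bandpass_low_hz / nyq, cfg.bandpass_high_hz / nyq],
                      btype="band")
    filt = sps.filtfilt(b, a, x)
    # 5-point central derivative
    der = np.convolve(filt, np.array([1, 2, 0, -2, -1]) / 8.0, mode="same")
    rect = np.abs(der)
    n_int = max(1, int(round(cfg.integration_ms / 1000.0 * fs)))
    mwi = np.convolve(rect, np.ones(n_int) / n_int, mode="same")
    return filt, mwi


def detect_qrs(rec: EcgRecord, cfg: QrsConfig | None = None) -> BeatSeries:
    """Detect QRS complexes; returns R-peak sample indices with '?' labels.

    Records shorter than 2 s yield an empty series.  Thresholds adapt to
    running averages of accepted QRS peaks and rejected noise peaks, so the
    detector is invariant to positive amplitude scaling.
    """
    cfg = cfg or QrsConfig()
    fs = rec.fs
    if rec.duration_s < 2.0:
        return BeatSeries(np.empty(0, dtype=int), fs)
    x = rec.samples
    filt, mwi = _preprocess(x, fs, cfg)

    refractory = int(round(cfg.refractory_ms / 1000.0 * fs))
    twave_win = int(round(cfg.twave_window_ms / 1000.0 * fs))
    # candidate peaks of the integrated envelope
    pk_idx, _ = sps.find_peaks(mwi, distance=max(1, refractory // 2))
    if len(pk_idx) == 0:
        return BeatSeries(np.empty(0, dtype=int), fs)

    # warm-up estimates from the first two seconds
    warm = mwi[: int(2 * fs)]
    spk = float(np.max(warm)) if warm.size else 1.0
    npk = float(np.mean(warm)) if warm.size else 0.0
    sig_peaks: list[float] = [spk]
    noise_peaks: list[float] = [npk]
    mem = cfg.peak_memory

    def threshold() -> float:
        s = float(np.mean(sig_peaks[-mem:]))
        n = float(np.mean(noise_peaks[-mem:]))
        return n + cfg.threshold_factor * (s - n)

    def slope_at(i: int) -> float:
        lo, hi = max(0, i - refractory // 2), min(len(filt), i + refractory // 2)
        seg = np.abs(np.diff(filt[lo:hi]))
        return float(seg.max()) if seg.size else 0.0

    qrs: list[int] = []
    qrs_slopes: list[float] = []
    rr_hist: list[float] = []
    unused: list[tuple[int, float]] = []  # sub-threshold peaks for search-back

    def accept(i: int, amp: float) -> None:
        qrs.append(i)
        qrs_slopes.append(slope_at(i))
        sig_peaks.append(amp)
        if len(qrs) >= 2:
            rr_hist.append((qrs[-1] - qrs[-2]) / fs)

    for i in pk_idx:
        amp = float(mwi[i])
        if qrs and i - qrs[-1] < refractory:
            noise_peaks.append(amp)
            continue
        thr = threshold()
        is_qrs = amp >= thr
        if is_qrs and qrs and i - qrs[-1] < twave_win:
            # T-wave rejection: markedly smaller max slope than the last QRS
            if slope_at(i) < 0.5 * qrs_slopes[-1]:
                is_qrs = False
        if is_qrs:
            accept(i, amp)
            unused.clear()
        else:
            noise_peaks.append(amp)
            unused.append((i, amp))
            # search-back when the current gap exceeds 1.5x the mean RR
            if qrs and len(rr_hist) >= 2:
                mean_rr = float(np.mean(rr_hist[-mem:]))
                if (i - qrs[-1]) / fs > cfg.searchback_factor * mean_rr:
                    cands = [
                        (j, a) for j, a in unused
                        if a >= cfg.searchback_threshold * thr
                        and j - qrs[-1] >= refractory
                    ]
                    if cands:
                        j, a = max(cands, key=lambda p: p[1])
                        accept(j, a)
                        qrs.sort()
                        unused.clear()

    if not qrs:
        return BeatSeries(np.empty(0, dtype=int), fs)

    # refine to the raw-signal R peak near each envelope detection
    half = int(round(cfg.r_refine_ms / 1000.0 * fs))
    base = float(np.median(x))
    refined = []
    for i in qrs:
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        j = lo + int(np.argmax(np.abs(x[lo:hi] - base)))
        refined.append(j)
    refined = sorted(set(refined))
    # enforce refractory after refinement (keep the larger deviation)
    out: list[int] = []
    for j in refined:
        if out and j - out[-1] < refractory:
            if abs(x[j] - base) > abs(x[out[-1]] - base):
                out[-1] = j
        else:
            out.append(j)
    return BeatSeries(np.asarray(out, dtype=int), fs)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _qrs_bounds(x: np.ndarray, r: int, fs: float, cfg: FeatureConfig,
                left_limit: int = 0, right_limit: int | None = None):
    """Scan outward from R until the signal stays near baseline.

    Baseline is the local median well outside the complex; onset/offset is
    where |x - baseline| drops below ``qrs_slope_fraction`` of the R deviation
    and stays there for >= 20 ms.
    """
    scan = int(round(cfg.qrs_scan_ms / 1000.0 * fs))
    hold = max(1, int(round(0.020 * fs)))
    # baseline from a +/-0.5 s neighborhood: wide enough that diastole,
    # not the QRS-T complex itself, dominates the median
    half = int(round(0.5 * fs))
    lo, hi = max(0, r - half), min(len(x), r + half)
    baseline = float(np.median(x[lo:hi]))
    amp = abs(x[r] - baseline)
    if amp == 0:
        return r, r, baseline
    thresh = cfg.qrs_slope_fraction * amp
    dev = np.abs(x - baseline)

    # boundary = last supra-threshold sample before a quiet run of >= 20 ms;
    # the scan never crosses into a neighboring beat's territory
    left_stop = max(0, r - scan, left_limit)
    right_stop = min(len(x), r + scan + 1,
                     right_limit if right_limit is not None else len(x))
    onset = left_stop
    run = 0
    for j in range(r - 1, left_stop - 1, -1):
        run = run + 1 if dev[j] < thresh else 0
        if run >= hold:
            onset = j + run
            break
    offset = right_stop - 1
    run = 0
    for j in range(r + 1, right_stop):
        run = run + 1 if dev[j] < thresh else 0
        if run >= hold:
            offset = j - run
            break
    return onset, offset, baseline


def extract_beat_features(rec: EcgRecord, beats: BeatSeries,
                          cfg: FeatureConfig | None = None) -> list[BeatFeatures]:
    """One :class:`BeatFeatures` per beat.

    RR neighborhood statistics pool up to ``cfg.neighborhood`` beats on each
    side (truncated at record edges).  The P wave is the largest positive
    deflection 40-240 ms before QRS onset; when no deflection rises above
    local noise the P-R interval is NaN.
    """
    cfg = cfg or FeatureConfig()
    x, fs = rec.samples, rec.fs
    n = len(beats)
    rr = beats.rr
    feats: list[BeatFeatures] = []
    p_lo = int(round(cfg.p_search_min_ms / 1000.0 * fs))
    p_hi = int(round(cfg.p_search_max_ms / 1000.0 * fs))
    for k in range(n):
        r = int(beats.beat_samples[k])
        f = BeatFeatures()
        left = (r + int(beats.beat_samples[k - 1])) // 2 if k > 0 else 0
        right = (r + int(beats.beat_samples[k + 1])) // 2 if k < n - 1 else len(x)
        onset, offset, baseline = _qrs_bounds(x, r, fs, cfg, left, right)
        f.qrs_duration = (offset - onset) / fs
        f.r_amplitude = float(x[r] - baseline)
        if k > 0:
            f.rr_prev = float(rr[k - 1])
        if k < n - 1:
            f.rr_next = float(rr[k])
        # pooled neighborhood: intervals among the 10 beats before and after
        lo = max(0, k - cfg.neighborhood)
        hi = min(n - 1, k + cfg.neighborhood)  # rr index range [lo, hi)
        neigh = rr[lo:hi]
        if neigh.size:
            f.rr_mean_20 = float(np.mean(neigh))
            f.rr_sd_20 = float(np.std(neigh))
        # P wave: largest deflection from baseline in the search window
        w_lo, w_hi = onset - p_hi, onset - p_lo
        prev_off = int(beats.beat_samples[k - 1]) + p_lo if k > 0 else 0
        w_lo = max(w_lo, prev_off, 0)
        if w_hi > w_lo + 2:
            seg = x[w_lo:w_hi] - baseline
            p_idx = w_lo + int(np.argmax(np.abs(seg)))
            p_amp = abs(seg[p_idx - w_lo])
            local_noise = float(np.std(seg)) if seg.size > 4 else 0.0
            if p_amp > max(0.02, 0.04 * abs(f.r_amplitude)) and p_amp > local_noise:
                f.pr_interval = (r - p_idx) / fs
        feats.append(f)
    return feats
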
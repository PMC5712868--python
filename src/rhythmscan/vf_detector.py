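"""Ventricular-fibrillation detection by periodogram band-peak ratio.

Each 2-s segment (400 samples at 200 Hz, so 0.5 Hz bin spacing) is
mean-removed and its rectangular-window periodogram computed.  Three band
maxima are extracted:

* ``p_vf``   — peak power at bins with frequency in [2.61, 4.95] Hz,
* ``p_nVF``  — peak in (0.5, 2.61) Hz,
* ``p_nVF2`` — peak in (4.95, 10] Hz,

and the segment is called VF when ``p_vf / (p_nVF + p_nVF2) >= 3.96``.
VF has a dominant oscillation of a few hertz and little power elsewhere, so
the ratio is large; organized rhythms spread QRS energy across harmonics
well outside the VF band and keep the ratio small.  The ratio is a quotient
of homogeneous quantities, so the decision is invariant to amplitude
scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import VfConfig
from .signal_io import EcgRecord

__all__ = ["SpectralBands", "segment_2s", "band_peaks", "classify_vf_segment",
           "vf_segments_to_episodes", "detect_vf"]


@dataclass
class SpectralBands:
    p_vf: float
    p_nvf: float
    p_nvf2: float
    threshold: float = 3.96

    @property
    def ratio(self) -> float:
        denom = self.p_nvf + self.p_nvf2
        if denom == 0:
            return math.inf if self.p_vf > 0 else 0.0
        return self.p_vf / denom


def segment_2s(rec: EcgRecord, cfg: VfConfig | None = None) -> list[np.ndarray]:
    """Cut into consecutive non-overlapping 2-s pieces; short tail dropped."""
    cfg = cfg or VfConfig()
    n_seg = int(round(cfg.segment_s * rec.fs))
    n = len(rec) // n_seg
    return [rec.samples[k * n_seg : (k + 1) * n_seg] for k in range(n)]


def band_peaks(segment: np.ndarray, fs: float = 200.0,
               cfg: VfConfig | None = None) -> SpectralBands:
    """Periodogram band maxima of one segment.

    Band membership is decided on exact bin frequencies (no zero padding),
    so with 0.5 Hz bins the stated band edges 2.61/4.95 Hz fall between
    bins and each bin belongs to exactly one band.
    """
    cfg = cfg or VfConfig()
    x = np.asarray(segment, dtype=float)
    if len(x) == 0:
        return SpectralBands(0.0, 0.0, 0.0, cfg.ratio_threshold)
    freqs, pxx = sps.periodogram(x, fs=fs, window="boxcar", detrend="constant")

    def peak(lo, hi, inc_lo, inc_hi):
        sel = ((freqs > lo) | (inc_lo & np.isclose(freqs, lo))) \
            & ((freqs < hi) | (inc_hi & np.isclose(freqs, hi)))
        sel &= (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
        return float(pxx[sel].max()) if np.any(sel) else 0.0

    p_vf = peak(*cfg.vf_band, True, True)
    p_nvf = peak(*cfg.nvf_band, False, False)
    p_nvf2 = peak(*cfg.nvf2_band, False, True)
    return SpectralBands(p_vf, p_nvf, p_nvf2, cfg.ratio_threshold)


def classify_vf_segment(bands: SpectralBands) -> bool:
    """VF iff the band ratio meets the fixed threshold (inclusive)."""
    if bands.p_vf == 0.0 and bands.p_nvf == 0.0 and bands.p_nvf2 == 0.0:
        return False
    return bands.ratio >= bands.threshold


def vf_segments_to_episodes(flags: list[bool], segment_samples: int,
                            bridge_gaps: int = 1) -> list[tuple[int, int]]:
    """Merge VF-positive segments into half-open sample episodes.

    Runs of negatives no longer than ``bridge_gaps`` segments between two
    positives are absorbed into the surrounding episode; rhythm-level
    scoring is sensitive to fragmentation, so brief dropouts inside a VF
    run should not split it.
    """
    episodes: list[tuple[int, int]] = []
    pos = [k for k, f in enumerate(flags) if f]
    if not pos:
        return episodes
    start = prev = pos[0]
    for k in pos[1:]:
        if k - prev - 1 <= bridge_gaps:
            prev = k
        else:
            episodes.append((start * segment_samples, (prev + 1) * segment_samples))
            start = prev = k
    episodes.append((start * segment_samples, (prev + 1) * segment_samples))
    return episodes


def detect_vf(rec: EcgRecord, cfg: VfConfig | None = None):
    """Full per-record VF pass: segments -> bands -> flags -> episodes.

    Returns ``(episodes, ratios)`` with episodes in half-open sample
    intervals and one ratio per 2-s segment.
    """
    cfg = cfg or VfConfig()
    segs = segment_2s(rec, cfg)
    bands = [band_peaks(s, rec.fs, cfg) for s in segs]
    flags = [classify_vf_segment(b) for b in bands]
    n_seg = int(round(cfg.segment_s * rec.fs))
    eps = vf_segments_to_episodes(flags, n_seg, cfg.bridge_gaps)
    return eps, [b.ratio for b in bands]
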
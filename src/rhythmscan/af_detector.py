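"""Atrial-fibrillation detection from RR-interval symbolic dynamics.

The per-window pipeline: ectopic (VPC) beats first have their adjacent RR
intervals replaced by a local average so ventricular prematurity does not
masquerade as AF irregularity; the corrected RR series becomes instantaneous
heart rate hr_n = 60/RR_n; heart rate is quantized to 5-bpm symbols

    sy_n = 63            if hr_n >= 315
    sy_n = floor(hr_n/5) otherwise

and three consecutive symbols form a base-64 word value

    wv_n = sy_{n-2} * 2^12 + sy_{n-1} * 2^6 + sy_n  in [0, 2^18 - 1].

AF is declared for a 5-min window when the sample entropy of the word-value
sequence exceeds a threshold: an irregularly irregular rhythm visits many
distinct words with little repetition, while sinus rhythm (even with rate
drift) produces long runs of near-identical words and near-zero entropy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .config import AfConfig
from .qrs_beats import BeatSeries

__all__ = ["RrDerived", "AfDecision", "correct_rr", "rr_to_hr", "symbolize",
           "word_values", "sample_entropy", "detect_af_window",
           "af_windows_to_episodes", "rr_derived"]

SY_MAX = 63
WV_MAX = (1 << 18) - 1


@dataclass
class RrDerived:
    """RR series with its heart-rate, symbol and word-value views."""

    rr: np.ndarray    # seconds
    hr: np.ndarray    # bpm, per interval
    sy: np.ndarray    # 0..63
    wv: np.ndarray    # 0..262143, len = len(sy) - 2


@dataclass
class AfDecision:
    window_id: str
    sampen: float | None          # None when undefined
    is_af: bool | None            # None when undetermined
    n_beats: int
    params: AfConfig


def correct_rr(rr: np.ndarray, labels: list[str] | np.ndarray) -> np.ndarray:
    """Replace intervals adjacent to V beats by a local non-ectopic average.

    For every beat labeled V, both touching intervals are set to the mean of
    the nearest intervals on either side that are not themselves adjacent to
    a V beat; at record edges the single available neighbor is used.  With
    every beat V the series is returned unchanged with a warning.
    """
    rr = np.asarray(rr, dtype=float)
    labels = list(labels)
    if len(rr) != len(labels) - 1:
        raise ValueError("need len(rr) == len(labels) - 1")
    v_beats = [i for i, lab in enumerate(labels) if lab == "V"]
    if not v_beats:
        return rr.copy()
    if len(v_beats) == len(labels):
        warnings.warn("all beats labeled V; RR series left uncorrected")
        return rr.copy()
    # interval j (between beats j and j+1) is tainted if either endpoint is V
    tainted = np.zeros(len(rr), dtype=bool)
    for i in v_beats:
        if i - 1 >= 0:
            tainted[i - 1] = True
        if i < len(rr):
            tainted[i] = True
    clean_idx = np.flatnonzero(~tainted)
    out = rr.copy()
    if clean_idx.size == 0:
        warnings.warn("no ectopy-free intervals; RR series left uncorrected")
        return out
    for j in np.flatnonzero(tainted):
        left = clean_idx[clean_idx < j]
        right = clean_idx[clean_idx > j]
        vals = []
        if left.size:
            vals.append(rr[left[-1]])
        if right.size:
            vals.append(rr[right[0]])
        out[j] = float(np.mean(vals))
    return out


def rr_to_hr(rr: np.ndarray) -> np.ndarray:
    """Instantaneous heart rate in bpm: hr_n = 60 / rr_n."""
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be positive")
    return 60.0 / rr


def symbolize(hr: np.ndarray) -> np.ndarray:
    """Quantize heart rate to 5-bpm symbols, saturating at 63 (hr >= 315)."""
    hr = np.asarray(hr, dtype=float)
    if np.any(hr < 0):
        raise ValueError("heart rate must be nonnegative")
    sy = np.floor(hr / 5.0).astype(np.int64)
    sy[hr >= 315.0] = SY_MAX
    return sy


def word_values(sy: np.ndarray) -> np.ndarray:
    """Base-64 positional code of consecutive symbol triples.

    wv_n = sy_{n-2}*4096 + sy_{n-1}*64 + sy_n; empty for fewer than three
    symbols.  Injective on triples, so distinct rhythm patterns map to
    distinct words.
    """
    sy = np.asarray(sy, dtype=np.int64)
    if np.any((sy < 0) | (sy > SY_MAX)):
        raise ValueError("symbols must lie in 0..63")
    if len(sy) < 3:
        return np.empty(0, dtype=np.int64)
    return (sy[:-2] << 12) + (sy[1:-1] << 6) + sy[2:]


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float | None:
    """Sample entropy: -ln(A/B) over template pairs within Chebyshev r.

    B counts ordered pairs i != j of length-m templates with max-norm
    distance <= r, A the same for length m+1; both use the N-m templates
    whose (m+1)-extension exists.  Returns None (undefined) when the series
    is too short or either count is zero — never silently 0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if m < 1 or r <= 0:
        raise ValueError("need m >= 1 and r > 0")
    if n <= m + 1:
        return None
    n_t = n - m  # templates for which both lengths exist
    # pairwise Chebyshev distances accumulated component-wise
    d_m = np.zeros((n_t, n_t))
    for k in range(m):
        d_m = np.maximum(d_m, np.abs(x[k : k + n_t, None] - x[None, k : k + n_t]))
    d_m1 = np.maximum(d_m, np.abs(x[m : m + n_t, None] - x[None, m : m + n_t]))
    off = ~np.eye(n_t, dtype=bool)
    B = int(np.count_nonzero((d_m <= r) & off))
    A = int(np.count_nonzero((d_m1 <= r) & off))
    if A == 0 or B == 0:
        return None
    return float(-math.log(A / B))


def rr_derived(rr: np.ndarray) -> RrDerived:
    """Compute the full hr/symbol/word view of an RR series."""
    hr = rr_to_hr(rr)
    sy = symbolize(hr)
    return RrDerived(rr=np.asarray(rr, float), hr=hr, sy=sy, wv=word_values(sy))


def detect_af_window(beats: BeatSeries, cfg: AfConfig | None = None,
                     window_id: str = "") -> AfDecision:
    """Decide AF for one 5-min window of labeled beats.

    Runs correct_rr -> rr_to_hr -> symbolize -> word_values ->
    sample_entropy(wv; m, r = r_factor*SD(wv)) and thresholds the entropy.
    Undetermined (is_af None) when the window has fewer than ``min_beats``
    beats or the entropy is undefined.
    """
    cfg = cfg or AfConfig()
    n = len(beats)
    if n < cfg.min_beats or n < 2:
        return AfDecision(window_id, None, None, n, cfg)
    rr = correct_rr(beats.rr, beats.labels)
    der = rr_derived(rr)
    if len(der.wv) <= cfg.m + 1:
        return AfDecision(window_id, None, None, n, cfg)
    sd = float(np.std(der.wv))
    if sd <= 0:
        # perfectly metronomic words: zero entropy by continuity
        return AfDecision(window_id, 0.0, False, n, cfg)
    s = sample_entropy(der.wv.astype(float), cfg.m, cfg.r_factor * sd)
    if s is None:
        return AfDecision(window_id, None, None, n, cfg)
    return AfDecision(window_id, s, bool(s >= cfg.threshold), n, cfg)


def af_windows_to_episodes(decisions: list[AfDecision],
                           window_samples: int) -> list[tuple[int, int]]:
    """Merge consecutive AF-positive windows into half-open sample episodes.

    Window k covers ``[k*window_samples, (k+1)*window_samples)``; episode
    boundaries fall on window boundaries.  Undetermined windows break runs.
    """
    episodes: list[tuple[int, int]] = []
    start = None
    for k, d in enumerate(decisions):
        if d.is_af:
            if start is None:
                start = k * window_samples
        else:
            if start is not None:
                episodes.append((start, k * window_samples))
                start = None
    if start is not None:
        episodes.append((start, len(decisions) * window_samples))
    return episodes
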
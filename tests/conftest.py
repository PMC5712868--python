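"""Shared fixtures and independent oracles.

The oracle implementations here are deliberately naive — per-pair loops,
per-sample grids, plain FFTs — so they share no code path with the package
routines they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from rhythmscan import synth_ecg


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_sample_entropy(x, m, r):
    """O(N^2) template-counting sample entropy; None when undefined."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1:
        return None
    nt = n - m
    A = B = 0
    for i in range(nt):
        ti_m = x[i : i + m]
        ti_m1 = x[i : i + m + 1]
        for j in range(nt):
            if i == j:
                continue
            if np.max(np.abs(ti_m - x[j : j + m])) <= r:
                B += 1
                if np.max(np.abs(ti_m1 - x[j : j + m + 1])) <= r:
                    A += 1
    if A == 0 or B == 0:
        return None
    return -np.log(A / B)


def grid_episode_stats(ref_eps, test_eps, resolution=1):
    """Per-sample overlap counter for episode/duration statistics.

    Rasterizes both interval streams onto an integer grid and counts, the
    dumbest possible way to get DSe/D+P and the hit counts for ESe/E+P.
    """
    hi = int(max([e for _, e in ref_eps + test_eps], default=1))
    ref_mask = np.zeros(hi, dtype=bool)
    test_mask = np.zeros(hi, dtype=bool)
    for s, e in ref_eps:
        ref_mask[int(s) : int(e)] = True
    for s, e in test_eps:
        test_mask[int(s) : int(e)] = True
    overlap = int(np.count_nonzero(ref_mask & test_mask))
    ref_hit = sum(1 for s, e in ref_eps
                  if np.any(test_mask[int(s) : int(e)]))
    test_hit = sum(1 for s, e in test_eps
                   if np.any(ref_mask[int(s) : int(e)]))
    return dict(
        ref_hit=ref_hit, test_hit=test_hit, overlap=overlap,
        ref_dur=int(np.count_nonzero(ref_mask)),
        test_dur=int(np.count_nonzero(test_mask)),
    )


def fft_band_peak(x, fs, lo, hi, inc_lo, inc_hi):
    """Periodogram band maximum via a direct rfft, boundary-aware."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) ** 2 / (fs * n)
    spec[1:-1] *= 2  # one-sided density, matching scipy's convention
    freqs = np.fft.rfftfreq(n, 1 / fs)
    sel = np.ones(len(freqs), dtype=bool)
    sel &= (freqs > lo) | (inc_lo & np.isclose(freqs, lo))
    sel &= (freqs < hi) | (inc_hi & np.isclose(freqs, hi))
    return float(spec[sel].max()) if np.any(sel) else 0.0


def random_episode_config(rng, horizon=10_000, max_eps=6):
    """Random non-overlapping half-open integer episodes."""
    out = []
    t = 0
    for _ in range(rng.integers(0, max_eps + 1)):
        t += int(rng.integers(1, horizon // (2 * max_eps)))
        dur = int(rng.integers(1, horizon // (2 * max_eps)))
        if t + dur >= horizon:
            break
        out.append((t, t + dur))
        t += dur
    return out


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def sinus_record():
    cfg = synth_ecg.SynthConfig(rhythm_plan=[("SINUS", 60.0)],
                                sinus_rate_bpm=60.0, sinus_rr_jitter_s=0.0,
                                seed=7)
    return synth_ecg.generate_record(cfg)


@pytest.fixture(scope="session")
def ectopic_record():
    cfg = synth_ecg.SynthConfig(rhythm_plan=[("SINUS", 300.0)],
                                sinus_rate_bpm=70.0, vpc_rate_per_min=4.0,
                                apc_rate_per_min=4.0, seed=3)
    return synth_ecg.generate_record(cfg)


@pytest.fixture(scope="session")
def mixed_record():
    cfg = synth_ecg.SynthConfig(
        rhythm_plan=[("SINUS", 300.0), ("AF", 300.0), ("SINUS", 240.0),
                     ("VF", 60.0), ("SINUS", 300.0)],
        vpc_rate_per_min=2.0, seed=11,
    )
    return synth_ecg.generate_record(cfg)
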
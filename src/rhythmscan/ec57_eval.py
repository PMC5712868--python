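"""EC57-style scoring of test annotations against a reference.

Beat-level: reference and test beat streams are paired one-to-one by greedy
nearest-neighbor matching within a time tolerance (150 ms by default); for a
target class (S or V) the pairing yields TP/FP/FN/TN and the statistics

    Se  = TP / (TP + FN)      sensitivity
    +P  = TP / (TP + FP)      positive predictivity
    FPR = FP / (FP + TN)      false positive rate

Rhythm-level (AF or VF), on half-open episode intervals:

    ESe = ref episodes touched by any test episode / ref episodes
    E+P = test episodes touching any ref episode / test episodes
    DSe = overlapped duration / total ref duration
    D+P = overlapped duration / total test duration

Aggregation is either *gross* (pool numerators and denominators across
records) or *average* (unweighted mean of per-record statistics, skipping
records where a statistic is undefined).  Undefined statistics stay NaN —
they are flagged, never zero-filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_io import Annotation

__all__ = ["BeatMatch", "EpisodeStats", "Ec57Report", "match_beats",
           "episode_duration_stats", "aggregate", "report_frame"]


@dataclass
class BeatMatch:
    """Pair counts for one record and one target beat class."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    cls: str = "V"
    tolerance_s: float = 0.15
    record_id: str = ""

    @property
    def se(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def pp(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def fpr(self) -> float:
        return _ratio(self.fp, self.fp + self.tn)


@dataclass
class EpisodeStats:
    """Episode/duration statistics for one record and rhythm."""

    n_ref: int = 0
    n_test: int = 0
    ref_hit: int = 0
    test_hit: int = 0
    ref_dur: float = 0.0
    test_dur: float = 0.0
    overlap_dur: float = 0.0
    rhythm: str = "AF"
    record_id: str = ""

    @property
    def ese(self) -> float:
        return _ratio(self.ref_hit, self.n_ref)

    @property
    def epp(self) -> float:
        return _ratio(self.test_hit, self.n_test)

    @property
    def dse(self) -> float:
        return _ratio(self.overlap_dur, self.ref_dur)

    @property
    def dpp(self) -> float:
        return _ratio(self.overlap_dur, self.test_dur)


def _ratio(num, den) -> float:
    return num / den if den else math.nan


@dataclass
class Ec57Report:
    """Per-record rows plus a gross/average aggregate, as percentages."""

    per_record: list = field(default_factory=list)
    mode: str = "gross"
    stats: dict[str, float] = field(default_factory=dict)


def _greedy_pairs(ref_t: np.ndarray, test_t: np.ndarray, tol: float):
    """One-to-one nearest-neighbor pairing within tolerance.

    Candidate pairs are sorted by |dt| and accepted greedily when both
    members are still free — symmetric in the two streams.
    """
    cands = []
    j0 = 0
    for i, t in enumerate(ref_t):
        j = int(np.searchsorted(test_t, t))
        for k in range(max(0, j - 2), min(len(test_t), j + 2)):
            dt = abs(test_t[k] - t)
            if dt <= tol:
                cands.append((dt, i, k))
    cands.sort()
    ref_used = np.zeros(len(ref_t), dtype=bool)
    test_used = np.zeros(len(test_t), dtype=bool)
    pairs = []
    for dt, i, k in cands:
        if not ref_used[i] and not test_used[k]:
            ref_used[i] = test_used[k] = True
            pairs.append((i, k))
    return pairs, ref_used, test_used


def match_beats(ref: Annotation, test: Annotation, cls: str = "V",
                tolerance_s: float = 0.15, fs: float = 200.0,
                record_id: str = "") -> BeatMatch:
    """Score test beats against reference beats for one target class.

    TP: paired beats where both carry ``cls``; FP: test-``cls`` beats
    unpaired or paired to another class; FN: the mirror image for the
    reference; TN: paired beats where neither carries ``cls``.
    """
    ref_t = np.array([s for s, _ in ref.beat_marks], dtype=float) / fs
    test_t = np.array([s for s, _ in test.beat_marks], dtype=float) / fs
    ref_lab = [lab for _, lab in ref.beat_marks]
    test_lab = [lab for _, lab in test.beat_marks]
    pairs, ref_used, test_used = _greedy_pairs(ref_t, test_t, tolerance_s)
    m = BeatMatch(cls=cls, tolerance_s=tolerance_s, record_id=record_id)
    for i, k in pairs:
        r_is, t_is = ref_lab[i] == cls, test_lab[k] == cls
        if r_is and t_is:
            m.tp += 1
        elif r_is:
            m.fn += 1
        elif t_is:
            m.fp += 1
        else:
            m.tn += 1
    m.fn += sum(1 for i in np.flatnonzero(~ref_used) if ref_lab[i] == cls)
    m.fp += sum(1 for k in np.flatnonzero(~test_used) if test_lab[k] == cls)
    return m


def _interval_overlap(a: list[tuple[float, float]],
                      b: list[tuple[float, float]]) -> float:
    """Total length of the intersection of two unions of intervals."""
    total = 0.0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0.0, min(e1, e2) - max(s1, s2))
    return total


def episode_duration_stats(ref_eps: list[tuple[float, float]],
                           test_eps: list[tuple[float, float]],
                           rhythm: str = "AF",
                           record_id: str = "") -> EpisodeStats:
    """Episode and duration statistics on half-open intervals.

    Any nonzero overlap counts as a hit.  Same-rhythm episodes must be
    non-overlapping within each stream (an error otherwise) so the pairwise
    intersection sum equals the union overlap.
    """
    for eps, name in ((ref_eps, "reference"), (test_eps, "test")):
        srt = sorted(eps)
        for (s1, e1), (s2, e2) in zip(srt, srt[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping episodes in {name} stream")
        if any(e <= s for s, e in eps):
            raise ValueError(f"empty episode in {name} stream")
    st = EpisodeStats(rhythm=rhythm, record_id=record_id,
                      n_ref=len(ref_eps), n_test=len(test_eps),
                      ref_dur=sum(e - s for s, e in ref_eps),
                      test_dur=sum(e - s for s, e in test_eps),
                      overlap_dur=_interval_overlap(ref_eps, test_eps))
    st.ref_hit = sum(
        1 for s, e in ref_eps
        if any(min(e, e2) > max(s, s2) for s2, e2 in test_eps)
    )
    st.test_hit = sum(
        1 for s, e in test_eps
        if any(min(e, e2) > max(s, s2) for s2, e2 in ref_eps)
    )
    return st


_BEAT_STATS = ("se", "pp", "fpr")
_EP_STATS = ("ese", "epp", "dse", "dpp")


def aggregate(per_record: list, mode: str = "gross") -> Ec57Report:
    """Aggregate per-record beat or episode statistics, as percentages.

    Gross pools counts/durations across records before forming each ratio;
    average takes the unweighted mean of defined per-record values.  A
    statistic undefined everywhere stays NaN.
    """
    if not per_record:
        raise ValueError("need at least one record")
    if mode not in ("gross", "average"):
        raise ValueError("mode must be 'gross' or 'average'")
    is_beat = isinstance(per_record[0], BeatMatch)
    names = _BEAT_STATS if is_beat else _EP_STATS
    rep = Ec57Report(per_record=list(per_record), mode=mode)
    if mode == "gross":
        if is_beat:
            pooled = BeatMatch(
                tp=sum(m.tp for m in per_record),
                fp=sum(m.fp for m in per_record),
                fn=sum(m.fn for m in per_record),
                tn=sum(m.tn for m in per_record),
                cls=per_record[0].cls,
            )
        else:
            pooled = EpisodeStats(
                n_ref=sum(s.n_ref for s in per_record),
                n_test=sum(s.n_test for s in per_record),
                ref_hit=sum(s.ref_hit for s in per_record),
                test_hit=sum(s.test_hit for s in per_record),
                ref_dur=sum(s.ref_dur for s in per_record),
                test_dur=sum(s.test_dur for s in per_record),
                overlap_dur=sum(s.overlap_dur for s in per_record),
                rhythm=per_record[0].rhythm,
            )
        for name in names:
            rep.stats[name] = 100.0 * getattr(pooled, name)
    else:
        for name in names:
            vals = [getattr(m, name) for m in per_record]
            vals = [v for v in vals if not math.isnan(v)]
            rep.stats[name] = 100.0 * float(np.mean(vals)) if vals else math.nan
    return rep


def report_frame(per_record: list) -> pd.DataFrame:
    """Tabular per-record + Gross + Average report (percent units)."""
    if not per_record:
        raise ValueError("need at least one record")
    is_beat = isinstance(per_record[0], BeatMatch)
    names = _BEAT_STATS if is_beat else _EP_STATS
    pretty = {"se": "Se", "pp": "+P", "fpr": "FPR",
              "ese": "ESe", "epp": "E+P", "dse": "DSe", "dpp": "D+P"}
    rows = []
    for m in per_record:
        rows.append({"record": m.record_id,
                     **{pretty[n]: 100.0 * getattr(m, n) for n in names}})
    for mode in ("gross", "average"):
        rep = aggregate(per_record, mode)
        rows.append({"record": mode.capitalize(),
                     **{pretty[n]: rep.stats[n] for n in names}})
    return pd.DataFrame(rows)
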
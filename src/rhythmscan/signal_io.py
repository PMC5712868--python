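"""ECG record and annotation I/O.

Reads single-lead records from WFDB header/signal pairs (formats 16 and 212)
or two-column CSV, and beat/rhythm annotations from MIT-style binary
annotation files or a plain JSON dialect.  Everything downstream works on the
normalized representation: millivolt samples at a known sampling rate,
0-based beat sample indices with AAMI class labels (N/S/V/Q), and half-open
``[start, end)`` rhythm episodes (SINUS/AF/VF/OTHER).

The WFDB reader/writer here is deliberately minimal: single segment, single
selected channel, formats 16 and 212 only — enough to ingest the public
arrhythmia databases and to round-trip the package's own synthetic records.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "EcgRecord",
    "Annotation",
    "FormatError",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations_json",
    "write_annotations_atr",
    "resample",
    "rescale_annotation",
    "slice_windows",
    "AAMI_MAP",
]


class FormatError(ValueError):
    """Unsupported or malformed file content."""


# MIT/WFDB beat symbol -> AAMI class.  Paced beats and fusions fall to Q.
AAMI_MAP = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
}

RHYTHMS = ("SINUS", "AF", "VF", "OTHER")


@dataclass
class EcgRecord:
    """Uniformly sampled single-lead voltage series."""

    samples: np.ndarray          # mV
    fs: float                    # Hz
    record_id: str = ""
    lead_name: str = "ECG"
    partial: bool = False        # set on flagged tail windows from slice_windows

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class Annotation:
    """Beat marks and rhythm episodes on a record's sample grid.

    ``beat_marks`` is a list of ``(sample_index, aami_label)`` with strictly
    increasing indices; ``rhythm_episodes`` a list of
    ``(start_sample, end_sample, rhythm)`` half-open intervals.
    """

    beat_marks: list[tuple[int, str]] = field(default_factory=list)
    rhythm_episodes: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self):
        idx = [s for s, _ in self.beat_marks]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("beat sample indices must be strictly increasing")
        for s, e, r in self.rhythm_episodes:
            if e <= s:
                raise ValueError(f"episode start must precede end: [{s}, {e})")
            if r not in RHYTHMS:
                raise ValueError(f"unknown rhythm {r!r}")
        for rhythm in RHYTHMS:
            eps = sorted((s, e) for s, e, r in self.rhythm_episodes if r == rhythm)
            for (s1, e1), (s2, e2) in zip(eps, eps[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping {rhythm} episodes: [{s1},{e1}) and [{s2},{e2})"
                    )

    def beats_of(self, cls: str) -> list[int]:
        return [s for s, lab in self.beat_marks if lab == cls]

    def episodes_of(self, rhythm: str) -> list[tuple[int, int]]:
        return sorted((s, e) for s, e, r in self.rhythm_episodes if r == rhythm)


# ---------------------------------------------------------------------------
# WFDB header + signal
# ---------------------------------------------------------------------------

def _parse_header(hea_path: Path):
    lines = [
        ln.strip() for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    record_id = rec_fields[0].split("/")[0]
    n_sig = int(rec_fields[1])
    fs = 250.0
    if len(rec_fields) >= 3:
        fs = float(rec_fields[2].split("/")[0])
    n_samples = int(rec_fields[3]) if len(rec_fields) >= 4 else None
    sig_specs = []
    for ln in lines[1 : 1 + n_sig]:
        f = ln.split()
        fname, fmt_field = f[0], f[1]
        fmt = int(fmt_field.split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        if len(f) >= 3:
            g = f[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.rstrip(")").split("(")
                baseline = int(b)
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(f[4]) if len(f) >= 5 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(f[8:]) if len(f) > 8 else f"ch{len(sig_specs)}"
        sig_specs.append(
            dict(file=fname, fmt=fmt, gain=gain, baseline=baseline,
                 units=units, desc=desc)
        )
    return record_id, fs, n_samples, sig_specs


def _read_dat(path: Path, fmt: int, n_sig: int) -> np.ndarray:
    """Return raw ADC counts, shape (n_frames, n_sig)."""
    raw = path.read_bytes()
    if fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2")
        n = len(adc) // n_sig
        return adc[: n * n_sig].reshape(n, n_sig)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: 3 * (len(b) // 3)].reshape(-1, 3).astype(np.int32)
        s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s1[s1 > 2047] -= 4096
        s2[s2 > 2047] -= 4096
        adc = np.empty(2 * len(b), dtype=np.int32)
        adc[0::2], adc[1::2] = s1, s2
        n = len(adc) // n_sig
        return adc[: n * n_sig].reshape(n, n_sig)
    raise FormatError(f"unsupported WFDB signal format {fmt}")


def read_record(path: str | Path, channel: int = 0) -> EcgRecord:
    """Read a WFDB record (``.hea``) or two-column CSV into an :class:`EcgRecord`.

    WFDB samples are converted to physical units via
    ``(adc - baseline) / gain``; CSV rows are ``time_s, mV`` and the rate is
    inferred from the first time step.
    """
    path = Path(path)
    if path.suffix == ".csv":
        return _read_csv(path)
    if path.suffix != ".hea":
        hea = path.with_suffix(".hea")
        if hea.exists():
            path = hea
        else:
            raise FileNotFoundError(f"no header file for {path}")
    if not path.exists():
        raise FileNotFoundError(path)
    record_id, fs, n_samples, specs = _parse_header(path)
    if not specs:
        return EcgRecord(np.empty(0), fs, record_id)
    spec = specs[channel]
    same_file = [s for s in specs if s["file"] == spec["file"]]
    col = same_file.index(spec)
    adc = _read_dat(path.parent / spec["file"], spec["fmt"], len(same_file))
    if n_samples is not None:
        adc = adc[:n_samples]
    mv = (adc[:, col] - spec["baseline"]) / spec["gain"]
    return EcgRecord(mv, fs, record_id, spec["desc"])


def _read_csv(path: Path) -> EcgRecord:
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    if data.shape[1] < 2:
        raise FormatError("CSV must have (time_s, mV) columns")
    t, mv = data[:, 0], data[:, 1]
    if len(t) < 2:
        fs = 200.0
    else:
        dt = t[1] - t[0]
        if dt <= 0:
            raise FormatError("CSV time column must be increasing")
        fs = 1.0 / dt
    return EcgRecord(mv, fs, path.stem)


def write_record(path: str | Path, rec: EcgRecord, fmt: int = 16,
                 gain: float = 200.0, baseline: int = 0) -> None:
    """Write ``rec`` as a WFDB header + signal pair (format 16 or 212)."""
    path = Path(path)
    stem = path.with_suffix("")
    adc = np.round(rec.samples * gain + baseline).astype(np.int64)
    lo, hi = (-32768, 32767) if fmt == 16 else (-2048, 2047)
    adc = np.clip(adc, lo, hi)
    dat_name = stem.name + ".dat"
    header = (
        f"{stem.name} 1 {rec.fs:g} {len(adc)}\n"
        f"{dat_name} {fmt} {gain:g}({baseline})/mV 12 {baseline} "
        f"{adc[0] if len(adc) else 0} 0 0 {rec.lead_name}\n"
    )
    stem.with_suffix(".hea").write_text(header)
    if fmt == 16:
        buf = adc.astype("<i2").tobytes()
    elif fmt == 212:
        a = adc.astype(np.int32) & 0xFFF
        if len(a) % 2:
            a = np.append(a, 0)
        b = np.empty((len(a) // 2, 3), dtype=np.uint8)
        s1, s2 = a[0::2], a[1::2]
        b[:, 0] = s1 & 0xFF
        b[:, 1] = ((s1 >> 8) & 0x0F) | (((s2 >> 8) & 0x0F) << 4)
        b[:, 2] = s2 & 0xFF
        buf = b.tobytes()
    else:
        raise FormatError(f"unsupported WFDB signal format {fmt}")
    (stem.parent / dat_name).write_bytes(buf)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

# MIT annotation code -> symbol (beat and relevant non-beat codes)
_CODE_TO_SYM = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 25: "B", 34: "e", 35: "n", 38: "f",
    41: "r",
}
_BEAT_CODES = set(_CODE_TO_SYM)
_SYM_TO_CODE = {v: k for k, v in _CODE_TO_SYM.items()}
_RHYTHM_CODE = 28


def _aux_to_rhythm(aux: str) -> str:
    a = aux.lstrip("(").rstrip("\x00").upper()
    if a.startswith("AFIB") or a.startswith("AF"):
        return "AF"
    if a.startswith("VF") or a.startswith("VFL"):
        return "VF"
    if a in ("N", "NSR", "SR") or a.startswith("N\x00"):
        return "SINUS"
    return "OTHER"


def map_symbol(sym: str) -> str:
    """Map an MIT beat symbol to its AAMI class (unknown symbols -> Q)."""
    if sym not in AAMI_MAP and sym not in ("Q", "/", "F", "f", "B", "n", "r"):
        warnings.warn(f"unknown beat symbol {sym!r} mapped to Q", stacklevel=2)
    return AAMI_MAP.get(sym, "Q")


def _read_atr(path: Path, record_len: int | None):
    raw = path.read_bytes()
    beats: list[tuple[int, str]] = []
    changes: list[tuple[int, str]] = []  # (sample, rhythm)
    t = 0
    i = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code, interval = word >> 10, word & 0x3FF
        if code == 0 and interval == 0:
            break  # EOF marker
        if code == 59:  # SKIP: next 4 bytes hold a long interval (PDP-11 order)
            if i + 3 >= len(raw):
                break
            high = raw[i] | (raw[i + 1] << 8)
            low = raw[i + 2] | (raw[i + 3] << 8)
            t += (high << 16) | low
            i += 4
            continue
        if code == 63:  # AUX: interval = byte count, padded to even
            n = interval
            aux = raw[i : i + n].decode("latin-1")
            i += n + (n % 2)
            if changes and not changes[-1][1]:
                changes[-1] = (changes[-1][0], aux)
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN modifiers — ignored
            continue
        t += interval
        if code in _BEAT_CODES:
            beats.append((t, map_symbol(_CODE_TO_SYM[code])))
        elif code == _RHYTHM_CODE:
            changes.append((t, ""))  # aux string follows as its own word
    return beats, changes


def read_annotations(path: str | Path, record_len: int | None = None) -> Annotation:
    """Read an MIT-style ``.atr``/``.qrs`` file or the JSON dialect.

    Rhythm change marks open an episode that closes at the next change of
    rhythm; a rhythm still open at the end of the record is closed at
    ``record_len`` (or the last annotation sample when unknown).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".json":
        return _read_json_ann(path)
    beats, changes = _read_atr(path, record_len)
    episodes: list[tuple[int, int, str]] = []
    end_of_record = record_len
    if end_of_record is None:
        last = max([s for s, _ in beats] + [s for s, _ in changes], default=0)
        end_of_record = last + 1
    open_start, open_rhythm = None, None
    for sample, aux in sorted(changes):
        rhythm = _aux_to_rhythm(aux) if aux else "OTHER"
        if open_rhythm is not None and sample > open_start:
            episodes.append((open_start, sample, open_rhythm))
        open_start, open_rhythm = sample, rhythm
    if open_rhythm is not None and end_of_record > open_start:
        episodes.append((open_start, end_of_record, open_rhythm))
    return Annotation(beats, episodes)


def _read_json_ann(path: Path) -> Annotation:
    raw = json.loads(path.read_text())
    beats = [(int(b["sample"]), str(b["label"])) for b in raw.get("beats", [])]
    eps = [
        (int(e["start"]), int(e["end"]), str(e["rhythm"]))
        for e in raw.get("episodes", [])
    ]
    return Annotation(beats, eps)


def write_annotations_json(path: str | Path, ann: Annotation) -> None:
    payload = {
        "beats": [{"sample": int(s), "label": lab} for s, lab in ann.beat_marks],
        "episodes": [
            {"start": int(s), "end": int(e), "rhythm": r}
            for s, e, r in ann.rhythm_episodes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_annotations_atr(path: str | Path, ann: Annotation) -> None:
    """Write beats and rhythm episodes in the MIT annotation format."""
    events: list[tuple[int, int, str | None]] = []  # (sample, code, aux)
    for s, lab in ann.beat_marks:
        events.append((s, _SYM_TO_CODE.get(lab, 13), None))
    rhythm_aux = {"AF": "(AFIB", "VF": "(VF", "SINUS": "(N", "OTHER": "(OTHER"}
    bounds = sorted(ann.rhythm_episodes)
    for k, (s, e, r) in enumerate(bounds):
        events.append((s, _RHYTHM_CODE, rhythm_aux[r]))
        nxt = bounds[k + 1][0] if k + 1 < len(bounds) else None
        if nxt != e:
            events.append((e, _RHYTHM_CODE, "(N"))
    events.sort(key=lambda x: (x[0], x[1] == _RHYTHM_CODE))
    out = bytearray()
    t = 0
    for sample, code, aux in events:
        delta = sample - t
        while delta > 1023:
            chunk = min(delta, (1 << 31) - 1)
            out += (59 << 10).to_bytes(2, "little")
            out += ((chunk >> 16) & 0xFFFF).to_bytes(2, "little")
            out += (chunk & 0xFFFF).to_bytes(2, "little")
            delta = 0  # SKIP carries the whole interval; event word gets 0
            t = sample
        out += ((code << 10) | delta).to_bytes(2, "little")
        t = sample
        if aux is not None:
            data = aux.encode("latin-1")
            out += ((63 << 10) | len(data)).to_bytes(2, "little")
            out += data + (b"\x00" if len(data) % 2 else b"")
    out += (0).to_bytes(2, "little")
    Path(path).write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# Resampling and windowing
# ---------------------------------------------------------------------------

def resample(rec: EcgRecord, target_fs: float = 200.0) -> EcgRecord:
    """Resample to ``target_fs`` with polyphase FIR anti-aliasing.

    Output length is ``round(n * target_fs / fs)``.  At ``target_fs == fs``
    the samples pass through unchanged.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if rec.fs == target_fs:
        return rec
    n_out = int(round(len(rec) * target_fs / rec.fs))
    if len(rec) == 0:
        return EcgRecord(np.empty(0), target_fs, rec.record_id, rec.lead_name)
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    y = sps.resample_poly(rec.samples, up, down)
    if len(y) >= n_out:
        y = y[:n_out]
    else:
        y = np.pad(y, (0, n_out - len(y)))
    return EcgRecord(y, target_fs, rec.record_id, rec.lead_name)


def rescale_annotation(ann: Annotation, fs_from: float, fs_to: float) -> Annotation:
    """Rescale annotation sample indices by ``fs_to / fs_from``."""
    ratio = fs_to / fs_from
    beats: list[tuple[int, str]] = []
    for s, lab in ann.beat_marks:
        ns = int(round(s * ratio))
        if beats and ns <= beats[-1][0]:  # collisions after coarse rescale
            ns = beats[-1][0] + 1
        beats.append((ns, lab))
    eps = [
        (int(round(s * ratio)), max(int(round(e * ratio)), int(round(s * ratio)) + 1), r)
        for s, e, r in ann.rhythm_episodes
    ]
    return Annotation(beats, eps)


def slice_windows(rec: EcgRecord, window_s: float = 300.0,
                  min_tail_s: float = 60.0) -> list[EcgRecord]:
    """Cut a record into consecutive non-overlapping windows.

    A trailing partial window is kept (with ``partial=True``) when it is at
    least ``min_tail_s`` long, otherwise dropped.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n_win = int(round(window_s * rec.fs))
    out: list[EcgRecord] = []
    for k, start in enumerate(range(0, len(rec), n_win)):
        chunk = rec.samples[start : start + n_win]
        if len(chunk) == n_win:
            out.append(EcgRecord(chunk, rec.fs, f"{rec.record_id}.w{k}",
                                 rec.lead_name))
        elif len(chunk) / rec.fs >= min_tail_s:
            out.append(EcgRecord(chunk, rec.fs, f"{rec.record_id}.w{k}",
                                 rec.lead_name, partial=True))
    return out
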
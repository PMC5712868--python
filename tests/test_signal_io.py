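"""Record/annotation I/O, resampling and windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhythmscan import signal_io
from rhythmscan.signal_io import (Annotation, EcgRecord, FormatError,
                                  read_annotations, read_record,
                                  rescale_annotation, resample, slice_windows,
                                  write_annotations_atr,
                                  write_annotations_json, write_record)


class TestRecordIO:
    def test_header_echo(self, tmp_path):
        rec = EcgRecord(np.sin(np.arange(6500) / 20.0), fs=360.0,
                        record_id="hdr")
        write_record(tmp_path / "hdr.hea", rec)
        back = read_record(tmp_path / "hdr.hea")
        assert back.fs == 360.0
        assert len(back) == 6500

    def test_csv_rate_inference(self, tmp_path):
        p = tmp_path / "two.csv"
        p.write_text("0,0.0\n0.005,0.1\n")
        rec = read_record(p)
        assert rec.fs == pytest.approx(200.0)
        assert len(rec) == 2

    @pytest.mark.parametrize("fmt", [16, 212])
    def test_write_read_round_trip(self, tmp_path, fmt):
        rng = np.random.default_rng(0)
        rec = EcgRecord(rng.uniform(-5, 5, 1001), fs=200.0, record_id="rt")
        write_record(tmp_path / "rt.hea", rec, fmt=fmt)
        back = read_record(tmp_path / "rt.hea")
        # exact up to the 1/200 mV ADC quantization of the writer
        assert np.max(np.abs(back.samples - rec.samples)) <= 0.5 / 200.0
        # and a second write/read of the quantized signal is lossless
        write_record(tmp_path / "rt2.hea", back, fmt=fmt)
        again = read_record(tmp_path / "rt2.hea")
        assert np.array_equal(again.samples, back.samples)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_record(tmp_path / "nope.hea")

    def test_unsupported_format_named(self, tmp_path):
        (tmp_path / "bad.hea").write_text("bad 1 200 10\nbad.dat 80 200/mV\n")
        (tmp_path / "bad.dat").write_bytes(b"\x00" * 10)
        with pytest.raises(FormatError, match="80"):
            read_record(tmp_path / "bad.hea")


def _atr_word(code, delta):
    return ((code << 10) | delta).to_bytes(2, "little")


class TestAnnotationIO:
    def test_symbol_mapping(self, tmp_path):
        # N@100, A@300, V@500 written as raw MIT words
        raw = _atr_word(1, 100) + _atr_word(8, 200) + _atr_word(5, 200)
        raw += (0).to_bytes(2, "little")
        p = tmp_path / "m.atr"
        p.write_bytes(raw)
        ann = read_annotations(p)
        assert ann.beat_marks == [(100, "N"), (300, "S"), (500, "V")]

    def test_rhythm_pairing(self, tmp_path):
        raw = _atr_word(28, 1000)
        aux = b"(AFIB"
        raw += _atr_word(63, len(aux)) + aux + b"\x00"
        # interval 4000 exceeds the 10-bit field: SKIP word + 4-byte interval
        raw += _atr_word(59, 0)
        raw += (0).to_bytes(2, "little") + (4000).to_bytes(2, "little")
        raw += _atr_word(28, 0)
        aux2 = b"(N"
        raw += _atr_word(63, len(aux2)) + aux2
        raw += (0).to_bytes(2, "little")
        p = tmp_path / "r.atr"
        p.write_bytes(raw)
        ann = read_annotations(p, record_len=9000)
        assert (1000, 5000, "AF") in ann.rhythm_episodes

    def test_dangling_rhythm_closed_at_end(self, tmp_path):
        raw = _atr_word(28, 100)
        raw += _atr_word(63, 5) + b"(AFIB" + b"\x00"
        raw += (0).to_bytes(2, "little")
        p = tmp_path / "d.atr"
        p.write_bytes(raw)
        ann = read_annotations(p, record_len=800)
        assert ann.episodes_of("AF") == [(100, 800)]

    def test_empty_annotation_file(self, tmp_path):
        p = tmp_path / "e.atr"
        p.write_bytes((0).to_bytes(2, "little"))
        ann = read_annotations(p)
        assert ann.beat_marks == [] and ann.rhythm_episodes == []

    def test_atr_writer_round_trip(self, tmp_path):
        ann = Annotation([(100, "N"), (2000, "V"), (90000, "S")],
                         [(0, 5000, "AF"), (60000, 95000, "VF")])
        p = tmp_path / "w.atr"
        write_annotations_atr(p, ann)
        back = read_annotations(p, record_len=95000)
        assert back.beat_marks == ann.beat_marks
        assert back.episodes_of("AF") == [(0, 5000)]
        assert back.episodes_of("VF") == [(60000, 95000)]

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 10**6),
                              st.sampled_from("NSVQ")),
                    unique_by=lambda b: b[0], max_size=20))
    def test_json_round_trip_lossless(self, tmp_path_factory, beats):
        ann = Annotation(sorted(beats), [(5, 10, "AF")])
        p = tmp_path_factory.mktemp("json") / "a.json"
        write_annotations_json(p, ann)
        back = read_annotations(p)
        assert back.beat_marks == ann.beat_marks
        assert back.rhythm_episodes == ann.rhythm_episodes


class TestResample:
    def test_output_length(self):
        rec = EcgRecord(np.zeros(65000), fs=360.0)
        out = resample(rec, 200.0)
        assert len(out) == round(65000 * 200 / 360) == 36111
        assert out.fs == 200.0

    def test_identity_at_same_rate(self, sinus_record):
        rec, _ = sinus_record
        out = resample(rec, rec.fs)
        assert out is rec

    def test_tone_survives_downsampling(self):
        fs, n = 360.0, 36000
        t = np.arange(n) / fs
        rec = EcgRecord(np.sin(2 * np.pi * 4.0 * t), fs=fs)
        out = resample(rec, 200.0)
        spec = np.abs(np.fft.rfft(out.samples))
        freqs = np.fft.rfftfreq(len(out), 1 / 200.0)
        dominant = freqs[np.argmax(spec)]
        assert abs(dominant - 4.0) <= freqs[1]  # within one bin

    def test_empty_record(self):
        out = resample(EcgRecord(np.empty(0), fs=360.0), 200.0)
        assert len(out) == 0 and out.fs == 200.0

    def test_annotation_rescale(self):
        ann = Annotation([(360, "N"), (720, "V")], [(0, 3600, "AF")])
        out = rescale_annotation(ann, 360.0, 200.0)
        assert out.beat_marks == [(200, "N"), (400, "V")]
        assert out.rhythm_episodes == [(0, 2000, "AF")]


class TestSliceWindows:
    def test_thirty_minutes(self):
        rec = EcgRecord(np.zeros(30 * 60 * 200), fs=200.0)
        wins = slice_windows(rec)
        assert len(wins) == 6
        assert all(len(w) == 60000 for w in wins)

    def test_short_tail_dropped(self):
        rec = EcgRecord(np.zeros(310 * 200), fs=200.0)
        wins = slice_windows(rec)
        assert len(wins) == 1 and not wins[0].partial

    def test_long_tail_kept_flagged(self):
        rec = EcgRecord(np.zeros(400 * 200), fs=200.0)
        wins = slice_windows(rec)
        assert len(wins) == 2 and wins[1].partial
        assert len(wins[1]) == 100 * 200

    def test_empty_record(self):
        assert slice_windows(EcgRecord(np.empty(0), fs=200.0)) == []

    def test_concatenation_reconstructs(self):
        rng = np.random.default_rng(1)
        rec = EcgRecord(rng.normal(size=75_000), fs=200.0)
        wins = slice_windows(rec, window_s=300.0, min_tail_s=60.0)
        rebuilt = np.concatenate([w.samples for w in wins])
        assert np.array_equal(rebuilt, rec.samples[: len(rebuilt)])
        # anything not reconstructed is a dropped sub-minimum tail
        assert len(rec) - len(rebuilt) < 60.0 * rec.fs
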
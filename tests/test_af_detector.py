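"""RR correction, symbolization, sample entropy and the AF window decision."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_sample_entropy
from rhythmscan import synth_ecg
from rhythmscan.af_detector import (af_windows_to_episodes, correct_rr,
                                    detect_af_window, rr_to_hr,
                                    sample_entropy, symbolize, word_values)
from rhythmscan.config import AfConfig
from rhythmscan.qrs_beats import BeatSeries


class TestCorrectRr:
    def test_interior_vpc(self):
        out = correct_rr([0.8, 0.8, 0.5, 1.1], ["N", "N", "V", "N", "N"])
        assert out.tolist() == pytest.approx([0.8, 0.95, 0.95, 1.1])

    def test_no_vpc_identity(self):
        rr = [0.8, 0.9, 1.0]
        out = correct_rr(rr, ["N"] * 4)
        assert out.tolist() == rr

    def test_edge_vpc_single_neighbor(self):
        out = correct_rr([0.5, 1.0], ["V", "N", "N"])
        assert out.tolist() == [1.0, 1.0]

    def test_all_v_returned_unchanged_with_warning(self):
        with pytest.warns(UserWarning):
            out = correct_rr([0.5, 0.6], ["V", "V", "V"])
        assert out.tolist() == [0.5, 0.6]

    def test_non_adjacent_intervals_untouched(self):
        rng = np.random.default_rng(0)
        rr = rng.uniform(0.5, 1.2, 30)
        labels = ["N"] * 31
        labels[10] = "V"
        out = correct_rr(rr, labels)
        mask = np.ones(30, dtype=bool)
        mask[[9, 10]] = False
        assert np.array_equal(out[mask], rr[mask])
        assert len(out) == len(rr)


class TestSymbolization:
    @pytest.mark.parametrize("rr,hr", [(1.0, 60.0), (0.5, 120.0),
                                       (60.0 / 315.0, 315.0)])
    def test_rr_to_hr(self, rr, hr):
        assert rr_to_hr([rr])[0] == pytest.approx(hr)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            rr_to_hr([1.0, 0.0])

    @pytest.mark.parametrize("hr,sy", [(315, 63), (400, 63), (60, 12),
                                       (314, 62), (0, 0), (4.9, 0)])
    def test_symbolize_cases(self, hr, sy):
        assert symbolize([hr])[0] == sy

    @pytest.mark.parametrize("sy,wv", [((12, 12, 12), 49932), ((0, 0, 0), 0),
                                       ((63, 63, 63), 262143)])
    def test_word_value_cases(self, sy, wv):
        assert word_values(np.array(sy))[0] == wv

    def test_word_values_too_short(self):
        assert len(word_values(np.array([1, 2]))) == 0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=50))
    def test_symbol_and_word_ranges(self, hr):
        sy = symbolize(np.array(hr, dtype=float))
        assert np.all((sy >= 0) & (sy <= 63))
        wv = word_values(sy)
        assert np.all((wv >= 0) & (wv <= 2**18 - 1))

    def test_word_values_injective_on_triples(self):
        rng = np.random.default_rng(3)
        triples = rng.integers(0, 64, size=(500, 3))
        codes = {tuple(t): int(word_values(t)[0]) for t in triples}
        assert len(set(codes.values())) == len(codes)


class TestSampleEntropy:
    def test_constant_sequence_zero(self):
        assert sample_entropy(np.ones(100), m=2, r=0.1) == 0.0

    def test_too_short_undefined(self):
        assert sample_entropy(np.array([1.0, 2.0, 3.0]), m=2, r=0.5) is None

    def test_no_matches_undefined_not_zero(self):
        x = np.array([0.0, 100.0, 0.0, 100.0, 50.0, -70.0, 3.0, 9.0])
        assert sample_entropy(x, m=2, r=1e-6) is None

    @pytest.mark.parametrize("seed,n,m", [(0, 100, 2), (1, 50, 1),
                                          (2, 200, 3), (3, 80, 2)])
    def test_matches_brute_force_oracle(self, seed, n, m):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=n)
        r = 0.2 * float(np.std(x))
        got = sample_entropy(x, m=m, r=r)
        want = brute_sample_entropy(x, m, r)
        assert got == pytest.approx(want, abs=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=120)
        a = sample_entropy(x, 2, 0.3)
        b = sample_entropy(x + 1000.0, 2, 0.3)
        assert a == pytest.approx(b, abs=1e-12)

    def test_non_increasing_in_r(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=150)
        vals = [sample_entropy(x, 2, r) for r in (0.1, 0.3, 0.6, 1.2)]
        vals = [v for v in vals if v is not None]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


def _beats_from_ann(ann, fs=200.0):
    return BeatSeries(np.array([s for s, _ in ann.beat_marks]), fs,
                      [lab for _, lab in ann.beat_marks])


class TestAfWindow:
    def test_metronomic_not_af(self):
        beats = BeatSeries(np.arange(300) * 160, 200.0, ["N"] * 300)
        d = detect_af_window(beats)
        assert d.sampen == 0.0 and d.is_af is False

    def test_few_beats_undetermined(self):
        beats = BeatSeries(np.arange(20) * 200, 200.0, ["N"] * 20)
        d = detect_af_window(beats)
        assert d.is_af is None and d.sampen is None

    def test_synthetic_af_positive(self):
        cfg = synth_ecg.SynthConfig(rhythm_plan=[("AF", 300.0)], seed=21)
        _, ann = synth_ecg.generate_record(cfg)
        d = detect_af_window(_beats_from_ann(ann))
        assert d.is_af is True

    def test_synthetic_sinus_negative(self):
        cfg = synth_ecg.SynthConfig(rhythm_plan=[("SINUS", 300.0)], seed=22)
        _, ann = synth_ecg.generate_record(cfg)
        d = detect_af_window(_beats_from_ann(ann))
        assert d.is_af is False

    def test_af_sinus_entropy_separation(self):
        af_vals, sinus_vals = [], []
        for k in range(5):
            for rhythm, store in (("AF", af_vals), ("SINUS", sinus_vals)):
                cfg = synth_ecg.SynthConfig(rhythm_plan=[(rhythm, 300.0)],
                                            seed=50 + k)
                _, ann = synth_ecg.generate_record(cfg)
                store.append(detect_af_window(_beats_from_ann(ann)).sampen)
        assert np.median(af_vals) > np.median(sinus_vals)

    def test_window_merge_to_episodes(self):
        cfg = AfConfig()
        mk = lambda flag: detect_af_window(
            BeatSeries(np.arange(2) * 100, 200.0, ["N", "N"]), cfg)
        # fabricate decisions directly
        from rhythmscan.af_detector import AfDecision
        ds = [AfDecision("", 1.5, f, 200, cfg)
              for f in (False, True, True, False, True)]
        eps = af_windows_to_episodes(ds, 60000)
        assert eps == [(60000, 180000), (240000, 300000)]
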
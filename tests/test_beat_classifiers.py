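"""VPC rule and APC perceptron."""

import math

import numpy as np
import pytest

from rhythmscan.beat_classifiers import (MlpModel, classify_apc, classify_vpc,
                                         loss_and_grad, mlp_forward,
                                         train_apc_mlp)
from rhythmscan.config import MlpConfig, VpcConfig
from rhythmscan.qrs_beats import BeatFeatures, BeatSeries


def _beats(n, fs=200.0, labels=None):
    return BeatSeries(np.arange(n) * 200, fs, labels)


def _feat(**kw):
    return BeatFeatures(**kw)


class TestVpcRule:
    def test_wide_premature_is_v(self):
        feats = [_feat(qrs_duration=0.08, rr_prev=1.0, rr_mean_20=1.0)
                 for _ in range(10)]
        feats[7] = _feat(qrs_duration=0.16, rr_prev=0.6, rr_mean_20=1.0)
        out = classify_vpc(feats, _beats(10))
        assert out.labels[7] == "V"
        assert out.labels.count("V") == 1

    def test_metronomic_narrow_all_n(self):
        feats = [_feat(qrs_duration=0.08, rr_prev=1.0, rr_mean_20=1.0)
                 for _ in range(20)]
        out = classify_vpc(feats, _beats(20))
        assert out.labels == ["N"] * 20

    def test_undefined_rr_prev_never_v(self):
        feats = [_feat(qrs_duration=0.20, rr_prev=math.nan, rr_mean_20=1.0)]
        feats += [_feat(qrs_duration=0.08, rr_prev=1.0, rr_mean_20=1.0)
                  for _ in range(9)]
        out = classify_vpc(feats, _beats(10))
        assert out.labels[0] == "N"

    def test_wide_but_not_premature_is_n(self):
        feats = [_feat(qrs_duration=0.08, rr_prev=1.0, rr_mean_20=1.0)
                 for _ in range(10)]
        feats[5] = _feat(qrs_duration=0.2, rr_prev=1.0, rr_mean_20=1.0)
        out = classify_vpc(feats, _beats(10))
        assert out.labels[5] == "N"


def _gaussian_clouds(n=600, sep=4.0, seed=42):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n // 2, 7)),
                   rng.normal(sep, 1, (n // 2, 7))])
    y = ["N"] * (n // 2) + ["S"] * (n // 2)
    return X, y


class TestMlpTraining:
    def test_separable_clouds_high_accuracy(self):
        X, y = _gaussian_clouds()
        _, rep = train_apc_mlp(X, y, seed=1)
        assert rep.test_accuracy >= 0.95

    def test_permuted_labels_chance_accuracy(self):
        X, y = _gaussian_clouds()
        rng = np.random.default_rng(9)
        _, rep = train_apc_mlp(X, list(rng.permutation(y)), seed=2)
        assert 0.40 <= rep.test_accuracy <= 0.60

    def test_same_seed_bitwise_identical(self):
        X, y = _gaussian_clouds()
        m1, _ = train_apc_mlp(X, y, seed=3)
        m2, _ = train_apc_mlp(X, y, seed=3)
        assert np.array_equal(m1.w1, m2.w1) and np.array_equal(m1.b1, m2.b1)
        assert np.array_equal(m1.w2, m2.w2) and m1.b2 == m2.b2

    def test_single_class_refused(self):
        X = np.random.default_rng(0).normal(size=(40, 7))
        with pytest.raises(ValueError, match="class"):
            train_apc_mlp(X, ["N"] * 40)

    def test_training_loss_non_increasing(self):
        X, y = _gaussian_clouds(n=200)
        _, rep = train_apc_mlp(X, y, seed=4)
        diffs = np.diff(rep.history)
        assert np.all(diffs <= 1e-9)

    def test_nan_features_imputed(self):
        X, y = _gaussian_clouds(n=200)
        X[::7, 3] = np.nan
        model, rep = train_apc_mlp(X, y, seed=5)
        assert rep.test_accuracy >= 0.9
        assert np.isfinite(model.impute).all()

    def test_model_json_round_trip(self, tmp_path):
        X, y = _gaussian_clouds(n=200)
        model, _ = train_apc_mlp(X, y, seed=6)
        p = tmp_path / "m.json"
        model.save(p)
        back = MlpModel.load(p)
        x = np.zeros(7)
        assert mlp_forward(back, x) == pytest.approx(mlp_forward(model, x))


class TestMlpForward:
    def test_zero_weights_give_half(self):
        m = MlpModel(w1=np.zeros((7, 4)), b1=np.zeros(4), w2=np.zeros(4),
                     b2=0.0, impute=np.zeros(7), mean=np.zeros(7),
                     std=np.ones(7))
        assert mlp_forward(m, np.zeros(7)) == pytest.approx(0.5)

    def test_large_bias_saturates(self):
        m = MlpModel(w1=np.zeros((7, 4)), b1=np.zeros(4), w2=np.zeros(4),
                     b2=50.0, impute=np.zeros(7), mean=np.zeros(7),
                     std=np.ones(7))
        assert mlp_forward(m, np.zeros(7)) > 0.999999

    def test_wrong_dimension_rejected(self):
        m = MlpModel(w1=np.zeros((7, 4)), b1=np.zeros(4), w2=np.zeros(4),
                     b2=0.0, impute=np.zeros(7), mean=np.zeros(7),
                     std=np.ones(7))
        with pytest.raises(ValueError):
            mlp_forward(m, np.zeros(5))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        w1 = rng.normal(size=(7, 5))
        b1 = rng.normal(size=5)
        w2 = rng.normal(size=5)
        b2 = 0.3
        X = rng.normal(size=(20, 7))
        y = (rng.uniform(size=20) > 0.5).astype(float)
        sw = rng.uniform(0.5, 2.0, 20)
        _, grads = loss_and_grad((w1, b1, w2, b2), X, y, sw)
        eps = 1e-6
        params = [w1.copy(), b1.copy(), w2.copy(), b2]

        def num_grad(pi, idx=None):
            def at(v):
                p = [q.copy() if isinstance(q, np.ndarray) else q
                     for q in params]
                if idx is None:
                    p[pi] = v
                else:
                    p[pi][idx] = v
                return loss_and_grad(tuple(p), X, y, sw)[0]
            v0 = params[pi] if idx is None else params[pi][idx]
            return (at(v0 + eps) - at(v0 - eps)) / (2 * eps)

        worst = 0.0
        for pi in range(3):
            it = np.nditer(params[pi], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                num = num_grad(pi, idx)
                ana = grads[pi][idx]
                worst = max(worst, abs(num - ana) / max(abs(num), abs(ana), 1e-8))
        worst = max(worst, abs(num_grad(3) - grads[3])
                    / max(abs(grads[3]), 1e-8))
        assert worst < 1e-4


class TestClassifyApc:
    def _model(self, bias):
        return MlpModel(w1=np.zeros((7, 2)), b1=np.zeros(2), w2=np.zeros(2),
                        b2=bias, impute=np.zeros(7), mean=np.zeros(7),
                        std=np.ones(7))

    def test_v_labels_preserved(self):
        feats = [_feat() for _ in range(3)]
        beats = _beats(3, labels=["V", "N", "N"])
        out = classify_apc(self._model(bias=50.0), feats, beats)
        assert out.labels == ["V", "S", "S"]

    def test_below_threshold_is_n(self):
        feats = [_feat()]
        out = classify_apc(self._model(bias=-0.1), feats, _beats(1))
        assert out.labels == ["N"]

    def test_tie_at_half_is_s(self):
        feats = [_feat()]
        out = classify_apc(self._model(bias=0.0), feats, _beats(1))
        assert out.labels == ["S"]
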
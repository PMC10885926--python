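"""SpO2 head: manual features, MFAM attention, CNN-BiLSTM, constrained
fusion, end-to-end loss, and the frozen-backbone training stage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vidspo2 import nn
from vidspo2.exceptions import (InsufficientLengthError, InvalidParameterError,
                                ShapeError)
from vidspo2.preprocess import VideoClip
from vidspo2.spo2_head import (MFAM, CnnBiLstm, Fusion, FusionWeights,
                               GenericLstmHead, SpO2Estimate, end_to_end_loss,
                               fuse, manual_features, mfam_forward,
                               photometric_summary, photometric_traces)


class TestManualFeatures:
    def test_constant_clip(self):
        clip = VideoClip(np.full((4, 8, 8, 3), 0.5, np.float32), 30.0)
        c = manual_features(clip)
        np.testing.assert_allclose(c.values[:3], 0.5, atol=1e-7)
        np.testing.assert_allclose(c.values[3:], 0.0, atol=1e-9)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(size=(3, 4, 5, 3)).astype(np.float32)
        c = manual_features(VideoClip(frames, 30.0))
        for ch in range(3):
            vals = [float(frames[t, i, j, ch])
                    for t in range(3) for i in range(4) for j in range(5)]
            assert c.values[ch] == pytest.approx(np.mean(vals), abs=1e-9)
            assert c.values[3 + ch] == pytest.approx(np.var(vals), abs=1e-9)

    def test_moment_scaling(self):
        rng = np.random.default_rng(1)
        frames = rng.uniform(0.0, 0.5, size=(3, 4, 4, 3)).astype(np.float32)
        c1 = manual_features(VideoClip(frames, 30.0))
        c2 = manual_features(VideoClip(2.0 * frames, 30.0))
        np.testing.assert_allclose(c2.values[:3], 2.0 * c1.values[:3],
                                   rtol=1e-5)
        np.testing.assert_allclose(c2.values[3:], 4.0 * c1.values[3:],
                                   rtol=1e-4)


class TestMFAM:
    @given(st.integers(min_value=0, max_value=10 ** 6))
    @settings(max_examples=30, deadline=None)
    def test_attention_weights_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        mfam = MFAM(rng=rng)
        c = nn.Tensor(np.abs(rng.normal(0.5, 0.2, size=(3, 6))))
        a, _ = mfam(c)
        np.testing.assert_allclose(a.data.sum(axis=1), 1.0, atol=1e-9)

    def test_equal_features_give_that_value(self):
        mfam = MFAM(rng=np.random.default_rng(2))
        c = np.full((2, 6), 0.42)
        _, m2 = mfam(nn.Tensor(c))
        np.testing.assert_allclose(m2.data, 0.42, atol=1e-9)

    def test_zero_params_give_uniform_mean(self):
        c = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        out = mfam_forward(c, np.zeros((6, 6)), np.zeros(6))
        assert out == pytest.approx(c.mean(), abs=1e-9)

    def test_nonfinite_params_rejected(self):
        with pytest.raises(InvalidParameterError):
            mfam_forward(np.full(6, 0.5), np.full((6, 6), np.nan), np.zeros(6))


class TestHeads:
    @pytest.mark.parametrize("head_cls", [CnnBiLstm, GenericLstmHead])
    def test_output_range_batch_and_determinism(self, head_cls):
        head = head_cls(rng=np.random.default_rng(3))
        x = nn.Tensor(np.random.default_rng(4).standard_normal(
            (5, 9, 40)).astype(np.float32))
        e = nn.Tensor(np.random.default_rng(5).standard_normal(
            (5, 6)).astype(np.float32))
        y1, y2 = head(x, extra=e), head(x, extra=e)
        assert y1.shape == (5,)
        assert np.all((y1.data > 0) & (y1.data < 1))
        np.testing.assert_array_equal(y1.data, y2.data)

    def test_short_window_rejected(self):
        head = CnnBiLstm(rng=np.random.default_rng(6))
        with pytest.raises(InsufficientLengthError):
            head(nn.Tensor(np.zeros((1, 9, 5), np.float32)))


class TestFusion:
    def test_initializes_at_even_split(self):
        w = Fusion().weights()
        assert (w.k1, w.k2) == (50.0, 50.0)

    def test_constraint_exact_after_optimization(self):
        fusion = Fusion()
        opt = nn.Adam(fusion.parameters(), lr=0.1)
        rng = np.random.default_rng(7)
        for _ in range(25):
            m1 = nn.Tensor(rng.uniform(0.9, 1.0, size=4))
            m2 = nn.Tensor(rng.uniform(0.4, 0.6, size=4))
            pred = fusion(m1, m2)
            loss = ((pred - nn.Tensor(np.full(4, 97.0))) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            w = fusion.weights()
            assert w.k1 + w.k2 == 100.0        # exact, every step

    def test_fuse_examples(self):
        w = FusionWeights(k1=87.0, k2=13.0)    # published trained split
        assert fuse(0.97, 0.97, w).value == pytest.approx(97.0)
        w2 = FusionWeights(k1=30.0, k2=70.0)
        assert fuse(0.8, 0.8, w2).value == pytest.approx(80.0)
        w3 = FusionWeights(k1=100.0, k2=0.0)
        assert fuse(0.9, 0.1, w3).value == pytest.approx(90.0)

    def test_invalid_weights_rejected(self):
        with pytest.raises(InvalidParameterError):
            FusionWeights(k1=60.0, k2=60.0)
        with pytest.raises(InvalidParameterError):
            FusionWeights(k1=-5.0, k2=105.0)

    def test_estimate_clipped(self):
        assert SpO2Estimate(140.0).value == 100.0
        assert SpO2Estimate(-3.0).value == 0.0


class TestEndToEndLoss:
    def test_examples(self):
        r = np.array([96.0, 97.0])
        assert end_to_end_loss(r, r) == 0.0
        assert end_to_end_loss(r + 2.0, r) == pytest.approx(4.0)
        assert end_to_end_loss([95.0, 99.0], [96.0, 96.0]) == pytest.approx(5.0)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            end_to_end_loss([95.0], [96.0, 96.0])


class TestPhotometricFeatures:
    def test_traces_are_relative_percent(self):
        frames = np.full((10, 4, 4, 3), 0.5, np.float32)
        frames[:, :, :, 0] *= (1 + 0.01 * np.sin(
            np.linspace(0, 4 * np.pi, 10)))[:, None, None]
        tr = photometric_traces(VideoClip(frames, 30.0))
        assert tr.shape == (3, 10)
        assert np.abs(tr[0]).max() == pytest.approx(1.0, rel=0.2)
        np.testing.assert_allclose(tr[1], 0.0, atol=1e-4)

    def test_summary_shift_invariance(self):
        rng = np.random.default_rng(8)
        photo = rng.standard_normal((3, 60))
        a = photometric_summary(photo)
        b = photometric_summary(np.roll(photo, 17, axis=1))
        np.testing.assert_allclose(a, b, rtol=0.2, atol=0.05)
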
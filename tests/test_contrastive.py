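"""Contrastive losses against literal brute-force oracles, pseudo-sample
construction, and the supervised cosine loss."""

import numpy as np
import pytest

from vidspo2 import nn
from vidspo2.contrastive import (ContrastiveBatch, build_pseudo_sample,
                                 negative_loss, positive_loss, psd_features,
                                 psd_grid, supervised_loss)
from vidspo2.exceptions import DegenerateSignalError
from vidspo2.preprocess import VideoClip
from vidspo2.signalcore import Waveform, compute_psd
from vidspo2.synthetic import SceneConfig, generate


def random_psds(rng, *shape):
    p = rng.uniform(0.01, 1.0, size=shape)
    return p / p.sum(axis=-1, keepdims=True)


def make_batch(rng, n=2, f=5):
    return ContrastiveBatch(
        f_a=random_psds(rng, n, f), f_b=random_psds(rng, n, f),
        f_c=random_psds(rng, n, f), f_d=random_psds(rng, n, f),
        hand_regions=random_psds(rng, n, 4, f),
        face_regions=random_psds(rng, n, 4, f),
    )


def brute_force_positive(batch):
    """Literal quadruple-loop evaluation of the positive loss."""
    fa, fb = batch.f_a.data, batch.f_b.data
    fd = batch.f_d.data
    hand, face = batch.hand_regions.data, batch.face_regions.data
    n = fa.shape[0]
    region = 0.0
    for n1 in range(n):
        for n2 in range(n):
            for i in range(4):
                for j in range(4):
                    region += np.sum((hand[n1, i] - hand[n2, j]) ** 2)
                    region += np.sum((face[n1, i] - face[n2, j]) ** 2)
    region /= 16.0 * n * n
    st = float(np.mean(np.sum((fa - fb) ** 2, axis=1))
               + np.mean(np.sum((fa - fd) ** 2, axis=1)))
    return region + st


def brute_force_negative(batch):
    fa, fc = batch.f_a.data, batch.f_c.data
    n = fa.shape[0]
    total = 0.0
    for n1 in range(n):
        for n2 in range(n):
            total += np.sum((fa[n1] - fc[n2]) ** 2)
    return -total / (n * n)


class TestPositiveLoss:
    @pytest.mark.parametrize("n", [1, 2])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, n, seed):
        batch = make_batch(np.random.default_rng(seed), n=n)
        assert float(positive_loss(batch).data) == pytest.approx(
            brute_force_positive(batch), abs=1e-9)

    def test_identical_psds_give_zero(self):
        rng = np.random.default_rng(3)
        p = random_psds(rng, 5)
        n = 2
        batch = ContrastiveBatch(
            f_a=np.tile(p, (n, 1)), f_b=np.tile(p, (n, 1)),
            f_c=np.tile(p, (n, 1)), f_d=np.tile(p, (n, 1)),
            hand_regions=np.tile(p, (n, 4, 1)),
            face_regions=np.tile(p, (n, 4, 1)))
        assert float(positive_loss(batch).data) == pytest.approx(0.0, abs=1e-12)

    def test_two_distinct_hand_regions_hand_term(self):
        """N=1, regions p,p,q,q on the hand: ordered-pair sum = 8*||p-q||^2."""
        rng = np.random.default_rng(4)
        p, q = random_psds(rng, 5), random_psds(rng, 5)
        base = random_psds(rng, 5)
        batch = ContrastiveBatch(
            f_a=base[None], f_b=base[None], f_c=base[None], f_d=base[None],
            hand_regions=np.stack([p, p, q, q])[None],
            face_regions=np.tile(base, (1, 4, 1)))
        expected = 8.0 * np.sum((p - q) ** 2) / 16.0
        assert float(positive_loss(batch).data) == pytest.approx(expected,
                                                                 abs=1e-9)

    def test_non_negative_and_permutation_invariant(self):
        rng = np.random.default_rng(5)
        batch = make_batch(rng, n=2)
        val = float(positive_loss(batch).data)
        assert val >= 0.0
        # permute batch order
        perm = ContrastiveBatch(
            f_a=batch.f_a.data[::-1].copy(), f_b=batch.f_b.data[::-1].copy(),
            f_c=batch.f_c.data[::-1].copy(), f_d=batch.f_d.data[::-1].copy(),
            hand_regions=batch.hand_regions.data[::-1].copy(),
            face_regions=batch.face_regions.data[::-1].copy())
        assert float(positive_loss(perm).data) == pytest.approx(val, abs=1e-12)
        # permute region labels within each body part
        rperm = ContrastiveBatch(
            f_a=batch.f_a.data, f_b=batch.f_b.data,
            f_c=batch.f_c.data, f_d=batch.f_d.data,
            hand_regions=batch.hand_regions.data[:, [2, 0, 3, 1]].copy(),
            face_regions=batch.face_regions.data[:, [1, 3, 0, 2]].copy())
        assert float(positive_loss(rperm).data) == pytest.approx(val, abs=1e-12)

    def test_gradient_flows_to_psds(self):
        rng = np.random.default_rng(6)
        fa = nn.Tensor(random_psds(rng, 2, 5), requires_grad=True)
        batch = ContrastiveBatch(
            f_a=fa, f_b=random_psds(rng, 2, 5), f_c=random_psds(rng, 2, 5),
            f_d=random_psds(rng, 2, 5), hand_regions=random_psds(rng, 2, 4, 5),
            face_regions=random_psds(rng, 2, 4, 5))
        positive_loss(batch).backward()
        assert fa.grad is not None and np.any(fa.grad != 0)


class TestNegativeLoss:
    @pytest.mark.parametrize("n", [1, 2])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force(self, n, seed):
        batch = make_batch(np.random.default_rng(seed), n=n)
        assert float(negative_loss(batch).data) == pytest.approx(
            brute_force_negative(batch), abs=1e-9)

    def test_known_values_and_bounds(self):
        rng = np.random.default_rng(7)
        p = random_psds(rng, 5)
        same = ContrastiveBatch(
            f_a=p[None], f_b=p[None], f_c=p[None], f_d=p[None],
            hand_regions=np.tile(p, (1, 4, 1)),
            face_regions=np.tile(p, (1, 4, 1)))
        assert float(negative_loss(same).data) == pytest.approx(0.0, abs=1e-12)

        disjoint = ContrastiveBatch(
            f_a=np.array([[1.0, 0.0]]), f_b=np.array([[1.0, 0.0]]),
            f_c=np.array([[0.0, 1.0]]), f_d=np.array([[1.0, 0.0]]),
            hand_regions=np.full((1, 4, 2), 0.5),
            face_regions=np.full((1, 4, 2), 0.5))
        assert float(negative_loss(disjoint).data) == pytest.approx(-2.0)

        batch = make_batch(rng, n=2)
        val = float(negative_loss(batch).data)
        assert -4.0 <= val <= 0.0


class TestSupervisedLoss:
    def setup_method(self):
        t = np.arange(60) / 30.0
        self.sin = np.sin(2 * np.pi * t)        # integer periods over window
        self.cos = np.cos(2 * np.pi * t)

    def as_rppg(self, x):
        from vidspo2.rppg_net import MultiChannelRppg
        return MultiChannelRppg(np.tile(x, (6, 1)), 30.0)

    def test_identical_orthogonal_negated(self):
        r1, r2 = Waveform(self.sin, 30.0), Waveform(self.sin, 30.0)
        assert supervised_loss(self.as_rppg(self.sin), self.as_rppg(self.sin),
                               r1, r2) == pytest.approx(0.0, abs=1e-9)
        assert supervised_loss(self.as_rppg(self.cos), self.as_rppg(self.cos),
                               r1, r2) == pytest.approx(2.0, abs=1e-9)
        assert supervised_loss(self.as_rppg(-self.sin), self.as_rppg(-self.sin),
                               r1, r2) == pytest.approx(4.0, abs=1e-9)

    def test_zero_reference_rejected(self):
        with pytest.raises(DegenerateSignalError):
            supervised_loss(self.as_rppg(self.sin), self.as_rppg(self.sin),
                            np.zeros(60), self.sin)


class TestPsdFeatures:
    def test_rows_are_normalized_and_peaked(self):
        t = np.arange(60) / 30.0
        y = np.tile(np.sin(2 * np.pi * 1.5 * t), (1, 6, 1))
        f = psd_features(nn.Tensor(y), 30.0)
        assert f.data.sum() == pytest.approx(1.0, abs=1e-5)
        grid = psd_grid(60, 30.0)
        assert grid[np.argmax(f.data[0])] == pytest.approx(1.5, abs=0.5)

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal((1, 6, 60))
        a = psd_features(nn.Tensor(y), 30.0).data
        b = psd_features(nn.Tensor(3.7 * y), 30.0).data
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestPseudoSample:
    @pytest.fixture(scope="class")
    def clip(self):
        s = generate(SceneConfig(duration_s=5.0, size=16, seed=2))
        return VideoClip(s.face_clip.frames, 30.0)

    def test_no_pulsatile_content(self, clip):
        """The source clip has a clear cardiac peak; the pseudo clip is
        static, so its trace carries no temporal structure at all."""
        g_src = clip.channel_means()[1]
        src_psd = compute_psd(Waveform(g_src - g_src.mean(), 30.0))
        assert src_psd.power.max() > 2.0 * np.median(src_psd.power)
        pseudo = build_pseudo_sample(clip, seed=1)
        g = pseudo.channel_means()[1]
        assert np.allclose(g, g[0], atol=1e-12)

    def test_seed_determinism(self, clip):
        a = build_pseudo_sample(clip, seed=5)
        b = build_pseudo_sample(clip, seed=5)
        np.testing.assert_array_equal(a.frames, b.frames)
        c = build_pseudo_sample(clip, seed=6)
        assert not np.array_equal(a.frames, c.frames)

    def test_zero_strength_replicates_frame(self, clip):
        pseudo = build_pseudo_sample(clip, seed=3, gain_jitter=0.0,
                                     offset_jitter=0.0, noise_sd=0.0)
        k = np.random.default_rng(3).integers(clip.n_frames)
        np.testing.assert_allclose(pseudo.frames,
                                   np.broadcast_to(clip.frames[k],
                                                   pseudo.frames.shape),
                                   atol=1e-7)
        assert np.all(pseudo.frames == pseudo.frames[0])
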
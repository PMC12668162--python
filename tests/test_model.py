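"""Generators, discriminators, intensity-aware normalization and NCE
sampling."""

import numpy as np
import pytest

from deftrus.model import (
    GeneratorConfig, ResnetGenerator, PatchDiscriminator, FeatureStack,
    TranslationModel, intensity_normalize, channel_stats, sample_patch_features,
)
from deftrus.nn import Tensor


@pytest.fixture(scope="module")
def small_gen():
    return ResnetGenerator(GeneratorConfig(n_res=2, base_channels=8),
                           np.random.default_rng(0))


class TestGenerator:
    def test_shape_preserved_and_bounded(self, small_gen, rng):
        x = rng.uniform(-1, 1, (1, 1, 64, 64)).astype(np.float32)
        y = small_gen(Tensor(x)).data
        assert y.shape == (1, 1, 64, 64)
        assert y.min() >= -1.0 and y.max() <= 1.0

    def test_indivisible_size_rejected(self, small_gen):
        with pytest.raises(ValueError, match="divisible"):
            small_gen(Tensor(np.zeros((1, 1, 30, 30), dtype=np.float32)))

    def test_deterministic_forward(self, small_gen, rng):
        x = rng.uniform(-1, 1, (1, 1, 32, 32)).astype(np.float32)
        a = small_gen(Tensor(x)).data
        b = small_gen(Tensor(x.copy())).data
        assert np.array_equal(a, b)

    def test_parameter_count_matches_layer_shape_arithmetic(self):
        cfg = GeneratorConfig(n_down=3, n_res=9, base_channels=64)
        gen = ResnetGenerator(cfg, np.random.default_rng(0))

        # independent closed-form sum over the layer shapes:
        def conv(cin, cout, k):
            return cout * cin * k * k + cout  # weights + bias

        b = 64
        expect = conv(1, b, 7)                                   # stem
        expect += sum(conv(b * 2 ** i, b * 2 ** (i + 1), 3) for i in range(3))
        cb = b * 8
        expect += 9 * 2 * conv(cb, cb, 3)                        # res blocks
        expect += sum(conv(b * 2 ** i, b * 2 ** (i - 1), 3) for i in range(3, 0, -1))
        expect += conv(b, 1, 7)                                  # head
        assert gen.n_parameters() == expect

    def test_shift_equivariance_of_translated_pattern(self, rng):
        # a compact pattern on a constant background, moved by 8 px (one
        # full downsampling period): the output must move with it.  The
        # image is large enough that the pattern's bottleneck footprint
        # stays a receptive field away from the padding-induced border
        # frame, which does not translate with the content.
        gen = ResnetGenerator(GeneratorConfig(n_res=1, base_channels=8),
                              np.random.default_rng(0))
        x = np.full((1, 1, 192, 192), -1.0, dtype=np.float32)
        patch = rng.uniform(-1, 1, (16, 16)).astype(np.float32)
        x[0, 0, 88:104, 80:96] = patch
        xs = np.full_like(x, -1.0)
        xs[0, 0, 88:104, 88:104] = patch
        y = np.squeeze(gen(Tensor(x)).data)
        ys = np.squeeze(gen(Tensor(xs)).data)
        inner = np.abs(np.roll(y, 8, axis=1) - ys)[48:144, 48:144]
        assert inner.max() < 1e-4

    def test_encoder_taps_cover_stem_and_downs(self, small_gen):
        x = Tensor(np.zeros((1, 1, 32, 32), dtype=np.float32))
        _, taps = small_gen.encode(x, return_taps=True)
        assert len(taps) == 4  # stem + 3 downsampling stages
        assert taps.layers[0].shape[2] == 32 and taps.layers[-1].shape[2] == 4


class TestIntensityNormalize:
    def test_fixed_point_when_stats_match(self, rng):
        x = rng.normal(size=(4, 16))
        out = intensity_normalize(x, x.copy())
        assert np.abs(out - x).max() < 1e-6

    def test_direct_arithmetic_example(self):
        x = np.array([[0.0, 2.0]])          # one channel: mu=1, sigma=1
        y = np.array([[5.0 - 2.0, 5.0 + 2.0]])  # mu=5, sigma=2
        out = intensity_normalize(x, y)
        assert np.allclose(out, [[3.0, 7.0]], atol=1e-4)

    def test_output_moments_equal_target_moments(self, rng):
        x = rng.normal(2.0, 3.0, size=(8, 100))
        y = rng.normal(-1.0, 0.5, size=(8, 100))
        out = intensity_normalize(x, y)
        mu_y, sd_y = channel_stats(y)
        assert np.abs(out.mean(axis=1) - mu_y.data.ravel()).max() < 1e-5
        assert np.abs(out.std(axis=1) - sd_y.data.ravel()).max() < 1e-4

    def test_idempotent_once_aligned(self, rng):
        x = rng.normal(size=(4, 50))
        y = rng.normal(3.0, 2.0, size=(4, 50))
        once = intensity_normalize(x, y)
        twice = intensity_normalize(once, y)
        assert np.abs(twice - once).max() < 1e-5

    def test_reverse_branch_is_same_op_with_roles_swapped(self, rng):
        x = rng.normal(size=(4, 30))
        y = rng.normal(2.0, 3.0, size=(4, 30))
        mu_x, sd_x = channel_stats(x)
        out = intensity_normalize(y, x)
        assert np.abs(out.mean(axis=1) - mu_x.data.ravel()).max() < 1e-5


class TestPatchSampling:
    def _stack(self, data):
        return FeatureStack([Tensor(np.asarray(data, dtype=np.float64))])

    def test_single_patch_two_location_grid_has_one_negative(self, rng):
        feats = rng.normal(size=(3, 1, 2))
        s = sample_patch_features(self._stack(feats), self._stack(feats.copy()),
                                  n_patches=1, rng=0)
        v, vp, vn = s[0]
        assert v.shape[0] == 1 and vn.shape[0] == 1

    def test_identical_stacks_give_unit_positive_similarity(self, rng):
        feats = rng.normal(size=(4, 6, 6))
        s = sample_patch_features(self._stack(feats), self._stack(feats.copy()),
                                  n_patches=8, rng=1)
        v, vp, _ = s[0]
        sims = (v.data * vp.data).sum(axis=1)
        assert np.allclose(sims, 1.0, atol=1e-6)

    def test_negatives_never_share_anchor_location_1000_draws(self):
        # encode each location's index as a unit direction (cos i, sin i);
        # unit normalization preserves it, so indices can be read back
        angles = np.arange(16, dtype=float) / 16 * 2 * np.pi
        coded = np.stack([np.cos(angles), np.sin(angles)]).reshape(2, 4, 4)

        def decode(vecs):
            a = np.arctan2(vecs[:, 1], vecs[:, 0]) % (2 * np.pi)
            return set(np.round(a / (2 * np.pi) * 16).astype(int) % 16)

        for draw in range(1000):
            s = sample_patch_features(self._stack(coded), self._stack(coded),
                                      n_patches=4, rng=draw)
            _, vp, vn = s[0]
            assert not (decode(vp.data) & decode(vn.data))

    def test_too_many_patches_rejected(self, rng):
        feats = rng.normal(size=(2, 2, 2))
        with pytest.raises(ValueError, match="exceeds"):
            sample_patch_features(self._stack(feats), self._stack(feats),
                                  n_patches=5, rng=0)

    def test_deterministic_given_seed(self, rng):
        feats = rng.normal(size=(3, 5, 5))
        a = sample_patch_features(self._stack(feats), self._stack(feats), 4, rng=9)
        b = sample_patch_features(self._stack(feats), self._stack(feats), 4, rng=9)
        assert np.array_equal(a[0][0].data, b[0][0].data)


class TestDiscriminatorsAndBundle:
    def test_patch_discriminator_outputs_probability_map(self, rng):
        d = PatchDiscriminator(1, 8, rng=np.random.default_rng(0))
        out = d(Tensor(rng.uniform(-1, 1, (1, 1, 64, 64)).astype(np.float32))).data
        assert out.ndim == 4 and 0.0 < out.min() and out.max() < 1.0

    def test_translation_model_state_round_trip(self):
        m = TranslationModel.create(GeneratorConfig(n_res=1, base_channels=4),
                                    seed=0, disc_channels=4)
        state = m.state_dict()
        m2 = TranslationModel.create(GeneratorConfig(n_res=1, base_channels=4),
                                     seed=1, disc_channels=4)
        m2.load_state_dict(state)
        for (ka, va), (kb, vb) in zip(sorted(m.state_dict().items()),
                                      sorted(m2.state_dict().items())):
            assert ka == kb and np.array_equal(va, vb)

    def test_generators_share_architecture(self):
        m = TranslationModel.create(GeneratorConfig(n_res=1, base_channels=4),
                                    seed=0, disc_channels=4)
        assert m.G.n_parameters() == m.H.n_parameters()
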
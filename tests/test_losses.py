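"""Objective functions: closed-form values, gradient checks, monotonicity
and the weighted totals."""

import numpy as np
import pytest

from deftrus import losses as L
from deftrus.nn import Tensor
from deftrus.roi import sobel_edges, masked_edges


class TestNCE:
    def test_uniform_similarity_gives_ln2(self):
        v = np.array([1.0, 0.0])
        loss = L.nce_loss(v, v, np.array([[1.0, 0.0]]))
        assert abs(loss.item() - np.log(2)) < 1e-6

    def test_two_orthogonal_negatives_closed_form(self):
        v = np.array([1.0, 0.0])
        negs = np.array([[0.0, 1.0], [0.0, -1.0]])
        expect = -np.log(np.e / (np.e + 2.0))
        assert abs(L.nce_loss(v, v, negs).item() - expect) < 1e-6

    def test_limit_matches_brute_force_softmax(self):
        # sim(v,v+) -> 1, all sim(v,v-) -> -1 with N negatives
        for n in (1, 3, 7):
            v = np.array([1.0, 0.0])
            negs = np.tile([-1.0, 0.0], (n, 1))
            expect = -np.log(np.e / (np.e + n * np.exp(-1.0)))
            assert abs(L.nce_loss(v, v, negs).item() - expect) < 1e-6

    def test_strictly_decreasing_in_positive_similarity(self):
        # negatives orthogonal to the sweep plane: their similarity stays 0
        negs = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
        anchor = np.array([1.0, 0.0, 0.0])
        vals = []
        for s in np.linspace(-0.95, 0.95, 9):
            vplus = np.array([s, np.sqrt(1 - s * s), 0.0])
            vals.append(L.nce_loss(anchor, vplus, negs).item())
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_gradient_matches_central_differences(self, rng):
        a = rng.normal(size=(3, 8))
        b = rng.normal(size=(3, 8))
        n = rng.normal(size=(5, 8))
        t = Tensor(a.copy(), requires_grad=True)
        L.nce_loss(t, Tensor(b), Tensor(n)).backward()
        eps = 1e-6
        num = np.zeros_like(a)
        for i in np.ndindex(a.shape):
            ap, am = a.copy(), a.copy()
            ap[i] += eps
            am[i] -= eps
            num[i] = (L.nce_loss(Tensor(ap), Tensor(b), Tensor(n)).item()
                      - L.nce_loss(Tensor(am), Tensor(b), Tensor(n)).item()) / (2 * eps)
        assert np.abs(num - t.grad).max() < 1e-4

    def test_zero_norm_vector_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            L.nce_loss(np.zeros(4), np.ones(4), np.ones((2, 4)))

    def test_no_negatives_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            L.nce_loss(np.ones(4), np.ones(4), np.zeros((0, 4)))


class TestAdversarial:
    def test_indifferent_discriminator_value(self):
        D = lambda img: Tensor(np.full((1, 1, 4, 4), 0.5))
        x = np.zeros((1, 1, 8, 8))
        loss = L.adversarial_loss(D, x, x, "discriminator")
        assert abs(loss.item() - 2 * np.log(2)) < 1e-9

    def test_perfect_discriminator_loss_approaches_zero(self):
        D = lambda img: Tensor(np.full((1, 1, 4, 4),
                                       0.9999 if np.mean(img.numpy()) > 0 else 1e-4))
        loss = L.adversarial_loss(D, np.ones((1, 1, 4, 4)),
                                  -np.ones((1, 1, 4, 4)), "discriminator")
        assert loss.item() < 1e-3

    def test_generator_loss_at_half_is_ln2(self):
        D = lambda img: Tensor(np.full((1, 1, 4, 4), 0.5))
        loss = L.adversarial_loss(D, None, np.zeros((1, 1, 8, 8)), "generator")
        assert abs(loss.item() - np.log(2)) < 1e-9

    def test_out_of_range_discriminator_is_clamped_finite(self):
        D = lambda img: Tensor(np.array([[[[0.0, 1.0]]]]))
        loss = L.adversarial_loss(D, np.zeros((1, 1, 1, 2)),
                                  np.zeros((1, 1, 1, 2)), "discriminator")
        assert np.isfinite(loss.item())


class TestIdentityAndStyle:
    def test_identity_map_gives_zero(self, rng):
        img = rng.uniform(-1, 1, (1, 1, 8, 8))
        assert L.identity_loss(lambda t: t, img).item() == 0.0

    def test_constant_generator_on_constant_image(self):
        img = np.full((1, 1, 8, 8), 0.3)
        gen = lambda t: Tensor(np.full_like(t.data, -0.2))
        assert abs(L.identity_loss(gen, img).item() - 0.5) < 1e-12

    def test_identity_loss_nonnegative(self, rng):
        img = rng.uniform(-1, 1, (1, 1, 8, 8))
        gen = lambda t: Tensor(rng.uniform(-1, 1, t.shape))
        assert L.identity_loss(gen, img).item() >= 0

    def test_style_zero_for_identical_inputs(self, rng):
        f = rng.normal(size=(32, 32))
        assert L.style_loss(f, f).item() == 0.0

    def test_style_first_moment_equals_shift(self, rng):
        f = rng.normal(size=(32, 32))
        assert abs(L.style_loss(f + 0.3, f).item() - 0.3) < 1e-10

    def test_style_invariant_to_in_patch_permutation(self, rng):
        f = rng.normal(size=(32, 32))
        g = f.copy()
        # permute pixels inside the top-left 16x16 cell of both inputs
        perm = rng.permutation(256)
        cell = f[:16, :16].ravel()[perm].reshape(16, 16)
        g[:16, :16] = cell
        assert abs(L.style_loss(g, g).item()) < 1e-12
        assert abs(L.style_loss(f, f).item() - L.style_loss(g, g).item()) < 1e-12


class TestStructureLosses:
    def _half_D(self):
        return lambda img: Tensor(np.full((1, 1, 4, 4), 0.5))

    def test_empty_mask_returns_zero_with_warning(self, rng):
        img = rng.uniform(-1, 1, (16, 16))
        with pytest.warns(UserWarning, match="empty"):
            loss = L.structure_loss_prostate(self._half_D(), img, img,
                                             np.zeros((16, 16)), sobel_edges)
        assert loss.item() == 0.0

    def test_indifferent_discriminator_value(self, rng):
        img = rng.uniform(-1, 1, (16, 16))
        cp = np.ones((16, 16))
        loss = L.structure_loss_prostate(self._half_D(), img, img, cp, sobel_edges)
        assert abs(loss.item() - 2 * np.log(2)) < 1e-9

    @pytest.mark.parametrize("fn", [L.structure_loss_prostate,
                                    L.structure_loss_rectum])
    def test_decomposes_into_adversarial_on_masked_edges(self, rng, fn):
        real = rng.uniform(-1, 1, (16, 16))
        fake = rng.uniform(-1, 1, (16, 16))
        mask = (rng.random((16, 16)) > 0.5).astype(float)
        calls = []

        def D(img):
            calls.append(np.squeeze(img.data))
            return Tensor(np.full((1, 1, 2, 2), 0.4))

        loss = fn(D, real, fake, mask, sobel_edges)
        # oracle: the same GAN value on independently pre-masked edge maps
        rm = masked_edges(sobel_edges(real), mask)
        fm = masked_edges(sobel_edges(fake), mask)
        oracle = L.adversarial_loss(D, rm.reshape(1, 1, 16, 16),
                                    fm.reshape(1, 1, 16, 16), "discriminator")
        assert abs(loss.item() - oracle.item()) < 1e-12
        assert np.allclose(calls[0], rm) and np.allclose(calls[1], fm)


class TestTotals:
    def test_unit_terms_with_default_weights(self):
        w = L.LossWeights()
        th = {"adv": 1.0, "nce": 1.0, "idt": 1.0}
        assert abs(L.total_loss_H(th, w).item() - 1.0) < 1e-12
        tg = {"adv": 1.0, "nce": 1.0, "idt": 1.0, "lp": 1.0, "lr": 1.0}
        assert abs(L.total_loss_G(tg, w).item() - 1.02) < 1e-12

    def test_zero_terms_give_zero(self):
        z = {"adv": 0.0, "nce": 0.0, "idt": 0.0, "lp": 0.0, "lr": 0.0}
        assert L.total_loss_G(z).item() == 0.0
        assert L.total_loss_H(z).item() == 0.0

    def test_linear_in_each_term(self):
        w = L.LossWeights()
        base = {"adv": 1.0, "nce": 1.0, "idt": 1.0, "lp": 1.0, "lr": 1.0}
        for key, lam in (("adv", w.lambda4), ("nce", w.lambda5),
                         ("idt", w.lambda6)):
            doubled = dict(base, **{key: 2.0})
            delta = L.total_loss_G(doubled, w).item() - L.total_loss_G(base, w).item()
            assert abs(delta - lam) < 1e-12

    def test_structure_weight_zero_reproduces_ablation_total(self):
        w = L.LossWeights(lambda7=0.0)
        with_structure = {"adv": 1.0, "nce": 1.0, "idt": 1.0, "lp": 5.0, "lr": 7.0}
        without = {"adv": 1.0, "nce": 1.0, "idt": 1.0, "lp": 0.0, "lr": 0.0}
        assert L.total_loss_G(with_structure, w).item() == \
            L.total_loss_G(without, w).item()

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            L.LossWeights(lambda3=-0.1)

    def test_loss_report_flags_non_finite_terms(self):
        with pytest.raises(FloatingPointError, match="nce"):
            L.LossReport({"adv": 1.0, "nce": float("nan")})

    def test_all_losses_finite_on_unit_range_inputs(self, rng):
        img = rng.uniform(-1, 1, (1, 1, 16, 16))
        D = lambda t: Tensor(np.clip(t.numpy()[:, :, :4, :4], 0, 1))
        for role in ("discriminator", "generator"):
            assert np.isfinite(L.adversarial_loss(D, img, img, role).item())
        assert np.isfinite(L.style_loss(img[0, 0], -img[0, 0]).item())
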
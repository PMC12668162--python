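"""Evaluation metrics against independent oracles, and cohort reporting."""

import numpy as np
import pytest

from deftrus import evaluation as ev
from deftrus import phantom as ph
from deftrus.preprocess import Volume


class TestPSNR:
    def test_identical_images_capped(self, rng):
        a = rng.random((16, 16))
        assert ev.psnr(a, a) == 99.0

    def test_closed_form_value(self):
        a = np.zeros((10, 10))
        b = np.full((10, 10), 0.1)  # MSE = 0.01 at range 1
        assert abs(ev.psnr(a, b, data_range=1.0) - 20.0) < 1e-9

    def test_invariant_to_common_affine_map(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        base = ev.psnr(a, b, data_range=1.0)
        scaled = ev.psnr(3 * a + 1, 3 * b + 1, data_range=3.0)
        assert abs(base - scaled) < 1e-9


def _brute_force_ssim(a, b, data_range=2.0, win=11, sigma=1.5):
    """Direct per-window SSIM with Gaussian weights (interior windows only)."""
    r = win // 2
    i = np.arange(-r, r + 1)
    g = np.exp(-(i ** 2) / (2 * sigma ** 2))
    w = np.outer(g, g)
    w = w / w.sum()
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    h, wid = a.shape
    vals = []
    for y in range(r, h - r):
        for x in range(r, wid - r):
            pa = a[y - r:y + r + 1, x - r:x + r + 1]
            pb = b[y - r:y + r + 1, x - r:x + r + 1]
            ua, ub = (w * pa).sum(), (w * pb).sum()
            va = (w * pa * pa).sum() - ua ** 2
            vb = (w * pb * pb).sum() - ub ** 2
            cov = (w * pa * pb).sum() - ua * ub
            vals.append(((2 * ua * ub + c1) * (2 * cov + c2))
                        / ((ua ** 2 + ub ** 2 + c1) * (va + vb + c2)))
    return float(np.mean(vals))


class TestSSIM:
    def test_identical_images_give_one(self, rng):
        a = rng.random((32, 32))
        assert abs(ev.ssim(a, a) - 1.0) < 1e-12

    def test_sign_flip_gives_negative_structure(self):
        # zero local mean (luminance term ~ +1) with anti-correlated
        # structure: the covariance term drives SSIM negative
        i, j = np.mgrid[0:32, 0:32]
        a = 0.5 * (-1.0) ** (i + j)
        assert ev.ssim(a, -a) < 0

    def test_matches_per_window_brute_force(self, rng):
        a = rng.random((32, 32))
        b = np.clip(a + rng.normal(0, 0.2, a.shape), 0, 1)
        assert abs(ev.ssim(a, b) - _brute_force_ssim(a, b)) < 1e-6


class TestRoiMetrics:
    def test_full_mask_equals_global_metric(self, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        mask = np.ones((32, 32))
        assert abs(ev.roi_psnr(a, b, mask) - ev.psnr(a, b)) < 1e-12
        assert abs(ev.roi_ssim(a, b, mask) - ev.ssim(a, b)) < 1e-12

    def test_differences_outside_mask_ignored(self, rng):
        a = rng.random((32, 32))
        b = a.copy()
        mask = np.zeros((32, 32))
        mask[10:20, 10:20] = 1
        b[0:5, 0:5] += 1.0  # outside the mask
        assert ev.roi_psnr(a, b, mask) == 99.0

    def test_bounding_box_is_tight(self):
        mask = np.zeros((32, 32))
        mask[11:21, 11:21] = 1
        box = ev._bbox(mask > 0)
        assert mask[box].shape == (10, 10)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            ev.roi_psnr(rng.random((8, 8)), rng.random((8, 8)), np.zeros((8, 8)))


class TestNCC:
    def test_self_and_negated(self, rng):
        a = rng.random((16, 16))
        assert abs(ev.ncc(a, a) - 1.0) < 1e-12
        assert abs(ev.ncc(a, -a) + 1.0) < 1e-12

    def test_invariant_to_positive_affine_map(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert abs(ev.ncc(a, b) - ev.ncc(a, 2.5 * b + 3)) < 1e-10

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            ev.ncc(np.ones((8, 8)), np.zeros((8, 8)))


class TestFrechet:
    def test_identical_sets_give_zero(self, rng):
        f = rng.normal(size=(20, 8))
        assert ev.frechet_distance(f, f.copy()) < 1e-6

    def test_one_dimensional_gaussian_closed_form(self):
        # sample mean 0 vs 3, sample std 1 each -> distance 9
        h = np.sqrt(2) / 2
        a = np.array([[-h], [h]])
        b = np.array([[3 - h], [3 + h]])
        assert abs(ev.frechet_distance(a, b) - 9.0) < 1e-3

    def test_symmetric_and_nonnegative(self, rng):
        for _ in range(20):
            a = rng.normal(size=(10, 4))
            b = rng.normal(size=(12, 4))
            d1, d2 = ev.frechet_distance(a, b), ev.frechet_distance(b, a)
            assert d1 >= 0 and abs(d1 - d2) < 1e-8

    def test_embedding_is_reproducible(self, rng):
        img = rng.random((32, 32))
        e1 = ev.RandomConvEmbedding(seed=7)(img)
        e2 = ev.RandomConvEmbedding(seed=7)(img)
        assert np.array_equal(e1, e2)


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((8, 8), bool)
        a[2:5, 2:5] = True
        assert ev.dsc(a, a) == 100.0
        b = np.zeros((8, 8), bool)
        b[6:8, 6:8] = True
        assert ev.dsc(a, b) == 0.0

    def test_shifted_square_pixel_counting(self):
        a = np.zeros((8, 8), bool)
        a[2:4, 2:4] = True          # 2x2 square
        b = np.roll(a, 1, axis=1)   # shifted by 1 px: overlap 2
        assert ev.dsc(a, b) == 50.0

    def test_both_empty_defined_as_100_with_warning(self):
        with pytest.warns(UserWarning):
            assert ev.dsc(np.zeros((4, 4)), np.zeros((4, 4))) == 100.0

    def test_matches_set_counting_oracle_1000_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a = rng.random((16, 16)) > 0.6
            b = rng.random((16, 16)) > 0.6
            inter = len({(i, j) for i, j in zip(*np.where(a))}
                        & {(i, j) for i, j in zip(*np.where(b))})
            expect = 200.0 * inter / (a.sum() + b.sum())
            assert ev.dsc(a, b) == expect


class TestTRE:
    def test_identical_contours_zero(self):
        m = np.zeros((8, 8, 2), bool)
        m[2:4, 2:4, 0] = True
        assert ev.tre(m, m) == 0.0

    def test_three_four_five_triangle(self):
        a = np.zeros((16, 16), bool)
        a[2:4, 2:4] = True
        b = np.roll(np.roll(a, 3, axis=0), 4, axis=1)
        assert abs(ev.tre(a, b, spacing=(1.0, 1.0)) - 5.0) < 1e-9

    def test_anisotropic_spacing(self):
        a = np.zeros((32, 8, 4), bool)
        a[2:4, 2:4, 1] = True
        b = np.roll(a, 10, axis=0)
        assert abs(ev.tre(a, b, spacing=(0.3, 0.3, 1.0)) - 3.0) < 1e-9

    def test_empty_contour_rejected(self):
        with pytest.raises(ValueError):
            ev.tre(np.zeros((4, 4)), np.ones((4, 4)))


class TestRegisterAndTransfer:
    @pytest.fixture(scope="class")
    def phantom_pair(self):
        spec = ph.PhantomSpec()
        labels = ph.generate_anatomy(spec)
        img = ph.render_mr(labels, spec)
        contour = np.isin(labels.labels, [1, 3, 4]).astype(float)
        return img, contour

    def test_identity_when_images_match(self, phantom_pair):
        img, contour = phantom_pair
        moved, tf = ev.register_and_transfer(img, img, contour)
        assert abs(tf.t_row) < 0.1 and abs(tf.t_col) < 0.1
        assert ev.dsc(moved, contour) > 99.0

    def test_translation_transfers_contour(self, phantom_pair):
        from deftrus.preprocess import apply_rigid, RigidTransform2D

        img, contour = phantom_pair
        real = apply_rigid(img, RigidTransform2D(0.0, 5.0, 3.0))
        moved, tf = ev.register_and_transfer(img, real, contour)
        c0 = np.array([c.mean() for c in np.where(contour > 0)])
        c1 = np.array([c.mean() for c in np.where(moved > 0)])
        assert np.abs((c1 - c0) - [5.0, 3.0]).max() < 0.5

    def test_mask_volume_preserved_under_rigid_nn(self, phantom_pair):
        from deftrus.preprocess import apply_rigid, RigidTransform2D

        img, contour = phantom_pair
        real = apply_rigid(img, RigidTransform2D(8.0, 2.0, -4.0))
        moved, _ = ev.register_and_transfer(img, real, contour)
        assert abs(moved.sum() - contour.sum()) / contour.sum() < 0.05


class _Replay:
    """Stand-in translator returning pre-recorded volumes in case order."""

    def __init__(self, volumes):
        self.volumes = list(volumes)

    def transform(self, _):
        return self.volumes.pop(0)


class TestEvaluateCohort:
    @pytest.fixture(scope="class")
    def ideal_cohort(self, tmp_path_factory):
        # no probe deformation and no speckle: the MR and TRUS eval members
        # share identical geometry, so a perfect translator scores perfectly
        out = tmp_path_factory.mktemp("ideal")
        spec = ph.PhantomSpec.for_size(64, n_slices=2, deform_amplitude=0.0,
                                       speckle_sigma=0.0, fan_angle=360.0)
        return ph.make_cohort(out, 0, 0, 2, seed=1, base_spec=spec)

    def test_ground_truth_against_itself_is_perfect(self, ideal_cohort):
        from pathlib import Path

        root = Path(ideal_cohort["root"])
        gts = [Volume.load(root / e["image"]) for e in ideal_cohort["entries"]
               if e["domain"] == "trus"]
        report = ev.evaluate_cohort(_Replay(gts), ideal_cohort)
        assert report.summary["psnr"] == 99.0
        assert abs(report.summary["ssim"] - 1.0) < 1e-9
        assert abs(report.summary["ncc"] - 1.0) < 1e-9
        assert report.summary["fid"] < 1e-3
        assert report.summary["dsc"] > 99.0
        assert report.summary["tre_mm"] < 0.2

    def test_report_rows_and_mean_audit(self, ideal_cohort, quick_translator,
                                        tmp_path):
        report = ev.evaluate_cohort(quick_translator, ideal_cohort,
                                    out_dir=tmp_path)
        assert len(report.cases) == 2
        for col in ("psnr", "ssim", "ncc", "dsc"):
            assert abs(report.summary[col] - report.cases[col].mean()) < 1e-12
        assert (tmp_path / "cases.csv").exists()
        assert (tmp_path / "summary.md").exists()
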
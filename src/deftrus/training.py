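"""Unpaired training orchestration.

The public surface is :class:`MRToTRUSTranslator`, a scikit-learn style
estimator: construct with hyperparameters, ``fit`` on a phantom cohort
manifest (or in-memory slice lists), ``transform`` MR slices or volumes into
synthetic TRUS.  ``train``/``translate`` are thin functional wrappers, and
``run_ablation`` builds each published ablation variant purely from the
estimator's flags.

Each iteration: a fresh random elastic perturbation of the ROI mask, one
discriminator update for every discriminator (domain pair + the two edge
discriminators), then a joint generator update of the weighted objectives.
All randomness flows from the single ``seed``; checkpoints capture weights,
optimizer moments, RNG state and the image pools, so a reloaded run
continues bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import losses as Lmod
from .losses import LossWeights, LossReport
from .model import TranslationModel, GeneratorConfig, channel_stats, sample_patch_features
from .nn import Tensor, astensor, Adam, no_grad
from .nn import functional as F
from .phantom import load_manifest
from .preprocess import Volume, extract_slices, stack_slices
from .roi import build_average_mask, elastic_perturb, canny_edges, edge_operator

__all__ = ["MRToTRUSTranslator", "train", "translate", "run_ablation",
           "ABLATION_VARIANTS", "load_checkpoint"]

ABLATION_VARIANTS = (
    "full",
    "w/o cycle breaking",
    "w/o NCE",
    "w/o normalization",
    "w/o structure constraint",
    "w/o style adjustment",
)

_SOBEL_R = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]],
                    dtype=np.float32).reshape(1, 1, 3, 3)
_SOBEL_C = _SOBEL_R.transpose(0, 1, 3, 2)


class _ImagePool:
    """Buffer of past generator outputs stabilizing discriminator updates."""

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.images: list[np.ndarray] = []

    def query(self, image: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return image
        if len(self.images) < self.size:
            self.images.append(image.copy())
            return image
        if self.rng.random() < 0.5:
            i = int(self.rng.integers(0, self.size))
            old = self.images[i]
            self.images[i] = image.copy()
            return old
        return image


def _diff_edges(img: Tensor, edge_filter: str, threshold: int) -> Tensor:
    """Differentiable edge map of a generated image, range [-1, 1].

    Sobel gradient magnitude (fixed-kernel convolution) normalized by its
    detached maximum; in 'canny' mode the magnitude is gated by the binary
    Canny support of the image values, so generator gradients act on the
    intensities along detected edges.
    """
    x = img.reshape(1, 1, img.shape[-2], img.shape[-1])
    gr = F.conv2d(F.pad2d(x, 1, "reflect"), Tensor(_SOBEL_R))
    gc = F.conv2d(F.pad2d(x, 1, "reflect"), Tensor(_SOBEL_C))
    mag = (gr * gr + gc * gc + 1e-12).sqrt()
    peak = float(mag.data.max())
    mag = mag * (1.0 / (peak + 1e-8))
    if edge_filter == "canny":
        gate = (canny_edges(np.squeeze(img.data), threshold=threshold) > 0)
        mag = mag * gate.reshape(1, 1, *gate.shape).astype(img.data.dtype)
    return (mag * 2.0 - 1.0).reshape(img.shape[-2], img.shape[-1])


class MRToTRUSTranslator(BaseEstimator, TransformerMixin):
    """Deformation-aware unpaired MR->TRUS translator.

    Parameters mirror the training configuration: optimizer settings,
    architecture size, contrastive sampling, ROI perturbation, loss weights
    (lambda1..lambda7) and the ablation flags.  Defaults reproduce the full
    method; each ``use_*`` flag removes exactly one component (or, for
    ``use_cycle``, adds the cycle-consistency loss back).

    Fitted attributes (trailing underscore): ``model_``, ``loss_log_``,
    ``roi_mask_``, ``trus_stats_``/``mr_stats_`` (running bottleneck
    statistics used for intensity-aware normalization at inference), and
    ``n_iter_``.
    """

    def __init__(self, iterations=200, batch_size=2, lr=2e-4, beta1=0.5,
                 beta2=0.999, base_channels=8, n_res=9, n_down=3,
                 disc_channels=8, nce_dim=64, n_patches=64, n_negatives=128,
                 pool_size=50, seed=0, edge_filter="canny",
                 canny_threshold=300, roi_grid_points=3, roi_sigma=20.0,
                 roi_alpha=7.0, lambda1=0.5, lambda2=0.25, lambda3=0.25,
                 lambda4=0.5, lambda5=0.25, lambda6=0.25, lambda7=0.01,
                 lambda_style=0.1, lambda_cycle=10.0, use_cycle=False,
                 use_nce=True, use_normalization=True, use_structure=True,
                 use_style=True):
        self.iterations = iterations
        self.batch_size = batch_size
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.base_channels = base_channels
        self.n_res = n_res
        self.n_down = n_down
        self.disc_channels = disc_channels
        self.nce_dim = nce_dim
        self.n_patches = n_patches
        self.n_negatives = n_negatives
        self.pool_size = pool_size
        self.seed = seed
        self.edge_filter = edge_filter
        self.canny_threshold = canny_threshold
        self.roi_grid_points = roi_grid_points
        self.roi_sigma = roi_sigma
        self.roi_alpha = roi_alpha
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.lambda3 = lambda3
        self.lambda4 = lambda4
        self.lambda5 = lambda5
        self.lambda6 = lambda6
        self.lambda7 = lambda7
        self.lambda_style = lambda_style
        self.lambda_cycle = lambda_cycle
        self.use_cycle = use_cycle
        self.use_nce = use_nce
        self.use_normalization = use_normalization
        self.use_structure = use_structure
        self.use_style = use_style

    # -- data loading ---------------------------------------------------------
    @staticmethod
    def _load_cohort(X) -> dict:
        """Accept a manifest path/dict or an in-memory dict of slice lists."""
        if isinstance(X, dict) and "mr" in X:
            return {"mr": [np.asarray(s, np.float32) for s in X["mr"]],
                    "trus": [np.asarray(s, np.float32) for s in X["trus"]],
                    "trus_labels": [np.asarray(s) for s in X.get("trus_labels", [])]}
        manifest = X if isinstance(X, dict) else load_manifest(X)
        root = Path(manifest["root"])
        mr, trus, trus_labels = [], [], []
        for e in manifest["entries"]:
            if e["role"] != "train":
                continue
            vol = Volume.load(root / e["image"])
            slices = [s.astype(np.float32) for s in extract_slices(vol)]
            if e["domain"] == "mr":
                mr.extend(slices)
            else:
                trus.extend(slices)
                lab = Volume.load(root / e["labels"])
                trus_labels.extend(extract_slices(lab))
        return {"mr": mr, "trus": trus, "trus_labels": trus_labels}

    def _weights(self) -> LossWeights:
        return LossWeights(
            lambda1=self.lambda1,
            lambda2=self.lambda2 if self.use_nce else 0.0,
            lambda3=self.lambda3,
            lambda4=self.lambda4,
            lambda5=self.lambda5 if self.use_nce else 0.0,
            lambda6=self.lambda6,
            lambda7=self.lambda7 if self.use_structure else 0.0)

    # -- core -----------------------------------------------------------------
    def fit(self, X, y=None):
        cohort = self._load_cohort(X)
        if len(cohort["mr"]) < 1 or len(cohort["trus"]) < 1:
            raise ValueError("need at least one training image per domain")
        self._init_state()
        if cohort["trus_labels"]:
            self.roi_mask_ = build_average_mask(cohort["trus_labels"])
        else:
            # fall back to a centered soft disc when no contours are available
            h, w = cohort["trus"][0].shape
            rr, cc = np.mgrid[0:h, 0:w]
            c0 = (((rr - h / 2) ** 2 + (cc - w / 2) ** 2) <= (min(h, w) / 3) ** 2)
            from .roi import RoiMask
            self.roi_mask_ = RoiMask(c0.astype(float), c0.astype(float),
                                     np.zeros_like(c0, float))
        self._cohort = cohort
        for _ in range(self.iterations):
            self._step()
        self.n_iter_ = len(self.loss_log_)
        return self

    def _init_state(self):
        self.rng_ = np.random.default_rng(self.seed)
        cfg = GeneratorConfig(n_down=self.n_down, n_res=self.n_res,
                              base_channels=self.base_channels)
        self.model_ = TranslationModel.create(cfg, seed=self.seed,
                                              disc_channels=self.disc_channels,
                                              nce_dim=self.nce_dim)
        gen_params = (list(self.model_.G.parameters())
                      + list(self.model_.H.parameters())
                      + [p for h in self.model_.heads_G for p in h.parameters()]
                      + [p for h in self.model_.heads_H for p in h.parameters()])
        disc_params = (list(self.model_.D_trus.parameters())
                       + list(self.model_.D_mr.parameters())
                       + list(self.model_.DP.parameters())
                       + list(self.model_.DR.parameters()))
        self.opt_gen_ = Adam(gen_params, lr=self.lr, betas=(self.beta1, self.beta2))
        self.opt_disc_ = Adam(disc_params, lr=self.lr, betas=(self.beta1, self.beta2))
        self.pool_trus_ = _ImagePool(self.pool_size, self.rng_)
        self.pool_mr_ = _ImagePool(self.pool_size, self.rng_)
        self.loss_log_: list[dict] = []
        self.trus_stats_ = None
        self.mr_stats_ = None
        self.n_iter_ = 0

    @staticmethod
    def _as4(img) -> Tensor:
        t = astensor(img)
        return t.reshape(1, 1, t.shape[-2], t.shape[-1])

    def _update_running_stats(self, name, stats, momentum=0.1):
        mu, sd = stats
        cur = getattr(self, name)
        if cur is None:
            setattr(self, name, (mu.copy(), sd.copy()))
        else:
            setattr(self, name, (cur[0] * (1 - momentum) + mu * momentum,
                                 cur[1] * (1 - momentum) + sd * momentum))

    def _nce_term(self, gen, heads, input_taps, fake: Tensor):
        _, fake_taps = gen.encode(fake, return_taps=True)
        samples = sample_patch_features(
            input_taps, fake_taps, self.n_patches,
            rng=int(self.rng_.integers(0, 2 ** 31)), heads=heads,
            n_negatives=self.n_negatives)
        total = astensor(0.0)
        for v, vp, vn in samples:
            total = total + Lmod.nce_loss(v, vp, vn)
        return total * (1.0 / len(samples))

    def _step(self):
        m = self.model_
        rng = self.rng_
        x = self._cohort["mr"][int(rng.integers(len(self._cohort["mr"])))]
        yimg = self._cohort["trus"][int(rng.integers(len(self._cohort["trus"])))]
        batch = [(x, yimg)]
        for _ in range(self.batch_size - 1):
            batch.append((self._cohort["mr"][int(rng.integers(len(self._cohort["mr"])))],
                          self._cohort["trus"][int(rng.integers(len(self._cohort["trus"])))]))
        roi = elastic_perturb(self.roi_mask_, self.roi_grid_points,
                              self.roi_sigma, self.roi_alpha,
                              seed=int(rng.integers(0, 2 ** 31)))
        edge_op = edge_operator(self.edge_filter, self.canny_threshold)
        w = self._weights()
        acc: dict[str, float] = {}
        gen_total = astensor(0.0)
        disc_total = astensor(0.0)

        def log(key, val):
            acc[key] = acc.get(key, 0.0) + float(val) / len(batch)

        for (xs, ys) in batch:
            x4, y4 = self._as4(xs), self._as4(ys)

            # identity passes double as encoder passes for the domain stats
            idt_y, taps_y_G = m.G(y4, return_taps=True)   # G on TRUS: identity
            idt_x, taps_x_H = m.H(x4, return_taps=True)   # H on MR: identity
            with no_grad():
                sy = channel_stats(taps_y_G.layers[-1].detach())
                sx = channel_stats(taps_x_H.layers[-1].detach())
                stats_y = (sy[0].data, sy[1].data)
                stats_x = (sx[0].data, sx[1].data)
            self._update_running_stats("trus_stats_", stats_y)
            self._update_running_stats("mr_stats_", stats_x)

            ref_y = stats_y if self.use_normalization else None
            ref_x = stats_x if self.use_normalization else None
            fake_trus, taps_x_G = m.G(x4, ref_stats=ref_y, return_taps=True)
            fake_mr, taps_y_H = m.H(y4, ref_stats=ref_x, return_taps=True)

            # ---- discriminators ----
            d_trus = Lmod.adversarial_loss(
                m.D_trus, y4, self.pool_trus_.query(fake_trus.data), "discriminator")
            d_mr = Lmod.adversarial_loss(
                m.D_mr, x4, self.pool_mr_.query(fake_mr.data), "discriminator")
            disc_total = disc_total + d_trus + d_mr
            log("d_trus", d_trus.item())
            log("d_mr", d_mr.item())
            if self.use_structure:
                d_p = Lmod.structure_loss_prostate(
                    m.DP, np.squeeze(x4.data), fake_trus.detach(), roi.cp, edge_op)
                d_r = Lmod.structure_loss_rectum(
                    m.DR, np.squeeze(y4.data), fake_trus.detach(), roi.cr, edge_op)
                disc_total = disc_total + d_p + d_r
                log("d_p", d_p.item())
                log("d_r", d_r.item())

            # ---- generators ----
            adv_G = Lmod.adversarial_loss(m.D_trus, None, fake_trus, "generator")
            adv_H = Lmod.adversarial_loss(m.D_mr, None, fake_mr, "generator")
            idt_G = (idt_y - y4).abs().mean()
            idt_H = (idt_x - x4).abs().mean()
            if self.use_nce:
                nce_G = self._nce_term(m.G, m.heads_G, taps_x_G, fake_trus)
                nce_H = self._nce_term(m.H, m.heads_H, taps_y_H, fake_mr)
            else:
                nce_G = astensor(0.0)
                nce_H = astensor(0.0)
            if self.use_structure:
                fe = _diff_edges(fake_trus.reshape(x4.shape[-2], x4.shape[-1]),
                                 self.edge_filter, self.canny_threshold)
                lp = Lmod.structure_loss_prostate(
                    m.DP, np.squeeze(x4.data), fake_trus, roi.cp, edge_op,
                    role="generator", fake_edges=fe)
                lr_ = Lmod.structure_loss_rectum(
                    m.DR, np.squeeze(y4.data), fake_trus, roi.cr, edge_op,
                    role="generator", fake_edges=fe)
            else:
                lp = astensor(0.0)
                lr_ = astensor(0.0)

            terms_G = {"adv": adv_G, "nce": nce_G, "idt": idt_G, "lp": lp, "lr": lr_}
            terms_H = {"adv": adv_H, "nce": nce_H, "idt": idt_H}
            total_G = Lmod.total_loss_G(terms_G, w)
            total_H = Lmod.total_loss_H(terms_H, w)
            if self.use_style:
                style_G = Lmod.style_loss(fake_trus.reshape(y4.shape), y4)
                style_H = Lmod.style_loss(fake_mr.reshape(x4.shape), x4)
                total_G = total_G + style_G * self.lambda_style
                total_H = total_H + style_H * self.lambda_style
                log("style_G", style_G.item())
                log("style_H", style_H.item())
            if self.use_cycle:
                cyc = (astensor(m.H(fake_trus)) - x4).abs().mean() + \
                      (astensor(m.G(fake_mr)) - y4).abs().mean()
                total_G = total_G + cyc * self.lambda_cycle
                log("cycle", cyc.item())
            gen_total = gen_total + total_G + total_H
            for k, t in (("adv_G", adv_G), ("adv_H", adv_H), ("nce_G", nce_G),
                         ("nce_H", nce_H), ("idt_G", idt_G), ("idt_H", idt_H),
                         ("lp", lp), ("lr", lr_), ("total_G", total_G),
                         ("total_H", total_H)):
                log(k, t.item())

        # validate finiteness, then update
        self.loss_log_.append(LossReport(acc).terms)
        nb = 1.0 / len(batch)
        self.opt_disc_.zero_grad()
        (disc_total * nb).backward()
        self.opt_disc_.step()
        self.opt_gen_.zero_grad()
        (gen_total * nb).backward()
        self.opt_gen_.step()

    # -- inference ------------------------------------------------------------
    def _translate_slice(self, s: np.ndarray) -> np.ndarray:
        with no_grad():
            ref = self.trus_stats_ if self.use_normalization else None
            out = self.model_.G(self._as4(np.asarray(s, np.float32)), ref_stats=ref)
        return np.squeeze(out.data)

    def transform(self, X):
        """Translate MR input to synthetic TRUS.

        Accepts a 2-D slice, a list of slices, a 3-D array or a
        :class:`Volume`; returns the same kind, same grid.
        """
        if not hasattr(self, "model_"):
            raise RuntimeError("translator is not fitted")
        if isinstance(X, Volume):
            out = [self._translate_slice(s) for s in extract_slices(X)]
            return stack_slices(out, X.affine.copy())
        arr = np.asarray(X, dtype=float) if not isinstance(X, list) else X
        if isinstance(arr, np.ndarray) and arr.ndim == 2:
            return self._translate_slice(arr)
        if isinstance(arr, np.ndarray) and arr.ndim == 3:
            return np.stack([self._translate_slice(arr[:, :, k])
                             for k in range(arr.shape[2])], axis=-1)
        return [self._translate_slice(np.asarray(s, float)) for s in X]

    # -- checkpointing --------------------------------------------------------
    def save(self, path):
        """Write a checkpoint (weights, optimizers, RNG, pools, config)."""
        path = Path(path)
        arrays = {f"model:{k}": v for k, v in self.model_.state_dict().items()}
        for name, opt in (("gen", self.opt_gen_), ("disc", self.opt_disc_)):
            for k, v in opt.state_dict().items():
                arrays[f"opt_{name}:{k}"] = np.asarray(v)
        for pname, pool in (("trus", self.pool_trus_), ("mr", self.pool_mr_)):
            for i, img in enumerate(pool.images):
                arrays[f"pool_{pname}:{i}"] = img
        if self.trus_stats_ is not None:
            arrays["stats:trus_mu"], arrays["stats:trus_sd"] = self.trus_stats_
            arrays["stats:mr_mu"], arrays["stats:mr_sd"] = self.mr_stats_
        if hasattr(self, "roi_mask_"):
            arrays["roi:c0"] = self.roi_mask_.c0
            arrays["roi:cp"] = self.roi_mask_.cp
            arrays["roi:cr"] = self.roi_mask_.cr
        meta = {"params": self.get_params(), "n_iter": self.n_iter_,
                "rng_state": self.rng_.bit_generator.state,
                "loss_log": self.loss_log_}
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "MRToTRUSTranslator":
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz",
                     allow_pickle=False) as z:
            arrays = {k: z[k] for k in z.files}
        meta = json.loads(arrays.pop("meta").tobytes().decode())
        est = cls(**meta["params"])
        est._init_state()
        est.model_.load_state_dict(
            {k.split(":", 1)[1]: v for k, v in arrays.items() if k.startswith("model:")})
        est.opt_gen_.load_state_dict(
            {k.split(":", 1)[1]: v for k, v in arrays.items() if k.startswith("opt_gen:")})
        est.opt_disc_.load_state_dict(
            {k.split(":", 1)[1]: v for k, v in arrays.items() if k.startswith("opt_disc:")})
        for pname, pool in (("trus", est.pool_trus_), ("mr", est.pool_mr_)):
            keys = sorted([k for k in arrays if k.startswith(f"pool_{pname}:")],
                          key=lambda k: int(k.split(":")[1]))
            pool.images = [arrays[k] for k in keys]
        if "stats:trus_mu" in arrays:
            est.trus_stats_ = (arrays["stats:trus_mu"], arrays["stats:trus_sd"])
            est.mr_stats_ = (arrays["stats:mr_mu"], arrays["stats:mr_sd"])
        if "roi:c0" in arrays:
            from .roi import RoiMask
            est.roi_mask_ = RoiMask(arrays["roi:c0"], arrays["roi:cp"],
                                    arrays["roi:cr"])
        # mutate in place: the image pools hold a reference to est.rng_
        est.rng_.bit_generator.state = meta["rng_state"]
        est.loss_log_ = meta["loss_log"]
        est.n_iter_ = meta["n_iter"]
        return est

    def resume(self, X, iterations: int):
        """Continue training for ``iterations`` more steps on cohort ``X``."""
        self._cohort = self._load_cohort(X)
        for _ in range(iterations):
            self._step()
        self.n_iter_ = len(self.loss_log_)
        return self


# ---------------------------------------------------------------------------
# Functional wrappers and ablation surface
# ---------------------------------------------------------------------------

def train(manifest, **params) -> MRToTRUSTranslator:
    """Train a translator on a cohort manifest; see MRToTRUSTranslator."""
    return MRToTRUSTranslator(**params).fit(manifest)


def load_checkpoint(path) -> MRToTRUSTranslator:
    return MRToTRUSTranslator.load(path)


def translate(checkpoint, volume):
    """Apply a trained translator (estimator or checkpoint path) slice-wise."""
    est = checkpoint if isinstance(checkpoint, MRToTRUSTranslator) \
        else MRToTRUSTranslator.load(checkpoint)
    return est.transform(volume)


def ablation_params(variant: str) -> dict:
    """Estimator parameter overrides realizing one ablation variant."""
    table = {
        "full": {},
        "w/o cycle breaking": {"use_cycle": True},
        "w/o NCE": {"use_nce": False},
        "w/o normalization": {"use_normalization": False},
        "w/o structure constraint": {"use_structure": False},
        "w/o style adjustment": {"use_style": False},
    }
    if variant not in table:
        raise ValueError(f"unknown ablation variant: {variant!r}; "
                         f"choose from {ABLATION_VARIANTS}")
    return table[variant]


def run_ablation(manifest, base_params: dict, variant: str,
                 eval_manifest=None) -> dict:
    """Train one ablation variant and evaluate it on the paired cohort.

    Returns a metrics row (variant name + cohort-mean metrics) mirroring the
    published ablation table layout.
    """
    params = dict(base_params)
    params.update(ablation_params(variant))
    est = MRToTRUSTranslator(**params).fit(manifest)
    row = {"variant": variant}
    from .evaluation import evaluate_cohort
    report = evaluate_cohort(est, eval_manifest if eval_manifest is not None else manifest)
    row.update(report.summary)
    row["loss_keys"] = sorted(est.loss_log_[-1].keys()) if est.loss_log_ else []
    return row
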
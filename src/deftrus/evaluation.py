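"""Image-quality and registration metrics for synthetic TRUS evaluation:
PSNR, SSIM (global and ROI-restricted), NCC, a Fréchet distance over a
pluggable feature embedding, Dice overlap, rigid registration transfer and
centroid target registration error (TRE), plus cohort-level reporting.

PSNR of identical images is capped at 99 dB.  SSIM uses the standard
11x11 Gaussian window (sigma 1.5, k1=0.01, k2=0.03); images live in [-1, 1]
so the default data range is 2.  The Fréchet distance defaults to a small
fixed-seed random-convolution embedding so no pretrained weights are needed;
any callable mapping an image to a feature vector can be plugged in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, stats as sstats
from skimage.metrics import structural_similarity

from . import nn
from .nn import Tensor, no_grad
from .phantom import load_manifest, LABEL_PROSTATE, LABEL_RECTUM
from .preprocess import Volume, rigid_align, apply_rigid, extract_slices

__all__ = [
    "MetricReport", "psnr", "ssim", "roi_psnr", "roi_ssim", "ncc",
    "frechet_distance", "RandomConvEmbedding", "dsc", "register_and_transfer",
    "tre", "evaluate_cohort", "paired_ttest", "canny_threshold_sweep",
]

PSNR_CAP = 99.0


def psnr(a, b, data_range: float = 2.0) -> float:
    """Peak signal-to-noise ratio in dB, capped at 99 for identical images."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return PSNR_CAP
    return min(PSNR_CAP, 10.0 * np.log10(data_range ** 2 / mse))


def ssim(a, b, data_range: float = 2.0) -> float:
    """Windowed SSIM with an 11x11 Gaussian window (sigma 1.5)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03, win_size=11))


def roi_psnr(a, b, mask, data_range: float = 2.0) -> float:
    """PSNR over the masked pixels only."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty ROI mask")
    a, b = np.asarray(a, float)[mask], np.asarray(b, float)[mask]
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return PSNR_CAP
    return min(PSNR_CAP, 10.0 * np.log10(data_range ** 2 / mse))


def _bbox(mask: np.ndarray) -> tuple[slice, ...]:
    idx = np.where(mask)
    return tuple(slice(int(i.min()), int(i.max()) + 1) for i in idx)


def roi_ssim(a, b, mask, data_range: float = 2.0) -> float:
    """SSIM on the tight bounding box enclosing the mask."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty ROI mask")
    box = _bbox(mask)
    a, b = np.asarray(a, float)[box], np.asarray(b, float)[box]
    win = min(11, (min(a.shape) // 2) * 2 - 1) if min(a.shape) < 11 else 11
    return float(structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03, win_size=max(3, win)))


def ncc(a, b) -> float:
    """Zero-mean normalized cross-correlation over all pixels, in [-1, 1]."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    if den == 0:
        raise ValueError("NCC undefined for a constant image")
    return float(np.clip((a * b).sum() / den, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Frechet distance over a pluggable embedding
# ---------------------------------------------------------------------------

class RandomConvEmbedding:
    """Fixed-seed random-convolution image embedding.

    Three stride-2 convolution + leaky-ReLU stages followed by global average
    pooling.  The weights are random but frozen by the seed, giving a
    reproducible feature space without any downloaded model.
    """

    def __init__(self, dim: int = 64, seed: int = 1234):
        rng = np.random.default_rng(seed)
        self.net = nn.Sequential(
            nn.Conv2d(1, 16, 3, stride=2, padding=1, rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(16, 32, 3, stride=2, padding=1, rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(32, dim, 3, stride=2, padding=1, rng=rng),
            nn.LeakyReLU(0.2))

    def __call__(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, float).reshape(1, 1, *np.asarray(image).shape[-2:])
        with no_grad():
            h = self.net(Tensor(x))
        return h.data.mean(axis=(2, 3)).ravel()


def frechet_distance(features_a, features_b, eps: float = 1e-6) -> float:
    """Fréchet distance between Gaussian fits of two feature sets:
    ||mu_a - mu_b||^2 + tr(Sa + Sb - 2 (Sa Sb)^{1/2})."""
    fa = np.atleast_2d(np.asarray(features_a, float))
    fb = np.atleast_2d(np.asarray(features_b, float))
    if fa.shape[0] < 2 or fb.shape[0] < 2:
        raise ValueError("need at least two samples per feature set")
    mu_a, mu_b = fa.mean(axis=0), fb.mean(axis=0)
    ca = np.cov(fa, rowvar=False) + eps * np.eye(fa.shape[1])
    cb = np.cov(fb, rowvar=False) + eps * np.eye(fb.shape[1])
    ca, cb = np.atleast_2d(ca), np.atleast_2d(cb)
    covmean = np.real(np.atleast_2d(linalg.sqrtm(ca @ cb)))
    d2 = float(((mu_a - mu_b) ** 2).sum() + np.trace(ca + cb - 2.0 * covmean))
    return max(0.0, d2)


# ---------------------------------------------------------------------------
# Overlap and registration transfer
# ---------------------------------------------------------------------------

def dsc(mask_a, mask_b) -> float:
    """Dice similarity coefficient in percent: 200 |A∩B| / (|A| + |B|)."""
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    if a.shape != b.shape:
        raise ValueError("masks are on different grids")
    denom = a.sum() + b.sum()
    if denom == 0:
        warnings.warn("both masks empty: DSC defined as 100")
        return 100.0
    return float(200.0 * np.logical_and(a, b).sum() / denom)


def register_and_transfer(synthetic_trus, real_trus, mr_contour,
                          metric: str = "ncc"):
    """Transfer an MR-delineated contour onto the real TRUS frame.

    The synthetic TRUS (already anatomy-aligned with the MR input) is
    rigidly registered to the real TRUS; the recovered transform is applied
    to the contour with nearest-neighbour interpolation.  Returns
    (transferred contour, transform).
    """
    _, tf = rigid_align(synthetic_trus, real_trus, metric=metric)
    contour = np.asarray(mr_contour, float)
    if isinstance(synthetic_trus, Volume) and contour.ndim == 3:
        moved = apply_rigid(Volume(contour, np.eye(4)), tf, order=0, cval=0.0).data
    else:
        moved = apply_rigid(contour, tf, order=0, cval=0.0)
    return (moved > 0.5).astype(contour.dtype), tf


def tre(contour_a, contour_b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Target registration error in mm: distance between mask centroids."""
    a = np.asarray(contour_a) > 0
    b = np.asarray(contour_b) > 0
    if not a.any() or not b.any():
        raise ValueError("empty contour in TRE computation")
    spacing = np.asarray(spacing, float)[: a.ndim]
    ca = np.array([c.mean() for c in np.where(a)]) * spacing
    cb = np.array([c.mean() for c in np.where(b)]) * spacing
    return float(np.linalg.norm(ca - cb))


def paired_ttest(col_a, col_b) -> float:
    """Two-sided paired t-test p-value over matched metric columns."""
    return float(sstats.ttest_rel(np.asarray(col_a), np.asarray(col_b)).pvalue)


# ---------------------------------------------------------------------------
# Cohort evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-case metric table plus cohort mean ± sd summary."""

    cases: pd.DataFrame
    summary: dict

    def to_markdown(self) -> str:
        lines = ["| metric | mean | sd |", "|---|---|---|"]
        for k in sorted(self.summary):
            if k.endswith("_sd"):
                continue
            sd = self.summary.get(k + "_sd", float("nan"))
            lines.append(f"| {k} | {self.summary[k]:.4f} | {sd:.4f} |")
        return "\n".join(lines)


_METRIC_COLS = ("psnr", "ssim", "ncc", "fid", "dsc", "tre_mm",
                "roi_psnr_prostate", "roi_psnr_rectum",
                "roi_ssim_prostate", "roi_ssim_rectum")


def _prostate_mask(labels: np.ndarray) -> np.ndarray:
    return (labels == LABEL_PROSTATE) | (labels > LABEL_RECTUM)


def evaluate_cohort(translator, manifest, out_dir=None,
                    embedding=None) -> MetricReport:
    """Translate every paired evaluation MR case and score it against its
    ground-truth TRUS rendering.

    Per case: global PSNR/SSIM/NCC, per-organ ROI PSNR/SSIM, Fréchet
    distance of embedded slices, registration DSC of the transferred
    prostate contour and its centroid TRE.  The report aggregates cohort
    mean ± sd; CSV and markdown are written when ``out_dir`` is given.
    """
    manifest = manifest if isinstance(manifest, dict) else load_manifest(manifest)
    root = Path(manifest["root"])
    embedding = embedding or RandomConvEmbedding()
    pairs: dict[int, dict] = {}
    for e in manifest["entries"]:
        if e["role"] == "eval":
            pairs.setdefault(e["anatomy_id"], {})[e["domain"]] = e
    if not pairs:
        raise ValueError("manifest has no paired evaluation cases")
    rows = []
    for aid, pair in sorted(pairs.items()):
        if "mr" not in pair or "trus" not in pair:
            raise ValueError(f"eval anatomy {aid} is missing a pair member")
        mr = Volume.load(root / pair["mr"]["image"])
        gt = Volume.load(root / pair["trus"]["image"])
        mr_lab = Volume.load(root / pair["mr"]["labels"]).data
        gt_lab = Volume.load(root / pair["trus"]["labels"]).data
        fake = translator.transform(mr)
        spacing = gt.spacing
        f, g = fake.data, gt.data
        feats_f = [embedding(s) for s in extract_slices(fake)]
        feats_g = [embedding(s) for s in extract_slices(gt)]
        p_mask = _prostate_mask(gt_lab)
        r_mask = gt_lab == LABEL_RECTUM
        contour, _ = register_and_transfer(fake, gt, _prostate_mask(mr_lab))
        rows.append({
            "case": aid,
            "psnr": psnr(f, g),
            "ssim": float(np.mean([ssim(f[:, :, k], g[:, :, k])
                                   for k in range(f.shape[2])])),
            "ncc": ncc(f, g),
            "fid": frechet_distance(feats_f, feats_g),
            "dsc": dsc(contour, p_mask),
            "tre_mm": tre(contour, p_mask, spacing),
            "roi_psnr_prostate": roi_psnr(f, g, p_mask),
            "roi_psnr_rectum": roi_psnr(f, g, r_mask) if r_mask.any() else np.nan,
            "roi_ssim_prostate": float(np.mean(
                [roi_ssim(f[:, :, k], g[:, :, k], p_mask[:, :, k])
                 for k in range(f.shape[2]) if p_mask[:, :, k].any()])),
            "roi_ssim_rectum": float(np.mean(
                [roi_ssim(f[:, :, k], g[:, :, k], r_mask[:, :, k])
                 for k in range(f.shape[2]) if r_mask[:, :, k].any()])) if r_mask.any() else np.nan,
        })
    cases = pd.DataFrame(rows)
    summary = {}
    for c in _METRIC_COLS:
        summary[c] = float(cases[c].mean())
        summary[c + "_sd"] = float(cases[c].std(ddof=1)) if len(cases) > 1 else 0.0
    report = MetricReport(cases=cases, summary=summary)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cases.to_csv(out_dir / "cases.csv", index=False)
        (out_dir / "summary.md").write_text(report.to_markdown() + "\n")
        pd.Series(summary).to_json(out_dir / "summary.json")
    return report


def canny_threshold_sweep(translator, manifest, thresholds=(200, 250, 300, 350, 400)):
    """Edge-threshold robustness protocol: run the evaluation pipeline per
    Canny threshold and report edge-pixel counts alongside PSNR/SSIM.

    Edge counts are pooled over the synthetic TRUS slices; they are
    non-increasing in the threshold by the hysteresis construction.
    """
    from .roi import canny_edges

    manifest = manifest if isinstance(manifest, dict) else load_manifest(manifest)
    root = Path(manifest["root"])
    mr_entries = [e for e in manifest["entries"]
                  if e["role"] == "eval" and e["domain"] == "mr"]
    gt_entries = {e["anatomy_id"]: e for e in manifest["entries"]
                  if e["role"] == "eval" and e["domain"] == "trus"}
    rows = []
    fakes, gts = [], []
    for e in mr_entries:
        fakes.append(translator.transform(Volume.load(root / e["image"])))
        gts.append(Volume.load(root / gt_entries[e["anatomy_id"]]["image"]))
    for t in thresholds:
        count = 0
        for fk in fakes:
            for s in extract_slices(fk):
                count += int((canny_edges(s, threshold=t) > 0).sum())
        rows.append({
            "threshold": t,
            "edge_pixels": count,
            "psnr": float(np.mean([psnr(fk.data, gt.data)
                                   for fk, gt in zip(fakes, gts)])),
            "ssim": float(np.mean([ssim(fk.data[:, :, 0], gt.data[:, :, 0])
                                   for fk, gt in zip(fakes, gts)])),
        })
    return pd.DataFrame(rows)
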
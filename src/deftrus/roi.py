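"""ROI structure guidance: the averaged organ mask c0, its per-iteration
random elastic perturbation, and masked edge extraction.

The image-independent soft mask c0 is the voxelwise average of pre-annotated
organ contours (prostate + rectum union); cp and cr are the corresponding
per-organ sub-masks.  During training c0 is re-perturbed every iteration by a
coarse-grid random displacement field, bicubically upsampled and Gaussian
smoothed — the perturbation keeps the structure losses from overfitting to
one average anatomy.

Edge maps live in [-1, 1] with background -1 and edges toward +1, matching
the image intensity convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature

from .phantom import LABEL_PROSTATE, LABEL_RECTUM, warp_image

__all__ = [
    "RoiMask", "build_average_mask", "elastic_perturb", "elastic_field",
    "sobel_edges", "sobel_magnitude", "canny_edges", "masked_edges",
    "edge_operator",
]


@dataclass
class RoiMask:
    """Soft mask c0 in [0, 1] with prostate (cp) and rectum (cr) sub-masks."""

    c0: np.ndarray
    cp: np.ndarray
    cr: np.ndarray

    def __post_init__(self):
        for m in (self.c0, self.cp, self.cr):
            if m.min() < 0 or m.max() > 1:
                raise ValueError("mask values must lie in [0, 1]")
        if self.c0.sum() == 0:
            raise ValueError("empty ROI mask")


def build_average_mask(contour_volumes) -> RoiMask:
    """Average pre-annotated label maps into the soft ROI mask c0.

    ``contour_volumes``: label arrays (2-D, or 3-D stacks whose slices are
    pooled) using the phantom labels (1 prostate, 2 rectum; the urethra and
    lesion count as prostate tissue).  c0 is the mean organ-union indicator;
    cp/cr are the per-organ means thresholded at 0.5.
    """
    if len(contour_volumes) == 0:
        raise ValueError("need at least one contour volume")
    unions, ps, rs = [], [], []
    for lab in contour_volumes:
        lab = np.asarray(lab)
        if lab.ndim == 3:
            slices = [lab[:, :, k] for k in range(lab.shape[2])]
        else:
            slices = [lab]
        for s in slices:
            if s.shape != np.asarray(contour_volumes[0]).shape[:2]:
                raise ValueError("contour volumes are not on a common grid")
            prostate = (s == LABEL_PROSTATE) | (s > LABEL_RECTUM)  # urethra/lesion
            rectum = s == LABEL_RECTUM
            unions.append((prostate | rectum).astype(float))
            ps.append(prostate.astype(float))
            rs.append(rectum.astype(float))
    c0 = np.mean(unions, axis=0)
    cp = (np.mean(ps, axis=0) >= 0.5).astype(float)
    cr = (np.mean(rs, axis=0) >= 0.5).astype(float)
    return RoiMask(c0=c0, cp=cp, cr=cr)


def elastic_field(shape, grid_points: int = 3, sigma: float = 20.0,
                  alpha: float = 7.0, rng=None) -> np.ndarray:
    """Random smooth displacement field, shape (2, H, W).

    Displacements are drawn i.i.d. N(0, alpha) on a ``grid_points`` square
    lattice, bicubically upsampled to the full grid and smoothed with a
    Gaussian of standard deviation ``sigma``.
    """
    if grid_points < 2:
        raise ValueError("grid_points must be >= 2")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(rng)
    coarse = rng.normal(0.0, alpha, size=(2, grid_points, grid_points))
    if alpha == 0:
        return np.zeros((2,) + tuple(shape))
    zoom = (1,) + tuple(n / grid_points for n in shape)
    field = ndimage.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)
    if sigma > 0:
        field = np.stack([ndimage.gaussian_filter(f, sigma) for f in field])
    return field


def elastic_perturb(mask: RoiMask, grid_points: int = 3, sigma: float = 20.0,
                    alpha: float = 7.0, seed=None) -> RoiMask:
    """One random elastic perturbation of the ROI mask (fresh per iteration).

    Deterministic given ``seed``; values stay in [0, 1] (linear warp of a
    [0, 1] mask, clipped against round-off).
    """
    field = elastic_field(mask.c0.shape, grid_points, sigma, alpha, rng=seed)

    def w(m, order):
        return np.clip(warp_image(m, field, order=order), 0.0, 1.0)

    return RoiMask(c0=w(mask.c0, 1), cp=w(mask.cp, 0), cr=w(mask.cr, 0))


# ---------------------------------------------------------------------------
# Edge operators
# ---------------------------------------------------------------------------

def sobel_magnitude(image: np.ndarray) -> np.ndarray:
    """Unnormalized 3x3 Sobel gradient magnitude (row kernel sum 8 per unit
    slope, the OpenCV/classical convention)."""
    image = np.asarray(image, dtype=float)
    gr = ndimage.sobel(image, axis=0, mode="nearest")
    gc = ndimage.sobel(image, axis=1, mode="nearest")
    return np.hypot(gr, gc)


def sobel_edges(image: np.ndarray) -> np.ndarray:
    """Sobel gradient-magnitude edge map rescaled to [-1, 1].

    Zero magnitude maps to -1; the maximal magnitude in the image maps to +1.
    A constant image (no gradient anywhere) returns all -1.
    """
    mag = sobel_magnitude(image)
    peak = mag.max()
    if peak == 0:
        return np.full_like(mag, -1.0)
    return 2.0 * mag / peak - 1.0


def canny_edges(image: np.ndarray, threshold: int = 300, sigma: float = 1.2) -> np.ndarray:
    """Binary Canny edge map normalized to {-1, +1}.

    The image is first rescaled to [0, 255]; ``threshold`` is the high
    hysteresis threshold in unnormalized 3x3-Sobel units (low = threshold/2,
    the standard hysteresis ratio) — the same gradient convention skimage's
    Canny uses internally, so thresholds pass through unchanged.
    ``sigma=1.2`` avoids non-maximum-suppression ties (doubled edges) that a
    unit-sigma Gaussian produces on perfectly symmetric intensity steps.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    scaled = np.zeros_like(image) if hi == lo else (image - lo) * (255.0 / (hi - lo))
    edges = feature.canny(scaled, sigma=sigma,
                          low_threshold=threshold / 2.0,
                          high_threshold=float(threshold))
    return np.where(edges, 1.0, -1.0)


def edge_operator(name: str = "canny", canny_threshold: int = 300):
    """Return the configured edge filter as image -> EdgeMap in [-1, 1]."""
    if name == "canny":
        return lambda img: canny_edges(img, threshold=canny_threshold)
    if name == "sobel":
        return sobel_edges
    raise ValueError(f"unknown edge filter: {name!r}")


def masked_edges(edges: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Retain edges inside the (soft) region mask.

    The product is taken in the non-negative [0, 2] representation so that a
    zero region yields the background value -1 rather than the mid-scale 0:
    out = region * (edges + 1) - 1.
    """
    edges = np.asarray(edges, dtype=float)
    region = np.asarray(region, dtype=float)
    if edges.shape != region.shape:
        raise ValueError("edge map and region grids differ")
    return region * (edges + 1.0) - 1.0
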
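"""Volume container and the preprocessing chain: resampling, rigid template
alignment, center crop/pad, intensity scaling and axial slice extraction.

The clinical recipe this mirrors: resample to 0.3 x 0.3 x 1 mm, rigidly
register each modality to its template, crop to 296 x 296 x 34, scale
intensities to [-1, 1], and operate on 2-D axial slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from scipy import ndimage, optimize

__all__ = [
    "Volume", "RigidTransform2D", "resample", "rigid_align", "apply_rigid",
    "crop_or_pad", "scale_intensity", "extract_slices", "stack_slices",
    "BACKGROUND_VALUE",
]

BACKGROUND_VALUE = -1.0


@dataclass
class Volume:
    """3-D scalar image with a grid-to-world affine (voxel indices 0-based)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self):
        return self.data.shape

    def save(self, path):
        nib.save(nib.Nifti1Image(np.asarray(self.data), self.affine), str(path))

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj), img.affine)


def resample(v: Volume, spacing_mm, order: int = 1) -> Volume:
    """Resample to the requested voxel spacing with linear interpolation.

    Assumes an axis-aligned affine (true for all phantom and template grids
    handled here); the world extent is preserved to within one voxel.
    """
    spacing_mm = np.asarray(spacing_mm, dtype=float)
    if (spacing_mm <= 0).any():
        raise ValueError("spacing must be positive")
    old = v.spacing
    zoom = old / spacing_mm
    if np.allclose(zoom, 1.0):
        return Volume(v.data.copy(), v.affine.copy())
    new_shape = np.maximum(1, np.round(np.array(v.data.shape) * zoom)).astype(int)
    # output voxel i samples input at i * new_spacing / old_spacing
    scale = spacing_mm / old
    out = ndimage.affine_transform(
        v.data.astype(float), np.diag(scale), output_shape=tuple(new_shape),
        order=order, mode="nearest")
    aff = v.affine.copy()
    aff[:3, :3] = v.affine[:3, :3] * (spacing_mm / old)[None, :]
    return Volume(out, aff)


def crop_or_pad(v: Volume, size, background: float = BACKGROUND_VALUE) -> Volume:
    """Center crop to ``size``; pad symmetrically with ``background`` when smaller."""
    size = tuple(int(s) for s in size)
    if any(s <= 0 for s in size):
        raise ValueError("size must be positive")
    out = np.full(size, background, dtype=float)
    src_sl, dst_sl, offsets = [], [], []
    for ax in range(3):
        n, m = v.data.shape[ax], size[ax]
        if m <= n:
            a = (n - m) // 2
            src_sl.append(slice(a, a + m))
            dst_sl.append(slice(0, m))
            offsets.append(a)
        else:
            b = (m - n) // 2
            src_sl.append(slice(0, n))
            dst_sl.append(slice(b, b + n))
            offsets.append(-b)
    out[tuple(dst_sl)] = v.data[tuple(src_sl)]
    aff = v.affine.copy()
    aff[:3, 3] = v.affine[:3, 3] + v.affine[:3, :3] @ np.array(offsets, dtype=float)
    return Volume(out, aff)


def scale_intensity(v: Volume) -> Volume:
    """Affine map of the intensity range onto exactly [-1, 1].

    A constant image has no range; it maps to all zeros (with a warning)
    rather than dividing by zero.
    """
    lo, hi = float(v.data.min()), float(v.data.max())
    if hi - lo == 0.0:
        warnings.warn("constant image: scaled output is all zeros")
        return Volume(np.zeros_like(v.data, dtype=float), v.affine.copy())
    out = 2.0 * (v.data.astype(float) - lo) / (hi - lo) - 1.0
    return Volume(out, v.affine.copy())


def extract_slices(v: Volume) -> list[np.ndarray]:
    """Axial slices in index order; slice k equals ``v.data[:, :, k]``."""
    if v.data.ndim != 3:
        raise ValueError("extract_slices expects a 3-D volume")
    return [np.asarray(v.data[:, :, k]) for k in range(v.data.shape[2])]


def stack_slices(slices, affine=None) -> Volume:
    return Volume(np.stack(slices, axis=-1), np.eye(4) if affine is None else affine)


# ---------------------------------------------------------------------------
# Rigid registration (in-plane)
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform2D:
    """In-plane rotation (degrees, about the image center) plus translation (px)."""

    theta_deg: float = 0.0
    t_row: float = 0.0
    t_col: float = 0.0


def _apply_rigid_2d(img: np.ndarray, tf: RigidTransform2D, order: int = 1,
                    cval: float = BACKGROUND_VALUE) -> np.ndarray:
    """Resample ``img`` under ``tf``: content rotates by +theta about the
    center and shifts by (+t_row, +t_col)."""
    th = np.deg2rad(tf.theta_deg)
    A = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    c = (np.asarray(img.shape, dtype=float) - 1.0) / 2.0
    t = np.array([tf.t_row, tf.t_col])
    # output(p) = input(A^-1 (p - t - c) + c); A is orthogonal so A^-1 = A.T
    Ai = A.T
    offset = c - Ai @ (c + t)
    return ndimage.affine_transform(img, Ai, offset=offset, order=order,
                                    mode="constant", cval=cval)


def apply_rigid(v: Volume | np.ndarray, tf: RigidTransform2D, order: int = 1,
                cval: float = BACKGROUND_VALUE):
    """Apply an in-plane rigid transform slice-wise (2-D arrays or volumes)."""
    if isinstance(v, Volume):
        out = np.stack([_apply_rigid_2d(v.data[:, :, k], tf, order, cval)
                        for k in range(v.data.shape[2])], axis=-1)
        return Volume(out, v.affine.copy())
    return _apply_rigid_2d(np.asarray(v, dtype=float), tf, order, cval)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    if den == 0:
        return 0.0
    return float((a * b).sum() / den)


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def _metric(name: str):
    if name == "ncc":
        return _ncc
    if name == "mi":
        return _mutual_information
    raise ValueError(f"unknown similarity metric: {name!r}")


def _coarse_translation(moving: np.ndarray, fixed: np.ndarray) -> tuple[float, float]:
    """Integer translation maximizing zero-mean cross-correlation (FFT)."""
    from scipy.signal import fftconvolve

    a = fixed - fixed.mean()
    b = moving - moving.mean()
    corr = fftconvolve(a, b[::-1, ::-1], mode="same")
    idx = np.unravel_index(np.argmax(corr), corr.shape)
    center = (np.array(corr.shape) - 1) // 2
    shift = np.array(idx) - center
    return float(shift[0]), float(shift[1])


def rigid_align(moving, fixed, metric: str = "ncc",
                theta_starts=(-12.0, 0.0, 12.0)):
    """Recover the in-plane rigid transform aligning ``moving`` to ``fixed``.

    Coarse FFT cross-correlation initializes the translation; multi-start
    Powell refinement then optimizes (theta, t_row, t_col) under the chosen
    similarity ('ncc' within modality, 'mi' across).  Returns
    (aligned image/volume, RigidTransform2D).  3-D volumes are registered on
    their mean axial projection and the transform applied slice-wise.
    """
    mov_vol = isinstance(moving, Volume)
    mov2 = moving.data.mean(axis=2) if mov_vol else np.asarray(moving, dtype=float)
    fix2 = fixed.data.mean(axis=2) if isinstance(fixed, Volume) else np.asarray(fixed, dtype=float)
    if mov2.shape != fix2.shape:
        raise ValueError("moving and fixed grids differ")
    sim = _metric(metric)
    if sim(mov2, fix2) == 0.0 and metric == "ncc" and (
            np.ptp(mov2) == 0 or np.ptp(fix2) == 0):
        raise ValueError("degenerate images: no overlap signal to register")

    t0 = _coarse_translation(mov2, fix2)

    def cost(p):
        tf = RigidTransform2D(p[0], p[1], p[2])
        return -sim(_apply_rigid_2d(mov2, tf), fix2)

    best, best_cost = None, np.inf
    starts = [np.array([th, t0[0], t0[1]]) for th in theta_starts]
    starts.append(np.zeros(3))
    for x0 in starts:
        res = optimize.minimize(cost, x0, method="Powell",
                                options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 400})
        if res.fun < best_cost:
            best_cost, best = res.fun, res.x
    # never return a transform worse than identity
    if -best_cost < sim(mov2, fix2):
        best = np.zeros(3)
    tf = RigidTransform2D(float(best[0]), float(best[1]), float(best[2]))
    return apply_rigid(moving, tf), tf
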
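"""Synthetic pelvic phantom: unpaired MR-like and TRUS-like cohorts.

The phantom emulates the clinical setting of endorectal-ultrasound-guided
prostate brachytherapy: a shared 2-D pelvic anatomy (prostate ellipse with an
embedded urethra and optional lesion, rectum disc adjacent to the inferior
image border) rendered twice —

* MR-like: high-contrast piecewise-constant tissue values with mild additive
  noise ("external coil", no deformation);
* TRUS-like: the same anatomy first warped by a smooth probe-insertion
  displacement field, then rendered with low contrast, multiplicative
  log-normal speckle and a fan-shaped field of view.

Training cohorts are unpaired (distinct anatomy draws per domain); the
evaluation cohort is paired (same anatomy, MR undeformed, TRUS deformed,
with the true displacement field saved alongside).  Volumes are thin axial
stacks written as NIfTI so the full volume I/O path is exercised.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess import Volume

__all__ = [
    "PhantomSpec", "AnatomyLabelMap", "generate_anatomy", "probe_deformation",
    "render_mr", "render_trus", "warp_image", "invert_field", "make_cohort",
    "LABEL_BACKGROUND", "LABEL_PROSTATE", "LABEL_RECTUM", "LABEL_URETHRA",
    "LABEL_LESION",
]

LABEL_BACKGROUND, LABEL_PROSTATE, LABEL_RECTUM, LABEL_URETHRA, LABEL_LESION = range(5)

# Tissue intensity tables in [-1, 1].  MR: bright prostate on dark background
# with a clearly separated urethra; TRUS: compressed low-contrast range.
MR_INTENSITY = {0: -0.60, 1: 0.30, 2: -0.20, 3: 0.70, 4: 0.50}
TRUS_INTENSITY = {0: -0.35, 1: -0.10, 2: -0.50, 3: 0.05, 4: -0.22}


@dataclass
class PhantomSpec:
    """Geometry and appearance parameters of one phantom anatomy."""

    image_size: int = 128
    prostate_center: tuple = (56.0, 64.0)     # (row, col), rows grow inferiorly
    prostate_axes: tuple = (26.0, 32.0)       # semi-axes in px (row, col)
    rectum_center: tuple = (112.0, 64.0)
    rectum_radius: float = 14.0
    urethra_radius: float = 4.0
    lesion_center: tuple | None = (48.0, 76.0)
    lesion_radius: float = 6.0
    deform_amplitude: float = 6.0             # peak probe displacement, px
    deform_sigma: float | None = None         # Gaussian decay length, px (default size/6)
    speckle_sigma: float = 0.25               # log-normal speckle scale
    mr_noise_sigma: float = 0.02
    fan_angle: float = 120.0                  # full fan opening, degrees
    n_slices: int = 3
    seed: int = 0

    @classmethod
    def for_size(cls, image_size: int, **overrides) -> "PhantomSpec":
        """Default geometry proportionally scaled to ``image_size`` pixels."""
        f = image_size / 128.0
        spec = dict(
            image_size=image_size,
            prostate_center=(56.0 * f, 64.0 * f),
            prostate_axes=(26.0 * f, 32.0 * f),
            rectum_center=(112.0 * f, 64.0 * f),
            rectum_radius=14.0 * f,
            urethra_radius=max(2.0, 4.0 * f),
            lesion_center=(48.0 * f, 76.0 * f),
            lesion_radius=max(2.5, 6.0 * f),
            deform_amplitude=6.0 * f,
        )
        spec.update(overrides)
        return cls(**spec)

    def validate(self):
        s = self.image_size
        if s < 16:
            raise ValueError("image_size too small")
        if self.deform_amplitude < 0:
            raise ValueError("deform_amplitude must be >= 0")
        pr, pc = self.prostate_center
        ar, ac = self.prostate_axes
        if pr - ar < 0 or pr + ar >= s or pc - ac < 0 or pc + ac >= s:
            raise ValueError("prostate extends outside the image")
        rr, rc = self.rectum_center
        if rc - self.rectum_radius < 0 or rc + self.rectum_radius >= s or rr >= s:
            raise ValueError("rectum extends outside the image laterally")


@dataclass
class AnatomyLabelMap:
    """Integer label image: 0 bg, 1 prostate, 2 rectum, 3 urethra, 4 lesion."""

    labels: np.ndarray
    spacing: tuple = (1.0, 1.0)

    def organ_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _disc(shape, center, radius) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _ellipse(shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def generate_anatomy(spec: PhantomSpec) -> AnatomyLabelMap:
    """Rasterize the phantom anatomy into a 2-D label map.

    Exactly one label per pixel: the urethra (and optional lesion) are carved
    out of the prostate; a prostate/rectum overlap is a validation error
    because the two organs are anatomically disjoint.
    """
    spec.validate()
    shape = (spec.image_size, spec.image_size)
    prostate = _ellipse(shape, spec.prostate_center, spec.prostate_axes)
    rectum = _disc(shape, spec.rectum_center, spec.rectum_radius)
    if (prostate & rectum).any():
        raise ValueError("requested prostate and rectum overlap")
    urethra = _disc(shape, spec.prostate_center, spec.urethra_radius)
    if not (urethra <= prostate).all():
        raise ValueError("urethra not contained in the prostate")
    labels = np.zeros(shape, dtype=np.int16)
    labels[prostate] = LABEL_PROSTATE
    labels[rectum] = LABEL_RECTUM
    labels[urethra] = LABEL_URETHRA
    if spec.lesion_center is not None:
        lesion = _disc(shape, spec.lesion_center, spec.lesion_radius)
        if not (lesion <= (prostate & ~urethra)).all():
            raise ValueError("lesion not contained in the prostate")
        labels[lesion] = LABEL_LESION
    return AnatomyLabelMap(labels=labels)


def probe_deformation(spec: PhantomSpec) -> np.ndarray:
    """Smooth displacement field of the endorectal probe push, shape (2, H, W).

    A Gaussian-windowed push directed away from the rectum center (anteriorly,
    toward the prostate), with peak magnitude ``deform_amplitude`` at the
    rectum center and a decay length of ``deform_sigma`` (default size/6).
    A linear taper over the outermost 4 pixels forces the field to zero at
    the image border so warps never read outside the grid.
    """
    s = spec.image_size
    sigma = spec.deform_sigma if spec.deform_sigma is not None else s / 6.0
    rr, cc = np.mgrid[0:s, 0:s].astype(float)
    d2 = (rr - spec.rectum_center[0]) ** 2 + (cc - spec.rectum_center[1]) ** 2
    mag = spec.deform_amplitude * np.exp(-d2 / (2.0 * sigma ** 2))
    margin = 4.0
    border = np.minimum.reduce([rr, cc, s - 1 - rr, s - 1 - cc])
    mag = mag * np.clip(border / margin, 0.0, 1.0)
    field = np.zeros((2, s, s))
    field[0] = -mag  # push anteriorly: toward smaller row index
    return field


def warp_image(image: np.ndarray, displacement: np.ndarray, order: int = 1) -> np.ndarray:
    """Backward-warp: output(p) = image(p - displacement(p)).

    Content therefore moves along ``+displacement``.  ``order=0`` for label
    maps, linear for intensities.
    """
    if displacement.shape[1:] != image.shape:
        raise ValueError("displacement field and image grids differ")
    rr, cc = np.mgrid[0:image.shape[0], 0:image.shape[1]].astype(float)
    coords = np.stack([rr - displacement[0], cc - displacement[1]])
    return ndimage.map_coordinates(image, coords, order=order, mode="nearest")


def invert_field(displacement: np.ndarray, n_iter: int = 20) -> np.ndarray:
    """Fixed-point inverse of a small displacement field: d_inv(p) = -d(p + d_inv(p))."""
    inv = -displacement.copy()
    rr, cc = np.mgrid[0:displacement.shape[1], 0:displacement.shape[2]].astype(float)
    for _ in range(n_iter):
        coords = np.stack([rr + inv[0], cc + inv[1]])
        inv = -np.stack(
            [ndimage.map_coordinates(displacement[i], coords, order=1, mode="nearest")
             for i in range(2)]
        )
    return inv


def _fan_mask(shape, apex, fan_angle_deg) -> np.ndarray:
    """Pixels inside a symmetric fan opening upward from ``apex``."""
    if fan_angle_deg >= 360.0:
        return np.ones(shape, dtype=bool)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    # angle of (p - apex) measured from the anterior (upward, -row) direction
    ang = np.degrees(np.arctan2(cc - apex[1], apex[0] - rr))
    return np.abs(ang) <= fan_angle_deg / 2.0


def render_mr(labels: AnatomyLabelMap, spec: PhantomSpec) -> np.ndarray:
    """MR-like rendering: high-contrast tissue table plus additive noise.

    With ``mr_noise_sigma == 0`` the output is exactly piecewise constant.
    """
    table = np.array([MR_INTENSITY[k] for k in range(5)])
    img = table[labels.labels]
    if spec.mr_noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        img = ndimage.gaussian_filter(img, 0.7)
        img = img + rng.normal(0.0, spec.mr_noise_sigma, img.shape)
    return np.clip(img, -1.0, 1.0)


def render_trus(labels: AnatomyLabelMap, field: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """TRUS-like rendering: warp labels by the probe field, then add
    multiplicative log-normal speckle and mask to a fan field of view.

    Outside-fan pixels are set to -1.  Deterministic given ``spec.seed``.
    """
    if field.shape[1:] != labels.labels.shape:
        raise ValueError("field and label grids differ")
    warped = warp_image(labels.labels.astype(float), field, order=0).astype(np.int16)
    table = np.array([TRUS_INTENSITY[k] for k in range(5)])
    img01 = (table[warped] + 1.0) / 2.0
    if spec.speckle_sigma > 0:
        rng = np.random.default_rng(spec.seed + 2)
        speckle = np.exp(rng.normal(0.0, spec.speckle_sigma, img01.shape))
        speckle = ndimage.gaussian_filter(speckle, 1.0)
        img01 = ndimage.gaussian_filter(img01, 0.7) * speckle
    img = np.clip(img01 * 2.0 - 1.0, -1.0, 1.0)
    apex = (float(spec.image_size - 1), float(spec.image_size - 1) / 2.0)
    img[~_fan_mask(img.shape, apex, spec.fan_angle)] = -1.0
    return img


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _jittered_spec(base: PhantomSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    """Draw one anatomy by jittering the base geometry (low-variance cohort)."""
    s = base.image_size
    scale = s / 128.0

    def j(a):
        return float(a + rng.normal(0.0, 2.0 * scale))

    pr = (j(base.prostate_center[0]), j(base.prostate_center[1]))
    ax = (max(8.0 * scale, j(base.prostate_axes[0])), max(8.0 * scale, j(base.prostate_axes[1])))
    lesion = None
    if base.lesion_center is not None:
        # keep lesion well inside the prostate ellipse
        lr = base.lesion_radius
        lesion = (pr[0] - ax[0] * 0.3, pr[1] + ax[1] * 0.35)
    return PhantomSpec(
        image_size=s,
        prostate_center=pr,
        prostate_axes=ax,
        rectum_center=(j(base.rectum_center[0]), j(base.rectum_center[1])),
        rectum_radius=max(6.0 * scale, j(base.rectum_radius)),
        urethra_radius=base.urethra_radius,
        lesion_center=lesion,
        lesion_radius=base.lesion_radius,
        deform_amplitude=max(0.0, base.deform_amplitude + rng.normal(0.0, 1.0)),
        deform_sigma=base.deform_sigma,
        speckle_sigma=base.speckle_sigma,
        mr_noise_sigma=base.mr_noise_sigma,
        fan_angle=base.fan_angle,
        n_slices=base.n_slices,
        seed=seed,
    )


def _slice_profile(n_slices: int) -> np.ndarray:
    """Organ axis scaling across the stack (mid slice largest)."""
    if n_slices == 1:
        return np.array([1.0])
    z = np.linspace(-0.6, 0.6, n_slices)
    return np.sqrt(1.0 - z ** 2)


def _stack(spec: PhantomSpec, render, deformed: bool):
    """Render a thin axial stack; returns (image, labels, field) arrays."""
    prof = _slice_profile(spec.n_slices)
    imgs, labs = [], []
    field = probe_deformation(spec)
    for k, f in enumerate(prof):
        sl = PhantomSpec(**{**asdict(spec),
                            "prostate_axes": (spec.prostate_axes[0] * f,
                                              spec.prostate_axes[1] * f),
                            "lesion_center": spec.lesion_center if f > 0.9 else None,
                            "seed": spec.seed * 1000 + k})
        anat = generate_anatomy(sl)
        if deformed:
            imgs.append(render(anat, field, sl))
            labs.append(warp_image(anat.labels.astype(float), field, order=0))
        else:
            imgs.append(render(anat, sl))
            labs.append(anat.labels.astype(float))
    img3 = np.stack(imgs, axis=-1)
    lab3 = np.stack(labs, axis=-1).astype(np.int16)
    return img3, lab3, field


def _default_affine(spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def make_cohort(out_dir, n_train_mr: int, n_train_trus: int, n_paired_eval: int,
                seed: int = 0, base_spec: PhantomSpec | None = None) -> dict:
    """Write an unpaired training cohort plus a paired evaluation cohort.

    Training MR and TRUS sets come from *distinct* anatomy draws; each paired
    evaluation case shares one anatomy between the undeformed MR rendering
    and the probe-deformed TRUS rendering (true field saved as NIfTI).
    Returns the manifest dict, also written to ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    entries = []
    anatomy_id = 0

    def write(vol, name, dtype=np.float32):
        path = out_dir / name
        Volume(np.asarray(vol, dtype=dtype), _default_affine()).save(path)
        return name

    def add_case(domain: str, role: str, paired_id=None):
        nonlocal anatomy_id
        spec = _jittered_spec(base, rng, seed=int(rng.integers(0, 2 ** 20)))
        aid = anatomy_id if paired_id is None else paired_id
        if paired_id is None:
            anatomy_id += 1
        tag = f"{role}_{domain}_{len(entries):03d}"
        entry = {"id": tag, "domain": domain, "role": role, "anatomy_id": aid}
        if domain == "mr":
            img, lab, _ = _stack(spec, render_mr, deformed=False)
            entry["image"] = write(img, f"{tag}.nii.gz")
            entry["labels"] = write(lab, f"{tag}_labels.nii.gz", np.int16)
        else:
            img, lab, field = _stack(spec, render_trus, deformed=True)
            entry["image"] = write(img, f"{tag}.nii.gz")
            entry["labels"] = write(lab, f"{tag}_labels.nii.gz", np.int16)
            f3 = np.moveaxis(np.stack([field] * spec.n_slices, axis=-1), 0, -1)
            entry["field"] = write(f3, f"{tag}_field.nii.gz")
        entries.append(entry)
        return spec

    for _ in range(n_train_mr):
        add_case("mr", "train")
    for _ in range(n_train_trus):
        add_case("trus", "train")
    for _ in range(n_paired_eval):
        aid = anatomy_id
        anatomy_id += 1
        # paired: freeze the rng state so both renderings share one anatomy
        state = rng.bit_generator.state
        add_case("mr", "eval", paired_id=aid)
        rng.bit_generator.state = state
        add_case("trus", "eval", paired_id=aid)

    manifest = {
        "seed": seed,
        "image_size": base.image_size,
        "n_slices": base.n_slices,
        "entries": entries,
    }
    text = json.dumps(manifest, indent=1, sort_keys=True)
    (out_dir / "manifest.json").write_text(text)
    manifest["hash"] = hashlib.sha256(text.encode()).hexdigest()
    manifest["root"] = str(out_dir)
    return manifest


def load_manifest(path) -> dict:
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    manifest = json.loads(path.read_text())
    manifest["root"] = str(path.parent)
    return manifest
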
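"""Training objectives: patch-contrastive NCE, domain adversarial, identity,
style (patchwise moment matching), the masked edge-adversarial structure
losses for prostate and rectum, and the weighted generator totals

    L_H = l1*Ladv + l2*Lnce + l3*Lidt
    L_G = l4*Ladv + l5*Lnce + l6*Lidt + l7*(Lp + Lr)

with default weights l1=0.5, l2=l3=0.25, l4=0.5, l5=l6=0.25, l7=0.01.

Every function accepts plain arrays or autodiff tensors and returns a scalar
:class:`~deftrus.nn.Tensor`; call ``float()``/``.item()`` on the result for
a plain number.  Discriminator probabilities are eps-clamped before logs so
all losses are finite on [-1, 1] inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np

from .nn import Tensor, astensor, concat
from .roi import masked_edges

__all__ = [
    "LossWeights", "LossReport", "nce_loss", "adversarial_loss",
    "identity_loss", "style_loss", "cycle_loss",
    "structure_loss_prostate", "structure_loss_rectum",
    "total_loss_G", "total_loss_H",
]

_EPS = 1e-7


@dataclass
class LossWeights:
    """Non-negative weights of the generator objectives."""

    lambda1: float = 0.5    # H: adversarial
    lambda2: float = 0.25   # H: NCE
    lambda3: float = 0.25   # H: identity
    lambda4: float = 0.5    # G: adversarial
    lambda5: float = 0.25   # G: NCE
    lambda6: float = 0.25   # G: identity
    lambda7: float = 0.01   # G: structure (Lp + Lr)

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")


@dataclass
class LossReport:
    """Named scalar values of every term plus the weighted totals."""

    terms: dict

    def __post_init__(self):
        bad = [k for k, v in self.terms.items() if not np.isfinite(v)]
        if bad:
            raise FloatingPointError(f"non-finite loss terms: {bad}")

    def __getitem__(self, key):
        return self.terms[key]


def _cosine(a: Tensor, b: Tensor, eps: float = 1e-8) -> Tensor:
    """Row-wise cosine similarity of (..., D) against (..., D)."""
    na = ((a ** 2).sum(axis=-1, keepdims=True) + eps).sqrt()
    nb = ((b ** 2).sum(axis=-1, keepdims=True) + eps).sqrt()
    return ((a / na) * (b / nb)).sum(axis=-1)


def nce_loss(v, v_plus, negatives, temperature: float = 1.0) -> Tensor:
    """Noise-contrastive estimation over cosine similarities:

        -log( e^{sim(v, v+)} / (e^{sim(v, v+)} + sum_n e^{sim(v, v-_n)}) )

    averaged over anchors.  ``v``/``v_plus``: (D,) or (M, D); ``negatives``:
    (K, D) shared pool or (M, K, D) per-anchor.  No temperature by default —
    the raw exponentiated similarity.
    """
    v = astensor(v)
    vp = astensor(v_plus)
    neg = astensor(negatives)
    if v.ndim == 1:
        v = v.reshape(1, -1)
        vp = vp.reshape(1, -1)
    if neg.ndim == 2 and neg.shape[0] == 0 or neg.ndim == 3 and neg.shape[1] == 0:
        raise ValueError("need at least one negative sample")
    if (np.linalg.norm(v.data, axis=-1) < 1e-12).any() or \
       (np.linalg.norm(vp.data, axis=-1) < 1e-12).any():
        raise ValueError("zero-norm vector in NCE input")
    pos = _cosine(v, vp).reshape(-1, 1)                       # (M, 1)
    if neg.ndim == 2:
        nv = neg / ((neg ** 2).sum(axis=-1, keepdims=True) + 1e-8).sqrt()
        uv = v / ((v ** 2).sum(axis=-1, keepdims=True) + 1e-8).sqrt()
        negs = uv @ nv.transpose(1, 0)                        # (M, K)
    else:
        negs = _cosine(v.reshape(v.shape[0], 1, v.shape[1]), neg)  # (M, K)
    logits = concat([pos, negs], axis=1) * (1.0 / temperature)
    # stable log-softmax of the positive logit
    mx = Tensor(logits.data.max(axis=1, keepdims=True))
    z = (logits - mx).exp().sum(axis=1, keepdims=True).log() + mx
    loss = (z.reshape(-1) - logits[:, 0]).mean()
    return loss


def adversarial_loss(D, real, fake, role: str = "discriminator") -> Tensor:
    """Vanilla GAN objective with sigmoid discriminator D.

    role='discriminator': the negated value of E[log D(real)] +
    E[log(1 - D(fake))] (a loss to minimize); the fake branch is detached.
    role='generator': the non-saturating -E[log D(fake)].
    """
    if role == "discriminator":
        d_real = astensor(D(astensor(real))).clip(_EPS, 1.0 - _EPS)
        d_fake = astensor(D(astensor(fake).detach())).clip(_EPS, 1.0 - _EPS)
        return -(d_real.log().mean() + (1.0 - d_fake).log().mean())
    if role == "generator":
        d_fake = astensor(D(astensor(fake))).clip(_EPS, 1.0 - _EPS)
        return -d_fake.log().mean()
    raise ValueError(f"unknown role: {role!r}")


def identity_loss(generator, target_image) -> Tensor:
    """L1 identity penalty: feed a target-domain image through the generator
    and require it unchanged, preserving domain intensity characteristics."""
    y = astensor(target_image)
    gy = astensor(generator(y))
    return (gy - y).abs().mean()


def style_loss(fake, reference, patch: int = 16) -> Tensor:
    """Patchwise first/second-moment matching of local intensity statistics.

    Images are tiled into non-overlapping ``patch`` x ``patch`` cells; the
    loss is the mean absolute difference of per-cell means plus per-cell
    standard deviations.  Zero when local intensity distributions match;
    invariant to permuting pixels within a cell.
    """
    f = astensor(fake)
    r = astensor(reference)
    if f.shape != r.shape:
        raise ValueError("style_loss inputs must share a grid")

    h, w = f.shape[-2], f.shape[-1]
    p = min(patch, h, w)
    hh, ww = (h // p) * p, (w // p) * p

    def moments(t):
        t = t.reshape(-1, h, w)[:, :hh, :ww]
        cells = t.reshape(t.shape[0], hh // p, p, ww // p, p)
        cells = cells.transpose(0, 1, 3, 2, 4).reshape(
            t.shape[0], (hh // p) * (ww // p), p * p)
        mu = cells.mean(axis=-1)
        var = ((cells - mu.reshape(mu.shape[0], mu.shape[1], 1)) ** 2).mean(axis=-1)
        return mu, (var + 1e-12).sqrt()

    mf, sf = moments(f)
    mr, sr = moments(r)
    return (mf - mr).abs().mean() + (sf - sr).abs().mean()


def cycle_loss(G, H, x, y) -> Tensor:
    """L1 cycle-consistency H(G(x)) ~ x plus G(H(y)) ~ y.  Not part of the
    default objective (cycle breaking); exposed for the ablation that adds
    it back."""
    x, y = astensor(x), astensor(y)
    return (astensor(H(G(x))) - x).abs().mean() + (astensor(G(H(y))) - y).abs().mean()


def _structure_loss(D, real_image, fake_image, region, edge_op,
                    role: str, fake_edges=None) -> Tensor:
    if np.asarray(region).sum() == 0:
        warnings.warn("empty structure mask: structure loss is 0")
        return Tensor(np.asarray(0.0))
    real_np = astensor(real_image).data
    region = np.asarray(region, dtype=real_np.dtype if real_np.dtype.kind == "f" else float)
    real_masked = masked_edges(edge_op(np.squeeze(real_np)), region).astype(region.dtype)
    if fake_edges is None:
        fake_edges = edge_op(np.squeeze(astensor(fake_image).data)).astype(region.dtype)
    fk = astensor(fake_edges)
    sq = np.squeeze(fk.data).shape
    fake_masked = astensor(region) * (fk.reshape(sq) + 1.0) - 1.0

    def as4(t):
        t = astensor(t)
        return t.reshape(1, 1, t.shape[-2], t.shape[-1])

    return adversarial_loss(D, as4(real_masked), as4(fake_masked), role=role)


def structure_loss_prostate(DP, mr_image, fake_trus, cp, edge_op,
                            role: str = "discriminator", fake_edges=None) -> Tensor:
    """Edge-adversarial prostate constraint: 'real' masked edges cp*S(x) come
    from the input MR image, 'fake' from the synthesized TRUS G(x) — the
    prostate structure must survive translation."""
    return _structure_loss(DP, mr_image, fake_trus, cp, edge_op, role, fake_edges)


def structure_loss_rectum(DR, trus_image, fake_trus, cr, edge_op,
                          role: str = "discriminator", fake_edges=None) -> Tensor:
    """Edge-adversarial rectum constraint: 'real' masked edges cr*S(y) come
    from an (unpaired) real TRUS image — the rectum must look TRUS-deformed."""
    return _structure_loss(DR, trus_image, fake_trus, cr, edge_op, role, fake_edges)


def _weighted(terms: dict, pairs) -> Tensor:
    total = astensor(0.0)
    for key, w in pairs:
        total = total + astensor(terms[key]) * w
    return total


def total_loss_H(terms: dict, weights: LossWeights | None = None) -> Tensor:
    """l1*Ladv + l2*Lnce + l3*Lidt for the TRUS->MR generator H."""
    w = weights or LossWeights()
    return _weighted(terms, [("adv", w.lambda1), ("nce", w.lambda2), ("idt", w.lambda3)])


def total_loss_G(terms: dict, weights: LossWeights | None = None) -> Tensor:
    """l4*Ladv + l5*Lnce + l6*Lidt + l7*(Lp + Lr) for the MR->TRUS generator G."""
    w = weights or LossWeights()
    total = _weighted(terms, [("adv", w.lambda4), ("nce", w.lambda5), ("idt", w.lambda6)])
    return total + (astensor(terms["lp"]) + astensor(terms["lr"])) * w.lambda7
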
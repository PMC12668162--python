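"""Translation networks: the paired resnet generators G (MR->TRUS) and
H (TRUS->MR), patch discriminators for the domain and masked-edge losses,
the patch-contrastive (NCE) sampling machinery, and intensity-aware
cross-domain feature normalization.

Intensity-aware normalization re-standardizes the source-domain bottleneck
features to the per-channel mean/std of the target domain,

    Norm(x) = sigma(y) * (x - mu(x)) / sigma(x) + mu(y),

so that anatomically similar structures from the two modalities land close
together in the latent space despite their very different intensity
responses.  The reverse branch is the same operation with the roles swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, astensor

__all__ = [
    "GeneratorConfig", "FeatureStack", "ResnetGenerator", "PatchDiscriminator",
    "EdgeDiscriminator", "ProjectionHead", "TranslationModel",
    "intensity_normalize", "channel_stats", "sample_patch_features",
]


@dataclass
class GeneratorConfig:
    """Architecture of G and H (shared): a 7x7 stem, ``n_down`` stride-2
    encoder convolutions, ``n_res`` residual blocks at the bottleneck and a
    mirrored nearest-neighbour-upsampling decoder with a tanh head."""

    n_down: int = 3
    n_res: int = 9
    base_channels: int = 64
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if self.n_res < 1:
            raise ValueError("n_res must be >= 1")
        if self.n_down < 1:
            raise ValueError("n_down must be >= 1")


@dataclass
class FeatureStack:
    """Ordered per-layer activations captured from a generator encoder."""

    layers: list

    def __len__(self):
        return len(self.layers)


# ---------------------------------------------------------------------------
# Intensity-aware normalization
# ---------------------------------------------------------------------------

def channel_stats(feat, eps: float = 1e-8):
    """Per-channel mean and std of a feature map.

    Accepts (C, ...) or (N, C, H, W) tensors/arrays; statistics are taken
    over every axis except the channel axis (axis 0 for <=3-D, axis 1 for
    4-D).  Returns (mu, sigma) shaped for broadcasting against the input.
    """
    t = astensor(feat)
    ch_axis = 1 if t.ndim == 4 else 0
    axes = tuple(a for a in range(t.ndim) if a != ch_axis)
    mu = t.mean(axis=axes, keepdims=True)
    var = ((t - mu) ** 2).mean(axis=axes, keepdims=True)
    sigma = (var + eps).sqrt()
    return mu, sigma


def intensity_normalize(x_feat, y_feat, eps: float = 1e-8):
    """Align ``x_feat`` to the per-channel intensity statistics of ``y_feat``.

    Output moments equal (mu(y), sigma(y)) per channel up to the eps guard.
    The operation is its own fixed point when the statistics already match,
    and swapping the arguments gives the reverse-branch normalization.
    Gradients flow through ``x_feat`` only; the target statistics act as a
    reference distribution.
    """
    x = astensor(x_feat)
    mu_x, sd_x = channel_stats(x, eps)
    with nn.no_grad():
        mu_y, sd_y = channel_stats(astensor(y_feat).detach(), eps)
    out = (x - mu_x) / sd_x * sd_y.data + mu_y.data
    return out if isinstance(x_feat, Tensor) else out.data


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

class ResnetGenerator(nn.Module):
    """Resnet encoder-decoder with reflection padding and a tanh output head.

    ``forward`` optionally captures encoder feature taps (stem + each
    downsampling stage) for the NCE module, and optionally applies
    intensity-aware normalization at the bottleneck against reference
    statistics of the opposite domain.
    """

    def __init__(self, config: GeneratorConfig, rng):
        super().__init__()
        self.config = config
        c = config.base_channels
        self.stem = nn.Sequential(
            nn.ReflectionPad2d(3),
            nn.Conv2d(config.in_channels, c, 7, rng=rng),
            nn.InstanceNorm2d(c), nn.ReLU())
        downs = []
        for i in range(config.n_down):
            downs.append(nn.Sequential(
                nn.Conv2d(c * 2 ** i, c * 2 ** (i + 1), 3, stride=2, padding=1, rng=rng),
                nn.InstanceNorm2d(c * 2 ** (i + 1)), nn.ReLU()))
        self.downs = nn.Sequential(*downs)
        cb = c * 2 ** config.n_down
        self.resblocks = nn.Sequential(*[nn.ResnetBlock(cb, rng) for _ in range(config.n_res)])
        ups = []
        for i in range(config.n_down, 0, -1):
            ups.append(nn.Sequential(
                nn.Upsample2d(2),
                nn.Conv2d(c * 2 ** i, c * 2 ** (i - 1), 3, padding=1,
                          pad_mode="reflect", rng=rng),
                nn.InstanceNorm2d(c * 2 ** (i - 1)), nn.ReLU()))
        self.ups = nn.Sequential(*ups)
        self.head = nn.Sequential(
            nn.ReflectionPad2d(3),
            nn.Conv2d(c, config.out_channels, 7, rng=rng),
            nn.Tanh())

    def _check(self, x: Tensor):
        h, w = x.shape[2], x.shape[3]
        div = 2 ** self.config.n_down
        if h % div or w % div:
            raise ValueError(f"spatial size {h}x{w} not divisible by {div}")

    def encode(self, x, return_taps: bool = False):
        x = astensor(x)
        self._check(x)
        taps = []
        h = self.stem(x)
        taps.append(h)
        for d in self.downs.layers:
            h = d(h)
            taps.append(h)
        if return_taps:
            return h, FeatureStack(taps)
        return h

    def forward(self, x, ref_stats=None, return_taps: bool = False):
        """Translate; ``ref_stats`` = (mu, sigma) arrays of the opposite
        domain's bottleneck features enables intensity-aware normalization."""
        x = astensor(x)
        got = self.encode(x, return_taps=True)
        h, taps = got
        if ref_stats is not None:
            mu_y, sd_y = ref_stats
            mu_x, sd_x = channel_stats(h)
            h = (h - mu_x) / sd_x * np.asarray(sd_y) + np.asarray(mu_y)
        h = self.resblocks(h)
        h = self.ups(h)
        y = self.head(h)
        if return_taps:
            return y, taps
        return y

    def bottleneck_stats(self, x):
        """Per-channel (mu, sigma) of the encoder bottleneck, detached."""
        with nn.no_grad():
            h = self.encode(astensor(x).detach())
            mu, sd = channel_stats(h)
        return mu.data, sd.data


# ---------------------------------------------------------------------------
# Discriminators
# ---------------------------------------------------------------------------

class PatchDiscriminator(nn.Module):
    """70x70-receptive-field patch discriminator with a sigmoid output map."""

    def __init__(self, in_channels=1, base_channels=64, n_layers=3, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        layers = [nn.Conv2d(in_channels, base_channels, 4, stride=2, padding=1, rng=rng),
                  nn.LeakyReLU(0.2)]
        c = base_channels
        for _ in range(n_layers - 1):
            layers += [nn.Conv2d(c, min(c * 2, base_channels * 8), 4, stride=2,
                                 padding=1, rng=rng),
                       nn.InstanceNorm2d(min(c * 2, base_channels * 8)),
                       nn.LeakyReLU(0.2)]
            c = min(c * 2, base_channels * 8)
        layers += [nn.Conv2d(c, min(c * 2, base_channels * 8), 4, stride=1,
                             padding=1, rng=rng),
                   nn.InstanceNorm2d(min(c * 2, base_channels * 8)),
                   nn.LeakyReLU(0.2),
                   nn.Conv2d(min(c * 2, base_channels * 8), 1, 4, stride=1,
                             padding=1, rng=rng),
                   nn.Sigmoid()]
        self.net = nn.Sequential(*layers)

    def forward(self, x):
        return self.net(astensor(x))


class EdgeDiscriminator(nn.Module):
    """Lighter 4-layer discriminator for the masked edge maps (DP / DR)."""

    def __init__(self, in_channels=1, base_channels=16, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        c = base_channels
        self.net = nn.Sequential(
            nn.Conv2d(in_channels, c, 4, stride=2, padding=1, rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(c, c * 2, 4, stride=2, padding=1, rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(c * 2, c * 4, 4, stride=2, padding=1, rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(c * 4, 1, 4, stride=1, padding=1, rng=rng),
            nn.Sigmoid())

    def forward(self, x):
        return self.net(astensor(x))


# ---------------------------------------------------------------------------
# NCE sampling
# ---------------------------------------------------------------------------

class ProjectionHead(nn.Module):
    """2-layer MLP projecting sampled patch features before the NCE loss."""

    def __init__(self, in_dim, out_dim=64, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.fc1 = nn.Linear(in_dim, out_dim, rng=rng)
        self.fc2 = nn.Linear(out_dim, out_dim, rng=rng)

    def forward(self, x):
        # leaky activation: a dead-ReLU patch would project to the zero
        # vector, which has no direction for the cosine similarity
        return self.fc2(self.fc1(x).leaky_relu(0.2))


def _unit_rows(v: Tensor, eps: float = 1e-8) -> Tensor:
    n = ((v ** 2).sum(axis=-1, keepdims=True) + eps).sqrt()
    return v / n


def sample_patch_features(input_stack: FeatureStack, translated_stack: FeatureStack,
                          n_patches: int, rng, heads=None, n_negatives=None):
    """Draw matched patch-feature samples for the contrastive loss.

    For each tapped layer: ``n_patches`` spatial locations are sampled; the
    anchor v comes from the translated image's features at those locations
    and the positive v+ from the *same* locations of the input's features.
    Negatives are the input's features at *other* (non-anchor) locations —
    all of them by default, or a random subsample of ``n_negatives``.
    Vectors are optionally projected by per-layer MLP heads, then unit
    normalized.  Returns a list of (v, v_plus, negatives) per layer with
    shapes (M, D), (M, D), (K, D); the negative pool is shared by anchors
    and never contains an anchor's own location.
    """
    if len(input_stack) != len(translated_stack):
        raise ValueError("feature stacks tap different layer sets")
    rng = np.random.default_rng(rng)
    out = []
    for li, (fin, ftr) in enumerate(zip(input_stack.layers, translated_stack.layers)):
        fin, ftr = astensor(fin), astensor(ftr)
        if fin.ndim == 4:  # (1, C, H, W) -> (C, H, W)
            fin = fin.reshape(fin.shape[1:])
            ftr = ftr.reshape(ftr.shape[1:])
        c, h, w = fin.shape
        n_loc = h * w
        if n_patches > n_loc:
            raise ValueError(f"n_patches={n_patches} exceeds {n_loc} locations")
        # cap anchors at half the grid so a negative pool always remains
        m = min(n_patches, max(1, n_loc // 2))
        perm = rng.permutation(n_loc)
        idx = perm[:m]
        others = perm[m:]
        if n_negatives is not None and len(others) > n_negatives:
            others = others[:n_negatives]
        fin_flat = fin.reshape(c, n_loc)
        v = ftr.reshape(c, n_loc).index_select(1, idx).transpose(1, 0)
        vp = fin_flat.index_select(1, idx).transpose(1, 0)
        vn = fin_flat.index_select(1, others).transpose(1, 0)
        if heads is not None:
            v = heads[li](v)
            vp = heads[li](vp)
            vn = heads[li](vn)
        out.append((_unit_rows(v), _unit_rows(vp), _unit_rows(vn)))
    return out


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class TranslationModel:
    """All trainable parts of the framework.

    G: MR->TRUS, H: TRUS->MR (identical architectures); one domain
    discriminator per direction; DP/DR judge masked prostate/rectum edge
    maps; per-tap-layer NCE projection heads for each generator.
    """

    config: GeneratorConfig
    G: ResnetGenerator
    H: ResnetGenerator
    D_trus: PatchDiscriminator
    D_mr: PatchDiscriminator
    DP: EdgeDiscriminator
    DR: EdgeDiscriminator
    heads_G: list
    heads_H: list

    @classmethod
    def create(cls, config: GeneratorConfig, seed: int = 0,
               disc_channels: int = 64, nce_dim: int = 64) -> "TranslationModel":
        rng = np.random.default_rng(seed)
        G = ResnetGenerator(config, rng)
        H = ResnetGenerator(config, rng)
        D_trus = PatchDiscriminator(1, disc_channels, rng=rng)
        D_mr = PatchDiscriminator(1, disc_channels, rng=rng)
        DP = EdgeDiscriminator(1, max(8, disc_channels // 4), rng=rng)
        DR = EdgeDiscriminator(1, max(8, disc_channels // 4), rng=rng)
        tap_dims = [config.base_channels * 2 ** i for i in range(config.n_down + 1)]
        heads_G = [ProjectionHead(d, nce_dim, rng=rng) for d in tap_dims]
        heads_H = [ProjectionHead(d, nce_dim, rng=rng) for d in tap_dims]
        return cls(config, G, H, D_trus, D_mr, DP, DR, heads_G, heads_H)

    def modules(self) -> dict:
        mods = {"G": self.G, "H": self.H, "D_trus": self.D_trus,
                "D_mr": self.D_mr, "DP": self.DP, "DR": self.DR}
        for i, h in enumerate(self.heads_G):
            mods[f"heads_G.{i}"] = h
        for i, h in enumerate(self.heads_H):
            mods[f"heads_H.{i}"] = h
        return mods

    def parameters(self):
        for m in self.modules().values():
            yield from m.parameters()

    def state_dict(self) -> dict:
        out = {}
        for name, m in self.modules().items():
            for k, v in m.state_dict().items():
                out[f"{name}:{k}"] = v
        return out

    def load_state_dict(self, state: dict):
        for name, m in self.modules().items():
            sub = {k.split(":", 1)[1]: v for k, v in state.items()
                   if k.startswith(name + ":")}
            m.load_state_dict(sub)
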
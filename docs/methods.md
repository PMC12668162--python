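# Methods

## Problem and model

The package translates MR prostate images into TRUS-like images under an
unpaired training regime, with the explicit goal that the synthetic image be
(a) in the TRUS intensity distribution and (b) anatomically faithful where
it matters clinically — the prostate (target) and the rectum (organ at risk,
and the structure most deformed by the endorectal probe).

Two resnet generators G (MR→TRUS) and H (TRUS→MR) share one architecture:
a 7×7 reflection-padded stem, three stride-2 downsampling convolutions, a
stack of residual blocks at the bottleneck, a mirrored decoder
(nearest-neighbour ×2 upsampling followed by a 3×3 convolution, which avoids
checkerboard artifacts of strided transposed convolutions) and a tanh head;
instance normalization throughout, non-affine. Domain realism comes from
one sigmoid patch discriminator per direction (4×4 convolutions, 70×70
receptive field). Cycle consistency is deliberately absent: a cycle L1 term
would penalize exactly the probe-induced deformation the method must be free
to synthesize ("cycle breaking"). It can be re-enabled as an ablation.

### Patch-contrastive consistency

Content preservation is enforced by noise-contrastive estimation over
encoder features. Four taps (stem + each downsampling stage) are sampled at
shared random locations in the input's and the translated image's feature
stacks; a 2-layer MLP head per tap projects the vectors, which are then unit
normalized. For an anchor v (translated image) the positive v⁺ is the input
feature at the same location; negatives are input features at other
locations. The loss is the softmax cross-entropy over raw exponentiated
cosine similarities (no temperature divisor by default; one is available).
Per layer, the number of anchors is capped at half the available locations
so a negative pool always remains; the pool is optionally subsampled
(default cap 128) for cost. Projection layers carry small random biases so
that an all-zero feature patch cannot project to the exact zero vector,
which has no direction under cosine similarity.

### ROI-guided structure losses

An image-independent soft mask c₀ is the voxelwise average of pre-annotated
organ label maps (prostate ∪ rectum), with binary sub-masks c_p, c_r from
the per-organ means thresholded at 0.5. Because c₀ is an average anatomy,
it is re-perturbed at every iteration by a random elastic deformation:
i.i.d. N(0, α) displacements on a 3×3 lattice, bicubically upsampled and
smoothed with a Gaussian of σ = 20 px. α = 7 px by default — the largest
amplitude for which the perturbed mask's support area stays within ±30% of
c₀'s across the 100-draw contract the tests enforce, keeping the
perturbation a regularizer rather than a destroyer of the prior.

Edge maps are extracted with either filter behind one interface: Sobel
(gradient magnitude rescaled to [−1, 1]) or, by default, Canny — images
rescaled to [0, 255], high hysteresis threshold 300 in unnormalized
3×3-Sobel gradient units (the convention skimage shares with OpenCV), low
threshold = high/2, output in {−1, +1}. The Canny pre-smoothing sigma is
1.2: a unit sigma produces non-maximum-suppression ties (doubled edges) on
perfectly symmetric steps. Masking an edge map e by a region m is the
product in the non-negative representation, m·(e+1) − 1, so that excluded
pixels take the background value −1.

The prostate loss L_p is a GAN objective whose "real" examples are
c_p-masked edges of the **MR input** (the prostate must survive translation)
and whose "fake" examples are masked edges of G(x); the rectum loss L_r
draws its "real" edges from an unpaired **real TRUS** image (the rectum must
look probe-deformed). Both use light 4-layer edge discriminators. Canny is
not differentiable, so on the generator side the edge map is a
differentiable Sobel magnitude (fixed-kernel convolution, normalized by its
detached maximum) gated by the binary Canny support of the image values:
gradients act on intensities along detected edges. Empty masks return a
zero loss with a warning.

### Intensity-aware normalization

At the generator bottleneck the source features are re-standardized per
channel to the opposite domain's statistics, Norm(x) = σ(y)(x−μ(x))/σ(x) +
μ(y) (and symmetrically for the reverse branch). During training the
reference statistics come from the same generator's encoder pass over the
current opposite-domain sample (the identity pass provides it at no extra
cost); an exponential running average (momentum 0.1) is stored and used at
inference. Statistics are per-channel; the variance guard ε = 1e−8 keeps
the operation within 1e−5 of an exact moment match and idempotent at the
same tolerance. Whether μ, σ should be per-channel or global scalars is an
open modeling choice; per-channel is implemented as the stronger and more
standard (AdaIN-like) variant.

### Objectives and optimization

L_H = λ₁L_adv + λ₂L_NCE + λ₃L_idt and
L_G = λ₄L_adv + λ₅L_NCE + λ₆L_idt + λ₇(L_p + L_r), with defaults λ₁ = 0.5,
λ₂ = λ₃ = 0.25, λ₄ = 0.5, λ₅ = λ₆ = 0.25, λ₇ = 0.01. The adversarial form
is the vanilla log loss with ε-clamped discriminator outputs and the
non-saturating generator branch. The identity loss is the L1 distance of a
target-domain image through the generator. A style term — mean absolute
difference of per-cell (16×16) means and standard deviations — refines local
intensity statistics; it is on by default with its own weight (0.1) so that
disabling it is a meaningful ablation, rather than folding it into the
identity weight. The optional cycle term (weight 10) exists only for the
"w/o cycle breaking" ablation.

Optimization is Adam (lr 2e−4, β = (0.5, 0.999)) with separate optimizers
for the generator side (G, H, NCE heads) and the discriminators; per
iteration, one unpaired MR/TRUS slice pair per batch element (batch 2), a
fresh ROI perturbation, discriminator updates first (with a 50-image pool
of past fakes), then a joint generator update. A non-finite loss term
aborts training naming the offending term. Training is bit-reproducible
from the seed; checkpoints store weights, optimizer moments, RNG state and
the image pools, so save→load→step equals an uninterrupted step exactly.

## Synthetic phantom

The phantom emulates the clinical data-generating process at desk scale:
a 2-D pelvic anatomy (prostate ellipse with embedded urethra and optional
lesion; rectum disc adjacent to the inferior border), rendered as a thin
axial NIfTI stack. MR-like rendering: high-contrast piecewise-constant
tissue table, mild blur and additive noise (σ = 0.02), values in [−1, 1].
TRUS-like rendering: the label map is first warped by a probe-insertion
field — a Gaussian-windowed anterior push centered on the rectum, peak
amplitude 6 px (at 128 px), decay length size/6, tapered to zero at the
border — then rendered with a compressed low-contrast table, multiplicative
log-normal speckle (σ = 0.25) blurred as a first-order ultrasound texture
model, and a 120° fan-shaped field of view (outside = −1). Training
cohorts draw distinct anatomies per domain (unpaired); evaluation cases pair
an undeformed MR with the deformed TRUS of the same anatomy and store the
true field. All geometry jitters are low-variance by construction, so the
averaged ROI mask covers every member's prostate.

What the phantom does **not** model: acoustic physics (shadowing,
attenuation, refraction), 3-D probe kinematics, patient-realistic anatomy
statistics, multi-institution intensity heterogeneity. Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline — not clinical-grade translation quality; the near-perfect Dice
and TRE numbers on the phantom reflect its low variance.

## Preprocessing and registration

Volumes carry a grid-to-world affine; the chain is resample (linear, world
extent preserved within a voxel; the clinical recipe is 0.3×0.3×1 mm),
rigid alignment to a modality template, center crop/pad (clinical size
296×296×34; background −1), min/max intensity scaling onto exactly [−1, 1]
(a constant image maps to zeros with a warning), and axial slice
extraction. Rigid registration is in-plane: an FFT cross-correlation
coarse translation search initializes multi-start Powell refinement over
(θ, t_row, t_col) under normalized cross-correlation (within modality) or
histogram mutual information (across); the result is never worse than the
identity transform. Volumes are registered on their mean axial projection
and transformed slice-wise. Contours transfer with nearest-neighbour
interpolation.

## Evaluation

PSNR (10·log₁₀(range²/MSE), 99 dB cap on identical inputs, data range 2 for
[−1, 1] images), SSIM (11×11 Gaussian window, σ 1.5, k₁ = 0.01, k₂ = 0.03),
masked-pixel ROI-PSNR, ROI-SSIM on the tight mask bounding box, zero-mean
NCC, and a Fréchet distance ‖μ_A−μ_B‖² + tr(Σ_A+Σ_B−2(Σ_AΣ_B)^{1/2}) over a
pluggable embedding — by default a fixed-seed random-convolution network
with global average pooling, so no pretrained weights are needed and any
external extractor can be hooked in. Registration quality: Dice
200|A∩B|/(|A|+|B|) of the transferred prostate contour (both masks empty is
defined as 100, with a warning) and centroid TRE in millimetres using voxel
spacing. Cohort evaluation reports per-case rows and mean ± sd, per volume
(a per-slice flag would be a small extension); a paired t-test utility
compares metric columns.

## Problem sizes and numerical choices

The tested smoke configuration is deliberately desk-scale: 64 px slices,
base 8 channels, 4 residual blocks, 200 iterations, batch 2, 64 NCE anchors
with a 128-negative cap — chosen so the full seeded study (five training
seeds plus the threshold sweep and registration trials) runs on a single
CPU in minutes. The architecture defaults (base 64, 9 residual blocks)
match the full-scale method; nothing in the code depends on the smoke
sizes. Training arrays are float32; closed-form and gradient tests run in
float64. Shift-equivariance of the generator holds exactly only while a
pattern's bottleneck footprint stays a receptive field away from the
padding-induced border frame, which does not translate with the content —
the property test uses a 192 px canvas for that reason. Degenerate inputs
are defined, not fatal: constant images scale to zeros, empty ROI masks
contribute zero loss, σ → 0 feature channels are ε-guarded, and a singular
covariance in the Fréchet distance is ε-regularized.

## Known limitations

The NumPy engine is single-threaded per operation and desk-scale only; no
GPU path. Rigid registration is in-plane (adequate for the phantom's
geometry; clinical volumes may need full 3-D rigid search). The Fréchet
embedding is not Inception — absolute values are not comparable to
published FID numbers, only relative ones within a run. The style loss is
a first/second-moment surrogate for local histogram matching.
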
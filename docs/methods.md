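# Methods

This note documents the models, conventions and tunable parameters of the
`vstain` pipeline, the assumptions behind its synthetic fixtures, and the
design choices made where more than one reasonable option existed.

## Problem setting

H&E and Masson's-Trichrome slides of the same specimen come from
*consecutive* tissue sections: the same anatomy appears in both, but
offset by a global rigid motion (placement, scanning) and distorted by a
smooth local warp (sectioning, stretching, folds), with staining
intensity varying from slide to slide. A supervised stain-translation
model needs co-located patch pairs, so the pipeline aligns, gates and
normalizes pairs before training, while the translation model itself
requires no alignment at inference time.

## Tiling

Slides are downsampled to ≤1024 px thumbnails with anti-aliased
(area-averaging) interpolation, chosen so the intensity histogram — and
hence the Otsu threshold — survives downsampling. Grayscale is the
ITU-R 601 luma weighting. The blur before thresholding uses σ = 2 px at
thumbnail scale (enough to suppress stain speckle without eroding tissue
boundaries). Otsu's threshold is computed by exhaustive scan of all 256
candidates, minimizing the within-class variance ω₁σ₁² + ω₂σ₂²; a
constant image is flagged degenerate (empty mask) rather than raising.
Coordinates are 0-based with x rightwards and y downwards; patch windows
are half-open `[x, x+S)`.

The patch grid is anchored on the ROI-bounding-box center: with patch
size S, overlap O (default 32 px) and box width w, there are
`N = ⌊(w−O)/(S−O)⌋` patches per side, centered at
`x_c + i(S−O)` for the N integers i centered on zero. The stored
coordinates are top-left corners (center − S/2); this is the only
convention under which a bounding box of exactly one patch width yields a
single *centered* patch. Thumbnail-space coordinates are mapped to full
resolution by dividing by the scale factor and rounding to the nearest
integer, and windows leaving either raster are dropped and counted.

## Registration cascade

**Stage 1 — slide gating (SIFT).** Keypoints and 128-d descriptors on the
grayscale thumbnails, brute-force nearest-2 matching under Euclidean
distance, Lowe's ratio test at 0.75 (ties, ratio 1, are rejected at any
threshold below 1). A pair proceeds only if surviving matches exceed 10%
of the smaller keypoint count. Both constants are conventional values;
the gate threshold is deliberately permissive because its purpose is to
reject *unrelated* slides, not to measure alignment quality. The SIFT
pyramid starts at native resolution (no 2× upsampling) — thumbnails are
already band-limited and slide gating does not need sub-pixel keypoints.

**Stage 2 — projective alignment (RANSAC homography).** 2000 iterations
of 4-point hypotheses (seeded generator), 3 px inlier residual, final
least-squares refit (normalized DLT) on the consensus set. With noiseless
correspondences this recovers H to ~1e−13 elementwise. At patch scale the
same machinery runs on ORB keypoints (256-bit binary descriptors, Hamming
distance); if fewer than 4 matches survive, the FAST threshold is relaxed
once, and failing that the patch is flagged and passed to FFD without a
homography.

**Stage 3 — free-form deformation.** A B-spline displacement field
(cubic, 8×8 control points by default → a 5×5 ITK mesh) is optimized
against Mattes mutual information (50 bins) with regular-step gradient
descent: initial step η = 2 px, relaxation 0.5 (step-halving whenever the
objective worsens), up to 200 iterations. The printed objective is a
similarity, so the optimizer minimizes its negative; the recorded trace
stores the similarity (higher = better). With dense metric evaluation the
fit is fully deterministic; the cascade default uses a seeded 30% pixel
sample for a ~4× speedup at equal landmark accuracy (deterministic given
the seed). The moving image is the H&E side — it is the image we are
willing to deform, since the MT side is the ground truth being predicted
— and registration runs on grayscale intensity, the common practice for
MI metrics. The Cox–de Boor recursion and a histogram MI are implemented
in-package as the reference formulations (validated against
`scipy.interpolate.BSpline` and closed-form joint distributions); the
optimization backend is SimpleITK.

Landmark errors are reported in the moving (H&E) frame: a fixed-frame
landmark is mapped through the FFD and then the inverse homography, and
compared with the true H&E landmark. On fixtures with shifts ≤ 30 px and
warps ≤ 8 px the cascade reduces the error monotonically per stage and
typically ends below 1 px.

## Patch quality control

Four rules in fixed order — empty, MI, cosine, pHash — with boundary
values inclusive on the keep side and the rejection reason defined as the
first failing rule:

| rule   | statistic                                   | default gate |
|--------|---------------------------------------------|--------------|
| empty  | fraction of pixels ≤ 10 or ≥ 245 (8-bit gray), worst of the two stains | ≤ 0.30 |
| mi     | plug-in histogram MI, 64 bins, log base 2   | ≥ 0.35 |
| cosine | cosine of flattened grayscale vectors       | ≥ 0.75 |
| pHash  | Hamming distance of 64-bit DCT hashes (32×32 resize, top-left 8×8 block, median sign) | ≤ 20 |

The black/white cutoffs (10/245) define "empty" pixels on 8-bit
grayscale. The MI gate value is calibrated for the base-2/64-bin
convention; both are recorded in every metadata record so the gate is
auditable. Because the cosine of two nonnegative image vectors is
dominated by their DC components, the cosine gate mostly detects gross
content mismatch, while MI detects statistical independence and pHash
structural disagreement — the rules are complementary, which is what the
defect-injection tests exercise.

## Reinhard normalization

The 8-bit-scaled LAB dialect is used (channels notionally stored as
bytes; the rescaling L/2.55, A−128, B−128 recovers L∈[0,100],
A,B∈[−128,127], which coincide with standard D65 CIELAB). Statistics are
per-channel mean and *population* standard deviation (divide by N);
consistency between source and target matters more than the convention
itself. The transfer is the per-channel affine map onto the target's
mean/σ, clipped to the valid LAB ranges before inverse conversion; a
source with a constant channel is passed through with a warning. The
alpha channel of RGBA tiles is untouched.

Caveats made explicit by the tests: the transfer is exact in LAB, but
the RGB export additionally (a) gamut-maps chroma that sRGB cannot
represent and (b) rounds to 8 bits. On channels with small σ (≈4 LAB
units) the rounding alone can move σ by >5%, so the statistics contract
is validated on the LAB output, while the RGB path is covered by the
identity-transfer bound (≤2 levels) and a same-stain tile test. The
reference tile defining the target statistics is a per-run configuration
choice and is logged next to the outputs.

## Stain-translation GAN

The generator embeds non-overlapping 8×8 patches of the H×W×C tile
(`N = HW/64` tokens; 1024 for 256², 4096 for 512², 16384 for 1024²) with
a learned projection plus learned positional embeddings, runs a pre-norm
transformer encoder, reshapes the tokens to a √N×√N feature map and
decodes with log₂P = 3 stride-2 transposed convolutions ending in tanh
(pixels live in [−1,1]). The discriminator is a 3-stage strided CNN with
LeakyReLU and instance normalization, ending in a sigmoid patch map.

Architecture constants not fixed by the training recipe: embedding
D = 256, 6 layers, 8 heads, FFN hidden 4D for the full profile; the smoke
profile used throughout the tests is 32×32 tiles, D = 64, 2 layers, 4
heads. Attention scales per head by 1/√(D/h) — the self-consistent
multi-head reading of the 1/√D softmax scale — with a flag restoring the
literal global scale. The decoder is the minimal stride-2 chain (no skip
connections); RGBA input passes the alpha channel through the embedding
as a fourth channel and discards generated alpha at export.

Losses: non-saturating adversarial terms (−log D(G(·)); the saturating
minimax form is available behind a flag), L1 cycle-consistency, and L1
identity, combined as
`total = adv_A + adv_B + λ_cycle(cyc_A + cyc_B) + λ_id(id_A + id_B)`.
The four study configurations are labelled `<O|R>/<λ_cycle>/<λ_identity>`
with λ pairs exactly (10,3) and (3,10); O trains on original tiles, R on
Reinhard-normalized tiles. Optimization is Adam at lr 1e−5, β = (0.5,
0.999), batch size 1 with gradient accumulation over 8 virtual batches;
up to 200 epochs with early stopping on a validation-loss plateau
(patience 10). The smoke profile raises the learning rate to 1e−3 and
accumulates over 2 steps so that 50-step runs show measurable progress.

The networks run on an in-package reverse-mode autodiff engine over
float64 numpy arrays (gradients of every primitive are finite-difference
checked in development). This makes seeded training runs bit-identical —
a property the test suite asserts — at the cost of throughput; the smoke
profile trains ~6 steps/second on one CPU. Checkpoints are .npz weight
archives with a JSON manifest (config label, hyperparameters, seed).

## Fusion

Pixelwise weighted sum of the four configuration outputs, accumulated in
floating point and quantized once at the end (round-half-even). Default
weights are fixed at 0.25 each; non-uniform weights are accepted for
weight-search experiments. The output is a convex combination, hence
bounded by the per-pixel min/max of the inputs pre-quantization and
within one level post-quantization.

## Evaluation

All metrics act on 8-bit grayscale renderings of equal-shape images;
histogram metrics use normalized 256-bin histograms. Conventions chosen
where the literature varies: NMI = MI/(H(X)+H(Y)) (range [0, 0.5]); SSIM
uses C₁=(0.01·255)², C₂=(0.03·255)², an 11×11 Gaussian window σ=1.5; UQI
uses an 8×8 sliding window; EMD is the closed-form 1-D transport distance
(L1 of histogram CDFs); JSD/KLD are base-2 with ε-smoothing for empty
bins; GMSD uses Prewitt gradients, c=170, at half scale; HD and BhD are
Hellinger and Bhattacharyya distances on the 256-bin histograms; PC is
the correlation of minimal log-Gabor phase-congruency maps (3 scales, 4
orientations); NQM is implemented as the CSF-weighted SNR core of the
noise-quality measure, without the full multi-band contrast-masking
model (documented in its docstring). BRISQUE requires a model pretrained
on natural-scene statistics and is delegated to an external scorer when
one is supplied; FBS and SRS have no established definitions and are
excluded from default reports.

Trial aggregation reports mean ± sample std (ddof = 1; zero for a single
trial) with a direction column. The statistics harness runs a one-way
repeated-measures ANOVA (error df = (k−1)(n−1); 92 for five approaches ×
24 trials), Tukey HSD over the pooled long-format data plus
Bonferroni-adjusted paired confidence intervals for fused-vs-individual
differences, paired Wilcoxon signed-rank tests (alternative configurable;
all-zero difference vectors are flagged degenerate), paired Cohen's d
(mean difference over SD of differences; 0 when the differences have no
spread), and Shapiro–Wilk plus Anderson–Darling normality screens. When
the ANOVA is degenerate (identical configurations), the harness falls
back to the plain sums-of-squares formula with the 0/0 → 0 convention.

## Synthetic fixtures

The generator renders one tissue geometry twice. Tissue is a union of
random ellipses textured with multi-octave value noise (smooth random
grids upsampled cubically) — deliberately rich in corners so SIFT and ORB
find keypoints; flat cartoons would starve both detectors. A noise-field
quantile designates a collagen fraction (default 0.35, a mid-range
fibrotic burden); another marks nuclei. The H&E palette is pink
cytoplasm / pale-pink collagen / blue-purple nuclei; the MT palette is
red cells / pale-blue collagen / dark nuclei. The brightness ordering
(collagen > cytoplasm > nuclei) is kept consistent across stains, as in
real sections where collagen stains palest — this is what makes
cross-stain grayscale matching and perceptual hashing meaningful.

The MT image is resampled through a known backward map
`G(y) = R(−θ)(y − shift − c) + c + d(y)`: the ground truth a registration
cascade must recover. `d` is a smooth field interpolated from a coarse
control grid and scaled to a peak amplitude (default 6 px; capped at 10%
of the slide side, beyond which local warps alias against the control
spacing). Landmarks are blob centroids plus extra interior points (≥16),
mapped by numerically inverting G by fixed-point iteration (sub-0.01 px
at the permitted deformations). Defaults — 384² slides, shift (18,−10),
rotation 3°, jitter ×[0.9,1.1], artifact fraction 1% — represent a
realistically misaligned consecutive-section pair at desk scale.
Artifacts are white blank rectangles plus one dark fold band restricted
to tissue (bare glass stays bright); their masks are retained so that QC
fixture patches can avoid them (a labelled defect must be the *only*
violation in its patch).

Injected QC defects are constructed to violate exactly their own rule:
`empty_heavy` paints the same 40% region white on both stains (similarity
scores survive); `decorrelated` replaces the MT side with an oscillating
remap of the quantized H&E intensities — an exact function of the 64-bin
gray value, so MI stays at the entropy of the bright/dark split, with
bright mass capped at 35% and interleaved across the intensity range so
the flattened-vector cosine falls well below 0.75; `hash_distant` is a
photometric inversion — MI is invariant under the bijection and mid-tone
cosine stays high, but the DCT hash bits flip. The oscillating remap can
also perturb the perceptual hash; since pHash is evaluated after cosine
in the fixed rule order, the recorded rejection reason is unaffected.

What the fixtures do *not* model: photorealistic histology, scanner
optics, true out-of-plane section differences (the two "sections" share
identical geometry by construction), stain co-localization noise, and
fine nuclear morphology. Passing tests therefore demonstrate that each
algorithmic stage meets its contract on controlled inputs — not that the
trained smoke-scale GAN produces diagnostic-quality virtual stains.

## Problem sizes

The test suite and the acceptance script run entirely at desk scale:
384² fixture slides, 20 registration fixtures, 400 QC patches, 96² (or
smaller) tiles for normalization, and 50-step GAN runs on 32² tiles with
the smoke architecture. These sizes were chosen so the full suite
completes in minutes on a single CPU while still exercising every code
path of the full-scale profile.

## Known limitations

- The FFD wrapper exposes the fitted control-point displacements but the
  optimization itself is delegated to SimpleITK; swapping in a pure-python
  optimizer would be needed to trace per-control-point updates.
- The GAN's numpy backend is single-threaded float64; the full 256²/200-
  epoch profile is defined and validated for shape/loss identities but is
  not practical to train without a accelerated backend.
- Reinhard transfer onto statistics far from the source's gamut compresses
  chroma at RGB export (see above); stain-vector methods (Macenko,
  Vahadane) would be the next step and are out of scope.
- The slide-acceptance match threshold (0.10) is an empirical default;
  slides with very little texture may need it lowered.
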
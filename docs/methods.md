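# Methods

`drseg` implements a domain-randomisation strategy for training 3D
segmentation networks without any acquired images: training data are
synthesised on the fly from anatomical label maps by a generative model whose
parameters — contrast, deformation, bias, resolution — are redrawn from wide
uniform priors at every example. Because real scans of any modality or
resolution lie inside the support of such a randomised generator, a network
trained this way segments unseen contrasts and resolutions without
retraining. This note records the model, its assumptions, the defaults, and
the numerical choices.

## Generative model

Given a corpus of integer label maps sharing one labelling convention at an
isotropic working resolution `r_hr` (default 1 mm), each draw proceeds:

1. **Corpus selection and label-level augmentation.** A map is selected
   uniformly. With probability 0.5 it is mirrored along the left–right axis
   with lateral label pairs swapped; it may be cropped to a configured shape
   at a uniform offset; with probability 0.5 all extra-cerebral labels are
   reset to background (emulating skull-stripped inputs); with probability
   0.5 one binary lesion mask, drawn uniformly from a supplied list, is
   pasted at a uniform offset, overwriting only host-tissue voxels. Drop and
   paste are independent events.
2. **Spatial deformation.** A random affine — rotations U(−15°, 15°) per
   axis, scalings U(0.85, 1.15), shearings U(−0.012, 0.012), translations
   U(−10, 10) voxels, composed as `T(c)·T(t)·Rz·Ry·Rx·Shear·Scale·T(−c)`
   about the volume centre `c` — is combined with a diffeomorphic warp: a
   10×10×10×3 field ~ N(0, σ²) with σ ~ U(0, b_nonlin) (default 3 voxels) is
   trilinearly upsampled (centre-aligned, edge-clamped) to the image grid and
   exponentiated by scaling-and-squaring with 7 steps. Labels are pulled back
   through `x ↦ A(x + d(x))` in a single nearest-neighbour pass;
   out-of-field samples become background.
3. **Contrast synthesis.** Each label receives μ ~ U(0, 255) and
   σ ~ U(0, 35), and voxel intensities are sampled independently as
   N(μ_label, σ²_label). The per-label σ absorbs both tissue heterogeneity
   and scanner noise; no separate noise model is used.
4. **Bias and gamma.** A 4³ grid ~ N(0, σ_B²), σ_B ~ U(0, 0.4), is upsampled
   to the image and exponentiated into a strictly positive multiplicative
   field (zero-mean in the log domain, so brightening and darkening are
   equally likely). The biased image is min–max rescaled to [0, 1] and raised
   voxel-wise to the power exp(γ), γ ~ N(0, 0.4²). Rescaling anchors are
   taken from the biased image by default; a config switch
   (`gamma_minmax_from="pre_bias"`) anchors on the unbiased image instead,
   for ablation.
5. **Resolution simulation.** A slice-normal axis is drawn uniformly; slice
   spacing r_spac ~ U(r_hr, b_res) (default b_res 9 mm) and thickness
   r_thick ~ U(r_hr, r_spac) (slices rarely overlap, so thickness is bounded
   by spacing). The slice profile is approximated by a 1D Gaussian of
   standard deviation `2·α·ln(10)/(2π)·r_thick/r_hr` HR voxels — the width
   that attenuates signal power tenfold at the low-resolution cut-off — with
   α ~ U(0.95, 1.05) jittering the nominal thickness. The blurred image is
   linearly downsampled along the axis to r_spac and resampled back to the
   HR grid, so image and target always share the grid.
6. **Target.** The segmentation target is the *same* deformed label map used
   for synthesis, with all labels outside the segmentation set reset to
   background. Alignment between image and target is exact by construction.

Collapsing every prior to its identity value (`GenerationConfig.degenerate`)
makes the draw a deterministic min–max-rescaled per-label mean map, which
anchors the pipeline's regression tests.

The GMM priors μ∈[0, 255], σ∈[0, 35] are the reference contrast
randomisation; the affine/bias/gamma/resolution defaults are plausible
wide-coverage values exposed in `GenerationConfig` — the approach is
deliberately insensitive to their exact settings, and narrowing them to match
a specific domain is exactly what the method argues against.

## Network and training

The segmenter is a 3D U-Net: per level two 3×3×3 convolutions, each followed
by per-channel instance normalisation (batch size is 1 throughout, so batch
statistics degenerate to instance statistics) and an ELU; 2× max-pooling
down; centre-aligned trilinear 2× upsampling up, with a 1×1×1 convolution
halving the feature maps before concatenation with the skip connection;
feature maps double per pooling from `first_features`; a 1×1×1 softmax head
over the background plus K′ foreground channels. The reference configuration is
5 levels / 24 features; the desk-scale default used throughout the tests is
3 levels / 8 features. The backend is a self-contained numpy implementation
with analytically derived gradients (verified against finite differences in
the test suite); the architecture is an interchangeable component behind the
`Checkpoint` interface.

The loss is the average soft Dice,
`1 − (1/K) Σ_k 2⟨Y_k,T_k⟩ / (‖Y_k‖² + ‖T_k‖²)`, bounded in [0, 1] and zero
exactly at the one-hot optimum. The metric form (`soft_dice_loss` default)
averages over the K′ foreground labels only. The *training objective*
additionally includes the background channel in the average
(`include_background=True`), for a stability reason worth recording: with
background unsupervised, a channel whose own Dice gradient vanishes (its
label absent from a draw's target, or its prediction disjoint from a tiny
target) still receives a positive logit push through the softmax coupling
`dz_k = −Y_k·Σ_c (∂L/∂Y_c)·Y_c`, and at batch size 1 with few labels this
drives a degenerate attractor in which one foreground channel annexes the
entire background — observed reproducibly in long desk-scale runs, and
essentially inescapable once entered because the squared-denominator
gradient is then O(1/N). Supervising background directly removes the
attractor and speeds convergence. A label empty in both prediction and
target contributes a perfect score, so all-background crops are tolerated.

Optimisation is Adam, one generated pair per update, with gradients rescaled
to a global norm of at most 2 (≈ the 99th percentile of observed norms) —
at batch size 1, rare draws with near-singular denominators produce spikes.
The reference schedule is 10⁻⁴ for 300k steps; the desk-scale harness uses
2×10⁻³ decayed to 10⁻³ at step 2,500 and 5×10⁻⁴ at 3,500, for 4,500 steps
on 32³ volumes — rates scaled to a network and problem ~100× smaller.
Checkpoints are snapshotted periodically. The retained model is the uniform
weight average of the last three checkpoints — tail averaging over the
low-learning-rate phase, a cheap variance reducer compared with trusting a
single snapshot — unless its mean foreground Dice on held-out synthetic
validation pairs falls more than 0.02 below the best single checkpoint, in
which case the validation-selected checkpoint is retained instead (the veto
guards against a tail contaminated by a degenerate phase).

## Inference

Scans are trilinearly resampled to isotropic `r_hr` — the network output is
therefore always a crisp HR segmentation regardless of input resolution —
and rescaled so the 1st/99th intensity percentiles map to 0/1 (clipped
outside). Test-time augmentation averages the soft maps of the scan and its
left–right mirror (mirror prediction un-mirrored with lateral channels
swapped); it can be disabled, e.g. for anatomies without lateral symmetry.
The labelling is the per-voxel argmax (ties to the lowest label) followed by
largest-connected-component filtering per foreground label at
26-connectivity, equal-size ties resolving to the component containing the
lexicographically smallest voxel. Resampling the output back to the native
grid is available as an explicit post-step but off by default.

## Evaluation statistics

Dice is defined as 1 for two empty masks. SD95 is the 95th percentile of the
*pooled* bidirectional surface-distance set (symmetric by construction;
boundaries via 6-connectivity erosion; distances in mm via exact Euclidean
distance transforms with anisotropic sampling). Soft volumes sum a label's
probability channel times the voxel volume. Group contrasts use Cohen's d
with unbiased pooled variance; volumes are first residualised on covariates
by pooled OLS (residual + grand mean), which leaves them orthogonal to every
covariate while preserving scale. The label-subdivision step fits a 1-D
Gaussian mixture per region by EM (quantile init plus k-means sweeps,
log-domain E-step, σ floored at 10⁻³ of the intensity range, convergence at
ΔLL < 10⁻⁶ or 100 iterations; the per-iteration log-likelihood trace is
exposed and is non-decreasing); foreground labels split into 2 clusters,
background into N ~ U{3..10}, and sub-labels always merge back to their
parents exactly.

## Phantom corpus

The synthetic-label corpus emulates the structural features the method needs
from a real training set while making no claim of anatomical realism (the
method's own premise is that realism is unnecessary): nested smooth blobby
shapes — background, an extra-cerebral shell, a tissue interior that hosts
lesions, and interior structures of which the first two are an exactly
mirrored left/right pair — individualised per corpus member by a small
smooth random warp, deterministic under seed, sharing one labelling
convention. What phantoms do *not* model: real anatomical shape statistics,
fine structures at the resolution limit (cortex-like sheets), real slice
excitation profiles, or pathology beyond blob-shaped lesions; passing the
desk-scale tests therefore demonstrates the mechanics and the
contrast/resolution-invariance principle, not clinical accuracy.

## Desk-scale study conditions

The repository's end-to-end check trains the reduced model (3 levels,
8 features, the step-decay schedule above, 4,500 steps, checkpoints every
500 with the retained model selected on 12 held-out synthetic pairs) on
eight 32³ phantoms with one lateral pair (three foreground labels) — enough
corpus members that morphological variety, not memorised shapes, drives the
fit — with full contrast randomisation and slice spacings up to 5 mm, then
segments 20 freshly generated scans of unseen contrast from held-out
phantoms, at native resolution and at 5 mm slice spacing/thickness (maximal
partial voluming at 5× the working grid).
The acceptance bar is mean foreground Dice ≥ 0.80 at native resolution with
the 5 mm score within 0.15 of it. Problem sizes were chosen so the whole
suite runs on a single CPU core in well under half an hour.

## Known limitations

- The numpy backend is CPU-bound and single-threaded; it is suitable for the
  desk-scale configuration, not for 160³/300k-step training.
- The coarse velocity and bias grids are centre-aligned to the image during
  upsampling; corner alignment would change boundary values slightly.
- Discrete Jacobian positivity of the integrated velocity field is a
  grid-resolution statement: velocity bounds are chosen relative to the
  image size (≈3 voxels at 64³, 1.5 at 32³) so the central-difference
  determinant stays positive; much rougher fields can alias on coarse grids
  even though the continuous flow is diffeomorphic.
- Lesion pasting places one mask per event at a uniform offset restricted to
  host labels; count and shape distributions of real lesion loads are not
  modelled.
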
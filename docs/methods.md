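# Methods

This note documents the models, conventions and numerical choices behind
`emboost`, and what the bundled synthetic data can and cannot show.

## Density simulation

The model-calculated map is a sum of per-atom Gaussians,
`rho(y) = Σ_i C·A_i·exp(−k‖x_i−y‖²)` with `k = (π/(0.9·R0))²` and
`C = (k/π)^{3/2}`, so each atom integrates to its atomic number `A_i`.
`R0` is the resolution of the paired experimental map in Å (unmasked
FSC@0.143); it is supplied by the caller — this package does not estimate
it from half maps.  Contributions are truncated at the radius where the
regularized upper incomplete gamma function `Γ(3/2, k·r²)/Γ(3/2)` falls to
1e-6 (solved with Brent's method), giving a provable relative mass error
below 1e-6 while making accumulation linear in the number of atoms
(per-atom scatter into a cubic sub-box, masked to the truncation sphere).
Alternate locations keep the highest-occupancy conformer; waters are kept
by default.

## Grid conventions

In-memory maps are float32 arrays indexed `[z, y, x]` (section axis
slowest, the MRC2014 convention); `voxel_size` and `origin` are (x, y, z)
triples in Å.  On read, axis-permuted files are transposed to this layout
and the original (mapc, mapr, maps) permutation is recorded.  The origin
comes from the ORIGIN header words when any is nonzero, otherwise from
`nstart × voxel`.  Non-orthogonal cells are rejected.  Resampling to the
1 Å working grid uses trilinear interpolation (spline order configurable);
points outside the source grid evaluate to 0, consistent with solvent
padding.  Trilinear was chosen over higher orders because it cannot ring
on noisy maps; it is exact on affine fields, which the tests exploit.

## Blocks

Training blocks are 64³ at stride 50; evaluation/inference blocks 48³ at
stride 38; the final block on each axis is clamped to the grid edge, so
coverage is complete and positions are unique and sorted.  Maps smaller
than one block are zero-padded symmetrically and cropped after assembly.
Normalization divides by the 99.999th-percentile density and clamps to
[0, 1]; both the experimental input and the simulated target are
normalized by their own percentile so the two live on a common scale.
Reassembly averages all block predictions covering a voxel, accumulating
sums and counts in float64; because an n-fold sum of a float32 value and
its division by n are exact in float64, extract→assemble is bit-exact,
which the suite asserts.  Averaging (rather than overwriting) was chosen
because it is the simplest scheme with that identity property.  Empty
target blocks (no voxel above zero) are dropped; the occupancy threshold
defaults to 0 and is configurable.

## Network

Four encoder stages (stride-2 3³ convolution, group normalization with 4
groups, three transformer layers) reduce 48³→24³→12³→6³→3³ with default
channel widths (32, 64, 128, 256); four decoder stages (kernel-2/stride-2
transposed convolution, skip concatenation, a 3³ fusing convolution, three
transformer layers) mirror them.  The final decoder's skip is the raw
input block.  Each transformer layer adds a learned positional embedding,
applies efficient paired attention to the batch-normalized features with a
residual connection, then a 3³ convolution → leaky rectifier (slope 0.01)
→ batch norm → dropout (p = 0.1), also residual.

Efficient paired attention: queries and keys come from linear maps
*shared* between the spatial and channel branches; each branch has its own
values.  The spatial branch projects keys and values along the token axis
to `epa_proj_dim` tokens (default 64, clamped to the stage's token count)
before the scaled dot product, making its cost linear in tokens; the
channel branch attends over the per-head channel Gram matrix (scaled by
1/√N).  Branch outputs pass through separate output projections, are
summed, and mixed by a 1³ convolution — so zeroing one branch's projection
exactly silences it, which the tests use for ablation.

A parallel ConvRes branch applies two convolution+group-norm pairs to the
raw block, concatenates the result with the input, and applies a third
convolution+norm and a leaky rectifier.  Its output is concatenated with
the last decoder output and fused by one 3³ convolution to a single 48³
channel; the fusion head restores the input shape regardless of the last
decoder's width.  Output is linear (no final activation): targets are
nonnegative but the loss, not a clamp, is left to enforce that.

**Initialization.**  Attention and token projections are truncated-normal
(σ = 0.02, clipped at 2σ); convolutions fan-in uniform.  The per-layer
output scales — the EPA mixing convolution and the gain of the post-conv
batch norm — start at zero, so every transformer layer begins as the
identity and its branches grow in as their output scales receive gradient.
This ReZero/Fixup-style choice is what makes from-scratch training usable
at desk-scale step budgets; disable with
`ModelConfig(residual_zero_init=False)`.  All initialization is seeded.

The network, reverse-mode automatic differentiation and Adam are written
on numpy inside the package (`emboost.nn`): convolution via per-offset
strided gathers and one matmul (the adjoint scatters through the same
disjoint slices), the stride-2 transposed convolution as an einsum.
Interior gradients and closures are freed progressively during the
backward sweep to bound peak memory.

## Training protocol

Adam (β = 0.9/0.999, ε = 1e-8) from 5e-4.  An epoch is one pass over the
retained training blocks; validation runs at the 25/50/75/100% marks
(`validations_per_epoch = 4`).  "Improvement" means strictly below the
best validation loss seen so far (a flag switches to
previous-value comparison).  Four consecutive non-improvements halve the
learning rate and reset the counter; the rate clamps at exactly 1e-5.
The schedule is a pure function of the validation-loss sequence and is
unit-tested in isolation.  The masked MSE masks voxels that are exactly
zero in both output and target; with floating-point outputs the mask is
effectively target-driven (model outputs are almost never exact zeros),
and an optional epsilon tolerance exists, off by default.  When no voxel
survives masking the loss is defined as 0.  A non-finite loss aborts with
the offending block positions.  Training is bit-reproducible for a fixed
seed, and per-epoch resume snapshots (weights, Adam moments, generator
states, schedule state) make checkpoint→resume→continue identical to an
uninterrupted run.

## Inference

Full-map enhancement: resample to 1 Å → percentile-normalize → pad if
needed → 48³ blocks at stride 38 → batched eval-mode forward → mean
overlap blending → crop → restore metadata.  Output stays in the
normalized [≈0, 1] density space the targets were in; the input's
normalization scale is reported for provenance, and an option resamples
back to the native voxel size.  Batch size cannot change the result
(batch norm uses running statistics in eval mode), asserted bit-exactly.

## Validation metrics

FSC uses full FFTs with shells one Fourier voxel wide (radial index
rounded to the nearest integer of `|s|/ds`, `ds = 1/box`); shells are
reported up to Nyquist.  Threshold resolution takes the first downward
crossing with linear interpolation between bracketing shells; a curve that
never crosses returns the Nyquist-limit resolution with a `limit_reached`
flag.  CC_box/CC_mask/CC_peaks are Pearson correlations over the full box,
the molecular mask (voxels within 3.0 Å of any atom by default — a
convention, configurable), and the union of each map's top-N voxels with
N the mask size.  Zero-variance regions yield a flagged report instead of
NaN.  The model-calculated map is this package's own Gaussian simulation,
so metric values are internally consistent but not expected to match
external tools digit-for-digit (their shell binning, mask construction
and map synthesis differ).

## Synthetic data

`random_structure` produces blob (Gaussian cloud), helix (1.5 Å rise,
100° twist, 2.3 Å radius spiral) or sheet (3.5 × 4.8 Å planar grid) atom
clouds with protein-like element frequencies (C/N/O/S) and ≥ 1 Å pairwise
spacing inside a 12% box margin.  `degrade` blurs (Gaussian, σ in Å),
optionally damps Fourier amplitudes by `exp(−B·s²/4)`, adds seeded
Gaussian noise scaled to the ideal map's peak, and clamps at zero.
Defaults: 4 Å simulation resolution, 1.5 Å blur, 5% noise, damping off.
This degradation gives the network a learnable inverse problem whose
difficulty is controlled; it does **not** model cryo-EM image formation
(no CTF, no projection geometry, no solvent, no B-factor heterogeneity),
so passing the end-to-end test demonstrates that the architecture, loss
and optimization can learn a deconvolution/denoising map on this family —
not that the defaults would enhance real EMDB maps.

## Scaled-down study sizes

All tests run on one CPU.  The end-to-end study trains the tiny
configuration (channels 4/8/16/32, 2 heads, projection 32) on 8 synthetic
maps (64 Å boxes → one 64³ training block each), validates on 2 maps
(48 Å boxes), and evaluates on 2 held-out 64 Å maps, with batch size 1
for 10 epochs (80 Adam steps).  These sizes were chosen once as the
smallest study in which learned enhancement is clearly measurable; the
default production-scale configuration (channels 32–256, batch 64) uses
the same code paths.

## Known limitations

- The simulation uses atomic numbers, not electron scattering factors or
  B-factors; peaks are sharper than physical maps at the same resolution.
- FSC shell binning assumes (near-)cubic grids; strongly anisotropic
  voxels are resampled before metrics in the standard pipeline.
- Restoring the native voxel size after enhancement uses the mean spacing
  when the input was anisotropic.
- The numpy network is CPU-bound; it is intended for method study and
  desk-scale experiments, not high-throughput production enhancement.
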
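# emboost

Cryo-EM density maps are noisy, blurred reconstructions of macromolecules,
and their interpretability limits how good an atomic model can be built
from them.  `emboost` is a toolkit for *learning-based map enhancement*:
it trains a 3D transformer U-Net to map blocks of an experimental density
map onto the corresponding blocks of an idealized, model-calculated map,
then applies the trained network block-by-block to whole maps.  It is
aimed at structural biologists and method developers who want a fully
self-contained, CPU-runnable implementation of the approach — from target
simulation through training to map-model validation — with no external
binaries.

## Method

**Target simulation.**  Given an atomic structure, the ideal ("simulated")
map places a normalized Gaussian on every atom:

```
rho(y) = sum_i  C · A_i · exp( -k · ||x_i − y||² )
k = ( π / (0.9 · R0) )²          C = ( k / π )^(3/2)
```

where `x_i` and `A_i` are the position and atomic number of atom *i* and
`R0` (Å) is the map's unmasked FSC@0.143 resolution.  With this `C` every
atom contributes total mass exactly `A_i`.  All atoms are used, including
hydrogens, waters, ligands and nucleic acids.

**Preprocessing.**  Maps are resampled to a 1 Å grid and normalized to
[0, 1] by their 99.999th-percentile density.  Training uses overlapping
64³ blocks at stride 50, randomly cropped to 48³ with random 90° rotations
and axis flips; validation and inference use 48³ blocks at stride 38.
Blocks with empty targets are discarded.

**Network.**  A UNETR++-style U-Net: four encoder stages (stride-2
convolution, group norm, three transformer layers) taking 48³→24³→12³→6³→3³,
mirrored by four decoder stages with skip concatenation.  Each transformer
layer uses *efficient paired attention* — a spatial branch whose keys and
values are projected to a small token count before the dot product, and a
channel branch, sharing the query/key mapping weights — plus a 3³
convolution, leaky rectifier, batch norm and dropout (p = 0.1).  A parallel
residual convolution branch (ConvRes) on the raw block is fused with the
last decoder output by a final convolution.  The network, its automatic
differentiation and the optimizer are implemented in numpy inside the
package (`emboost.nn`).

**Training.**  Masked mean squared error — voxels zero in both output and
target are excluded — minimized with Adam from 5e-4; validation 4×/epoch;
four consecutive non-improving validations halve the learning rate, floored
at 1e-5.

**Validation metrics.**  Map-model Fourier shell correlation with
threshold resolutions (FSC@0.143, FSC@0.5), and the three real-space
correlations CC_box / CC_mask / CC_peaks against the package's own
model-calculated map, with a 3 Å molecular mask.

## Worked example

```python
import numpy as np
from emboost import (
    VoxelGrid, random_structure, gaussian_params_from_resolution,
    simulate_map, degrade, DegradationParams, fsc, resolution_at,
    molecular_mask, cc_scores,
)

structure = random_structure(150, motif="helix", box=48.0, seed=7)
params = gaussian_params_from_resolution(4.0)
print(f"kernel: k = {params.k:.4f} A^-2, C = {params.c:.4f} A^-3, "
      f"cutoff = {params.cutoff_radius:.2f} A")

template = VoxelGrid(np.zeros((48, 48, 48), dtype=np.float32))
ideal = simulate_map(structure, params, template)
noisy = degrade(ideal, DegradationParams(blur_sigma=1.5, noise_sigma=0.05, seed=7))

mask = molecular_mask(structure, ideal, radius=3.0)
for name, g in [("ideal", ideal), ("degraded", noisy)]:
    curve = fsc(ideal, g)
    r = resolution_at(curve, 0.5)
    cc = cc_scores(g, ideal, mask)
    print(f"{name:9s} FSC@0.5 = {r.resolution:.2f} A  "
          f"CC_box = {cc.cc_box:.4f}  CC_mask = {cc.cc_mask:.4f}  CC_peaks = {cc.cc_peaks:.4f}")
```

prints

```
kernel: k = 0.7615 A^-2, C = 0.1193 A^-3, cutoff = 4.49 A
ideal     FSC@0.5 = 2.00 A  CC_box = 1.0000  CC_mask = 1.0000  CC_peaks = 1.0000
degraded  FSC@0.5 = 5.47 A  CC_box = 0.2869  CC_mask = 0.3693  CC_peaks = 0.1327
```

The simulated map at 4 Å resolution has a kernel decay of 0.76 Å⁻²; the
self-comparison is perfect by construction, while blurring (1.5 Å) plus 5%
noise degrades the FSC@0.5 resolution from the 2 Å Nyquist limit to
5.5 Å and drops all three cross-correlations — the quantities the trained
network is asked to restore.

To train and apply a model, use the estimator:

```python
from emboost import MapEnhancer, pairs_from_maps

est = MapEnhancer(channels=(4, 8, 16, 32), num_heads=2, epa_proj_dim=32,
                  batch_size=1, max_epochs=10, seed=0)
est.fit(pairs_from_maps(noisy_map, ideal_map, mode="train"))
enhanced = est.transform([held_out_map])[0]
```

or the equivalent CLI: `emboost fixtures`, `emboost simulate`,
`emboost preprocess`, `emboost train`, `emboost enhance`,
`emboost evaluate` (see `emboost --help`).

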
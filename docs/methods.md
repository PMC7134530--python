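# Methods

`atriaseg` implements joint segmentation of the left-atrial (LA) blood pool
(with proximal pulmonary veins, PV) and of atrial scar from a single 3D
late-gadolinium-enhanced (LGE) CMR-like volume, with a multiview two-task
(MVTT) recursive attention network, together with everything needed to
exercise it without clinical data: a phantom generator with known ground
truth, classical unsupervised scar baselines, and the full metric and
agreement panel.

## Model

A 3D volume is resampled to an isotropic cube (default edge 48) and sliced
into ordered 2D stacks along the three orthogonal axes. Internally grids
are indexed `(z, y, x)`; axial slices are constant-`z` planes, matching a
transverse acquisition.

**Axial sequence branch.** Each axial slice passes a small conv+BN+ReLU
encoder; a convolutional LSTM then walks the slice sequence in ascending
`z` from a zero initial state, mimicking how a reader steps through a
stack. The cell is the peephole formulation

    f_t = sigma(Wxf*x_t + Whf*h_{t-1} + Wcf o c_{t-1} + b_f)
    i_t = sigma(Wxi*x_t + Whi*h_{t-1} + Wci o c_{t-1} + b_i)
    c_t = f_t o c_{t-1} + i_t o ReLU(Wxc*x_t + Whc*h_{t-1} + b_c)
    o_t = sigma(Wxo*x_t + Who*h_{t-1} + Wco o c_t + b_o)
    h_t = o_t o ReLU(c_t)

with `*` a same-padded 2D convolution and `o` the Hadamard product. The
peephole weights are learned per location and per channel, literally as
the Hadamard notation states, and initialize at zero. ReLU replaces the
conventional tanh as the state activation (tanh remains available as the
`convlstm_activation` ablation). Because the ReLU cell is unbounded, the
cell is initialized subcritically: gate kernels at Xavier scale (they feed
sigmoids), the candidate's input kernel at He scale (it feeds the ReLU),
recurrent kernels damped by 0.5, and the forget bias at -1 so the memory
starts as a leaky accumulator. At a neutral initialization the recurrent
loop gain exceeds one on spatially correlated slice sequences and the
hidden state grows exponentially over a 48-slice stack, which saturates
the gates and stalls training.

**Orthogonal-view branches.** Sagittal and coronal stacks pass dilated
residual subnetworks: conv blocks whose dilation rates cycle through
(1, 2, 5) — a hybrid-dilated-convolution cycle without a common divisor,
so the stacked receptive field has no periodic "gridding" gaps — each conv
followed by BN and ReLU, with an additive shortcut per block. `conv_mode =
"plain"` collapses the cycle to all-ones for the no-dilation ablation.

**Fusion.** Because sagittal/coronal stacks index the cube along `x`/`y`,
an axis permutation `T` re-orders their feature stacks into axial order;
the fused features are `F_v = F_a + T F_c + T F_s`. The transposition is
exact (pure re-indexing), which the tests assert voxel-for-voxel.

**Heads and attention.** The anatomy head maps `F_v` through two 3x3
16-kernel conv+BN+ReLU layers whose outputs are concatenated (32 channels)
into a 3x3 single-kernel conv + sigmoid, giving the anatomy probability
volume `m_l`. A dilated attention branch maps the raw axial slices to a
single-channel mask `AM = sigma(.)` in (0, 1); the scar head consumes the
modulated trunk `O = (1 + AM) o F_v` — the `1 +` skip keeps trunk
information when the mask closes — through the same two-layer head with a
1x1 final conv, giving the scar probability volume `m_as`. The
single-channel mask broadcasts across trunk channels.

**Loss.** Both tasks train jointly with the hybrid soft-Dice loss
`L = delta(m_l, g_l) + delta(m_as, g_as)`,
`delta(m, g) = 1 - (2 sum(mg) + eps) / (sum(m) + sum(g) + eps)` with
`eps = 1` so empty masks cannot produce 0/0. Probability maps are
binarized at 0.5 for evaluation.

Every architectural ingredient is a configuration switch (`use_multiview`,
`use_convlstm`, `use_attention`, `kernel_size` 3/5, `conv_mode` hdc/plain,
`convlstm_activation` relu/tanh, `tasks` both/anatomy_only/scar_only), so
the model-variation grid (SV+CLSTM, MV, MV+AT, MV+CLSTM, SV+CLSTM+AT,
S-LA/PV, S-Scar, K5, AFT, NDC) is a table of named flag sets.

## Numerical core

The network runs on a small in-package reverse-mode autodiff engine over
NumPy arrays (`atriaseg.autodiff`): broadcasted elementwise ops,
reductions, concatenation/permutation/slicing, batch normalization, and a
stride-1 same-padded dilated 2D convolution evaluated by im2col + BLAS
matmul. Convolution gradients reuse the same kernel: the input gradient is
a convolution with the spatially flipped, channel-transposed weights; the
weight gradient contracts the unfolded input with the output gradient.
Scratch arrays (padding and column buffers, slice-gradient buffers) come
from a reusing pool — they recur thousands of times per run, and cycling
multi-megabyte allocations through the system allocator otherwise
dominates wall time. float32 is the training precision; float64 inputs
propagate unchanged, which the equation-level tests (1e-6 agreement with
an independently coded scalar LSTM oracle) rely on.

Training uses Adam (beta1 0.9, beta2 0.999) with the decayed learning rate
`lr(e) = 0.001 * 0.98^e` applied per epoch, one whole volume's slice
stacks per optimization step, global gradient-norm clipping at 1.0 (the
ReLU-activated memory cell is unbounded, so occasional gradient spikes
through the 48-step recurrence are expected), early stopping on validation
loss with best-checkpoint restoration, and randomized k-fold splitting
utilities. Head output biases initialize at the foreground prior (-1.0
anatomy, -3.0 scar) so the Dice loss does not spend its first epochs
collapsing a half-gray prediction. Subnetwork depth and width (default: a
2-layer axial encoder, one dilated residual block per orthogonal view,
base width 6) are declared configuration, chosen so a full training run on
one CPU stays in minutes; the head layout (16+16 -> 32 -> 1) is fixed
architecture.

## Phantom generator

The generator emulates the contrast regime of an LGE acquisition on a
cubic grid (default 48^3 at 1.25 mm): an ellipsoidal LA cavity
(semi-axes ~ (16, 13, 11) mm, mildly jittered per sample) plus tubular PV
stubs attached near the superior pole (default 4, radius 3 mm); a wall
shell of voxels within 2.25 mm of the anatomy surface (the fixed
wall-thickness assumption used for scar burden); and scar as contiguous
angular sectors (spherical caps) of that shell. Tissue intensities are
piecewise Gaussian: nulled myocardium/background (0.18 +/- 0.05), bright
blood (0.60 +/- 0.05), scar (0.85 +/- 0.06), satisfying
`scar_mean > blood_mean + 2 blood_sd` so the 2-SD baseline is well posed.

Three degradations make the task honest rather than trivially separable:

- **Wall enhancement texture.** Non-scar wall voxels draw from a smooth
  spatially correlated field (mean 0.40, sd 0.18, correlation length
  4 mm) rather than the nulled myocardium value: real atrial walls show a
  continuum of mild enhancement (diffuse fibrosis, contrast kinetics),
  which is exactly why global-intensity scar rules over-segment.
- **Point-spread blur** (Gaussian, sigma 1 mm): partial volume in a wall
  only 2-3 voxels thick.
- **Multiplicative bias field** (+/-20%, low order) and additive Gaussian
  noise (sd 0.03): coil-gain inhomogeneity and acquisition noise.

Scar-patch half-angles follow the spherical-cap solid-angle formula and,
when a target burden is requested, are refined against the realized shell
geometry, so the generated `true_scar_fraction` hits the target up to
discretization. By default the half-angle jitters +/-35% per sample,
giving cohorts a spread of burdens (roughly 10-40% of the wall) for the
correlation and Bland-Altman analyses. Randomness flows from one root
seed; cohort sample `i` uses `root + i`.

What the phantom does **not** model: inversion-recovery physics, navigator
or motion artefacts, anisotropic acquisition blur, partial volume beyond
grid discretization, and anatomical variation beyond an ellipsoid + tubes.
Passing tests therefore demonstrate that the implementation learns and
quantifies the intended structures under controlled conditions — not
clinical-grade performance.

## Baselines and evaluation

The unsupervised comparators operate on intensities inside the
ground-truth-derived wall shell (at the fixed 2.25 mm thickness): 2-SD
thresholding against blood-pool statistics measured on the eroded cavity;
1-D k-means (k-means++ seeding, scikit-learn) taking the highest-centroid
cluster as scar; and fuzzy c-means (c = 2, fuzzifier 2.0, tolerance 1e-6,
spread-quantile initialization) with majority membership. Ties (equal
centroids) conservatively yield an empty mask.

Evaluation computes voxelwise confusion counts; accuracy, sensitivity,
specificity and Dice (NaN with a warning on empty denominators); scar
burden as 100 x scar volume / wall-shell volume; Pearson correlation; and
Bland-Altman bias with 95% limits of agreement (mean difference +/- 1.96
sample standard deviations, n-1 convention). Metrics are averaged across
cases, not pooled voxelwise.

## Design choices on genuinely open points

- Orientation, slice counts and in-plane size are reconciled by resampling
  to an isotropic cube before multiview fusion — the minimal assumption
  under which the view transposition is well defined.
- A constant slice under mean-range normalization maps to zeros (the
  numerator is identically zero; zeros are the unique continuous
  completion).
- The ConvLSTM runs unidirectionally in ascending slice order from a zero
  initial state.
- Fusion happens once, at a single scale.
- The scar branch's head follows the 16+16 -> 32 -> 1x1 description; the
  attention mask branch consumes the raw axial slice while the trunk is
  the fused feature stack.
- Scar burden is volumetric (scar voxels over shell voxels), not
  surface-projected.
- The wall region for the unsupervised baselines derives from the
  ground-truth anatomy at 2.25 mm, isolating scar detection from anatomy
  errors.

## Problem sizes

The scaled-down study trains on 40-phantom cohorts at 48^3 (32 train / 8
held out, 5 epochs with best-validation checkpoint selection; the
acceptance script allows 8) — sized so a full train-evaluate cycle runs in
a few minutes on one CPU while still exercising every component end to
end. The overfit sanity check uses 2 phantoms at 32^3 (base width 8,
initial learning rate doubled to 0.002 with clipping at 5 — under the
0.98-per-epoch decay, the default initial rate leaves too little total
step budget to memorize within 200 epochs); equation-level and protocol
checks are closed-form and run in seconds.

## Known limitations

- The in-package autodiff engine is deliberately minimal: no GPU, no
  parallelism, stride-1 convolutions only.
- Phantom realism is bounded (see above); absolute Dice values on
  phantoms do not transfer to clinical data.
- Layer counts and widths of the original subnetworks are not public in
  text form; the defaults here are declared, configurable choices.
- Checkpoints are NPZ archives of named tensors plus the architecture
  config as JSON; they restore only into the same package version's
  architecture definitions.
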
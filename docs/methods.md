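# Methods

## Network family

Three variants share one construction path:

* **Unet baseline** — five levels of two 3×3 convolutions, each followed
  by ReLU and batch normalization, filter widths 32/64/128/256/512, 2×2
  stride-2 max pooling, 2×2 stride-2 transposed-convolution upsampling
  with plain skip concatenation, one 1×1 sigmoid head.  With a 1-channel
  input this graph holds 7,765,409 trainable parameters (7.765 M).
* **T-Unet** — each of the nine nodes (4 encoder, transition, 4 decoder)
  holds three convolution units.  Unit *i* = two 3×3 dilated convolutions
  (rate 4 − *i*, i.e. 3/2/1) each followed by ReLU and dropout, then one
  batch normalization.  Unit *i* concatenates the outputs of units
  1..*i−1* of its own node with its cross-node input: the pooled
  unit-matched feature `M(χ_{h−1}^i)` in the encoder (the 16-filter stem
  output at node 1), or the transposed-convolution upsampling
  `τ(γ_{h+1}^i)` plus the unit-matched encoder skip `χ_h^i` in the
  decoder.  Node widths are 16/32/64/128/256.  Each sub-output *i* is a
  1×1 convolution + sigmoid on `γ_1^i`; the three sub-outputs concatenated
  pass through a final 1×1 convolution + sigmoid (55 parameters for the
  whole fusion head at width 16).
* **TMD-Unet** — T-Unet plus (a) the multi-scale input pyramid: level
  `L_j` is the j-fold 2×2 max pooling of the stem features concatenated
  with the raw input (so each level carries `base_filters +
  input_channels` = 17 channels for grayscale input), injected into every
  unit of encoder node `j+1` and the transition node; and (b) dense skips:
  decoder unit *i* concatenates encoder units `χ_h^1..i`.

Conventions the parameter accounting depends on (chosen once, from the
reference totals that pin them down):

* transposed convolutions: 2×2 kernel, stride 2, output width = the
  receiving node's filter count, bias included;
* one batch normalization per unit (after the second convolution) for the
  triple variants; one after *each* convolution for the Unet baseline;
* batch-normalization trainable parameters are scale+shift (2 per
  channel); running statistics are not counted;
* size-preserving padding everywhere (a dilated 3×3 convolution pads by
  its rate); 1-channel input;
* dropout is parameter-free and sits after each convolution's activation,
  active only in training mode;
* millions are reported by truncating the raw count at the third decimal,
  which is how whole-parameter totals render to the printed values
  (1,944,609 → 1.944).

### Parameter accounting per sub-output

`count_parameters(model, i)` sums the layers upstream of sub-output *i*:
the stem, units 1..*i* of every node (unit *j* ≤ *i* feeds unit *i*
through the intra-node dense links), their transposed convolutions, and
sub-output *i*'s 1×1 convolution; the full fusion head is included for the
last index (it is two orders of magnitude below the rounding granularity).
An independent closed-form count computed from the connectivity equations
alone is asserted against the registry sum in the test suite for every
variant and index.

With these conventions the construction reproduces the reference totals
for the Unet baseline (7.765 M) and for sub-output 1 of both triple
variants (T-Unet 1.944 M; TMD-Unet 2.018 M — the latter only under the
17-channel pyramid reading, which is also the literal reading of "fusing
the input image information at multiple scales").  For sub-outputs 2 and 3
the reference table prints totals 0.39–0.47 M *below* any reading of the
connectivity equations we could construct: an exhaustive search over the
plausible convention space (intra-node connectivity variants, pooled-input
and pyramid-width variants, 2×2/3×3 transposed kernels, shared vs per-unit
upsampling, bias/normalization toggles, rounding vs truncation) found no
assignment consistent with all six printed values at once — the reductions
required at sub-output 2 versus 3 differ between the two variants by ~2k
parameters, so no single structural choice can explain both.  We therefore
report the counts our faithful construction yields (T-Unet
4.870/8.778 M, TMD-Unet 5.213/9.586 M) rather than force agreement.

### Receptive fields

Unit 1 (rate 3) has a 13-pixel single-unit receptive field, unit 2 (rate
2) 9 pixels, unit 3 (rate 1) 5 pixels — computed by dilation bookkeeping
(`2·rate·(k−1)+1`), asserted rather than measured.

## Losses

`L = L_dice + L_CE`.  Dice: `1 − (2Σyk + δ)/(Σ(y+k) + δ)` with smoothing
δ = 1.0 (the reference states δ's purpose, not its value; 1.0 is the
common choice).  Cross-entropy: BCE, or the weighted form
`−mean((1−w)·y·log k + w·(1−y)·log(1−k))` — note the printed formula
attaches `1−w` to the foreground term although `w` is described as the
foreground weight; we implement the formula as printed and flag the
tension here rather than silently swapping.  Under it, setting `w` to the
foreground-pixel *fraction* (the `class_balance_weight` helper, the
default policy) up-weights the rarer class's error term.  Probabilities
are clipped to `[1e-7, 1−1e-7]` before logarithms.  Training applies the
loss to the fused output only; a `deep_supervision` flag adds the three
sub-output losses (the reference is silent on this, so it is off by
default and not claimed as its intent).

## Metrics

DSC, mIoU, precision, recall, specificity and F1 from exact pixel tallies;
predictions binarized at 0.5 (unstated in the reference).  Empty-vs-empty
overlap scores are defined as 1 (correct rejection).  Both aggregations
are computed: per-image means and globally pooled confusion counts.  The
default report mixes them — per-image DSC/mIoU, pooled rates — because
printed DSC and F1 columns in the reference differ even though the two
statistics coincide on pooled counts (both equal `2TP/(2TP+FP+FN)`), which
implies different aggregation bases; the mixed policy is a reasoned
default, not a documented procedure of the reference.

## Preprocessing

* **Tiling** — square window, equal stride both axes ("64×128 overlap of
  adjacent 128-px windows" reads as stride 64 by symmetry); this uniquely
  reproduces the 1078/147/245 train/val/test tile counts for 22/3/5
  512-px micrographs (49 tiles each).  Non-divisible geometries are
  rejected rather than padded — all reference geometries divide exactly.
* **Intensity windowing** — clip to `[low, high]`, map affinely to
  `[0,1]`; idempotent on already-windowed data.  Applied to MRI too
  (where Hounsfield units are not physically defined) as plain intensity
  windowing, matching the reference recipe.
* **Center crop** — odd margins leave the extra pixel on the trailing
  side; "cropped" for the MRI/CT recipes is read as center crop.
* **Slice stacking** — channels (i−1, i, i+1); boundary slices duplicate
  the edge slice (unstated; duplication keeps the channel statistics of
  interior slices).
* **Empty-slice decimation** — within each maximal run of foreground-free
  slices keep every third starting from the first (the reference fixes
  only the 2-of-3 exclusion ratio, not the phase); a run of length L keeps
  ⌈L/3⌉ slices and no foreground slice is ever dropped.
* **Resizing** — bilinear for intensities, nearest-neighbour for masks.

## Training harness

Adam (β₁ 0.9, β₂ 0.999, ε 1e-7), he-normal truncated initialization,
epoch-wise schedule `lr = ILR · 0.9^(E/10)` with a real-valued exponent (a
`floor_schedule` flag switches to integer division; the two readings
coincide at multiples of 10, which is all the reference exercises; the
update granularity — batch vs epoch — is unstated, epoch-wise chosen).
Early stopping monitors validation loss (the monitored quantity is
unstated; loss chosen) with default patience 10, retaining the
best-validation weights.  Augmentation draws one affine transform per
sample — shear 0.5, rotation ±50°, zoom ±0.2, horizontal flip, shift
±0.2, reflection fill — applied identically to image and mask, the mask
warped nearest-neighbour and re-binarized.  The seven preset YAMLs under
`tmdunet/presets/` carry the per-application settings (loss kind, initial
learning rate, epochs, batch size, input size, augmentation on/off) and
the 80/20 train/validation split default.

## Synthetic data

The generator emulates only what the operators need: blob images are
unions of 1–3 random ellipses at intensity 0.8 over a 0.2 background with
Gaussian noise (σ 0.05), masks are the exact ellipse unions, foreground
fractions are constrained to a requested range (default 5–35 %, typical of
organ segmentation slices); volumes place a blob in a contiguous organ
span and leave other slices empty.  Fixture sizes 128 and 224 mirror the
two input sizes of the reference protocol.  The generator is deterministic
per seed (single PCG64 stream).  What it does **not** model: modality
texture, contrast inhomogeneity, anisotropic voxels, ambiguous boundaries,
multi-object scenes.  Consequently, passing desk-scale tests demonstrates
that the architecture, losses, optimizer and plumbing are correct and can
memorize small datasets (the overfit smoke test: eight 128-px blob images,
base-width-4 TMD-Unet, dropout off, ILR 3e-3, ≤60 epochs, training
DSC > 0.95) — it says nothing about segmentation accuracy on real medical
images, which in the reference requires the seven external datasets and
GPU-scale training and is out of scope here.

## Numerical choices and degenerate inputs

* float32 forward/backward; im2col + GEMM convolutions; transposed
  convolutions as non-overlapping block einsums (kernel = stride).
* Batch normalization: ε 1e-3, running-statistics momentum 0.9;
  max-pooling routes gradients to the first maximal element of a window.
* Rate metrics return 0 with a warning on zero denominators; dice with
  δ = 0 on two empty masks raises.
* Problem sizes in the test suite are deliberately small (32-px inputs,
  base widths 2–4) so the full suite and the overfit check run in a few
  minutes on one CPU core; the accounting tests use the full published
  widths since graph construction is cheap.

## Known limitations

No 3-D convolutions, multi-class heads, pretrained weights, focal/Tversky
losses or surface-distance metrics; single-device training only.  The
NumPy engine favours clarity over speed — roughly laptop-CPU scale, not a
replacement for a GPU framework at dataset scale.
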
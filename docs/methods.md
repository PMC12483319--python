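# Methods

This note documents the models and procedures implemented in `synrec`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic phantoms do and do not establish
about behaviour on real tomograms.

## Volumes and resolution handling

All arrays are (z, y, x) with per-axis voxel sizes in nanometres; 2D
images are (y, x). MRC2014 (pixel spacing converted from Å), HDF5
(datasets `raw`/`labels`, voxel size in a `voxel_size_nm` attribute) and
TIFF (voxel size as JSON in the description tag) round-trip losslessly
for integer labels. When a file carries no voxel size the caller must
supply one — analyses are in nm, and silently assuming 1 nm would
corrupt every downstream distance. The MRC codec is a minimal reader and
writer for the modes used here (int8/int16/uint16/float32).

Resampling to a model's training resolution uses linear interpolation
for intensities and nearest-neighbour for labels (no invented ids);
output shapes are `round(shape × in_voxel / target_voxel)` per axis, so
factor-k binning is the special case target = k × input. All pixel-unit
postprocessing thresholds (seed distances 8/6 px, minimum size 500 px)
are interpreted at the model's training resolution.

## Synthetic phantoms

The generator emulates presynaptic tomogram content at a
vesicle-segmentation working resolution (default 1.554 nm voxels):
vesicles are rendered as dark membrane rings (3.5 nm shell) with a
slightly darker-than-cytosol lumen on a flat background, with additive
Gaussian noise (default SD 5% of the intensity range) — defaults chosen
as a realistic, mildly noisy room-temperature tomogram. Vesicle radii
default to 16–24 nm (diameters 32–48 nm, the canonical SV range).
Placement is rejection sampling with a deterministic RNG and a retry cap;
dense scenes (e.g. 100 vesicles in 128³ voxels) need slightly narrower
radii (15–17 nm) because the default range would exceed the ~38% jamming
density of random sphere packing. Touching-vesicle fixtures are placed
explicitly (two spheres at a chosen centre separation, the overlap lens
split by the bisector plane), not sampled. Optional structures (AZ slab,
ribbon, PD, mitochondrion, stacked compartments) are rendered with
separate label volumes. Oracle probability maps rasterize the labels into
a binary foreground channel and a rim channel (inter-object and
object–background interfaces, optionally widened and smoothed) and stand
in for network output wherever the postprocessing, metrics or morphometry
are under test.

What the phantoms do **not** model: reconstruction artefacts (missing
wedge is available only as an optional anisotropic blur), CTF, membrane
texture, crowded cytoplasm, or irregular vesicle shapes. Passing tests
on phantoms therefore validates the algorithmic contracts (segmentation
recovers known objects, measurements recover known geometry) — not
real-data segmentation accuracy, which depends on training data.

## Supervised segmentation

The UNet has 4 levels with 32 initial features doubling per level,
max-pool downsampling, nearest-neighbour upsampling with skip
concatenation, two 3×3 convolutions + ReLU per block and a sigmoid
per output channel. In 3D the first downsampling can be restricted to
the image plane, matching the thin, missing-wedge-affected depth axis.
The implementation is pure NumPy in float32: convolutions are im2col
matrix products (BLAS), and every layer implements its own backward
pass; the full-network gradient is verified against finite differences
in the test suite.

Training targets derived from instance labels: foreground = any object;
boundary = the one-voxel interface rim between touching objects and
between object and background (the same rasterization the oracle maps
use); the compartment variant adds a normalized distance-to-boundary
regression channel trained with the same Dice-style loss, weighted 1:1
by channel averaging — the simplest symmetric choice. The loss is the
negative soft Dice (a perfect prediction scores −1); the optimizer AdamW
with lr 10⁻⁴, betas (0.9, 0.999), weight decay 0.01; the learning rate
is halved when the validation loss fails to improve for 5 consecutive
epochs; the checkpoint with the lowest validation loss is returned. The
validation split is 10% *by volume*, never by patch, to avoid leakage.
Training patches are augmented by default with flips/rot90 and mild
appearance jitter (blur σ ∈ [0, 1] px, noise ∈ [0, 5%] of range) —
standard practice that also underpins reliable teacher confidence during
domain adaptation (below). Production-scale training would run ~10⁵
iterations; the desk-scale experiments in the tests and acceptance
script use 400–1,500 iterations at patch 48×48, batch 4, in 2D, which
suffices on phantoms.

Tiled prediction reflect-pads the volume by a halo (default 4× the
downsampling divisor) so tile borders see real context; tiled and
untiled predictions agree to float tolerance and the halo choice covers
the receptive field for the tested depths.

## Postprocessing

Vesicle/mitochondrion instances: (1) EDT of the complement of the
thresholded boundary map; (2) threshold these distances at the seed
distance and take connected components (26-connectivity) as seeds; (3)
heightmap = distance to the nearest seed; (4) mask = thresholded
foreground; (5) seeded watershed of the heightmap within the mask.
Presets: boundary 0.5 / seed distance 8 px (vesicles), 0.25 / 6 px
(mitochondria); foreground 0.5. One reading was open: whether the seed
components are restricted to the foreground mask. Unrestricted,
large background regions also exceed the seed distance and their seeds
capture the outer shell of every object; restricting seeds to the mask
is the only reading under which oracle maps reproduce the ground truth
exactly, so seeds are intersected with the mask. Instance count then
equals seed-component count, and the instances partition the mask.

Active zones: threshold 0.5, remove components strictly smaller than
500 voxels (a 500-voxel component is kept), return the binary mask.

Compartments: per-slice seeded watershed on the distance to the
thresholded boundary (or on the network's regressed distance channel
when present), then a graph over fragments in adjacent slices with edge
cost = overlap fraction (intersection over the smaller fragment) −
offset (default 0.5). The multicut objective is solved greedily by
contracting attractive edges in descending cost — an exact ILP is out of
scope, and the tests only assert cases where every correct solution
coincides. The contraction is symmetric in z, so reversing the stack
yields the same clustering.

Ribbon structures: the ribbon is the candidate component with the most
vesicles within the association distance (default 80 nm, the
ribbon-association criterion, exposed as a parameter); the PD is the
candidate closest to the chosen ribbon. Empty candidate masks yield
empty outputs with a warning rather than an error.

## Mean-teacher domain adaptation

Teacher and student share the pretrained architecture and weights. Per
iteration: sample unannotated target patches; sample an augmentation
(blur bandwidth ∈ [0, 2.5] px, additive noise ∈ [0, 15%] of the data
range); the teacher predicts pseudo-labels without gradients; the
confidence mask keeps voxels with p > t_c or p < 1 − t_c (strict,
channelwise; t_c = 0.75); the student minimizes the masked negative soft
Dice against the teacher's *continuous* probabilities (no binarization);
AdamW (fresh, lr 10⁻⁴) updates the student; the teacher follows as the
EMA w_t ← α w_t + (1 − α) w_s, α = 0.999. Batches with an empty mask
skip the gradient step and are logged. The returned model is the final
teacher.

Two design points deserve record:

- **Which view each network sees.** Assigning the *augmented* view to
  the teacher and the original to the student consistently degraded the
  student in our phantom experiments: where augmentation pushes a faint
  object below the teacher's confidence floor, the teacher becomes
  confidently wrong, and that error is distilled into the student's
  clean-view behaviour. The package therefore defaults to the standard
  consistency arrangement — teacher on the original view, student on the
  augmented view — under which the student is robustified across the
  augmentation family and the EMA teacher ensembles its trajectory; the
  alternative remains available as `teacher_view="augmented"`.
- **EMA horizon.** With α = 0.999 the teacher retains 0.999^T of its
  initial weights after T iterations; adaptation runs must be ≥ ~10³
  iterations for the teacher to reflect the student at all. The
  desk-scale experiment uses 1,000 iterations at batch 2.

Self-training can only help when the source model already finds most
target structures; when it confidently misses them, adaptation
reinforces the miss. This failure mode is best caught by inspection, so
`sanity_report` compares instance counts before/after adaptation. The
desk-scale adaptation experiment constructs a target domain with
genuinely different appearance (membrane contrast 0.10 vs 0.35 at
training, plus blur σ = 2 px and 10% noise): per-volume standardization
and ordinary training augmentation absorb blur/noise alone, so without
the appearance change a converged source model shows no domain gap to
close.

## Morphometry

Distances are surface-to-surface: per vesicle the minimum, over its
voxels, of the EDT of the structure complement, with per-axis voxel
sampling, in nm (0 for contact/overlap; an empty structure is an error
naming the structure). Diameters are twice the maximum interior EDT
(inscribed-sphere diameter; a single-voxel object gets 2 × voxel size by
the same convention); volumes are voxel counts × voxel volume. Pool
assignment applies inclusive thresholds ("within X nm") with precedence
docked → membrane-proximal → ribbon-associated → unassigned; docked
vesicles by construction also satisfy the membrane-proximal membrane
criterion. In the AZ workflow a vesicle is docked when its distance is
≤ 2 nm — one voxel at 1.554 nm, i.e. the 0–2 nm bin.

AZ surface area comes from a marching-cubes mesh of the (smoothed)
mask at iso-level 0.5 with voxel-size spacing. The default smoothing of
σ = 1 voxel suppresses the voxelization staircase that otherwise
inflates a digital sphere's area by ~8%; structures too thin to survive
smoothing (one-voxel sheets) are meshed raw. Mesh areas remain
convention-sensitive, so occupancy normalization also accepts an
externally supplied area. Occupancy histograms use half-open bins
(default edges 0, 5, 10, 20, 30, 40 nm) normalized per 0.01 µm².
Compartment restriction keeps the compartment overlapping the most
vesicle ids (ties to the lower id) and discards vesicles that do not
overlap it; an empty compartment map keeps everything with a warning.

## Metrics

Detection F1 matches objects with IoU strictly above the threshold
(default 0.5, where matching is unique) and reports
2·TP / (2·TP + FP + FN). Dice is 2|s∩a| / (|s| + |a|), defined as 1 for
two empty masks. Best dice averages, over ground-truth objects, the best
Dice against any predicted object; the directional (gt→seg) variant is
the default reported value and a min-symmetrized variant is provided —
the two coincide on identical inputs. Surface Dice skeletonizes both
masks (masks ≤ 2 voxels thick are their own skeleton, since thinning
would erase them), computes precision/recall as the fraction of skeleton
voxels within a tolerance (default 1 voxel) of the other skeleton, and
takes the harmonic mean. Aggregation reports the mean, with the SD once
five or more items contribute.

## Numerical and determinism notes

Connected components use full (26/8) connectivity; watershed ties are
resolved by scikit-image's deterministic scan order. All randomness
flows from explicit integer seeds (phantom placement, weight
initialization, patch sampling, augmentation), so phantoms, training
runs and segmentations are bit-reproducible for a given seed on the same
library stack. Float32 training means gradient checks use directional
finite differences at ~1% tolerance. Degenerate inputs are defined
rather than accidental: all-background maps segment to empty (not an
error), empty label volumes yield empty tables, both-empty masks score
Dice 1, and an empty adaptation target set is an error.

## Known limitations

The NumPy network stack is CPU-bound and desk-scale; it trains the
phantom tasks in minutes but is not suited to 10⁵-iteration production
training. The greedy multicut is a heuristic; adversarial overlap
configurations could be partitioned suboptimally. Phantom realism is
deliberately limited (see above), so phantom scores bound correctness of
the machinery, not expected accuracy on tomograms. The 2D training path
covers the 2D-micrograph use case; 3D training works but is slow beyond
small volumes.
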
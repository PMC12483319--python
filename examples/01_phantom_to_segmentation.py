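"""Segment a phantom tomogram with the distance-seeded watershed.

Builds a synthetic 3D tomogram of 25 synaptic vesicles, renders oracle
probability maps from the ground truth, runs the vesicle watershed
preset (boundary threshold 0.5, seed distance 8 px) and scores the
result against the known labels.
"""

import numpy as np

from synrec import (
    PhantomSpec,
    VESICLE_PRESET,
    best_dice,
    distance_watershed_instances,
    generate_phantom,
    matched_f1,
    render_oracle_maps,
)

spec = PhantomSpec(shape=(64, 128, 128), n_vesicles=25, seed=42)
volume, labels = generate_phantom(spec)
print(f"phantom: {volume.shape} voxels at {volume.voxel_size[0]:.3f} nm, "
      f"{labels['vesicles'].ids().size} vesicles")

maps = render_oracle_maps(labels["vesicles"])  # (foreground, boundary) channels
segmentation = distance_watershed_instances(maps, VESICLE_PRESET)
n_found = np.unique(segmentation[segmentation > 0]).size

f1, match = matched_f1(segmentation, labels["vesicles"].labels)
sbd = best_dice(segmentation, labels["vesicles"].labels)
print(f"instances found: {n_found}")
print(f"detection F1 @ IoU 0.5: {f1:.3f}  (TP {match.tp}, FP {match.fp}, FN {match.fn})")
print(f"best dice (morphological agreement): {sbd:.3f}")
# F1 of 1.0 means every vesicle was recovered with >50% overlap; best
# dice near 1 means the recovered shapes match the spheres themselves.
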
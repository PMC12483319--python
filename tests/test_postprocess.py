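import numpy as np
import pytest
from scipy import ndimage as ndi

from synrec import (
    MITOCHONDRION_PRESET,
    VESICLE_PRESET,
    CompartmentParams,
    WatershedParams,
    distance_watershed_instances,
    filter_ribbon_structures,
    matched_f1,
    render_oracle_maps,
    segment_active_zone,
    segment_compartments,
)
from synrec.phantoms import place_touching_pair


def test_watershed_splits_touching_spheres():
    lab = place_touching_pair((52, 52, 52), radius_vox=12, separation_factor=1.9)
    maps = render_oracle_maps(lab)
    seg = distance_watershed_instances(maps, VESICLE_PRESET)
    ids = np.unique(seg[seg > 0])
    assert ids.size == 2
    f1, res = matched_f1(seg, lab.labels)
    assert res.tp == 2 and f1 == 1.0


def test_watershed_single_sphere_equals_mask():
    from synrec import InstanceSegmentation

    lab = np.zeros((40, 40, 40), dtype=np.int32)
    idx = np.indices(lab.shape)
    lab[sum((idx[a] - 20) ** 2 for a in range(3)) <= 14**2] = 1
    maps = render_oracle_maps(InstanceSegmentation(lab, 1.0))
    seg = distance_watershed_instances(maps, VESICLE_PRESET)
    mask = maps[0] > 0.5
    assert np.unique(seg[seg > 0]).size == 1
    assert np.array_equal(seg > 0, mask)


def test_watershed_empty_input_and_missing_channel():
    maps = np.zeros((2, 16, 16, 16), dtype=np.float32)
    seg = distance_watershed_instances(maps, VESICLE_PRESET)
    assert seg.shape == (16, 16, 16) and seg.max() == 0
    with pytest.raises(ValueError):
        distance_watershed_instances(np.zeros((1, 8, 8, 8), dtype=np.float32))


def test_watershed_partition_and_seed_count(small_phantom):
    """Instances partition the mask exactly; one instance per seed component."""
    _, _, labels = small_phantom
    maps = render_oracle_maps(labels["vesicles"])
    params = VESICLE_PRESET
    seg = distance_watershed_instances(maps, params)
    mask = maps[0] > params.foreground_threshold
    assert np.array_equal(seg > 0, mask)  # union of instances == mask
    boundary = maps[1] > params.boundary_threshold
    dist = ndi.distance_transform_edt(~boundary)
    _, n_seeds = ndi.label((dist > params.seed_distance) & mask, structure=np.ones((3, 3, 3)))
    assert np.unique(seg[seg > 0]).size == n_seeds


def test_active_zone_size_filter():
    prob = np.zeros((10, 40, 40), dtype=np.float32)
    prob[2, :10, :40] = 0.9  # 400-voxel component
    prob[6, :15, :40] = 0.9  # 600-voxel component
    out = segment_active_zone(prob, threshold=0.5, min_size=500)
    comp, n = ndi.label(out)
    assert n == 1
    assert out[6].any() and not out[2].any()


def test_active_zone_boundary_semantics():
    prob = np.full((10, 10, 10), 0.49, dtype=np.float32)
    assert not segment_active_zone(prob).any()  # below threshold
    prob2 = np.zeros((10, 50, 10), dtype=np.float32)
    prob2[2, :50, :10] = 0.9  # exactly 500 voxels -> retained
    assert segment_active_zone(prob2, min_size=500).sum() == 500


def _stack_boundary_maps(nz, centers, shape=(64, 64), radius=16):
    """Boundary probability volume: compartment interiors are discs, all
    other space (walls and exterior) reads as boundary."""
    idx = np.indices(shape)
    bd2 = np.ones(shape, dtype=np.float32)
    for cy, cx in centers:
        d2 = (idx[0] - cy) ** 2 + (idx[1] - cx) ** 2
        bd2[d2 < (radius - 2) ** 2] = 0.0
    return np.broadcast_to(bd2, (nz,) + shape).copy()


def test_compartments_single_stack_merges_to_one():
    bd = _stack_boundary_maps(10, [(32, 32)])
    seg = segment_compartments(bd, CompartmentParams())
    inner = np.zeros((64, 64), dtype=bool)
    idx = np.indices((64, 64))
    inner[((idx[0] - 32) ** 2 + (idx[1] - 32) ** 2) < 13**2] = True
    ids = np.unique(seg[:, inner])
    ids = ids[ids > 0]
    assert ids.size == 1  # all 10 disc fragments merged into one 3D label


def test_compartments_two_disjoint_stacks():
    bd = _stack_boundary_maps(8, [(20, 20), (44, 44)])
    seg = segment_compartments(bd, CompartmentParams())
    idx = np.indices((64, 64))
    ids = set()
    for cy, cx in [(20, 20), (44, 44)]:
        inner = ((idx[0] - cy) ** 2 + (idx[1] - cx) ** 2) < 13**2
        got = np.unique(seg[:, inner])
        got = set(got[got > 0])
        assert len(got) == 1
        ids |= got
    assert len(ids) == 2


def test_compartments_zero_overlap_never_merged():
    # alternate slices with discs in non-overlapping positions
    a = _stack_boundary_maps(1, [(16, 16)])[0]
    b = _stack_boundary_maps(1, [(48, 48)])[0]
    bd = np.stack([a, b, a, b])
    seg = segment_compartments(bd, CompartmentParams())
    idx = np.indices((64, 64))
    in_a = ((idx[0] - 16) ** 2 + (idx[1] - 16) ** 2) < 13**2
    in_b = ((idx[0] - 48) ** 2 + (idx[1] - 48) ** 2) < 13**2
    ids_a = set(np.unique(seg[0][in_a])) | set(np.unique(seg[2][in_a]))
    ids_b = set(np.unique(seg[1][in_b])) | set(np.unique(seg[3][in_b]))
    assert not (ids_a - {0}) & (ids_b - {0})


def test_compartments_z_reversal_invariant():
    bd = _stack_boundary_maps(6, [(20, 20), (44, 44)])
    seg_fwd = segment_compartments(bd, CompartmentParams())
    seg_rev = segment_compartments(bd[::-1].copy(), CompartmentParams())[::-1]
    # same clustering up to relabeling
    pairs = set(zip(seg_fwd.ravel(), seg_rev.ravel()))
    fwd_ids = {p[0] for p in pairs}
    rev_ids = {p[1] for p in pairs}
    assert len(pairs) == max(len(fwd_ids), len(rev_ids))


def test_ribbon_filtering_most_vesicles_and_closest_pd(rng):
    shape = (24, 48, 48)
    ribbon_mask = np.zeros(shape, dtype=bool)
    ribbon_mask[8:12, 8:12, 8:12] = True  # candidate A
    ribbon_mask[8:12, 36:40, 36:40] = True  # candidate B
    vesicles = np.zeros(shape, dtype=np.int32)
    vid = 1
    for dz, dy, dx in [(0, 6, 0), (0, 0, 6), (6, 0, 0), (0, -5, 0), (0, 0, -5)]:
        vesicles[10 + dz, 10 + dy, 10 + dx] = vid  # near A
        vid += 1
    vesicles[10, 38, 30] = vid  # single vesicle near B
    pd_mask = np.zeros(shape, dtype=bool)
    pd_mask[14:16, 8:10, 8:10] = True  # 2-3 voxels from A
    pd_mask[20:22, 40:42, 40:42] = True  # far from A
    ribbon, pd = filter_ribbon_structures(
        ribbon_mask, pd_mask, vesicles, proximity_radius_nm=10.0, voxel_size=1.0
    )
    assert ribbon[8:12, 8:12, 8:12].all() and not ribbon[8:12, 36:40, 36:40].any()
    assert pd[14:16, 8:10, 8:10].all() and not pd[20:22, 40:42, 40:42].any()


def test_ribbon_filtering_empty_candidates():
    shape = (8, 8, 8)
    ves = np.zeros(shape, dtype=np.int32)
    with pytest.warns(UserWarning):
        ribbon, pd = filter_ribbon_structures(
            np.zeros(shape, bool), np.zeros(shape, bool), ves
        )
    assert not ribbon.any() and not pd.any()


def test_mitochondrion_preset_values():
    assert MITOCHONDRION_PRESET.boundary_threshold == 0.25
    assert MITOCHONDRION_PRESET.seed_distance == 6.0
    with pytest.raises(ValueError):
        WatershedParams(boundary_threshold=0.0)
    with pytest.raises(ValueError):
        WatershedParams(seed_distance=0.5)
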
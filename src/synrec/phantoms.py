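"""Synthetic tomogram phantoms with ground-truth labels.

The generator emulates the content of a presynaptic tomogram at the scale
of a vesicle-segmentation working resolution (default 1.554 nm voxels):
synaptic vesicles as dark membrane rings with a lighter lumen, a slab-like
active-zone membrane, an ellipsoidal mitochondrion, a dense ribbon with a
nearby presynaptic density, and stacked compartments. Every structure has
its own ground-truth label volume, so probability maps, postprocessing,
training and evaluation can all be exercised without real data.

Oracle probability maps rendered from the labels stand in for network
output; parameterized corruptions (blur / noise / gamma) emulate a domain
shift between imaging conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import find_boundaries

from .volumes import InstanceSegmentation, Volume

__all__ = [
    "PhantomSpec",
    "DomainShiftSpec",
    "generate_phantom",
    "place_touching_pair",
    "render_oracle_maps",
    "apply_domain_shift",
]

#: Background (cytosol) intensity of rendered phantoms, in [0, 1].
BACKGROUND_INTENSITY = 0.55
#: Vesicle lumen intensity before noise.
LUMEN_INTENSITY = 0.45
#: Membrane thickness of rendered vesicles in nm (~ bilayer + stain).
MEMBRANE_THICKNESS_NM = 3.5


@dataclass
class PhantomSpec:
    """Parameters of a phantom tomogram.

    Defaults describe a realistic presynaptic scene at 1.554 nm voxels:
    vesicle diameters of 32-48 nm, mild shot noise (5% of the intensity
    range) and a membrane contrast of 0.35 relative to a unit range.
    """

    shape: tuple[int, ...] = (64, 128, 128)
    voxel_size: float | tuple[float, ...] = 1.554
    n_vesicles: int = 25
    vesicle_radius_range: tuple[float, float] = (16.0, 24.0)  # nm
    structures: tuple[str, ...] = ()
    membrane_contrast: float = 0.35
    noise_sd: float = 0.05
    min_gap_nm: float = 3.0
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.n_vesicles < 0:
            raise ValueError("n_vesicles must be >= 0")
        lo, hi = self.vesicle_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid vesicle_radius_range")
        known = {
            "active_zone_slab",
            "mitochondrion",
            "ribbon",
            "presynaptic_density",
            "compartments",
        }
        unknown = set(self.structures) - known
        if unknown:
            raise ValueError(f"unknown structures: {sorted(unknown)}")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def voxel_size_array(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.voxel_size, dtype=np.float64), (self.ndim,)
        ).copy()


@dataclass
class DomainShiftSpec:
    """Deterministic corruption emulating a source-to-target domain shift.

    blur_sigma is in pixels, noise_scale a fraction of the data range,
    contrast_gamma a unitless exponent (1 = no change). The all-default
    spec is the identity.
    """

    blur_sigma: float = 0.0
    noise_scale: float = 0.0
    contrast_gamma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_sigma < 0 or self.noise_scale < 0 or self.contrast_gamma < 0:
            raise ValueError("domain-shift parameters must be non-negative")


def _sphere_mask(shape, center, radius_vox):
    """Boolean ball; radius_vox is per-axis (anisotropic voxels allowed)."""
    slices, grids = [], []
    for ax, (c, r) in enumerate(zip(center, radius_vox)):
        lo = max(int(np.floor(c - r)) - 1, 0)
        hi = min(int(np.ceil(c + r)) + 2, shape[ax])
        slices.append(slice(lo, hi))
        grids.append((np.arange(lo, hi) - c) / r)
    mesh = np.meshgrid(*grids, indexing="ij", sparse=True)
    mask = sum(g**2 for g in mesh) <= 1.0
    return tuple(slices), mask


def _paint_sphere(labels, intensity, center, radius_nm, voxel_size, label_id, spec):
    """Rasterize one vesicle: label = full ball, intensity = ring + lumen."""
    r_vox = radius_nm / voxel_size
    sl, grids = [], []
    for ax, (c, r) in enumerate(zip(center, r_vox)):
        lo = max(int(np.floor(c - r)) - 1, 0)
        hi = min(int(np.ceil(c + r)) + 2, labels.shape[ax])
        sl.append(slice(lo, hi))
        grids.append((np.arange(lo, hi) - c) * voxel_size[ax])  # nm from center
    sl = tuple(sl)
    mesh = np.meshgrid(*grids, indexing="ij", sparse=True)
    dist2 = sum(g**2 for g in mesh)
    ball = dist2 <= radius_nm**2
    inner = max(radius_nm - MEMBRANE_THICKNESS_NM, 0.0)
    lumen = dist2 <= inner**2
    labels[sl][ball] = label_id
    ring = ball & ~lumen
    intensity[sl][ring] = BACKGROUND_INTENSITY - spec.membrane_contrast
    intensity[sl][lumen] = LUMEN_INTENSITY


def _place_vesicles(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping sphere centers/radii (voxel units)."""
    shape = np.asarray(spec.shape, dtype=np.float64)
    vs = spec.voxel_size_array()
    lo, hi = spec.vesicle_radius_range
    placed = []  # (center_vox, radius_nm)
    for _ in range(spec.n_vesicles):
        ok = False
        for _try in range(spec.max_retries):
            radius = rng.uniform(lo, hi)
            margin = radius / vs + 1.0
            if np.any(shape - 2 * margin <= 0):
                continue
            center = np.array(
                [rng.uniform(m, s - m) for m, s in zip(margin, shape)]
            )
            for c2, r2 in placed:
                # distance in nm between centers must exceed the radii + gap
                d = np.linalg.norm((center - c2) * vs)
                if d < radius + r2 + spec.min_gap_nm:
                    break
            else:
                ok = True
                placed.append((center, radius))
                break
        if not ok:
            raise RuntimeError(
                f"could not place {spec.n_vesicles} non-overlapping vesicles "
                f"in shape {spec.shape} after {spec.max_retries} retries each"
            )
    return placed


def _render_structures(spec: PhantomSpec, intensity, out):
    """Paint non-vesicle structures and their label volumes."""
    shape = spec.shape
    vs = spec.voxel_size_array()
    nd = spec.ndim
    idx = np.indices(shape)

    def ellipsoid(center_frac, semi_axes_nm):
        center = np.asarray(center_frac) * (np.asarray(shape) - 1)
        semi = np.asarray(semi_axes_nm[:nd]) / vs
        q = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(nd))
        return q <= 1.0

    if "active_zone_slab" in spec.structures:
        # thin sheet near the low-y face, slightly tilted is unnecessary
        ax = nd - 2  # y axis
        pos = int(0.08 * shape[ax])
        thick = max(int(round(4.0 / vs[ax])), 2)
        mask = np.zeros(shape, dtype=bool)
        sl = [slice(None)] * nd
        sl[ax] = slice(pos, pos + thick)
        mask[tuple(sl)] = True
        out["active_zone"] = mask
        intensity[mask] = BACKGROUND_INTENSITY - spec.membrane_contrast

    if "mitochondrion" in spec.structures:
        semi = (60.0, 90.0, 60.0) if nd == 3 else (90.0, 60.0)
        mask = ellipsoid((0.75,) * nd, (semi if nd == 3 else (*semi, 0)))
        out["mitochondria"] = mask
        intensity[mask] = BACKGROUND_INTENSITY - 0.6 * spec.membrane_contrast

    if "ribbon" in spec.structures:
        center = (0.3, 0.45, 0.5)[:nd]
        mask = ellipsoid(center, (30.0, 40.0, 30.0))
        out["ribbon"] = mask
        intensity[mask] = BACKGROUND_INTENSITY - spec.membrane_contrast

    if "presynaptic_density" in spec.structures:
        center = (0.3, 0.10, 0.5)[:nd]
        mask = ellipsoid(center, (22.0, 12.0, 22.0))
        if "ribbon" in out:
            mask &= ~out["ribbon"]
        out["presynaptic_density"] = mask
        intensity[mask] = BACKGROUND_INTENSITY - 0.9 * spec.membrane_contrast

    if "compartments" in spec.structures:
        # two compartments stacked along y, separated by a membrane sheet
        ax = nd - 2
        cut = shape[ax] // 2
        comp = np.zeros(shape, dtype=np.int32)
        sl_lo, sl_hi = [slice(None)] * nd, [slice(None)] * nd
        sl_lo[ax] = slice(0, cut - 1)
        sl_hi[ax] = slice(cut + 1, shape[ax])
        comp[tuple(sl_lo)] = 1
        comp[tuple(sl_hi)] = 2
        out["compartments"] = comp
        sheet = [slice(None)] * nd
        sheet[ax] = slice(cut - 1, cut + 1)
        intensity[tuple(sheet)] = BACKGROUND_INTENSITY - spec.membrane_contrast


def generate_phantom(spec: PhantomSpec):
    """Generate a phantom tomogram and per-structure ground-truth labels.

    Returns
    -------
    vol : Volume
        Rendered intensity in roughly [0, 1] with additive Gaussian noise.
    labels : dict[str, InstanceSegmentation]
        Keys: ``vesicles`` always; other structures when requested
        (``active_zone``, ``mitochondria``, ``ribbon``,
        ``presynaptic_density``, ``compartments``).
    """
    rng = np.random.default_rng(spec.seed)
    vs = spec.voxel_size_array()
    intensity = np.full(spec.shape, BACKGROUND_INTENSITY, dtype=np.float32)
    ves_labels = np.zeros(spec.shape, dtype=np.int32)

    masks: dict[str, np.ndarray] = {}
    _render_structures(spec, intensity, masks)

    for i, (center, radius) in enumerate(_place_vesicles(spec, rng), start=1):
        _paint_sphere(ves_labels, intensity, center, radius, vs, i, spec)

    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(
            0.0, spec.noise_sd, size=spec.shape
        ).astype(np.float32)

    vol = Volume(intensity.astype(np.float32), vs, provenance=f"phantom(seed={spec.seed})")
    out = {"vesicles": InstanceSegmentation(ves_labels, vs)}
    for name, arr in masks.items():
        out[name] = InstanceSegmentation(arr.astype(np.int32), vs)
    return vol, out


def place_touching_pair(shape, radius_vox, separation_factor, voxel_size=1.554, axis=-1):
    """Two spheres with centers ``separation_factor * radius`` apart.

    For separation < 2 the spheres overlap; the lens is split by assigning
    each voxel to the nearer center, producing a touching two-object label
    image for watershed splitting tests.
    """
    shape = tuple(shape)
    nd = len(shape)
    center = (np.asarray(shape, dtype=np.float64) - 1) / 2
    offset = np.zeros(nd)
    offset[axis] = separation_factor * radius_vox / 2
    c1, c2 = center - offset, center + offset
    idx = np.indices(shape)
    d1 = sum((idx[a] - c1[a]) ** 2 for a in range(nd))
    d2 = sum((idx[a] - c2[a]) ** 2 for a in range(nd))
    labels = np.zeros(shape, dtype=np.int32)
    labels[(d1 <= radius_vox**2) & (d1 <= d2)] = 1
    labels[(d2 <= radius_vox**2) & (d2 < d1)] = 2
    return InstanceSegmentation(labels, np.full(nd, float(voxel_size)))


def render_oracle_maps(
    labels: InstanceSegmentation,
    rim_width: int = 1,
    softness: float = 0.0,
) -> np.ndarray:
    """Render idealized foreground/boundary probability maps from labels.

    The result stands in for network output: channel 0 is the foreground
    probability (1 inside any object), channel 1 the boundary probability,
    peaking on the rims between objects and between object and background.
    ``rim_width`` widens the rim; ``softness`` applies Gaussian smoothing
    (renormalized so the peak stays at 1).
    """
    if rim_width < 1:
        raise ValueError("rim_width must be >= 1")
    lab = labels.labels
    fg = (lab > 0).astype(np.float32)
    if lab.max() == 0:
        return np.zeros((2, *lab.shape), dtype=np.float32)
    rim = find_boundaries(lab, mode="thick")
    if rim_width > 1:
        rim = ndi.distance_transform_edt(~rim) < rim_width
    bd = rim.astype(np.float32)
    if softness > 0:
        for ch in (fg, bd):
            ndi.gaussian_filter(ch, softness, output=ch)
            peak = ch.max()
            if peak > 0:
                ch /= peak
    return np.stack([fg, bd])


def apply_domain_shift(vol: Volume, spec: DomainShiftSpec) -> Volume:
    """Corrupt a volume deterministically: blur, additive noise, gamma."""
    data = np.asarray(vol.data, dtype=np.float32)
    out = data.copy()
    if spec.blur_sigma > 0:
        out = ndi.gaussian_filter(out, spec.blur_sigma)
    rng = np.random.default_rng(spec.seed)
    drange = float(data.max() - data.min())
    if drange == 0.0:
        drange = 1.0  # constant input: fall back to a nominal unit range
    if spec.noise_scale > 0:
        out = out + rng.normal(0.0, spec.noise_scale * drange, size=out.shape).astype(
            np.float32
        )
    if spec.contrast_gamma not in (0.0, 1.0):
        lo, hi = float(out.min()), float(out.max())
        if hi > lo:
            norm = np.clip((out - lo) / (hi - lo), 0.0, 1.0)
            out = norm**spec.contrast_gamma * (hi - lo) + lo
    return Volume(out.astype(np.float32), vol.voxel_size, provenance=vol.provenance + "+shift")
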
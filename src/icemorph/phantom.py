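"""Synthetic frozen-porous-cake phantoms with exact ground-truth labels.

No raw tomogram of the frozen sponge cake is publicly deposited, so every
quantitative test in this package runs against synthetic volumes whose phase
composition is known by construction. A phantom emulates the salient
microstructural features of a frozen, highly porous starch matrix:

* a connected multi-scale pore space (macropores ~0.1–1 mm in the real
  product), modelled as a thresholded Gaussian random field;
* a wall-conformal ice layer lining the pore surfaces — thin for fast
  freezing, 20–30 µm thick for slow freezing;
* prismatic (cuboid) ice crystals 20–100 µm in edge length embedded in the
  matrix — many small ones for fast freezing, fewer large ones for slow;
* three well-separated grey-level modes (air darkest, ice intermediate,
  starch brightest) with additive Gaussian noise and an optional blur.

The generator is fully deterministic given the spec's seed: a single RNG is
seeded once per phantom and sub-steps draw from it in a fixed order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy import ndimage

from .volio import AIR, ICE_OUTSIDE, ICE_INSIDE, STARCH, GreyVolume, LabelVolume

__all__ = [
    "PhantomSpec",
    "PhantomVolume",
    "fast_freezing_spec",
    "slow_freezing_spec",
    "unfrozen_spec",
    "generate_pore_space",
    "deposit_wall_ice",
    "seed_internal_crystals",
    "render_greyscale",
    "generate_phantom",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of a synthetic frozen-porous volume.

    Lengths are physical (µm); ``shape`` is in voxels, ``(z, y, x)``.
    """

    shape: tuple[int, int, int] = (200, 200, 200)
    voxel_size: float = 2.0
    target_porosity: float = 0.60
    pore_scale: float = 100.0
    wall_ice_thickness: float = 0.0
    n_crystals: int = 0
    crystal_size_range: tuple[float, float] = (20.0, 100.0)
    grey_means: tuple[float, float, float] = (50.0, 120.0, 200.0)
    noise_sigma: float = 0.0
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_porosity < 1.0:
            raise ValueError("target_porosity must be in (0, 1)")
        a, i, s = self.grey_means
        if not a < i < s:
            raise ValueError("grey_means must be strictly increasing (air < ice < starch)")
        if self.wall_ice_thickness < 0:
            raise ValueError("wall_ice_thickness must be >= 0")
        if self.voxel_size <= 0 or self.pore_scale <= 0:
            raise ValueError("voxel_size and pore_scale must be > 0")
        lo, hi = self.crystal_size_range
        if not 0 < lo <= hi:
            raise ValueError("crystal_size_range must satisfy 0 < min <= max")
        if self.n_crystals < 0:
            raise ValueError("n_crystals must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomVolume:
    """A rendered phantom: grey tomogram + exact ground-truth labels + its spec."""

    grey: GreyVolume
    truth: LabelVolume
    spec: PhantomSpec

    def truth_counts(self) -> dict[str, int]:
        """Exact voxel count per phase, by direct counting on the truth labels."""
        counts = np.bincount(self.truth.data.ravel(), minlength=4)
        return {
            "air": int(counts[AIR]),
            "ice_outside": int(counts[ICE_OUTSIDE]),
            "ice_inside": int(counts[ICE_INSIDE]),
            "starch": int(counts[STARCH]),
        }


def _scaled_preset(base: PhantomSpec, overrides: dict) -> PhantomSpec:
    """Apply overrides, scaling the preset crystal count with volume so the
    crystal number density stays that of the default 200^3 domain."""
    spec = replace(base, **overrides)
    if "shape" in overrides and "n_crystals" not in overrides:
        ratio = np.prod(spec.shape) / np.prod(base.shape)
        spec = replace(spec, n_crystals=int(round(base.n_crystals * ratio)))
    return spec


def fast_freezing_spec(**overrides) -> PhantomSpec:
    """Fast-freezing regime: thin wall ice, many small embedded crystals.

    Mirrors the fast-frozen microstructure: a thin conformal ice film on the
    pore walls and a homogeneous population of small intramatrix crystals, so
    most of the ice sits inside the matrix.
    """
    base = PhantomSpec(
        wall_ice_thickness=4.0,
        n_crystals=400,
        crystal_size_range=(20.0, 45.0),
        noise_sigma=8.0,
        blur_sigma=1.0,
        seed=101,
    )
    return _scaled_preset(base, overrides)


def slow_freezing_spec(**overrides) -> PhantomSpec:
    """Slow-freezing regime: thick (20–30 µm) wall ice, fewer large crystals."""
    base = PhantomSpec(
        wall_ice_thickness=25.0,
        n_crystals=150,
        crystal_size_range=(30.0, 60.0),
        noise_sigma=8.0,
        blur_sigma=1.0,
        seed=202,
    )
    return _scaled_preset(base, overrides)


def unfrozen_spec(**overrides) -> PhantomSpec:
    """Unfrozen regime: no ice at all, air/starch only."""
    base = PhantomSpec(wall_ice_thickness=0.0, n_crystals=0, noise_sigma=8.0,
                       blur_sigma=1.0, seed=303)
    return replace(base, **overrides)


def generate_pore_space(spec: PhantomSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Generate the solid/air partition as a thresholded Gaussian random field.

    A white-noise field is smoothed with a Gaussian kernel whose standard
    deviation is ``pore_scale / (2 * voxel_size)`` voxels, giving connected
    blobs whose typical diameter is about one pore scale, and thresholded at
    the empirical ``target_porosity`` quantile so the air fraction matches the
    target almost exactly. Returns the boolean *solid* mask.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sigma_vx = spec.pore_scale / (2.0 * spec.voxel_size)
    if sigma_vx >= min(spec.shape) / 2:
        raise ValueError(
            f"pore_scale {spec.pore_scale} µm too large for shape {spec.shape} "
            f"at {spec.voxel_size} µm/vx; porosity target cannot be realised"
        )
    field = rng.standard_normal(spec.shape)
    field = ndimage.gaussian_filter(field, sigma_vx, mode="reflect")
    threshold = np.quantile(field, spec.target_porosity)
    solid = field >= threshold
    air_fraction = 1.0 - solid.mean()
    if abs(air_fraction - spec.target_porosity) > 0.02:
        raise ValueError(
            f"achieved air fraction {air_fraction:.3f} deviates from target "
            f"{spec.target_porosity:.3f} by more than 0.02 (degenerate field?)"
        )
    return solid


def deposit_wall_ice(solid_mask: np.ndarray, thickness_um: float, voxel_size: float) -> np.ndarray:
    """Deposit a conformal ice shell on the air side of every solid surface.

    The shell is the set of air voxels within ``round(thickness_um/voxel_size)``
    voxels (Euclidean distance) of the solid; it is disjoint from the solid by
    construction. Emits a warning if the shell closes off most of the pore
    space (thickness exceeding the pore radius).
    """
    if thickness_um < 0:
        raise ValueError("thickness_um must be >= 0")
    t_vx = int(round(thickness_um / voxel_size))
    if t_vx == 0:
        return np.zeros_like(solid_mask, dtype=bool)
    dist = ndimage.distance_transform_edt(~solid_mask)
    ice_out = (~solid_mask) & (dist <= t_vx)
    air_before = int((~solid_mask).sum())
    air_after = air_before - int(ice_out.sum())
    if air_before and air_after < 0.05 * air_before:
        warnings.warn(
            f"wall ice of {thickness_um} µm closes nearly all pores "
            f"({air_after}/{air_before} air voxels remain)",
            stacklevel=2,
        )
    return ice_out


def seed_internal_crystals(
    solid_mask: np.ndarray,
    n: int,
    size_range: tuple[float, float],
    voxel_size: float,
    rng: np.random.Generator,
    margin_vx: int = 0,
) -> np.ndarray:
    """Embed ``n`` axis-aligned cuboid ice crystals in the solid matrix.

    Crystal centers are drawn uniformly from the solid voxels (crystals grow
    embedded in the matrix); edge lengths are drawn independently per axis,
    uniformly in ``size_range`` (µm). Cuboids are clipped to the solid mask
    (eroded by ``margin_vx`` voxels when set, keeping crystals strictly
    intramatrix), so the returned mask is a subset of the solid mask.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    crystals = np.zeros_like(solid_mask, dtype=bool)
    if n == 0:
        return crystals
    shape = solid_mask.shape
    clip_mask = solid_mask
    if margin_vx > 0:
        clip_mask = ndimage.distance_transform_edt(solid_mask) > margin_vx
    solid_idx = np.flatnonzero(clip_mask)
    if solid_idx.size == 0:
        warnings.warn("no solid voxels: crystals cannot be seeded", stacklevel=2)
        return crystals
    lo, hi = size_range
    for _ in range(n):
        center = np.unravel_index(solid_idx[rng.integers(0, solid_idx.size)], shape)
        edges_vx = np.maximum(1, np.round(rng.uniform(lo, hi, size=3) / voxel_size).astype(int))
        sl = tuple(
            slice(max(0, c - e // 2), min(s, c - e // 2 + e))
            for c, e, s in zip(center, edges_vx, shape)
        )
        crystals[sl] = True
    return crystals & clip_mask


def render_greyscale(
    truth: LabelVolume,
    grey_means: tuple[float, float, float],
    noise_sigma: float,
    blur_sigma: float,
    rng: np.random.Generator,
) -> GreyVolume:
    """Render a grey-level tomogram from truth labels.

    Each voxel takes the mean intensity of its phase (both ice phases share
    the ice mean), plus i.i.d. Gaussian noise, then an optional Gaussian blur
    (``blur_sigma`` in µm) emulating the finite imaging point-spread.
    """
    mean_air, mean_ice, mean_starch = grey_means
    if not mean_air < mean_ice < mean_starch:
        raise ValueError("grey_means must be strictly increasing (air < ice < starch)")
    lut = np.array([mean_air, mean_ice, mean_ice, mean_starch], dtype=np.float32)
    grey = lut[truth.data]
    if noise_sigma > 0:
        grey = grey + rng.normal(0.0, noise_sigma, size=grey.shape).astype(np.float32)
    if blur_sigma > 0:
        grey = ndimage.gaussian_filter(grey, blur_sigma / truth.voxel_size)
    return GreyVolume(grey.astype(np.float32), truth.voxel_size)


def generate_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Generate a complete phantom: pore space, wall ice, crystals, rendering.

    Draw order from the single per-phantom RNG is fixed (pore field, crystal
    placement, rendering noise), so identical specs give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    solid = generate_pore_space(spec, rng)
    ice_out = deposit_wall_ice(solid, spec.wall_ice_thickness, spec.voxel_size)
    ice_in = seed_internal_crystals(
        solid, spec.n_crystals, spec.crystal_size_range, spec.voxel_size, rng,
        margin_vx=2,
    )
    labels = np.full(spec.shape, AIR, dtype=np.uint8)
    labels[solid] = STARCH
    labels[ice_in] = ICE_INSIDE
    labels[ice_out] = ICE_OUTSIDE
    truth = LabelVolume(labels, spec.voxel_size)
    grey = render_greyscale(truth, spec.grey_means, spec.noise_sigma, spec.blur_sigma, rng)
    return PhantomVolume(grey=grey, truth=truth, spec=spec)
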
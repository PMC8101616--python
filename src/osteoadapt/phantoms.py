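"""Seeded synthetic phantoms: verification tubes and a reduced mouse-tibia stand-in.

Every downstream stage (segmentation, morphometry, micro-FE, strain
statistics) is testable against these generators without any scan data.
The tibia phantom is an idealised straight bone on a 10 um isotropic grid:
a hollow diaphyseal shaft distally and a flared metaphyseal shell with
trabecular interior proximally, plus an explicit growth-plate reference
slice.  Trabecular microstructure is a thresholded smoothed Gaussian random
field whose threshold is tuned so the connected solid phase matches a target
bone volume fraction.  Geometry is synthetic and reduced in scale; it is a
test substrate, not an anatomical model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import Calibration, VoxelVolume

__all__ = [
    "PhantomSpec",
    "make_tube_phantom",
    "make_elliptical_tube_phantom",
    "make_plate_phantom",
    "make_trabecular_phantom",
    "make_synthetic_tibia",
    "add_imaging_noise",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic tibia generator.

    Lengths/radii in mm, densities in g HA/cm^3, voxel size in um.  Densities
    default above the 0.41/0.34 segmentation thresholds so both compartments
    segment cleanly; blur/noise default to a mild imaging emulation.
    """

    total_length: float = 1.2
    diaphysis_outer_radius: float = 0.18
    diaphysis_inner_radius: float = 0.13
    metaphysis_length_fraction: float = 0.30
    metaphysis_outer_radius: float = 0.23
    metaphysis_shell_thickness: float = 0.04
    growth_plate_position: float = 0.06
    cortical_density: float = 1.0
    trabecular_density: float = 0.75
    target_bvtv: float = 25.0
    trabecular_feature_size: float = 0.04
    voxel_size: float = 10.0
    blur_sigma: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.diaphysis_inner_radius < self.diaphysis_outer_radius:
            raise ValueError("diaphysis inner radius must be < outer radius")
        if not 0 < self.metaphysis_length_fraction < 1:
            raise ValueError("metaphysis_length_fraction must lie in (0, 1)")
        if not 0 < self.growth_plate_position < 1:
            raise ValueError("growth_plate_position must lie in (0, 1)")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be > 0")
        if not 0 < self.target_bvtv < 100:
            raise ValueError("target_bvtv must lie in (0, 100)")


def _disk_mask(ny: int, nx: int, radius_vox: float) -> np.ndarray:
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    y, x = np.ogrid[:ny, :nx]
    return (y - cy) ** 2 + (x - cx) ** 2 <= radius_vox**2


def make_tube_phantom(
    outer_radius: float,
    inner_radius: float,
    length: float,
    density: float = 1.0,
    voxel_size: float = 10.0,
    pad: int = 2,
) -> VoxelVolume:
    """Axis-aligned hollow cylinder; the workhorse verification shape.

    Voxels whose centers fall inside the annulus carry ``density``; the
    background is 0.  ``inner_radius = 0`` degenerates to a solid cylinder.
    """
    if not (outer_radius > inner_radius >= 0):
        raise ValueError("need outer_radius > inner_radius >= 0")
    if not (length > 0 and voxel_size > 0):
        raise ValueError("length and voxel_size must be > 0")
    h = voxel_size / 1000.0  # mm
    r_out_vox = outer_radius / h
    nxy = int(np.ceil(2 * r_out_vox)) + 2 * pad
    nz = int(round(length / h))
    if nz < 1:
        raise ValueError("length shorter than one voxel")
    outer = _disk_mask(nxy, nxy, r_out_vox)
    annulus = outer & ~_disk_mask(nxy, nxy, inner_radius / h) if inner_radius > 0 else outer
    if annulus[0].any() or annulus[-1].any() or annulus[:, 0].any() or annulus[:, -1].any():
        raise ValueError("tube radius exceeds the field of view; refusing to crop")
    vol = np.zeros((nz, nxy, nxy), dtype=np.float32)
    vol[:, annulus] = density
    return VoxelVolume(values=vol, voxel_size=voxel_size, calibration=Calibration())


def make_elliptical_tube_phantom(
    a_outer: float,
    b_outer: float,
    thickness: float,
    length: float,
    density: float = 1.0,
    voxel_size: float = 10.0,
    pad: int = 2,
) -> VoxelVolume:
    """Thin elliptical shell (semi-axes ``a_outer`` x, ``b_outer`` y), for
    verifying principal second moments on a non-circular section."""
    h = voxel_size / 1000.0
    nx = int(np.ceil(2 * a_outer / h)) + 2 * pad
    ny = int(np.ceil(2 * b_outer / h)) + 2 * pad
    nz = int(round(length / h))
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    y, x = np.ogrid[:ny, :nx]
    xm, ym = (x - cx) * h, (y - cy) * h

    def inside(a: float, b: float) -> np.ndarray:
        return (xm / a) ** 2 + (ym / b) ** 2 <= 1.0

    shell = inside(a_outer, b_outer) & ~inside(a_outer - thickness, b_outer - thickness)
    vol = np.zeros((nz, ny, nx), dtype=np.float32)
    vol[:, shell] = density
    return VoxelVolume(values=vol, voxel_size=voxel_size, calibration=Calibration())


def make_plate_phantom(
    plate_thickness: float,
    plate_spacing: float,
    n_plates: int = 4,
    lateral_extent: float = 0.6,
    density: float = 1.0,
    voxel_size: float = 10.0,
) -> VoxelVolume:
    """Parallel plates stacked along z (thickness/spacing in mm): the analytic
    reference for trabecular thickness and separation."""
    h = voxel_size / 1000.0
    t_vox = int(round(plate_thickness / h))
    s_vox = int(round(plate_spacing / h))
    nxy = int(round(lateral_extent / h))
    nz = n_plates * t_vox + (n_plates - 1) * s_vox
    vol = np.zeros((nz, nxy, nxy), dtype=np.float32)
    for i in range(n_plates):
        z0 = i * (t_vox + s_vox)
        vol[z0 : z0 + t_vox] = density
    return VoxelVolume(values=vol, voxel_size=voxel_size, calibration=Calibration())


def _threshold_for_fraction(field: np.ndarray, domain: np.ndarray, frac: float) -> float:
    """Threshold such that (field >= t) covers ``frac`` of ``domain``."""
    return float(np.quantile(field[domain], 1.0 - frac))


def _connected_to_shell(solid: np.ndarray, shell: np.ndarray) -> np.ndarray:
    """Keep solid components face-connected to the bounding shell."""
    lab, n = ndimage.label(solid | shell)
    if n == 0:
        return solid
    keep = np.unique(lab[shell])
    keep = keep[keep > 0]
    return solid & np.isin(lab, keep)


def make_trabecular_phantom(spec: PhantomSpec, shape: tuple[int, int, int] | None = None) -> VoxelVolume:
    """Porous trabecular cube: thresholded smoothed Gaussian random field.

    The threshold is chosen (by bisection on the post-cleanup structure) so
    the solid fraction of the interior matches ``spec.target_bvtv`` within
    0.25 percentage points; small components disconnected from the bounding
    one-voxel shell are removed.  Deterministic for a fixed seed.
    """
    if shape is None:
        n = max(24, int(round(8 * spec.trabecular_feature_size * 1000.0 / spec.voxel_size)))
        shape = (n, n, n)
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(shape)
    sigma = max(0.5, spec.trabecular_feature_size * 1000.0 / spec.voxel_size / 2.0)
    field = ndimage.gaussian_filter(noise, sigma, mode="wrap")

    shell = np.ones(shape, dtype=bool)
    shell[1:-1, 1:-1, 1:-1] = False
    interior = ~shell
    target = spec.target_bvtv / 100.0

    def achieved(frac: float) -> tuple[float, np.ndarray]:
        t = _threshold_for_fraction(field, interior, frac)
        solid = (field >= t) & interior
        solid = _connected_to_shell(solid, shell)
        return solid[interior].mean(), solid

    lo, hi = target, min(0.999, target * 1.6 + 0.05)
    frac = target
    bv, solid = achieved(frac)
    for _ in range(30):
        if abs(bv - target) < 0.0025:
            break
        if bv < target:
            lo = frac
        else:
            hi = frac
        frac = 0.5 * (lo + hi)
        bv, solid = achieved(frac)
    else:
        raise ValueError(
            f"target BV/TV {spec.target_bvtv}% unreachable at feature size "
            f"{spec.trabecular_feature_size} mm (achieved {100*bv:.1f}%)"
        )

    vol = np.zeros(shape, dtype=np.float32)
    vol[shell] = spec.cortical_density
    vol[solid] = spec.trabecular_density
    return VoxelVolume(values=vol, voxel_size=spec.voxel_size, calibration=Calibration())


def make_synthetic_tibia(spec: PhantomSpec) -> tuple[VoxelVolume, int]:
    """Reduced straight-tibia phantom with an explicit growth-plate reference.

    Proximal (low z): a dense growth-plate cap, then a metaphyseal cortical
    shell with trabecular interior; distal: a hollow diaphysis.  Returns the
    volume and the growth-plate reference slice index.  Phases before noise
    are exactly {0, cortical_density, trabecular_density}.
    """
    h = spec.voxel_size / 1000.0
    nz = int(round(spec.total_length / h))
    r_out = max(spec.metaphysis_outer_radius, spec.diaphysis_outer_radius)
    nxy = int(np.ceil(2 * r_out / h)) + 4

    gp_slice = int(round(spec.growth_plate_position * nz))
    n_meta = int(round(spec.metaphysis_length_fraction * nz))
    meta_end = gp_slice + 1 + n_meta
    # the 10%-of-length cancellous VOI must fit inside the metaphysis
    if n_meta < int(np.ceil(0.10 * nz)) or meta_end >= nz:
        raise ValueError(
            "metaphysis_length_fraction leaves less than 10% of bone length "
            "distal to the growth plate"
        )

    vol = np.zeros((nz, nxy, nxy), dtype=np.float32)

    meta_outer = _disk_mask(nxy, nxy, spec.metaphysis_outer_radius / h)
    meta_inner = _disk_mask(
        nxy, nxy, (spec.metaphysis_outer_radius - spec.metaphysis_shell_thickness) / h
    )
    meta_shell = meta_outer & ~meta_inner
    dia = _disk_mask(nxy, nxy, spec.diaphysis_outer_radius / h) & ~_disk_mask(
        nxy, nxy, spec.diaphysis_inner_radius / h
    )

    # growth-plate cap: solid disc spanning slices [0, gp_slice]
    vol[: gp_slice + 1, meta_outer] = spec.cortical_density

    # metaphysis: shell + trabecular interior
    interior_shape = (n_meta, nxy, nxy)
    rng_spec = spec
    trab = _trabecular_field(rng_spec, interior_shape, meta_inner)
    for i, z in enumerate(range(gp_slice + 1, meta_end)):
        vol[z][meta_shell] = spec.cortical_density
        vol[z][trab[i]] = spec.trabecular_density

    # diaphysis
    vol[meta_end:, dia] = spec.cortical_density

    out = VoxelVolume(values=vol, voxel_size=spec.voxel_size, calibration=Calibration())
    if spec.blur_sigma > 0 or spec.noise_sd > 0:
        out = add_imaging_noise(out, spec.blur_sigma, spec.noise_sd, seed=spec.seed + 1)
    return out, gp_slice


def _trabecular_field(
    spec: PhantomSpec, shape: tuple[int, int, int], interior2d: np.ndarray
) -> np.ndarray:
    """Trabecular solid mask inside a cylindrical interior, tuned to target BV/TV
    and connected to the surrounding shell."""
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(shape)
    sigma = max(0.5, spec.trabecular_feature_size * 1000.0 / spec.voxel_size / 2.0)
    field = ndimage.gaussian_filter(noise, sigma, mode="nearest")
    domain = np.broadcast_to(interior2d, shape)
    shell3d = np.broadcast_to(ndimage.binary_dilation(interior2d) & ~interior2d, shape)
    target = spec.target_bvtv / 100.0

    def achieved(frac: float) -> tuple[float, np.ndarray]:
        t = _threshold_for_fraction(field, domain, frac)
        solid = (field >= t) & domain
        solid = _connected_to_shell(solid, shell3d)
        return solid[domain].mean(), solid

    lo, hi = target, min(0.999, target * 1.8 + 0.05)
    frac = target
    bv, solid = achieved(frac)
    for _ in range(30):
        if abs(bv - target) < 0.0025:
            return solid
        if bv < target:
            lo = frac
        else:
            hi = frac
        frac = 0.5 * (lo + hi)
        bv, solid = achieved(frac)
    raise ValueError(
        f"target BV/TV {spec.target_bvtv}% unreachable at feature size "
        f"{spec.trabecular_feature_size} mm (achieved {100*bv:.1f}%)"
    )


def add_imaging_noise(
    vol: VoxelVolume, blur_sigma: float, noise_sd: float, seed: int
) -> VoxelVolume:
    """Partial-volume blur (Gaussian, sigma in voxels) then additive zero-mean
    Gaussian detector noise (SD in g HA/cm^3).  Identity at (0, 0)."""
    if blur_sigma < 0 or noise_sd < 0:
        raise ValueError("blur_sigma and noise_sd must be >= 0")
    data = np.asarray(vol.values, dtype=np.float32)
    if blur_sigma > 0:
        data = ndimage.gaussian_filter(data, blur_sigma, mode="nearest")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape).astype(np.float32)
    return VoxelVolume(values=data, voxel_size=vol.voxel_size, calibration=vol.calibration)
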
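"""Calibrated voxel volumes: I/O, segmentation, bone length, and VOI extraction.

The analysis substrate is a 3D grayscale microCT-like volume calibrated to
mineral density (g HA/cm^3).  The image z-axis is the bone's long axis,
oriented proximal (slice 0) to distal; all volume-of-interest (VOI) extents
are fractions of *bone length* measured along z, never of image extent.

Segmentation follows the conventional fixed-threshold scheme for the mouse
tibia: 0.34 g HA/cm^3 for midshaft cortical bone and 0.41 g HA/cm^3 for
proximal cancellous bone.  Thresholding is inclusive (value >= threshold).
Slice ranges are 0-based and half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "Calibration",
    "VoxelVolume",
    "BoneMask",
    "VOISpec",
    "CORTICAL_THRESHOLD",
    "CANCELLOUS_THRESHOLD",
    "read_volume",
    "write_volume",
    "segment",
    "bone_length",
    "extract_voi",
]

#: Default segmentation thresholds in g HA/cm^3.
CORTICAL_THRESHOLD = 0.34
CANCELLOUS_THRESHOLD = 0.41


@dataclass(frozen=True)
class Calibration:
    """Affine grayscale -> mineral density map: density = slope * gray + intercept."""

    slope: float = 1.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")

    def apply(self, gray: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(gray, dtype=np.float32) + self.intercept


@dataclass
class VoxelVolume:
    """A calibrated 3D image with isotropic voxels.

    Parameters
    ----------
    values
        3D array indexed [z, y, x], in g HA/cm^3 after calibration.
    voxel_size
        Isotropic voxel edge length in micrometres.
    calibration
        The grayscale -> density map that produced ``values``.
    axis_order
        Fixed tag; z is the proximal->distal bone axis.
    """

    values: np.ndarray
    voxel_size: float
    calibration: Calibration = field(default_factory=Calibration)
    axis_order: str = "zyx"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("VoxelVolume requires a 3D array")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be > 0")
        if self.axis_order != "zyx":
            raise ValueError("only the zyx axis convention is supported")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size / 1000.0


@dataclass
class BoneMask:
    """Binary mask aligned with a :class:`VoxelVolume`.

    ``region`` optionally carries the total-volume (TV) reference region for
    cancellous indices: the endocortical interior of a peeled VOI.  When
    absent, TV defaults to the whole mask array extent.
    """

    values: np.ndarray
    voxel_size: float
    threshold_used: Optional[float] = None
    compartment: str = "whole"
    region: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("BoneMask requires a 3D array")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be > 0")
        if self.compartment not in ("cortical", "cancellous", "whole"):
            raise ValueError(f"unknown compartment {self.compartment!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size / 1000.0

    def count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class VOISpec:
    """A z-slab VOI defined as a fraction of bone length.

    ``region``: ``midshaft_cortical`` (anchored at the bone-length midpoint),
    ``proximal_cancellous`` or ``proximal_cortico_cancellous`` (anchored just
    distal to the growth-plate reference slice).
    """

    region: str
    extent_fraction: float

    _REGIONS = ("midshaft_cortical", "proximal_cancellous", "proximal_cortico_cancellous")

    def __post_init__(self) -> None:
        if self.region not in self._REGIONS:
            raise ValueError(f"unknown VOI region {self.region!r}")
        if not 0 < self.extent_fraction < 1:
            raise ValueError("extent_fraction must lie in (0, 1)")

    @classmethod
    def midshaft(cls, extent_fraction: float = 0.025) -> "VOISpec":
        return cls("midshaft_cortical", extent_fraction)

    @classmethod
    def proximal_cancellous(cls, extent_fraction: float = 0.10) -> "VOISpec":
        return cls("proximal_cancellous", extent_fraction)

    @classmethod
    def proximal_cortico_cancellous(cls, extent_fraction: float = 0.10) -> "VOISpec":
        return cls("proximal_cortico_cancellous", extent_fraction)

    @classmethod
    def from_dict(cls, d: dict) -> "VOISpec":
        return cls(region=d["region"], extent_fraction=float(d["extent_fraction"]))


# ---------------------------------------------------------------------------
# I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_name(path.with_suffix("").name + ".calib.yaml")


def write_volume(vol: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as multipage TIFF or MetaImage (.mhd/.raw).

    Density values are stored as float32; voxel size and calibration go to a
    ``<stem>.calib.yaml`` sidecar so that read(write(v)) round-trips both the
    array (bit-exactly) and the metadata.
    """
    path = Path(path)
    data = np.asarray(vol.values, dtype=np.float32)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    elif suffix == ".mhd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data)
        s = vol.voxel_size_mm
        img.SetSpacing((s, s, s))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format {suffix!r} (use .tif/.tiff/.mhd)")
    sidecar = {
        "voxel_size_um": float(vol.voxel_size),
        "calibration": {
            "slope": float(vol.calibration.slope),
            "intercept": float(vol.calibration.intercept),
        },
        "values_are": "density_gHA_cm3",
        "axis_order": vol.axis_order,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar))
    return path


def read_volume(
    path: str | Path,
    calibration: Optional[Calibration] = None,
    voxel_size: Optional[float] = None,
) -> VoxelVolume:
    """Read a TIFF or MetaImage volume written by :func:`write_volume`.

    A sidecar YAML (or explicit arguments) must provide the calibration; raw
    grayscale volumes without one are rejected rather than silently assumed
    calibrated.  Anisotropic MetaImage spacing is an error.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    meta = yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}

    if calibration is None:
        if "calibration" not in meta:
            raise ValueError(
                f"missing calibration for {path.name}: no sidecar field 'calibration' "
                "and no explicit calibration argument"
            )
        calibration = Calibration(**meta["calibration"])

    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
        if voxel_size is None:
            if "voxel_size_um" not in meta:
                raise ValueError(f"missing voxel_size_um for {path.name}")
            voxel_size = float(meta["voxel_size_um"])
    elif suffix == ".mhd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        spacing = np.array(img.GetSpacing())
        if not np.allclose(spacing, spacing[0], rtol=1e-6):
            raise ValueError(f"anisotropic voxels {tuple(spacing)} are not supported")
        data = sitk.GetArrayFromImage(img)
        voxel_size = float(spacing[0] * 1000.0)
    else:
        raise ValueError(f"unsupported volume format {suffix!r}")

    if data.ndim == 2:
        data = data[None]
    if meta.get("values_are", "density_gHA_cm3") != "density_gHA_cm3":
        data = calibration.apply(data)
    return VoxelVolume(values=data, voxel_size=float(voxel_size), calibration=calibration)


# ---------------------------------------------------------------------------
# Segmentation and geometry


def segment(vol: VoxelVolume, threshold: float, compartment: str = "whole") -> BoneMask:
    """Fixed-threshold segmentation: bone where density >= threshold."""
    mask = vol.values >= threshold
    if not mask.any():
        warnings.warn(
            f"segmentation at {threshold} g HA/cm^3 produced an empty mask",
            stacklevel=2,
        )
    return BoneMask(
        values=mask,
        voxel_size=vol.voxel_size,
        threshold_used=threshold,
        compartment=compartment,
    )


def _occupied_z(mask: BoneMask) -> np.ndarray:
    return np.flatnonzero(mask.values.any(axis=(1, 2)))


def bone_length(mask: BoneMask) -> float:
    """Bone length in mm: occupied z-extent (inclusive) times voxel size."""
    occ = _occupied_z(mask)
    if occ.size == 0:
        raise ValueError("bone_length of an empty mask is undefined")
    return float((occ[-1] - occ[0] + 1) * mask.voxel_size_mm)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _peel_cortex_slice(bone2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove the outermost cortical shell of one slice.

    The slice is eroded by one voxel (the erosion margin) so that thin
    in-plane bridges between trabeculae and the shell break; the outermost
    connected component of the eroded image — the one adjacent to the outside
    background (background connected to the slice border) — is dilated back
    and removed as cortex.  Returns (trabecular bone, interior TV region);
    the interior excludes the cortex plus a one-voxel margin.
    """
    if not bone2d.any():
        return np.zeros_like(bone2d), np.zeros_like(bone2d)
    bg_labels, nbg = ndimage.label(~bone2d)
    outside = np.zeros_like(bone2d)
    if nbg:
        border = np.zeros_like(bone2d)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        outside_ids = np.unique(bg_labels[border & ~bone2d])
        outside_ids = outside_ids[outside_ids > 0]
        outside = np.isin(bg_labels, outside_ids)

    eroded = ndimage.binary_erosion(bone2d)
    seed = ndimage.binary_dilation(outside) & bone2d  # periosteal surface layer
    lab, n = ndimage.label(eroded)
    cortex_core = np.zeros_like(bone2d)
    if n:
        near_surface = ndimage.binary_dilation(seed) & eroded
        ids = np.unique(lab[near_surface])
        ids = ids[ids > 0]
        cortex_core = np.isin(lab, ids)
    cortex = (ndimage.binary_dilation(cortex_core) & bone2d) | seed
    margin = ndimage.binary_dilation(cortex)
    interior = ~outside & ~margin
    return bone2d & interior, interior


def extract_voi(
    mask: BoneMask,
    spec: VOISpec,
    growth_plate_slice: Optional[int] = None,
) -> BoneMask:
    """Extract a z-slab VOI from a whole-bone mask.

    Midshaft VOIs are centered at the bone-length midpoint (any extra slice
    of an even-count slab goes distal).  Proximal VOIs start one slice distal
    to the growth-plate reference and extend the stated fraction of bone
    length.  ``proximal_cancellous`` additionally peels the cortical shell
    per slice, keeping interior trabecular voxels and recording the
    endocortical interior as the TV ``region``.
    """
    occ = _occupied_z(mask)
    if occ.size == 0:
        raise ValueError("cannot extract a VOI from an empty mask")
    z0, z1 = int(occ[0]), int(occ[-1])
    total = z1 - z0 + 1
    n = max(1, _round_half_away(spec.extent_fraction * total))

    if spec.region == "midshaft_cortical":
        center = z0 + total // 2
        start = center - (n - 1) // 2
        stop = start + n
    else:
        if growth_plate_slice is None:
            raise ValueError(f"{spec.region} VOI requires growth_plate_slice")
        start = int(growth_plate_slice) + 1
        stop = start + n
    if start < 0 or stop > mask.shape[0]:
        raise ValueError(
            f"VOI slab [{start}, {stop}) exceeds image extent {mask.shape[0]} slices"
        )

    out = np.zeros_like(mask.values)
    out[start:stop] = mask.values[start:stop]
    region = None
    compartment = "cortical"
    if spec.region == "proximal_cancellous":
        region = np.zeros_like(mask.values)
        for z in range(start, stop):
            trab, interior = _peel_cortex_slice(mask.values[z])
            out[z] = trab
            region[z] = interior
        compartment = "cancellous"
    elif spec.region == "proximal_cortico_cancellous":
        region = np.zeros_like(mask.values)
        region[start:stop] = True
        compartment = "whole"

    return BoneMask(
        values=out,
        voxel_size=mask.voxel_size,
        threshold_used=mask.threshold_used,
        compartment=compartment,
        region=region,
    )
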
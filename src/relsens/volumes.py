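"""Volume container, NIfTI-1 I/O, physical-units smoothing and rigid resampling.

Every per-voxel quantity in this package (weighted intensities, sensitivity
fields, transmit-efficiency maps, R1 maps) is carried as a :class:`Volume`:
a 3D scalar array plus a 4x4 voxel-to-world affine in millimetres.  Voxel
indices are 0-based and the affine maps homogeneous voxel coordinates
``(i, j, k, 1)`` to world mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "Volume",
    "RigidTransform",
    "read_volume",
    "write_volume",
    "smooth_fwhm",
    "resample_rigid",
]

#: FWHM of a Gaussian in units of its standard deviation, ``sqrt(8 ln 2)``.
FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


@dataclass
class Volume:
    """A 3D scalar image with a voxel-to-world affine (world units: mm)."""

    data: np.ndarray
    affine: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel size: column norms of the 3x3 block of the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_grid(self, other: "Volume", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def with_data(self, data: np.ndarray, description: str | None = None) -> "Volume":
        """New Volume on the same grid with different voxel data."""
        return Volume(
            np.asarray(data, dtype=np.float64),
            self.affine.copy(),
            self.description if description is None else description,
        )

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy(), self.description)


@dataclass
class RigidTransform:
    """Rigid-body motion: Euler rotations (degrees) then translation (mm).

    The rotation is applied about the world x, y, z axes in that order
    (extrinsic convention), followed by the translation.  The transform maps
    world coordinates of a point before motion to its coordinates after.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = Rotation.from_euler(
            "xyz", self.rotation_deg, degrees=True
        ).as_matrix()
        m[:3, 3] = self.translation_mm
        return m

    def inverse(self) -> "RigidTransform":
        rot = Rotation.from_euler("xyz", self.rotation_deg, degrees=True).inv()
        t_inv = -rot.apply(np.asarray(self.translation_mm, dtype=float))
        return RigidTransform(
            tuple(rot.as_euler("xyz", degrees=True)), tuple(t_inv)
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        m = self.matrix @ other.matrix
        rot = Rotation.from_matrix(m[:3, :3])
        return RigidTransform(
            tuple(rot.as_euler("xyz", degrees=True)), tuple(m[:3, 3])
        )

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.matrix, np.eye(4), atol=1e-12)


def read_volume(path) -> Volume:
    """Read a 3D NIfTI-1 image (.nii or .nii.gz).

    Raises a ``ValueError`` naming the path for non-3D images; 4D inputs are
    rejected rather than silently squeezed.
    """
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) != 3:
        raise ValueError(
            f"{path}: expected a 3D image, got shape {tuple(shape)}"
        )
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    return Volume(data, np.asarray(img.affine, dtype=np.float64), description=str(path))


def write_volume(volume: Volume, path) -> None:
    """Write a Volume as float32 NIfTI-1; the affine is stored unmodified."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))


def smooth_fwhm(volume: Volume, fwhm_mm: float) -> Volume:
    """Isotropic Gaussian smoothing with the kernel width given in world mm.

    The per-axis sigma in voxels is ``(fwhm / voxel_size) / sqrt(8 ln 2)``,
    so anisotropic grids are smoothed isotropically in physical space.
    Boundary handling is replicate (nearest) padding: sensitivity fields are
    multiplicative and nonzero at tissue edges, so zero-padding would drag
    edge values down.  ``fwhm_mm = 0`` returns an identical copy.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = (fwhm_mm / volume.voxel_size_mm) / FWHM_PER_SIGMA
    out = ndimage.gaussian_filter(volume.data, sigma=sigma_vox, mode="nearest")
    return volume.with_data(out)


def resample_rigid(
    volume: Volume,
    transform: RigidTransform,
    reference: Volume,
    outside: str = "zero",
) -> Volume:
    """Apply a rigid transform to the image content, sampled on a reference grid.

    The output at world coordinate ``w`` is the input sampled (trilinearly) at
    ``T^-1 w``; i.e. the image content is moved by ``transform``.  Passing the
    identity transform with ``reference=volume`` reproduces the input; passing
    the identity with a different reference regrids between resolutions.

    Voxels mapping outside the source FOV are set to 0 (``outside="zero"``)
    or NaN (``outside="nan"``).
    """
    if outside not in ("zero", "nan"):
        raise ValueError(f"outside must be 'zero' or 'nan', got {outside!r}")
    # output voxel -> world -> back through T^-1 -> source voxel
    src_vox_from_out_vox = (
        np.linalg.inv(volume.affine)
        @ transform.inverse().matrix
        @ reference.affine
    )
    if volume.same_grid(reference) and np.allclose(
        src_vox_from_out_vox, np.eye(4), atol=1e-12
    ):
        return Volume(volume.data.copy(), reference.affine.copy(), volume.description)
    idx = np.indices(reference.shape, dtype=np.float64).reshape(3, -1)
    coords = src_vox_from_out_vox[:3, :3] @ idx + src_vox_from_out_vox[:3, 3:4]
    fill = np.nan
    out = ndimage.map_coordinates(
        volume.data, coords, order=1, mode="constant", cval=fill
    ).reshape(reference.shape)
    if outside == "zero":
        out = np.nan_to_num(out, nan=0.0)
    return Volume(out, reference.affine.copy(), volume.description)
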
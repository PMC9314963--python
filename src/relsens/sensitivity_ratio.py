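"""Ratio method: relative receive sensitivity from smoothed calibration images.

Each head position k comes with a rapid low-resolution coil-combined
calibration image ``x_k = s_k * r`` (common anatomy ``r``, position-specific
net receive field ``s_k``).  After rigid co-registration the relative
sensitivity between position k and a reference position is estimated as

    kappa_{k,ref} = smooth(x_k) / smooth(x_ref),

with an isotropic Gaussian kernel (default 12 mm FWHM) applied to numerator
and denominator separately before division.  kappa equals the true relative
sensitivity Delta_{k,ref} = s_k / s_ref only in the absence of
position-specific transmit-field effects; the error_simulation module
quantifies the residual transmit contamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import RigidTransform, Volume, resample_rigid, smooth_fwhm

__all__ = ["RelativeSensitivity", "relative_sensitivity_ratio", "apply_receive_correction"]

#: Division guard: fraction of the robust maximum of the smoothed reference
#: below which the ratio is undefined (set to 1, excluded from the mask).
GUARD_FRACTION = 1e-3


@dataclass
class RelativeSensitivity:
    """Dimensionless relative receive field Delta_{k,ref} plus validity mask."""

    field: Volume
    ref_index: int = 0
    fwhm_mm: float = 0.0
    mask: Volume | None = None

    def __post_init__(self) -> None:
        if self.mask is not None:
            inside = self.mask.data > 0
            if np.any(self.field.data[inside] <= 0):
                raise ValueError("relative sensitivity must be positive inside mask")


def relative_sensitivity_ratio(
    cal_k: Volume,
    cal_ref: Volume,
    fwhm_mm: float = 12.0,
    mask: Volume | None = None,
) -> RelativeSensitivity:
    """Relative sensitivity of ``cal_k`` with respect to ``cal_ref`` (Eq-5 ratio).

    Both images must be co-registered on the same grid.  Smoothing happens at
    the native calibration resolution, before division.  Voxels where the
    smoothed reference falls below ``GUARD_FRACTION`` of its 99th-percentile
    maximum are set to 1 and flagged invalid in the returned mask.
    """
    if not cal_k.same_grid(cal_ref):
        raise ValueError(
            f"calibration grids differ: {cal_k.shape} vs {cal_ref.shape}"
        )
    num = smooth_fwhm(cal_k, fwhm_mm).data
    den = smooth_fwhm(cal_ref, fwhm_mm).data
    robust_max = np.nanpercentile(den, 99.0)
    guard = den > GUARD_FRACTION * robust_max
    kappa = np.ones_like(den)
    np.divide(num, den, out=kappa, where=guard)
    valid = guard & (kappa > 0)
    if mask is not None:
        valid &= mask.data > 0
    kappa[~valid] = 1.0
    return RelativeSensitivity(
        field=cal_k.with_data(kappa, description="relative sensitivity (ratio)"),
        ref_index=0,
        fwhm_mm=fwhm_mm,
        mask=cal_k.with_data(valid.astype(np.float64), description="validity mask"),
    )


def apply_receive_correction(vfa: Volume, delta: RelativeSensitivity) -> Volume:
    """Divide a VFA volume by its relative sensitivity.

    If the sensitivity lives on a coarser calibration grid it is first
    resampled (trilinearly) to the VFA grid.  Correcting the reference
    contrast, for which Delta == 1, is the identity.
    """
    field = delta.field
    if not field.same_grid(vfa):
        field = resample_rigid(field, RigidTransform(), vfa, outside="zero")
        # outside the calibration FOV the field is unknown; leave data unscaled
        field.data[field.data == 0] = 1.0
    if np.any(field.data <= 0):
        raise ValueError("relative sensitivity must be positive on the VFA grid")
    return vfa.with_data(vfa.data / field.data)
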
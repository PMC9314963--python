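"""Two-point variable-flip-angle R1 estimation with TE=0 extrapolation and
optional relative-sensitivity and transmit-field correction.

The estimator is the standard small-flip-angle two-point form.  With
effective flip angles ``a_k = fT_k * alpha_k`` (radians) and the PD-weighted
intensity referenced to the T1-weighted position's receive modulation by
dividing by the relative sensitivity ``Delta = s1/s2``:

    J1 = I1 / Delta
    R1 = 1/2 * (I2*a2/TR2 - J1*a1/TR1) / (J1/a1 - I2/a2)

Dividing the PDw acquisition by Delta restores a common receive modulation
across the two contrasts, which the estimator then cancels (it is invariant
to scaling both intensities by any common factor).  When the transmit field
is assumed position-independent the fT dependence factors out:

    R1 = fT^2 / 2 * (I2*alpha2/TR2 - J1*alpha1/TR1) / (J1/alpha1 - I2/alpha2).

On signals generated by the small-angle SPGR forward model with the true
Delta and per-position fT supplied, the estimator is algebraically exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sensitivity_ratio import RelativeSensitivity, apply_receive_correction
from .signal_model import SequenceParams
from .volumes import RigidTransform, Volume, resample_rigid

__all__ = [
    "VFAInput",
    "R1Map",
    "extrapolate_te0",
    "r1_two_point",
    "r1_shared_transmit",
    "compute_r1_map",
]

#: Physically plausible R1 range (s^-1); estimates outside are masked out.
R1_VALID_RANGE = (0.0, 10.0)


@dataclass
class VFAInput:
    """One VFA contrast: multi-echo volumes, sequence parameters, optional B1+ map."""

    echoes: list[Volume]
    seq: SequenceParams
    b1_map: Volume | None = None

    def __post_init__(self) -> None:
        if len(self.echoes) < 1:
            raise ValueError("at least one echo required")
        ref = self.echoes[0]
        for e in self.echoes[1:]:
            if not e.same_grid(ref):
                raise ValueError(f"echo grids differ: {e.shape} vs {ref.shape}")
        if self.seq.te_s is not None and len(self.seq.te_s) != len(self.echoes):
            raise ValueError(
                f"{len(self.echoes)} echoes but {len(self.seq.te_s)} echo times"
            )

    @property
    def grid(self) -> Volume:
        return self.echoes[0]


@dataclass
class R1Map:
    """R1 map (s^-1) with a boolean validity mask; invalid voxels are NaN."""

    r1: Volume
    mask: Volume


def extrapolate_te0(vfa: VFAInput) -> tuple[Volume, np.ndarray]:
    """Extrapolate the multi-echo signal to TE = 0 by log-linear least squares.

    Per voxel, ordinary least squares of ``ln I`` on TE; returns
    ``exp(intercept)`` and a boolean array flagging voxels where the fit was
    valid (all echoes positive).  Flagged-invalid voxels fall back to the
    first-echo value.  A single echo is passed through unchanged.
    """
    n_echo = len(vfa.echoes)
    if n_echo == 1:
        warnings.warn("single echo: returning it unchanged (no TE=0 extrapolation)")
        return vfa.echoes[0].copy(), np.ones(vfa.grid.shape, dtype=bool)
    if vfa.seq.te_s is None:
        raise ValueError("echo times required for TE=0 extrapolation")
    te = np.asarray(vfa.seq.te_s)
    stack = np.stack([e.data for e in vfa.echoes], axis=-1)
    valid = np.all(stack > 0, axis=-1) & np.all(np.isfinite(stack), axis=-1)
    logi = np.log(np.where(stack > 0, stack, 1.0))
    # closed-form simple linear regression of log-signal on TE
    te_mean = te.mean()
    te_var = np.sum((te - te_mean) ** 2)
    y_mean = logi.mean(axis=-1)
    slope = np.tensordot(logi, te - te_mean, axes=([-1], [0])) / te_var
    intercept = y_mean - slope * te_mean
    out = np.exp(intercept)
    out[~valid] = vfa.echoes[0].data[~valid]
    return vfa.grid.with_data(out, "TE=0 extrapolated"), valid


def _two_point(J1, I2, a1, a2, tr1, tr2):
    num = I2 * a2 / tr2 - J1 * a1 / tr1
    den = J1 / a1 - I2 / a2
    with np.errstate(divide="ignore", invalid="ignore"):
        return 0.5 * num / den


def r1_two_point(I1, I2, seq1: SequenceParams, seq2: SequenceParams, fT1=1.0, fT2=1.0, delta=1.0):
    """Two-point R1 with per-position transmit fields and relative sensitivity.

    ``I1`` is the PDw (low-flip) intensity, ``I2`` the T1w intensity;
    ``delta = s1/s2`` is the relative receive sensitivity between the two
    positions.  With ``delta=1`` and ``fT1=fT2=1`` this is the uncorrected
    nominal-flip-angle estimator.  Non-physical voxels are returned as
    computed (possibly negative/NaN); map-level masking happens in
    :func:`compute_r1_map`.
    """
    a1 = np.asarray(fT1) * seq1.flip_rad
    a2 = np.asarray(fT2) * seq2.flip_rad
    J1 = np.asarray(I1) / np.asarray(delta)
    return _two_point(J1, np.asarray(I2), a1, a2, seq1.tr_s, seq2.tr_s)


def r1_shared_transmit(I1, I2, seq1: SequenceParams, seq2: SequenceParams, fT=1.0, delta=1.0):
    """Two-point R1 assuming a position-independent transmit field.

    Algebraically identical to :func:`r1_two_point` with ``fT1 = fT2 = fT``:
    the transmit efficiency factors out of the small-angle estimator as
    ``fT**2`` on the nominal-flip-angle form.
    """
    J1 = np.asarray(I1) / np.asarray(delta)
    nominal = _two_point(
        J1, np.asarray(I2), seq1.flip_rad, seq2.flip_rad, seq1.tr_s, seq2.tr_s
    )
    return np.asarray(fT) ** 2 * nominal


def _resample_to(vol: Volume, ref: Volume) -> Volume:
    if vol.same_grid(ref):
        return vol
    out = resample_rigid(vol, RigidTransform(), ref, outside="zero")
    out.data[out.data == 0] = 1.0  # outside calibration FOV: no correction
    return out


def compute_r1_map(
    pdw: VFAInput,
    t1w: VFAInput,
    delta: RelativeSensitivity | None = None,
    b1_mode: str = "shared",
) -> R1Map:
    """Voxelwise R1 map from co-registered PDw/T1w multi-echo inputs.

    Both contrasts are extrapolated to TE = 0, the PDw contrast is divided by
    the relative sensitivity (if provided), and the two-point estimator is
    applied with either a shared transmit field (``b1_mode="shared"``, the
    PDw-position B1+ map used for both contrasts) or per-contrast fields
    (``b1_mode="per_contrast"``, requires a B1+ map on each input).
    """
    if b1_mode not in ("shared", "per_contrast"):
        raise ValueError(f"b1_mode must be 'shared' or 'per_contrast', got {b1_mode!r}")
    if not pdw.grid.same_grid(t1w.grid):
        raise ValueError(
            f"PDw and T1w grids differ: {pdw.grid.shape} vs {t1w.grid.shape}"
        )
    grid = pdw.grid
    i1, valid1 = extrapolate_te0(pdw)
    i2, valid2 = extrapolate_te0(t1w)
    if delta is not None:
        i1 = apply_receive_correction(i1, delta)

    if b1_mode == "per_contrast":
        if pdw.b1_map is None or t1w.b1_map is None:
            raise ValueError("per_contrast B1 correction requires a B1+ map on both inputs")
        ft1 = _resample_to(pdw.b1_map, grid).data
        ft2 = _resample_to(t1w.b1_map, grid).data
        r1 = r1_two_point(i1.data, i2.data, pdw.seq, t1w.seq, ft1, ft2)
    else:
        ft = (
            _resample_to(pdw.b1_map, grid).data
            if pdw.b1_map is not None
            else 1.0
        )
        r1 = r1_shared_transmit(i1.data, i2.data, pdw.seq, t1w.seq, ft)

    mask = (
        valid1
        & valid2
        & np.isfinite(r1)
        & (r1 > R1_VALID_RANGE[0])
        & (r1 <= R1_VALID_RANGE[1])
    )
    r1 = np.where(mask, r1, np.nan)
    return R1Map(
        r1=grid.with_data(r1, "R1 map (s^-1)"),
        mask=grid.with_data(mask.astype(np.float64), "R1 validity mask"),
    )
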
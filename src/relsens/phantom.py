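"""Synthetic acquisition generator with known ground truth.

The phantom emulates a two-position multiparameter-mapping session in which
the subject moves between the PD-weighted and T1-weighted acquisitions:

* a three-class ellipsoidal "brain" (WM core, GM shell, CSF ventricle) with
  per-class R1, proton density and R2*, softened by a small partial-volume
  blur so that rigid resampling is well behaved;
* smooth multiplicative receive-sensitivity and transmit-efficiency fields
  that are **anchored to the scanner frame**: when the head moves, the
  anatomy is resampled through the rigid transform while the fields stay
  put, which is precisely what makes inter-scan motion produce differential
  modulation of the weighted volumes;
* single-echo low-resolution calibration images (small-angle SPGR forward
  model) on a coarse grid, one per position;
* multi-echo VFA volumes (full SPGR steady state times ``exp(-TE*R2*)``) on
  the fine grid, PDw at position 1, T1w at position 2;
* optional B1+ maps per position on the coarse grid;
* additive Gaussian noise, scaled from a target SNR.

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .signal_model import (
    CALIBRATION_SEQUENCE,
    PDW_SEQUENCE,
    SequenceParams,
    T1W_SEQUENCE,
    spgr_signal,
    spgr_signal_small_angle,
)
from .volumes import RigidTransform, Volume, resample_rigid, smooth_fwhm

__all__ = ["PhantomSpec", "PhantomBundle", "make_phantom", "smooth_random_field"]

# nominal tissue parameters: R1 (s^-1), proton density (a.u.), R2* (s^-1).
# CSF R1 is clipped up to 0.5 so the in-mask truth stays inside the
# simulated range [0.5, 1.4] s^-1 that the error study covers.
DEFAULT_TISSUE = {
    "wm": {"r1": 1.1, "pd": 0.69, "r2s": 50.0},
    "gm": {"r1": 0.6, "pd": 0.83, "r2s": 40.0},
    "csf": {"r1": 0.5, "pd": 1.0, "r2s": 5.0},
}


@dataclass
class PhantomSpec:
    """Everything needed to generate one reproducible two-position session."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float = 2.0
    cal_voxel_mm: float = 4.0
    tissue: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TISSUE.items()})
    #: min/max of the *relative* receive field s2/s1 over the brain mask
    receive_rel_range: tuple[float, float] = (0.84, 1.18)
    #: min/max of the *relative* transmit field fT2/fT1 over the brain mask
    transmit_rel_range: tuple[float, float] = (0.85, 1.18)
    #: baseline (position-1) field ranges over the brain mask
    receive_base_range: tuple[float, float] = (0.7, 1.3)
    transmit_base_range: tuple[float, float] = (0.8, 1.2)
    field_correlation_mm: float = 60.0
    motion: RigidTransform = field(default_factory=RigidTransform)
    snr: float | None = 50.0
    partial_volume_fwhm_mm: float = 3.0
    pdw_seq: SequenceParams = field(default_factory=lambda: PDW_SEQUENCE)
    t1w_seq: SequenceParams = field(default_factory=lambda: T1W_SEQUENCE)
    calib_seq: SequenceParams = field(default_factory=lambda: CALIBRATION_SEQUENCE)
    #: "full" = steady-state Ernst equation (realistic; carries the ~2-4%
    #: small-angle scale bias of the estimator at a 26 deg flip); or
    #: "small_angle" = the rational model the estimator inverts exactly
    #: (for algebraic round-trip tests).
    vfa_signal_model: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vfa_signal_model not in ("full", "small_angle"):
            raise ValueError("vfa_signal_model must be 'full' or 'small_angle'")


@dataclass
class PhantomBundle:
    """Generated volumes plus the ground truth that produced them.

    Scanner-frame acquisitions (``cal``, ``t1w_echoes``, ``b1``) at position 2
    contain the *moved* anatomy; ``motion`` maps position-1 world coordinates
    to position-2, so analyses register position-2 volumes back with
    ``resample_rigid(vol, motion.inverse(), reference)``.
    """

    # ground truth on the fine (VFA) grid, position-1 frame
    r1: Volume
    pd: Volume
    r2s: Volume
    labels: Volume
    brain_mask: Volume
    # scanner-frame fields on the fine grid (position index 0/1)
    receive_fields: list[Volume]
    transmit_fields: list[Volume]
    #: true relative sensitivity s1(w)/s2(T w) on the registered fine grid
    true_delta: Volume
    # acquisitions
    pdw_echoes: list[Volume]
    t1w_echoes: list[Volume]
    cal: list[Volume]
    b1: list[Volume]
    motion: RigidTransform
    spec: PhantomSpec
    noise_sigma_vfa: float
    noise_sigma_cal: float


def smooth_random_field(
    shape: tuple[int, ...],
    voxel_mm: float,
    correlation_length_mm: float,
    log_amplitude: float,
    seed: int,
    mask: np.ndarray | None = None,
    rel_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Strictly positive smooth random field, exp of band-limited Gaussian noise.

    ``correlation_length_mm`` is the half-width at half-maximum of the field's
    autocorrelation: white noise smoothed by a Gaussian kernel of standard
    deviation ``sigma`` has autocorrelation ``exp(-r^2 / (4 sigma^2))``, so
    ``sigma = correlation_length / (2 sqrt(ln 2))``.  If ``rel_range`` is
    given, the log-field is affinely rescaled so the field's min/max over
    ``mask`` (or the full grid) equal the requested bounds exactly;
    otherwise the log-field has standard deviation ``log_amplitude``.
    ``log_amplitude = 0`` (with no rel_range) yields the constant field 1.
    """
    if correlation_length_mm < 2 * voxel_mm:
        raise ValueError("correlation length must be well above the voxel size")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    sigma_vox = correlation_length_mm / (2.0 * np.sqrt(np.log(2.0))) / voxel_mm
    b = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = b.std()
    if sd == 0:
        return np.ones(shape)
    b = b / sd
    if rel_range is not None:
        lo, hi = rel_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid relative range {rel_range}")
        sel = b if mask is None else b[mask]
        bmin, bmax = float(sel.min()), float(sel.max())
        if bmax == bmin:
            return np.full(shape, lo)
        b = np.log(lo) + (b - bmin) * (np.log(hi) - np.log(lo)) / (bmax - bmin)
        return np.exp(b)
    return np.exp(log_amplitude * b)


def _centered_affine(shape, voxel_mm: float) -> np.ndarray:
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_mm
    return aff


def _ellipsoid(grid: Volume, semi_axes_mm, center_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    idx = np.indices(grid.shape, dtype=np.float64)
    world = np.einsum(
        "ab,b...->a...", grid.affine[:3, :3], idx
    ) + grid.affine[:3, 3].reshape(3, 1, 1, 1)
    d = (world - np.asarray(center_mm).reshape(3, 1, 1, 1)) / np.asarray(
        semi_axes_mm
    ).reshape(3, 1, 1, 1)
    return np.sum(d * d, axis=0) <= 1.0


def _tissue_maps(grid: Volume, spec: PhantomSpec):
    """Three-class ellipsoid brain; returns (r1, pd, r2s, labels, mask)."""
    fov = np.asarray(grid.shape) * grid.voxel_size_mm
    brain = _ellipsoid(grid, 0.42 * fov)
    wm = _ellipsoid(grid, 0.28 * fov)
    csf = _ellipsoid(grid, 0.10 * fov, center_mm=(0.0, 0.08 * fov[1], 0.0))
    labels = np.zeros(grid.shape, dtype=np.int16)  # 0 bg, 1 gm, 2 wm, 3 csf
    labels[brain] = 1
    labels[wm] = 2
    labels[csf] = 3
    t = spec.tissue
    lut = {
        "r1": [0.0, t["gm"]["r1"], t["wm"]["r1"], t["csf"]["r1"]],
        "pd": [0.0, t["gm"]["pd"], t["wm"]["pd"], t["csf"]["pd"]],
        "r2s": [0.0, t["gm"]["r2s"], t["wm"]["r2s"], t["csf"]["r2s"]],
    }
    maps = {}
    for name, vals in lut.items():
        m = np.asarray(vals)[labels]
        if spec.partial_volume_fwhm_mm > 0:
            m = smooth_fwhm(grid.with_data(m), spec.partial_volume_fwhm_mm).data
        maps[name] = m
    return maps["r1"], maps["pd"], maps["r2s"], labels, brain


class _ArrayTissue:
    """Voxelwise tissue parameters fed to the vectorized forward models."""

    def __init__(self, r1, pd, r2s=0.0):
        self.r1_hz = r1
        self.pd = pd
        self.r2s_hz = r2s


def make_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Generate one two-position session with ground truth (see module docs)."""
    if spec is None:
        spec = PhantomSpec()
    grid = Volume(np.zeros(spec.shape), _centered_affine(spec.shape, spec.voxel_mm))
    cal_shape = tuple(
        max(2, int(round(s * spec.voxel_mm / spec.cal_voxel_mm))) for s in spec.shape
    )
    cal_grid = Volume(np.zeros(cal_shape), _centered_affine(cal_shape, spec.cal_voxel_mm))

    r1, pd, r2s, labels, brain = _tissue_maps(grid, spec)

    # guard: the moved brain must stay inside the field of view
    moved_mask = resample_rigid(
        grid.with_data(brain.astype(np.float64)), spec.motion, grid, outside="zero"
    ).data
    if moved_mask.sum() < 0.999 * brain.sum():
        raise ValueError("motion moves the brain partially outside the field of view")

    # scanner-frame fields (fine grid); position 2 = baseline x relative field
    seeds = np.random.SeedSequence(spec.seed).generate_state(8)
    cl = spec.field_correlation_mm
    s1 = smooth_random_field(
        spec.shape, spec.voxel_mm, cl, 0.0, int(seeds[0]), brain, spec.receive_base_range
    )
    rel_s = smooth_random_field(
        spec.shape, spec.voxel_mm, cl, 0.0, int(seeds[1]), brain, spec.receive_rel_range
    )
    f1 = smooth_random_field(
        spec.shape, spec.voxel_mm, cl, 0.0, int(seeds[2]), brain, spec.transmit_base_range
    )
    rel_f = smooth_random_field(
        spec.shape, spec.voxel_mm, cl, 0.0, int(seeds[3]), brain, spec.transmit_rel_range
    )
    s2, f2 = s1 * rel_s, f1 * rel_f

    # per-position anatomy in the scanner frame
    def moved(data):
        return resample_rigid(grid.with_data(data), spec.motion, grid, outside="zero").data

    anat = [
        (r1, pd, r2s, brain.astype(np.float64)),
        tuple(moved(m) for m in (r1, pd, r2s, brain.astype(np.float64))),
    ]
    recv, tx = [s1, s2], [f1, f2]

    rng = np.random.default_rng(int(seeds[4]))

    def to_cal(data):
        return resample_rigid(grid.with_data(data), RigidTransform(), cal_grid, "zero").data

    # noiseless signals first, so noise sigmas come from the clean amplitudes
    forward = spgr_signal if spec.vfa_signal_model == "full" else spgr_signal_small_angle

    def vfa_echoes(seq, pos):
        a_r1, a_pd, a_r2s, a_mask = anat[pos]
        ok = a_r1 > 0.05
        tis = _ArrayTissue(np.where(ok, a_r1, 1.0), np.where(a_pd > 0, a_pd, 1.0), a_r2s)
        base = forward(seq, tis, fT=tx[pos], s=recv[pos])
        base = np.where(ok & (a_mask > 0.5), base, 0.0)
        return [base * np.exp(-te * a_r2s) for te in seq.te_s]

    def cal_image(pos):
        a_r1, a_pd, a_r2s, a_mask = (to_cal(m) for m in anat[pos])
        ok = a_r1 > 0.05
        tis = _ArrayTissue(np.where(ok, a_r1, 1.0), np.where(a_pd > 0, a_pd, 1.0))
        sig = spgr_signal_small_angle(
            spec.calib_seq, tis, fT=to_cal(tx[pos]), s=np.maximum(to_cal(recv[pos]), 1e-6)
        )
        return np.where(ok & (a_mask > 0.5), sig, 0.0)

    pdw_clean = vfa_echoes(spec.pdw_seq, 0)
    t1w_clean = vfa_echoes(spec.t1w_seq, 1)
    cal_clean = [cal_image(0), cal_image(1)]

    if spec.snr is None:
        sig_vfa = sig_cal = 0.0
    else:
        sig_vfa = float(pdw_clean[0][brain].mean()) / spec.snr
        sig_cal = float(cal_clean[0][to_cal(brain.astype(float)) > 0.5].mean()) / spec.snr

    def noisy(data, sigma):
        return data if sigma == 0 else data + rng.normal(0.0, sigma, data.shape)

    pdw = [grid.with_data(noisy(e, sig_vfa), f"PDw echo {i}") for i, e in enumerate(pdw_clean)]
    t1w = [grid.with_data(noisy(e, sig_vfa), f"T1w echo {i}") for i, e in enumerate(t1w_clean)]
    cal = [
        cal_grid.with_data(noisy(c, sig_cal), f"calibration position {i+1}")
        for i, c in enumerate(cal_clean)
    ]
    b1 = [
        cal_grid.with_data(to_cal(tx[i]), f"B1+ map position {i+1}") for i in range(2)
    ]

    # oracle relative sensitivity on the registered (position-1) grid:
    # after registration, voxel w of the T1w volume was acquired at scanner
    # location T(w), hence carries modulation s2(T w).
    s2_reg = resample_rigid(
        grid.with_data(s2), spec.motion.inverse(), grid, outside="zero"
    ).data
    true_delta = np.where(s2_reg > 0, s1 / np.maximum(s2_reg, 1e-6), 1.0)

    return PhantomBundle(
        r1=grid.with_data(r1, "true R1"),
        pd=grid.with_data(pd, "true PD"),
        r2s=grid.with_data(r2s, "true R2*"),
        labels=grid.with_data(labels.astype(np.float64), "tissue labels"),
        brain_mask=grid.with_data(brain.astype(np.float64), "brain mask"),
        receive_fields=[grid.with_data(s1, "receive field position 1"),
                        grid.with_data(s2, "receive field position 2")],
        transmit_fields=[grid.with_data(f1, "transmit field position 1"),
                         grid.with_data(f2, "transmit field position 2")],
        true_delta=grid.with_data(true_delta, "true relative sensitivity (registered)"),
        pdw_echoes=pdw,
        t1w_echoes=t1w,
        cal=cal,
        b1=b1,
        motion=spec.motion,
        spec=spec,
        noise_sigma_vfa=sig_vfa,
        noise_sigma_cal=sig_cal,
    )
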
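"""Forward spoiled-gradient-echo (SPGR) signal equations.

The steady-state SPGR intensity at a voxel with longitudinal rate ``R1``,
proton density ``rho``, receive sensitivity ``s`` and transmit efficiency
``fT`` (1 = nominal flip achieved), for nominal flip angle ``alpha`` and
repetition time ``TR``, is

    I = s * rho * (1 - exp(-TR*R1)) * sin(fT*alpha)
        / (1 - cos(fT*alpha) * exp(-TR*R1)).

For small effective flip angles and short TR this is well approximated by
the rational form

    I ~= s * rho * R1 * fT*alpha * TR / ((fT*alpha)^2 / 2 + R1*TR),

which is the form the two-point variable-flip-angle (VFA) R1 estimator
inverts exactly.  Flip angles are carried in degrees at the interface and
converted to radians in exactly one place; times are seconds so R1 is s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SequenceParams",
    "TissueState",
    "spgr_signal",
    "spgr_signal_small_angle",
    "ernst_angle",
    "PDW_SEQUENCE",
    "T1W_SEQUENCE",
    "CALIBRATION_SEQUENCE",
    "MPM_ECHO_TIMES_S",
]


@dataclass(frozen=True)
class SequenceParams:
    """Nominal flip angle (degrees), TR (s) and optional echo times (s)."""

    flip_deg: float
    tr_s: float
    te_s: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.flip_deg < 90.0:
            raise ValueError(f"flip angle must be in (0, 90) deg, got {self.flip_deg}")
        if self.tr_s <= 0:
            raise ValueError(f"TR must be positive, got {self.tr_s}")
        if self.te_s is not None:
            te = tuple(float(t) for t in self.te_s)
            if any(t < 0 for t in te) or any(
                b <= a for a, b in zip(te, te[1:])
            ):
                raise ValueError("echo times must be non-negative and strictly increasing")
            object.__setattr__(self, "te_s", te)

    @classmethod
    def from_ms(
        cls, flip_deg: float, tr_ms: float, te_ms=None
    ) -> "SequenceParams":
        """Build from times in ms, the units protocols are printed in."""
        te = None if te_ms is None else tuple(t * 1e-3 for t in te_ms)
        return cls(flip_deg, tr_ms * 1e-3, te)

    @property
    def flip_rad(self) -> float:
        return float(np.deg2rad(self.flip_deg))


@dataclass(frozen=True)
class TissueState:
    """Voxel tissue parameters: R1 (s^-1), proton density (a.u.), R2* (s^-1)."""

    r1_hz: float
    pd: float = 1.0
    r2s_hz: float = 0.0

    def __post_init__(self) -> None:
        r1 = np.asarray(self.r1_hz)
        pd = np.asarray(self.pd)
        if np.any(r1 <= 0) or np.any(r1 >= 10):
            raise ValueError("R1 must lie in (0, 10) s^-1")
        if np.any(pd <= 0):
            raise ValueError("proton density must be positive")


# Multi-echo MPM protocol: 8 echoes, 2.56-15.02 ms in 1.78 ms steps.
MPM_ECHO_TIMES_S = tuple(np.round((2.56 + 1.78 * np.arange(8)) * 1e-3, 8))

#: PD-weighted VFA acquisition: 6 degrees, TR 19.5 ms.
PDW_SEQUENCE = SequenceParams(6.0, 19.5e-3, MPM_ECHO_TIMES_S)
#: T1-weighted VFA acquisition: 26 degrees, TR 19.5 ms.
T1W_SEQUENCE = SequenceParams(26.0, 19.5e-3, MPM_ECHO_TIMES_S)
#: Single-echo receive-calibration acquisition: 6 degrees, TE 2.4 ms, TR 6.5 ms.
CALIBRATION_SEQUENCE = SequenceParams(6.0, 6.5e-3, (2.4e-3,))


def spgr_signal(seq: SequenceParams, tissue: TissueState, fT=1.0, s=1.0):
    """Full steady-state SPGR intensity (Ernst equation with modulations).

    ``fT`` and ``s`` may be scalars or arrays broadcastable against the
    tissue parameters; the TE decay factor is *not* included here (the
    multi-echo phantom applies ``exp(-TE*R2*)`` explicitly).
    """
    fT = np.asarray(fT, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if np.any(fT <= 0) or np.any(s <= 0):
        raise ValueError("fT and s must be positive")
    a = fT * seq.flip_rad
    e1 = np.exp(-seq.tr_s * np.asarray(tissue.r1_hz, dtype=np.float64))
    return s * tissue.pd * (1.0 - e1) * np.sin(a) / (1.0 - np.cos(a) * e1)


def spgr_signal_small_angle(seq: SequenceParams, tissue: TissueState, fT=1.0, s=1.0):
    """Small-flip-angle, short-TR rational approximation to the SPGR signal."""
    fT = np.asarray(fT, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if np.any(fT < 0) or np.any(s <= 0):
        raise ValueError("fT must be >= 0 and s positive")
    a = fT * seq.flip_rad
    r1 = np.asarray(tissue.r1_hz, dtype=np.float64)
    return s * tissue.pd * r1 * a * seq.tr_s / (a * a / 2.0 + r1 * seq.tr_s)


def ernst_angle(tr_s: float, r1_hz) -> np.ndarray | float:
    """Small-angle Ernst angle in radians, ``alpha_E = sqrt(2 * TR * R1)``.

    This is the form the kappa-misestimation analysis uses, rather than the
    exact ``cos(alpha_E) = exp(-TR*R1)``; the two agree to O(alpha_E^2).
    """
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    r1 = np.asarray(r1_hz, dtype=np.float64)
    if np.any(r1 < 0):
        raise ValueError("R1 must be non-negative")
    out = np.sqrt(2.0 * tr_s * r1)
    return float(out) if np.isscalar(r1_hz) else out
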
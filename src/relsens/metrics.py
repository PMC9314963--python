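"""Evaluation metrics and masking for R1 maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vfa import R1Map
from .volumes import Volume

__all__ = ["MaeResult", "mae", "tissue_mask"]


@dataclass
class MaeResult:
    """Mean absolute relative error of an R1 map against a reference, in %."""

    mae_pct: float
    n_voxels: int
    per_tissue: dict[str, float] | None = None


def mae(r1: R1Map, reference: R1Map, mask: Volume | None = None) -> MaeResult:
    """Mean absolute error, ``(1/N) sum |ref - est| / ref``, reported in %.

    The evaluation mask is intersected with the validity masks of both maps;
    the reference must be strictly positive on the final mask.
    """
    if not r1.r1.same_grid(reference.r1):
        raise ValueError("R1 map and reference are on different grids")
    sel = (r1.mask.data > 0) & (reference.mask.data > 0)
    if mask is not None:
        if not mask.same_grid(r1.r1):
            raise ValueError("mask is on a different grid")
        sel &= mask.data > 0
    n = int(sel.sum())
    if n == 0:
        raise ValueError("empty evaluation mask")
    ref = reference.r1.data[sel]
    est = r1.r1.data[sel]
    if np.any(ref <= 0):
        raise ValueError("reference R1 must be strictly positive on the mask")
    return MaeResult(mae_pct=float(np.mean(np.abs(ref - est) / ref)) * 100.0, n_voxels=n)


def tissue_mask(prob_maps: list[Volume], threshold: float = 0.5) -> Volume:
    """Voxels whose mean class probability across the given maps exceeds a threshold."""
    if not prob_maps:
        raise ValueError("at least one probability map required")
    ref = prob_maps[0]
    for p in prob_maps[1:]:
        if not p.same_grid(ref):
            raise ValueError("probability maps are on different grids")
    stack = np.stack([p.data for p in prob_maps])
    if stack.min() < 0 or stack.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return ref.with_data((stack.mean(axis=0) > threshold).astype(np.float64), "tissue mask")
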
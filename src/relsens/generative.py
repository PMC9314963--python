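"""Generative model of calibration images: joint mean image and smooth
per-position receive-sensitivity fields.

Model
-----
Each co-registered calibration image is an unknown common image ``r``
modulated by a position-specific smooth sensitivity field and corrupted by
Gaussian noise:

    x_k = exp(b_k) * r + eps_k,     eps_k ~ N(0, sigma_k^2)

with the log-sensitivities ``b_k`` penalized by a membrane (first-order)
energy weighted by a per-image regularization parameter ``lambda_k`` keyed by
coil class (array coils vary spatially much more than body coils, hence
``lambda_body >> lambda_array``).  The penalized negative log-likelihood is

    F = sum_k [ N/2 log(2 pi sigma_k^2) + ||x_k - exp(b_k) r||^2 / (2 sigma_k^2) ]
        + sum_k lambda_k/2 * E_mem(b_k),

where ``E_mem(b) = (1/N) sum_axes sum_vox (forward-diff(b) / h_axis)^2`` with
``h_axis`` the voxel size in mm (Neumann / zero-flux boundaries).  The
energy is averaged over the N voxels so the printed regularization weights
(1e7 array, 1e9 body) act per voxel, independent of grid size.

Fitting alternates block updates, each of which cannot increase F:

* ``r``: closed-form voxelwise weighted least squares;
* each ``b_k``: one damped Gauss-Newton step, solving the sparse SPD system
  ``(diag(w) + lambda L) delta = -grad`` by Jacobi-preconditioned conjugate
  gradients, with step halving until F does not increase;
* identifiability: the voxelwise mean of the ``b_k`` (their log-barycenter)
  is transferred into ``r``, so ``sum_k b_k == 0`` — sensitivities are
  expressed relative to their barycenter mean.

Intensities are normalized to unit mean before fitting and the scale is
restored on the output mean image, so the printed ``lambda`` values behave
identically across scanners with different raw signal scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .sensitivity_ratio import RelativeSensitivity
from .volumes import Volume

__all__ = [
    "CalibrationSet",
    "GenerativeConfig",
    "SensitivityFit",
    "fit_generative",
    "relative_sensitivity_from_fit",
    "membrane_operator",
    "membrane_energy",
]

#: Default regularization per coil class (dimensionless, for unit-mean data).
DEFAULT_LAMBDA = {"array": 1.0e7, "body": 1.0e9}


@dataclass
class CalibrationSet:
    """K co-registered calibration volumes, each labelled by coil class."""

    volumes: list[Volume]
    coil_classes: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.volumes) < 2:
            raise ValueError("need at least 2 calibration volumes")
        if self.coil_classes is None:
            self.coil_classes = ["array"] * len(self.volumes)
        if len(self.coil_classes) != len(self.volumes):
            raise ValueError("one coil class per volume required")
        ref = self.volumes[0]
        for v in self.volumes[1:]:
            if not v.same_grid(ref):
                raise ValueError(
                    f"calibration grids differ: {v.shape} vs {ref.shape}"
                )

    def __len__(self) -> int:
        return len(self.volumes)


@dataclass
class GenerativeConfig:
    lambda_per_class: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAMBDA)
    )
    n_iter: int = 15
    #: None -> per-iteration ML estimate; scalar or per-image sequence -> fixed.
    noise_variance: float | list[float] | None = None
    cg_rtol: float = 1e-6
    cg_maxiter: int = 500
    max_halvings: int = 10

    def __post_init__(self) -> None:
        if any(lam <= 0 for lam in self.lambda_per_class.values()):
            raise ValueError("all lambda must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class SensitivityFit:
    """Result of the generative fit on a common grid."""

    mean_image: Volume
    log_sens: list[Volume]
    objective_trace: list[float]
    noise_variance: list[float]

    @property
    def n_positions(self) -> int:
        return len(self.log_sens)


def membrane_operator(shape: tuple[int, ...], voxel_mm) -> sparse.csr_matrix:
    """Sparse SPSD membrane operator L with mm-scaled forward differences.

    ``b^T L b`` equals the voxel-averaged membrane energy
    ``(1/N) sum_a sum_i ((b[i+e_a]-b[i])/h_a)^2`` with Neumann boundaries
    (no wrap, boundary differences simply absent).
    """
    n = int(np.prod(shape))
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    L = sparse.csr_matrix((n, n))
    eye = [sparse.identity(s, format="csr") for s in shape]
    for ax, s in enumerate(shape):
        if s < 2:
            continue
        # 1D forward difference (s-1) x s
        d = sparse.diags([-1.0, 1.0], [0, 1], shape=(s - 1, s), format="csr")
        d = d / voxel_mm[ax]
        ops = [eye[a] if a != ax else (d.T @ d).tocsr() for a in range(len(shape))]
        term = ops[0]
        for op in ops[1:]:
            term = sparse.kron(term, op, format="csr")
        L = L + term
    return (L / n).tocsr()


def membrane_energy(b: np.ndarray, voxel_mm) -> float:
    """Voxel-averaged membrane energy, computed directly from finite differences."""
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    e = 0.0
    for ax in range(b.ndim):
        d = np.diff(b, axis=ax) / voxel_mm[ax]
        e += float(np.sum(d * d))
    return e / b.size


def _objective(x, r, b, lam, sig2, L, n_vox):
    f = 0.0
    for k in range(len(x)):
        resid = x[k] - np.exp(b[k]) * r
        f += 0.5 * n_vox * np.log(2.0 * np.pi * sig2[k])
        f += 0.5 * float(resid @ resid) / sig2[k]
        f += 0.5 * lam[k] * float(b[k] @ (L @ b[k]))
    return f


def _noise_variance_mad(img: np.ndarray) -> float:
    """Robust noise-variance estimate from first-difference pseudo-residuals.

    Differences of adjacent voxels cancel smooth structure (anatomy times a
    smooth sensitivity field) but retain ``sqrt(2) sigma`` of iid noise, so
    ``sigma ~= 1.4826 * MAD(diff) / sqrt(2)``.  This deliberately estimates
    the *noise floor*, not the model misfit: using the (bias-dominated)
    fitting residuals instead would over-estimate sigma early on and freeze
    the regularized fit far from the data.  The estimate only seeds the
    first iteration; later iterations use the closed-form ML update.
    """
    d = np.concatenate([np.diff(img, axis=ax).reshape(-1) for ax in range(img.ndim)])
    mad = np.median(np.abs(d - np.median(d)))
    return float((1.4826 * mad) ** 2 / 2.0)


def _update_mean(x, b, sig2):
    """Closed-form voxelwise WLS update of the mean image r."""
    num = np.zeros_like(x[0])
    den = np.zeros_like(x[0])
    for k in range(len(x)):
        s = np.exp(b[k])
        num += s * x[k] / sig2[k]
        den += s * s / sig2[k]
    return num / np.maximum(den, 1e-300)


def fit_generative(cals: CalibrationSet, config: GenerativeConfig | None = None) -> SensitivityFit:
    """Penalized-ML fit of the mean image and log-sensitivity fields.

    Returns the fit on the calibration grid; the objective trace (one entry
    per outer iteration, after all block updates) is non-increasing.
    """
    if config is None:
        config = GenerativeConfig()
    K = len(cals)
    grid = cals.volumes[0]
    shape = grid.shape
    n_vox = int(np.prod(shape))
    lam = []
    for cls in cals.coil_classes:  # type: ignore[union-attr]
        if cls not in config.lambda_per_class:
            raise ValueError(f"no lambda configured for coil class {cls!r}")
        lam.append(float(config.lambda_per_class[cls]))

    # normalize intensities to unit mean so lambda is scale-free
    raw = [v.data.reshape(-1) for v in cals.volumes]
    scale = float(np.mean(np.abs(np.concatenate(raw))))
    if scale <= 0 or not np.isfinite(scale):
        raise ValueError("calibration images have non-positive mean intensity")
    x = [xi / scale for xi in raw]

    L = membrane_operator(shape, grid.voxel_size_mm)
    b = [np.zeros(n_vox) for _ in range(K)]

    # noise variances: estimated once from the data, or fixed from config.
    # Held fixed across iterations: re-estimating sigma^2 from the fitting
    # residuals lets early (bias-dominated) misfit masquerade as noise,
    # which collapses the data weight and freezes the fit.
    sig2_floor = 1e-12  # relative to unit-mean intensities
    if config.noise_variance is None:
        sig2 = [
            max(_noise_variance_mad(x[k].reshape(shape)), sig2_floor)
            for k in range(K)
        ]
    else:
        nv = config.noise_variance
        sig2 = (
            [float(nv) / scale**2] * K
            if np.isscalar(nv)
            else [float(v) / scale**2 for v in nv]  # type: ignore[union-attr]
        )
        if len(sig2) != K or any(v <= 0 for v in sig2):
            raise ValueError("noise_variance must be positive (one value or one per image)")
    r = _update_mean(x, b, sig2)

    trace: list[float] = []
    f_cur = _objective(x, r, b, lam, sig2, L, n_vox)
    for it in range(config.n_iter):
        # Gauss-Newton update of each log-sensitivity field
        for k in range(K):
            m = np.exp(b[k]) * r  # model prediction
            resid = m - x[k]
            g = m * resid / sig2[k] + lam[k] * (L @ b[k])
            w = m * m / sig2[k]
            H = sparse.diags(np.maximum(w, 1e-300)) + lam[k] * L
            precond = sparse.diags(1.0 / (H.diagonal() + 1e-300))
            delta, _info = cg(
                H, -g, rtol=config.cg_rtol, maxiter=config.cg_maxiter, M=precond
            )
            # damped step: halve until the objective does not increase
            step = 1.0
            b_old = b[k]
            for _ in range(config.max_halvings + 1):
                b[k] = b_old + step * delta
                f_new = _objective(x, r, b, lam, sig2, L, n_vox)
                if f_new <= f_cur:
                    break
                step *= 0.5
            else:
                b[k] = b_old
                f_new = f_cur
            f_cur = f_new

        # barycenter identifiability: move the voxelwise mean of b into r
        mean_b = np.mean(b, axis=0)
        for k in range(K):
            b[k] = b[k] - mean_b
        r = r * np.exp(mean_b)

        r = _update_mean(x, b, sig2)
        f_cur = _objective(x, r, b, lam, sig2, L, n_vox)
        if not np.isfinite(f_cur):
            raise FloatingPointError(f"objective became non-finite at iteration {it}")
        trace.append(f_cur)

    return SensitivityFit(
        mean_image=grid.with_data((r * scale).reshape(shape), "mean image r"),
        log_sens=[
            grid.with_data(b[k].reshape(shape), f"log sensitivity b_{k}")
            for k in range(K)
        ],
        objective_trace=trace,
        noise_variance=[v * scale**2 for v in sig2],
    )


def relative_sensitivity_from_fit(
    fit: SensitivityFit, k: int, ref: int
) -> RelativeSensitivity:
    """Relative sensitivity Delta_{k,ref} = exp(b_k - b_ref) from a fit."""
    if not (0 <= k < fit.n_positions and 0 <= ref < fit.n_positions):
        raise IndexError(
            f"indices ({k}, {ref}) out of range for {fit.n_positions} positions"
        )
    delta = np.exp(fit.log_sens[k].data - fit.log_sens[ref].data)
    return RelativeSensitivity(
        field=fit.log_sens[k].with_data(delta, "relative sensitivity (generative)"),
        ref_index=ref,
        fwhm_mm=0.0,
    )
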
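# Methods

## Signal model

The steady-state spoiled gradient-echo (SPGR) intensity at a voxel is

    I_k = s_k · ρ · (1 − e^(−TR·R1)) · sin(fT_k α_k) / (1 − cos(fT_k α_k) e^(−TR·R1)),

where `s_k` is the net receive sensitivity at head position k, `ρ` the
proton density, `fT_k` the transmit efficiency (1 = nominal flip achieved),
`α_k` the nominal flip angle and `R1` the longitudinal rate in s⁻¹. For
small effective flip angle and short TR this reduces to the rational form

    I_k ≈ s_k · ρ · R1 · a_k · TR / (a_k²/2 + R1·TR),   a_k = fT_k α_k (rad),

which the two-point VFA estimator inverts exactly. Angles enter interfaces
in degrees and are converted to radians once; times are seconds internally
(`SequenceParams.from_ms` accepts protocol-sheet ms values). Sequence
defaults follow the MPM protocol: PDw 6° / T1w 26°, TR 19.5 ms, eight
echoes TE 2.56–15.02 ms in 1.78 ms steps; calibration 6°, TR 6.5 ms,
TE 2.4 ms.

The two-point estimator carries a systematic small-angle truncation error
of ≈ α²/6 ≈ 2.6% at the 26° flip when applied to full-model signals; in
practice it cancels in map-to-map comparisons (references are maps computed
the same way), but against absolute ground truth it is visible, which is
why the phantom offers both forward models (`vfa_signal_model="full"`,
default, and `"small_angle"` for algebraic round-trip tests). At the 2°-6°
calibration flips the truncation error is below 0.5%.

## Relative receive sensitivity

Both methods consume co-registered low-resolution calibration images
`x_k ≈ s_k r`.

**Ratio.** `κ = smooth(x_k)/smooth(x_ref)`, smoothing applied to numerator
and denominator separately at native calibration resolution, isotropic
Gaussian kernel specified in mm (default 12 mm FWHM; per-axis sigma derived
from the affine, replicate padding so tissue-edge values are not dragged
toward zero). Voxels where the smoothed reference falls below 10⁻³ of its
99th-percentile maximum are set to 1 and flagged invalid; the background is
therefore excluded from any downstream statistics via the returned mask.

**Generative model.** Penalized Gaussian likelihood

    F = Σ_k [ N/2·log(2πσ_k²) + ‖x_k − e^{b_k} r‖²/(2σ_k²) ] + Σ_k λ_k/2 · E(b_k),
    E(b)  = (1/N) Σ_axes Σ_vox (Δb/h_axis)²     (membrane energy, Neumann edges),

with log-sensitivities `b_k` (positivity for free, and the identifiability
constraint `Σ_k b_k = 0` is a plain zero-mean condition: sensitivities are
expressed relative to their barycenter mean, which is absorbed into `r`).
Numerical scheme per outer iteration (default 15):

1. one damped Gauss–Newton step per `b_k`: solve
   `(diag((e^b r)²/σ²) + λL)·δ = −grad` by Jacobi-preconditioned conjugate
   gradients (relative tolerance 10⁻⁶), halving the step until F does not
   increase (≤10 halvings);
2. re-center `{b_k}` to zero voxelwise mean, compensating `r`;
3. closed-form weighted-least-squares update of `r`.

The recorded objective trace is non-increasing by construction. Input
intensities are normalized to unit mean before fitting (scale restored on
the output mean image) so the λ values are independent of scanner units.
The membrane energy is *averaged* over voxels; this is what makes the
per-coil-class defaults λ_array = 10⁷ and λ_body = 10⁹ act as meaningful
per-voxel weights — with a summed energy the same numbers would crush even
the smoothest fields by orders of magnitude at realistic calibration SNR.
λ_body ≫ λ_array encodes that body-coil modulation is nearly flat.

Noise variances σ_k² are estimated once per image from first-difference
pseudo-residuals (`σ ≈ 1.4826·MAD(diff)/√2`), a statistic that measures the
noise floor rather than the model misfit, and are then held fixed. Two
alternatives were evaluated and rejected: estimating σ from the fitting
residuals after an initial mean-image update over-estimates σ by the
(initially large) bias misfit and freezes the regularized fit far from the
data; re-estimating σ² by its ML update each iteration is monotone in F but
converges to a degenerate optimum in which the unexplained bias is absorbed
as noise (the data weight collapses and the fields flatten). Fixed
variances can be supplied via `GenerativeConfig.noise_variance` (used by
the brute-force single-voxel oracle test).

## R1 estimation

Multi-echo volumes are extrapolated to TE = 0 by per-voxel, per-contrast
ordinary least squares of log-signal on TE (voxels with non-positive echoes
fall back to the first echo and are masked). The PDw intensity is divided
by Δ — this, not multiplication, is what restores a common modulation:
`I₁/Δ = s₂ρu₁` matches the `s₂ρu₂` modulation of the T1w volume, and makes
the estimator algebraically exact on rational-model signals (verified to
10⁻⁹ over 10⁴ random parameter draws). Transmit handling is either shared
(the PDw-position B1+ map, with `fT²` factoring out of the nominal-angle
estimator) or per-contrast (`a_k = fT_k α_k`). Estimates outside (0, 10] s⁻¹,
non-finite values and extrapolation failures are masked and written as NaN.

## Error-propagation study

Under the small-angle model the calibration-image ratio relates to the true
relative sensitivity by `κ = Δ · g` with

    g(fT₁, fT₂, R1) = fT₁(fT₂²α_c² + 2TR_c·R1) / (fT₂(fT₁²α_c² + 2TR_c·R1)),

and `g = 1` exactly iff `fT₁ = fT₂` or `fT₁fT₂ = α_E²/α_c²`
(`α_E² = 2TR_c·R1`, the small-angle Ernst form). The 4D lattice spans
`fT₁ ∈ [0.5, 1.5]`, `R1 ∈ [0.5, 1.4] s⁻¹`, relative transmit
`fT₁/fT₂ ∈ [0.85, 1.18]` and **measured** relative receive
`κ ∈ [0.84, 1.18]` (41 points per axis, linear, inclusive). The receive
axis is the measured quantity because that is what field ranges observed
through calibration-image ratios constrain; the true `Δ = κ/g` is derived
per point (it extends beyond the κ range where g ≠ 1, up to ≈ [0.74, 1.32]).
Four estimates are formed per point — none (shared fT₁, Δ̂=1), transmit-only
(per-position fT, Δ̂=1), receive-only (shared fT₁, Δ̂=κ), both — and the
signed relative error in % is stored.

Attribution: per lattice point, the transmit-attributed error is the
residual after receive-only correction and vice versa; shares are formed
from squared residuals (error energy) normalized to 100% per point, and the
median is taken over points with nonzero total. The absolute-residual
variant is computed alongside and reported by the CLI; it shifts the median
attribution by ≈ ±10 percentage points, which is the main sensitivity of
this statistic. The medians move by < 0.4 percentage points between 21- and
41-point lattices. With the default settings the study yields a 30.2%/69.8%
transmit/receive split and a 122% worst-case uncorrected error.

## Synthetic data generator

The phantom emulates a two-position MPM session: a three-class nested
ellipsoid brain (WM R1 1.1, GM 0.6, CSF 0.5 s⁻¹ — CSF clipped up to the
simulated range floor — with per-class PD and R2*), softened by a 3 mm
partial-volume blur; calibration images on a 4 mm grid and eight-echo VFA
volumes on a 2 mm grid; optional B1+ maps at calibration resolution.
Receive and transmit fields are exponentials of band-limited Gaussian
random fields (default correlation half-width 60 mm, on the scale of coil
sensitivity variation) rescaled so the position-2/position-1 relative
fields span exactly [0.84, 1.18] (receive) and [0.85, 1.18] (transmit)
over the brain — the empirically observed 7T ranges. Fields are anchored
to the scanner frame while the anatomy moves through the rigid transform:
this is the physical mechanism that makes inter-scan motion produce
differential modulation. Gaussian noise is added with σ set from a target
SNR (default 50, chosen to reproduce the ~5% no-motion test–retest error
level of comparable in vivo maps) on the mean in-brain signal. Everything
is reproducible bit-for-bit from a single seed.

What the phantom does *not* emulate: realistic anatomy, k-space artifacts
(partial Fourier, elliptical sampling), intra-scan motion, Rician noise,
B0-related effects and imperfect spoiling (the generator produces ideally
spoiled signals, so the estimator's omission of a spoiling correction is
self-consistent). Passing tests therefore demonstrate correctness of the
estimators and the correction logic under the stated field/motion/noise
conditions, not robustness to those unmodeled effects.

Study sizes used by the test suite: the correction study runs on a 64³
(2 mm) phantom with rigid motion of root-sum-of-squares 7.8 mm / 10.5°
within the observed motion envelope; unit tests use 16³–32³ grids. At
these resolutions the double trilinear interpolation of the moved anatomy
(generation plus registration) sets a ~2% MAE floor for oracle-corrected
maps, scaling as O(h²) with voxel size; it is small compared to the ~12%
uncorrected motion bias but not negligible against perfect recovery.

## Evaluation

MAE (in %) is the mean of |R̂1 − R1|/R̂1 over a mask, with the reference R̂1
in the denominator; masks combine the maps' validity masks with a
user-supplied (tests: eroded phantom-truth) tissue mask. On the 64³ study
the orderings reported in the README hold: uncorrected ≫ receive-only >
receive+per-contrast-B1 ≈ no-motion. Receive-only correction plateaus at
the residual transmit error — with 7T-scale transmit differentials the
ratio of uncorrected to receive-only-corrected MAE is ≈ 1.8, and supplying
the true Δ instead of the estimated one does not improve it further —
which is precisely the motivation for per-contrast transmit mapping.

## Known limitations

* Registration is consumed, never estimated: volumes must be pre-registered
  or accompanied by explicit rigid transforms.
* The generative model assumes Gaussian noise; background air voxels
  violate this (Rician), which matters only at very low SNR.
* The TE = 0 extrapolation is per-contrast; a joint-R2* (ESTATICS-style)
  fit across contrasts could differ slightly on real data.
* The small-angle estimator's ~2–4% truncation bias at the 26° flip is not
  corrected; it is common mode across correction regimes.
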
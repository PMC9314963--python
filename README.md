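# relsens

Inter-scan motion correction for variable-flip-angle (VFA) R1 mapping,
based on estimating the *relative* receive-sensitivity field between head
positions — with no body-coil reference, so it works at 7T.

## The problem

Quantitative R1 (=1/T1) maps are commonly computed from two spoiled
gradient-echo volumes acquired with different flip angles (a PD-weighted
6° and a T1-weighted 26° acquisition in the multiparameter-mapping, MPM,
protocol). The estimator assumes both volumes share the same receive-coil
modulation. If the subject moves *between* the acquisitions, each volume is
modulated by a position-specific net sensitivity field `s_k`; rigid
co-registration realigns the anatomy but cannot remove the differential
modulation, which biases R1 severely (up to ~130% in the regimes simulated
here). At 7T the transmit field `fT` also changes with position, adding a
second bias that receive correction alone cannot remove.

## The methods

A rapid low-resolution calibration image `x_k ≈ s_k · r` (common anatomy
`r`) is acquired at each position. Two estimators of the relative
sensitivity `Δ₁,₂ = s₁/s₂` are provided:

* **ratio** — `κ₁,₂ = smooth(x₁)/smooth(x₂)` with a 12 mm FWHM Gaussian
  kernel;
* **generative** — penalized maximum likelihood in the model
  `x_k = exp(b_k)·r + ε_k`, with a per-voxel-averaged membrane energy
  `λ‖∇b_k‖²` (λ = 10⁷ for array coils, 10⁹ for body coils), fitted by
  alternating closed-form mean-image updates and damped Gauss–Newton steps,
  with the log-sensitivities constrained to their barycenter
  (`Σ_k b_k = 0`); then `Δ₁,₂ = exp(b₁ − b₂)`.

Dividing the PDw volume by `Δ₁,₂` restores a common modulation, and the
small-flip-angle two-point estimator

    R1 = ½ · (I₂a₂/TR₂ − (I₁/Δ)a₁/TR₁) / ((I₁/Δ)/a₁ − I₂/a₂),  a_k = fT_k·α_k

recovers R1, with either a shared transmit map (the PDw position's) or
per-contrast B1+ maps. The error-propagation study quantifies when the
measured `κ` equals the true `Δ` (exactly iff `fT₁ = fT₂` or
`fT₁fT₂ = α_E²/α_c²`, the small-angle Ernst condition of the calibration
sequence) and how residual transmit contamination propagates into R1.

## Worked example

Everything runs on synthetic data; no scanner data are required. Generate a
two-position session (rigid motion, 7T-range differential fields, SNR 50),
estimate the relative sensitivity, and fit R1:

```sh
relsens phantom --preset 7t-motion --seed 7 --size 32 --out-dir ph
relsens ratio --cal ph/cal_pos1.nii.gz --cal ph/cal_pos2.nii.gz --fwhm 12 --out delta.nii.gz
relsens fit-r1 --pdw ph/pdw_e*.nii.gz --t1w ph/t1w_e*.nii.gz \
    --b1 ph/b1_pos1.nii.gz --delta delta.nii.gz --out r1.nii.gz
relsens mae --r1 r1.nii.gz --ref ph/truth_r1.nii.gz --mask ph/brain_mask.nii.gz
```

(The phantom writes scanner-frame volumes; in this pipeline the position-2
volumes are used as-is, so the printed MAE shows the *uncorrected* motion
bias unless you first resample them back through the rigid transform in
`ph/manifest.json`, as the test suite does.)

The error-propagation study prints the headline numbers directly:

```sh
$ relsens simulate --points 41 --out-prefix sim_
median_tx_pct,median_rx_pct,max_uncorrected_pct,median_tx_pct_abs,median_rx_pct_abs
30.23,69.77,122.21,39.70,60.30
```

Reading: over a 4D lattice spanning transmit efficiency 0.5–1.5, R1
0.5–1.4 s⁻¹ and the empirically observed 7T ranges of relative transmit
(0.85–1.18) and relative receive (0.84–1.18) fields, a median 30% of the
R1 error energy is attributable to transmit-field change and 70% to
receive-sensitivity change, and uncorrected inter-scan motion can corrupt
R1 by up to 122%. The last two columns are the same attribution computed
from absolute instead of squared residuals, as a sensitivity check. The
command also writes the 4D error grids (`sim_grids.npz`) and figures: the
κ/Δ misestimation surface and error planes under the four correction
regimes (none / transmit-only / receive-only / both).

On the 64³ end-to-end phantom study in `tests/test_acceptance.py`
(inter-scan motion of ~8 mm / ~11°, SNR 50), the mean absolute R1 error
against ground truth is: uncorrected 12.3%, receive-corrected 6.8% (ratio)
/ 6.9% (generative), receive + per-contrast-B1 corrected 4.1% / 4.7%,
versus 5.2% without motion — receive correction removes most of the bias,
and adding position-specific transmit maps restores the no-motion level.

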
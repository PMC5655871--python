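# Methods

## Scope and model

The package implements a desk-scale analog of MRI-guided near-infrared
spectral tomography (NIRST) for breast lesion characterization. The breast
cross-section is a 2-D circular domain (default radius 40 mm) discretized
with linear triangles; all equations are dimension-agnostic, and 2-D keeps
every experiment runnable in seconds while preserving the structure of the
method. Real systems reconstruct on 3-D patient-specific meshes; nothing in
the code assumes otherwise beyond the mesh generator.

### Forward model

Light propagation is modeled by the frequency-domain diffusion
approximation,

    −∇·(D ∇Φ) + (μa + iω/c_m) Φ = S,     D = 1/(3 (μa + μs′)),

valid when μs′ ≫ μa (a warning is emitted below μs′/μa = 10). The FEM
discretization is a standard Galerkin assembly on linear triangles with
exact element integration; the air–tissue interface carries a Robin
condition Φ + 2AD ∂Φ/∂n = 0 with A = (1+R_eff)/(1−R_eff) and R_eff from the
empirical internal-reflection polynomial at relative index 1.33/1.0.
c_m = c₀/1.33 is the in-tissue light speed.

Sources and detectors are identical operators: a unit-strength Gaussian
density (σ = 2 mm) centered one transport mean free path (1/μs′) inside the
boundary, converted to a consistent FEM load through the mass matrix.
Identical source/detection operators make source–detector reciprocity exact
up to solver tolerance (the system matrix is complex symmetric), and the
consistent load keeps the represented source fixed under mesh refinement.
The measurement is m = q_dᵀ Φ_s; data are log|m| and the phase delay
−arg(m), reduced mod 2π (true delays at breast scale and 100 MHz stay below
2π, so this unwraps exactly). CW wavelengths (ω = 0) carry log-amplitude
only.

Spectral composition: μa(λ) = Σ_c ε_c(λ) C_c over oxy-/deoxy-hemoglobin
(mM), water and lipid (volume fractions), with a piecewise-linear extinction
table embedded in `forward_model.py`. The hemoglobin molar extinctions
follow the widely used compiled oxy/deoxy spectra (Prahl's tabulation),
water follows Hale & Querry-type data and lipid follows van Veen-type
measurements, all smoothed onto a coarse 650–1000 nm grid; the table is an
approximation adequate for synthetic studies, not a metrology reference.
Reduced scattering follows μs′ = a (λ/λ₀)^−b with λ₀ = 785 nm.

**Accuracy envelope.** Between meshes of target edge 4 mm and 2 mm, the
RMS relative log-amplitude difference across all 9 × 240 measurements is
about 1.1%, dominated by numerical dispersion of linear elements at the
most attenuating wavelength (660 nm; kh ≈ 0.6 at h = 4 mm), with worst-case
entries near 4% at short source–detector separations. The unit suite pins
this envelope (RMS < 1.5%, monotone improvement under refinement). Absolute
data offsets of this kind are largely removed by reference-phantom
calibration, which is how the pipeline consumes data.

### Calibration

Measured data are corrected by a reference phantom:
`calibrated = measured − (reference_measured − reference_model)` in
(log-amplitude, phase) space, removing per-channel coupling offsets. A
single uniform chromophore state (default unknowns: HbO₂, Hb, water) is
then fit to the calibrated data by bounded nonlinear least squares and
serves as the initial estimate of the iterative reconstruction.

### Grayscale-weighted regularization

The MR-like prior enters through the weighting matrix L described in the
README. Implementation decisions:

- Grayscale values are normalized to [0, 1] (16-bit counts / 65535) before
  σ_g = 0.01 applies; a fixed σ_g is only meaningful on a normalized scale.
- The row normalizer is Mᵢ = Σ_{j≠i} w_ij over the *unnormalized* Gaussian
  weights, making L a well-defined smoothing operator whose connected rows
  sum to zero (L annihilates constants, so spatially uniform images are
  never penalized). Defining Mᵢ through the normalized entries themselves
  would be circular.
- The Heaviside distance cutoff is strict (θ(0) = 0): pairs at exactly the
  normalized distance σ_d are excluded. The boundary case is a convention;
  exclusion is the sparser choice.
- The normalization scale is the global maximum inter-node distance (the
  mesh diameter). With fewer than three nodes, no pair can be inside a
  σ_d ≤ 1 neighborhood under this convention; rows without in-range
  neighbors keep a bare unit diagonal.
- In the spectral inversion LᵀL is applied block-diagonally, one block per
  unknown field; no cross-parameter coupling.

### Reconstruction

Each iteration solves the damped normal equations of the update equation
(README) by Cholesky factorization; the regularization parameter
λ = 10 · max(diag(JᵀJ)) is recomputed from the current Jacobian each
iteration (`lambda_policy="first"` freezes the first value instead — the
choice is exposed because either reading of "the regularization parameter
was 10·max(diag(JᵀJ))" is defensible; per-iteration is the default as the
standard practice). The Jacobian is assembled by the adjoint method — since
detection and source operators coincide, the adjoint fields are the forward
fields — and includes both the absorption mass term and the diffusion-
coefficient chain term ∂D/∂μa = ∂D/∂μs′ = −3D², chained through ε_c(λ) and
the scattering power law. The dependence of the source position on μs′ (via
the transport mean free path) is neglected in the Jacobian; it vanishes for
the default unknowns.

Defaults: unknowns (hbo, hb, water); lipid and the scattering parameters
stay at their calibrated homogeneous values. With six FD and three CW
wavelengths the hemoglobin columns dominate the normal equations and HbT —
the diagnostic readout — is well determined; freeing all six fields is
supported but poorly conditioned at this acquisition and λ rule. After each
step the state is projected to physical bounds (non-negative
concentrations, fractions in [0, 1]). Iterations stop when the relative
misfit change drops below 2% (default) or after 15 iterations; a misfit
growing three iterations in a row flags the result as non-converged and
returns the best state seen, without raising.

### Diagnostics

HbT contrast is mean(HbT|ROI)/mean(HbT|complement). The automated ROI
surrogate for the radiologist's manual segmentation is an Otsu threshold on
the nodal grayscale values with the largest connected component retained;
when the prior is uninformative (constant grayscale) the pipeline falls
back to the true inclusion mask, standing in for the morphology-based
manual ROI. "Positive" means score strictly greater than the cutoff. ROC
curves sweep all observed scores; the trapezoidal AUC equals the
tie-corrected Mann–Whitney concordance by construction, and the best cutoff
maximizes sensitivity + specificity with ties broken toward specificity.
The logistic combination is an ordinary (unpenalized) binary fit; perfect
separation — the rule rather than the exception in well-separated cohorts
of 24 — is detected from the fitted linear predictor and triggers a
ridge-penalized refit (penalty 1e-2) flagged in the output. Group
comparisons use the pooled-variance Student's t test (Welch available),
two-tailed, α = 0.05. Simulated radiology scores are class-conditional
Gaussians rounded onto the 1–5 ordinal scale (means 4.6/2.4, SD 1.0),
giving roughly 85–90% sensitivity/specificity at the conventional ≥ 4
positivity rule; they are a stand-in for real readings, used only to
exercise the combination machinery.

## Synthetic study conditions

The default cohort emulates the clinical study design: 16 malignant and 8
benign subjects. True inclusion HbT contrast is lognormal with median 2.5
(σ_log = 0.3) for malignant and median 1.0 (σ_log = 0.25) for benign
subjects; inclusions are 8 mm disks placed uniformly within 45% of the
domain radius. Background tissue: HbT 0.02 mM at 70% oxygen saturation,
water 0.6, lipid 0.3, μs′ = 1.0 mm⁻¹ at 785 nm with scatter power 1.0 —
representative breast values. Noise: 1% multiplicative amplitude, 1°
additive phase (FD channels), typical instrument specs. Priors are rendered
at 1 mm pixels with 1 mm blur and mild additive noise; with probability
1 − prior_fidelity a subject's prior is uninformative (constant). The six
FD wavelengths default to an even spread over 660–850 nm and the three CW
wavelengths over 900–950 nm (the instrument's exact laser lines are not
fixed by the design; all are configurable), and the modulation frequency
defaults to 100 MHz, standard for FD breast systems.

What the generator does *not* emulate: 3-D geometry, breast-shape and
tissue heterogeneity, chromophore differences beyond HbT (benign and
malignant differ only in hemoglobin), MR artifacts, fiducial coregistration
error beyond a rigid misalignment option, and detector saturation. Data are
simulated on the same mesh used for reconstruction (an "inverse crime"),
with measurement noise as the only model mismatch; passing recovery tests
therefore demonstrates correctness of the estimator chain, not clinical
performance. Cohort-level AUCs from this generator are expected to exceed
the clinical values.

## Problem sizes

Unit tests run on 40 mm domains with target edges 8–11 mm (50–110 nodes);
recovery experiments and the acceptance script use 5 mm edges (~250 nodes,
688 elements), where one guided reconstruction takes a few seconds and the
full 24-subject cohort study a few minutes. These sizes were chosen so the
whole suite iterates quickly on a laptop; the code paths are identical at
finer resolutions.

## Known limitations

- Linear (P1) elements limit raw data accuracy at the strongest-attenuating
  wavelengths (see accuracy envelope above).
- The extinction table is a smoothed literature compilation; swap in a
  calibrated `ExtinctionTable` for quantitative spectroscopy.
- Water and lipid are weakly determined at the default acquisition; their
  recovered maps stay close to the homogeneous fit.
- The phase convention assumes total delays below 2π; at much larger
  domains or modulation frequencies the mod-2π unwrapping would fold.
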
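# mrnirst

MRI-guided near-infrared spectral tomography (NIRST) at desk scale:
simulate breast-like optical phantoms with co-registered grayscale MR-style
priors, reconstruct chromophore images with grayscale-weighted direct
regularization, and score benign-vs-malignant discrimination from the total
hemoglobin contrast statistic.

## The problem

Diffuse optical tomography recovers tissue chromophores — oxy- and
deoxy-hemoglobin, water, lipid — from multi-wavelength near-infrared boundary
measurements, but on its own it is severely resolution-limited. Guiding the
reconstruction with the grayscale structure of a co-registered MR slice
(e.g. a T2 image, which needs no contrast injection) sharpens the recovered
total hemoglobin (HbT = HbO₂ + Hb) map enough that the **HbT contrast**

```
C = mean(HbT | suspicious ROI) / mean(HbT | rest of the breast)
```

separates malignant (elevated, ~2–3×) from benign (~1×) lesions. This
package implements that full chain on synthetic 2-D phantoms so every stage
is testable without clinical data: it is aimed at researchers in diffuse
optics who want a compact, fully inspectable reference pipeline.

## The method

**Forward model.** Per wavelength λ the frequency-domain diffusion equation
`−∇·(D∇Φ) + (μa + iω/c)Φ = S`, `D = 1/(3(μa + μs′))`, is solved with linear
triangular finite elements and a Robin boundary condition for the tissue–air
index mismatch. Spectrally, `μa(λ) = Σ_c ε_c(λ) C_c` (Beer law over an
embedded extinction table) and `μs′(λ) = a (λ/λ₀)^−b`. The acquisition
mirrors a hybrid FD/CW breast system: 16 boundary fibers, 240
source–detector pairs per wavelength, 6 FD wavelengths (660–850 nm,
amplitude + phase) and 3 CW wavelengths (900–950 nm, amplitude only).

**Grayscale-weighted regularization.** MR grayscale values γᵢ sampled onto
the mesh nodes build the weighting matrix

```
L_ij = 1                                                         (i = j)
L_ij = −(1/Mᵢ) exp(−|γᵢ−γⱼ|² / 2σ_g²) θ(σ_d − |rᵢ−rⱼ|/max|rᵢ−rⱼ|)  (i ≠ j)
```

with Mᵢ the row's weight sum (so connected rows sum to zero), σ_g = 0.01 the
characteristic grayscale difference and σ_d = 0.4 the distance of influence
as a fraction of the mesh diameter.

**Update equation.** Each Gauss–Newton iteration solves

```
Δx_k = (J_kᵀ J_k + λ LᵀL)⁻¹ J_kᵀ (d − f(x_{k−1})),   λ = 10 · max(diag(J_kᵀ J_k))
```

with J_k the adjoint-assembled Jacobian of the (log-amplitude, phase) data
with respect to the nodal chromophores, and LᵀL applied block-diagonally per
unknown field.

**Diagnostics.** ROC analysis of the per-subject HbT contrast (trapezoidal
AUC ≡ tie-corrected Mann–Whitney concordance), the best cutoff maximizing
sensitivity + specificity, logistic-regression combination of contrast with
an ordinal radiology score, and Student's t tests between pathology groups.

## Worked example

```python
import mrnirst as mn
from mrnirst import forward_model as fm, prior_regularization as pr
from mrnirst import reconstruction as rc, diagnostics as dx, phantom_synth as ps

# one malignant subject: true inclusion HbT contrast 2.5, faithful T2-like prior
spec = ps.CohortSpec(n_malignant=1, n_benign=1, seed=7,
                     contrast_law_malignant={"name": "point", "value": 2.5},
                     contrast_law_benign={"name": "point", "value": 1.0})
acq = mn.AcquisitionSpec()                     # 6 FD + 3 CW wavelengths
subject = ps.simulate_cohort(spec, acq, edge_mm=5.0)[0]
mesh = subject.phantom.mesh
layout = mn.place_optodes(mesh, 16)            # 16 fibers, 240 pairs

# reference-phantom calibration and homogeneous initial estimate
ref = fm.forward(fm.ChromophoreState.uniform(mesh.n_nodes, ps.TissueProperties()),
                 mesh, layout, acq)
calibrated, initial = fm.calibrate(subject.measurements, ref, ref,
                                   mesh, layout, acq)

# grayscale-weighted regularization from the MR-like prior
gamma = pr.sample_prior_to_nodes(subject.prior, mesh)
weights = pr.build_L(gamma, mesh.nodes)        # sigma_g = 0.01, sigma_d = 0.4
result = rc.reconstruct(calibrated, initial, weights, mesh, layout, acq)

roi = dx.roi_from_prior(gamma, mesh.node_adjacency())
contrast = dx.hbt_contrast(result.state.hbt, roi)
print(f"iterations: {result.iterations}, converged: {result.converged}")
print(f"background HbT: {result.state.hbt[~roi].mean()*1000:.1f} uM")
print(f"ROI HbT contrast: {contrast:.2f} (true 2.5, malignant if > 1.1)")
```

prints

```
iterations: 3, converged: True
background HbT: 20.0 uM
ROI HbT contrast: 2.32 (true 2.5, malignant if > 1.1)
```

The reconstruction recovers the 20 µM background exactly and pulls the
inclusion's contrast to 2.32 of its true 2.5 — the prior-guided penalty lets
the lesion region rise collectively while keeping the background smooth.
Without the prior (uniform γ), the same data yield a contrast near 1.3.

## Command-line pipeline

```
mrnirst simulate    --config cfg.toml --out sim
mrnirst reconstruct --config cfg.toml --manifest sim/manifest.csv --out recon
mrnirst diagnose    --config cfg.toml --manifest sim/manifest.csv \
                    --results recon --out diag
```

Each command accepts `--seed`, `--force` and a TOML config; every output
file is stamped with the hash of the resolved configuration, and the whole
pipeline is bit-reproducible under a fixed seed.

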
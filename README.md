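# mpimet

Magnetic particle imaging (MPI) detects superparamagnetic iron-oxide tracer
with zero tissue background, which makes it a candidate modality for finding
lung metastases by the tracer that tumor-associated macrophages engulf.
`mpimet` is a desk-scale, fully synthetic re-implementation of that
computational pipeline: it simulates field-free-line (FFL) MPI scans of
digital phantoms, reconstructs images with a model-based MAP estimator,
quantifies tracer iron through a linear calibration, and runs the diagnostic
cutoff analysis (Youden index + bootstrap) on synthetic mouse cohorts. It is
aimed at people who want a testable, end-to-end sandbox for FFL MPI
quantification and small-cohort diagnostic statistics — no scanner or animal
data required.

## The model in brief

**Forward model.** An ideal superparamagnet in field B carries magnetization
L(βB), with the Langevin function L(x) = coth x − 1/x and β = m/(k_B T),
m = M_s (π/6) d³. An FFL scanner applies a gradient G so that a voxel at
signed distance u from the line sees B = G·u + A cos(ωt). Per drive period
the Fourier coefficients of L(β(G·u + A cos ωt)) at harmonics 2–5 define
four spatial kernels k_h(u); the measurement at a scan angle is the CT-style
line projection of the tracer map convolved with each kernel. The map from
concentration to signal is linear — the basis of all quantification.

**Reconstruction.** Stacking all (angle, harmonic) blocks gives an operator
A, and the image is the MAP estimate

    x* = argmin_{x ≥ 0} ½‖Ax − y‖² + (λ/2)‖x‖²,

solved by a monotone FISTA variant (projected accelerated gradient with a
descent fallback), 250 iterations by default, λ = 10⁻³‖AᵀA‖.

**Quantification.** Summed voxel values ("MPI signal") are linear in iron
mass; a ladder of known masses fits signal = slope·mass + intercept, and
SNR = (S_NP − S_PBS)/SD_PBS compares a tracer-injected organ with a control.

**Diagnostics.** With per-animal lung signals and metastasis labels, the
optimal cutoff maximizes the Youden index J = Se + Sp − 1 over observed
values (rule: signal ≥ threshold ⇒ metastasis); 1,000 bootstrap resamples
give threshold-selection frequencies and percentile 95% CIs for Se, Sp, PPV
and NPV. Synthetic cohorts are generated with a Gaussian-copula severity
latent so rank correlations between burden covariates and signal hit
prescribed Spearman targets.

## Worked example

```python
import mpimet as m

tracer = m.TracerModel()                      # 30 nm core, Ms = 300 kA/m
config = m.ScannerConfig(fov=(32.5, 32.5), grid=(65, 65), angles=(0.0, 90.0))

# shine-through phantom: 300 ug center well, six 30 ug satellites
phantom = m.make_shine_through_phantom(config=config)
print(f"phantom mass: {phantom.total_mass:.1f} ug")

signal = m.simulate_scan(phantom, tracer, config, seed=0)
operator = m.build_operator(tracer, config)
recon = m.reconstruct_map(signal, operator, n_iter=250)
print(recon.summary())

sep = m.min_resolvable_separation(10.0, tracer, config, operator=operator)
print(f"10x pair resolvable from {sep:.1f} mm")

table = m.generate_cohort(m.spec_4t1(seed=1))
report = m.classify_cohort(table, n_iterations=1000, seed=1)
print(report.summary())
```

prints

```
phantom mass: 480.0 ug
MAP reconstruction
  grid:            65 x 65
  iterations:      215
  prior weight:    0.2394
  final objective: 326.187
  total signal:    740.202 a.u.
10x pair resolvable from 1.5 mm
Cohort metastasis classification
  threshold 21725.4: Se 1.00, Sp 1.00, PPV 1.00, NPV 1.00, J 1.00 (tp 10, fp 0, tn 4, fn 0)
  1000 bootstrap iterations; modal threshold 21725.4 selected 618x; 95% CIs: Se [1.00, 1.00], Sp [1.00, 1.00], PPV [1.00, 1.00], NPV [1.00, 1.00]
```

The phantom carries 480 µg of iron (300 + 6×30). The MAP solver converged
(early stop at iteration 215 of 250) and the 10-fold intensity pair is
disjointly detected from 1.5 mm separation — well inside the scanner's
5 mm requirement for liver-adjacent lung lesions. The synthetic 14-mouse
cohort separates perfectly at its fitted threshold, with the modal
threshold re-selected in 618 of 1,000 bootstrap resamples.

A CLI mirrors the stages (`mpimet phantom|cohort|simulate|reconstruct|
calibrate|quantify|classify|run`); `mpimet run --out demo_out` executes the
whole pipeline with provenance-stamped artifacts.

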
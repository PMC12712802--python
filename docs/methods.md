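# Methods

This note records the model, the numerical choices, and the boundaries of
what the synthetic experiments can show. It accompanies the code; nothing
here states a result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Signal model

A tracer particle of core diameter d (nm) and volumetric saturation
magnetization M_s (A/m) at temperature T carries moment m = M_s (π/6) d³
and equilibrium magnetization L(βB) along the applied field, with
L(x) = coth x − 1/x and β = m/(k_B T). We assume ideal spheres with no
relaxation: magnetization follows the field instantaneously. `langevin`
switches to the odd series x/3 − x³/45 for |x| < 1e-4, where the closed
form loses ~8 digits to cancellation; the function is total and odd.

The scanner applies an FFL gradient G (T/m) and sinusoidal drive of
amplitude A (mT). For a voxel at signed distance u (mm) from the FFL the
field is B(t) = G·u·10⁻³ + A·10⁻³·cos ωt. One drive period of L(β·B(t)) is
Fourier-analysed (1024 samples, rFFT) and the real cosine coefficients at
harmonics 2–5 are retained, sampled on the line-scan pitch. A cosine (rather
than sine) drive phase makes the waveform even in t, so all coefficients are
real and the inverse problem stays over the reals; odd harmonics are even
functions of u (peaked on the FFL), even harmonics are odd (dispersive
lobes). Kernel support extends one drive sweep radius A/G plus ten Langevin
transition widths 1/(βG); coefficients beyond that are negligible because L
saturates. The drive frequency only labels the time axis — band-compressed
content is frequency-invariant by construction — and the per-harmonic
receive-chain factors (n·ω from induction, filter gains) are constants
absorbed into the arbitrary signal units.

The measurement at angle θ is the line projection of the concentration map
onto u = x cos θ + y sin θ (each voxel's mass deposited on its two
neighbouring line samples with linear weights — mass-conserving, and exactly
the transpose-friendly CT operator), convolved with each harmonic kernel.
Signals are therefore linear in concentration; noise, when requested, is
i.i.d. Gaussian added in the harmonic domain (the simulation baseline is
noise-free). Volumes are handled per axial slice: with the FFL in-plane,
slices project independently and the tomographic coupling is within-slice
across angles.

Tracer defaults (d = 30 nm, M_s = 300 kA/m, T = 300 K) give
β ≈ 1024 T⁻¹ and a native point-spread FWHM of 2·x₁⁄₂/(βG) ≈ 0.71 mm at
5.7 T/m (x₁⁄₂ ≈ 2.0785 solves L'(x) = 1/6), i.e. a high-performance
multicore-tracer regime with sub-millimetre intrinsic resolution. All three
parameters are configurable.

## Reconstruction

The forward operator stacks, per scan angle, a sparse projection matrix and
four Toeplitz convolution blocks; desk-scale grids (≤ 20,000 voxels)
materialize the matrix, larger grids use the identical matrix-free
apply/adjoint pair. The image estimate solves

x* = argmin_{x ≥ 0} ½‖Ax − y‖² + (λ/2)‖x‖²,

a convex nonnegative ridge problem (Gaussian likelihood and prior;
nonnegativity because concentrations are masses). The solver is monotone
FISTA: accelerated proximal-gradient steps with step 1/(‖AᵀA‖ + λ), where
‖AᵀA‖ comes from 50 power iterations with a fixed internal seed; whenever
the accelerated candidate would raise the objective the solver takes a plain
projected-gradient step and resets momentum, so the recorded objective trace
is non-increasing by construction. Default 250 iterations with early stop at
relative objective change < 1e-8.

λ defaults to 10⁻³·‖AᵀA‖, keeping the prior a fixed small fraction of the
data-fit curvature across grids and unit choices. Two consequences worth
knowing:

* The iteration map is positively homogeneous in the data, so scaling a
  noise-free measurement scales the reconstruction exactly — total image
  signal is exactly linear in tracer mass at *any* iteration count. The
  2.55 mg / 0.3 mg hollow-phantom ratio of 8.5 is therefore a check of
  pipeline linearity, not of solver convergence.
* The default λ slightly biases *relative* mass shares between separate
  sources (a few percent at ‖AᵀA‖·10⁻³). Quantitative multi-source work
  should drop λ to ~10⁻⁶·‖AᵀA‖, which recovers shares to <0.1% in the
  noise-free tests. Two scan angles also leave a diagonal source pair
  underdetermined (limited-angle ghosts); use ≥ 4 angles, or align the
  sources with a scan axis, when mass apportionment matters.

A normalized adjoint backprojection Aᵀy is kept purely as a smoke-test
baseline.

**Resolvability.** "Disjointly detected at the expected location" is
operationalized as: the reconstruction has a local maximum within one voxel
of each source position, and the image profile along the segment between
the two peaks dips below 90% of the smaller peak. The 90% dip fraction is a
package choice, exposed as a parameter. The separation sweep advances in
0.5 mm steps with the strong source at the FOV center and the weak one on
the +x ray, and returns inf when nothing inside the FOV resolves.

## Quantification

ROI statistics are plain sums/means/sample-sds over a mask (whole grid by
default — the full-area segmentation of 2D organ scans; 241×241 px covers
6×6 cm at ~0.25 mm pitch). The calibration is ordinary least squares of
signal on mass, with an optional forced zero intercept; the fitted line
carries a 12-hex configuration hash and signal-to-iron conversion refuses
images from a different configuration, because the arbitrary units change
with drive amplitude. The two printed threshold/iron pairs
(33,163 ↔ 3.2 µg; 50,346.7 ↔ 4.9 µg) are consistent with a zero-intercept
line, which the worked examples adopt. Reported iron masses round to 2
significant figures (3 for pellet iron), matching how such values are
printed; raw floats are always available. No partial-volume or attenuation
corrections are attempted.

## Diagnostics

Candidate thresholds are the observed signal values with the rule
"signal ≥ threshold ⇒ metastasis" (direction fixed by the biology; the
package does not search both directions). The Youden maximizer is selected
on the exact integer score tp·n_neg + tn·n_pos, so equal-J ties are exact
ties and break toward the smallest threshold (favouring sensitivity);
floating-point J values cannot reorder them. The bootstrap resamples
(value, label) pairs unstratified, redraws single-class resamples so the
iteration count stays exact, and reports percentile 2.5/97.5 intervals;
resamples where PPV or NPV is undefined (no predicted negatives/positives)
are excluded from that interval only. A stratified option exists. Controls
never enter the cutoff fit — they characterize background signal only.
Pooling two cohorts is plain concatenation of rows; no dose harmonization
is applied.

## Synthetic cohorts

Each metastatic animal draws a severity latent z ~ N(0,1); nodule area is
lognormal in z, and lung signal = background + slope·area + Gaussian noise.
Covariates with a Spearman target ρ share the latent through a Gaussian
copula with loading r = 2 sin(πρ/6) (exact for bivariate normal ranks), so
realized rank correlations approach the target as noise shrinks; the
area–signal correlation is governed directly by the slope/noise ratio and
reaches 1 in the noise-free limit. Non-metastatic tracer animals and
controls draw background-only signals; controls carry no primary tumor.
Cohort presets mirror the two study layouts (10 + 4 tracer animals; 7 + 4
tracer plus 5 controls) with the reported rank-correlation targets
(0.873/0.934 and 0.892/0.515). Marginals (lognormal medians and sigmas)
are realism choices — the study reports only rank statistics — so tests
against these cohorts validate the *statistical machinery*, not the
biological distributions. The generator is deterministic given its seed.

What the generator does not emulate: spatial lung images (cohort signals
are scalars, not reconstructed from phantoms), inter-organ signal
spillover, dose differences between cohorts, censoring or measurement
drift. Passing tests therefore show the pipeline's statistics behave
correctly under the stated generative model, not that real cohorts meet
that model.

## Problem sizes and numerical conventions

World coordinates in mm, origin at the FOV center, voxel centers addressed;
images are (ny, nx) with x along columns. Phantom maps store µg Fe per
voxel, so total mass is the array sum; all generators conserve requested
mass to well below 0.1%. Test and acceptance runs use 33–65 px grids
(0.25–1 mm pitch) and 2–4 angles, where explicit operators build in well
under a second; the tumor-phantom comparison runs on a 64×64 grid at 1 mm
with an elliptical support standing in for a segmented tumor boundary, and
the dynamic-range sweep on a 65×65 grid at 0.5 mm with angles (0°, 90°) —
the two collinear projection directions of 2D mode. The shine-through
default keeps 6 satellites at 2.5 mm increments (farthest well 15 mm);
spacing and count are independent parameters. The bootstrap-coverage
simulation uses Gaussian classes N(0,1) vs N(2,1) with 30 animals per class,
where percentile CIs show their nominal behaviour; materially smaller
cohorts exhibit the known percentile-bootstrap undercoverage.

## Known limitations

* No relaxation, no receive-chain filtering, no field inhomogeneity: the
  harmonic kernels are exact equilibrium responses.
* The harmonic-domain noise model is the simplest consistent choice; real
  scanners have correlated, filtered noise.
* The band-compressed operator is one consistent realization of
  harmonic-band demodulation; other demodulation orders would differ by
  fixed per-band factors.
* Per-slice 3D handling ignores FFL tilt out of plane.
* Animal-level published thresholds and bootstrap frequencies depend on
  unreleased per-mouse data and are not reproduced here; the package
  reproduces the arithmetic, the phantom-level physics, and the
  statistical procedure.
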
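# Methods

## Forward model

A localization event exposes a single emitter at position r_E (2-D lateral
plane, nanometres, origin at the pattern center) to K placements of a
doughnut beam with its intensity minimum at r_i. The beam is the paraxial
doughnut

    I(ρ) = e · (ρ²/R²) · exp(−ρ²/R²),        ρ = |r − r_i|,

peak-normalized (I(R) = 1) with an exact on-axis zero. The doughnut radius
defaults to the diffraction-limited R = λ/(2NA) (231 nm at 647 nm, NA 1.4)
and can be overridden. This analytic form was chosen because it has an exact
quadratic zero, closed-form gradients, and a single shape parameter;
absolute intensity units never matter because only intensity *ratios* enter
the probabilities. It does not attempt vectorial high-NA focal fields,
aberrations or axial structure.

Fluorescence under an excitation process of order c ≥ 1 is proportional to
I^c. Integer c covers one-, two- and three-photon excitation; fractional c
is accepted to represent effective superlinear schemes (e.g. photoswitching
kinetics folded into an exponent), but no photophysics is modeled — c is a
free parameter of the rate law.

### Sequences

* **MINFLUX**: three exposures at the vertices of an equilateral triangle
  of circumradius L/2 plus a final exposure at the pattern center (K = 4).
  The first vertex is placed on the +y axis; the orientation is a
  convention fixed for reproducibility.
* **RASTMIN**: an m×m raster of minima with corners at (±L/2, ±L/2)
  (default m = 4, K = 16), row-major with rows along y ascending. K for the
  raster case is a free choice; m = 4 keeps the exposure count within a
  factor four of MINFLUX while sampling the FOV uniformly.

L is the full pattern extent (MINFLUX circumcircle diameter, raster span)
and defines the field of view [−L/2, L/2]².

### Counts and background

Counts are Poisson with mean λ_i ∝ I^c(r_E − r_i) plus uniform background.
We condition on the total detected photon budget N, making the count vector
multinomial(N, p) with

    p_i = s · u_i / Σ_j u_j + (1 − s)/K,
    u_i = I^c(r_E − r_i),   s = SBR/(SBR + 1).

Conditioning removes the emitter brightness as a nuisance parameter and
leaves the position Fisher information unchanged; it also matches the
fixed-N convention in which precision is quoted ("σ at N = 500"). The SBR
is a single scalar per configuration: it is defined for an emitter at the
pattern center, with the background spread uniformly over the exposures, so
the mixing is position-independent. `SBR = inf` (pure signal) is supported
in the forward model; for information calculations the **no-background
limit is operationalized as SBR = 1e6**, which keeps every p_i strictly
positive and the Fisher information continuous across the FOV (relative
bias < 1e−3). If every u_i vanishes simultaneously (only possible for a
single-exposure sequence), the signal weights fall back to uniform so the
model stays total.

Default scenario parameters — L = 100 nm, N = 500, SBR = 4, λ = 647 nm,
NA 1.4, c = 1 — are the reference operating point of the precision-map
calculations; the multiphoton rows of a typical comparison use λ = 800 nm
(c = 2) and λ = 1300 nm (c = 3), with the doughnut radius scaling
accordingly.

## Cramér–Rao bound

With analytic probability gradients (chain rule through I^c and the mixing
formula; rows of ∇p sum to zero exactly),

    F(r) = N Σ_i (1/p_i) ∇p_i ∇p_iᵀ,      σ_CRB(r) = √(tr F⁻¹ / 2).

F is exactly linear in N, so σ_CRB(kN) = σ_CRB(N)/√k algebraically. The
scalarization √(tr F⁻¹/2) is the root of the per-axis average variance —
the standard isotropic summary. The 2×2 inverse is closed-form with a
condition-number guard (error above 1e12); exposures with p_i = 0 *and*
zero gradient (the center exposure for an emitter exactly on the zero at
SBR = ∞) contribute nothing and are skipped, while p_i = 0 with a non-zero
gradient raises a singular-model error directing the caller to a finite
SBR. Precision maps evaluate σ_CRB on a g×g lattice over [−L/2, L/2]²
(default g = 41, which resolves the map structure at negligible cost).

Two cross-order summaries are defined at the pattern center with the
background switched off (SBR = 1e6) and the *same* beam for both orders:
the improvement ratio σ_CRB(c_a)/σ_CRB(c_b) and the photon-equivalence
ratio N_b/N_a = (σ_b/σ_a)², exact by the 1/√N law. At the center the
probabilities are order-independent by symmetry and the log-gradient of I^c
is exactly c times that of I, so the improvement ratio for c_a = 1 vs
c_b = c approaches c in the small-L/R limit; at L/R ≈ 0.43 (L = 100 nm,
R = 231 nm) it is still 2.000 for c = 2 because the normalization-induced
corrections cancel at the symmetric point.

## Maximum-likelihood estimator

The position estimate maximizes the multinomial log-likelihood
ℓ(r) = Σ n_i ln p_i(r), with the same SBR mixing model used for generation
(matched model; mismatch studies are out of scope). Because the likelihood
can be multimodal at low N, optimization is grid-first:

1. coarse lattice at 1 nm pitch over the FOV plus a 20% margin, ties broken
   toward the smallest |r|;
2. Nelder–Mead refinement from the best coarse node, with an explicit
   initial simplex of edge 1 nm (scipy's adaptive simplex degenerates when
   a start coordinate is exactly zero, and an explicit simplex makes the
   refinement exactly translation-equivariant), xatol = 0.01 nm,
   fatol = 1e−4 (the likelihood varies by ~0.5·F·xatol² ≈ 1e−5 across an
   xatol-sized simplex, so tighter function tolerances only stall).

Coarse-grid probabilities depend only on the forward model, not the counts,
and are cached across records in Monte-Carlo batches. Estimates are not
clipped to the FOV; optima beyond the margin are flagged as unconverged
rather than truncated, and Monte-Carlo summaries exclude and count failed
records instead of imputing. A model whose probabilities concentrate on a
single exposure carries no position information and is flagged
non-identifiable.

`monte_carlo_precision` draws seeded count records (per-record substreams
via `SeedSequence(master_seed, spawn_key=(record_index,))`, so any record is
reproducible in isolation), fits each, and reports per-axis and pooled
empirical standard deviations, the bias vector, and σ_CRB at the true
position. At the reference operating point the pooled empirical σ of 1000
fits lies within ~2–4% of the bound for both sequences and c ∈ {1, 2}.

## Synthetic data: what it does and does not emulate

The generator produces exactly the statistics the model assumes:
multinomial counts over K exposures with probabilities from the doughnut
model plus uniform background, at fixed total N. It emulates shot noise,
background mixing and the excitation nonlinearity. It does **not** emulate
detector dead-time or afterpulsing, emitter blinking or photobleaching,
drift, model mismatch between the assumed and the true beam, or
position-dependent background — so estimator tests certify efficiency
*under the matched model*, not robustness of real instruments to these
effects.

## Numerical choices and degenerate inputs

* Probability normalization asserted to 1e−12; sampling rejects weight
  vectors off by more than 1e−9.
* Gradients are analytic everywhere (the I^(c−1) factor at the beam zero is
  masked explicitly; the gradient vanishes there for every c ≥ 1). Central
  finite differences (step 0.01 nm) serve only as a test oracle, compared
  norm-wise at 1e−6 relative.
* The 2×2 Fisher inverse uses the closed form with eigenvalue-based
  condition guard; collinear-minima sequences (no transverse information)
  raise a singular-model error rather than returning garbage.
* All-zero count records and K-mismatched count vectors are rejected;
  repeats < 2 in the Monte-Carlo harness are rejected.

## Known limitations

* Lateral (2-D) only; no axial bound, no vectorial PSF, no saturation.
* N and SBR are treated as known — the bound is for position estimation
  alone, not joint estimation with brightness/background.
* The CV (std/mean) of a σ_CRB map over the square FOV is a blunt
  heterogeneity summary: it is dominated by the bulk of the map, while the
  physically salient feature of superlinear excitation — a deepening
  center relative to the periphery — is better captured by the max/min
  contrast, which map summaries also report. Under this beam model the
  contrast ordering (2p-MINFLUX most heterogeneous, raster scanning more
  uniform at matched order) holds where the CV ordering need not.
* Adaptive pattern re-centering / shrinking-L iteration schemes are out of
  scope; a single static pattern is analyzed per event.
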
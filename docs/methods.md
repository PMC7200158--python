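# Methods

## Isodesmic equilibrium

A protomer P self-associates head-to-tail into linear oligomers Pₙ with
the same stepwise dissociation constant K for every addition, so
cₙ = m (m/K)ⁿ⁻¹ with m the free monomer concentration.  Two observables
close the system once the series is truncated at order N:

* protomer conservation, Σ n cₙ = c_tot;
* the number-average species mass, M₁ Σ n cₙ / Σ cₙ = M_avg.

K_D is reported as m²/c₂ (identical to K at the solution).

**Solver.**  Substituting x = m/K makes the mass constraint
Σ n xⁿ⁻¹ / Σ xⁿ⁻¹ = M_avg/M₁ a strictly increasing function of x alone
(range (1, N)), so it is solved by bracketed Brent root finding
(xtol 1e-12, machine-precision rtol); m then follows from conservation
and K = m/x.  This guarantees uniqueness and convergence, unlike a
generic 2-D Newton solve of (m, K).  Feasibility demands
M₁ < M_avg < N·M₁ strictly; both boundaries raise an explicit
infeasibility error (pure monomer leaves K_D unbounded).

**Averaging convention.**  The constraint uses the *number*-average over
species, matching the worked system of equations this module
implements, although MALS instruments conventionally report a
weight-average.  `SpeciesDistribution.weight_average_mass` exposes the
weight-average for comparison; the solver itself is defined on the
number-average.

**Monomer mass.**  The reference protomer mass defaults to 10 kDa in the
worked examples (the equations use 10m + 20d + 30t), while the constructs
measured by SEC-MALS are nominally 9.9 kDa; the mass is an explicit
parameter everywhere.

**Truncation behavior.**  K_D(N) is non-decreasing in N and converges to
the closed form K = c_tot (1−x)²/x, x = 1 − M₁/M_avg, within 1 nM by
N = 11 at the reference conditions.  Exact solution of the N = 11 system
gives 946.554 nM, which rounds to 947 nM.

**Series fitting.**  `fit_kd_to_series` generalizes the single-point
inversion to a dilution series by least squares on predicted vs observed
average mass, with K searched on a log scale (bounded scalar
minimization, 1e-12 tolerance).  Each row's detector concentration is
taken as that row's total protomer concentration (µM converted to nM).

## Helical geometry

`HelicalSymmetry` holds the per-protomer twist (degrees) and rise (Å);
pitch = rise·360/twist and protomers-per-turn = 360/twist.  The builder
places strand A centroids on a cylinder,
(R cos iΔφ, R sin iΔφ, iΔz), and generates the antiparallel strand B by
a two-fold rotation about an in-plane axis at a configurable
`dyad_phase`.  The dyad is an involution and flips the axial polarity,
so antiparallelism holds by construction.  The radius (default 20 Å),
dyad phase (default 0°) and handedness (default right) are presentation
parameters: the filament's true values are map-derived quantities that
the symmetry numbers alone do not determine, and the builder is intended
for schematic coordinates, not atomic modeling.  Centroids are exported
as CA pseudo-atoms (chains A/B) through gemmi at PDB precision (1e-3 Å).

## TIRF spot counting

The pipeline converts a short movie of diffraction-limited spots into an
estimate of the single-fluorophore intensity g and per-spot copy
numbers.

1. **Background subtraction** uses the classic rolling-ball estimate
   (ball diameter 5 px by default): at each pixel the background is the
   apex height of the ball rolled under the intensity surface.  A ball
   this small shaves a brightness-dependent few percent off narrow
   peaks (about 10% of peak height at σ = 1 px); the shave is close to
   constant per spot in integrated terms, which the calibration step
   cancels (below).
2. **Time averaging**: centered window-5 rolling mean, edge-truncated.
3. **Detection**: candidate local maxima at least 2 px apart and above
   the frame median + 4 robust σ (median absolute deviation scaled) are
   refined by a damped Gauss–Newton least-squares fit of a 2-D Gaussian
   with σ fixed at the PSF width (default 1 px) over a 7×7 window, with
   a constant local-background term.  The fit model is the
   *pixel-integrated* Gaussian; point-sampled models systematically
   under-estimate integrated intensities by ~5–10% at σ = 1 px.  The
   fitted amplitude is tested one-sided against its standard error
   (normal reference) at α = 0.05.  Because candidates are *selected
   maxima*, this amplitude test alone does not set the false-positive
   rate; the candidate threshold does, and the downstream ≥10-frame
   trajectory filter removes what survives on pure noise.  When a
   single-spot fit leaves a structured residual (> 4σ of noise), a
   constrained two-spot fit on the same window is attempted and kept if
   it reduces the residual sum of squares by >30%; pairs closer than
   about one PSF σ merge into a single detection.
4. **Linking**: per consecutive frame pair, detections are matched by
   minimal total squared displacement (optimal assignment), gated at
   `max_disp_px` (default 2 px — generous for spots diffusing
   ~0.05 px/frame, tight enough that correlated noise cannot chain).
   Track ends are then joined to later track starts across gaps of at
   most 4 missed frames, greedily by ascending per-frame displacement,
   with the displacement budget scaled by the frames bridged.
   Trajectory length counts *detected* frames (gaps excluded), and the
   ≥10-frame filter is boundary-inclusive.
5. **Intensities**: one sample per selected trajectory — the integrated
   fitted intensity 2πσ²A at its first frame (peak amplitude optionally
   available).
6. **Mixture modeling**: 1..k_max-component 1-D Gaussian mixtures, each
   fit with 100 random EM restarts capped at 500 iterations, component
   variances floored at 1e-6 of the sample variance; the component count
   minimizing BIC (or AIC) is selected, and counts whose fits fail are
   excluded, effectively lowering k_max.
7. **Calibration**: with sorted component means μ₍₁₎ ≤ μ₍₂₎ ≤ …, the
   single-fluorophore intensity is g = μ₍₂₎ − μ₍₁₎ and the implied
   offset b = μ₍₁₎ − g; intensities normalize as (raw − b)/g.  Using the
   *spacing* rather than μ₍₁₎ itself makes the estimate robust to any
   per-spot constant intensity deficit (imperfect background
   subtraction, bleaching within the exposure): such a deficit shifts
   every component mean equally and cancels in the difference, being
   absorbed into b instead.  The "fraction within 10×" summary is
   computed on the normalized values, boundary-inclusive.

`mean_gray_values` provides per-field MGVs over an optional crop (with a
helper for the centered 1000×1000 convention).

## Resampling statistics

* `bootstrap_diff_means`: each group resampled with replacement at its
  own size (default 5000 resamples); the middle-95% empirical interval
  of mean(a*) − mean(b*); "significant positive" means the interval
  excludes zero from below.
* `ratio_of_means_bootstrap`: each group's mean bootstrapped, a Gaussian
  fit to each bootstrap distribution, and the ratio's standard error
  propagated to first order, r·√((σ_a/μ_a)² + (σ_b/μ_b)²).
* `rank_sum_test`: two-sided Mann–Whitney U; exact enumeration when the
  pooled sample is ≤12 without ties, otherwise the tie-corrected normal
  approximation with continuity correction.

## Synthetic data

`simulate_tirf_stack` renders spots with an explicit copy-number
probability vector (so ground-truth summaries are exact), pixel-integrated
Gaussian PSFs normalized so one surviving fluorophore contributes
exactly g counts, per-fluorophore binary survival with probability
exp(−bleach·frame) (no blinking), a linear background gradient, Poisson
shot noise followed by Gaussian read noise (camera gain fixed at
1 count/photon), and Gaussian random-walk motion.  Defaults describe
the regime the pipeline targets: 512×512 px, 150 spots, 40 frames,
g = 120 counts, σ = 1 px, background 20 counts with a 10-count gradient,
read noise 2 counts, bleach 0.02/frame, diffusion 0.05 px/frame, and a
copy-number vector over 1..12 fluorophores with 10% of spots above 10 —
so the ground-truth "fraction within 10× of g" is 0.90.  What the
simulator does *not* emulate: fluorophore blinking and maturation,
realistic cell morphology and autofluorescence structure, TIRF
evanescent-field depth effects, and camera gain/offset maps.  Passing
end-to-end tests therefore demonstrate correctness of the analysis chain
under a faithful noise/bleaching model, not robustness to every artifact
of live-cell data.

`simulate_mals_series` forward-models average masses from a ground-truth
K_D with lognormal mass noise; `simulate_mgv_fields` draws two normal
MGV sets with a known fractional effect.

## Problem sizes and determinism

Tests run the full pipeline at the default 512×512 / 150-spot / 40-frame
scale (a few tens of seconds) and smaller 256–320 px movies for unit
checks.  All stochastic stages consume a single seed through
`numpy.random.default_rng` (sklearn states derived from it), and outputs
are byte-identical across reruns with the same configuration and seed.

## Known limitations

* The amplitude significance test is conditional on candidate selection
  (see above); α is honored at the fit level, not as a per-pixel
  false-discovery control.
* The two-spot refinement caps at two Gaussians per window; clusters of
  three or more overlapping spots bias intensities upward.
* The isodesmic fit to a dilution series assumes the detector
  concentration is the equilibrium total protomer concentration for that
  row (no on-column dilution kinetics).
* GMM-based calibration needs the two smallest-copy-number classes to be
  populated; pools dominated by high-copy spots yield a spacing that
  reflects consecutive high multiples instead (still g, but with larger
  variance).
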
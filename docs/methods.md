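# Methods

## The two-state occupancy model

The model treats the interior of a condensate as two sub-volumes: a fraction
*f*_occupy = *V*_occupy/*V*_total in which all client molecules reside (at the
effective concentration *c*_occupy), and the remainder, which is client-free.
Averaging over the droplet gives the two observables

* *c*_actual = *c*_occupy·*f*_occupy — the global client concentration a
  linear (dye) reporter measures, and
* *I*_observed = *I*(*c*_occupy)·*f*_occupy — the droplet-averaged signal of a
  nonlinear proximity reporter with calibration *I(c)*.

This "all-or-none" distribution is deliberately the simplest caricature of
client localization around the scaffold network; real concentration profiles
are continuous. The model's value is that *f*_occupy is identifiable from two
droplet-level measurements whenever *I* is superlinear, and that it converts
directly into two interpretable numbers: the overall proximity enhancement
factor 1/*f*_occupy, and the effective per-molecule client–scaffold binding
free energy obtained by equating the free-energy cost of the volume
reduction with the binding gain, ε = *k*_B*T*·ln *f*_occupy. ε is returned
signed (≤ 0, favorable); magnitudes are reported alongside. The temperature
defaults to 300 K (*k*_B*T* = 0.5962 kcal/mol, using
*k*_B·*N*_A = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹) and is configurable.

### Solver

Substituting *c*_occupy = *c*_actual/*f* gives the scalar equation
*g(f)* = *I*(*c*_actual/*f*)·*f* − *I*_observed = 0 on *f* ∈ (0, 1]. For a
superlinear *I*, *I(c)/c* is increasing, so *g* is strictly decreasing in
*f* and the root is unique. It is found with Brent's method bracketed on
[*c*_actual/*c*_max, 1] (a bracketed, derivative-free method with guaranteed
convergence on a monotone objective, converging faster than plain bisection)
to a tolerance of ~1e−12 in *f*. Degenerate cases are reported as statuses
rather than numbers:

* `no_enhancement` — *I*_observed ≤ *I*(*c*_actual): *f* is pinned at 1
  (enhancement 1, ε = 0). This is the behavior of a free client with no
  scaffold affinity.
* `out_of_range` — even *c*_occupy = *c*_max cannot reproduce
  *I*_observed; the implied effective concentration exceeds the calibration
  limit, so no factor is reported (no clamping). With the bundled
  50 µM-capped surrogate calibration, the worked droplet
  (*c*_actual = 4.87 µM, *I*_obs = 15 582) lands here — its implied
  *c*_occupy ≈ 93 µM — which is exactly how such droplets should be treated.
* `non_identifiable` — the objective varies by less than 1e−9 (relative to
  *I*_observed) across the bracket, i.e. the reporter is numerically linear:
  *I*(*c*/*f*)·*f* is then constant in *f* and no degree of localization is
  detectable. A linear reporter is structurally blind to localization.

Every `ok` solution closes both model equations:
|*c*_occupy·*f* − *c*_actual|/*c*_actual < 1e−8 and
|*I*(*c*_occupy)·*f* − *I*_obs|/*I*_obs < 1e−6 (tested). For power-law
curves *I* ∝ *c*ⁿ (n ∈ {1.5, 2, 3, 4}) the solver is checked against the
closed form 1/*f* = (*I*_obs/*I*_exp)^(1/(n−1)) to 1e−6 relative.

## Reporter calibration

The measured reporter curve is represented as a monotone interpolant through
the calibration table. Noisy tables are first projected onto the nearest
nondecreasing sequence (isotonic regression); if that projection moves more
than 20% of the intensity mass the table is rejected as not credibly
monotone. Interpolation uses a shape-preserving piecewise cubic (PCHIP) in
log–log space when all coordinates are positive: power-law-like stretches of
the curve are straight lines there, so a 16-point log-spaced grid over
1–50 µM reconstructs the smooth surrogate to < 1% everywhere (tested), and
monotonicity is preserved exactly. Evaluation outside the tabulated range is
flagged rather than forbidden. Dye calibrations (client and scaffold
channels) are ordinary least-squares lines, optionally through the origin;
inversion outside the fitted concentration range is flagged, and refused when
extrapolation is disallowed. The scaffold-density workflow intentionally
extrapolates (droplet scaffold concentrations of hundreds of µM against a
10–160 µM calibration); linear extrapolation is assumed.

## FRAP

The analysis operates on the ratio r(t) = *I*_ROB/*I*_TOT, which cancels
unintended whole-field acquisition bleaching (the generator reproduces this
cancellation exactly and it is tested). Normalization maps the pre-bleach
mean of r to 1 and r at the *first post-bleach sample* to 0 — not the
post-bleach minimum; this choice is deliberate (the first sample defines the
bleach depth; a later minimum would be noise-selected) and the bleach index
can be supplied or autodetected as the largest single-step drop in r. The
post-bleach series, re-zeroed in time, is fit to A(1 − e^(−t/τ)) by
least squares with deterministic initialization (A₀ = last value, τ₀ = time
to reach A₀(1 − 1/e)). A is not clipped: fits above 1 are flagged and above
1.05 warned, since silent clipping would mask normalization errors. Traces
are fit individually and aggregated afterwards.

## Image statistics

Puncta are 8-connected components of pixels strictly above threshold within
the cell mask. The default threshold is Otsu's method computed inside the
mask (deterministic and standard; a fixed value can be supplied, and every
run records the threshold used). The area filter keeps regions strictly
greater than the minimum (default 0.01 µm²), with a 1e−9 relative tolerance
so a region whose area equals the cutoff only through floating-point
round-off is still excluded. The partition coefficient uses **mean** per-pixel
intensities inside vs outside (totals over regions of unequal area are not
scale-free); the condensate-formation ratio uses summed intensities by
construction. Both statistics are invariant under global intensity rescaling
(tested). Cell outlines are supplied explicitly, or crudely estimated as
pixels above a low quantile for synthetic frames.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated:

* **Reporter surrogate.** The proximity reporter is modeled as a single-step
  4M ⇌ T mass-action equilibrium ([T] = k_tet·[M]⁴; only tetramer-bound
  monomers fluoresce), the simplest model producing the required
  superlinear, saturating, monotone curve. The mass balance
  4·k_tet·m⁴ + m = c is solved by bracketed root finding (closure tested to
  1e−10 relative). Defaults: k_tet = 1e−4 µM⁻³ — placing the half-tetramer
  transition near 27 µM, mid-range of the 1–50 µM calibration window so the
  curve is strongly superlinear across the solver's working range —
  brightness 100 a.u. per µM of tetramer-bound monomer.
* **Droplet measurements** are generated exactly under the two-state model
  (c_actual = c_added·enrichment; I_observed = I(c_actual/f)·f) with
  independent multiplicative unit-mean lognormal noise (stated CV) on
  c_actual and I_observed. Default 33 droplets per condition; the demo
  conditions are a strong client (enrichment 5, f = 1/16) and a weak one
  (enrichment 2.09, f = 1/4.5), with doses chosen so c_occupy stays inside
  the calibrated range.
* **Images** are circular disks (pixel-center membership, so truth masks are
  exact) at prescribed inside/outside ratios on a uniform background with
  additive Gaussian noise, clipped at zero. No point-spread function, shot
  noise, partial-pixel coverage, 3D structure, or cell-to-cell variability
  is modeled — passing recovery tests demonstrates correctness of the
  estimators, not robustness to real microscope physics.
* **FRAP traces** impose the first-order recovery on the ratio and multiply
  both raw channels by a global exponential decay; noise is Gaussian on the
  ratio. Default amplitudes/half-lives emulate a fast mobile client
  (A = 0.86, t½ ≈ 18.3 s) and a slow scaffold (A = 0.46, t½ = 156 s).

All generators are deterministic under a fixed seed.

## Problem sizes and numerical choices

Validation runs use 33 droplets per condition, 16-point calibration grids,
and 50–100-replicate Monte-Carlo checks for FRAP — sizes chosen to match the
per-condition sampling the analysis is designed for while keeping the whole
suite fast. Noise defaults (5% measurement CV, 2% FRAP ratio SD, image noise
at 5% of background) are plausible confocal magnitudes chosen once, not
inferred from any dataset. Measured recovery under these conditions: solved
enhancement unbiased to < 2% noiselessly (limited only by calibration
interpolation error) and < 10% at 5% CV with n = 33.

## Known limitations

* The two-state model is a simplification; the recovered *f*_occupy is an
  effective volume fraction, not a measured spatial distribution.
* ε assumes the volume-reduction entropy is exactly compensated by binding;
  it is an effective free energy, not a dissociation constant.
* Enhancement is only measurable where the reporter is meaningfully
  nonlinear and c_occupy stays within the calibrated range; outside that
  window the solver reports statuses instead of numbers by design.
* No spatially resolved occupancy, no diffusion-model (spot-size-aware)
  FRAP, no double-exponential fits, no spectral unmixing, no correction for
  imperfect two-channel co-registration.
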
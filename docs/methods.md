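# Methods

## Forward transport model

Photons are transported through a one-dimensional stack of homogeneous
layers (default: 1.0 mm glass slide, tissue, 1.0 mm glass slide; glass
n = 1.524, tissue n = 1.4) using the standard weighted-photon
hop–drop–spin random walk for multi-layered media. Scattering
deflections are sampled from the Henyey–Greenstein phase function with a
fixed anisotropy factor (default g = 0.9, typical for soft tissue in the
visible range); the tissue scattering coefficient is derived from the
reduced coefficient through the similarity relation μs = μs′/(1 − g).
Boundaries apply unpolarized Fresnel reflection/refraction; the
dimensionless remaining step is carried across layer interfaces, and
clear (non-scattering, non-absorbing) layers are traversed ballistically.

Measurement geometry follows a double-integrating-sphere instrument:

| parameter | default | meaning |
|---|---|---|
| beam | 1.0 mm flat-top disk | collimated illumination (pencil beam available) |
| port radius | 3.175 mm | detection port (0.25 inch diameter apertures) |
| sample half width | 5 mm | ~1 cm samples; photons beyond it are lost |
| specular cone | 5° | back-exits within the cone count as specular, not Rd |
| weight threshold / roulette survival | 1e-4 / 0.1 | standard termination |
| photon budget | 1e6 reported values, 1e5 in optimizer iterations | keeps the MC standard error of Rd/Tt near or below 0.5 %, under the 0.8 % instrument calibration error the noise model assumes |

The collimated specular reflection at launch is computed analytically
(two-interface expression for the air/glass/tissue entry,
r1 + (1 − r1)² r2 / (1 − r1 r2)) and excluded from Rd, matching a DIS
measurement with background subtraction; whether near-axial diffuse
exits join the specular or the Rd tally is controlled by the cone angle
(set it to 0° to put everything in Rd).

Energy bookkeeping is exact per run, not just in expectation:
specular + Rd + Tt + absorbed + lost = 1 to 1e-9. Russian roulette
preserves this by moving a killed photon's residual weight into the
absorbed tally and subtracting the survivor's weight boost (w/p − w)
from it; the expected adjustment is zero, so the absorbed estimate stays
unbiased while the identity holds exactly.

Tallies report standard errors from the per-photon contribution
variance. Identical inputs and seed give bitwise-identical results (the
kernel is a single-threaded numba loop with one seeded generator).

## Inverse solver

Per wavelength, (μa, μs′) is recovered from a measured (Rd, Tt) pair by
minimizing the combined relative misfit

    f = [(Rd_sim − Rd)/Rd]² + [(Tt_sim − Tt)/Tt]²

Relative residuals keep the two observables comparable despite their
different magnitudes. The search runs in (log μa, log μs′):

1. **Initialization.** A lookup table of forward simulations on a
   log-spaced grid (default 10×10 over μa ∈ [0.01, 5] mm⁻¹,
   μs′ ∈ [0.1, 10] mm⁻¹ — covering soft-tissue values with margin) is
   interpolated bilinearly in log space; the misfit is minimized on the
   interpolated surface (cheap Nelder–Mead) to produce the start point.
2. **Refinement.** Nelder–Mead on the true forward model, every
   evaluation with the *same* seed (common random numbers), which makes
   the noisy objective a deterministic function of the parameters and
   lets the simplex descend below the nominal noise floor. Convergence:
   √f ≤ tol (default 0.01) or max_iter (default 200) forward
   evaluations. A quadratic penalty keeps the simplex inside the search
   range; solutions within numerical reach of a range bound are flagged
   `at_bound` and `converged=False` rather than silently clipped.

A final forward run at the full photon budget and an independent seed
stores the fitted (Rd, Tt) and their standard errors as diagnostics.
The whole procedure is deterministic for fixed inputs and configuration.

Replicate handling mirrors triplicate DIS practice: `average_replicates`
averages Rd/Tt per (sample, wavelength) before inversion; cohort spectra
aggregate per-record results as arithmetic mean ± sample SD (ddof = 1,
reported as absent for a single record). Wavelengths are inverted
independently — no spectral smoothing or constraint ties neighbours
together.

## Penetration depth

δ = 1/√(3 μa (μa + μs′)), valid in the diffusion regime μa ≪ 3 μs′. The
ratio μa/(3 μs′) is reported as a validity diagnostic with a warning
threshold of 0.1 (no published cutoff exists; beyond it δ is an
extrapolation, which is flagged but still computed since the comparisons
remain informative).

Cohort depths are computed **per sample first**, then averaged. δ is
convex in μa, so this mean exceeds the depth evaluated at the
cohort-mean properties — evaluating the human-ureter reference means at
635 nm gives 0.825 mm while the published cohort value is 0.9 ± 0.2 mm;
the per-sample-first convention explains that gap and the two agree
within the SD. A `mean_properties` mode covers inputs that only provide
tabulated means. Band comparisons return b/a ratios or fractional
differences (a − b)/a per shared wavelength plus band extrema; summaries
are conventionally rounded to one decimal (full precision is kept
internally).

## Sensitivity scan

The g/n scan re-inverts the same measurement table one assumption at a
time (g varied at n = 1.4, n varied at g = 0.9; defaults
g ∈ {0.8, 0.9, 0.95}, n ∈ {1.3, 1.4, 1.5}) and reports
100·(x_scan − x_base)/x_base per wavelength with signed band extrema.
The baseline cell is compared against itself and is identically 0 %. On
synthetic ureter cohorts the g-scan moves the recovered coefficients by
a few percent — well inside the cohort SD — while the n-scan shifts μa
by roughly ±25–30 % and μs′ by ∓5–8 %, reproducing the known ordering
(refractive-index mismatch feeds mainly into the recovered absorption).
The exact published percentages depend on the measured raw spectra and
are not reproducible from tabulated summaries; only the ordering is
asserted.

## Synthetic tissue generator

Ground-truth spectra use an embedded chromophore basis instead of
literature extinction tables (no downloads, and the calibration below
absorbs any shape mismatch). Each curve is a sum of Gaussian bands on
400–700 nm:

* deoxyhemoglobin: 427 nm (σ 22), α-band centered at 554 nm (σ 26, its
  physical position; on the 5 nm grid the resulting peak sits at 550),
  plus 605 nm (σ 60) and 758 nm (σ 60) shoulders that keep deoxy- above
  oxyhemoglobin absorption everywhere in 600–700 nm;
* oxyhemoglobin: 416 (σ 18), 540 and 575 nm (σ 11) plus a weak flat red
  tail;
* bilirubin: 485 nm (σ 20).

The main hemoglobin band is scaled to 100 mm⁻¹ so fitted blood volume
fractions land at physiological few-percent values. Absorption is linear
in the weights:

    μa(λ) = bvf [S εoxy + (1 − S) εdeoxy] + c_bil εbil + μa0

and reduced scattering is a Rayleigh/Mie mixture normalized at 500 nm:

    μs′(λ) = a [f_Ray (λ/500)⁻⁴ + (1 − f_Ray) (λ/500)^(−b_Mie)]

strictly decreasing in wavelength for a > 0 (b_Mie is kept ≥ 0.05).

**Preset calibration.** The six tissue presets were fitted once by
weighted least squares (weights 1/SD) to the bundled reference table of
mean ± SD optical properties at 11 wavelengths, with the oxygen
saturation bounded at ≤ 0.2 for the deoxy-dominant ureter/carcinoma
spectra and ≥ 0.9 for the oxy-dominant fat spectra, then frozen as
package constants. Every preset reproduces the reference means within
1 SD at ≥ 10 of 11 wavelengths for both coefficients, peaks at the grid
points nearest the named hemoglobin bands, and decreases strictly in
μs′.

**Cohorts.** Per-sample variability is multiplicative lognormal
(unit median) on the chromophore weights and the scattering amplitude,
with per-preset coefficients of variation taken as the median SD/mean of
the reference table (e.g. ureter: 44 % absorption, 24 % scattering);
thickness is truncated normal (floor 0.1 mm) with per-tissue means/SDs
from the study cohorts (human ureter 1.2 ± 0.4 mm, porcine ureter
0.6 ± 0.2 mm, fat 1.5 ± 0.3 / 1.6 ± 0.2 mm, carcinomas 1.8 ± 0.5 /
1.7 ± 0.2 mm). Everything is reproducible from one seed.

**Measurements.** One forward simulation per wavelength; each replicate
(default 3) then receives an independent multiplicative calibration
error uniform within ±0.8 %, the instrument's calibration accuracy. The
generator does *not* emulate: spatial heterogeneity within a sample
(layered mucosa/muscle structure), oxygenation drift during ex vivo
handling, wavelength-correlated instrument drift, or replicate-level
repositioning error. Passing end-to-end tests therefore demonstrate the
correctness of the inversion chain under the stated noise model, not
robustness to structured artifacts in real measurements.

## Numerical choices and test problem sizes

* Log-space bilinear interpolation of the lookup table; interpolation is
  exact at the nodes.
* Degenerate inputs: μt = 0 layers are ballistic; μa ≤ 0 makes δ
  undefined (error); Rd + Tt ≥ 1 is rejected as non-physical; a
  TIR-trapped photon in a clear layer of an infinitely wide slab is
  terminated to `lost` after 1e6 events.
* All randomness flows from explicit integer seeds; every pipeline stage
  is bitwise reproducible.
* The regression suite runs scaled-down problem sizes chosen to keep the
  full suite near 15–20 single-core minutes: lookup tables 6×6–8×8 at
  2–5·10⁴ photons/node, 3–5·10⁴ photons per optimizer evaluation,
  1e6-photon forward data for the 4×4 recovery grid, cohorts of 2
  samples × 3 wavelengths for the end-to-end and sensitivity checks.
  Library defaults remain at the full budgets (10×10 lookup, 1e5
  iteration / 1e6 verification photons).

## Known limitations

* The slab model is laterally homogeneous; real ureter wall layering is
  volume-averaged into one set of coefficients.
* δ is a diffusion-regime projection; at short wavelengths with strong
  absorption (fatty tissue below ~450 nm) the validity ratio exceeds 0.1
  and δ should be read as a comparative index, not a depth.
* The chromophore basis is a calibrated surrogate: band positions are
  physical, band shapes are Gaussian conveniences; it is not a
  substitute for measured extinction spectra outside 400–700 nm.
* Inversion assumes fixed (g, n); the sensitivity module quantifies, but
  does not remove, the resulting systematic uncertainty.
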
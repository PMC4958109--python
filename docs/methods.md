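# Methods

This note documents the models, numerical choices, and limitations behind
beamkit, in the order a user meets them.

## Energy grid and spectra

All spectra live on a shared 1 keV grid: bin *i* (1-based) covers
[i, i+1) keV and carries the fluence evaluated at the bin center
i + 0.5 keV, in photons/mm²/mAs at 100 cm from the focal spot. The default
grid has 150 bins (diagnostic range); nothing in the code assumes that
length, so orthovoltage-range tables simply use a larger grid. The
Duane–Hunt limit — no photons at or above the tube potential — is a hard
invariant: spectral tables are clamped on load (with a logged warning if
the clamp changed data), and generated spectra respect it by construction.

## kV interpolation

Tabulated models give fluence at discrete tube-potential nodes. The
engine fits a cubic spline independently per energy bin across the nodes
(`scipy.interpolate.CubicSpline`, axis 0). Boundary condition:
**not-a-knot**, the standard default, chosen over a natural spline because
it reproduces exactly any table that was itself generated by a single
cubic polynomial of kV — a contract the test suite enforces at 1e-9
relative — whereas a natural spline distorts generic cubics near the end
nodes. Queries at a node return the stored row verbatim; queries outside
the node range raise (`OutOfRangeError`) rather than extrapolate.
Interpolated fluence is clamped at zero from below, since spline ringing
near the Duane–Hunt cutoff can produce small negative values.

## kV ripple

Generator ripple r (%) is modeled as a sawtooth sweeping the potential
from kV·(1 − r/100) up to kV over one period; the output spectrum is the
unweighted mean of the interpolated spectra at `n_samples = 100` uniform
phase samples (endpoints included, so `n_samples = 2` averages trough and
peak exactly). The waveform shape is a modeling choice — ripple is
reported as a peak-to-trough percentage and the sawtooth is the simplest
waveform consistent with that — and the sample count is configurable.

## Attenuation data

Mass attenuation coefficients are tabulated per element as (energy, μ/ρ)
pairs and interpolated **linearly in log(μ/ρ) vs log E**, the standard
treatment for NIST-style tables. Duplicated-energy rows mark absorption
edges; interpolation never crosses them, and a query exactly at a
tabulated energy returns the stored value bit-for-bit. Compounds use the
mass-fraction mixture rule μ/ρ = Σ wᵢ(μ/ρ)ᵢ with the registry density;
the registry holds 14 standard imaging materials (water, air, PMMA,
scintillators, semiconductors...), with compositions computed from atomic
weights and, notably, GaAs at 5.31 and Gd₂O₂S at 7.44 g/cm³.

The built-in default library is **synthetic**: μ/ρ(E) = 12·Z³/E³ + 0.18
cm²/g, i.e. a photoelectric E⁻³ term plus a Compton-like plateau, with a
K-edge discontinuity for elements whose edge falls in the diagnostic range
(handbook edge energies; the photoelectric term is divided by a jump ratio
of 4.5 below the edge). Magnitudes are roughly right for light elements
(synthetic Al at 30 keV: 1.16 cm²/g vs the handbook 1.13) and deliberately
approximate for heavy ones. Its role is structural realism — E⁻³
hardening, edge discontinuities, correct unit bookkeeping — not
cross-section fidelity; real tables load through the attenuation CSV
schema and are used identically.

## Dosimetry

Air kerma is the mass energy-absorption integral

    K [mGy/mAs] = Σ_E q(E) · 100 · E_c · (μ_en/ρ)_air(E) · k / 10⁻⁶

with E_c the bin center (keV), k = 1.602176e-16 J/keV, the factor 100
converting photons/mm² to photons/cm², and 10⁻⁶ taking J/g to mGy.
Exposure uses the air-kerma-per-roentgen constant 8.764 mGy/R
(2.58·10⁻⁴ C/kg per R × W/e = 33.97 J/C). Both constants live in
`DoseConstants` and are overridable; the default (μ_en/ρ)_air is the
synthetic curve 3.5·10³/E³ + 0.027 cm²/g (within ~25 % of handbook air
values across 20–150 keV). HVL is defined on air kerma (exposure-based
HVL differs only by a constant factor and therefore gives the same
thicknesses).

HVL search: the kerma-vs-thickness objective is strictly monotone, so the
nth HVL is found by growing the upper bracket geometrically and bisecting
until |K − K₀/2ⁿ|/K₀ ≤ 1e-9, far below any physical meaning; successive
HVLs are computed on the progressively hardened beam, so t₂ ≥ t₁ whenever
attenuation decreases with energy. A missing bracket within 10⁴ mm raises.

## Cross-model normalization

Two spectral models generally disagree in absolute output. The engine
stores per-kV scale factors s(kV) = K_ref(kV) / K_model(kV after the
stated added Al), linearly interpolated between stored kV; generating with
`normalize=True` applies the default 1.6 mm Al (the inherent filtration
the built-in reference model embodies) and multiplies by s(kV), making the
normalized model's mGy/mAs match the reference exactly at the listed
potentials. The built-in reference ("legacy") table is the synthetic
primary model with a hotter continuum, the two Kα lines merged into one
(emulating a coarser-resolution provenance), and 1.6 mm Al already
applied — so the default comparison exhibits the characteristic
line-placement discrepancy around 58–60 keV that model comparisons of
this kind show in practice. Matching is by air kerma; matching by HVL
would be an alternative and is left as an extension.

## Model comparison

`compare_spectra` pools 100·(a−b)/b per (kV, bin) with model b as the
reference, excluding (and counting) zero-reference bins, and reports the
pooled median plus the squared Pearson correlation per kV. The sign
convention is asymmetric through the denominator; swapping the roles maps
+5 % to −4.76 %, which the tests document.

## Synthetic data generator

`kramers_spectrum` builds q(E) = c·(kV − E_c) above zero (Kramers
continuum, c = 40 photons/mm²/mAs/keV), plus Gaussian-profiled tungsten
Kα₁/Kα₂ lines at 57.98 / 59.32 keV (σ = 0.35 keV, relative amplitudes
1.0 / 0.55) that appear only above the K-edge, taken as 69.5 keV, with
total line fluence proportional to the overvoltage. Everything is
deterministic given the config. The generator reproduces the *structure*
of real tube spectra — cutoff, characteristic lines, hardening under
filtration — but not their magnitudes or detailed shape; tests passing on
fixture data therefore validate the machinery (units, invariants,
optimization), not agreement with any measured spectrum.

Synthetic measurements emulate a bench: readings = output(truth-filtered
beam) · mAs · (1000/SDD)² · (1 + ε), ε ~ N(0, noise %), SDD = 745 mm, six
mAs stations per set, all seeded.

## Inherent-filtration tuning

The tuner minimizes Σ_m (calc − reading_m/mAs_m, scaled to 100 cm)² over
effective Al and W thicknesses with Nelder–Mead (initial simplex step 10 %
of the estimate with a 0.01 mm floor; converged when the simplex is below
1e-6 mm and the cost change below 1e-12; 2000 iterations max, with the
best point returned and flagged when not converged). Negative thicknesses
are admitted inside the search — exp(−μt) with t < 0 amplifies, letting
the fit remove filtration the model over-assumes; saturation to the float
maximum keeps runaway probes ordered. Readings in mR are matched against
exposure, mGy against air kerma.

**Identifiability.** A measurement set at one kV constrains exactly one
scalar (the mAs-normalized output), so the zero-cost set in the
(t_Al, t_W) plane is a one-dimensional valley and the simplex simply
returns the valley point nearest the starting estimate — a property of
the problem, not the optimizer. Fitting one pair jointly across sets at
several kV removes the exact degeneracy but remains ill-conditioned for
open beams, because the Al and W sensitivities are nearly proportional
across kV: a Fisher-information analysis (reproducible with handbook
attenuation values, not just the synthetic library) predicts ~30 %
standard error in t_Al at 1 % reading noise. The package therefore
defines a *characterization protocol* — kV 60–140 in 10 kV steps, each
measured open and behind known 1 mm Al, 2 mm Al, 0.1 mm Cu, and 0.2 mm Cu
filters, six mAs stations each — varying known filtration being the
classical half-value-layer route to conditioning filtration estimates.
Joint fits weight residuals relative to each set's mean reading, the
even-handed weighting when meter noise is multiplicative. Under this
protocol, noiseless recovery is exact to ~1e-7 mm and a 20-draw study at
1 % noise keeps median recovery errors near 4 % for both thicknesses.

## I/O and reproducibility

All artifacts are plain CSV with `# key: value` metadata lines; numeric
fields are written with the shortest decimal that reproduces the float64
exactly, so every writer/reader pair is lossless and regression tests are
bit-stable. Loaders validate everything the in-memory types enforce —
fixture-generated and user-loaded data share one code path. Spectra carry
a filtration log (every applied layer) so any spectrum is reproducible
from its own metadata. CLI runs log the package version, inputs, seed, and
config hash; exit codes distinguish usage errors (2), data errors (3), and
non-convergence (4).

## Known limitations

- Narrow-beam attenuation only: no scatter, buildup, or geometry.
- The synthetic library's heavy-element cross sections are coarse
  (single power law + K-edge; no L-edges), so absolute dosimetry with the
  built-in data is illustrative, not clinical.
- No effective energy, kerma-area product, or in-phantom dose.
- Spectral tables for other anode materials load fine, but the built-in
  generator is tungsten-specific (K-line energies and edge).
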
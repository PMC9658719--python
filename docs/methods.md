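# Methods

## Model and assumptions

Everything rests on the Beer–Lambert law with base-10 logarithms:
A = −log₁₀ T = 2 − log₁₀ %T, and A(λ) = Σᵢ εᵢ(λ) cᵢ d for co-dissolved
absorbing species at concentrations cᵢ (mol/L) over path d (cm), with ε in
M⁻¹ cm⁻¹. This assumes dilute, non-scattering solutions, a linear detector,
and monochromatic sampling at each grid wavelength; none of the instrument
corrections that would relax these assumptions (stray light, baseline
drift, bandpass convolution) are modeled — they are explicit non-goals.

Raw and incident intensities I and I₀ are never represented individually;
only their ratio T enters the data model.

### Anchor-rescaling route

Solvent subtraction, A_comp = (2 − log₁₀ %T_sol) − (2 − log₁₀ %T_w), leaves
an absorbance proportional to ε_comp(λ) with unknown constant
k′ = k·c·d, where k absorbs any normalization the spectrometer applied to
the recorded transmittance. Since ε(λ₂)/ε(λ₁) = A(λ₂)/A(λ₁), one literature
anchor (λ₁, ε₁) determines the absolute spectrum; k and k′ are structurally
unidentifiable and deliberately never estimated. Two consequences are
enforced as invariants and tested: output invariance under positive
rescaling of the input absorbance, and exact anchor passthrough for a
single on-grid anchor.

With multiple anchors, per-anchor scale factors sᵢ = εᵢ/A(λᵢ) are combined
by **geometric mean** — scale factors are multiplicative quantities, so the
geometric mean is the symmetric choice that commutes with inverting the
scale; a `single` policy (first anchor only) is also provided since the
historical combination rule for the 535/593 nm anchor pair is not
documented anywhere we could verify. Scale factors disagreeing by more than
1 % trigger a logged warning: with exact data and consistent anchors the
factors coincide, so disagreement measures data/anchor inconsistency.

### Concentration-series route

At each wavelength the dilution series gives pairs (xᵢ, Aᵢ) with xᵢ = cᵢ·d,
and ε_sol(λ) is the slope of the **no-intercept** least-squares fit
Σxᵢ Aᵢ / Σxᵢ², vectorized over wavelengths. The zero intercept is imposed
rather than estimated because the physics forces A = 0 at c = 0; an
A/(c·d)-averaging estimator is provided for comparison but the OLS slope is
the default (it weights concentrated, higher-signal members more). With a
single member the formula degenerates to ε = A/(c·d) exactly. The
per-wavelength RMS residual of the fit is attached to the result.

Replicates are averaged **in the absorbance domain before** the fit
(Beer–Lambert is linear in A, not in %T), with the n−1 sample standard
deviation attached; replicate-first ordering (average, then regress, then
correct) is a package choice where the alternative orderings give identical
results in the noiseless limit.

The mixture correction ε_HbA1c = [ε_sol − (1 − f)·ε_non]/f is the exact
algebraic inverse of ε_sol = f·ε_HbA1c + (1 − f)·ε_non for any f ∈ (0, 1];
round-trip identity to ~1e−12 relative is an acceptance-level test.
Negative outputs are preserved and flagged, never clipped — clipping would
silently distort the ratios near the band edges where ε is small.

**Concentration basis.** ε is expressed per mole of hemoglobin *as
supplied* (the stated mmol/L "hemoglobin content"); whether that molarity
counts tetramers or heme equivalents is left to the data provider and
documented, not resolved, here. Likewise the oxygenation state of the
ε_non reference (oxy-, deoxy-, or mixed) is whatever the supplied table
contains.

**Glycated fractions.** The two bilevel assay-control fractions are always
computed at run time from the certified concentrations — level 1:
0.228/9.43 mmol/L, level 2: 0.488/7.44 mmol/L — never stored as rounded
decimals.

### Peak reporting

Q-band peaks are strict local maxima inside a search window (default
500–600 nm), ranked by height, greedily thinned to a minimum 10 nm
wavelength separation, ties broken toward the lower wavelength, and
reported in wavelength order. The 10 nm separation sits well below the
~34 nm Q-band spacing while suppressing noise-split doublets; strictness
(no plateaus) avoids double-counting flat tops on coarse grids. Detection
is invariant under positive rescaling. Fewer maxima than requested yields a
shorter report plus a warning rather than an error.

### Error-grid analysis

Three zones on the NGSP % scale: A if |est − ref| ≤ 0.20·ref (boundary
*inclusive* — "within 20 %" is read inclusively and documented as such); C
if the estimate's diagnostic category crosses the normal/diabetes divide
relative to the reference in either direction (both "unnecessary treatment"
and dangerous non-treatment map to the single C bucket of a 3-zone grid);
B otherwise. The B/C geometry is a package decision — published 3-zone
variants do not state it numerically — and is configurable via
`ZonePolicy`; zone-count reproductions depend only on counts, not on this
geometry. Category cutpoints: normal < 5.7, prediabetes 5.7–6.4 (both ends
inclusive; "above 6.4" defines diabetes, so 6.4 itself is prediabetes),
diabetes > 6.4.

Percentages are 100·count/total rounded **half-up** to two decimals. Note
5/19 → 26.32 under this rule; one published table prints 26.31 for the same
split (apparent truncation), which we do not reproduce.

## Synthetic data generator

Emulates: ε spectra as sums of Gaussian bands with an exponentially
declining baseline (level-1-like: bands at 545/579 nm; level-2-like:
544/577 nm; amplitudes chosen to place corrected peak ε in the 4–9×10⁵
M⁻¹cm⁻¹ range reported for HbA1c); Beer–Lambert mixing at glycated fraction
f; the five-point dilution design 0.03–0.07 mmol/L in 1 cm cuvettes with
three replicates; additive zero-mean Gaussian noise in the absorbance
domain (detector-log-domain noise would require an instrument model we do
not have; 0.002 absorbance units is the working convention for "replicate
scatter", a free parameter, as real replicate noise levels are not
reported); and an optional multiplicative normalization of the emitted
transmittance realizing the unknown factor k. One `numpy.random.default_rng`
stream per seed drives all draws; identical seeds are bit-identical.

Gaussian line shapes are a stand-in, not hemoglobin photophysics: they make
peak positions and the forward model exactly known, which is what recovery
testing needs. Passing tests on this generator therefore demonstrate
*algorithmic* correctness (exact inversion, invariances, noise behavior
matching the analytic OLS standard error), not robustness to real-world
effects it omits: scattering/turbidity, wavelength-correlated baselines,
instrument nonlinearity, pH/temperature shifts, oxygenation-state mixtures.

The packaged `nonglycated_hb_synthetic.csv` reference spectrum is generated
from the same band-model machinery (oxyhemoglobin-like Q-bands at
541/576 nm, per-heme-scale amplitudes) and is labeled synthetic; scientific
use requires substituting a literature ε table in the same CSV dialect.

Error-grid point clouds with exact per-zone counts are drawn by rejection
sampling inside each zone's region (references in 4–12 NGSP %), with a
bounded rejection budget so infeasible zone/policy combinations fail loudly.

## Numerical choices

- Linear interpolation is the single alignment path (`resample_to_grid`,
  anchor evaluation, wavelength lookup); extrapolation always raises.
- Binary spectrum operations require bit-identical grids; callers resample
  explicitly, so no silent interpolation differences can arise.
- Transmittance domain (0, 100] excludes zero so absorbance stays finite;
  %T > 100 appears only on explicitly flagged inversions of negative
  (difference) absorbance.
- Averaging identical replicates returns the input values and zero
  dispersion exactly (summation-rounding guard).
- CSV interchange uses 9-significant-digit formatting, which round-trips
  the dialect bit-stably.
- Default grids: 300–1100 nm span at a 1 nm step (a sampling convention,
  not an instrument fact), reporting band 450–700 nm, peak window
  500–600 nm.

## Problem sizes

The test suite and the acceptance script use the generator's study design
as-is: 5 concentrations × 3 replicates on the 801-point grid, 100 Monte
Carlo seeds for the noisy-recovery check, 1000 random spectra for the
round-trip identity — small enough to run in seconds, large enough that the
Monte Carlo RMSE concentrates on the analytic standard error.

## Known limitations

- No uncertainty propagation beyond regression residuals and replicate
  standard deviations; anchor error bars are not propagated.
- The theoretical route inherits any shape error in the input
  transmittance verbatim; only scale errors cancel.
- The mixture correction amplifies ε_sol noise by 1/f (~41× at the
  level-1 fraction), which is intrinsic to the method, not an artifact.
- The 3-zone grid is not the five-zone (A–E) glucose Clarke grid; trend
  lines beyond the point-zone summary are out of scope.
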
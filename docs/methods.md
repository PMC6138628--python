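# Methods

This note records the models behind each analysis stage, the conventions
and tunable parameters, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Models and conventions

### Laurdan generalized polarization

The Laurdan probe's emission maximum sits near 440 nm in ordered (gel)
bilayer phases and near 490 nm in disordered (liquid) phases.  Membrane
order is summarized as GP = (I₄₄₀ − I₄₉₀)/(I₄₄₀ + I₄₉₀) ∈ [−1, 1].  Band
intensities are read from the emission spectrum by linear interpolation at
exactly 440 and 490 nm (`band_rule="interp"`, the default); a
maximum-in-window rule (±5 nm, `band_rule="window_max"`) is available for
spectra whose band maxima wander.  Temperature is carried as metadata
only; nothing uses it computationally.

### Lipid mixing, inner-monolayer mixing, leakage

All three assays share one normalization: percent = 100·(F − F₀)/(F₁₀₀ −
F₀), with F₀ the initial residual fluorescence of intact FRET-labelled
vesicles and F₁₀₀ the intensity after Triton X-100 solubilization.
Percentages are deliberately **not clamped**: values outside [0, 100] are
returned with a per-point flag (and a warning), because dequenching
artifacts are diagnostically useful.  For the inner-monolayer assay the
caller must supply F₀/F₁₀₀ measured on the dithionite-treated population;
whether the 100% level is re-measured after dithionite treatment is an
experimental choice the module does not second-guess — both anchors are
explicit arguments.  Leakage (ANTS/DPX dequenching) uses the identical
0–100 scale.

Saturation is located by fitting a Hill curve p(x) = P·xⁿ/(xⁿ + Kⁿ)
(plateau P, half-constant K, exponent n ∈ [0.5, 8]) and reporting the
smallest P/L at which the fitted curve reaches 95% of its plateau.  The
95% convention is also what the generator uses to place its half-constant,
so the round trip is exact at zero noise.  Curves whose maximum extent
stays below one percentage point are reported as flat (no saturation
point) rather than force-fitted.

### Partition coefficient

Binding is a surface partition equilibrium X_b = K_p·C_f with X_b mol
bound peptide per mol total lipid and C_f the free peptide concentration.
Because an externally added peptide initially reaches only the outer
leaflet (≈60% of the lipid in sonicated vesicles), the isotherm uses
X_b\* = X_b/`outer_leaflet_fraction` (default 0.6, a config knob — the
same correction is conventionally applied to large-vesicle titrations even
though their outer fraction is nearer 0.5).

Pipeline per titration point: f_b = (F − F₀)/(F_∞ − F₀); bound = f_b·P;
C_f = (1 − f_b)·P; X_b = bound/L; X_b\* = X_b/0.6.  K_p is the slope of a
least-squares line through the origin over the **initial region** of the
isotherm: points with C_f ≤ 30% of the largest observed C_f, minimum 3
points, falling back to the 4 smallest-C_f points when fewer qualify.
Fitting only the initial slope makes K_p insensitive (±5% in tests) to
upward curvature from surface self-association at higher coverage.

F_∞ (fluorescence at complete binding) comes from a double-reciprocal
extrapolation against the outer-leaflet lipid concentration L' = 0.6·L.
Two readings are supported: 1/F vs 1/L' (`mode="total"`, the default,
literal "total peptide fluorescence") and 1/(F − F₀) vs 1/L'
(`mode="delta"`), which is *exactly* linear when the binding curve is a
hyperbola on top of a free-peptide baseline F₀.  The end-to-end pipelines
use delta mode for that reason.  Weighting: plain OLS in reciprocal space
hands the noisiest low-signal points the greatest leverage (the classic
Lineweaver–Burk pathology; with 2% multiplicative noise it inflates the
F_∞ spread to ~11%).  `weights="response"` applies the inverse-variance
weights w = R⁴/F² appropriate for constant relative fluorescence error,
which the pipelines use; both weightings agree exactly on noiseless data.
A non-positive reciprocal intercept aborts with an explicit extrapolation
error — never a silent clamp.

The pipelines treat F₀ (free-peptide or quencher-free reference intensity)
as known rather than re-reading it off a single noisy titration point: it
is a separate, repeatable reference measurement, and an error in it is
common-mode across the whole series (for the Stern–Volmer ratio F₀/F a 2%
F₀ error alone would move K_sv by ~9% at the smallest constants).

### Stern–Volmer quenching

F₀/F = 1 + K_sv[Q].  The primary fit regresses (F₀/F − 1) on [Q] through
the origin, since the law has intercept exactly 1; an unconstrained
F₀/F-vs-[Q] line is fitted alongside and its intercept reported as a
diagnostic (it should be 1).  Quencher concentrations above the configured
0.2 M maximum (the experimental acrylamide ceiling) warn about likely
inner-filter artifacts but do not abort.

### Circular dichroism

Observed ellipticity (mdeg) is normalized to mean residue ellipticity.
Two conventions are supported and recorded in every output: the
"unscaled" MRE = θ/(l·c·n) and the standard "factor10" MRE =
θ/(10·l·c·n).  Helicity is only meaningful when data and reference share a
convention, which the API enforces by carrying the convention through;
a mismatch shows up as a clamped (flagged) helix fraction.  Helix fraction
= MRE₂₂₂ / (−40000·(1 − 2.5/n)), clamped to [0, 1] with a flag — noisy
spectra legitimately overshoot.  The θ₂₂₂/θ₂₀₈ ratio is computed on MRE
values (units cancel) interpolated at exactly 222 and 208 nm, and
classified monomeric (<0.8), oligomeric (>1.0) or indeterminate (the
closed boundary band [0.8, 1.0]).  Emission λmax for blue-shift estimates
is refined with a local parabola through the three grid points around the
maximum, because membrane-induced shifts can be smaller than the
wavelength step.

### Imaging

Integrated density (ID) = mean fluorescence over an ROI × ROI area in µm²;
it is additive over disjoint ROIs by construction.  The inbound
compartment is the vessel mask itself; the outbound compartment is the
thresholded signal outside the vessels (vessels and background both
excluded).  Masks are boolean pixel arrays supplied by the caller — vessel
segmentation is out of scope; the generator emits ground-truth masks.
"Non-zero" thresholding defaults to pixels strictly above a floor of 0;
the floor can be a number (the pipelines use 5× the background noise
level, so symmetric background noise cannot accumulate into the outbound
sum) or `"mode"` (histogram-mode background subtraction), and Otsu
thresholding is available for bimodal images.  Calibration curves mapping
amount → ID support a linear model and the 4-parameter logistic that
ImageJ calls "Rodbard" (y = d + (a − d)/(1 + (x/c)^b), initialized at a =
response near zero amount, d = response at the largest amount, c = median
amount, b = 1); `model="auto"` prefers the linear fit when its r² ≥ 0.99,
matching the expectation that slide-spot calibrations are linear.  Percent
delivered = 100 × (inverse-calibrated amount)/(administered amount), with
the 4PL inverted only strictly between its asymptotes.

## Synthetic data: what it emulates, what it does not

Every generator is a pure function of (parameters, seed) — same inputs,
bit-identical output — and returns the truth as a sidecar record, never
embedded in the data.  Default noise is multiplicative Gaussian with
σ = 2% on fluorescence (photodetector-style) and additive Gaussian on
images.

- **Laurdan**: two Gaussian bands at 440/490 nm, σ = 18 nm, amplitudes
  solved (including cross-band tails) so the interpolated band reads give
  the target GP exactly at zero noise.  |GP| is capped at
  (1 − t)/(1 + t) ≈ 0.96 by the tail overlap, t = exp(−50²/(2·18²)).
- **Mixing**: Hill extent curves (default exponent 2; the experiments
  constrain only the endpoints, not the curve family) crossing 95% of
  plateau at the nominal saturation P/L; grid of 12 log-spaced ratios from
  sat/20 to 3·sat plus zero.
- **Titrations**: the bound fraction at each lipid point solves the exact
  partition balance (f_b·P/L' = K_p·C_f, optionally plus a quadratic
  self-association term above a critical C_f); the default 12-point lipid
  grid spans bound fractions 0.10–0.85, how a titration is planned to
  cover the binding transition.
- **Quenching**: F = F₀/(1 + K_sv[Q]) on a 9-point grid over 0–0.2 M.
- **CD**: fixed analytic Gaussian-mixture bases (helix: negative bands at
  222/6.5 and 208/5.5 nm, positive 1.6× band at 193/6 nm; coil: −1.3×
  band at 198/7 nm), linearly combined to hit the target MRE₂₂₂ and
  222/208 ratio exactly, then converted back to millidegrees so the
  analyzer exercises its own normalization.  These are self-contained
  stand-ins, not experimental basis sets.
- **Images**: a vessel rendered as a dilated random-walk tube carrying
  slope×inside_amount total fluorescence; parenchymal puncta (default 30
  Gaussian blobs, σ = 1.5 px, placed clear of the vessel) carrying
  slope×outside_amount; additive background noise σ = 0.02 (puncta peaks
  sit ~30× above the 5σ detection floor, as puncta in real micrographs
  are clearly visible above background).

What passing the round-trip tests therefore shows: the analysis formulas,
fits and error propagation are correct and stable under realistic
photometric noise, and the qualitative contrasts between the membrane
conditions survive that noise.  What it does not show: robustness to
baseline drift, scattering, inner-filter effects, wavelength
miscalibration, autofluorescence, vessel-mask error, or model
misspecification (e.g. non-Hill fusion kinetics, electrostatic corrections
to the partition model) — none of which the generators simulate.

## Problem sizes

Recovery statistics use 200 replicates per condition in the test suite
(medians under 2% noise) and 50 in the acceptance script; ordering checks
use 100 end-to-end replicates; imaging uses 192×192 px fields of view with
5 replicates.  These sizes give stable medians while keeping the whole
suite in the low seconds.

## Known limitations

- The monomer/oligomer call is a hard threshold rule; near 0.8 or 1.0 a
  small MRE error flips the label, which is why the band in between is
  reported as indeterminate rather than forced.
- The Hill saturation fit assumes a monotone saturating curve; biphasic
  fusion curves will fit poorly (diagnosable via the returned parameters).
- The 4PL inverse is undefined outside its asymptotes; densities beyond
  the calibrated range raise rather than extrapolate.
- K_p recovery quality depends on the titration design: points
  concentrated at very high bound fraction make C_f = (1 − f_b)·P
  hypersensitive to noise.  The default grid avoids f_b > 0.85 for this
  reason.
- CSV is the only tabular input format; instrument vendor binaries and
  JCAMP-DX are out of scope.
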
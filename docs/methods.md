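# Methods

## Model

`petaloptics` works entirely within two-flux (Kubelka–Munk) radiative
transfer: inside each layer, light is reduced to a downward and an upward
diffuse flux, coupled by an absorption coefficient K and a scattering
coefficient S. This presumes diffuse, incoherent illumination and optically
thick, strongly multiple-scattering tissue; interference, polarization,
collimated beams and angular detail are outside the model. Because only the
products K\* = K·d and S\* = S·d enter a layer's diffuse reflectance r and
transmittance t, those dimensionless parameters are what a measurement can
determine; converting to coefficients (mm⁻¹) requires an independently known
thickness.

The forward single-layer solution and its closed-form inverse are the
hyperbolic expressions given in the README. Layers are composed with the
adding equations, which close the infinite inter-reflection series exactly.
Side-resolved bookkeeping (r_top ≠ r_bottom for sub-stacks) is carried
explicitly: every single layer is symmetric, but a stack is not, and the
abaxial predictions depend on that asymmetry. Bottom-illumination
observables are obtained by folding the reversed layer list through the same
code path rather than by separate algebra, so one implementation serves both
directions; the two folds yield bitwise-independent but equal
transmittances, and the prediction API returns a single shared transmittance
array because side-invariance of T is a theorem for stacks of symmetric
plates.

## The four-layer petal and the fit

The corolla model is surface / pigmented / unpigmented / surface. The
surfaces are non-absorbing, wavelength-independent plates with r = 0.03
(t = 0.97), a value appropriate for plant material with refractive index
~1.4 facing air; a spectrum can be substituted for sensitivity studies. The
unpigmented layer has K = 0 and a constant scattering parameter S\*ᵤ,
treated as a swept assumption (0.0 / 0.1 / 0.2 are typical; 0.0 degenerates
to a homogeneously pigmented interior) — fitting S\*ᵤ from data is
deliberately out of scope.

The fit runs per wavelength and entirely in closed form: (i) peel the top
surface off the measured adaxial (R, T); (ii) solve for the symmetric middle
plate against the combined lower sub-stack (unpigmented layer + lower
surface), giving (r_p, t_p); (iii) invert the two-flux mapping to
(K\*ₚ, S\*ₚ); (iv) convert K\*ₚ to decadic absorbance D = log₁₀(e)·K\*ₚ.
There is no optimisation, no smoothing, and no regularisation: recovered
parameter spectra are reported raw.

## Numerical choices

- **Overflow branch.** For b·S\* > 350 the hyperbolic forms are replaced by
  the semi-infinite asymptote r = 1/(a+b), t = 0.
- **Degenerate branches.** S\* = 0 uses Beer–Lambert (r = 0, t = e^(−K\*));
  K\*/S\* small enough that a rounds to 1 (b = 0) uses the exact K\* = 0
  limit; in inversion, a ≤ 1 + 1e−9 takes the non-absorbing branch
  K\* = 0, S\* = r/t to avoid the 0/0 in the arccoth form.
- **Invalid wavelengths.** Energy violations (R + T > 1), arccoth domain
  violations (argument ≤ 1) and out-of-range solved plates — all of which
  measurement noise can produce — are flagged NaN per wavelength with
  per-step failure counts, never raised; a fit only errors out when *every*
  wavelength fails. Recovered parameters within 1e−9 below zero are clamped
  to zero (rounding); larger negatives are flagged.
- **Tolerances.** The forward/inverse round trip holds to 1e−9, adding vs.
  bounce-series to 1e−10, and fit/predict closure on noiseless synthetic
  data to 1e−10; these are verified by the test suite, with an independent
  boundary-value ODE solution of the two-flux equations (agreement 1e−6) as
  the external oracle for the closed forms.

## Synthetic data

No measured spectra ship with the package, so the generator supplies ground
truth. Pigment absorption K\*ₚ(λ) is a sum of Gaussian bands; the default
emulates a purple corolla pigment with a green band at 545 nm peaking at
K\* = 1.4 and a stronger ultraviolet band (center 310 nm, width 35 nm,
amplitude 3.5), leaving a weakly absorbing violet window between them. The
band widths and the UV amplitude are free modelling choices — only the peak
position, peak height and qualitative shape are anchored. Scattering S\*ₚ(λ)
defaults to a flat 0.5 (the long-wavelength asymptote of recovered petal
spectra); an optional coupling term depresses it in proportion to
normalised absorption, mimicking the troughs that appear in recovered
scattering spectra where absorption is severe. Measurements are simulated
by running the four-layer stack forward (grid 300–700 nm at 1 nm) and
adding independent Gaussian noise truncated to [0, 1]; every stochastic call
takes an explicit seed.

What the generator does *not* emulate: instrument stray light and dark
current, wavelength-dependent noise, spatial heterogeneity (veins vs.
inter-vein tissue appear only as alternative S\*ᵤ values), and surface
gloss. Passing closure tests therefore demonstrates the *algebraic*
correctness of the pipeline and its noise robustness under an idealised
instrument, not fidelity to any particular measured flower.

## Scenarios

The scenario builder holds the per-wavelength totals of K\* and S\* fixed
and redistributes them: **asymmetric** (all pigment in the upper layer,
scattering layer below), **homogeneous** (one pooled layer, S\* summed), and
**symmetric** (pigment and its scattering halved into an upper and lower
flank around the unpigmented layer). Splitting the pigmented layer's
scattering along with its pigment in the symmetric case is an assumption —
the alternative (full S\*ₚ per flank) would not conserve total scattering.
Saturation is quantified as 1 − R(λ_max)/max_λ R with λ_max = 545 nm.
Under the default pigment the asymmetric arrangement gives the most
saturated adaxial colour, and the homogeneous and symmetric arrangements
differ from each other by less than either differs from the asymmetric one.

## Known limitations

- Two-flux theory is quantitatively rough for weakly scattering or strongly
  forward-scattering media; recovered K and S are *effective* two-flux
  coefficients, not intrinsic cross-sections.
- The closed-form fit propagates measurement noise without damping;
  wavelengths where little light survives (deep UV) invert noisily or get
  flagged. Users wanting smooth parameter spectra should average replicate
  measurements first (`average_spectra`) rather than smooth the output.
- Surfaces are modelled as diffuse plates inside the same adding algebra;
  specular gloss and the focusing optics of papillose epidermal cells are
  not represented.
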
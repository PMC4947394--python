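# Methods

`tetrachroma` models how the spectral filtering of the avian SWS2 cone's
C-type oil droplet shapes color discrimination in violet-sensitive (VS)
and ultraviolet-sensitive (UVS) birds, and provides the chemistry-side
utilities (polyene λmax rules, exact masses, spectral unmixing) used to
identify the apocarotenoid pigments that do the filtering.

## Receptor model

A single cone's spectral sensitivity is

R(λ) = v(λ) · p(λ) · o(λ),

the product of the visual-pigment absorbance v, the oil-droplet
transmittance p, and the ocular-media transmittance o, all sampled on a
closed 300–700 nm grid (default step 1 nm); every integral over λ is a
trapezoid sum.

* **Pigment template.** v is the A1 nomogram of Govardovskii et
  al. (2000): the four-exponential α band in x = λmax/λ plus the
  Gaussian β band, renormalized to unit peak.  The template function is
  injectable so an alternative nomogram can be substituted without
  touching the rest of the pipeline.
* **Oil droplet.** Droplet transmittance is a Gompertz long-pass curve
  T(λ) = exp(−exp(−b_mid(λ − λ_mid))).  λcut is defined as the
  x-intercept of the tangent at the mid-slope point, which gives
  λ_mid = λcut + 1/b_mid analytically.  Default slope b_mid =
  0.08 nm⁻¹ when a species table does not supply one; the SWS1 cone's
  T-type droplet is transparent.
* **Ocular media.** A measured transmittance spectrum per species when
  available; otherwise a synthetic sigmoidal UV cutoff of the same
  Gompertz form, with a shorter cutoff for UVS species (~324 nm) than VS
  (~348 nm).

## Object-color solid and the number of discriminable colors

Quantum catch is Q_i = ∫ R_i(λ) S(λ) I(λ) dλ for reflectance S and
illuminant I.  Writing the illuminant as a normalized shape j(λ) (max 1)
times an intensity T, defining quantum efficiencies k_i = ∫R_i j dλ,
normalized sensitivities r_i = R_i/k_i and normalized catches
x_i = ∫ r_i S j dλ gives Q_i = T·k_i·x_i, with x_i ∈ [0, 1] and the
ideal white surface at x = (1,…,1).  The k are rescaled so k_LWS = 1,
and T is calibrated as the LWS quantum catch of the ideal white surface:
10⁵, 10², and 10 photons per integration time for the bright, dim, and
very dim regimes.

The object-color solid is the set of achievable x.  Because reflectances
are bounded in [0, 1] and the map S ↦ x is linear, the solid is the
image of a hypercube: a *zonotope* whose generators are the per-bin
catch increments over a transition grid (default 4 nm; coarser grids are
used for sweeps, see *Problem sizes*).  Its extreme points are images of
the optimal color stimuli — binary reflectance spectra with at most
n−1 transitions for n receptor classes — which the package enumerates
exactly.

Receptor noise defines a confusion volume u = c·∏δQ_i around each locus
(c is an unknown threshold constant fixed at 1; all counts are defined
up to 1/c).  The noise laws per regime are

* very dim: δQ_i = d_i (dark noise; 50 events per integration time for
  every cone — the absolute level only scales N, it never moves optima),
* dim: δQ_i = √Q_i (photon-shot noise),
* bright: δQ_i = √(Q_i + ω_i²Q_i²) (shot noise plus a Weber fraction ω;
  solid-model defaults 0.2 : 0.14 : 0.14 : 0.1 for SWS1:SWS2:MWS:LWS).

The count of discriminable colors is N = ∫ u⁻¹ ∏dQ_i over the solid.
Substituting Q_i = T·k_i·x_i:

* very dim: N = Tⁿ·G·∏k_i / (c·∏d_i),  G = ∫∏dx_i (the solid volume),
* dim: N = (1/c)·T^(n/2)·∏√k_i·G,  G = ∫ ∏x_i^(−1/2) ∏dx_i,
* bright: same prefactor as dim with
  G = ∫ ∏(x_i + ω_i²·T·k_i·x_i²)^(−1/2) ∏dx_i.

The dim/bright square roots follow from ∏δQ_i =
∏√(T k_i x_i + ω_i² T² k_i² x_i²) = T^(n/2)∏√k_i·∏√(x_i + ω_i²Tk_i x_i²)
and the Jacobian ∏dQ_i = Tⁿ∏k_i ∏dx_i.  The package also evaluates
N = ∫(c∏δQ)⁻¹∏dQ directly in Q coordinates through a separate code path
(`count_colors_qspace`); the two routes agree within Monte-Carlo error
on every regime, which is asserted in the test suite.

### Monte-Carlo evaluation

The dim and bright integrands diverge like ∏x^(−1/2) at the black apex;
they are integrable, but naive uniform sampling in x has
infinite-variance weights.  The package therefore substitutes
x_i = y_i², after which every regime's transformed integrand is bounded
(very dim: 2ⁿ∏y_i; dim: the constant 2ⁿ; bright:
∏ 2/√(1 + ω_i²Tk_i y_i²)), and samples y uniformly in the solid's
bounding box with rejection of points whose image y² falls outside the
solid.  Membership is tested against the solid's exact half-space
representation, computed analytically from the zonotope generators
(facet normals orthogonal to (d−1)-subsets of generators; offsets from
the support function).  This is both exact and much cheaper than
point-against-triangulated-facet tests, and it avoids the numerical
fragility of convex-hull construction on nearly-degenerate inputs (a
scipy `ConvexHull` is still built lazily, with joggled input, wherever a
volume or hull object is requested).  Default 10⁵ samples; the seed is a
mandatory argument of every stochastic routine, and one membership draw
is shared by all three regimes of a solid.  Reported G and N carry their
Monte-Carlo standard errors.  Samples landing exactly on a coordinate
plane (measure zero) contribute zero weight by construction.

## Droplet-cutoff sweep

Following the headline experiment, the C-type cutoff is swept from 370
to 500 nm in 6 nm steps; at each cutoff only the SWS2 receptor is
rebuilt (so k_SWS1, k_MWS, k_LWS stay fixed) and N is recomputed with a
shared seed, making the across-cutoff comparison paired and the argmax
robust to Monte-Carlo noise.  The optimum is the cutoff maximizing N,
ties broken toward the shorter wavelength; a species' relative
performance is N at its actual cutoff (nearest sweep grid point) over
the optimum, which lies in (0, 1].  The SWS2 tuning target is also
summarized by the midpoint formula λ_SWS1 + (λ_MWS − λ_SWS1)/2, compared
against the wavelength of maximum of the droplet-filtered SWS2
sensitivity.

## Increment spectral sensitivity

Detection of a monochromatic increment I_t at wavelength λ on a large
adapting background I_b is chromatic-mechanism-limited: receptor signals
enter as Δq_i = R_i(λ)·I_t / ∫R_i I_b dλ, and contrast is the standard
receptor-noise-limited combination over all receptor pairs

ΔS² = Σ_{i<j} (∏_{k∉{i,j}}ω_k)²(Δq_j − Δq_i)² / Σ_i (∏_{k≠i}ω_k)²,

in just-noticeable-difference units.  Weber fractions come from cone
pooling: ω_i = v/√η_i with relative abundances 1:2:2:4
(SWS1:SWS2:MWS:LWS) and the LWS mechanism anchored at ω = 0.05 (hence
v = 0.1).  ΔS is homogeneous of degree 1 in I_t, so the threshold is
closed-form: I_t* = 1/ΔS(I_t = 1); bisection root-finding is kept only
as a test oracle.  Wavelengths where the Δq vector is achromatic are
flagged "not detectable via the chromatic channel" rather than given a
sentinel threshold.  The background is the daylight shape scaled so the
LWS background catch is 10⁵ photons (overridable); since Δq depends only
on the I_t/I_b ratio, rescaling the background rescales thresholds
proportionally.  The mismatch experiment recomputes the spectrum with
the C-droplet cutoff typical of the opposite visual-system class,
holding background and noise fixed.

## Spectral unmixing of droplet absorbances

Measured (or simulated) C-droplet absorbance spectra are fitted as
additive mixtures of unit-peak pure carotenoid spectra by non-negative
least squares (scipy `nnls`) over a 350–700 nm window (below 350 nm
instrument noise dominates; the window is a parameter).  Non-negativity
is imposed because absorbances add — negative weights are unphysical.
Because the library is peak-normalized, reported proportions are in
spectrum units, not molar concentrations.  A near-collinear library
(condition number > 10⁶ on the window) triggers a warning.  An optional
constant-baseline term is deliberately absent: mixtures are fitted as
pure sums.  Goodness of fit is r² = 1 − SS_res/SS_tot and the residual
RMS in absorbance units.

## Chromophore rules and exact masses

Polyene absorbance maxima follow the Woodward–Fieser rule for ≤ 4
conjugated C=C bonds (endocyclic base 214 + 30n + 5M + 5R_exo, acyclic
base 215 + 30n + 5M, n counting bonds beyond the base diene) and the
Fieser–Kuhn rule otherwise (114 + 5M + n(48.0 − 1.7n) − 16.5R_endo −
10R_exo, n counting all conjugated bonds); the rule is selected
automatically from the total conjugation count.  For the galloxanthin
chromophore (n = 8, M = 6, one endocyclic bond) this predicts 402.7 nm
against the 402 nm measured peak, and saturating the terminal 11′,12′
bond (n → 7, substituents unchanged) predicts a 22.5 nm blue-shift —
the number that identifies the second retinal apocarotenoid as
11′,12′-dihydrogalloxanthin.  Saturating an internal bond splits the
conjugated run; the longer fragment is scored and the variant flagged.
The per-bond bookkeeping (surviving n, M, R_endo per saturation) is
caller-supplied data; the package ships a galloxanthin fixture that is a
structural *reconstruction* (marked as such in its docstring), not a
parsed structure — structure parsing is out of scope.

Monoisotopic masses use IUPAC most-abundant-isotope masses to ≥ 6
decimals.  Adduct m/z supports M+H, M−H, and M+H−H₂O at charge 1, with
the mass of the adduct "H" an explicit per-call choice between the
proton (1.007276 Da) and the neutral hydrogen atom (1.007825 Da):
published apocarotenoid tables mix both conventions, and reproducing
them requires making the choice explicit.  ppm error is
(observed − theoretical)/theoretical × 10⁶, reported to 2 decimals
against the 4-decimal theoretical value, matching how such tables are
printed.

## Synthetic data

The generator produces every input the pipeline needs, deterministically
from (config, seed):

* **Species panels.**  SWS1 λmax ~ U(355, 375) for UVS, U(402, 426) for
  VS; SWS2 ~ U(440, 475); MWS ~ U(497, 510); LWS ~ U(543, 571) — the
  ranges spanned by published avian microspectrophotometry.  The C-type
  cutoff follows λcut = 187.75 + 0.65·λmax(SWS1) + N(0, 4 nm), anchoring
  UVS near 425 nm and VS near 457 nm and reproducing the strong positive
  SWS1–λcut correlation observed across real species.  Y- and R-droplet
  cutoffs sit near 510 and 565 nm; ocular-media cutoffs are shorter for
  UVS (318–330 nm) than VS (340–355 nm).
* **Pure spectra.**  Seven unit-peak components: galloxanthin-like
  (402 nm) and dihydrogalloxanthin-like (380 nm) vibronic triplets (side
  bands at ±1400 cm⁻¹), three further vibronic carotenoids spread over
  440–470 nm, and two keto-carotenoid-like single broad bands at 485 and
  505 nm.
* **Droplet observations.**  Σw_j·pure_j plus i.i.d. Gaussian noise on
  absorbance (default SD 0.01), clipped at zero.  Additive Gaussian
  noise is the simplest defensible model for microspectrophotometric
  traces; it does not emulate baseline drift or wavelength-dependent
  stray light.
* **Illuminants.**  d65 from the embedded public CIE 5 nm table,
  converted to photon units (×λ) and normalized to unit peak; a flat
  (equal-photon) illuminant; and a green-foliage illuminant (d65 times a
  fixed chlorophyll-like transmission peaking near 550 nm) for
  robustness checks.

What passing tests on synthetic panels do and do not show: they verify
the machinery end to end and reproduce the *orderings* reported for real
species (UVS optima short-shifted relative to VS, bright-light fit best,
UVS discriminating more colors, the asymmetric mismatch blind spot); the
published *magnitudes* (e.g. a mean UVS bright-light optimum of exactly
425.1 nm) depend on the study's own species measurements, which are not
redistributable here, so the synthetic panel reports its own honest
values for those quantities.

## Problem sizes and numerical choices

* Transition grid 4 nm by default (≈100 generators, ≈3.2×10⁵ optimal
  stimuli).  Panel sweeps in the analysis scripts use 12 nm with
  3×10⁴ Monte-Carlo samples, which resolves the optima to the 6 nm sweep
  grid while keeping a full 18-species, three-regime sweep under two
  minutes; toy-solid checks use exact 100 nm bins where the geometry is
  analytic.
* Membership tolerance 10⁻⁹ in normalized-catch units; slab normals
  deduplicated at 10⁻¹² after sign canonicalization.
* Linear interpolation for all resampling; no extrapolation, ever.
* Ties in the sweep argmax break toward the shorter wavelength
  (numpy's first-maximum convention, stated as policy).

## Known limitations

* Confusion volumes are the tesseract proportionality c·∏δQ, not exact
  ellipsoidal volumes; absolute N is meaningful only up to c.
* No achromatic/luminance channel in either model; no natural-spectra
  statistics (all of color space is counted, not the subset a bird
  encounters).
* A1 pigments only; no A2/porphyropsin templates, no droplet aperture
  optics.
* Unmixing proportions are spectrum-unit fractions, not concentrations;
  no Beer–Lambert pathlength inversion.
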
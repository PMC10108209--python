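# Methods

`anthosense` re-implements, as a tested pipeline, an intrafloral sensory
analysis of the caper bush (*Capparis spinosa*), a night-blooming
brush-flowered shrub with a mixed bee/hawkmoth pollination system. The
pipeline has four analysis stages — colorimetry for pollinator visual
systems, psychometric color discrimination, floral volatilomics, and
camera-trap visitation rates — plus a synthetic-data module that generates
inputs with the statistical structure each stage assumes. This note
records the models, their assumptions, the tunable parameters, and the
numerical choices made where the design was open.

## Colorimetry

**Model.** For a stimulus with reflectance R(λ) viewed by a receptor with
peak-normalized sensitivity S_i(λ) under illuminant I(λ), the quantum
catch is Q_i = ∫ R S_i I dλ over 300–700 nm (trapezoidal integration on a
1-nm grid). Catches are von Kries-normalized against the adapting
background, q_i = Q_i / Q_i(background), which places the background at
the achromatic center of every color space. Color loci are computed in:

* the **Maxwell triangle** (trichromats, hawkmoth models): relative
  catches q_i/Σq_j are barycentric weights on vertices at unit distance
  from the center; loci depend only on catch ratios;
* the **bee color hexagon**: receptor excitations E = q/(q+1) with
  x = (√3/2)(E_G − E_UV), y = E_B − (E_UV + E_G)/2;
* a **regular tetrahedron** (tetrachromats) with unit-circumradius
  vertices, again from relative catches.

All three spaces put vertices at unit distance from the achromatic
center, so **saturation** — the Euclidean distance of a locus from the
center — is comparable across systems and bounded by 1.

**Receptor sensitivities.** Only peak wavelengths are published for the
four modeled visual systems (tobacco hornworm 357/450/520 nm; honeybee
344/436/544 nm; swallowtail 360/400/460/520/600 nm; hummingbird hawkmoth
349/440/521 nm). Full curves are reconstructed with the Govardovskii
A1-pigment α-band template; the weak UV β-band is off by default
(`beta_band=True` switches it on). The swallowtail is treated as a
tetrachromat using the UV, blue, green and red receptors, the violet
receptor being excluded by default and configurable, since behavioral
tetrachromacy does not identify which four of the five receptor classes
contribute.

**Illuminant and background.** Defaults are an equal-photon (flat)
illuminant and an ideal achromatic (flat) background; both are
configurable. Saturation is invariant to uniform scaling of the
illuminant because the scale cancels in the von Kries step. Any
saturation marginally above 1 (numerical) is clipped before the arcsine
transform, with a warning.

**Statistics.** Mean brightness (arithmetic mean reflectance over the
full range) is compared across floral parts with a Friedman test paired
by flower, post hoc pairwise Wilcoxon signed-rank tests with Bonferroni
adjustment. Saturation (a proportion) is arcsine-square-root transformed
and tested with one-way repeated-measures ANOVA; the Greenhouse–Geisser
corrected p-value is reported when Mauchly's test rejects sphericity;
post hoc paired t-tests are Bonferroni-adjusted. Degenerate inputs with
no between-part variation return statistic 0 and p = 1 by convention.

## Color discrimination

The probability of correctly discriminating two stimuli is a sigmoid in
the chromatic distance V between their loci. Two published
parameterizations are built in: a three-parameter logistic for the
honeybee on hexagon distances (Mo = 0.492, K = 1, r = 78.5) and a
four-parameter logistic for the hummingbird hawkmoth on Maxwell-triangle
distances (Mo = 0.33, K = 1, r = 0.015, x_mid = 0.143). Pairwise
application over two sets of loci evaluates h at every cross pairing
(7 × 7 = 49 in the field design) and reports the mean ± SE over pairings;
pairings are treated as exchangeable, ignoring the dependence induced by
shared flowers — a documented simplification. The default curve is the
point-estimate parameterization; an uncertainty envelope requires
user-supplied parameter draws, since the underlying behavioral-fit
uncertainty distributions are not published. `fit_discrimination`
estimates the free parameters by maximum binomial likelihood (L-BFGS-B,
K fixable at 1) and refuses degenerate all-success/all-failure data,
where the asymptotes are unidentifiable.

## Volatilomics

**Quantification.** Kováts retention indices use linear interpolation in
retention time between bracketing n-alkanes (the non-isothermal
convention): KRI = 100n + 100(rt − rt_n)/(rt_{n+1} − rt_n). Emission
rates are internal-standard ratios: ER = (area_compound / area_IS) × IS
mass / (duration × basis), with the basis either one flower or the fresh
mass in grams — the standard single-point internal-standard calibration
in toluene equivalents. ER is homogeneous of degree 1 in peak area and
−1 in duration.

**Multivariate-abundance test.** Intrafloral distribution differences
are tested mvabund-style: one GLM per compound with floral part as the
predictor, with the multivariate statistic the sum of per-compound
likelihood-ratio deviances. The default family is negative binomial
(NB2) with a per-compound moment estimate of the dispersion held fixed
across the null and alternative fits; with fixed dispersion and a single
categorical predictor the ML fitted values are group means, so deviances
have closed form and resampling is fast. A Poisson family is available.
Because ERs are continuous, responses are optionally log(x+1) transformed
and then scaled and rounded to integers before the count-family fit
(`transform`, `scale` arguments); the rounding convention is documented
rather than hidden, and a practitioner wanting a continuous family can
test class totals with the ANOVA path instead. Significance uses
**PIT-trap residual resampling**: randomized probability-integral-
transform residuals of the null fit are computed per observation,
resampled by row (preserving between-compound correlation), inverted
through the null quantile function, and the statistic recomputed; p =
(1 + #{Dev* ≥ Dev}) / (B + 1), giving a resolution floor of 1/(B+1)
(0.001 at the conventional B = 999). Univariate per-compound p-values
are adjusted by free step-down (Westfall–Young maxT) resampling with
enforced monotonicity.

**Ordination, clustering, partition.** NMDS embeds Bray–Curtis
dissimilarities with SMACOF-based non-metric MDS (50 random restarts by
default, seeded, best configuration kept) and reports Kruskal stress-1
computed by isotonic regression. Hierarchical clustering of part-mean
volatile profiles uses Ward's minimum-variance method on Euclidean
distances (merge heights are nondecreasing). The Venn-style partition
counts a compound as present in a part when its mean ER there exceeds a
threshold (default 0, i.e. detected in at least one sample).
Per-biosynthetic-class totals are compared across parts with one-way
ANOVA plus Tukey HSD.

## Visitation

A visit is one event row; bout aggregation is out of scope. Sessions are
overnight recordings (one camera, 1–2 flowers); the diel periods are
dusk 20:00–21:00, night 21:00–05:00 (crossing midnight, handled with
date-aware windows), morning 05:00–10:00. Per session × taxon × period,
the rate is count / (flowers × overlap hours); the table reports the
mean ± SE across sessions, with sessions where the taxon was absent
contributing zeros. Rates are invariant to splitting a session at a
period boundary, and summed per-period exposures equal total session
flower-hours. Group aggregates sum member means; the group SE combines
member SEs in quadrature, which is exact only if taxa fluctuate
independently across sessions — the within-session covariance is not
recoverable from a per-taxon summary table.

## Synthetic data

The generators define the study conditions for all property tests.

* **Spectra**: each floral-part archetype is a baseline plus a sum of
  Gaussian reflectance peaks, with additive i.i.d. Gaussian noise (sd
  0.02 by default, a free parameter — the field study reports no spectral
  variance beyond error bands) clipped to [0, 1]; 7 flowers × 3 parts.
  The default archetypes give a bright, weakly chromatic white petal
  (broad plateau above ~400 nm), a dim but strongly chromatic green
  nectary-access patch (narrow 555-nm band), and an intermediate
  pink-magenta stamen (blue + red peaks), reproducing the qualitative
  field pattern (white brightest, green patch dimmest and most
  bee-saturated). All parts are UV-absorbing.
* **Emissions**: cell means are baseline ER × multiplicative part
  effect; draws are gamma with shape 1/φ and scale mean·φ (squared CV =
  φ, default 0.3), or lognormal with matched mean and variance. The law
  is the fixture's assumption — the field data's generating law is
  unknown; ERs there are overdispersed and strictly positive, which both
  laws respect. The default design uses the intrafloral sample sizes
  (calyx+gynoecium 4, corolla 5, nectar 5, stamens 6) and baseline ERs
  of the magnitude observed for eight representative headspace
  compounds.
* **Visits**: homogeneous Poisson within each diel period (block rates
  only; no diel smoothing), six overnight sessions at the recorded
  per-taxon rates.

What passing tests on these fixtures do **not** show: instrument noise
structure in real spectra (smooth, wavelength-correlated errors), GC-MS
co-elution and identification uncertainty, non-Poisson clumping of
visits ("big nights"), or between-flower covariance of volatile
profiles.

## Problem sizes and tolerances

The statistical property suites run at deliberately modest sizes chosen
to make Monte-Carlo assertions sharp but cheap: type-I error of the
multivariate test is estimated from 200 null datasets at B = 199
resamples (accepted band 0.02–0.09 at α = 0.05); discrimination-constant
recovery uses 12 distance levels × 500 trials; visitation recovery uses
the six-session design with a 3-SE band. Exact identities (round trips,
closed forms, brute-force oracles) are asserted at 1e-9 or tighter;
quantities recomputed from the packaged survey tables are asserted at
the precision printed there (one decimal).

## Known limitations

* The NB-on-rounded-values convention for continuous ERs is one of
  several defensible readings of applying a count-family multivariate
  model to log-transformed continuous data; Poisson and class-total
  ANOVA routes are provided as alternatives.
* The discrimination SE ignores shared-flower dependence (see above).
* The illuminant/background actually used in the field analysis are not
  published; defaults are ideal flat spectra and results depending on
  them (absolute saturations) should be read comparatively, not
  absolutely.
* Camera-trap rates assume perfect detection within sessions.
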
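# anthosense

Intrafloral sensory ecology for pollination biologists: given reflectance
spectra of floral parts, a GC–MS volatile peak table, and camera-trap
visit logs, `anthosense` quantifies what a flower looks and smells like
*to its visitors*, and how often those visitors actually come.

The motivating system is the caper bush (*Capparis spinosa*), a
night-blooming, brush-flowered Mediterranean shrub whose sphingophilous
display (white petals, nocturnal anthesis, massive scent emission)
contrasts with visitation dominated by diurnal bees. Resolving that kind
of discrepancy needs pollinator-subjective measurements, which is what
this package provides:

* **Colorimetry** — quantum catches Q_i = ∫ R(λ) S_i(λ) I(λ) dλ over
  300–700 nm, von Kries normalization against the adapting background,
  color loci in the Maxwell triangle, the bee color hexagon
  (E = q/(q+1)), and a tetrahedral space, and saturation *r* as the
  distance of a locus from the achromatic center. Built-in visual
  systems: tobacco hornworm, honeybee, swallowtail, hummingbird
  hawkmoth (receptor curves from the Govardovskii A1 template at the
  published peak wavelengths). Friedman and repeated-measures ANOVA
  statistics for comparing floral parts paired by flower.
* **Color discrimination** — psychometric functions giving the
  probability of correct discrimination at chromatic distance V:
  h(V) = Mo·K / (Mo + (K−Mo)e^{−rV}) for the honeybee (hexagon units)
  and h(V) = Mo + (K−Mo)/(1 + e^{(x_mid−V)/r}) for the hummingbird
  hawkmoth (Maxwell-triangle units), applied over all flower pairings.
* **Volatilomics** — Kováts retention indices, emission rates in
  internal-standard (toluene) equivalents per flower (or g fresh mass)
  per hour, composition shares, Bray–Curtis NMDS, Ward clustering,
  shared-compound Venn partitions, multivariate-abundance tests (summed
  per-compound GLM deviances, PIT-trap residual resampling) and
  per-class ANOVA with Tukey HSD.
* **Visitation** — per-taxon, per-diel-period rates in visits·fl⁻¹·h⁻¹
  from timestamped event logs, with SEs across recording sessions.
* **Synthetic data** — seeded generators for all three input families,
  so every stage is testable without field data.

Two small reference tables from the published caper field survey (mean
volatile emission rates for two Lesvos populations; visitation rates
from six camera nights at Mytilene) ship with the package and anchor the
internal-consistency checks.

## Worked example

Run the all-synthetic demo pipeline (every stage, fixed seed):

```sh
anthosense run-all --seed 42 --out demo_out
```

which prints (abridged):

```
anthosense 0.1.0 run (seed=42)
  brightness_friedman_Q: 14.0
  brightness_friedman_p: 0.000912
  discrimination_min_apis_logistic3: 0.9999
  discrimination_min_macroglossum_logistic4: 0.9929
  mglm_deviance: 497.09
  mglm_p: 0.005
  nmds_stress: 0.0433
  reference_checks_passed: 15
  reference_checks_total: 15
  visits_dusk: 32.17
  visits_morning: 7.33
  visits_night: 0.15
```

Reading this: the seven synthetic flowers differ maximally in brightness
across their three parts (Friedman Q = 14 is the largest value possible
for k = 3 parts and n = 7 blocks; p < 0.001); both the bee and the
hawkmoth models discriminate every part pair almost perfectly on these
strongly separated archetypes (minimum pairwise probability 0.99+); the
floral part explains the volatile matrix (multivariate deviance 497, p
at the 1/(B+1) = 0.005 resolution floor for B = 199 resamples); the
2-D NMDS embeds the Bray–Curtis structure at stress 0.04; and the
recovered visitation rates (32.2 dusk / 7.3 morning / 0.15 night
visits·fl⁻¹·h⁻¹) sit within Poisson error of the generating rates. All
15 reference-table checks pass. Per-stage CSVs and `report.json` land in
`demo_out/`.

The library surface mirrors the CLI; for instance the composition shares
of the packaged survey table:

```python
>>> from anthosense import datasets
>>> from anthosense.volatilomics import composition_shares
>>> means = datasets.population_means(population="koudouroudia")
>>> composition_shares(means, {"aldoximes": datasets.ALDOXIMES})
aldoximes    41.629969
dtype: float64
```

i.e. the six branched-chain aldoximes alone carry 41.6% of total
emissions in the Koudouroudia population — an enormous investment in
amino-acid-derived volatiles, typical of hawkmoth-pollinated blends.

## Layout

```
src/anthosense/
  colorimetry.py     spectra, visual systems, color spaces, statistics
  discrimination.py  psychometric functions, pairwise matrices, fitting
  volatilomics.py    KRI, emission rates, NMDS, Ward, Venn, MGLM, ANOVA
  visitation.py      event logs -> rate tables
  synthetic.py       seeded generators for spectra, emissions, visits
  datasets.py        packaged reference tables
  pipeline.py, cli.py  orchestration and command-line interface
docs/methods.md      models, assumptions, parameter choices, limitations
```
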
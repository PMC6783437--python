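# Methods

This note documents the models implemented by `mnapport`, the defaults
they ship with, the choices made where the methodology was genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Units and table conventions

All intakes and requirements are carried internally in mg day⁻¹; µg-scale
elements (Se, I, Mo) are fractional mg. Water concentrations are mg L⁻¹
for Ca and Mg and µg L⁻¹ for the trace elements, with the unit encoded in
the column name (`Ca_mg_L`, `Se_ug_L`). Crop and soil concentrations are
mg kg⁻¹ dry weight. Tables are plain CSV (UTF-8, `.` decimal, one header
row, element columns named by symbol).

Censored cells are written `<LOD` (e.g. `<0.01`) and substituted at read
time; the default policy is half the detection limit, the convention in
trace-element geochemistry, with `zero` and `lod` available. A censored
value is distinct from a missing (not-measured) cell: missing cells stay
NaN and are excluded from medians and regressions rather than imputed.

## Soil classification and summaries

Soils are classified operationally by pH measured in CaCl₂ slurry:
calcareous iff pH > 6.5, strictly — a soil at exactly 6.5 is
non-calcareous. High-Ca soils below the threshold remain non-calcareous;
the classification is by pH alone. Group summaries report medians with
quartiles by linear interpolation between order statistics (the "type 7"
rule, numpy's default); the choice of quantile rule is a fixed convention,
not a result.

## Composition scenarios

Measured composition tables are medians per (country, food item, element)
over crop samples whose linked soil (via `site_id`) falls in the scenario
class, so the calcareous and non-calcareous tables are disjoint by
construction. Food-group medians pool all underlying samples of the group
rather than taking a median of item medians; pooling is robust to items
measured only once and treats the group as a sampling stratum. The
published scenario is a first-class composition table assembled from an
external source plus a substitute source for gaps, with per-cell
provenance (`measured` / `substituted`); an item missing from both is a
hard error rather than a silent hole.

## Supply model

Supplies are computed in dry-weight space: fresh-weight FBS supply ×
(1 − moisture fraction) × DW concentration / 1000, summed over items.
Items in the supply table without composition data in a scenario are
dropped from that scenario — never imputed, to keep scenario contrasts
honest — and the fraction of fresh-weight supply mass covered is reported
as a completeness ratio. The shipped moisture fractions and non-staple
supply figures are standard food-composition values intended to be
replaced by user data; the maize dry-weight supplies default to 144
(Tanzania) and 187 (Kenya) g capita⁻¹ day⁻¹.

## EAR cut-point risk model

Intake of element *e* is modelled Normal(S, (cv·S)²) with cv = 0.25 by
default; risk% = 100·Φ((EAR − S)/(cv·S)). The Normal/0.25 pair is the
combination that reproduces the published calcium prevalence pair
(852 → 95%, 914 → 89% against EAR 1200) exactly at integer rounding; a
log-normal intake model with the same mean and CV is one switch away
(`distribution="lognormal"`), since the literature this family of
calculations descends from is not explicit about the distributional form.
Zero supply returns 100% by convention (logged). Report tables round
half-up to integer percent; machine outputs keep full precision.

RNI→EAR conversion divides by 1.2 (EAR = RNI/(1 + 2×0.10), the usual
FAO/WHO convention), configurable.

### Requirements table

The shipped adult EAR table is data, not constants, and is fully
overridable. Ca (1200), Cu (0.7), I (0.150) and Mo (0.034) mg day⁻¹ are
published figures; Fe, Mg, Se and Zn per-sex EARs are *reconstructions*
back-derived from published prevalence tables under the Normal/0.25 model
(each checked against at least two independent printed percentages where
possible) and are tagged `reconstructed` in the `source` column. Fe and
Zn carry lowest-bioavailability EARs. Two printed percentages sit on
rounding boundaries that no single EAR value can satisfy simultaneously
with the others; the shipped values favour the majority of printed cells.

## Drinking-water contributions

Per (country, source) element medians — and maxima, since headline figures
for sporadically contaminated sources (roof-collected rainwater Zn) rest
on maxima — are converted to mg day⁻¹ at a consumption volume of
1.7 L day⁻¹ (a deliberately conservative default for hot climates; a
volume-grid sensitivity helper is built in) and expressed as % of the EAR,
rounded half-up to one decimal in report output.

## LMG variance decomposition

Per food group × element: response ln(crop concentration); predictors the
soil concentration of the same element, pH, organic matter (LOI), and soil
Fe, Mn, Al, Ca, Mg, K, P and S. Element concentrations are natural-log
transformed (they are right-skewed); pH and LOI enter untransformed, since
pH is already a log quantity and LOI is a bounded percentage. When the
response element duplicates a named slot (e.g. crop Ca vs soil Ca) the
named slot is dropped and rendered "—" in reports.

The LMG share of predictor *k* is the average over all p! orderings of the
R² increase when *k* enters, computed exactly with the subset identity

    share(k) = (1/p) Σ_{S ⊆ others} C(p−1,|S|)⁻¹ (R²(S∪{k}) − R²(S)),

one pass over the 2^p cached subset R² values (p = 10–11 here, so ~1–2k
subset fits per model). Shares are reported in percentage points and sum
to 100·R² of the full model to 10⁻⁸. The test suite carries an independent
factorial-enumeration oracle for p ≤ 6.

Inference: p-values are two-sided t-tests on the full-model coefficients
(shares themselves have no native p-value); direction is the full-model
coefficient sign; "dominant" (** in reports) is the largest share among
predictors significant at 0.05, at most one per model. Designs with fewer
than p + 2 complete rows, or rank-deficient designs, are flagged
degenerate and rendered blank rather than fitted. Countries are pooled by
default (fit per country by filtering the input tables); note that pooled
fits on heterogeneous countries absorb between-country differences into
the soil predictors, which inflates explained variance relative to a
within-country fit — visible in the synthetic default, where pooled totals
exceed the single-country 5–30% regime.

## Synthetic survey generator

The generator emulates the measurement campaign's statistical structure,
not its spatial texture. Defaults are the study conditions: 50 Tanzanian
sites (28% calcareous) and 232 Kenyan sites (15%), per-source water group
sizes as surveyed (down to n = 1–2 for rare sources), and soil/water
geometric medians calibrated to the published per-group medians. Soil pH
is a two-component Normal mixture (non-calcareous mean 5.5 sd 0.5;
calcareous 7.2 sd 0.4; truncated to (3, 9)); concentrations are
log-normal with geometric SD 1.5 for major elements and 2.0 for traces
(plausible geochemical spread, configurable). Crops follow a known
log-linear soil model: ln c = ln gm(item) + δ_e·1[calcareous] + Σβ_j z_j +
ε, with per-predictor variance fractions configurable (defaults give 5–30%
within-country explained variance) and β recorded in a ground-truth
sidecar that never enters the data tables. Water is per-source log-normal.
Identical seed and configuration give byte-identical files (numpy
`default_rng`/PCG64, recorded in the sidecar).

Not modelled: spatial autocorrelation, seasonality, measurement error and
inter-element correlation beyond the soil-class effect. Passing recovery
tests therefore demonstrates correctness of the estimators under the
assumed sampling model, not robustness to real-survey artefacts.

## Problem sizes used in the test suite

Acceptance-grade checks run at the sizes their statements require: the
Monte-Carlo risk oracle uses 1,000 random (S, EAR, cv) triples × 10⁶
draws; the LMG enumeration oracle 50 instances at p ≤ 6; type-I control
1,000 pure-noise 11-predictor models; signal recovery 200 replicates at
n = 200 sites; calibration 10 seeds at 2,000 samples per group. Everything
else runs on the study-scale default survey (282 sites) or the hand-written
tiny fixture.

## Known limitations

- FBS supplies are national averages: no household variation, seasonality
  or waste adjustment; the intake CV is a single fixed population value.
- Bioavailability enters only through the choice of EAR (lowest class for
  Fe/Zn); no phytate or anti-nutrient modelling.
- The reconstructed EAR entries are model-dependent (Normal/0.25); users
  with authoritative requirement tables should replace the shipped file.
- The water contribution treats source medians as exposure; it does not
  model source-switching or treatment.
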
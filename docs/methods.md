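# Methods

## Scope and model

`toptrees` analyses stem-level forest inventories organised as 1-ha plots
grouped into sites. Three quantities drive everything: a stem's diameter at
breast height D (cm, census threshold 10 cm), its height H (m, measured or
predicted), and its wood specific gravity ρ (g/cm³). Stem AGB is estimated
with the pantropical moist-forest allometry

    AGB = a (ρ D² H)^b,      defaults a = 0.0673, b = 0.976  [kg dry mass]

or, when no height information exists, with the diameter-only form

    ln AGB = c₀ − c₁E + c₂ ln ρ + c₃ ln D + c₄ (ln D)²,

where E is a dimensionless environmental stress factor supplied per site.
Both coefficient sets live in `AllometryConfig`, not in code, so alternative
published calibrations can be swapped in; the pipeline-level test
`test_robust_to_allometry_choice` checks that the fitted top-20 exponent
moves by less than 0.05 when switching between the two forms. Plugging the
E-dependent reference height relation into the with-height model reproduces
the height-free model within 1% over D ∈ [10, 150] cm, which is the
consistency the cross-check test asserts at a 5% tolerance.

Wood density is assigned per stem by strict taxonomic fallback:
species mean → genus mean → family mean → table-wide mean. The terminal
global-mean step is deliberate: an unmatched stem keeps a density (and thus
an AGB) rather than silently dropping out of plot totals; the provenance
level is recorded on the record. Unidentified stems are pooled under a
sentinel taxon that carries AGB but is excluded from richness counts and
can never be a dominant species (toggleable in the hyperdominance calls).

## Height–diameter allometries

Site-specific H–D models come in three forms: power `H = aD^b` (default,
fitted exactly by log-log least squares), Michaelis–Menten `H = aD/(b+D)`
and Weibull `H = a(1 − e^{−bD^c})` (both by nonlinear least squares).
`form="auto"` keeps whichever form minimises the log-scale residual sd.
Power-form predictions apply the half-variance back-transformation
correction `exp(σ²/2)` by default (switchable), since the fit is on the log
scale. Fits require at least 20 height observations; fitted models are
validated to predict positive, nondecreasing heights over D ∈ [10, 300] cm.

## Accumulation and the top-N model

Within a plot, stems are ranked by decreasing AGB with deterministic
tie-breaking (larger DBH first, then stem id), and cumulative AGB and
species-richness fractions are tracked over N = 1..stems. Site summaries
cap N at each plot's stem count so every plot contributes at every grid
point; with a single plot the sd is reported as 0 with a `single_plot` flag
rather than as missing, which keeps downstream tables stable.

The cross-plot relation between the summed AGB of the N largest trees and
the plot total is a power law without intercept, `AGB_TOT = α·AGB_topN^β`,
fitted by nonlinear least squares on the natural scale with start values
from log-log ordinary regression. Natural-scale fitting makes the residual
standard error directly interpretable in kg/ha; RSEr divides it by the mean
observed AGB_TOT. R² is computed about the observed mean (not the
uncentered form), so values are comparable across N. When the pairs follow
an exact power law (log residuals below 1e-12) the closed-form log-log
solution is returned directly, which makes the identity limit
(N ≥ stems ⇒ α = β = R² = 1) exact to machine precision. A failed
nonlinear fit raises an error carrying the log-log fallback coefficients.

The meta-model over N uses `α(N) = a·N^b` (power, no intercept) and
`β(N) = k₁(1 − exp(−k₂N^{k₃}))`, a standard 3-parameter Weibull growth
curve started at (1, 0.1, 1) with box bounds k₁ ∈ (0, 10], k₂ ∈ (0, 50],
k₃ ∈ [−5, 5]. The saturating Weibull shape matches the asymptotic rise of
β with N; the exact published variant of this meta-fit is not available, so
the package fits its own coefficients and makes no claim of numerical
equality with any published set. Predictions are refused outside the
calibrated validity range N ∈ [5, 100].

Site-wise leave-one-out cross-validation refits the per-N model without one
site and scores that site's plots. "Bias" is reported as the mean absolute
relative error mean(|pred − obs|/obs); the signed mean relative error is
computed alongside, since the absolute form is the stricter and less
ambiguous headline. Sites with fewer than two plots are excluded with a
warning, and at least three usable sites are required.

## Hyperdominance

A site's species contributions are its species AGB totals divided by the
site's sampled area (number of 1-ha plots), in t/ha. The regional
contribution of a species is the **unweighted mean over sites** of these
site-standardized values (absent = 0), so each site contributes equally
regardless of how many plots it has; with equal site areas this coincides
with pooling, and the choice is the natural reading of equal-site
weighting. Species are ranked by decreasing contribution (alphabetical
tie-break) and the hyperdominant set is the minimal prefix whose cumulative
share reaches the threshold, inclusive: a prefix summing to exactly 50%
stops there. Local dominance applies the same operator within one site.

The packaged reference table (`data/regional_hyperdominants.tsv`) carries
the printed values of the 18 Central African biomass-hyperdominant species
and the recorded-species count (1194) as metadata. Its printed cumulative
column is reproduced by the package's cumulation operator within 0.02, the
slack expected from summing 2-decimal rounded inputs. One printed row
(Coula edulis) lists three site codes against a printed site count of 2;
the table is shipped exactly as printed and tests use only the numeric
columns.

## Synthetic stands

The generator emulates the structural features the analysis assumes, not
any particular forest:

- **Diameters**: truncated Pareto on [10, 250] cm with exponent 2.0
  (inverse-CDF sampling; the KS distance of a 5 000-stem sample to the
  closed-form CDF is ~0.01). The power-law form is the metabolic-scaling
  size–abundance prediction; the exponent is configurable to emulate
  reported systematic deviations for the largest size classes.
- **Abundances**: a log-series (default, shape 0.995) or geometric species
  abundance distribution over a 300-species pool; each site permutes which
  species occupy the abundant ranks, producing compositional turnover.
- **Wood density**: species-level draws from N(0.60, 0.15) g/cm³ clipped to
  [0.1, 1.2]; species are assigned independently of size by default.
- **Heights**: power H–D law H = 3.0·D^0.56 with 10% lognormal noise —
  roughly 11 m at 10 cm and 40 m at 100 cm DBH, typical of African moist
  forest. Stem AGB is computed through the allometry module, so generated
  regions exercise the full pipeline.
- **Site effects**: lognormal multipliers (sd 0.10) on stem density and on
  stature, giving between-site AGB variation.
- **Monodominance**: one site by default mimics Gilbertiodendron-type
  stands; the dominant species takes the largest stems until it holds the
  configured share (default 0.70) of large-tree (≥ 50 cm) basal area. This
  size-sorted assignment reflects how monodominant species monopolise the
  upper canopy and makes the share parameter translate directly into
  site-level AGB dominance.

Defaults (8 sites × 20 plots, ~450 stems/ha) produce a mean top-20 AGB
fraction around 0.65 — inside the plausible tropical band (0.25–0.85) the
tests assert, though higher than typical observed means near 0.5, because a
pure truncated Pareto holds more mass in big stems than real mixed stands.
The generator also omits spatial structure, measurement error in DBH,
taxonomic misidentification and growth dynamics; passing tests therefore
demonstrate the correctness and stability of the estimators under the
stated stochastic structure, not calibration to any real census.

`true_agb_law` estimates the (α, β) the generator implies at a given N by
regenerating replicate regions on independent seed streams and refitting,
returning means with standard errors for use as recovery targets.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled-down regions (3–7 sites, 5–25
plots per site, 120–250 stems/ha) chosen so each property is measured on
hundreds of plots while the whole suite stays fast; the 175-plot
configuration used for recovery checks matches the sampling breadth of a
realistic regional census. All randomness flows through
`numpy.random.default_rng` seeded from explicit integers, so every result
in the README and test suite is bit-reproducible.

Known limitations: no propagation of allometric or wood-density uncertainty
into plot AGB; no spatial-autocorrelation correction in dominance
estimates (dominance can be overstated when plots cluster within sites);
richness analyses use raw counts, not rarefaction; the DBH census threshold
is fixed at 10 cm.
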
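# Methods

## The dilution-replicate model

Quantitative PCR amplifies template exponentially: after `c` cycles a
template present at relative quantity `Q` has grown by `E^c`, where the
amplification efficiency `E ∈ (1, 2]` is a property of the primer pair
and reaction (2 = perfect doubling).  The quantification cycle Cq is the
cycle at which fluorescence crosses a threshold common to all compared
genes, giving

```
Cq = baseline − log10(Q)/log10(E) + log10(D)/log10(E)
```

for a sample diluted by factor `D` (1 = undiluted).  In the
dilution-replicate design every biological replicate is run at a short
dilution series (defaults 1, 5, 25), so within one amplicon the wells of
replicate `r` lie on a line with replicate-specific intercept `a_r` and a
slope `b = 1/log10(E)` shared by all replicates.

**Collinear fit.**  `curves.fit_collinear` estimates this model by one
ordinary least squares per amplicon on the full indicator design matrix:
one intercept column per fit-eligible replicate (≥ 2 distinct dilutions
with observed Cq) plus one shared `log10(D)` column.  There is no global
intercept; the model has (#replicates + 1) parameters.  The fit fails
loudly when the design is rank deficient (a single dilution level) and
warns, without failing, when the estimated efficiency falls outside the
plausible [1.6, 2.1] range or the slope is not positive.  R² is the
centered coefficient of determination.

**Sign conventions.**  The regressor is the dilution *factor*, so the
slope is positive and `E = 10^(1/b)`.  The classical standard-curve
formula `E = 10^(-1/slope)` regresses Cq on log10 *concentration*
(= 1/D); `curves.classical_efficiency` implements it as a comparison
utility, and the two conventions agree to machine precision on the same
data (a test asserts 1e-9).

**Quantification.**  Intercept differences are log-quantity differences:
`log10(Q_r) = (a_ref − a_r)/b`.  The reference replicate is arbitrary —
it moves all quantities by one factor — because the final rescaling fixes
the scale.  Normalized expression divides each gene-of-interest quantity
by the geometric mean of the same replicate's reference-gene quantities
(geometric, not arithmetic, averaging is the correct way to combine
ratio-scale reference genes), then rescales each gene so the
scaling-reference group (default: first group in file order, matching
all-to-one semantics) has geometric mean 1.  Group contrasts of mean
log2 expression are invariant to both choices; only plot axes move.

**Cq–Cq lines.**  Eliminating `log10(D)` between the gene-of-interest and
reference-gene curves of one replicate gives
`Cq_goi = (b_goi/b_rg)·Cq_rg + (a_goi,r − (b_goi/b_rg)·a_rg,r)`.
The package derives these diagnostic lines from the two collinear fits
rather than regressing GOI Cq on RG Cq directly; the derived form uses
the pooled slope information and is exact on noiseless data.

## Outlier flagging

Wells with externally studentized residual |t| > 3 (configurable) are
flagged, never removed: with the small well counts typical of qPCR,
silent deletion is more dangerous than an annotated point.
`refit_without_outliers` performs one explicit refit on request.  With
fewer than 3 residual degrees of freedom no flagging is attempted (the
studentized residual is undefined or useless there) and a warning is
issued.

## Imputation of missing reference-gene Cq

Missing reference-gene cells (failed wells, pipetting dropouts) are
imputed by weighted predictive mean matching, a single-imputation scheme:

1. regress the amplicon's observed Cq on the predictors available in the
   same plate row — `log10(D)` plus the Cq of every other amplicon;
2. predict the missing cell; rank observed rows by |predicted − predicted|
   distance;
3. keep the `k = 5` closest donors, draw one with probability
   proportional to inverse distance, and impute the donor's *observed*
   Cq.

Imputed values are therefore always observed values of the same amplicon
and can never extrapolate outside the observed Cq range.  The "weighted"
donor draw is this package's concretization of weighted PMM; published
variants differ in their weighting internals, and the exact scheme
matters little at the k = 5 pool size used here.  Rows whose predictors
are themselves partly missing fall back to the available subset (at worst
dilution only).  Columns missing > 50% are refused, > 30% warned about:
imputing that much data produces curves that mostly reflect the
imputation model.  Genes of interest are never imputed — a missing GOI
triple simply drops that replicate from that gene.

Single rather than multiple imputation is deliberate: one completed table
feeds one regression pass, and no pooling step exists downstream that
could consume between-imputation variance.

## Statistics

All tests consume log2 normalized expression.  Expression ratios are
approximately log-normal; parametric tests on the linear scale would be
invalid.  The user picks the family and comparison mode; the test is then
fixed:

| groups | mode | parametric | nonparametric |
|---|---|---|---|
| 2 | — | Welch t (paired t) | Mann-Whitney U (Wilcoxon signed-rank) |
| >2 | all to one | Dunnett many-to-one | Kruskal-Wallis + Dunn, Holm |
| >2 | all pairs | Tukey HSD | Kruskal-Wallis + Dunn, Holm |
| >2 | selected pairs | Welch t + Holm | Mann-Whitney + Holm |

Dunnett and Tukey control the familywise error by construction;
elsewhere the Holm step-down adjustment is applied within each gene
(per-gene families match per-plot annotation; no adjustment is made
across genes).  The Dunn post-hoc test is implemented in
`stats.dunn_test` (pooled-rank z statistics with tie correction); for two
groups its z² equals the Kruskal-Wallis H, which a test uses as an
independent cross-check.  Paired tests require a complete `Pairs` column
for the groups involved; otherwise the run falls back to unpaired with a
warning rather than silently dropping samples.  Groups with fewer than
two replicates are dropped; a gene with fewer than two usable groups is
skipped; all-constant data yields p = 1 with a degenerate-data warning.
Significance labels: `*` p < 0.05, `**` p < 0.01, `***` p < 0.001, while
the `significant` flag itself uses the user's α.

## Synthetic data

The generator (`synthetic`) draws from exactly the generative model the
fit assumes: exponential amplification, i.i.d. Gaussian Cq noise
(`noise_sd`, cycles; 0.1–0.3 spans typical plate-to-plate technical
noise, with 0.2 used as the working value in the recovery tests), and
missingness injected completely at random, only into reference-gene
cells.  Defaults mirror the canonical design: fivefold dilutions 1/5/25,
three biological replicates per group, efficiency 2.0, baseline Cq 20.

This means passing tests demonstrate *method correctness* — parameter
recovery, invariances, calibration — under the stated model.  They do not
probe model violations real plates can show: plateau effects and
Cq-dependent noise, pipetting bias in the dilution series (which biases
efficiency in real data exactly as it would in the original design),
informative missingness near the detection limit, or between-gene
threshold mismatch.  The requirement that a common fluorescence threshold
be set for all compared genes is a property of the Cq export, invisible
to this package, and is documented rather than validated.

## Numerical choices

* Least squares via `statsmodels` OLS on the explicit indicator matrix;
  tests verify equality with an independent normal-equations solve to
  1e-10.
* Geometric means as `exp(mean(log(·)))`; inputs are positive by
  construction (parser rejects non-positive expression, quantities are
  exponentials).
* CSV output always uses point-decimal/comma-field with 12 significant
  digits (round-trip safe); the two input dialects are auto-detected
  from the header line and must not be mixed.
* Dilutions enter regressions as `log10(factor)`; factor 1 = undiluted.
* Imputation ties in the donor pool are broken by a stable argsort, and
  a 1e-12 floor prevents division by zero for exact-match donors, which
  then dominate the draw as intended.
* Determinism: every stochastic step (simulation, donor draws) takes an
  integer seed through `numpy.random.default_rng`; figure and PDF output
  suppresses timestamps so identical inputs give identical bytes.

## Problem sizes used in the checks

The self-contained checks run at desk scale, chosen to keep the full
suite under a minute while leaving comfortable statistical margins:
noiseless recovery on 2 groups × 3 replicates; halving-design recovery
with 9 replicates averaged over 20 seeds (tolerance ±0.1 log2 units);
oracle equivalence on 100 randomized instances; type-I-error calibration
over 200 simulated null datasets per family (band: two binomial standard
errors around α = 0.05); imputation behaviour over 50 seeds at 10%
missingness.

## Known limitations

* One-factor designs only; for two-way layouts export the intermediate
  expression table and use external statistical software.
* No inter-run/multi-plate calibration; all wells are assumed to share
  one run and one threshold.
* Imputation assumes reference-gene missingness is unrelated to
  expression level (MCAR); dropouts near the detection limit violate
  this.
* Efficiencies are per amplicon, not per well; per-well estimation
  requires raw fluorescence curves, which Cq tables no longer contain.
* Vendor thermocycler export formats are not parsed; inputs must follow
  the two CSV layouts described in the README.
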
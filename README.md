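# repdil

Analysis of qPCR assays run in the **dilution-replicate design**: instead
of identical technical replicates plus a separate standard curve, each
biological replicate is pipetted as a short serial-dilution series
(typically fivefold: factors 1, 5, 25).  All series of one amplicon then
jointly define the standard curve, every sample contributes to the
efficiency estimate, and all Cq values are guaranteed to sit inside the
curve's dynamic range.

The package is for bench scientists and bioinformaticians who have a
plate of Cq values (or precalculated relative expression values) and want
efficiency-corrected, reference-normalized expression with statistics and
plots in one command.

## The model

For amplicon *g* with amplification efficiency *E* (2 = perfect
doubling), replicate *r* at dilution factor *D*:

```
Cq_{r,d} = a_r + b · log10(D),      b = 1 / log10(E)
```

One ordinary-least-squares fit per amplicon shares the slope *b* across
replicates and gives each replicate its own intercept *a_r* (its Cq at
*D* = 1).  From the fit:

* efficiency `E = 10^(1/b)` (the classical standard-curve formula
  `E = 10^(-1/slope)` under the opposite axis convention — the package
  ships both and they agree exactly);
* relative quantity of replicate *r* versus a reference replicate:
  `log10(Q_r) = (a_ref − a_r) / b`;
* normalized expression `N = Q_goi / geomean(Q_rg)` over one or more
  reference genes (geometric averaging), rescaled so the scaling-reference
  group has geometric mean 1;
* group comparisons on `log2(N)` (never linear values), with the test
  chosen from the user's family (parametric / nonparametric) and
  comparison mode (all-to-one, all-pairs, selected pairs).

Missing reference-gene Cq values can be imputed by weighted predictive
mean matching before fitting; wells with extreme studentized residuals
are flagged as possible outliers.

## Worked example

Simulate a two-condition experiment in which the second group's gene of
interest has one quarter of the template, then analyze it end to end:

```sh
repdil simulate --groups "ctrl:1.0,treat:0.25" --n-replicates 4 \
    --noise-sd 0.1 --seed 3 --out sim.csv
repdil run --input sim.csv --reference-genes RG1 \
    --stats parametric --comparisons all-to-one --outdir out/
```

The run prints the written files followed by the comparisons:

```
GOI1: ctrl vs treat [Welch t-test] p_adj=7.853e-06 ***
```

`out/sim_fits.csv` holds per-amplicon slope, efficiency, R² and slope SE
(here E ≈ 2.0 for both amplicons, matching the simulated truth);
`out/sim_expression.csv` the per-replicate normalized expression (treat
centred near log2 = −2, i.e. the simulated 4-fold reduction); and
`out/sim_stats.csv` the tests.  Plots come as a multi-page PDF plus one
PNG per gene; log2-scale files carry `_log` in their names.

The same `repdil run` works on precalculated relative expression values
with `--mode precalc` (no `Dilution` column, no reference genes needed).

Library use mirrors the CLI: `read_cq_table` → `analyze_cq_dataset` →
`ExpressionTable` / `StatsResult`, see `repdil/pipeline.py`.

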
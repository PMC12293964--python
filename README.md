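# strokeconn

Predicting acute stroke severity from lesion volume and resting-state
functional connectivity.

In patients with acute subcortical ischemic stroke, early neurological
deficit — the NIHSS score — is partly explained by how much tissue the
lesion destroyed and partly by how much it disrupted large-scale brain
networks. `strokeconn` implements the full analysis chain for this question
as a tested, reusable Python package, aimed at neuroimaging researchers who
want to reproduce, stress-test or extend this class of severity model:

1. **Lesion volumetrics** — volume in mm³ from binary lesion masks
   (voxel count × voxel volume), read from NIfTI with header-derived voxel
   dimensions.
2. **Network connectivity features** — from ROI-averaged BOLD time series
   (optionally 0.01–0.1 Hz zero-phase band-passed): Pearson correlation
   between every region pair, Fisher transform *z* = arctanh *r*, then
   unweighted averaging over region pairs within one network configuration
   (intra) or across two (inter). Six predefined networks (four motor
   networks, default mode, frontoparietal; AAL3-style lateralized regions)
   crossed with hemisphere scopes {left, right, both} give 18
   configurations and 18 + C(18,2) = **171 named predictors**.
3. **Incremental regression** — OLS of NIHSS on at most 5 predictors,
   added greedily by largest training-R² gain, with a variance-inflation
   gate (VIF < 2) and Shapiro–Wilk residual checks; generalization
   estimated by 5-fold cross-validation (fold R² = 1 − SSE/SST about the
   held-out fold's mean) on one shared partition.
4. **Model comparison** — a seven-model suite (lesion-only, best single
   connectivity predictor, incremental with/without lesion, left/right/both
   hemisphere candidate sets) compared by ΔAIC, fold-paired *t*-tests and
   likelihood-ratio tests for nested fits
   (χ² = 2 Δlog L = n ln(RSS_nested/RSS_full)).

Because clinical cohorts of this kind are not publicly shareable, the
package ships a first-class **synthetic cohort generator**: block-structured
multivariate-normal ROI time series whose within-network correlations are
degraded by a lateralized lesion-impact process, lesion masks grown to exact
target volumes, and NIHSS produced by a linear model with Gaussian noise —
so the entire pipeline is testable end to end with no data download.

## Worked example

Simulate a 44-subject cohort under the default conditions and run the full
suite:

```bash
strokeconn suite --seed 17 --out report/
```

prints (and writes to `report/model_metrics.{csv,md}`):

```
| Model Description | R-Squared | Adjusted R-Squared | AIC | BIC | Cross-Validated R-Squared | Cross-Validated MSE |
|---|---|---|---|---|---|---|
| Lesion Size Only | 0.39 | 0.38 | 203.19 | 208.55 | 0.17 | 5.84 |
| Best Connectivity Predictor Only | 0.31 | 0.30 | 208.46 | 213.81 | -0.25 | 7.99 |
| Best Predictors Without Lesion Size | 0.58 | 0.53 | 194.39 | 206.88 | 0.14 | 5.80 |
| Best Predictors Including Lesion Size | 0.71 | 0.67 | 178.90 | 191.39 | 0.38 | 3.91 |
| Best Predictors for Left Hemisphere Only | 0.37 | 0.29 | 212.36 | 224.85 | 0.09 | 6.86 |
| Best Predictors for Right Hemisphere Only | 0.35 | 0.26 | 214.06 | 226.55 | -0.33 | 9.03 |
| Best Predictors for Both Hemispheres | 0.58 | 0.53 | 194.39 | 206.88 | 0.14 | 5.80 |
```

Reading the table: the combined model (lesion volume seeded, connectivity
features added greedily) explains 71% of NIHSS variance in-sample versus
39% for lesion volume alone, and keeps a clear cross-validated advantage
(CV R² 0.38 vs 0.17) — connectivity adds severity information beyond lesion
size, which is the scientific point of the suite. `report/comparisons.json`
holds the pairwise tests; here the likelihood-ratio test for extending a
primary-motor-only baseline with four left-hemisphere predictors gives
χ² = 17.26, df = 4, p = 0.0017.

The same machinery is available as a library:

```python
import strokeconn as sc

cohort = sc.simulate_cohort(sc.SimulationConfig(seed=17))
report = sc.run_model_suite(cohort.table, sc.SuiteConfig(cv_seed=17))
print(report.to_dataframe().round(2))
```

Other subcommands: `strokeconn simulate` (cohort CSV + generating truth),
`strokeconn extract` (features from a 4-D NIfTI + label volume or a TSV of
ROI series), `strokeconn lesion-volume` (mm³ from a mask), `strokeconn fit`
(a single forward-selection fit).

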
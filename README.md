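# pmdisparity

Population-weighted ambient PM2.5 exposure and subgroup disparity analysis
over geocoded, sample-weighted survey clusters.

## What this package is for

Environmental-justice analyses of air pollution in survey-based settings
(e.g., Demographic and Health Surveys) ask whether demographic subgroups —
by gender, wealth quintile, or caste — breathe systematically different
ambient PM2.5, and whether that gap is widening. The raw ingredients are a
satellite-derived ~1-km annual-mean concentration grid, survey clusters with
geocodes, urban/rural designations, expansion weights and subgroup
compositions, a gridded settlement-classification layer, and per-state
socio-demographic index (SDI) values. Because the microdata and satellite
product are access-restricted, the package ships a synthetic-data generator
that emulates all of them with *known, injectable* disparity structure, so
every stage is testable end to end.

## The statistics at the core

**Exposure extraction.** Each cluster's exposure is the unweighted mean of
concentration cells whose centers fall within a circular buffer around the
cluster centroid: 2 km (urban) / 5 km (rural) by convention, with uniform
2-km and 5-km variants as sensitivity settings.

**Population-weighted concentration (PWC).** For region *i* with *m*
clusters, subgroup *k*:

    PWC_ik = Σ_j C_ij · P_ijk / Σ_j P_ijk

where `C_ij` is the cluster exposure and `P_ijk = weight_j × fraction_jk`
the subgroup's effective population. Higher-level PWCs pool clusters
directly; they are not averages of district PWCs.

**Absolute disparity** is the 99th-minus-1st percentile of the exposure
distribution (linear-interpolation quantiles; weighted when weights are
supplied).

**Relative disparity** is a standardized mean difference on natural-log
district-level PWCs:

    z = (M1 − M2) / S_pooled,
    S_pooled = √(((n1−1)S1² + (n2−1)S2²) / (n1+n2−2))

A positive z means group 1 (by convention the reference subgroup: male,
richest, or general) is more exposed, by z pooled standard deviations.
Confidence intervals and p-values use the Hedges–Olkin large-sample standard
error; |z| ≤ 0.01 is flagged negligible. Distributional differences are
tested with a weighted two-sample Kolmogorov–Smirnov statistic using
effective sample sizes (Σw)²/Σw², at a relaxed significance threshold
p < 0.1. Temporal change is reported as the percent change in |z| between
survey rounds, and a state-to-national z ratio > 1 flags disparities that
grow at finer spatial scale.

## Worked example

Generate a synthetic two-survey world in which the richest quintile is
tilted toward high-concentration urban clusters, then recover that
disparity:

```python
import pmdisparity as pm

sim = pm.SimulationConfig(seed=7, tilt=3.0, tilt_partition="wealth",
                          tilt_subgroup="richest", tilt_stratum="urban")
bundle = pm.run_pipeline(pm.RunConfig(sim=sim), two_rounds=False)
r1 = bundle.rounds["round1"]

print(r1.pwc.query(
    "region_level == 'national' and partition == 'wealth' and stratum == 'urban'"
)[["subgroup", "pwc", "cv", "n_clusters"]])
print(r1.zscores.query(
    "level == 'national' and stratum == 'urban' and partition == 'wealth'"
)[["subgroup", "reference", "z", "ci_lo", "ci_hi", "p_value"]].round(4))
```

Output:

```
subgroup       pwc       cv  n_clusters
 richest 62.438832 0.166364         398
  richer 50.986601 0.177606         398
  middle 50.844830 0.173043         398
  poorer 50.753697 0.179704         398
 poorest 50.973223 0.173425         398

subgroup reference      z  ci_lo  ci_hi  p_value
  richer   richest 0.7469 0.3412 1.1526   0.0003
  middle   richest 0.7333 0.3281 1.1385   0.0004
  poorer   richest 0.6920 0.2882 1.0958   0.0008
 poorest   richest 0.7319 0.3268 1.1371   0.0004
```

The injected tilt shows up exactly where it should: the richest subgroup's
national urban PWC (62.4 µg/m³) sits ~11.5 µg/m³ above every other wealth
quintile, and each richest-vs-other comparison yields a positive z of ~0.7
pooled standard deviations with p ≪ 0.1. Under `tilt=0` the same pipeline
flags essentially all comparisons negligible or non-significant.

A CLI mirrors the library (`pmdisparity synth / extract / pwc / bands /
absolute / strata / report / sweep`); rasters are read and written as
plain-text ESRI ASCII grids, tables as CSV.

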
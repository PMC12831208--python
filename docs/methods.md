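# Methods

This note documents the models, conventions and deliberate design choices
behind `pmdisparity`, in the order data flows through the pipeline.

## Synthetic study world

The generator stands in for restricted inputs: georeferenced survey
microdata and a proprietary satellite concentration product. It emulates
their *structure* — not any particular country's geography — with defaults
chosen once to match published national-scale conditions:

- **Concentration field.** White noise convolved with a Gaussian kernel
  (correlation length 15 km at 1-km cells), affinely rescaled to mean
  51.5 µg/m³ and sd 16.7 µg/m³, then clipped to 28.6–86 µg/m³. These are
  the published urban annual-mean calibration values for the 2019–2021
  survey window; clipping shifts the realized mean up by ≈0.5 µg/m³ and
  shrinks the realized sd, which the calibration tests allow for. The
  15-km correlation length is deliberately at the sub-regional end of
  plausible PM2.5 scales so that districts contain internal exposure
  contrast; a much longer length would make within-district disparity
  injection invisible by construction.
- **Administrative nesting.** States tile the grid into near-square blocks,
  districts tile each state block, clusters fall uniformly in their
  district block. Defaults: 10 states × 5 districts × 20 clusters = 1,000
  clusters over a 200 × 200 km grid.
- **Settlement raster.** An independent smoothed field sliced at quantiles
  into seven classes with marginals (4, 5, 6, 15, 30, 30, 10)% — about 30%
  urban after collapsing classes 1–4, an India-like urban share.
- **Cluster attributes.** Stratum follows the settlement class at the
  cluster location, then flips with probability 0.28 — emulating the
  observed ~0.71–0.72 concordance between settlement-layer and survey
  urban/rural classifications, which are genuinely independent
  methodologies. Expansion weights are LogNormal(ln 5×10⁵, 0.5), anchored
  to the documented scale at which one cluster represents ~500,000 people.
  Compositions are Dirichlet within each partition (gender 50/50, wealth
  5 × 20%, caste 30/40/30) with concentration parameter 50; the survey
  literature does not pin down within-cluster composition variance, so this
  is surfaced in `SimulationConfig` rather than hard-coded.
- **Disparity injection.** The target subgroup's fraction is re-weighted in
  odds space by `exp(tilt · (r − 0.5))`, where r is the percentile rank of
  the local concentration among affected clusters (optionally ranked within
  districts, or restricted to one stratum). This is bounded, monotone in
  tilt, exactly partition-preserving, and symmetric under sign flip —
  properties the recovery tests rely on. `tilt=0` is the byte-identical
  identity.
- **Household sampling is not modelled.** Clusters carry aggregate
  composition and weight — the granularity the weighted-mean consumes.
  Wealth quintiles are assigned directly rather than derived from an asset
  PCA, because the analysis uses quintile labels only.

What passing tests on this world do *not* show: robustness to survey
non-response, geocode displacement, non-Gaussian concentration extremes, or
spatially structured composition gradients beyond the injected tilt.

## Exposure extraction

Cell membership is **cell-center-within-radius** (not area-weighted
intersection): standard zonal practice at 1-km cells with radii ≥ 2 km, and
exactly reproducible by a brute-force distance loop, which the tests
exploit. Distances are Euclidean in planar-km mode and haversine in lon/lat
mode; the upstream GIS convention is unspecified, so both are provided and
all tests run planar. Missing cells inside a buffer are skipped; a buffer
with no valid cell either errors (default) or falls back to the nearest
valid cell with `n_cells=1`. Each survey round maps to its own annual-mean
raster; residence is assumed fixed within a round.

## PWC conventions

- `P_ijk = sample_weight × subgroup fraction` — the only construction
  consistent with the documented weight semantics; the statistic is
  invariant to uniform weight rescaling and linear in the concentrations.
- Supra-district PWCs pool clusters via the same formula (the definition
  holds for any region), never by averaging district PWCs.
- The CV attached to national/state/SDI rows is sd/mean of the district
  subgroup PWCs beneath them (population-weighted cluster-level CV for
  district rows); the source tables never define their CV, so this choice
  is documented here rather than silently embedded.
- Zero subgroup population in a region yields a missing value, never zero.

## Disparity statistics

- **Absolute disparity** uses type-7 (linear-interpolation) quantiles.
  With weights, sorted values receive plotting positions
  `p_k = (C_k − w_k)/(S − w_last)`, chosen because they collapse exactly to
  the type-7 positions `(k−1)/(n−1)` under equal weights, keeping the
  weighted and unweighted paths mutually consistent. The 99/1 trimming
  itself is the outlier exclusion; no additional filter is applied.
- **z score.** Natural logs (the statistic is provably log-base invariant);
  groups treated as independent in the pooled SD even though the same
  districts underlie both subgroups — a fidelity-to-source choice, noted
  as conservative since positive pairing would shrink the true SE. CI/p
  from the Hedges–Olkin SE `√((n1+n2)/(n1 n2) + z²/(2(n1+n2−2)))` with
  normal theory. Degenerate input (both groups constant) defines z = 0
  with a flag rather than NaN.
- **Weighted KS.** D is the sup-distance between weighted ECDFs (ties
  handled on the merged support); p substitutes effective sample sizes
  `(Σw)²/Σw²` into the asymptotic two-sample null distribution
  `kstwo.sf(D, round(n1·n2/(n1+n2)))`, which reproduces the reference
  implementation exactly at unit weights and is calibrated to ~0.10
  type-I error at n=50/group under moderate weight dispersion. The KS
  operand for district counting is the subgroup-weighted distribution of
  cluster exposures — the level/transform is ambiguous in the source and
  this choice is configurable in spirit (the function accepts any weighted
  samples).
- **Bands.** Thresholds are weighted 34th/66th percentiles of cluster
  exposure (weights = total sample weight); bands are (<P34), [P34, P66],
  (>P66). Shares are normalized within partition × band and sum to 100 by
  construction; empty bands are omitted and logged.
- **Burdened districts.** A district counts for a subgroup when its PWC
  exceeds the reference subgroup's *and* the weighted KS p < 0.1 (the
  relaxed threshold adopted throughout). Districts with <2 clusters or a
  zero-population subgroup are excluded from the evaluable denominator.
- **Change and scale ratio.** Percent change in |z| between rounds is
  undefined (flagged, not fabricated) when the baseline |z| ≤ 0.01; sign
  flips are reported separately since they carry direction information the
  magnitude change hides. The state/national ratio requires a non-negligible
  national z.

## Numerical and problem-size choices

Default problem sizes (1,000 clusters, 50 districts, 200×200 grid; 1,000
replicates for recovery experiments, 2,000 for KS calibration) were chosen
so each property is measured with comfortable Monte-Carlo margin — e.g. the
mean recovered z at 1,000 replicates has standard error ≈0.003 against a
±0.02 acceptance band — while a full test-plus-acceptance run stays well
under a minute of compute. Determinism is end-to-end: every random stage
derives its generator from `(seed, stream)` seed sequences, and the report
bundle exposes a content hash over all tables.

## Known limitations

- The SDI category gap (0.53, 0.54) left by the printed thresholds is
  closed into the middle category; values there are rare but the rule is
  explicit.
- No design-based variance estimation for the complex survey design; the
  source method does not use it either.
- Alternative inequality indices (Atkinson, Gini, Theil, concentration
  index) are intentionally out of scope.
- Raster I/O is plain-text ASCII grid only; georeferenced binary formats
  are not written.
- No multiple-testing correction is applied across the many region ×
  subgroup comparisons, matching the source procedure; interpret the
  p < 0.1 maps as descriptive screening, not confirmatory inference.
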
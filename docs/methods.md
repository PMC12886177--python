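# Methods

## Mortality model

Each taxon *i* (or the bulk community) is assumed to grow exponentially
over the 24 h incubation with intrinsic rate `mu_i` (h⁻¹) and to die at
rates proportional to predator concentration. Predator encounter is
taken linear in the whole-water fraction `x = 1 − filtrate fraction`;
no saturation or functional response is modelled. The two filtrates
differ in what they remove: 0.2 µm filtrate removes protists but passes
phages, so in the protist series phage pressure stays at its
whole-water level regardless of `x`; 30 kDa filtrate removes both, so
in the combined series both pressures scale with `x`. Phage growth
during the incubation is ignored. The expected apparent growth rate is
therefore

```
protist series :  mu_i − g_i·x − v_i
combined series:  mu_i − (g_i + v_i)·x
```

with `g_i` grazing and `v_i` lysis mortality at 100 % whole water. The
protist-series slope in `x` is `−g_i`, the combined-series slope is
`−(g_i + v_i)`, and their difference is `−v_i`. These are the three
quantities the estimator reports per experiment.

Filtrate is assumed to contribute no bacteria, so a bottle's initial
abundance is `x` times the whole-water abundance; `x = 0` bottles are
below detection and never enter a regression.

## Estimation procedure

1. **Apparent growth rate** per bottle: `ln(P_t/P_0)/t`. Non-positive
   abundances yield no rate (below detection), never a pseudocount.
2. **Replicate outlier filter**: within each (series, fraction) cell a
   replicate is discarded when it deviates from the mean of the other
   two by more than twice their sample (n−1) standard deviation. When
   the other two are identical, an absolute floor of 1e-6 h⁻¹ replaces
   the zero threshold so float jitter survives. Each member is tested
   against the other two independently; when more than one member
   trips the rule (possible for symmetric spreads) only the single
   worst offender — the largest deviation-to-threshold ratio — is
   discarded, and exact ties discard nothing. This caps losses at one
   replicate per cell and makes the decision invariant to replicate
   order. With fewer than three rates no filtering occurs.

   A property of this rule worth knowing: for any triple that is not
   exactly equally spaced, at least one extreme always deviates from
   the other two by more than twice their sample SD (the smallest
   possible maximum deviation ratio, attained at equal spacing, is
   3/(2√2) ≈ 1.06). Under replicate noise the filter therefore
   typically trims the single most extreme replicate in each cell —
   leaving two — rather than acting only on rare wild values; exactly
   equally spaced triples produce a tie and are fully retained. The
   parameter-recovery simulations show the resulting estimates remain
   essentially unbiased, and genuinely wild replicates are always the
   ones removed.
3. **Slope fit**: ordinary least squares of rate on `x`, pooling
   individual bottles (all residual degrees of freedom contribute to
   the slope SE). Fitting on replicate means is available
   (`pool_replicates=False`), as is an endpoint-difference estimator
   (mean rate at the largest `x` minus mean rate at the smallest,
   normalised by the span) for sensitivity analysis; OLS is the
   default. Regressions with fewer than two points or a single distinct
   `x` raise typed errors.
4. **Phage decomposition**: `phage_mortality = slope_combined −
   slope_protist`, so phage predation is negative, matching the
   convention that a more negative change in growth rate means more
   predation. The opposite sign convention is available
   (`convention="protist-minus-combined"`). The error combines the two
   slope SEs in quadrature; the two fits use disjoint bottles and are
   treated as independent, so the combined error is at least as large
   as either component.

## ASV-level extension

Per-sample relative abundances are converted to absolute abundances by
multiplying by the sample's total bacterial count (from flow
cytometry). The starting composition of an experiment is the mean of
the triplicate whole-water start samples, scaled by the mean start
total; a bottle's initial per-ASV abundance is that composition times
the bottle's `x`. Rates needing a log of zero (ASV absent at start or
in a bottle) are skipped; a pseudocount mode (`pseudocount=1`) exists
for sensitivity analysis but is off by default because it biases rates
of rare taxa. The per-ASV pipeline then reuses the bulk machinery
(filter, OLS, decomposition) unchanged, so a one-taxon community gives
bit-identical slopes by either path.

Across experiments each ASV is summarised by six averages: the mean of
strictly negative per-experiment values and the mean of strictly
positive values for each condition (combined slope, protist slope,
phage mortality). Zeros count toward neither side; an empty average is
missing, not zero. *Activity* is the largest magnitude among the three
negative (predation-side) averages; per-condition activities are also
present in the output table. Classification against PRMDT uses two
thresholds, both configurable and with no claim of optimality: a
fast/slow split at 5 h doubling time and an activity cut at 0.01 h⁻¹.
Per-experiment ASV predation events can be ranked by their most
negative per-experiment value per condition.

## Flow-cytometry gating

Events arrive as delimited text (one row per event, one column per
channel); FCS binary parsing is out of scope. Channels listed in
`log10_channels` are log10-transformed (floored at 1, appropriate for
fluorescence intensities spanning decades) and all channels are
z-scored by default; the transform is stored in the grid and re-applied
at classification. The SOM is the classic online algorithm on a
toroidal grid (default 41×41): per presented event the best-matching
unit is found by Euclidean distance and all nodes within the current
neighbourhood radius (bubble neighbourhood, toroidal grid distance) are
pulled toward the event. Defaults: 100 passes over the training events
in seeded random order, learning rate decaying linearly 0.05 → 0.01,
radius decaying linearly from ⅔ of the larger grid dimension to 1.
Non-decaying schedules are rejected. The inner loop is numba-compiled;
results are bit-reproducible under a fixed seed. Codebook clustering is
k-means (Lloyd) in channel space with 25 seeded restarts keeping the
lowest inertia; grid geometry does not enter the clustering. Mapping
cluster indices to named populations (HNA, LNA, high Chl, …) is a
user-supplied label map, as it requires domain judgment.

Counts convert to concentrations as
`cells/mL = events / (flow rate × run time) × 1000 × dilution factor`.
Volume-based conversion is the default; an optional multiplicative bead
correction (expected/observed bead concentration) can be applied when
bead spikes are available. Derived statistics: total bacteria =
HNA + LNA; fraction of actively respiring cells = high-RSG / total.

## Ancillary statistics

The induction test responds to the per-tube VLP change (end − start),
so baseline differences between tubes cancel; an endpoint-response
option exists. Significance is a one-way ANOVA of treated vs control
(two groups, so F = t²); lysogeny is called when the treated mean
change exceeds the control's at p < 0.05. Degenerate inputs: identical
zero-variance groups give p = 1 by convention, differing means with
zero within-group variance give p = 0. The stratification proxy is
|T(10 m) − T(50 m)|. Shannon diversity is `−Σ p ln p` over non-zero
proportions in nats (configurable base), after internal
renormalisation.

## Synthetic data: what it does and does not emulate

The generator plants a community with four classes — select-winners
(fast PRMDT, full predation), spared-winners (fast, none), slow
high-turnover taxa (slow, full predation) and background — with
deterministic class counts (`round(frac·n)`) and seeded assignment.
Defaults: predation rates 0.05 h⁻¹ for active taxa, intrinsic growth
uniform on [0, 0.1] h⁻¹ (typical of cold, productive surface seawater),
PRMDT uniform on [1, 4.5] h for fast and [6, 12] h for slow taxa around
the 5 h split, initial abundances lognormal (σ = 1) around 2×10⁴
cells/mL so a 40-taxon community totals ~10⁶ cells/mL.

Observation noise is multiplicative lognormal on every measured
concentration (mean-1, CV configurable; counts span orders of
magnitude, so multiplicative noise is the natural choice) and
multinomial read sampling at fixed depth. Flow-count measurement noise
is rarely quantified for field samples, so the CV default (0.05) is a
deliberate, configurable choice rather than a measured value. With
CV = 0 and exact compositions (`read_depth=None`) every observation
equals its closed-form expectation, which is what makes exact
parameter-recovery tests possible. Cytometry fixtures are Gaussian
clouds with Poisson event counts and retained true labels.

Not emulated: seasonal or hydrodynamic forcing, phytoplankton bloom
dynamics, predator growth during incubation, saturating grazing
responses, chimeras/contamination in sequencing, spectral spillover or
doublets in cytometry. Passing recovery tests therefore demonstrates
estimator correctness under the stated generative model, not robustness
to every artefact of real field data.

## Numerical choices and problem sizes

* OLS is closed-form (centred normal equations); slope SE is
  `sqrt(RSS/(n−2)/Sxx)`, reported as 0 for an exactly determined
  two-point fit.
* The outlier floor (1e-6 h⁻¹) is far below any biologically
  meaningful rate difference and far above double-precision jitter on
  rates of magnitude ≲ 1.
* Recovery test sizes were chosen to make the checks sharp at desk
  scale: 200 noiseless communities (exactness), 100 noisy simulations
  (bias, judged by the median relative error across simulations), 20
  seeded seasons of 12 experiments × 40 taxa at read depth 10⁵ for
  classification recovery, 10⁴-event clouds for the 41×41 SOM, and
  1000 replicates for ANOVA calibration.
* k-means ties are resolved by lowest inertia across 25 seeded
  restarts; SOM determinism comes from a fixed presentation order per
  seed.

## Known limitations

* The linear-encounter assumption means saturated grazing would bias
  slopes toward zero; no nonlinear dilution model is provided.
* Bulk slopes on a mixed community are a log-sum-exp of per-taxon
  dynamics and only exactly linear in `x` for a single taxon; the bulk
  estimate is the community-average mortality, not a per-taxon rate.
* Compositional zeros at low read depth censor rare-taxon rates toward
  the active side; the depth-10⁵ default keeps this negligible for
  abundances ≥ 0.1 %.
* The SOM k (populations per sample type) and the cluster-to-population
  naming are inputs, not inferred.
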
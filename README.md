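# ksw

Top-down mortality of marine bacteria from two-filtrate dilution
experiments, down to the level of individual amplicon sequence variants
(ASVs).

Bacterivorous protists and bacteriophages both remove bacterial biomass
from surface seawater, and the "kill the winner" hypothesis predicts
they preferentially remove the fastest-growing taxa. This package
implements the inference machinery for testing that prediction with
serial dilution experiments: whole seawater is mixed with increasing
proportions of predator-free filtrate — 0.2 µm filtrate removes protists
but passes phages (the *protist* series), 30 kDa filtrate removes both
(the *combined* series) — and incubated for 24 h in triplicate at
filtrate fractions {0, 30, 70, 95, 100}%.

The apparent growth rate in each bottle is

```
mu = ln(P_t / P_0) / t
```

with `P_0`, `P_t` the initial and final abundance and `t` the
incubation time. Because predator encounter scales with the whole-water
fraction `x`, regressing `mu` on `x` gives per-series slopes with a
clean decomposition:

```
slope_protist  = -g          (protistan grazing mortality)
slope_combined = -(g + v)
phage mortality = slope_combined - slope_protist = -v
```

so a more negative slope means more predation, and the series
difference isolates phage lysis. The same estimator runs per ASV by
converting relative amplicon abundances to absolute abundances
(relative abundance × total bacterial count from flow cytometry). Each
ASV is summarised over a season of experiments by six averages (mean of
negative and mean of positive per-experiment values for each of the
three conditions) and classified against its predicted relative minimal
doubling time (PRMDT, a codon-usage growth proxy): predicted fast
growers under heavy predation are *winners killed*, fast growers left
alone are *winners spared* — the "kill select winners" distinction.

The package also includes:

* a flow-cytometry gater (`ksw.cytometry`): toroidal 41×41
  self-organising map trained on event tables, k-means on the codebook,
  event classification by best-matching unit, and events→cells/mL
  conversion;
* ancillary statistics (`ksw.ancillary`): prophage-induction ANOVA on
  VLP changes, the |T(10 m) − T(50 m)| stratification proxy, Shannon
  diversity;
* a synthetic-data module (`ksw.synthetic`) that simulates the whole
  experimental design — planted per-taxon rates, lognormal count noise,
  multinomial read sampling, Gaussian event clouds — so every estimator
  is testable by parameter recovery.

## Worked example

Simulate a 20-taxon community observed over six dilution experiments
(count CV 5%, 50 000 reads per sample) and run the full pipeline:

```python
from ksw.io import RunConfig, run_pipeline, read_table

cfg = RunConfig(outdir="demo", seed=11, n_asv=20, n_experiments=6,
                count_cv=0.05, read_depth=50_000)
manifest = run_pipeline(cfg)

res = read_table("demo/experiment_results.tsv")
print(res[["experiment_id", "slope_protist", "slope_combined",
           "phage_mortality", "phage_error"]].round(4).head(3))
```

```
experiment_id  slope_protist  slope_combined  phage_mortality  phage_error
      exp-001        -0.0039         -0.0163          -0.0124       0.0008
      exp-002        -0.0038         -0.0146          -0.0108       0.0015
      exp-003        -0.0041         -0.0142          -0.0101       0.0018
```

Both series' slopes are negative — predation exceeds growth in the bulk
community — and the gap between them (≈ −0.011 h⁻¹) is the mortality
attributed to phage lysis. The per-ASV summary separates the planted
structure:

```
 asv_id  neg_avg_protist  neg_avg_phage  activity  prmdt_h     ksw_class
asv0000          -0.0015        -0.0029    0.0029  10.1462    background
asv0001          -0.0509        -0.0477    0.0986   1.2909 winner-killed
```

`asv0001` is a predicted fast grower (PRMDT 1.3 h) with predation-side
activity ~0.1 h⁻¹, hence a winner being killed; `asv0000` is slow and
quiet. On this run the classification recovers the planted labels
exactly (`manifest["ksw_recovery_accuracy"] == 1.0`).

The same stages are exposed on the command line (`ksw simulate`,
`ksw dilution`, `ksw asv`, `ksw train-som`, `ksw classify`,
`ksw report`, `ksw run`).

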
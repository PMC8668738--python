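# irakit

Integrated Resilience Assessment (IRA) of annual ecological time series:
regime-shift detection, threshold generalized additive modelling, and
quantified resilience on a folded stability landscape.

## Who this is for

Ecologists and fisheries scientists asking whether a multivariate
"system" (e.g. landings-per-unit-capacity, LPUC in kg/GT, of a demersal
assemblage) has responded *discontinuously* to a multivariate "stressor"
complex (temperature, salinity, productivity, pH, ...), and if so, how
resilient each state was and where the tipping points lie. The package
follows the IRA recipe end to end on two annual tables (years ×
variables), and ships a seeded synthetic-scenario generator so every
stage can be validated against known ground truth without external data.

## What it computes

1. **Preprocessing** — LPUC construction (Σ landings / Σ fleet GT),
   anomaly standardization ((x − x̄)/s), distance-correlation screening
   of redundant stressors (Székely's dCor), traffic-light quintile
   matrices.
2. **Ordination** — correlation-matrix PCA of each block; PC1sys and
   PC1str serve as holistic state indicators.
3. **Shift detection**, three independent detectors, all reporting
   *threshold years* (the last year of the old regime):
   - CONISS chronological clustering: only temporally adjacent clusters
     may merge; merge cost is the within-cluster sum-of-squares
     increment nᵢnⱼ/(nᵢ+nⱼ)·‖x̄ᵢ−x̄ⱼ‖².
   - Breakpoint structural analysis: dynamic-programming segmentation
     into constant-mean regimes, the number of breaks chosen by
     BIC(m) = n·log(RSS_m/n) + (2m+1)·log n, with a permutation sup-F
     test and RSS-profile 95% confidence intervals.
   - STARS (sequential t-test analysis of regime shifts) with the
     Regime Shift Index: a candidate year beyond the critical
     difference diff = t_crit·√(2σ²_L/L) is confirmed or rejected by the
     cumulative sum of normalized exceedances (cut-off length L = 15,
     p = 0.05).
4. **Threshold GAMs** — penalized cubic spline smooths (GCV-selected
   smoothing); a TGAM splits the years at a threshold year θ into two
   independent branches, searching 50 candidate years between the 0.2
   and 0.8 quantiles of the year range. GAM vs TGAM is decided by the
   *genuine* cross-validatory squared prediction error (gCV):
   leave-one-out with the full procedure — threshold search included —
   re-estimated on every fold. A second, sequential TGAM is fitted to
   the years after the first threshold.
5. **Resilience** — TGAM branches become attractors; tipping points
   F1..F4 are placed so every year's resilience Res_y = hComp_y −
   vComp_y is non-negative within its regime (hComp: stressor-axis
   distance to the regime's tipping point; vComp: distance to the
   attractor). rRes_y = Res_y/max(Res) is interpolated (piecewise-linear
   Delaunay) onto a 100 × 100 stability landscape, with two theoretical
   repulsion "years" inserted between the fold pairs.

## Worked example

Run the whole pipeline on the bundled synthetic scenario — 52 years
(1966–2017), 12 system + 12 stressor variables, true threshold years
1991 and 2002, latent noise 0.3:

```python
from irakit import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(preset="aegean", seed=3,
                                     coniss_k=3, out_dir="out"))
print(result["shifts"].to_string(index=False))
```

```
    method  threshold_year  statistic  p_value
    coniss            1991        NaN      NaN
    coniss            2002        NaN      NaN
breakpoint            1991 490.123561    0.005
breakpoint            2002 490.123561    0.005
     stars            1991   2.650936    0.050
     stars            2002   0.770110    0.050
```

All three detectors recover both planted thresholds exactly. For
breakpoints the statistic column holds the sup-F statistic (490.1) with
its permutation p-value (0.005, i.e. no shuffled series reached it in
199 permutations); for STARS it holds each shift's Regime Shift Index
(2.65 and 0.77 — the first shift is much the stronger, as its larger
level change implies).

```python
print(result["comparison"].table.round(3).to_string(index=False))
```

```
 lag  gam_gcv  gam_dev  tgam_gcv  tgam_dev  threshold_year
   0    4.056    0.685     2.056     0.909            1991
   1    3.073    0.780     2.010     0.912            1991
   2    2.409    0.823     1.567     0.922            1991
```

At every stressor lag the TGAM's prediction error is well below the
GAM's and its deviance explained higher — the system–stressor relation
is discontinuous — and the threshold year is 1991 throughout. The
sequential stage then finds the second threshold:

```python
seq = result["sequential"]
seq.threshold_years        # [1991, 2002]
seq.gcv_gam, seq.gcv_tgam  # [4.056, 2.170], [2.056, 0.819]
```

Resilience per year and the landscape:

```python
print(result["resilience"].table.head(3).round(3).to_string(index=False))
print([(t.label, round(t.x, 2)) for t in result["tipping_points"]])
```

```
 year  regime      x     y  hcomp  vcomp   res  rres
 1966       1 -3.162 3.451  5.607  0.231 5.376 0.608
 1967       1 -6.728 3.535  9.173  0.331 8.842 1.000
 1968       1 -4.036 3.075  6.480  0.141 6.340 0.717
[('F1', 2.44), ('F2', 0.01), ('F3', 5.4), ('F4', 0.21)]
```

1967 is the most resilient year observed (rRes = 1): it lies far from
its regime's tipping point (hComp 9.17 stressor-score units) and close
to its attractor (vComp 0.33). The run directory now holds ten artifact
files (anomalies, PCA scores/loadings, traffic-light matrix, shift
table, model comparison, TGAM stages, resilience series, landscape
grid) plus a manifest that reproduces the run bit-exactly.

The same pipeline runs from the shell on your own tables
(`year`-indexed CSVs):

```sh
irakit run --system system.csv --stressors stressors.csv --out-dir out
irakit simulate --preset aegean --seed 1 --out-dir demo   # synthetic data
irakit detect demo/system.csv --method stars --out shifts.csv
```

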
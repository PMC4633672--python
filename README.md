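# rcbvpipe

Radiogenomic analysis of brain-tumor perfusion: quantify relative cerebral
blood volume (rCBV) from dynamic susceptibility contrast (DSC) MRI and
predict IDH-1/2 mutation status from the tumor's rCBV histogram.

IDH-1/2 mutant gliomas suppress the HIF1A/VEGF angiogenesis axis, so mutant
tumors perfuse less than their wild-type counterparts. That biology makes
perfusion imaging a candidate non-invasive genotype marker: segment the
FLAIR-hyperintense tumor, read out its voxelwise rCBV distribution, and ask
how well any given histogram percentile separates the genotypes. `rcbvpipe`
implements that analysis end to end, together with a synthetic-cohort
simulator with known ground truth, so every stage is testable without
patient data.

## What the pipeline computes

1. **Simulation** (`rcbvpipe.simulate`) — two-genotype cohorts of 4-D DSC
   series plus FLAIR volumes. Bolus: gamma-variate arterial input Ca(t);
   tissue: C(t) = CBF·(Ca ⊗ R)(t) with exponential residue
   R(t) = exp(−t/MTT); signal: S(t) = S0·exp(−TE·ΔR2*(t)); optional linear
   contrast leakage in a configurable fraction of tumor voxels. Subject-level
   tumor rCBV medians follow class log-normals (mutant median 1.09,
   IQR 0.80–1.47; wild-type 2.08, IQR 1.49–2.57); voxel values follow a Gamma
   scaled to the subject median, with wild-type tumors more heterogeneous.
2. **Perfusion quantification** (`rcbvpipe.perfusion`) —
   ΔR2*(t) = −ln(S/S0)/TE; automatic AIF detection by iterated k-means
   cluster analysis (earliest-first-moment cluster); rCBV per voxel as
   AUC(C)/AUC(AIF) over the first pass; leakage correction by the
   two-regressor linear model (fit K1, K2 against the non-tumor reference
   curve, add back K2·∫ref); CBF by delay-insensitive block-circulant SVD
   deconvolution with singular-value truncation.
3. **Segmentation** (`rcbvpipe.segmentation`) — slice-by-slice region
   growing from an operator seed with a fixed intensity band around the
   seed-neighborhood mean, plus voxelwise rCBV extraction from the ROI.
4. **Statistics** (`rcbvpipe.stats`) — 50-bin relative-frequency profile on
   rCBV ∈ [0, 7.5) (width 0.15); percentiles {5, 10, 15, 25, 50, 75, 90, 95,
   99}; Mann-Whitney U per percentile (tie-corrected normal z); per
   percentile, a leave-one-out cross-validated logistic model of mutation
   status (odds ratio per one rCBV unit with Wald CI, LOOCV accuracy /
   PPV / NPV at probability cutoff 0.5) and the marker's ROC area
   (= U/(n₁n₂)) with a DeLong CI; subjects-by-bins heat-map.
5. **Orchestration** (`rcbvpipe.pipeline`, CLI `rcbvpipe`) — simulate →
   segment → quantify → analyze with a single YAML config, one global seed,
   and a checksum manifest.

## Worked example

The numbered drivers under `analysis/` run the study-scale experiment (73
subjects: 59 mutant, 14 wild-type) and write their tables to `results/`:

```bash
python analysis/01_simulate.py   # DSC + FLAIR + truth maps (scratch/)
python analysis/02_segment.py    # region-grown tumor masks
python analysis/03_quantify.py   # leakage-corrected rCBV maps
python analysis/04_analyze.py    # histogram / Mann-Whitney / LOOCV tables
```

The final driver prints, for this seed:

```
 percentile  odds_ratio  p_value   auc  pct_correct    ppv    npv  odds_decrease_pct
         50       0.201    0.002 0.792       80.822 83.582 50.000             79.899
         75       0.245    0.001 0.851       82.192 84.848 57.143             75.518
         90       0.290    0.000 0.889       83.562 87.302 60.000             71.018
         95       0.324    0.000 0.907       86.301 88.889 70.000             67.601
         99       0.360    0.000 0.931       84.932 87.500 66.667             63.958
```

Read the 90th-percentile row as: tumors one rCBV unit higher at their 90th
percentile have 71% lower odds of carrying an IDH-1/2 mutation; the marker
separates genotypes with ROC area 0.889, and the cross-validated classifier
labels 83.6% of subjects correctly. The upper percentiles discriminate best
because wild-type tumors carry high-rCBV hotspots that the median misses.
`02_segment.py` and `03_quantify.py` report the internal accuracy checks on
the same cohort (Dice 1.0 against the simulated masks; median voxelwise rCBV
error ≈ 5.6% at the simulated SNR).

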
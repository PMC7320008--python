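# fuscon

Resting-state functional connectivity (FC) analysis for functional
ultrasound (fUS) brain imaging, built around a two-group rodent study
design: healthy controls versus a chronic inflammatory-pain (arthritis)
model.

fUS measures cerebral blood volume through ultrafast power-Doppler
imaging; slow (0.05–0.2 Hz) coherent fluctuations of the Doppler signal
between brain regions carry the resting-state connectivity signal.
`fuscon` implements the complete analysis chain on ROI-averaged Doppler
time series:

1. **Signal conditioning** — ROI averaging over mask images, zero-phase
   Butterworth band-pass in the resting-state band, energy
   normalization.
2. **Static connectivity** — seed-based pixel correlation maps, ROI–ROI
   Pearson correlation matrices, and a group "significance matrix":
   per-pair Fisher z = atanh(r), a Shapiro–Wilk-gated choice between
   Welch's t-test and the (exact, small-sample) Mann–Whitney U test, and
   Benjamini–Hochberg FDR control over each imaging plane's pair set.
3. **Dynamic brain states** — instantaneous phases φᵢ(t) from the
   analytic signal z(t) = f(t) + iH[f(t)], edge-trimmed by 100 frames per
   side; frame-wise phase-locking matrices
   M_PL(i,j,t) = cos(φᵢ(t) − φⱼ(t)); frames of all animals pooled and
   clustered by k-means under the cityblock (L1) distance (centroid =
   component-wise median) with 200 random restarts, keeping the
   lowest-objective replicate.  Cluster centroids are the "brain
   states"; per-animal occurrence rates get the same group statistics as
   static FC.
4. **Behavior links** — three-block Spearman correlation matrices
   relating per-animal FC features, state occurrences and behavioral
   covariates (weight gain, inflammation score, von Frey thresholds,
   foot-bend scores).
5. **Diagnostics** — composite biomarkers over selected ROI pairs (sum
   of correlations, or a logistic model fit on the test cohort), ROC/AUC
   with DeLong confidence intervals, Youden threshold selection, and
   frozen-threshold evaluation on an independent validation cohort.

So that every stage is testable without any data download, the package
ships a first-class synthetic-cohort generator (`fuscon.simulate`): a Markov
state-switching oscillator whose per-state phase offsets, group-specific
state occupancies, sub-network amplitude attenuation and
severity-driven behavior plant a known ground truth for every stage.

## Worked example

```python
from fuscon import CohortConfig, simulate_cohort
from fuscon.pipeline import static_fc_study, dynamic_states_study

cohort = simulate_cohort(CohortConfig(), seed=7)   # 9 control + 9 arthritic
features, significance = static_fc_study(cohort)
flagged = significance[significance.significant]
print(f"{len(flagged)} of {len(significance)} ROI pairs differ between groups")
print(flagged[["roi_a", "roi_b", "test_used", "p_raw"]].head(5).to_string(index=False))

models = dynamic_states_study(cohort, k_list=(5,), n_replicates=50, seed=7)
occ = models[5].occurrence
groups = cohort.groups.loc[occ.index]
print(f"control:   {occ.loc[groups == 'control', 'state_0'].mean():.3f}")
print(f"arthritic: {occ.loc[groups == 'arthritic', 'state_0'].mean():.3f}")
```

prints

```
18 of 45 ROI pairs differ between groups
 roi_a  roi_b    test_used    p_raw
S1HL_L S1HL_R        welch 0.008992
S1HL_L   M1_L        welch 0.000170
S1HL_L   M1_R        welch 0.008801
S1HL_R   M1_L        welch 0.008480
S1HL_R   M1_R mann_whitney 0.000041
control:   0.534
arthritic: 0.285
```

The flagged pairs concentrate on the hind-limb somatosensory ROIs whose
carrier amplitude the generator attenuates in arthritic animals, and the
globally synchronous brain state (`state_0`) occurs less often in the
arthritic group — both planted effects, recovered by the analysis.

The same stages are available from the shell:

```bash
fuscon simulate-cohort --out cohort/ --seed 7
fuscon static-fc --cohort cohort/ --fdr 0.05 --out static/
fuscon dfc-states --cohort cohort/ --k 5 6 7 --replicates 200 --seed 7 --out dfc/
fuscon behavior-links --cohort cohort/ --out links/
fuscon diagnose --cohort cohort/ --pairs pairs.txt --mode sum --out diag/
```

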
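# msdyn — EEG microstate dynamics

`msdyn` implements the resting-state EEG microstate analysis used to ask
whether preoperative brain dynamics differ between patients who do and do
not develop chronic pain after breast-cancer surgery: polarity-invariant
two-level modified k-means segmentation, backfitting, temporal metrics,
and the accompanying group statistics. Because clinical recordings of
this kind are not distributable, the package also ships a fully seeded
synthetic cohort generator with planted ground truth, so every stage of
the pipeline is testable end to end.

It is written for clinical neurophysiology researchers who want a
transparent, reproducible, scriptable implementation of the standard
microstate protocol — and for methodologists who want a ground-truthed
sandbox in which segmentation and statistics can be validated.

## The model

Resting EEG passes through brief (~80–120 ms) periods of quasi-stable
scalp topography (microstates), classically four classes A–D. The
analysis chain:

1. **GFP peaks.** GFP(t) = √(1/C · Σ_c (v_c(t) − v̄(t))²); topographies
   are sampled at GFP peaks, excluding peaks above mean + 2·SD of peak
   GFP.
2. **Modified k-means** (k = 4, 100 restarts) clusters the peak maps,
   treating a map and its sign-flipped copy as identical: assignment by
   maximal |Pearson correlation| across channels, centers updated as
   sign-aligned means. Fit is scored by the global explained variance
   GEV = Σₜ (GFPₜ·corr(vₜ, a_{L(t)}))² / Σₜ GFPₜ² and the
   cross-validation criterion σ̂²·((C−1)/(C−K−1))².
3. **Two levels.** Per-subject template sets are pooled and re-clustered;
   group templates are labeled A–D by optimal assignment against
   canonical maps.
4. **Backfitting & metrics.** Each sample gets the label of the best
   matching template; per subject the pipeline reports mean duration
   (ms), occurrence (runs/s), coverage (%) per class, and the 12
   transition percentages (joint, summing to 100).
5. **Statistics.** Shapiro–Wilk-routed t / Mann–Whitney tests with
   BH-FDR per family, Cohen's d (HP − LP, pooled SD), mixed ANOVA
   (group × class), a covariate-adjusted GLM (age, surgery type, BDI-II,
   ALND), and Pearson/Spearman correlations with the NRS pain score.

The synthetic cohort plants a group effect by biasing high-pain subjects'
transition matrices toward class C so the standardized MS-C occurrence
difference equals d = 0.88, and rank-links NRS to true C coverage
(cohort Spearman ≈ 0.6). See `docs/methods.md` for the full model and
design rationale.

## Worked example

```python
from msdyn import SimConfig, load_config, run_pipeline

cfg = load_config(None)                       # all defaults
cfg.simulation = SimConfig(n_high=10, n_low=10, duration_s=60.0, seed=4)
res = run_pipeline(cfg, write_outputs=False)

print("mean individual GEV:", round(res.mean_individual_gev, 3))
print("group template labels:", res.group_templates.labels)
occ = res.stats.query("comparison == 'occ_C'").iloc[0]
print("MS-C occurrence: test=%s d=%.2f p_fdr=%.3f"
      % (occ["test"], occ["d"], occ["p_fdr"]))
rho, p = res.correlations["cov_C~nrs"]["spearman"]
print("Spearman(cov_C, NRS): rho=%.2f p=%.4f" % (rho, p))
```

prints

```
mean individual GEV: 0.982
group template labels: ('A', 'B', 'C', 'D')
MS-C occurrence: test=t d=0.88 p_fdr=0.129
Spearman(cov_C, NRS): rho=0.80 p=0.0000
```

Read: the four individual-level templates explain 98% of GFP-weighted
topographic variance at SNR 5 (real EEG sits nearer 0.8); the realized
MS-C occurrence effect in this 20-subject draw matches the planted
d = 0.88 but is not significant after FDR at n = 10+10 (the planted
design is powered for n = 21/45); C coverage and pain rating are rank
correlated as planted. `res.metrics` holds the per-subject table
(`dur_A..dur_D`, `occ_*`, `cov_*`, `tr_AB..tr_DC`).

The same pipeline is scriptable from the shell:

```bash
msdyn run-all --seed 4 --out results_dir          # simulate + analyze
msdyn simulate --n-high 3 --n-low 3 --out sim_dir # recordings as CSV
```

Every run writes a `manifest.json` echoing the config, seed, package
versions, and per-file checksums; identical seed and config reproduce
every output byte-identically.

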
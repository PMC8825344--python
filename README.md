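# bloomclock

Time-course floral-transcriptome analysis and RNA-marker bloom
forecasting for flowering cherry (*Cerasus* × *yedoensis* 'Somei-Yoshino').

Cherry blossom dates are traditionally forecast from cumulative
temperature. An alternative is to read the tree's own molecular clock:
as floral buds progress from ecodormancy release to anthesis, waves of
genes switch on at characteristic times before bloom. If two marker
transcripts peak at different, known days before flowering, a single
qPCR measurement of both (relative to a constitutively increasing
control gene) pins down where on the bloom timeline a bud sits.

`bloomclock` implements that analysis end to end for people working with
bulk RNA-seq time courses of perennial buds:

1. **Preprocessing** — FPKM normalization of fragment counts
   (`FPKM = count · 10⁹ / (length · library size)`), an across-sample
   variance ≥ 1 gene filter, correlation-based outlier-sample detection,
   and the sliding-window smoother (window 8 samples, step 4) used for
   every profile and peak call.
2. **Module detection** — a deterministic weighted-correlation-network
   workflow: unsigned adjacency |r|^β on log1p FPKM, topological overlap
   dissimilarity, average-linkage clustering with a fixed height cut,
   small-cluster merging, and eigengene-based module merging. Each
   module's eigengene (first principal component of its z-scored
   submatrix) is assigned a flowering stage — 4–5 WBF through 1–2 WAF —
   or classed constitutive / replicate-variable.
3. **GO enrichment** — one-sided Fisher's exact test per module against
   the filtered gene universe, Benjamini–Hochberg corrected, rendered as
   a stage × ontology table.
4. **Marker selection** — genes of stage-specific modules ranked by
   replicate stability, stage specificity and peak expression; a control
   gene chosen for monotone expression increase along the time course.
5. **Forecasting** — ΔCt = Ct_target − Ct_control; quadratic (CBFb) and
   cubic (CBFg) stage curves over days-to-flowering with estimated
   extremum days; and the interaction regression

   ```
   days_to_flowering ~ β_g·ΔCt_CBFg + β_b·ΔCt_CBFb + β_gb·ΔCt_CBFg·ΔCt_CBFb + β_0
   ```

   fitted by ordinary least squares, valid from 21 days before flowering
   to the flowering day.
6. **Synthetic data** — a seeded generator producing expression
   matrices, metadata, GO annotations and Ct tables with planted module
   structure, markers and forecast coefficients, so the whole pipeline
   is testable without sequencing data.

## Worked example

The full pipeline on the default synthetic dataset (2,000 genes, seven
planted stage modules, 7 trees × 12 sampling days spanning −36 to +11
days around bloom):

```
$ bloomclock run --outdir demo --seed 42
INFO bloomclock: simulated 2000 genes x 84 samples into demo/data
INFO bloomclock: variance filter retained 1514 / 2000 genes (75.7%)
INFO bloomclock: picked soft power 6
INFO bloomclock: detected 8 modules (7 stage-specific)
INFO bloomclock: selected markers: {'CBFb': 'GENE00161', 'CBFg': 'GENE00351', 'CBFr': 'GENE00651'}
INFO bloomclock: model: days ~ 4.373*dCt_g -1.145*dCt_b -0.324*dCt_g*dCt_b -6.808 (r=0.975)
INFO bloomclock: pipeline complete: 8 modules, 7 stage-specific
```

Reading the output: the seven planted stage-peaked modules are all
recovered and staged (the eighth module is the monotone control-gene
group, classed constitutive); the three selected marker genes are
exactly the planted ones; and the forecast model calibrated on the
simulated (noisy, full-window) Ct series predicts held-in days to
flowering with Pearson r = 0.975. Individual stages are available as
subcommands (`simulate`, `preprocess`, `modules`, `enrich`, `markers`,
`calibrate`, `predict`) and as library functions
(`bloomclock.detect_modules`, `bloomclock.fit_forecast_model`, ...).

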
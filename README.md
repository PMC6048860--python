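# dgscore

Integrative driver-gene detection from copy number, expression and
functional networks, with survival validation — built for cohorts like
high-risk neuroblastoma, where point mutations are rare and the prognostic
signal lives in recurrent copy-number alterations (CNAs) that actually move
expression and the interaction network around them.

## What it computes

Given per-patient aCGH-style probe log2-ratios, gene-level FPKM expression,
a functional gene-interaction network and a clinical table, the pipeline:

1. **Calls CNAs** per patient by penalized least-squares changepoint
   segmentation; gains at mean log2-ratio ≥ +0.15, losses at ≤ −0.15;
   segments kept only with FDR ≤ 1e−05, length ≥ 1 kb and ≥ 10 probes.
2. **Detects recurrent regions** altered in ≥ 10 % of patients (ceil rule).
3. **Builds the functional gene set (FGS)**: genes on recurrent regions
   whose expression is concordant with the alteration (one-sided Welch
   t-test on within-patient standardized log2(FPKM+1), carriers vs
   copy-neutral patients, P < 0.05). The *common* FGS additionally drops
   genes from regions carrying both gains and losses.
4. **Builds altered gene sets (AGS)**: per patient, the top 100 + bottom
   100 genes by cross-sample expression rank; the common AGS collects genes
   recurrent in ≥ 5 patient AGSs, optionally extended by a literature list.
5. **Calls drivers by network enrichment analysis (NEA)**. Each candidate
   gene is scored by its direct links to the AGS,

   ```
   z = (d_AF − μ_AF) / σ_AF
   ```

   with d_AF the observed candidate–AGS links and μ_AF, σ_AF the null
   moments (default: exact hypergeometric over AGS placements; degree-aware
   analytic and edge-rewiring nulls available). Genes with z > 2 are
   putative drivers — common (vs the common AGS) or patient-specific
   (vs that patient's AGS, among the patient's own altered FGS genes).
6. **Summarizes driver burden**: DGscore = number of called driver genes a
   patient carries as a filtered CNA. Patients split at the cohort median
   are compared by Kaplan–Meier/log-rank and a battery of Cox
   proportional-hazards models (DGscore, stage 4/4S vs 1–3, MYCN
   amplification, age in days, and adjusted combinations).
7. **Assesses stability** by bootstrap: 50 patient-resamples, rerunning the
   common-driver pipeline each time; a gene selected x times gets the exact
   binomial upper tail P(X ≥ x) under X ~ Binomial(50, p), p = observed
   drivers / annotated genes.

A first-class synthetic-cohort generator (`dgscore.synth`) plants recurrent
gain/loss regions, driver genes with cis dosage effects and trans effects
on wired network neighbors, and survival whose hazard rises with planted
driver burden — so every stage is testable against known ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (48 high-risk patients, 2000 genes, 10 planted drivers):

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_call_cnas.py
python analysis/03_build_gene_sets.py
python analysis/04_call_drivers.py
python analysis/05_score_survival.py
python analysis/06_bootstrap_stability.py
```

which prints (seed 1):

```
672 segments across 48 patients
192 CNAs after filtering (per patient: min 1, max 9)
16 recurrent regions (>= 10% of patients)
128 genes annotated on 16 recurrent regions
FGS: 14 concordant genes (10.9% of annotated)
common drivers (z > 2 vs common AGS): G0254, G0504, G1254, G1754
37 patient-specific calls over 11 unique genes
DGscore median split: 15 high vs 33 low
log-rank P = 2.58e-05
model 1a: DGscore: 7.88, 0.000245
model 6:  DGscore: 7.99, 0.000488, Age: 1.00, 0.905, MYCN: 0.73, 0.435, Tumor stage: 2.67, 0.0705
```

Ten planted drivers, eleven unique called driver genes — the DGscore split
separates survival (log-rank P = 2.6e−05) and stays the only significant
term after adjusting for age, MYCN and stage (model 6), while the bootstrap
(`06`) shows the planted drivers re-selected far above the binomial null.
The same pipeline is scriptable via the `dgscore` CLI
(`simulate`, `segment`, `recur`, `fgs`, `ags`, `nea`, `score`, `survival`,
`bootstrap`, `run-all`) on any inputs in the documented TSV formats.

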
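# senuro

Tools for studying **urinary surrogates of renal epithelial senescence**.
Senescent tubular epithelia — P21+ (CDKN1A) and KI67− — accumulate in the
ageing and diseased kidney and secrete a characteristic protein set (the
SASP).  Quantifying them normally requires a biopsy; this package implements
the full analysis chain by which a urinary biomarker (a clusterin-to-
creatinine ratio, uCCR) can stand in for that histology and predict chronic
kidney disease (CKD) progression:

1. **histology** — per-cell P21/KI67 classification tables → senescent
   fraction per biopsy (section counts pooled), and P21/clusterin
   co-expression odds ratios with Fisher exact tests;
2. **proteomics_screen** — spike-in (ADH) and creatinine normalisation of
   urinary LC-MS/MS intensities, a Spearman + Benjamini–Hochberg screen of
   every protein against tissue senescence, strict shortlist (adjusted
   p < 0.05, ρ > 0.5) flagged against a SASP list, and 2^−ΔΔCt qPCR
   expression;
3. **spatial_enrichment** — for subcellular-resolution spatial
   transcriptomics: CDKN1A+ classification (≥ 2 transcripts in the cell
   boundary) and the radial enrichment profile
   e(r) = log2[q(r)/b(r)], where q and b are pseudocounted transcript
   densities per 1 µm annulus (r ≤ 50 µm) around query cells and a random
   background population, plus Wilcoxon differential expression;
4. **outcomes** — risk-based cohort filtering, the composite progression
   endpoint (renal replacement therapy, eGFR < 15 mL/min sustained
   > 90 days, or > 40% decline from baseline sustained > 90 days), ROC
   threshold selection under a specificity floor, Kaplan–Meier/log-rank,
   and Cox proportional-hazards models with Harrell's c-index;
5. **synthetic_data** — a seeded generator producing matched cohort,
   biopsy, proteome, spatial and outcome datasets with tunable effect
   sizes, so the whole pipeline is testable without clinical data;
6. **core_io** — shared record types, CSV/TSV readers and writers, the
   2009 CKD-EPI eGFR equation and analyte/creatinine ratios.

See `docs/methods.md` for the statistical definitions and the design
decisions behind them.

## Worked example

The numbered scripts under `analysis/` run the whole study flow on a
synthetic dataset (each step prints what it found and writes its tables
under `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_histology.py
python analysis/03_screen.py
python analysis/04_spatial.py
python analysis/05_outcomes.py
```

which prints, step by step:

```
biopsy cohort n=51, outcome cohort n=570, 20400 classified cells, 34506 CLU transcripts -> results/data
n=51  median senescent epithelia 5.7% (IQR 3.0-7.9%)  rank correlation with latent truth rho=0.92
331 proteins screened; 7 positively correlated at adjusted p<0.05; shortlist (rho>0.5):
      protein      rho        p_adj  sasp_flag
SEN_MARKER_08 0.803459 1.225554e-09      False
...
          CLU 0.660488 1.487789e-05       True
235 CDKN1A+ PT cells of 1507 PT; mean log2 enrichment e(r<=20µm)=0.66 vs e(r>40µm)=-0.08; CLU DE p_adj=1.50e-35, log2FC=0.72
included 375/570 (excluded: 88 low-risk, 107 low-eGFR)
uCCR threshold 117.4 µg/mmol (AUC 0.80); progression 26/97 high vs 32/278 low (log-rank p=2.2e-04)
adjusted HR 1.99 (95% CI 1.15-3.45); c-index 0.796 with vs 0.786 without uCCR
```

Reading this: the clusterin analogue is recovered by the unbiased screen
and is the only shortlisted protein carrying a SASP flag; CLU transcripts
are concentrated within ~20 µm of CDKN1A+ proximal-tubule centroids but not
at larger radii; and after adjustment for baseline eGFR, albuminuria, age,
blood pressure and sex, a high uCCR roughly doubles the progression hazard
and adds concordance to the survival model.

The same stages are scriptable via the `senuro` CLI
(`senuro simulate|histology|screen|spatial|outcomes --help`).

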
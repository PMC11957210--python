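# plasmad

A toolkit for plasma-proteomics case/control analysis of Alzheimer disease
cohorts: assay QC, three-stage differential abundance with meta-analysis,
cross-study concordance statistics, Gaussian-mixture biomarker
dichotomization, progression/survival modelling, a sparse predictive-panel
procedure with frozen transfer evaluation, CDR-SB decline slopes, and
set-enrichment/module ranking — exercised end-to-end on a synthetic cohort
generator so every stage is testable without access-controlled data.

## Modules

| Module | What it does |
| --- | --- |
| `plasmad.datamodel` | Typed data model (`ProteomicsMatrix`, sample/CDR tables, gene sets) and TSV/GMT I/O |
| `plasmad.simulate` | Synthetic cohorts with planted effects, LOD censoring, plate scale factors, bimodal biomarkers, conversion hazards, CDR-SB trajectories, plus ground truth |
| `plasmad.qc` | LOD / scale-factor / CV analyte filters, log10 Tukey outlier masking, two-pass call-rate filtering, per-cluster z-score normalization |
| `plasmad.daa` | Per-analyte OLS association, discovery→replication gating, weighted Stouffer meta-analysis, BH-FDR with explicit universe, tertile odds ratios |
| `plasmad.concordance` | Sign concordance, exact log-space binomial enrichment, effect-size correlation, intersection-pattern summaries |
| `plasmad.biomarker` | 2-component GMM cutoffs (equal-posterior rule), biomarker dichotomization, AT status |
| `plasmad.survival` | Time-to-event construction, Cox models (Efron ties), Kaplan–Meier tables, CDR-SB slopes, Wilcoxon group comparison |
| `plasmad.panel` | Stratified split, CV'd L1 logistic path (covariates unpenalized), 90%-of-best λ rule, frozen logistic panel (weights + cutoff + standardization), plain/undersampled evaluation, horizon AUCs |
| `plasmad.enrichment` | Hypergeometric over-representation, ACAT p-value combination, module ranking |

## CLI

Every stage is exposed as a `plasmad` verb reading/writing TSVs so the
pipeline can be chained from the shell:

```bash
plasmad simulate --config cfg.yaml --out sim/          # synthetic study + truth
plasmad qc --matrix sim/matrix.tsv --metadata sim/samples.tsv \
    --scale-factors sim/scale_factor.tsv --lods sim/lod.tsv --out qc/
plasmad daa --disc-matrix qc_d/matrix_qc.tsv --disc-metadata d/samples.tsv \
    --rep-matrix qc_r/matrix_qc.tsv --rep-metadata r/samples.tsv \
    --m 6905 --out daa/
plasmad concordance --internal daa/meta.tsv --external external.tsv
plasmad biomarker --metadata samples.tsv --column csf_abeta42 --direction low_is_positive
plasmad survival --matrix qc/matrix_qc.tsv --metadata samples.tsv --cdr cdr.tsv --out surv/
plasmad decline --metadata samples.tsv --cdr cdr.tsv --groups groups.tsv --out decline/
plasmad model-train --matrix qc/matrix_qc.tsv --metadata samples.tsv --out model.json
plasmad model-eval --model model.json --matrix qc2/matrix_qc.tsv --metadata samples2.tsv
plasmad enrich --hits hits.txt --sets sets.gmt --universe universe.txt
```

A simulation config is plain YAML mapping `SimulationConfig` fields, e.g.

```yaml
cohorts: {K1: [600, 400]}
n_analytes: 1000
fraction_nonnull: 0.05
effect_size_sd_units: 0.4
lod_quantile: 0.005
missing_rate: 0.01
seed: 1
```

## Conventions

- All tables are tab-separated with one header row; missing cells are empty
  (`NA` also accepted on read); the abundance matrix is wide (rows =
  samples) with `sample_id` and `plate` columns.
- Status coding CO=0 / AD=1; positive effects mean higher abundance in AD.
- Times are ages in years; CDR windows are specified in days.
- Every stochastic routine takes an explicit seed and is deterministic
  under it.
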
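# baxloc

Quantitative scoring of BAX/BAK subcellular localization from fractionation
western blots, and classification of BAX-protected tumors in paired
tumor/non-tumor cohorts — with the downstream expression-signature and
survival analyses, and a synthetic-cohort simulator that makes the whole
chain testable end to end.

## The problem

The proapoptotic BCL-2 effectors BAX and BAK kill cells by permeabilizing
the outer mitochondrial membrane; cells restrain them by continuously
retrotranslocating them from the mitochondria back into the cytosol.  The
steady-state balance — how much BAX sits on the mitochondria — therefore
measures a cell's apoptosis predisposition.  In hepatocellular carcinoma,
a subgroup of tumors shifts BAX several orders of magnitude toward the
cytosol relative to the matched non-tumor tissue, protecting itself
specifically from BAX-dependent apoptosis ("BAX-protected" tumors), with
consequences for drug sensitivity and survival.

The measurement chain is densitometry of fractionation western blots.  For
a sample's fraction lanes, with band amounts calibrated against a HeLa
whole-cell-lysate titration run on every blot, the **relative
localization** of an analyte is

    rel_loc = (amount_mito / amount_COXIV) / (amount_cyto / amount_ACTIN)

i.e. the quotient of relative mitochondrial protein (per COX IV) over
relative cytosolic protein (per β-ACTIN), reported on log10 scale.  High
values mean mitochondrial shift.  The per-patient tumor shift

    Δ = log10 rel_loc(tumor) − log10 rel_loc(non-tumor)

classifies a patient as BAX-protected when Δ ≤ −1 (protected tumors sit
near −2).

## What's in the package

| module | contents |
| --- | --- |
| `baxloc.shuttle_sim` | two-compartment shuttling kinetics at steady state; cohort, blot-rendering, expression and survival generators |
| `baxloc.blot_quant` | per-blot standard-curve fits, band quantification, marker normalization |
| `baxloc.localization` | relative localization, paired shifts, rank categorization (8/9/9/8 for n = 34), protection calls, carbonate-extraction ratios |
| `baxloc.cohort_stats` | Pearson correlation, Student's t-tests, one-way ANOVA with Holm–Šidák adjustment (formula-level implementations) |
| `baxloc.omics_stats` | quantile normalization, detection-p masking and presence filter, t-test differential expression, hierarchical clustering, kNN imputation |
| `baxloc.survival` | Kaplan–Meier curves, log-rank (Mantel–Cox) test, signature-projection workflow |
| `baxloc.pipeline` / `baxloc.cli` | one-config orchestration with deterministic per-stage seeding and a run manifest; `baxloc` console script |

The `analysis/` scripts run the study-scale workflow as a narrative
sequence (simulate → calibrate/score → classify → differential expression →
survival projection), writing tables under `results/analysis/`.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/02_calibrate_and_score.py
python analysis/03_classify_protection.py
```

prints (seed 7, the defaults):

```
simulated 34 patients (68 tissue samples), 11 planted protected
rendered 748 bands on 17 blots -> results/analysis/lanes.tsv
calibrated 408 bands, scored 136 sample x analyte localizations
  BAX vs BAK localization (tumor): R = 0.487, p = 3.52e-03
  BAX vs BAK localization (non_tumor): R = 0.881, p = 6.21e-12
called 11 of 34 patients BAX-protected
category sizes: {'low_extreme': 8, 'low_moderate': 9, 'high_moderate': 9, 'high_extreme': 8}
truth-aware evaluation: accuracy = 1.000 (11 called / 11 planted)
```

The cohort's BAX and BAK localizations correlate (tightly in non-tumor
tissue, more loosely in tumors, where the planted protected subgroup moves
BAX but not BAK); rank-partitioning the 34 patients by non-tumor
mitochondrial BAX gives the balanced 8/9/9/8 categories; and the classifier
recovers all 11 planted protected patients from the rendered blots alone.
Continuing with `04_differential_expression.py` and
`05_survival_projection.py` recovers the planted 50-gene signature
(50/50 at p < 0.05) and separates the two signature clusters of an
external-style cohort by log-rank at χ² = 65.5 (p ≈ 6e−16).

The same can be run from one config: `baxloc run-all --seed 7 --outdir out/`.

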
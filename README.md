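# habitat-rfa

Habitat-based radiomics for assessing the immediate response of lung
metastases to CT-guided radiofrequency ablation (RFA).

After RFA of a small lung metastasis, radiologists must judge from the
intra-procedural CT whether the ablation achieved a complete response (CR)
— a judgement complicated by ground-glass change, haemorrhage and
atelectasis around the ablation zone. This package implements a full
radiomics pipeline for that problem: it preprocesses paired pre-/
post-ablation volumes, partitions each lesion into **habitats** (spatially
coherent subregions of similar local texture, found by K-means on
77-dimensional block-level feature vectors with Calinski-Harabasz
cluster-count selection), builds **peritumoral** shells by physical-unit
dilation, extracts IBSI-style geometry/intensity/texture features,
reduces them through an ICC → t-test → correlation-pruning → mRMR → LASSO
cascade, fits per-region classifier signatures (Intra, Peri-5, Peri-10,
Habitat, Habitat+Peri-5, Clinical) with cross-validated grid search, and
compares them with DeLong tests, Youden-index operating points,
Hosmer-Lemeshow calibration and decision-curve analysis.

Because cohorts of this kind are not publicly deposited, the package
includes a first-class synthetic-cohort generator
(`habitat_rfa.synthcohort`) that reproduces the statistical structure the
analysis needs — ~20% non-CR prevalence, ~1.2 cm nodules with three
latent texture zones, ablation zones with margins and halos, residual
tumour texture in non-CR lesions, and outcome-linked clinical covariates
— so the whole pipeline is testable end to end. See `docs/methods.md` for
the model details and design decisions.

## Worked example

```python
from habitat_rfa import RunConfig, run_all

cfg = RunConfig(
    n_lesions=60,               # desk-scale cohort
    spacing_mm=(1.0, 1.0, 1.0),
    k=3,                        # habitat count (use "auto" for CH selection)
    icc_enabled=False,
    grid_search=False,
    signatures=("Intra", "Peri5", "Habitat", "HabitatPeri5"),
    seed=205,
)
result = run_all(cfg)
print(result.report_test.summary_table().to_string(index=False))
```

prints (seed 205):

```
   signature  ACC  AUC  CI_low  CI_high  Sensitivity  Specificity  PPV  NPV  Youden
       Intra  1.0  1.0     1.0      1.0          1.0          1.0  1.0  1.0     1.0
       Peri5  1.0  1.0     1.0      1.0          1.0          1.0  1.0  1.0     1.0
     Habitat  1.0  1.0     1.0      1.0          1.0          1.0  1.0  1.0     1.0
HabitatPeri5  1.0  1.0     1.0      1.0          1.0          1.0  1.0  1.0     1.0
```

Each row is one signature evaluated on the held-out test split (12 of the
60 lesions, 2 non-CR events): AUC with its DeLong confidence interval,
and the confusion metrics at the Youden threshold that was frozen on the
training split. On this strong-effect synthetic cohort the residual-tumour
texture is separable enough that the signatures saturate at AUC 1.0 on the
small test set; across repeated seeds the fused Habitat+Peri-5 signature
matches or beats the intratumoral signature in >= 80% of runs (the
`habitat_peri5_ge_intra_pct` quantity the acceptance script computes).
`result.selected_features` shows which fused pre/post features each
signature kept, and `result.report_test.delong` the pairwise DeLong
comparisons.

The same workflow is scriptable from the shell:

```bash
habitat-rfa simulate --n 60 --seed 17 --out cohort/
habitat-rfa preprocess cohort/L0000_pre.nii.gz --spacing 1 1 1 --out pre.nii.gz
habitat-rfa ring cohort/L0000_tumor.nii.gz --mm 5 --lung cohort/L0000_lung.nii.gz --out ring5.nii.gz
habitat-rfa habitat pre.nii.gz tumor_iso.nii.gz --k auto --k-range 2 6 --out habitats.nii.gz
habitat-rfa run-all --seed 17 --out results/
```

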
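# ketox

Pathway-based hepatotoxicity evaluation from concentration-response
high-throughput screening (HTS) data.

Given per-assay curve-fit parameters (top, slope, AC50, curve error, hit
call), hepatotoxicity labels, an assay-to-key-event (KE) map, steady-state
plasma concentrations (Css) and chemical structures, the package:

1. **reconstructs** Hill concentration-response curves on a shared
   log-spaced grid (1 pM - 100 mM) and normalizes each assay to [0, 1]
   (`ketox.curves`);
2. **selects** assays associated with hepatocellular / hepatobiliary
   toxicity via Fisher's exact test with Benjamini-Hochberg control at
   FDR 0.15 (`ketox.assay_select`);
3. **composes** each KE's member assays into per-chemical KE curves,
   scores them by normalized log-concentration AUC, ranks chemicals and
   evaluates each KE by ROC AUC (`ketox.ke_model`);
4. **overlays** Css to quantify the bioavailable ("realized") portion of
   in vitro activity and flags chemicals whose activity lies entirely
   above systemic exposure (`ketox.tk_overlay`);
5. **clusters** chemicals with Butina sphere-exclusion at Tanimoto >= 0.70
   on 2048-bit circular fingerprints, detects hepatotoxicant-enriched
   clusters (> 2/3 toxicants) and computes Lipinski-type descriptors
   (`ketox.chem`);
6. **fits** two logistic hepatotoxicity models with leave-one-out
   validation after class balancing — Model 1 (KE scores) and Model 2
   (KE scores + log10 Css + Lipinski descriptors) (`ketox.aop_model`);
7. **simulates** complete input bundles with known ground truth —
   associated assays, TK-rescued chemicals — for end-to-end validation
   (`ketox.synthetic`).

## Command line

```bash
# generate a synthetic bundle with ground truth
ketox simulate --n-chemicals 200 --n-assays 40 --n-kes 8 --seed 1 \
      --out-dir bundle/

# run everything: selection, KE scores, TK overlay, clustering, models
ketox run-all --curve-fits bundle/curve_fits.csv --labels bundle/labels.csv \
      --ke-map bundle/ke_map.csv --css bundle/css.csv \
      --smiles bundle/smiles.csv --seed 1 --out-dir results/
```

Individual stages are available as `select-assays`, `ke-scores`,
`tk-overlay`, `cluster` and `fit-models`. A YAML config file
(`--config`) can set any `ketox.config.PipelineConfig` key; defaults
follow the published analysis (FDR 0.15, similarity cutoff 0.70,
classification threshold 0.5, 10 grid points per decade). `run-all`
writes a `manifest.json` with the config hash; reruns are bit-identical.

## Input formats

Plain CSV with a header row:

| file       | columns                                                    |
|------------|------------------------------------------------------------|
| curve fits | `chem_id,assay_id,top,slope,ac50_uM,curve_error,hit_call`  |
| labels     | `chem_id,hepatotoxic,hepatocellular,hepatobiliary`         |
| KE map     | `assay_id,ke_id,ke_name`                                   |
| Css        | `chem_id,css95_uM`                                         |
| structures | `chem_id,smiles`                                           |

Blank `top`/`slope`/`ac50` cells mean "no response" (flat curve).
Concentration columns accept unit suffixes `_pM`/`_nM`/`_uM`/`_mM`/`_M`
and are converted to micromolar on read.

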
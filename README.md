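# cystomics

Integrated metabolomic/lipidomic analysis of targeted concentration
panels (cyst fluid and plasma), built as a tested, reusable pipeline:

1. **Synthetic cohort generation** (`cystomics.cohort`) — runs the
   hierarchical lognormal model forward: grand mean + sample, molecule,
   group-by-molecule and age/BMI covariate effects, Gaussian log-scale
   noise, and left-censored (MNAR) missingness.  Every downstream stage
   is testable against known ground truth.
2. **Preprocessing** (`cystomics.preprocess`) — natural-log transform,
   the *modified 80% rule* (a molecule is discarded only when missing in
   more than 80% of samples of **every** clinical group), and QRILC-style
   imputation (censored normal probability-plot estimation plus draws
   from the truncated normal below each molecule's minimum observed
   value).
3. **Hierarchical Bayesian mixed model** (`cystomics.hierarchical`) —
   `y_gij ~ N(theta + phi_i + lambda_j + eta_gj + sum_v gamma_vj x_vi,
   sigma^2)` with Student-t(3, 0, 10) / half-t(3, 0, 10) weakly
   informative priors and sum-to-zero constraints per discrete category.
   Inference is an exact blocked Gibbs sampler (inverse-gamma auxiliary
   representation of the half-t scales; collapsed slice updates of the
   variance components to avoid funnel pathologies; report-time sweeping
   of likelihood-flat directions so every stored draw satisfies the
   constraints exactly).  Provides fold changes `exp(eta_gj - eta_hj)`
   with 95% credibility intervals, PSIS-LOO covariate selection, group
   merging, and confounder adjustment + per-molecule standardization.
4. **CPPLS-DA classification** (`cystomics.cppls`) — canonical powered
   PLS discriminant analysis (power chosen per component by canonical
   correlation with the dummy-coded responses; linear discriminant on
   the scores), VIP scores, leave-one-out cross-validated AUC /
   sensitivity / specificity / balanced accuracy, and recursive 5%
   lowest-VIP feature elimination.
5. **Exploration** (`cystomics.explore`) — PCA projection,
   Ward/Euclidean clustering orders for heatmaps, and a Pearson screen
   of molecules against clinical blood markers (CA19-9, albumin,
   bilirubin) with Benjamini–Hochberg adjustment; hits are
   `|r| > 0.6` and adjusted `p <= 0.05`.
6. **I/O and orchestration** (`cystomics.io`, `cystomics.pipeline`,
   `cystomics.cli`) — CSV/TSV table formats, a YAML-configured
   `run-all` pipeline with a reproducibility manifest, and a `click`
   CLI.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (metric
arithmetic, full-scale parameter recovery, imputation recovery, the
CPPLS/NIPALS equivalence oracle, elimination-loop sanity, and null
calibration).

## CLI

```sh
# simulate a cohort with known ground truth
cystomics simulate --groups SCN:5,LGD:8,HGD:7,Cancer:11 \
    --molecules 200 --seed 17 --out sim/

# full pipeline from a YAML config (seed is mandatory)
cystomics run-all --config run.yaml
```

Example `run.yaml`:

```yaml
concentrations: sim/concentrations.csv
clinical: sim/clinical.csv
out_dir: run1
seed: 17
merge:
  - labels: [HGD, Cancer]
    new_label: HGD/Cancer
n_draws: 4000
n_chains: 4
```

The run directory contains the preprocessed and adjusted matrices,
fold-change TSVs per group pair, PCA scores, the classification report
with VIP trace, the correlation screen, and `manifest.json` (config
hash, per-stage seeds, outputs).  Identical configs reproduce
byte-identical tables.  Individual stages are also available as
subcommands: `preprocess`, `fit`, `foldchange`, `adjust`, `classify`,
`correlate`.

## Caveats

- The published workflow adjusts for confounders once and then runs
  LOO-CV; the adjustment is not refitted inside each fold, which leaks
  a small amount of information across folds.  This package replicates
  that order and inherits the same optimism.
- Single-loop LOO-CV over the elimination trace selects the feature set
  with the best cross-validated balanced accuracy; the reported peak is
  an optimistic estimate of generalization error (no nested CV by
  design).
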
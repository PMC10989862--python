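# vinegp

Genomic prediction and multitrait ideotype selection for grapevine-style
breeding programs built from biparental crosses that share parents.

Breeding programs for perennial crops increasingly split their offspring
into a phenotyped **training set** (TS) and a genotyped-only **validation
set** (VS) of candidates pre-screened by marker-assisted selection on
major disease-resistance loci. `vinegp` implements the full analysis chain
such a program needs, as a library of scikit-learn-style estimators plus a
thin command-line interface:

- **`simcross`** — synthetic founders, Haldane-meiosis biparental crosses,
  additive QTL trait architectures with a cross variance component, p-rep
  field designs (unreplicated genotypes + replicated controls), binary
  major-gene traits, and genotype missingness: a complete truth-known
  emulation of the study design.
- **`genomat`** — genotype QC (missingness, MAF), within-cross mean
  imputation, the VanRaden genomic relationship matrix, marker PCA,
  per-cross Mahalanobis outlier detection, and coordinate-based marker
  intersection between populations.
- **`phenomodel`** — the per-trait mixed model
  `y = μ + year + genotype + cross + row + col + ε` fitted by REML
  (profiled residual, derivative-free search over variance ratios),
  backward model selection (LRT for random terms, F-test for year),
  broad-sense heritability `H² = (σ²_G + σ²_C)/(σ²_G + σ²_C + σ²_ε)`,
  BLUPs with prediction error variances, and deregression
  `drgBLUP = BLUP/(1 − PEV/σ²_g)`.
- **`genopred`** — `GBLUP` (spectral REML, equivalent ridge marker
  effects), `MarkerLasso` and `LogisticMarkerLasso` (pathwise coordinate
  descent with inner-CV penalty choice), repeated K-fold cross-validated
  predictive ability (Pearson correlation of observed vs predicted; K=5,
  R=10 by default), per-trait best-method choice, validation-set
  prediction and a second deregression.
- **`selindex`** — the multitrait genotype–ideotype distance index
  (`MGIDI`): 0–100 rescaling toward each trait's desired pole, factor
  analysis (Kaiser retention, varimax, regression scores), Euclidean
  distance to the ideotype in factor space, ranks and per-factor
  strength/weakness contributions.
- **`pipeline`** — one-call within-population runs, across-population
  prediction with marker intersection, MAS pre-filtering, deterministic
  master-seed fan-out and TSV/JSON reporting.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate a small program (4 crosses over 4 shared parents, ~140 TS and 60
VS genotypes), run the whole pipeline, and rank the candidates:

```python
from vinegp import simcross as sc, pipeline as pl

cfg = sc.SimConfig(n_founders=4, n_chromosomes=5, snps_per_chromosome=80, seed=11)
prog = sc.simulate_program(
    cfg,
    crosses=[{"parent_a": "P1", "parent_b": "P3", "n_ts": 35, "n_vs": 15},
             {"parent_a": "P1", "parent_b": "P4", "n_ts": 35, "n_vs": 15},
             {"parent_a": "P2", "parent_b": "P3", "n_ts": 35, "n_vs": 15},
             {"parent_a": "P2", "parent_b": "P4", "n_ts": 35, "n_vs": 15}],
    traits=[sc.TraitArchitecture(name="acidity", n_qtl=120, target_h2=0.6,
                                 cross_variance_fraction=0.3, year_var=0.3),
            sc.TraitArchitecture(name="color", n_qtl=20, target_h2=0.4,
                                 cross_variance_fraction=0.2, year_var=0.2)],
    years=[2018, 2019], grid_rows=15, grid_cols=10,
    control_parents=["P1", "P2"], control_reps=5,
    missing_rate=0.03, binary_penetrance=0.95, seed=11,
)
report = pl.run_within_population(
    prog.genotypes, prog.phenotypes,
    pl.RunConfig(seed=1, cv_r=2, lasso_n_lambda=40, n_select=10),
    ideotype={"acidity": {"direction": "maximize"},
              "color": {"direction": "minimize"}},
    binary_labels=prog.binary_labels,
)
print(report.trait_table[["trait", "h2", "best_method", "pa_gblup", "pa_lasso"]].to_string(index=False))
print("selected:", report.selected[:5])
print("binary accuracy:", round(report.binary_accuracy, 3))
```

which prints

```
  trait       h2 best_method  pa_gblup  pa_lasso
acidity 0.567477       lasso  0.779375  0.784880
  color 0.448446       gblup  0.903598  0.896062
selected: ['C3_042', 'C3_040', 'C3_039', 'C3_036', 'C2_047']
binary accuracy: 0.951
```

`h2` is the broad-sense
heritability estimated by REML from the two-year p-rep trial; `pa_*` is
the mean cross-validated predictive ability (Pearson correlation between
deregressed BLUPs and predictions over 5 folds × repetitions) for each
method, and `best_method` the one used to predict the validation set. The
selected genotypes are the candidates closest to the ideotype in factor
space; `report.selection` carries their distances, ranks and per-factor
contributions, and `report.binary_accuracy` the cross-validated accuracy
of the major-gene (berry-color-style) classifier.

The same stages are available from the shell:

```bash
vinegp simulate --config config.yaml --out-dir data/
vinegp qc --geno data/geno --out data/geno_qc
vinegp fit-pheno --pheno data/pheno.tsv --out-dir values/
vinegp cv --geno data/geno_qc --values values/genovalues_acidity.tsv \
          --methods gblup,lasso --k 5 --reps 10 --seed 1 --out cv.tsv
vinegp run-all --config config.yaml
```

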
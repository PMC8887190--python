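# cthbench

Spike-in benchmarking of **cell-type-heterogeneity (CTH) adjustment** in
bulk DNA-methylation studies.

## The problem

Epigenome-wide association studies (EWAS) measure DNA methylation on DNA
extracted from bulk tissue — blood, saliva, solid biopsies — which is a
mixture of cell types with radically different methylomes (between-cell-type
differences of 80% methylation at individual CpGs are common). If the
cell-type composition of samples varies, composition dominates the variance
landscape of the data: differentially methylated cytosines (DMCs) that
merely track a composition shift swamp the signal, while genuine
within-cell-type changes in a minority population (e.g. monocytes, ~10% of
whole blood) are diluted by a factor of ten and become undetectable.

`cthbench` quantifies both failure modes — and what reference-based
deconvolution buys back — with a fully synthetic, seeded spike-in
experiment for anyone developing or teaching EWAS pipelines:

1. **simulate** matched purified methylomes for neutrophils, CD4+ T cells
   and monocytes (139 individuals, 69 exposed cases vs 70 controls by
   default), spike 1000 ground-truth DMCs into the monocyte compartment of
   the cases with beta-scale effects drawn uniformly from [0.01, 0.2], and
   mix them into bulk profiles with Dirichlet-distributed whole-blood-like
   cell fractions (means 0.70/0.20/0.10);
2. **deconvolve** the mixtures: build a reference matrix of cell-type-
   specific marker CpGs and estimate per-sample fractions by constrained
   least squares (`w >= 0`, `sum(w) <= 1`), robust (Huber) regression, or a
   two-level hierarchical scheme for nested panels;
3. **test** every CpG for differential methylation three ways —
   unadjusted (`beta ~ exposure`), CTH-adjusted
   (`beta ~ exposure + fractions`), and cell-type-specific via the
   interaction model `beta ~ sum_k w_k + sum_k w_k * exposure` — with
   Benjamini–Hochberg control;
4. **score** each arm against the spike-in truth (sensitivity, FPR,
   precision) and reproduce the variance-structure diagnostics: PC variance
   fractions (fVAR) with factor annotation, selection of exposure-correlated
   PCs, and hierarchical clustering over them before and after
   residualising the betas on the estimated fractions.

A third *oracle* arm tests the purified monocyte profiles directly,
upper-bounding what any bulk analysis could achieve.

## Model summary

Purified beta values follow a latent-Gaussian model,
`beta = expit(logit(m) + N(0, sigma_bio^2))` with per-CpG per-cell-type
mean `m`, plus beta-scale measurement noise at mixing; bulk values are the
per-individual convex combination `sum_k w_ik P_k(g, i)`. Marker CpGs are
planted with one-vs-rest mean gaps >= 0.8. Fractions are estimated per
sample by minimising `||R w - b||` subject to `w >= 0`, `sum(w) <= 1`,
where `R` is the marker-CpG reference matrix. See `docs/methods.md` for
parameters, defaults and limitations.

## Worked example

```python
from cthbench import SimConfig, run_benchmark

config = SimConfig(n_cpgs=10_000, n_dmcs=500, markers_per_type=50, seed=7)
report = run_benchmark(config, replicates=1)

print(report.mean_metrics().round(3).to_string())
print("pooled fraction R^2:", round(report.fraction_r2.iloc[0], 4))
```

prints

```
            sensitivity    fpr  precision     tp    fp      tn     fn
arm
oracle            0.996  0.003      0.949  498.0  27.0  9473.0    2.0
unadjusted        0.000  0.000        NaN    0.0   0.0  9500.0  500.0
adjusted          0.620  0.002      0.942  310.0  19.0  9481.0  190.0
pooled fraction R^2: 0.9999
```

Reading the table: testing the raw mixtures finds **none** of the 500
monocyte DMCs (the 10% monocyte fraction dilutes a <=0.2 effect below the
composition-driven noise), while adding the estimated cell fractions as
covariates recovers 62% of them at ~94% precision — most of the gap to the
purified-monocyte oracle. Precision is reported as NaN, not 0 or 1, when
an arm makes no calls. Fraction estimates themselves are essentially
exact here (pooled R^2 vs the true mixing weights ~1.0).

The same pipeline is scriptable from the shell:

```bash
cthbench simulate  --config config.yaml --outdir sim/
cthbench deconvolve --bulk sim/bulk_beta.tsv --ref ref.tsv \
                    --method constrained --out fractions.tsv
cthbench dmc        --bulk sim/bulk_beta.tsv --pheno sim/pheno.tsv \
                    --fractions fractions.tsv --mode adjusted --out dmc.tsv
cthbench pcacluster --bulk sim/bulk_beta.tsv --pheno sim/pheno.tsv --outdir pca/
cthbench benchmark  --config config.yaml --replicates 5 --outdir bench/
```

All tables are plain TSV with header row and row names in the first
column; configs are YAML mirroring `SimConfig` field-for-field.

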
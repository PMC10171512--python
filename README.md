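# modecca

Modes of population covariation between a brain functional connectome and
health phenotypes: PCA–CCA with max-statistic permutation inference.

## The problem

Large population-imaging cohorts ask how the resting-state functional
connectome relates to health and lifestyle, not one variable at a time but
as joint *modes of covariation*: paired linear combinations of connectome
edges (X) and phenotypes (Y) that maximally correlate across subjects.
`modecca` implements that analysis end to end for researchers working with
subject × variable tables:

1. **Connectome construction** — per-subject ROI time series →
   partial-correlation matrix (−P_ij/√(P_ii·P_jj) from the inverse
   covariance P) → edge vector over the strict upper triangle
   (R(R−1)/2 features; 55 edges for the default 11-node interoceptive
   network).
2. **Cleaning** — per block: exclusion of variables with >50% missing
   data, winsorisation at the 1st/99th percentiles, k-nearest-neighbour
   (k=1) imputation, standardisation to mean 0 / SD 1, and confound
   regression (age, sex, site, …).
3. **PCA–CCA** — each block is reduced to the smallest number of principal
   components cumulatively explaining 80% of its variance; canonical
   correlation analysis of the two score matrices yields modes with
   correlations ρ₁ ≥ ρ₂ ≥ … and subject-level canonical variates.
4. **Inference** — family-wise error control by a max-statistic
   permutation test: subject rows of one block are permuted B times
   (default 100,000), the largest canonical correlation of each
   permutation forms the null, and every observed mode is compared to it
   (plus-one p-values, α = 0.05).
5. **Interpretation** — for each significant mode, the two variates are
   averaged, correlated with the original (non-reduced) processed
   variables, reported only where |r| ≥ 0.2, and edge loadings are
   multiplied by the sign of the population-mean connectivity so that a
   positive value always reads "stronger connection in high-scoring
   subjects".  Variance explained per mode is 100·ρ².

Because the cohorts this method targets are access-restricted, the package
ships a synthetic population generator with *known ground truth*: two
blocks sharing K latent modes of specified canonical correlation, plus
confound contamination, missingness, outliers, and per-subject time
series drawn from known precision matrices.  Every stage is tested
against that ground truth or an independent oracle.

## Worked example

Plant two modes with canonical correlations 0.5 and 0.3 in a cohort of
2000 subjects (10 edges × 20 phenotypes, 2% missing cells, 1% outliers,
age/sex/site confounds) and recover them:

```yaml
# example.yaml
synthetic: true
n_subjects: 2000
p: 10
q: 20
rho: [0.5, 0.3]
variance_target: 1.0
n_permutations: 999
seed: 7
```

```text
$ modecca run --config example.yaml --out results
significant modes: 2
  mode 1: r=0.4784 p=0.001 variance explained=22.89%
  mode 2: r=0.2869 p=0.001 variance explained=8.23%
total variance explained: 31.11%
```

Exactly the two planted modes are declared significant: their estimated
canonical correlations (0.478, 0.287) sit near the planted (0.5, 0.3) —
slightly attenuated by the injected outliers, imputation noise and
deconfounding — and the third sample correlation (0.146) is correctly
absorbed by the permutation null (p = 0.806).  The smallest attainable
p-value at B = 999 is 1/1000.  The results directory contains the
processed tables, PCA/CCA summaries, the null distribution, per-mode
loading reports, an edge list for graph rendering, and a `manifest.json`
from which the run can be reproduced bit for bit.

The same analysis is available as a library:

```python
from modecca import PipelineConfig, run
res = run(PipelineConfig(synthetic=True, n_subjects=2000, p=10, q=20,
                         rho=[0.5, 0.3], variance_target=1.0,
                         n_permutations=999, seed=7), outdir="results")
res["model"].correlations_    # canonical correlations
res["pvalues"]                # family-wise corrected p-values
res["reports"][0].edge_loadings  # sign-adjusted thresholded loadings
```

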
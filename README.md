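# distage

Screening for age-related changes in **single-cell gene expression
distributions**. Classical age-association analysis correlates a gene's
mean expression with donor age and is blind to any change that leaves the
mean alone — variance growth, shifting mixture fractions of positive and
negative cells, tail behaviour. `distage` treats each donor's single-cell
expression profile of a gene as a probability distribution and asks whether
the *distribution itself* drifts monotonically with age.

For every gene g and donor pair (s, t):

1. pool the two samples' values and lay k = 1000 equally spaced grid points
   across the pooled range;
2. estimate each sample's Gaussian-kernel density on that shared grid and
   renormalise to a probability mass function;
3. score the pair with the Hellinger distance
   H(P,Q) = (1/√2)·√Σ_m (√P_m − √Q_m)².

This fills a sample × sample distance matrix D_g; a second matrix holds the
absolute age differences |age_s − age_t|. The gene's score is Spearman's ρ
between the upper triangles of the two matrices, its significance a
one-sided Mantel permutation test (1000 permutations by default), with
Benjamini–Hochberg adjustment across genes and a ρ > 0.85 classification
cutoff. Jensen–Shannon and Kolmogorov–Smirnov distances are drop-in
alternative metrics; a pseudo-bulk comparator (Spearman of per-sample mean
expression vs age) shows what a mean-based screen would see. A built-in
simulator generates the three-pattern validation data (per-cell σ
monotonic / non-monotonic / stable in age) with ground-truth labels.

Inputs: a cells × genes matrix with per-cell sample labels and per-sample
donor ages, as an `.h5ad` file, a MatrixMarket directory, or a dense TSV
directory. Values are used as given — preprocessing/normalisation is
assumed done upstream.

## Worked example

```python
import numpy as np
from distage import default_config, simulate_dataset, run_workflow

cfg = default_config(n_genes=6, fraction_monotonic=1/3, fraction_nonmonotonic=1/3,
                     samples_per_age=5, cells_per_sample=300, seed=11)
sim = simulate_dataset(cfg)
table = run_workflow(sim.dataset, metric="hellinger", n_perm=500, seed=1)
print(table.join(sim.true_pattern.reset_index(drop=True)).round(4).to_string(index=False))
```

```
  gene_id     rho  mantel_p  adjusted_p  n_samples  n_permutations    metric  passed_cutoff true_pattern
gene00000  0.9046    0.0020      0.0060         20             500 hellinger           True    monotonic
gene00001  0.8602    0.0020      0.0060         20             500 hellinger           True    monotonic
gene00002  0.2304    0.0220      0.0329         20             500 hellinger          False nonmonotonic
gene00003  0.3324    0.0080      0.0160         20             500 hellinger          False nonmonotonic
gene00004 -0.0215    0.5848      0.5848         20             500 hellinger          False       stable
gene00005 -0.0217    0.5609      0.5848         20             500 hellinger          False       stable
```

The two genes whose per-cell spread grows monotonically with age score
ρ ≈ 0.86–0.90 at the Mantel permutation floor (p = 1/501) and gene00000
clears the 0.85 cutoff; the non-monotonic genes score moderately; the
stable genes sit at ρ ≈ 0 with large p. None of this is visible to the
mean: `pseudobulk_correlation(sim.dataset)` returns correlations scattered
around zero for all six genes (−0.34 … 0.53 here), because the simulated
means do not depend on age.

The same analysis from the shell:

```sh
distage simulate --n-genes 200 --samples-per-age 10 --cells-per-sample 1000 \
                 --seed 1 --out sim_dir
distage analyze --input sim_dir --format dense_tsv --metric hellinger \
                --n-perm 1000 --seed 1 --top-genes 0 --out results.tsv
distage plot --kind score_histogram --input results.tsv --out scores.png
```

For real data, e.g. an annotated `.h5ad` with per-cell `mouse.id`, `age`
and `sex` columns:

```sh
distage analyze --input tissue.h5ad --sample-key mouse.id --age-key age \
                --subset "sex == 'male'" --top-genes 3000 --out results.tsv
```

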
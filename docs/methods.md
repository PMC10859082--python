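# Methods

## The model

For a gene g and a donor (sample) s, the single-cell expression values of g
in the cells of s are treated as draws from an unknown distribution F_{g,s}.
The question is whether F_{g,s} changes monotonically with the donor's age —
in location, spread, shape, or mixture composition — without assuming any
parametric form of the change.

The procedure, per gene:

1. **Pairwise pooled-grid PMFs.** For each unordered sample pair (s, t), the
   two raw value vectors are pooled; k = 1000 equally spaced grid points are
   laid from the pooled minimum to the pooled maximum (endpoints inclusive,
   no tail padding). Each sample's Gaussian kernel density is evaluated on
   that shared grid and renormalised to sum to 1, giving discrete PMFs
   P and Q on identical support. Grids are deliberately pair-specific.
2. **Distribution distance.** The Hellinger distance
   H(P,Q) = (1/√2)·√Σ_m (√P_m − √Q_m)² fills the (s,t) entry of a
   sample × sample distance matrix. Jensen–Shannon distance (sqrt of the JS
   divergence against M = (P+Q)/2, base-2 logs so the range is [0,1]) is a
   drop-in alternative on the same PMFs; the Kolmogorov–Smirnov distance is
   computed on the raw vectors instead, matching its two-sample definition.
3. **Age association.** A second matrix holds |age_s − age_t|. The score is
   Spearman's rho between the two strictly-upper-triangle vectors (average
   ranks for ties). Significance comes from a one-sided Mantel permutation
   test: rows and columns of the age matrix are permuted together and the
   statistic recomputed; p = (1 + #{perm ≥ observed}) / (1 + n_perm) with
   n_perm = 1000 by default.
4. **Across genes.** Mantel p-values are Benjamini–Hochberg adjusted, and
   genes are classified by raw rho > 0.85 (the adjusted p is reported
   alongside, not used for classification). Genes whose distance vector is
   constant (e.g. unexpressed everywhere) get rho = NaN and p = 1 rather
   than being dropped, so gene counts are stable across runs.

The Mantel statistic defaults to Spearman so that the test addresses the
same statistic that is reported as the score; Pearson is available via the
`stat` argument for users who want the classic formulation.

## Numerical choices

- **Bandwidth**: the rule-of-thumb 0.9·min(sd, IQR/1.34)·n^(−1/5). A zero
  IQR falls back to the sd; a fully constant sample falls back to
  max(1e−8, 0.01·grid range), which keeps distances well defined for
  unexpressed genes (0 between identical constants, →1 between separated
  constants).
- **KDE evaluation** uses linear binning of the values onto the k-point
  grid followed by convolution with a Gaussian kernel truncated at 8
  bandwidths. The binning error is O(δ²) in the grid spacing δ — at
  k = 1000 it is far below the Monte-Carlo noise of the samples — and it
  reduces the per-pair cost from O(n·k) to O(n + k·m), which is what makes
  the all-pairs, all-genes workload tractable.
- **Mantel permutations**: because a simultaneous row/column permutation
  only re-selects the same unordered pairs, the rank transform of the age
  matrix is permutation-invariant; each permutation therefore costs one
  re-indexing and one dot product. Permuted statistics are counted as ≥ the
  observed one with a 1e−12 tolerance so mathematically tied values are not
  lost to float noise.
- **Reproducibility**: every (gene, metric) pair gets an independent RNG
  stream seeded by (master seed, gene index, metric index), so results are
  reproducible and a single-metric run reproduces the matching table of a
  multi-metric run exactly.
- **Degenerate inputs**: if all pooled values of a pair coincide, both PMFs
  collapse to the same point mass and every PMF distance is 0; constant
  upper-triangle vectors yield the NaN/p = 1 convention above; fewer than
  3 samples is an error (the upper triangle would have < 3 entries).

## Data handling

Expression values are used exactly as given — the package applies no
normalisation, log transform, batch correction or cell-type annotation;
inputs are assumed preprocessed. Optional helpers mirror the common
screening setup: subsetting cells by any annotation (e.g. one sex, one cell
type) and keeping the union over age categories of the top-k genes by mean
expression within each age (k = 3000 by default). The union (rather than
intersection) keeps any gene that is highly expressed at some age; the
`per_age=False` flag switches to a single overall top-k.

## The simulation generator

The generator emulates the reference validation conditions: four ordered
age categories; per gene and sample i, μ_i ~ Normal(10, 0.1),
σ_i ~ Normal(σ[age_i], 0.1), cells ~ Normal(μ_i, σ_i), 10 samples per age
and 1000 cells per sample. Three per-age σ patterns define the ground
truth: monotonic (0.5, 1, 1.5, 2), non-monotonic (0.5, 1, 1, 0.5), stable
(0.5, 0.5, 0.5, 0.5); by default 5% / 5% / 90% of genes, 20,000 genes in
the reference configuration. A drawn σ_i is floored at 0.01 — at the
default parameters the floor sits more than 4.9 sampling sds below every
pattern mean, so it essentially never binds but keeps the generator total.
Pattern labels are assigned in deterministic blocks for reproducible
fixtures; `shuffle_patterns=True` randomises their placement.

What the generator does *not* emulate: counts (values are real, can be
negative), zero inflation and dropout, cell-type mixtures, mean shifts with
age, and donor-level covariates. Passing the simulation checks therefore
demonstrates that the statistical machinery detects distributional (here:
variance) change against age under clean sampling noise; it does not by
itself validate behaviour on raw UMI counts or confounded designs.

## Problem sizes used in tests and the acceptance script

The shipped study runs the generator at 200 genes (10 monotonic / 10
non-monotonic / 180 stable) with the full per-gene sampling depth
(4 ages × 10 samples × 1000 cells) and 200 Mantel permutations — enough
genes per pattern for stable medians while keeping a laptop-friendly
runtime. Expected outcomes: median rho ordering monotonic > non-monotonic >
stable with the stable median within ±0.1 of zero; monotonic Mantel p
concentrated at the permutation floor and stable p approximately uniform;
pseudo-bulk correlations (Spearman of per-sample means vs age) centred on
zero for all patterns, since the simulated signal is purely in the
variance.

## Known limitations

- Only genes expressed well enough for density estimation carry signal;
  the top-k mean-expression filter reflects that.
- The score is a correlation of distances: it flags association, not the
  kind of change; histograms/QQ plots (the `reporting` module) are the
  intended follow-up for interpreting hits.
- Hellinger and JS ranks agree almost perfectly (they are computed from
  the same PMFs); KS ranks agree strongly on genes with signal but add
  independent noise on null genes, so whole-screen rank concordance with
  KS is a little lower when most genes are null.
- The O(n_samples²) pairwise KDE per gene dominates runtime; the
  implementation mitigates but does not remove it.
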
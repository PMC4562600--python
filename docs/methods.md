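# Methods

## Model and objective

Input is a genes × samples matrix of raw read counts with a two-class
sample labelling (control = the first class encountered). Counts are
depth-normalized by median-of-ratios size factors — for sample *j*, the
median over all-positive genes of `count_ij / geomean_i` — and
transformed to `V_il = log2(count_il / sf_l + pseudocount)`. The
pseudocount defaults to 1, which guarantees `V ≥ 0`; smaller values are
accepted only when the result stays nonnegative, since the factorization
requires a nonnegative input. The log transform matters beyond
nonnegativity: it turns the between-class *differences* the Fisher
penalty works with into fold-change contrasts, and it keeps highly
expressed genes from dominating the reconstruction loss.

The factorization `V ≈ W H` (W: genes × K, H: K × samples, everything
nonnegative, each W column summing to one) minimizes

    F(W,H) = D_KL(V ‖ WH) + γ·tr(S_w) − δ·tr(S_b)

with the generalized KL divergence `D_KL = Σ v ln(v/x) − v + x`
(natural logarithm; `0·ln 0 = 0`) and the Fisher scatter matrices of H's
per-sample coefficient columns:

    S_w = Σ_r Σ_{ρ∈r} (η_ρ − μ^(r))(η_ρ − μ^(r))ᵀ
    S_b = Σ_r N_r (μ^(r) − μ)(μ^(r) − μ)ᵀ

`μ^(r)` is the mean coefficient vector of class *r* and `μ` the grand
mean over all L samples (so unequal class sizes are weighted by sample
count). KL loss suits count-derived data, whose noise is
Poisson-family; the penalty compresses within-class scatter and rewards
between-class separation of the sample coefficients.

## Updates

Each iteration applies the **W step** then the **H step**:

* W step: `w_ik ← w_ik · Σ_l (V_il/(WH)_il) h_kl`, then each column is
  divided by its sum. The normalization is part of the model (it fixes
  the scale gauge of the factorization and makes the leading coefficient
  of the H step exact); update-plus-normalization is the simplex-
  constrained KL-NMF step, so it cannot increase the loss.
* H step: every entry `h_kl` (sample *l* in class *r*) is replaced by the
  nonnegative root of `a h² + b h + c = 0` with

      a = 2γ + 2δ/L − (2γ + 2δ)/N_r
      b = 1 + (2δ/L)·Σ_{j≠l} h_kj − ((2γ+2δ)/N_r)·Σ_{λ≠l, λ∈r} h_kλ
      c = −h_kl · Σ_i V_il w_ik / (WH)_il ≤ 0

  These coefficients come from differentiating the penalized auxiliary
  function, holding all other entries at their current values and using
  the grand mean `μ_k = (1/L)Σ_j h_kj`; the leading 1 in `b` is
  `Σ_i w_ik` in the normalized gauge. Since `a > 0` whenever each class
  has at least two samples (for the default γ ≫ δ) and `c ≤ 0`, the
  discriminant `b² − 4ac ≥ b²` and the root
  `(−b + √(b²−4ac))/(2a)` is the unique nonnegative solution; it is
  evaluated in the cancellation-free form `−2c/(b + √(b²−4ac))`. With
  γ = δ = 0 the equation is linear and the update is exactly the
  Lee–Seung KL rule — the reduction the test-suite exploits as an
  independent oracle.

A floor of `eps = 1e-16` is added to `(WH)_il` and to column sums before
division. Iteration stops when the relative objective change drops below
`tol` (default 1e-6) or after `max_iter` (default 1000) iterations. Note
the objective can be negative (the `−δ·tr(S_b)` term has no lower-bound
role at the default δ), so the relative-change criterion uses
`|Δ|/max(|obj|, tiny)`.

### Initialization and degeneracy

W and H start uniform(0,1) from a seeded generator; then the scalar sum
S of all H entries is added to `H[k, samples of class k]` (this requires
K = number of classes). Because S exceeds every individual entry, each
metagene row starts strictly dominant on its own class, which empirically
stabilizes which metagene tracks which condition. For ranking, K = 2.

A converged fit is *oriented* by class means: row *k* of H is
down-regulated if its control mean exceeds its treatment mean,
up-regulated in the opposite case. If both rows land on the same side, or
any class means tie exactly, the orientation is degenerate and the fit is
rerun from a fresh seed (`seed + rerun index`), up to `max_reruns`
(default 10) attempts before a hard error. Single-class inputs are
rejected outright.

## Ranking and permutation test

`d_i = W[i, up] − W[i, down]`; genes are sorted by `d` descending, ties
broken by input order (stable sort). Sign gives direction; magnitude
orders strength. The `.rnk` export (two tab-separated columns, no
header) feeds preranked gene-set enrichment directly.

P-values follow the pooled permutation scheme: all n·2 entries of W are
shuffled jointly B = 1000 times, each shuffle reshaped into two columns
and differenced, and

    p_i = (1/(nB)) Σ_b Σ_j 1[ |d_i| < |d^b_j| ].

**Calibration caveat.** This null discards the within-gene pairing of
the two weights: both columns of W track each gene's overall expression
share, so observed `|d_i|` are small within-gene differences while the
permuted `|d^b_j|` are differences of two *random* genes' weights, whose
spread is dominated by between-gene expression variation. On null
simulations the pooled p-values are therefore strongly conservative
(median ≈ 0.7, ≈0.1% of genes below 0.05 instead of 5%), not uniform.
They are useful as a conservative screen and for ordering, but should
not be treated as calibrated frequentist p-values; the ranking statistic
`d` itself, not p, is the intended primary output. No multiple-testing
correction is applied by default.

## Synthetic data

The simulator emulates a two-condition bulk RNA-seq comparison:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 1000 | endogenous transcripts |
| `n_per_class` | 5 | replicates per condition |
| `de_fraction` | 0.1 | fraction of genes with planted signal |
| `logfc_values` | {2} | planted \|log2FC\| magnitudes, sign randomized |
| `base_mean_range` | 10–10⁴ | log-uniform baseline expression means |
| `dispersion` | 0.1 | NB dispersion α (variance m + αm²); 0 → Poisson |
| `size_factor_range` | 0.5–2 | log-uniform per-sample depth factors |
| `spikein_count` | 93 | spike-in panel size |
| `spikein_subgroup_logfc` | 2, 0, −0.58, −1 | four subgroup fold changes |

Counts are NB with mean `sf_j · q_i · 2^{lfc_i}` (fold-change term in the
treatment class only). Spike-ins are split as evenly as possible over the
four subgroups (93 → 24/23/23/23, remainder to the leading groups) with
fixed subgroup fold changes; their baseline abundances are drawn like
gene abundances. The truth table records per-row log2FC, DE flag,
spike-in flag and subgroup.

What the simulator does **not** model: transcript-length and GC bias,
batch/flow-cell effects, correlated gene modules, outlier samples, and
library-preparation artefacts. Passing benchmarks on this generator
therefore demonstrates correctness of the algorithm and its ranking
behaviour under idealized count noise, not performance on any particular
real dataset.

## Evaluation

AUC is computed in the Mann–Whitney rank formulation (ties at half
credit) of `|d|` against the binary truth `|true log2FC| ≥ t`, at the
canonical cutoffs t ∈ {0.58, 1, 2} and over the 0.5–2 sweep in 0.1
steps; thresholds that empty a class are flagged undefined rather than
scored 0. The MA export gives per-gene A (mean log2 expression), M
(treatment − control class-mean difference) and a top-k flag by |score|
(default k = 1000) for expression-bias diagnostics.

Measured on the reference simulation (seed 1, 1000 genes + 93 spike-ins,
5 per class): AUC ≈ 0.98 at t = 0.58 and ≈ 0.998 at t = 2, with 100%
sign agreement on the |log2FC| = 2 genes — the numbers
`scripts/acceptance.py` recomputes on every run.

## Design choices and limitations

* Natural log in the KL loss; only relative objective values depend on
  the base.
* The W update precedes the H update so the H step's leading `b`
  coefficient (which assumes `Σ_i w_ik = 1`) is exact each iteration.
* Size factors use the natural-scale median of ratios, excluding genes
  whose geometric mean is zero; a matrix in which every gene contains a
  zero is rejected with advice to filter or add pseudo-counts.
* K > 2 is supported by the factorization core (with purely random
  initialization), but orientation, ranking and the permutation test are
  defined for K = 2 with two classes.
* Multi-factor designs and unreplicated designs are out of scope; at
  least two samples per class are required.
* Problem sizes in the test-suite and acceptance script (1000-gene
  simulations, 200-iteration monotonicity runs, B = 1000 permutations)
  were chosen to exercise every code path at full fidelity while keeping
  a complete run in the order of seconds.
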
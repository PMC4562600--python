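# dnmfrank

Gene ranking for two-condition RNA-seq experiments via **discriminant
non-negative matrix factorization** (DNMF).

Differential-expression tools usually reduce an experiment to a list of
genes passing a significance cutoff, discarding the information carried by
every other gene. Rank-based downstream analyses — gene set enrichment in
particular — instead want a complete, well-ordered gene list. `dnmfrank`
produces that list directly from a count matrix: it factorizes the
expression data into exactly two *metagenes*, one capturing the
up-regulated and one the down-regulated expression pattern, and orders
genes by the difference of their weights in the two.

## The model

Let `V` (genes × samples) be the depth-normalized, log-transformed
expression matrix, `V ≈ W H` with nonnegative `W` (genes × 2, columns
summing to one) and `H` (2 × samples). The fit minimizes the generalized
Kullback–Leibler divergence penalized by Fisher's discriminant criterion
on the per-sample coefficient columns of `H`:

```
F(W, H) = Σ_il [ V_il ln(V_il/(WH)_il) − V_il + (WH)_il ]
          + γ·tr(S_w) − δ·tr(S_b)
```

where `S_w` and `S_b` are the within- and between-class scatter matrices
of `H`'s columns, and `γ = 0.1`, `δ = 10⁻⁴` by default. Optimization uses
multiplicative updates: the standard KL-NMF rule with column
normalization for `W`, and a per-entry quadratic root for `H` that
carries the penalty terms (with `γ = δ = 0` both reduce exactly to
Lee–Seung KL-NMF). A class-seeded initialization of `H` anchors one
metagene per condition.

After orienting the metagenes by their class means (the row higher in the
treatment class is up-regulated), each gene gets the signed statistic

```
d_i = W[i, up] − W[i, down]
```

Genes sorted by `d` descending form the ranking (top = most up-regulated,
bottom = most down-regulated). An empirical P-value per gene is computed
by jointly shuffling all entries of `W` `B = 1000` times and pooling the
permuted column differences across genes.

The package also ships a negative-binomial two-class count simulator with
planted fold changes and a 93-transcript spike-in panel (four subgroups
at log2FC 2, 0, −0.58, −1), plus an AUC benchmark harness, so the whole
method is testable without any external data.

## Worked example

```sh
dnmfrank simulate --n-genes 500 --n-per-class 5 --seed 42 --out-dir demo
# wrote 593 x 10 counts (120 DE, 93 spike-ins) to demo
dnmfrank rank demo/counts.tsv --labels demo/labels.tsv --seed 42 --out-dir demo
# seed=42 iterations=1000 reruns=0 converged=False objective=-273.7
# wrote demo/ranking.tsv and demo/ranking.rnk
dnmfrank evaluate demo/ranking.tsv demo/truth.tsv --out-dir demo
#  threshold      auc  n_positive  n_negative  defined
#       0.58 0.952555         120         473     True
#       1.00 0.979485          97         496     True
#       2.00 0.997136          74         519     True
```

The simulation plants 120 differentially expressed transcripts among 593;
the evaluate step scores `|d|` against the known |log2 fold change| at
the three canonical cutoffs — here the ranking separates true DE genes
from null genes with AUC 0.95–0.997, tightening as the cutoff (and hence
the planted effect size) grows. The head of the ranking table shows the
strongest up-regulated genes with their statistic and permutation
P-value:

```
gene_id      d          rank  direction  p_value
gene_00231   0.0031663  1     up         0.0018
spikein_010  0.0031659  2     up         0.0018
spikein_017  0.0030569  3     up         0.0027
```

`demo/ranking.rnk` is the same ordering in the headerless two-column
format that GSEAPreranked consumes.

The same pipeline is available as a library, scikit-learn style:

```python
from dnmfrank import DNMFRanker, simulate_counts

counts, truth, labels = simulate_counts(n_genes=500, seed=42)
ranker = DNMFRanker(random_state=42)
table = ranker.fit_predict(counts.values.T, labels.indices(counts.sample_ids),
                           gene_ids=counts.gene_ids)
```

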
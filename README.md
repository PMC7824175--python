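# topoga

Genetic-algorithm selection of fixed-size marker-gene panels for spatial
mapping of single-cell transcriptomes onto a binary in situ reference atlas.

## The problem

Dissociation-based single-cell RNA-seq destroys spatial context. When a
reference atlas is available — a set of spatial bins, each with 3-D
coordinates and a binarized in situ expression profile over a panel of
*driver genes* — each sequenced cell can be mapped back to space by scoring
it against every bin. Here a cell's expression is binarized gene-wise at the
0.23 quantile and each cell–bin pair is scored by the Matthews correlation
coefficient (MCC) of the two binary gene vectors, giving a cells × bins
score matrix. Mapping with the **full** driver panel yields the
gold-standard matrix **M**.

In situ hybridization is expensive, so a natural question is how few genes
suffice: find a subset of size *n* whose score matrix **N** best reproduces
**M**. `topoga` frames this as combinatorial optimization and solves it with
a genetic algorithm over fixed-length chromosomes of distinct gene indices.
Candidate subsets are judged by the geometric mean of four discrepancy
metrics, each minimized when **N** = **M**:

| metric | meaning |
|--------|---------|
| s1 | root-mean-square deviation between **N** and **M** |
| s2 | 2 − mean per-cell Spearman correlation of bin scores |
| s3 | 2 − mean recovery of the gold best bin among the subset's top-k bins |
| s4 | mean Euclidean distance between gold and subset best-predicted bins |

The package also provides variance- and network-degree-based baseline
selectors, two location-assignment strategies (top-k MCC bins, or best bin
plus its geometric nearest neighbours), hypergeometric annotation-term
enrichment with Benjamini–Hochberg correction for re-prioritizing candidate
panels, and a synthetic half-embryo generator so everything can be exercised
without downloading any dataset.

## Worked example

Generate a synthetic instance, select a 6-gene panel, and place a cell:

```python
import topoga as tg

cfg = tg.SyntheticConfig(
    n_bins=100, n_cells=150, n_informative_genes=12, n_noise_genes=6,
    dropout_rate=0.1, flip_rate=0.01, seed=7,
)
atlas, geometry, expression, truth = tg.make_instance(cfg)

evaluator = tg.build_evaluator(atlas, geometry, expression)
trace = tg.evolve(evaluator, tg.GAConfig(
    n=6, pop_size=100, n_crossovers=40, max_generations=60,
    plateau_patience=20, strict_pool=True, seed=0,
))

panel = evaluator.gene_set(trace.best)
print("selected panel:", list(panel))
fv = trace.best.fitness
print(f"s1={fv.s1:.4f} s2={fv.s2:.4f} s3={fv.s3:.4f} "
      f"s4={fv.s4:.4f} composite={fv.composite:.4f}")

scores = tg.map_cells(tg.binarize_cells(expression, panel), atlas, panel)
table = tg.assign_tn(scores, geometry, k=10)
print("cell_0000 placed at bins:", table.bins[0].tolist())
```

Output:

```
selected panel: ['info_blob_008', 'info_blob_005', 'info_gradient_000',
                 'info_stripe_004', 'info_gradient_003', 'noise_005']
s1=0.3517 s2=1.4085 s3=1.4333 s4=0.9707 composite=0.9112
cell_0000 placed at bins: [23, 96, 72, 47, 32, 66, 93, 11, 1, 79]
```

The run converges in 25 generations (449 distinct subsets evaluated) and
recovers 5 of the 6 panel slots from the 12 truly informative genes.

On the reference recovery benchmark (200 bins, 300 cells, 20 informative +
20 decoy genes, dropout 0.2, flip 0.02), a 10-gene GA selection reaches
composite fitness 0.881, versus 0.983 for the mean of 100 random 10-gene
subsets and 1.049 for a decoy-only subset, and recovers 8–10 informative
genes across seeds with a composite-fitness coefficient of variation of
0.12% over 5 seeds.

## Command line

Every stage is also exposed through the `topoga` CLI:

```bash
topoga simulate --seed 7 --out demo/                  # synthetic instance
topoga select --dge demo/dge.tsv --atlas demo/atlas.tsv \
    --geometry demo/geometry.tsv --n 6 --seed 0 --out demo/run/
topoga assign --dge demo/dge.tsv --atlas demo/atlas.tsv \
    --geometry demo/geometry.tsv --genes demo/run/genes_n6.txt \
    --strategy tn --out demo/run/assignment.tsv
```

`topoga select` writes the gene set, a per-generation fitness trace, and a
JSON run manifest (configuration, seed, input digests) that makes the run
bit-for-bit reproducible. `topoga map`, `fitness`, `baseline`, `compare`
and `report` cover the remaining workflows; see `--help` on each.

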
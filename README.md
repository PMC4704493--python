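# mimictox

Analysis toolkit for genome-scale **miRNA-mimic toxicity screens** in
cancer cell-line panels.

Gain-of-function screens transfect a library of synthetic miRNA mimics
(here, 400 mimics) into each line of a tumor cell panel (here, 16
epithelial ovarian cancer lines) in biological triplicate and read out
viability by luminescence. The analytical questions — which mimics are
selectively toxic, whether toxicity is "private" (1–2 responsive lines)
or "public" (many lines), which phenotype clusters exist, which gene
targets explain a mimic's toxicity, and whether a miRNA's expression
stratifies patient survival — are what this package answers. It is aimed
at functional-genomics analysts who have plate-level screen data (or want
a fully synthetic test-bed) and need a reproducible, tested pipeline.

## What it computes

- **Screen processing** (`mimictox.screen`). Each well in a plate row is
  normalized to the row median (removing position and batch effects),
  triplicates are averaged, and each cell line's mean-viability vector is
  standardized: `z = (x − mean) / sd` (sample SD). Hits are cells with
  `z ≤ −2`. Summaries: responsiveness histogram, fraction of private
  hits, unique mature sequences among hits, and the three screen-quality
  SD distributions (across-panel, within-seed-family, within-replicate)
  with Gaussian KDEs.
- **Affinity-propagation clustering** (`mimictox.apcluster`), implemented
  from the message-passing update rules: responsibility
  `r(i,k) ← s(i,k) − max_{k′≠k}{a(i,k′) + s(i,k′)}`, availability
  `a(i,k) ← min{0, r(k,k) + Σ_{i′∉{i,k}} max(0, r(i′,k))}`, and
  self-availability `a(k,k) ← Σ_{i′≠k} max(0, r(i′,k))`, with damping;
  exemplars are points with `r(k,k) + a(k,k) > 0`. The procedure is
  iterated hierarchically: exemplars are re-clustered until no further
  merging occurs. Similarities: negative Euclidean distance or Pearson
  correlation; preference defaults to the median off-diagonal similarity.
- **Enrichment and target inference** (`mimictox.enrichment`). Exact
  upper-tail hypergeometric overlap tests; probability-of-downregulation
  curves over TargetScan-style context-score bins (a gene is "down" at
  log2 ratio ≤ −1 for the default 2-fold threshold); and the dual-pool
  phenocopy rule that nominates a predicted target when its siRNA
  toxicity profile is positively correlated with the mimic profile with
  `r² > 0.35` in **both** independent reagent pools, after an activity
  filter (relative viability < 0.5 in the index line).
- **Survival cutoff scan** (`mimictox.survival`). A cohort is split 2/3
  training / 1/3 validation; every integer expression percentile in
  [25, 75] is tried as a cutpoint on the training set with the log-rank
  test; training-significant cutoffs (p < 0.05) are re-tested at the same
  absolute expression value in the validation cohort, with Kaplan–Meier
  medians per arm.
- **Feature preparation** (`mimictox.genomics`). Top-variance gene
  filtering for expression clustering and read-depth-ratio copy-number
  calls (gain at ratio ≥ 1.5, loss at ≤ 0.5).
- **Synthetic data** (`mimictox.simulate`). Seeded generators for every
  input above, with ground truth returned alongside, so the whole
  pipeline runs and is scored without any external download.

## Worked example

```python
from mimictox import simulate, screen, apcluster

plates, truth, ann = simulate.simulate_screen(seed=1)   # 400 mimics x 16 lines x 3
normed = [screen.normalize_row_median(p) for p in plates]
mean, sd, n = screen.aggregate_replicates(normed, exclude=("miR-NC",))
zm = screen.compute_zscores(mean)
hits = screen.call_hits(zm, threshold=-2.0)
summary = screen.responsiveness_summary(hits, n_lines=16)
print(f"hit mimics: {summary.n_hit_mimics}")
print(f"unique mature sequences: {screen.collapse_unique_mature(hits, ann)}")
print(f"private (1-2 lines): {100 * summary.fraction_private:.1f}%")
hierarchy = apcluster.hierarchical_ap(zm.z.T)
print(f"cell-line clusters: {len(hierarchy.levels[0].exemplars)}")
```

prints

```
hit mimics: 108
unique mature sequences: 103
private (1-2 lines): 80.6%
cell-line clusters: 5
```

meaning 108 of the 400 mimic reagents (103 distinct mature sequences)
were toxic (`z ≤ −2`) in at least one line, about 80% of them in only one
or two lines — the private-vulnerability architecture the generator
plants — and hierarchical affinity propagation on the z-matrix recovers
the five planted cell-line response groups.

The same chain is available from the shell:

```sh
mimictox simulate  --out-dir run --seed 1
mimictox normalize --out-dir run
mimictox zscore    --out-dir run
mimictox hits      --out-dir run
mimictox cluster   --out-dir run
mimictox report    --out-dir run     # responsiveness summary table
```

Every stage writes a manifest (parameters, input/output digests, seed,
version) under `run/manifests/`. `mimictox config init` dumps the full
default configuration as YAML.

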
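# striatlas

Integrative analysis of the striatal epigenome in a CAG-knockin (Q140)
Huntington's disease mouse model — as a tested, reusable Python pipeline.

In the diseased striatum, neuronal identity genes and their super-enhancers
lose H3K27ac while glial enhancers gain it, the same sign structure that
normal aging shows; the mutation accelerates it. Testing that claim takes a
chain of machinery: broad-domain ("island") detection on binned ChIP-seq
coverage, count-based differential enrichment, a cell-type-specific
enhancer catalogue from sorted NeuN⁺/NeuN⁻ nuclei, attribution and
age-by-genotype concordance statistics, gene-body epigenetic profile
clustering with enrichment tests of dysregulated genes, 4C-seq interaction
calling, and 4C-derived 3D bead models with insulation-score TAD-boundary
detection. `striatlas` implements each stage as a library function (plus a
thin CLI) and ships a synthetic-data generator that plants ground truth so
every stage has a parameter-recovery test.

## The statistics at the core

* **Islands**: windows of width w are *eligible* when P(X ≥ c; λ) < p₀
  under a global Poisson background λ; islands are gap-tolerant runs of
  eligible windows scored by Σ −ln P(c; λ) and filtered so the expected
  number of equally scoring null islands per genome is ≤ E (defaults
  w = 200 bp, E = 0.003, gaps 1000/600/1400 bp for H3K27ac/RNAPII/H3K27me3).
* **Differential enrichment**: a negative-binomial Wald test on
  background-equalized (median-of-ratios) normalized counts, with a
  trended, moderated variance; `dispersion=0` degenerates to the exact
  conditional Poisson (binomial) test used for the NeuN⁺ vs NeuN⁻ contrast
  at p < 10⁻¹⁵.
* **Enrichment tests**: two-sided exact binomial against universe
  composition (k-means cluster shares, chromosome shares, neuronal share of
  cell-type-specific genes), Bonferroni or BH corrected.
* **4C**: DpnII/Csp6I fragment maps, quantile normalization, 21-fragment
  running-mean smoothing, interaction calling against an isotonic
  (monotone-decay) background with cross-sample reproducibility, and
  paired/unpaired t-tests on region means.
* **3D**: bait-bead distance restraints d ∝ s^(−1/α) fitted by multi-restart
  distance-geometry optimization; virtual Hi-C distance matrices; insulation
  I(k, b) = mean 1/(d+ε) over the b × b square crossing k, aggregated over
  b = 4..30 and minimized to call TAD boundaries.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Run the full synthetic study — simulate tracks, call islands, build the
catalogue, test both contrasts, attribute, cluster, and test enrichment:

```python
from striatlas.pipeline import accelerated_aging_study

res = accelerated_aging_study(seed=1)
for key in ("n_universe_regions", "frac_down_neuronal", "frac_up_glial",
            "spearman_rho", "neuronal_cluster_adj_p"):
    print(key, res.summary[key])
```

prints

```
n_universe_regions 386
frac_down_neuronal 0.9157894736842105
frac_up_glial 0.9393939393939394
spearman_rho 0.9128474084669328
neuronal_cluster_adj_p 2.5775914986695137e-11
```

Reading: of 386 high-confidence H3K27ac regions, the regions losing the
mark in the mutant are 92% neuronal-specific and the regions gaining it are
94% glial-specific; genotype and age fold-changes agree with Spearman
ρ = 0.91 (the accelerated-aging signature); and the top downregulated genes
are enriched in the neuronal-archetype k-means cluster at Bonferroni-
adjusted p far below 0.05 — recovering the planted structure end to end.

The same stages are scriptable from the shell:

```bash
striatlas simulate --seed 1 --out sim/
striatlas islands call --track sim/H3K27ac_bulk_WT_2mo_rep1.bedgraph \
    --mark H3K27ac --seed 1 --out islands.bed
striatlas threed insulation --matrix vhic.tsv --bmin 4 --bmax 30 --out ins.tsv
```

Every stage is byte-deterministic under a fixed `--seed`.

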
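# otunet

Diversity and co-occurrence network analysis for OTU count tables, with a
synthetic-data generator that plants the statistical structure the analysis
is supposed to detect.

## Who this is for

Microbiome studies that compare gut (or other) bacterial communities across
host groups — for example, bird species fed different diet types — typically
run the same downstream recipe on a sample × OTU count table: rarefy, compute
alpha and beta diversity, test group structure by permutation, attribute
community distances to host covariates, and build a correlation network of
co-occurring taxa. `otunet` implements that recipe as a tested, seeded,
scriptable library, and — because the raw data behind published tables are
rarely re-processable at desk scale — ships a generator that produces tables
with *known* planted structure, so every stage can be validated end to end.

## What it computes

**Alpha diversity** per sample: bias-corrected Chao1
`S_obs + F1(F1−1)/(2(F2+1))`, Shannon entropy `−Σ p_i ln p_i`, and Faith's
phylogenetic diversity (total branch length of the rooted subtree spanning
the observed taxa). Group differences use a two-sided permutation test on the
Welch t statistic.

**Beta diversity**: Bray-Curtis dissimilarity `d(x,y) = Σ|x_i−y_i| / Σ(x_i+y_i)`,
classical PCoA (Gower double-centering, negative eigenvalues reported but
excluded from variance denominators), single-factor PERMANOVA
(pseudo-F from Anderson's sum-of-squared-distances partition, label
permutation, `p = (#{F_perm ≥ F_obs}+1)/(B+1)`), UPGMA dendrograms, and
Mantel tests between distance matrices (diet as one-hot Euclidean distances;
host phylogeny as patristic distances expanded to samples).

**Co-occurrence network**: OTUs below 0.01% mean relative abundance are
removed; pairwise Spearman ρ (midranks, t-approximation p-values) is
thresholded at `|ρ| ≥ 0.6` and Benjamini-Hochberg-adjusted `p < 0.01`;
connected components with fewer than 4 nodes are pruned; the surviving graph
is decomposed into subcommunities (SCs). Per sample and SC the pipeline
reports completeness (`100 × members present / SC size`) and richness (summed
relative abundance of members), compared between groups by Wilcoxon rank-sum
tests with BH adjustment over the whole family.

**Generator**: a latent-factor log-normal–multinomial model — per-OTU
baseline log-abundances, per-block latent Gaussian factors inducing a chosen
within-block correlation (one pair may be anti-correlated), diet-group
log-fold effects, a Brownian-motion host-phylogeny effect, log-normal
sequencing depths, and multinomial counts. Sparsity is calibrated so a target
fraction of detectable OTUs is rare. Ground truth (block membership, effect
sets, the host tree) is returned for recovery scoring.

## Worked example

Run the full analysis on a simulated study-scale dataset (128 samples,
2,400 OTUs, 7 diet groups):

```python
from otunet.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(simulate={}, rarefaction_depth=5000, seed=1,
                        out_dir="out")
report = run_pipeline(config)
print(report.headline)
```

which prints (seed 1):

```
{'samples_analyzed': 128,
 'otus_observed': 1356,
 'otus_after_filter': 232,
 'fraction_otus_prevalence_below_20pct': 0.9008333333333334,
 'pc1_percent_variance': 5.979323733776993,
 'permanova_r2': 0.09553726908324353,
 'permanova_p': 0.001,
 'mantel': {'diet': {'r': 0.12372547148728659, 'p': 0.0001},
            'phylogeny': {'r': 0.023415107134293334, 'p': 0.2321}},
 'network_nodes': 120,
 'network_edges': 1041,
 'n_subcommunities': 5,
 'sc_significant_comparisons': 47}
```

Reading this: after rarefying to 5,000 counts all 128 samples are retained;
90.1% of the simulated OTUs occur in fewer than 20% of samples (heavy
sparsity); diet-type group explains 9.6% of Bray-Curtis variance and is
highly significant (PERMANOVA, 999 permutations); host diet correlates with
community distances (Mantel r = 0.124, p = 0.0001) while the planted
host-phylogeny effect is too weak to reach significance at this seed
(r = 0.023, p = 0.23) — it is detected at most other seeds; the Spearman
network retains 120 of 232 filter-passing OTUs in 1,041 edges and splits
into 5 subcommunities — the generator planted 6 correlated blocks of 20
OTUs, two of which are anti-correlated and merge into one component through
their negative edges — and 47 (SC × group-pair × metric) comparisons remain
significant after BH adjustment, reflecting the planted block–diet
affinities. Per-stage tables (alpha diversity, PCoA coordinates,
network edge lists, SC statistics, a JSON run report with per-stage seeds and
counts) are written to `out/`.

The same pipeline runs from the shell:

```bash
otunet simulate --fixture tiny --seed 3 --out sim/
otunet preprocess --table sim/otu_table.tsv --depth 1000 --seed 1 --out prep/
otunet pipeline --config run.yaml
```

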
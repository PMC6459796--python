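# tssmeta

Tools for TSS-centered analysis of repressive-chromatin ChIP-seq, built
around the question of how a genotype shifts H3K27me3 (the PRC2/EZH2 mark)
over gene promoters in neurons. The pipeline consumes depth-scaled coverage
pileups (bedGraph) and UCSC refGene annotations, and provides:

- **annotations** — refGene parsing, longest-transcript-per-gene collapsing,
  strand-aware TSS coordinates (0-based; `tx_end - 1` on the minus strand);
- **coverage** — bedGraph tracks with implicit-zero semantics, scaling to one
  million mappable reads, fast interval-mean queries, and a genome-binned
  Pearson similarity between two tracks;
- **occupancy** — the genes × bins matrix of mean signal in 100-bp bins over
  ±5 kb of each TSS, rows oriented 5′→3′ per gene;
- **clustering** — k-means (k = 4 by default) on raw bin profiles, labels
  ordered from the most to the least marked class, and the application of one
  fixed partition across genotypes;
- **profiles** — per-cluster metagenes (mean ± SEM per bin) and mutant − WT
  difference profiles;
- **genesets** — neuronal gene classification from annotation-term text
  ("synapse"/"synaptic" in any branch, "neuron" in cellular component),
  per-cluster gene-set distributions, and EASE-score enrichment (the
  DAVID-style conservative Fisher variant) with Benjamini–Hochberg
  correction;
- **qpcr** — ΔΔCt relative expression for unpaired genotype designs
  (folds `2^-(ΔCt_i - ΔCt_mean)`, equal-variance Student's t) and paired
  vehicle/drug designs (folds `2^-(ΔCt_d - ΔCt_v)`, paired t vs 1);
- **simulate** — a synthetic-data generator with four occupancy archetypes
  (broad domain, strong TSS summit, weak TSS summit, unmarked), planted
  genotype amplitude effects, Poisson depth noise, and matching term and Ct
  tables, so every stage is testable offline against known ground truth.

## The model in brief

For gene *g* with TSS *t* on a depth-scaled track *s(x)*, the occupancy row
is the mean of *s* over bins of width *b* tiling *[t − W, t + W)* (defaults
*W* = 5000, *b* = 100, so *B* = 100 bins), reversed for minus-strand genes.
Rows are partitioned by Lloyd k-means (squared-Euclidean, k-means++ best of
10 restarts) and relabeled 1..k by descending cluster mean occupancy. The
partition is fit on one genotype and held fixed for the other, so cluster
metagenes (per-bin means across a cluster's genes) are directly comparable;
the mutant − WT difference profile carries SEMs added in quadrature.

Enrichment of a gene list against term sets uses the EASE score: the
one-sided Fisher/hypergeometric upper tail after decrementing the
list∩term count by one, which sends single-gene overlaps to p = 1 and is
conservative relative to plain Fisher everywhere.

## Worked example

```python
import numpy as np
from tssmeta import simulate as sim, coverage as cov, occupancy as occ, clustering as clu
from tssmeta import profiles as mg

_, models = sim.simulate_annotation(500, seed=1)
truth = sim.assign_truth(models, seed=1)
wt_raw, n_wt = sim.simulate_tracks(models, truth, "WT", seed=2)
mut_raw, n_mut = sim.simulate_tracks(models, truth, "Mut", seed=3)
wt = cov.scale_to_million(wt_raw, n_wt)
mut = cov.scale_to_million(mut_raw, n_mut)

cfg = occ.OccupancyConfig()          # +/- 5 kb, 100-bp bins
m_wt = occ.build_matrix(models, wt, cfg)
m_mut = occ.build_matrix(models, mut, cfg)

assignment = clu.kmeans_occupancy(m_wt, clu.ClusterConfig(k=4, seed=1))
print("cluster sizes:", assignment.sizes())
print("mean occupancy:", np.round(assignment.mean_occupancy, 2))

groups_wt = clu.apply_assignment(assignment, m_wt)
groups_mut = clu.apply_assignment(assignment, m_mut)
for c in (1, 2, 3):
    diff = mg.genotype_difference(mg.metagene(groups_wt[c]), mg.metagene(groups_mut[c]))
    tss = np.abs(diff.offsets) <= 500
    print(f"cluster {c}: mutant - WT at TSS = {diff.mean[tss].mean():+.2f}")
```

prints

```
cluster sizes: {1: 10, 2: 50, 3: 275, 4: 165}
mean occupancy: [7.96 2.01 1.01 0.5 ]
cluster 1: mutant - WT at TSS = +2.20
cluster 2: mutant - WT at TSS = -2.99
cluster 3: mutant - WT at TSS = -1.10
```

Cluster 1 is the small broad-domain class (highest mean occupancy), clusters
2 and 3 the strong and weak TSS-summit classes, cluster 4 the unmarked
background. The simulated genotype raises broad-domain amplitude by 30% and
lowers summit amplitude by 30%; the difference profiles recover exactly those
signs — more signal over cluster-1 promoters in the mutant, less at the TSS
of clusters 2–3.

The same pipeline is available from the shell:

```sh
tssmeta simulate --n-genes 1000 --seed 1 --outdir study/
tssmeta matrix --refgene study/refgene.txt --bedgraph study/wt.bedgraph \
        --reads 1000000 --out wt_matrix.tsv
tssmeta cluster-fit --matrix wt_matrix.tsv --k 4 --seed 1 --out assignment.tsv
tssmeta metagene --matrix wt_matrix.tsv --assignment assignment.tsv --out profiles.tsv
```

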
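# Methods

## Coordinate and binning conventions

All coordinates are UCSC-style: 0-based, half-open `[tx_start, tx_end)`.
The TSS of a plus-strand gene is `tx_start`; of a minus-strand gene,
`tx_end - 1` (the last covered base). When a gene symbol maps to several
transcripts, the genome-wide longest is kept; ties break deterministically
by `(chrom, tx_start, transcript_id)`. Symbols appearing on multiple
chromosomes collapse to one model with a logged warning — the analysis
treats a gene as a single unit, and keeping paralog copies would double-count
rows in the occupancy matrix.

The occupancy window is `[tss - W, tss + W)` tiled by `B = 2W/b` bins
(defaults `W = 5000`, `b = 100`, `B = 100`). For a plus-strand gene, bin
`i` covers `[tss - W + i·b, tss - W + (i+1)·b)`; the first downstream bin
starts exactly at the TSS. Minus-strand rows are the reversed genomic
binning of the same window, so bin 0 is always 5′ of the gene. With this
convention the mirror symmetry is exact about the half-integer point
`tss - 1/2`: reflecting a track's bases via `x -> 2·tss - 1 - x` and
flipping the gene's strand reproduces the row bit-for-bit (a property the
test suite checks). Orientation can be disabled (`orient_by_strand=False`)
for purely genomic left-to-right rows.

Bins reaching below position 0 are zero-filled and the gene is flagged, not
dropped, so cluster counts always cover the full gene universe. Genes on
chromosomes absent from a track get zero rows with a warning — a common,
recoverable mismatch between annotation and pileup builds.

## Coverage model and queries

Tracks are piecewise-constant with implicit zeros (the bedGraph convention).
Queries go through a per-chromosome cumulative mass function
`M(x) = ∫ s over [0, x)` evaluated by binary search, so a B-bin row is one
vectorized pass rather than B interval scans. Depth scaling multiplies all
values by `1e6 / mappable_reads` and records the factor on the track; the
definition of "mappable reads" (before or after duplicate removal) is the
caller's, since pileup files do not carry it.

Two tracks are compared by Pearson correlation of genome-wide binned means
(default 1-kb bins). This turns a qualitative "no redistribution of binding
sites" judgement into a single scale-invariant statistic; it is deliberately
blunt — it detects relocation of signal, not uniform amplitude changes.

## Clustering

Lloyd k-means with k-means++ initialization, squared-Euclidean distance on
the raw bin profiles, best of 10 restarts by within-cluster sum of squares
(scikit-learn's `KMeans` is the engine). No per-row standardization: the
classes are meant to order genes from high to low modification level, which
row scaling would erase. Rows are processed in gene-name-sorted order, so
the gene→label map is invariant to input row order given a seed. Raw labels
are remapped 1..k by descending cluster mean occupancy (mean over each
cluster's row means): label 1 is the broad/high class, label k the unmarked
background.

The partition is fit on the wild-type matrix and applied unchanged to the
mutant matrix. Fitting jointly (or on the mutant) is possible through the
same API; the single-genotype fit keeps group membership identical across
genotypes, which is what makes the difference metagenes interpretable.
The genotype choice is exposed rather than hidden in the pipeline.

## Metagenes

A metagene is the per-bin arithmetic mean across a gene group, with the SEM
(ddof = 1) as a descriptive band; no per-bin hypothesis testing is attached.
The difference profile is mutant − WT with SEMs added in quadrature. The
identity "metagene of all genes = size-weighted mean of cluster metagenes"
holds exactly and is tested.

## Gene sets and enrichment

Neuronal genes are classified by case-insensitive substring on term names:
"synapse" or "synaptic" in any ontology branch, or "neuron" restricted to
cellular component ("neurogenesis" in biological process does not qualify).
The annotation table is an input — no ontology release is pinned, and the
shipped fixtures are synthetic — so the rule, not any particular gene list,
is the reproducible object.

Enrichment uses the EASE score: for a 2×2 table (a = list∩term, b = list
only, c = term only, d = neither), the one-sided hypergeometric upper tail
is computed after replacing a with max(a − 1, 0). The decrement makes
single-gene overlaps uninformative (p = 1) and is conservative relative to
plain Fisher for every table (verified by exhaustive enumeration over all
tables with margins ≤ 12). Benjamini–Hochberg step-up q-values are computed
across all tested terms; the significance cutoff is q < 0.05. The default
background is the clustered gene universe, overridable.

Because of the decrement, the null distribution of EASE p-values is slightly
sub-uniform: with well-populated tables (here 200-gene terms against a
1000-gene universe) the fraction of null terms below 0.05 sits a little
under 5% (typically 3–5% in the calibration runs); with small overlaps the
conservatism is much stronger. The calibration check therefore uses
large-ish terms, where the decrement is a small perturbation.

## ΔΔCt statistics

Per sample, ΔCt = Ct(target) − Ct(reference), after averaging technical
replicates on the Ct scale. Unpaired design: the baseline (wild-type) arm's
mean ΔCt anchors the normalization, giving folds `2^-(ΔCt - ΔCt_mean)`;
consequently the baseline log2 folds average exactly zero. Arms are compared
by the classical equal-variance two-sample t test on the fold values (the
design names Student's test, not Welch's). Paired design: per pair,
`fold_d = 2^-(ΔCt_d - ΔCt_v)` with the vehicle side defined as 1, tested by
a paired t of folds against 1; testing on the ΔΔCt scale instead is offered
as an explicit option (`on_delta_scale=True`) and documented as an
alternative presentation. Testing on the fold scale matches the quantity
plotted and reported; the two scales do not give identical p-values because
the transform is nonlinear. Zero-variance degenerate inputs (all folds
equal) return t = 0, p = 1 with a warning rather than an error, so batch
runs over many genes do not abort on a flat gene.

## Synthetic-data generator

The generator emulates the statistical structure of a two-genotype promoter
ChIP-seq study, not its sequences: no reads, alignment or fragment model.
Genes are laid on one synthetic chromosome with TSS spacing ≥ 11 kb (window
width plus 1 kb), strands alternating, TSS on the 100-bp grid so that
noise-free runs are exactly recoverable. Four archetypes define expected
signal in each TSS window:

| class | shape | default |
|---|---|---|
| broad | constant plateau across ±W | height 8 |
| tss_strong | baseline + Gaussian summit at TSS | height 12, σ 500 bp |
| tss_weak | baseline + lower summit | height 4, σ 500 bp |
| unmarked | baseline only | 0.5 |

Class proportions default to 2/10/55/33% — a small heavily marked class, a
modest summit class, a large weak class, and an unmarked remainder, echoing
the strongly skewed class sizes real promoter H3K27me3 shows. The mutant
multiplies broad-domain amplitude by 1 + δ_broad (default +0.3) and summit
amplitude by 1 + δ_summit (default −0.3). The broad plateau scales
wholesale (baseline included), so the noise-free mutant row is exactly
(1 + δ_broad) × the wild-type row — a construction chosen to make the
planted effect exactly recoverable; for summit classes only the Gaussian
component scales, leaving the genome-wide background untouched.

Noise is Poisson per 100-bp segment around expectation × (reads/1e6),
mimicking count noise in a pileup; the declared mappable read count is the
same depth, so scaling to one million reads recovers the expectation scale
in mean. A variance-zero mode supports exact tests. All outputs are
bit-reproducible under a fixed seed.

What the generator does **not** emulate: mappability and GC structure,
fragment-size smearing, inter-replicate biological variance, overlapping or
nested genes, multiple chromosomes (available via config but not default),
and realistic gene-density heterogeneity. Passing tests therefore show the
pipeline's operations are correct and planted effects are recovered under
idealized noise — not that the biological conclusions would survive real
data artifacts.

Ct tables: target ΔCt ~ Normal(base + e·1[mutant], sd) with the reference
gene at fixed Ct, so the planted shift e appears as fold 2^-e exactly at
sd = 0. Term tables: planted "synaptic"/"neuron" terms draw members with
configurable odds favoring summit-class genes; null terms draw uniformly.

## Problem sizes and runtime choices

The default verification study uses 1000 genes (a ~12-Mb synthetic
chromosome), which gives every class enough members for stable k-means
recovery (the smallest class holds 20 genes) while a full
simulate→scale→matrix→cluster→metagene cycle stays around a second. The
replicate-seed checks use 10 seeds; the EASE calibration uses 1000 null
terms of 200 genes. The exhaustive EASE/Fisher enumeration covers all 2×2
tables with margins ≤ 12 (2400 tables).

## Known limitations

- `track_similarity` is a global statistic; it will not localize where two
  tracks diverge.
- The EASE decrement is applied to the observed table only; no continuity
  correction or mid-p variant is offered.
- k is fixed by the caller (default 4); there is no model selection, and
  with badly chosen k the ordered labels remain well-defined but lose their
  intended broad/summit/weak/unmarked reading.
- Amplification efficiency in qPCR is assumed to be exactly 2 per cycle; no
  standard-curve correction or multi-reference normalization.
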
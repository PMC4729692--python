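# Methods

`epistate` reimplements, as a tested library, the integrative computational
analysis used to characterise the H3K9me2 / H3K27me3 repressive chromatin
states that form in the mouse epiblast around implantation: region-level
ChIP enrichment with k-means mark calling, a per-embryo Fisher-combined
differential-expression (DE) procedure, repeat-subfamily regulation
analysis, enhancer calling and state classification, SOM-based clustering
of epigenetic signatures, and motif enrichment against a resampled genomic
null. Because the original sequencing data are not bundled, the package
ships a first-class synthetic-data generator with planted ground truth;
every analysis is exercised end to end against that truth.

## Coordinates and region model

All coordinates are 0-based half-open (BED native) internally; 1-based
display is formatting only. Tiling emits fixed-length windows at starts
0, offset, 2·offset, … and keeps one final truncated tile only when the
full tiles do not already reach the chromosome end, so base coverage is
conserved and consecutive starts always differ by exactly the offset.
Promoters default to TSS −2000/+500 bp strand-aware (a common convention;
the window is configurable because no single definition is canonical).
CpG promoter classes (HCP/ICP/LCP) are input labels; when sequence is
available they can be derived with Weber-style thresholds (best 500 bp
window with CpG observed/expected > 0.75 and GC > 0.55 ⇒ HCP; maximum
observed/expected < 0.48 ⇒ LCP; else ICP).

## ChIP enrichment and mark calling

A replicate's region density is (count + 0.5)/(library total/10⁶)/(length
in kB); enrichment is log2(ChIP density / input density), averaged over
replicates *after* the log transform (two biological replicates by
default). The 0.5-read pseudocount keeps zero-count regions finite and is
configurable.

Mark calling splits the per-region enrichments into three groups and
designates the most highly enriched group "marked". We compute the exact
1-D k-means optimum by dynamic programming over the sorted values
(optimal 1-D clusters are contiguous in sorted order), rather than
restarted Lloyd iterations: the result is the global SSE minimum and is
fully deterministic. `seed`/`restarts` arguments are retained for API
compatibility but unused. Two practical caveats:

- k-means always produces a top cluster, so on data with *no* truly
  enriched regions the rule would mark roughly a third of them. The
  pipeline therefore applies an optional floor on the marked cluster's
  mean enrichment (default 1.0 log2 units, half the simulated effect);
  a top cluster below the floor yields an empty marked set. Library
  calls without the floor reproduce the literal rule.
- Whether the original clustering ran per region class (promoters vs
  gene bodies) or jointly is not recoverable; we cluster per region class.

Differential enrichment between two cell types over the same regions
combines a NB tail test of each replicate's per-million count against the
other cell type's mean (Fisher-combined, method-of-moments dispersion
pooled across replicates and floored at 0.01) with the replicate-mean
enrichment difference; thresholds are p < 0.05 and |log2FC| > 2. A region
is A-only if marked in A and either unmarked in B or significantly higher
in A; "both" requires marking in both without a significant difference.

Metagene profiles rescale each gene body to 100 bins with 5 kb fixed-width
flanks (25 bins each), strand-flipped for minus-strand genes, then average
per gene class. Absolute scaling of a relative track adds log2 of an
externally measured global mark-abundance factor.

## Differential expression

Single-embryo RNA-seq is too heterogeneous for a pooled two-group test,
so each KO embryo is compared against all control samples and the
per-comparison p-values are combined with Fisher's method
(X = −2·Σ ln pᵢ ~ χ² with 2k df; p-values floored at 1e-300 first; k = 1
returns the input p exactly).

Counts are normalised with median-of-ratios size factors (geometric-mean
pseudo-reference; factors rescaled to geometric mean 1). RPKM divides the
normalised count by gene length (kB) and the *normalised* library total
(per 10⁶), making it invariant to a common rescaling of library sizes —
the per-million anchor after normalisation is otherwise ambiguous.

The per-comparison test is a two-sided NB tail by probability-mass
ordering: p is the total mass of all counts whose point probability does
not exceed the observed one; dispersion 0 degenerates to Poisson. Note
that observing the *mean* of a skewed NB gives p < 1 (the mode, not the
mean, has p = 1).

Dispersion is estimated from the control replicates by method of moments,
floored at 0.01, and shared conservatively as the maximum of the
gene-wise and the global-median estimate (the classic DESeq "maximum"
sharing mode): with 3–4 replicates the gene-wise estimate is noisy, and
downward noise is anti-conservative. Because the control mean is itself
estimated, the test variance is additionally inflated by (1 + 1/n_ctrl)
plus a 1/(n_ctrl·μ) term. With the literal one-sample recipe ~17% of null
genes reached p < 0.05; with these corrections the rate is ~5–6% while
sensitivity for 8-fold planted changes remains ≈ 0.98. The remaining
one-sample character of the design is a stated limitation.

Call cascade for "up": Fisher-combined p < 0.05 AND log2FC > 1.4 in
*every* KO comparison (0.5-read pseudocount in the ratio) AND
log2(RPKM) > 1 in every KO replicate; "down" is mirrored with the
controls as the upregulated sample. Stage transitions (e.g. ICM →
epiblast) use the same machinery group-vs-group with log2FC > 1 and
log2(RPKM) < 4 required in the lower-expressed stage; repression is
implemented as activation of the swapped comparison, so
repressed(A,B) = activated(B,A) holds exactly. Chromosome enrichment of a
DE set (the X-linked observation) is a hypergeometric upper tail.

## Repeats

Repeat locus counts (uniquely mapping reads) are normalised by the
per-sample reads on protein-coding genes (per 10⁶) and locus length (kB);
DE reuses the per-embryo machinery with protein-coding-anchored size
factors. Loci with fewer than 5 total reads are never tested
("sufficient coverage" is not defined in the source analyses; the cutoff
is a config knob). A subfamily (≥ 20 loci) is "regulated by" a mark when
both one-sided Fisher exact tests — marked fraction vs the genome-wide
fraction, and upregulated fraction vs genome-wide — survive BH adjustment
(within each test family) at 0.05. The dual-test rule is our
formalisation of the marked-and-upregulated intersection display.

## Enhancers

Active enhancers are p300 peaks overlapping at least one H3K27ac and one
H3K4me1 peak and no promoter; the emitted region is the summit (peak
midpoint when no summit is given) ± 800 bp, i.e. 1601 bp unless clipped
at a chromosome edge. State classification across cell types uses the
repressive-mark k-means calls plus K27ac evidence with a fixed precedence
(dual K9+K27ac > K9 > K27me3-poised > active > inactive) so calls are
deterministic; the dual class captures enhancers transiently retaining
acetylation while gaining H3K9me2. In the pipeline, H3K27ac evidence at
the later stage is peak-derived (peak calling is upstream of this
package and its output is an input), while the repressive marks are
called from simulated ChIP: a majority of enhancers legitimately retain
K27ac, and the top-of-three-clusters rule presumes a minority-marked
distribution. Nearest-gene assignment links enhancers to genes; elements
regulating distant promoters will be mis-assigned — a known limitation of
the proxy. Expression contrasts between state classes use the rank-sum
test with effect size r against the active class.

## Self-organizing maps

Feature vectors (mark enrichments, methylation, expression) are
centre-scaled per column (constant columns → zeros). Training is online:
codebooks are initialised by seeded sampling of input rows; per step the
best-matching unit (BMU, Euclidean; ties to the lowest node index) and
its neighbourhood within the current radius σ move toward the sample with
weight α·exp(−d²/2σ²). Both α (0.05 → 0.01) and σ (2/3 of the grid
diagonal → 0) decay linearly over all steps; σ = 0 updates only the BMU,
which is online k-means. The grid is hexagonal (odd rows offset 0.5, row
spacing √3/2) with distances in the offset-coordinate embedding. Sample
order is reshuffled each epoch with a per-epoch derived seed, so training
is bit-reproducible given the seed. Grid size, epochs and schedules are
exposed (none is canonical); the pipeline default is a small grid sized
to its synthetic inputs. Node summaries report per-node feature means and
member counts ranked by a chosen feature (empty nodes: count 0, NaN
means).

## Motif enrichment

Site scores are log2-odds sums over PWM positions (PWM pseudocount 0.01
per cell; background estimated from the sequence universe unless given).
The score threshold for a site p-value (default 1e-5) is exact: column
score distributions, discretised to 1e-3 bits, are convolved under the
background model and the threshold is the smallest *achievable* score
whose upper tail mass is ≤ p. When p is below the minimal achievable
tail (short/degenerate motifs) the threshold is set above the maximum
score with a warning, so nothing matches. Scanning scores every window
on both strands (reverse-complemented matrix; windows containing N are
skipped).

Region-set enrichment compares the fraction of query regions with ≥ 1
hit against 1000 width-matched random region sets drawn uniformly from
gene bodies ± 50 kb of flanking sequence: fold is
(query + ε)/(mean background + ε) with ε = half a region, and the
empirical p uses the add-one estimator (1 + #sets ≥ query)/(n + 1), so
it is never 0 and is floored at 1/1001. Per-region frequency (not total
hit count) is the default statistic; a hit-count mode is available.

## Shared statistics

χ² overlap tests use the closed form N(ad−bc)²/(row·col margins) with
df 1 (no Yates correction by default; flag available). The rank-sum test
is exact by full enumeration for tie-free samples of ≤ 10 per group,
otherwise the normal approximation with tie and continuity corrections;
the effect size is r = |Z|/√N (the threshold convention * r ≤ 0.10,
** 0.10 < r ≤ 0.15, *** r > 0.15 applies when p < 0.05, else "ns"; the
r formula itself is our choice, documented because only the thresholds
are fixed by convention). Fisher exact p-values come from direct
hypergeometric summation (two-sided by minimum likelihood). Methylation
contrasts report (optionally coverage-weighted) group means plus the
rank-sum result. BH adjustment is the standard monotone step-up.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure of the study designs:

- **RNA-seq**: NB counts with mean baseline·library·2^(log2FC·is_KO),
  4 KO + 4 control embryos (3+3 configurable), log-normal library factors
  (sd 0.2), dispersion 0.1, planted upregulation at log2FC 3. Pipeline
  baselines are log-normal around 100 (log2 sd 0.75); the DE benchmark
  dataset uses constant mean 100. Planted DE genes are drawn
  preferentially from the deleted writer's mark targets (60% of autosomal
  picks) and from chrX (30%), mirroring de-repression of direct targets
  and the X-linked clusters; cross-mark overlap stays at chance.
- **ChIP**: Poisson counts at depth·length(kB), ×2^log2FC (default 2) at
  truly marked regions, two replicates; NB noise available by config.
  Library totals are the nominal genome-wide read count (identical for
  ChIP and input) because real totals are genome-wide and the
  marked-region excess is negligible there — this makes the per-million
  normalisation neutral and the planted effect recoverable on the
  enrichment scale. Promoter marks are mutually exclusive between K9 and
  K27 by default (co-marking configurable).
- **Repeats**: 20 subfamilies × 100 loci; regulated subfamilies get 60%
  marked / 30% upregulated loci vs 10% / 1% background.
- **Enhancers**: placed intergenically clear of promoter windows, all
  active at the first stage with p300/K27ac/K4me1 peak evidence (plus
  decoy p300 peaks lacking co-marks or overlapping promoters); at the
  later stage 12% gain H3K9me2 and 15% become H3K27me3-poised.
- **Sequences**: IID uniform composition; the consensus motif (a 10-mer,
  wide enough that site p = 1e-5 is achievable under a uniform
  background) is planted in 50% of K9-gaining enhancers, on either
  strand.
- **Methylation**: per-CpG Beta draws — Beta(8,2) at K9-marked,
  Beta(2,8) at K27-marked, Beta(6,4) elsewhere (typical bulk epiblast
  levels; only the marked classes are constrained by the biology being
  modelled).

Not emulated: read-level artefacts (mappability, GC bias, bisulfite
conversion error), overdispersion structure beyond a single NB parameter,
correlated replicates, genomic sequence composition, and real repeat
phylogeny. Passing recovery tests therefore demonstrates correctness of
the *procedures* under the modelled noise, not performance on real data.

All generators are deterministic given the mandatory seed; stage
substreams are derived from (seed, CRC32(stage name)), and derived integer
seeds stay below 2³¹.

## Numerical choices and degenerate inputs

- NB tails are summed over a support extended to the 1−1e-13 quantile;
  truncation error is below 1e-13.
- k-means needs ≥ k distinct values; fewer raises a degenerate-input
  error telling the caller to relax k.
- Fold changes use a 0.5 pseudocount on both sides; a zero control mean
  is floored at 0.5 normalised reads for the NB test (all-zero genes are
  "unchanged" by definition).
- Nearest-gene ties break to the lexicographically smaller gene id; BMU
  ties to the lowest node index; k-means assignment ties to the lower
  cluster.
- The PWM DP granularity (1e-3 bits) bounds the threshold error by about
  granularity × width; tests compare at twice that.

## Problem sizes

Default test and pipeline sizes are scaled for a desk run: 300–800 genes
on 4 × 3 Mb chromosomes, 2000 repeat loci, 100–300 enhancers, a 4×4–6×6
SOM for 8–20 epochs, 50–200 background sets per motif trial (1000 for the
planted-significance case). The DE benchmark uses the full 5200-gene
design. These sizes are the package's defaults; every threshold and count
is configurable.
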
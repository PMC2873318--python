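# Methods

## The model

`clustex` identifies *responsive gene modules* — connected subnetworks of a
genome-wide gene network whose genes act together in a cellular response —
from two inputs: a time-course expression matrix (non-log signal values with
a 0 h baseline column) and an undirected gene network (e.g. protein-protein
interactions).  The underlying picture: a group of closely connected and
co-expressed differentially expressed (DE) genes is the *signature* of a
responsive module; the full module is recovered by adding the intermediate
genes that connect the DE genes in the network, even when those
intermediates show no RNA-level change themselves (e.g. regulation at the
protein level).

The workflow has two steps plus downstream statistics:

1. **Clustering step.**  DE genes are those whose maximum fold change over
   the time course, relative to the baseline signal and computed on the raw
   (non-log) scale, reaches 2.0 in either direction (inclusive).  Every
   network edge (x, y) is weighted by co-expression, w = |cor(x, y)|
   (Pearson, absolute value), and carries the distance d = 1 − w; the
   gene-gene distance is the shortest-path length under d (Dijkstra).
   DE genes are clustered by average-linkage (UPGMA) hierarchical
   clustering on this distance matrix and partitioned at a distance cutoff.
2. **Extending step.**  Per DE cluster: (i) add the genes on one shortest
   path per DE pair, forming a connected sub-network; (ii) extend one step
   in the whole network; (iii) within that bounded search space, extract
   all genes and edges on the k-shortest loopless paths (Yen's algorithm,
   k = 10) between every DE pair.  Stages (i)–(ii) exist purely to bound
   the cost of (iii).  Each module gene is labelled `de`,
   `shortest_path` or `k_shortest` by the stage that recruited it.
3. **Module significance.**  Edge score escore = sd(x)·sd(y)·|cor(x, y)|
   (the absolute sample covariance); module score mscore = Σ escore over
   module edges; significance as a z-score against 10,000 draws of the
   same number of distinct edges sampled uniformly from the whole network.
4. **Gene-set analysis.**  Pathways/GO terms: Meet/Min = |A∩B| / min(|A|,|B|)
   with z-scores from 1,000 degree-preserving permutations of the gene set
   (log2-width degree bins; each gene replaced by a uniformly chosen gene
   of its bin, mutually distinct within a permutation); enriched at
   z > 3.0.  miRNA target sets: tscore = Σ gscore over the module/target
   overlap, where gscore(x) = log2(max fold change of x) · Σ_{module
   neighbours y} |cor(x, y)| combines expression change, neighbour
   co-expression and module degree; enriched at the looser z > 2.0.  The
   [50, 500] size filter is applied to GO-style collections after
   restricting sets to the analysis universe.
5. **Evaluation.**  Against a reference gene list: sensitivity =
   |module ∩ reference| / |reference| and the signal-to-noise ratio S/N =
   observed overlap divided by the mean overlap of 10,000 same-size control
   gene sets drawn uniformly from the complete gene list.

All analyses are restricted by default to the intersection of the network's
node set and the expression matrix's gene set (the *analysis universe*); a
retention mode instead keeps unmeasured network genes with edge weight 0 /
distance 1.

## Functional forms as configuration

The edge weight, edge distance, escore and gscore forms above are the
package defaults, each realized as an injectable callable
(`weight_fn`/`distance_fn`/`escore_fn`) so an alternative (e.g.
d = 1/w − 1) can be swapped without code change.

## Determinism and tie-breaking

Every stochastic stage takes a seed; a single global seed fans out to named
substreams (scoring, enrichment, evaluation, simulation), so re-running any
command with the same configuration and seed reproduces its outputs
byte-for-byte.  Deterministic tie-breaks: equal-length paths are ordered
lexicographically by node sequence (the Dijkstra subroutine returns the
lexicographically minimal shortest path, and Yen's candidate pool is keyed
by (length, sequence)); equal-height merge candidates are resolved by the
pair whose lexicographically smallest member sorts first; clusters and
modules are ordered by size descending with lexicographic ties.  Edges with
distance exactly 0 (|cor| = 1) are permitted.  Without-replacement subset
sampling is vectorized by taking the indices of the m smallest of n iid
uniforms (argpartition), one seeded generator per routine; draws are not
parallelized, so a single stream suffices for reproducibility.

## Cutoff selection

The clustering cutoff has no universal value; it is chosen from the growth
curve of the biggest DE cluster versus the cutoff (grid: 0 to the top merge
height in 100 steps, endpoint included exactly).  `suggest_cutoff`
automates the visual rule "the point after which expansion becomes much
slower": for a concave curve it returns the knee — the grid point of
maximum vertical distance above the end-to-end chord after normalizing both
axes to [0, 1]; when no pronounced knee exists (maximum deviation < 0.15 —
typical of network-distance curves, which consolidate gradually and end
with whole groups coalescing) it returns the smallest cutoff attaining the
maximal cluster size, i.e. the single-dominant-group regime.  A local
slope-drop detector and a stop-below-the-last-coalescence-jump variant were
evaluated and rejected: the biggest-cluster curve carries no information
about whether the *second* cluster has consolidated, and both variants
frequently fragmented true modules on benchmark data.  The suggestion is
advisory: `clustex run --cutoff auto` prints it and proceeds only with
`--yes` or an explicit value.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_fold` | 2.0 | DE threshold on the max time-course fold change (ratio, unitless) |
| `signal_floor` | 1.0 | floor on raw signals before ratios/logs (signal units) |
| `correlation_scale` | `log2` | scale for correlations/sds; `raw` optional |
| `cutoff` | `auto` | clustering distance cutoff (same units as 1 − \|cor\|) |
| `k` | 10 | paths per DE pair in the extending step |
| `min_de` | 5 | minimum DE genes for a cluster to yield a module |
| `n_edge_samples` | 10000 | null draws for module z-scores |
| `n_perm` | 1000 | degree-preserving permutations for enrichment |
| `n_controls` | 10000 | control sets for S/N |
| `z_pathway` / `z_mirna` | 3.0 / 2.0 | enrichment cutoffs |
| `go_min_size`, `go_max_size` | 50, 500 | gene-set size filter (inclusive) |

Fold changes are always computed on raw signals.  Correlations and standard
deviations default to log2(max(signal, floor)): the log transform stabilizes
Pearson correlation against the magnitude outliers typical of array signals.
The raw-scale option exists because either convention is defensible; the
choice is recorded in the run's provenance file.  Zero-variance series get
correlation 0 (maximally uninformative) rather than an error.

## The synthetic benchmark

`clustex simulate` (module `clustex.synthetic`) generates complete, fully
labelled inputs.  The default scenario: a 500-gene preferential-attachment
network (m = 3, mean degree ≈ 6, chosen to match the density of curated
human PPI networks at this scale) with two planted 30-gene modules —
connected subgraphs induced by random walks, whose degree-biased local
looping makes them cycle-rich like real complexes — 25 time points, target
intra-module |correlation| 0.8, DE fraction 0.6.

Expression is simulated on the log2 scale and exponentiated: baseline level
~ N(7, 0.5) (≈128, array-like magnitudes, so the signal floor of 1 is
negligible), plus, for module genes, a signed amplitude times the module's
response curve, plus Gaussian noise.  Each module gets its own response by
default (alternating saturating-rise and transient-pulse kinds with a
per-module time constant in [0.2, 0.4]) so distinct modules are co-expressed
internally but not with each other.  DE members draw their fold from
(2.5, 6); the rest from (1.1, 1.4), below threshold.  Module-gene noise is
derived per gene from the correlation target
(σ_g = b_g·sqrt(VarR·(1−ρ)/ρ)), which makes every intra-module pair hit ρ
up to estimation error; `noise_sd` (default 0.15 on log2) is the technical
noise of background genes and the reference level for the warning emitted
when the correlation target demands less noise than that.  `noise_sd = 0`
is the noise-free limit (intra-module |cor| exactly 1).

What the generator does *not* emulate: probe-level effects, normalization
artifacts, missing values, heteroscedastic array noise, correlated
background structure, or modules overlapping in membership.  Passing the
recovery benchmark therefore shows the machinery is correct and calibrated
under the stated model, not that real arrays will behave as cleanly.

## Benchmark problem sizes

The test suite runs the recovery benchmark at its defining size (20 seeds,
500 genes); permutation depths in tests are scaled to keep each statistic's
Monte-Carlo error far from the asserted margin rather than at production
defaults — module-z calibration uses 2,000 edge samplings per module (500
modules), recovery evaluation 2,000 control sets (observed S/N ≥ 3.5 versus
a margin at 3), enrichment power 300 permutations.  The acceptance script
uses the full production depths (10,000 / 1,000 / 10,000).

## Degenerate inputs and edge cases

All-zero or constant series: fold 1, direction "up", sd 0, correlation 0.
Clusters spanning network components are processed per component with a
warning; DE pairs unreachable inside the extended subnetwork are skipped
with a warning.  Modules without edges cannot be scored (mscore undefined).
A permutation null with zero spread marks the gene set not-evaluable (never
enriched).  A degree bin holding a single gene maps that gene to itself
with a warning.  Reference or module genes outside the analysis universe
are dropped (with a warning) before evaluation.

## Known limitations

Path-based extraction cannot recruit a gene whose only module attachment is
a single edge (a leaf lies on no loopless DE–DE path); such genes are
recovered only as DE seeds.  The biggest-cluster growth curve does not
reveal the consolidation state of smaller clusters, so the automatic cutoff
prefers the robust dominant-group regime over aggressive splitting; users
who want separated sub-modules should inspect the curve and set the cutoff
manually.  Runtime grows with the square of cluster size times k (Yen per
DE pair); the staged search-space restriction keeps desk-scale problems in
seconds but genome-scale networks with thousands of DE genes are expensive,
as for the original implementation.
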
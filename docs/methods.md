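# Methods

## Scope and model

`hausnet` implements a desk-scale, fully seeded version of a standard
hub-gene discovery analysis for multi-tissue RNA-seq: normalization →
variability filter → map clustering → thresholded coexpression network →
modularity partition → centrality hub ranking → term enrichment.  The
pipeline starts at a count matrix; read mapping, BLAST searches, GO
ontology handling and visualization are out of scope (networks are
exported as edge/node TSV and GraphML for Cytoscape).

## Normalization (TMM + log-CPM)

The trimmed-mean-of-M-values estimator is implemented from its
definition.  Reference sample: the one whose upper-quartile count rate
(75th percentile of x/N) is closest to the mean upper-quartile rate.
For sample k vs reference r, over genes positive in both:

    M_g = log2[(x_gk/N_k) / (x_gr/N_r)]
    A_g = ½[log2(x_gk/N_k) + log2(x_gr/N_r)]
    w_g = (N_k − x_gk)/(N_k x_gk) + (N_r − x_gr)/(N_r x_gr)

M is trimmed two-sided by 30 % and A by 5 % (rank-based, midranks for
ties), the factor is 2^(Σ M_g/w_g / Σ 1/w_g) over the survivors, and
factors are recentered to geometric mean 1.  Proportional samples short-
circuit to factor 1 (max |M| < 1e-6).  If a caller-supplied trim fraction
leaves no genes (possible at ≥50 % trims on tiny gene sets; unreachable
at the defaults), the untrimmed weighted mean is used with a warning.
The implementation agrees with edgeR's `calcNormFactors(method="TMM")`
to ~4e-15 on negative-binomial fixtures.

Note an honest limitation of TMM itself: the precision weights contain a
reference-sample term that does not rescale when a single sample's depth
changes, so factors are only approximately depth-invariant (≲0.01 drift
for realistic depth ratios; edgeR behaves identically).  Global
rescaling of all counts is exactly invariant.

Expression values are log2(1e6·x/(N·f) + 1); the prior of 1 keeps zeros
finite (a zero count maps exactly to 0) and is the conventional choice
for downstream correlation work.  Genes with zero counts in every sample
are dropped with a log message.  TMM is applied jointly across all
provided samples.

## Variability filter

CV = sd/mean per gene with the sample (n−1) standard deviation.  CV is
computed on the **linear CPM scale** (un-logging the stored values) by
default: conventional cutoffs such as CV > 0.85 live on that scale — a
fold-6 two-of-six-tissues pattern has CV ≈ 0.9 there, while on log2
values the CV of any well-expressed gene is ~0.1 and the cutoff would
select nothing.  A `scale="log"` option exists for completeness.
Quantile mode keeps genes strictly above the requested CV quantile.

## Scaling, PCA, MDS

Genes are z-scored (n−1 sd) either across samples or across tissue-class
means (replicates averaged first); zero-variance genes are dropped with
a logged count.  PCA treats genes as observations, centers columns and
uses SVD; the largest-magnitude entry of each loading vector is made
positive so results are sign-deterministic.  Classical (Torgerson) MDS
double-centers the squared distance matrix and eigendecomposes it;
only positive eigenvalues contribute coordinates.  On Euclidean
distances of centered data it reproduces PCA scores up to sign, which is
tested.

## Self-organizing map

Online Kohonen algorithm on a hexagonal grid (odd rows offset 0.5,
vertical spacing √3/2), units numbered 1-based row-major so "unit 9" of
a 6×2 map has a fixed meaning.  Codebook initialized from `rows·cols`
distinct gene profiles sampled with the seed; presentation order
reshuffled per epoch.  Learning rate decays linearly α_start → α_end
(default 0.05 → 0.01 over 100 epochs); the neighborhood radius decays
linearly from ⅔ of the grid diagonal to 0, so late epochs update only
the best-matching unit.  The default neighborhood is a hard bubble
(h = 1 within the radius), with a Gaussian option.  BMU ties break to
the lowest unit index.  After training, assignments are recomputed as
exact nearest-codebook — the invariant every summary relies on.

"Multilevel" training is interpreted as multiple epochs of the standard
online algorithm; there is no hierarchical second layer (nothing in the
analysis consumes one).  The map trains on tissue-mean z-scores by
default (6 dimensions for a six-tissue design), configurable to
per-sample columns.

A 1×1 map is stochastic mean-tracking whose fixed point is the data
centroid; with a decaying learning rate the codebook ends within
O(α_final·spread) of the mean (~1e-3 on unit-spread data), which is the
tolerance tested — exact convergence would require α → 0 faster than
the presentation noise, which online SOM does not do.

## Coexpression network

Pearson correlation of per-gene z-scores (equal to correlation of the
raw profiles; Spearman available).  The *normal quantile* rule Fisher-
transforms all off-diagonal upper-triangle correlations (|r| clipped to
1−1e−12 so degenerate r = ±1 pairs stay finite), fits a normal by their
mean and sample sd, and keeps pairs with z strictly above
mean + Φ⁻¹(q)·sd.  The *empirical* rule keeps the top ⌈(1−q)·n⌉ pairs
(inverse-ECDF order statistic), chosen so the q → 0 limit is the
complete graph and edge sets nest exactly under increasing q.  Both
record method, q, realized cutoff, candidate-pair and edge counts.
Isolated nodes are retained — they are real genes whose correlations
fell below the cutoff.

## Modules, centrality, hubs

Fast-greedy (CNM) agglomeration on the unweighted thresholded topology:
from singletons, merge the connected pair with maximal
ΔQ = m_AB/m − 2(d_A/2m)(d_B/2m), ties broken by the lexicographically
smallest pair of smallest member ids; the returned partition is the
merge-history state with maximal Q, relabeled by decreasing size then
smallest member.  Q is recomputed from the final labels and must agree
with the running value to 1e-9.  Greedy agglomeration is not globally
optimal: on an 8-node path and one 8-node random graph it stops ~0.02
below the exhaustive optimum (identical to networkx's CNM); those gaps
are recorded in the test fixtures rather than hidden.

Betweenness is Brandes' algorithm (networkx), unnormalized, endpoints
excluded — the scores are used only for ranking, where normalization
cancels.  Hub ranking sorts by degree desc, betweenness desc, id asc,
optionally restricted to one module and/or to annotated transcription
factors.  TF status comes from a caller-supplied id list; there is no
built-in TF database.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ k) for overlap k between a target
set (n of N universe genes) and a term (K genes), Benjamini–Hochberg
across tested terms, results sorted by p then term id.  Only
over-representation is tested.  The default universe is the gene set
entering the network stage — enrichment conditional on network
membership — with any other universe available by argument.  Discrete
upper-tail p-values are sub-uniform, so the null false-positive rate
sits slightly below the nominal level; calibration is checked with
large disjoint terms where the discreteness bias is a fraction of the
sampling noise.

## Synthetic data: what it emulates, what it does not

`simulate_tissue_counts`: per-gene base means log-normal (ln-mean 5,
ln-sd 1; median ≈ 148 counts — realistic coverage), per-sample depth
factors log-normal(0, 0.2) so TMM has signal, counts negative-binomial
with variance μ + φμ² (φ = dispersion = 0.1 by default, a typical
bulk-RNA-seq value).  The default plants twelve expression patterns —
the invasive-stage cluster (up fold 6 in prehaustoria + haustoria, 60
genes), one tissue-specific cluster per tissue and five further
dual-tissue clusters (50 genes each, fold 6) — because a real
multi-tissue transcriptome puts a distinct dominant pattern in every
populated unit of a 6×2 map; with a single planted pattern the CV
filter passes essentially only that cluster and any 12-unit map would
scatter one homogeneous cloud over many units.

`simulate_module_expression`: one-factor model per module — gene =
loading·latent + noise, hub loading 1.0, member loading 0.6, noise sd
0.5 (hub–member r ≈ 0.69, member–member r ≈ 0.59, a realistic module
strength); background genes are standard-normal noise.  The exact
hub–member correlation l_h·l_m/√((l_h²+σ²)(l_m²+σ²)) is tested against
its empirical value.

`planted_partition_graph` wraps the networkx stochastic-block-model
generator (independent Bernoulli edges at p_in/p_out).

Not emulated: batch effects, GC/length bias, isoform structure,
correlated library composition, dropout beyond NB sampling, and any
read-level detail.  Passing recovery tests therefore demonstrates the
correctness of the algorithms under the stated generative models, not
performance on arbitrary real data.

## Problem sizes and determinism

Recovery checks use 1000-gene six-tissue simulations (three replicates),
300-gene factor-model networks (30 samples), and 60-node planted-
partition graphs, each over 10 seeds; the enrichment null uses 1000
random target sets of 500 genes against 10 disjoint 400-gene terms in a
4000-gene universe.  These sizes keep the full suite and the acceptance
script in the low minutes on one CPU while leaving all recovery margins
wide.  Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); the pipeline writes the seed into every
artifact header and a SHA-256 manifest, and reruns are byte-identical.

## Known limitations

- CNM greedy modularity can stop below the global optimum (documented
  fixtures); no Louvain/Leiden refinement is provided by design.
- The normal-quantile cutoff assumes the Fisher-z pool is roughly
  normal; with few columns or heavy planted structure the fitted sd is
  inflated by the signal itself, making the cutoff conservative.
- TMM factors are only approximately invariant to single-sample depth
  changes (see above).
- Enrichment takes the gene→term mapping as given: no true-path
  propagation or term ancestry.
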
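# Methods

This note documents the models, defaults and numerical choices behind the
`scld` pipeline, what the synthetic-data generator does and does not
emulate, and the limitations a user should know before applying the
package to real data.

## Problem setting

The pipeline identifies *seasonal comorbid lifestyle diseases*: diseases
that (i) co-occur prominently in a literature corpus and in curated
chemical–disease associations, (ii) are semantically close in a disease
ontology — a proxy for shared signs and symptoms, hence possible
comorbidity — and (iii) show coherent seasonal rhythms in population-scale
search interest (Google-Trends-style relative search volume, RSV, a 0–100
integer series whose maximum over the query window is scaled to 100).

## Corpus stage

Term frequencies (how often a disease name occurs in the abstract corpus)
enter as a CSV; curated chemical–disease links as a second CSV. Diseases
with no chemical link are removed before any outlier analysis, because an
isolated disease node carries no comorbidity signal. Bottleneck selection
uses two conjunctive, strict cutoffs: count > the 90th percentile of
counts over the drug-linked diseases (linear interpolation between order
statistics) and count > 10. The percentile is computed over the network
diseases, not the raw term list: the outlier analysis belongs to the
filtered network. Both cutoffs are parameters (`percentile`, `min_count`);
raising either can only shrink the selection.

## Semantic similarity and the DSN

Wang's measure was chosen because it is fully determined by the DAG alone
(no information-content corpus is needed) and is the standard graph-based
measure in ontology-similarity tooling. Semantic contribution weights
default to 0.8 for `is_a` and 0.6 for `part_of`. Each disease maps to at
most one ontology term; diseases without a term have undefined similarity
and are excluded from the network ("scored" diseases are those with at
least one defined off-diagonal score). S-values are computed by
max-product relaxation over the ancestor closure, and all reductions
iterate in sorted key order so that results are bit-reproducible across
processes (hash-randomized set iteration otherwise perturbs the last bit
of floating-point sums).

Two DSN modes are provided because the two published descriptions of the
network conflict: a per-node top-3 thresholding rule on the one hand, and
an edge count equal to the complete graph on the scored diseases on the
other. `complete` (default) emits every defined pair; `topk` keeps each
disease's k = 3 strongest partners, symmetrized by union — an edge
survives if *either* endpoint picked it, with ties broken by score then
partner id. The reported "overall similarity" of a network is the mean of
its edge weights.

## Community detection and consensus

Four algorithms are run on the weighted DSN: fast greedy
(Clauset–Newman–Moore), edge betweenness (Girvan–Newman), walktrap
(Pons–Latapy, t = 4 steps) and spin glass (Reichardt–Bornholdt, γ = 1).
Fast greedy, walktrap and spin glass are delegated to igraph. Two
numerical choices matter:

* **Dendrogram cuts.** igraph's automatic cut ignores edge weights, which
  mis-cuts weighted graphs (on a planted weighted two-block graph it
  returns a single community even though the two-block cut has modularity
  0.378). All dendrograms are therefore cut by an explicit sweep over
  community counts, maximizing *weighted* modularity; the first maximum
  wins, so results are deterministic.
* **Edge betweenness on similarity graphs.** Girvan–Newman is implemented
  as an explicit removal loop using weighted edge betweenness with the
  similarity weights acting as traversal costs. Weakly similar edges are
  then "cheap" paths, concentrate betweenness, and are removed first;
  modularity of each intermediate partition is evaluated with the
  similarity weights on the original graph.
* **Spin glass.** Simulated annealing (geometric cooling, factor 0.99)
  with a seeded RNG and best-of-5 restarts per call, keeping the
  highest-modularity state. Annealing on ~40-node graphs is cheap, and
  restarts remove the occasional convergence to a split one merge short
  of the optimum. A seed is required; refusing to run unseeded keeps the
  pipeline reproducible by construction.

Disconnected graphs are handled per connected component with disjoint
label ranges; an empty graph yields singletons with modularity defined as
zero.

Consensus requires co-assignment by all supplied partitions (a quorum
parameter relaxes this; the default is unanimity, matching the idea that a
comorbid module should be tightly maintained by every algorithm).
Consensus communities are the size-≥ 2 connected components of the
co-assignment graph. The core network is the bottleneck diseases plus all
non-bottleneck members of any consensus community containing a bottleneck.

## Time-series statistics

* **Mann-Kendall.** S over all pairs; variance with the standard tie-group
  correction; z continuity-corrected by ∓1 on S; τ is the tie-corrected
  τ_b; p two-sided normal. A constant series has varS = 0 and z defined
  as 0. This z convention reproduces published worked examples
  reconstructed from their printed (S, varS) pairs to within one unit in
  the last printed decimal (the printed variances are integer-rounded, so
  exact rounding equality is not attainable for every row).
* **Seasonal Mann-Kendall.** Per-season S_i and varS_i summed, then the
  same z convention on the totals. Monthly date-indexed series slice by
  calendar month; weekly series by ISO week-of-year capped at 52; plain
  arrays by position modulo the period. No serial-correlation covariance
  correction is applied — the published total variances are consistent
  with the plain sum. Every season must contain at least 3 observations.
* **STL.** Cleveland's seasonal-trend decomposition by LOESS via
  statsmodels (seasonal span 7, 2 inner / 0 outer iterations by default).
  The additive identity seasonal + trend + remainder = x is exact by
  construction; on a pure cosine the remainder is at rounding level
  (~1e-13 of the amplitude).
* **Periodogram.** Linear detrend by default (monotone drifts of the
  magnitude seen in chronic-disease RSV otherwise dominate the low
  frequencies), then power |X_k|²/n at positive Fourier frequencies;
  dominant periods are the highest-power bins, ties to the shorter
  period. Detrending with "constant"/None is available; with mean removal
  the usual Parseval accounting holds exactly.
* **Seasonality F-test.** Partial F-test of paired sin/cos regressors at
  periods P/h (h = 1..2 by default) over an intercept + slope null. This
  is the package's seasonality yes/no flag: a transparent,
  exactly-calibrated alternative to fitting a full exponential-smoothing
  state-space (TBATS-style) model, whose estimation machinery is out of
  proportion to a binary flag. The substitution is recorded in every run's
  metadata. Under trend-plus-noise nulls the empirical size is ~0.05.
* **Block moving averages.** Fixed calendar windows anchored at October
  (Oct–Mar / Apr–Sep), partial end blocks retained and flagged. The
  hemisphere opposition score deviates each block mean from the disease's
  own mean (within the aligned block set) in each region and reports the
  fraction of aligned blocks with strictly opposite signs, pooled over
  diseases: 1.0 for anti-phase annual cycles, 0.0 for identical panels,
  ~0.5 for independent ones. Note that only the *annual* harmonic carries
  hemisphere information: a 6-month harmonic is invariant under a 6-month
  shift and averages out within 6-month blocks.

## Shape clustering and classification

SBD uses FFT cross-correlation over all 2n−1 shifts of the z-normalized
series (verified against direct shift enumeration to 1e-10); it is
symmetric, zero on affine copies, bounded by [0, 2], and deliberately not
a metric (no triangle inequality). Constant series z-normalize to zero
vectors; two constants are defined as distance 0, a constant against a
non-constant as 1. Hierarchical clustering is average-linkage on items in
lexicographic order (deterministic tie-breaking), cut by maxclust.

Classification defaults: retention threshold mean RSV ≥ 20, α = 0.05,
two shape groups and two trend groups (k = 2), period 12. Trend groups
cluster pairwise |Δz| of the seasonal Mann-Kendall statistics — the
simplest one-number-per-disease summary whose magnitudes separate strongly
trending from weakly trending diseases; clustering per-year p-value
vectors was considered and rejected as noisier at 13 annual replicates.
The benchmark disease must survive retention; severe status requires
sharing both its groups *and* an individually significant seasonal trend,
so a disease cannot become severe on cluster geometry alone.

## Synthetic data: what it emulates, and what it does not

The generator plants ground truth at every stage: bottleneck diseases
receive term counts strictly above both cutoffs while all other counts
follow a Zipf law truncated at the absolute cutoff (so the planted set is
exactly the outlier set by construction); each planted disease class is
annotated to fresh sibling leaves under a common ontology parent (high
within-class Wang similarity); and RSV series follow

    s_t = base + slope·t + amp6·cos(2πt/6 + φ) + amp12·cos(2πt/12 + φ) + ε_t

with ε ~ N(0, σ²), one shared phase per class, max-rescaled to 100,
clipped to [0, 100] and rounded to integers — the Google Trends coding.
Defaults describe 156 months (Jan 2004 – Dec 2016), 73 diseases, 6
chemicals, noise σ = 3, and per-class parameters: severe (base 60, slope
−0.15/month, amp6 = 8, amp12 = 4), moderate (base 45, slope +0.05,
amp6 = 1, phase-shifted by π), mild (base 4 plus a single 40-unit spike
month). The spike is how low-volume terms behave in real exports: the
max-100 rescaling pins the peak at 100 and leaves the mean far below the
retention threshold — a mean below 20 with a maximum of 100 mathematically
requires a peaky series. Severe-class means land near 65–70 RSV and
moderate means near 80–85; both comfortably clear the retention
threshold, and the classes are separated by seasonality strength and
trend direction rather than by mean level.

Not emulated: Google's server-side joint-query normalization beyond the
shared max-100 rescaling (the benchmark term is metadata only), non-12
month calendars, missing values, regional language bias, and serially
correlated noise. Passing tests on synthetic panels therefore demonstrate
the pipeline's correctness and statistical calibration under the stated
signal model, not robustness to every artifact of real search data.

## Degenerate inputs and tie-breaking

Constant series: Mann-Kendall z = 0; autocorrelation raises (undefined);
the F-test reports F = 0, not seasonal; z-normalization returns zeros.
Ontologies must be single-rooted DAGs (validated on read). All writers
sort rows, and all similarity reductions iterate sorted keys, so a fixed
seed reproduces every output file byte for byte.

## Problem sizes

Default test and acceptance runs use 156-month monthly panels, 73-disease
corpora, 41-disease similarity matrices, 20-node planted community
graphs (20 seeds), 50 synthetic panels for label recovery and 500
simulations per type-I-error estimate; these sizes match the study
conditions the pipeline targets while keeping a full run in tens of
seconds on one CPU.

## Known limitations

* The seasonal Mann-Kendall variance omits the between-season covariance
  correction; with strong serial correlation the test is anti-conservative
  (on the synthetic signal model its empirical size is below nominal).
* Wang similarity is computed for single-term annotations only; best-match
  averaging over multi-term annotations is out of scope.
* The spin-glass annealer is stochastic; results are reproducible only
  through the seed, and on graphs with weak community structure different
  seeds may legitimately disagree.
* The weekly season index (ISO week capped at 52) folds week 53 into week
  52, slightly inflating that season's sample.
* Live Google Trends querying, TBATS/Box-Cox modelling, bootstrap cluster
  probabilities and forecasting are deliberately out of scope.
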
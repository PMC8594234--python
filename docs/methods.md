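# Methods

`gutnet` reimplements, as a tested pipeline, the ecology workflow used to
characterise the gut microbiome of an algivorous sea urchin under restricted
diets: classify every taxon's niche breadth, infer signed co-occurrence
networks per niche from compositional counts, characterise the networks'
topology, and detect hub and driver taxa between case and control niches.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic benchmark does and does not establish.

## Data model and pre-filters

Counts are an integer taxa x samples table; the sample metadata assigns each
sample one diet level and one gut-region level, whose cross defines the
habitat cells of a factorial design. Before any analysis, taxa are removed
when they (in this precedence, each taxon counted once) have fewer than 5
total reads, overall relative abundance below 1e-5, or presence in fewer
than 10% of samples. "Overall relative abundance" is pooled
(taxon total / grand total) by default; a per-sample-mean variant is a
switch, since either reading of a prevalence cut-off is defensible and the
two differ for taxa concentrated in few samples.

## Niche breadth and classification

For each taxon, with `p_j` the share of its reads in habitat unit `j`:

* Levin's index `B = 1 / sum_j p_j^2` (inverse Simpson concentration);
  `B = k` under perfectly even use of `k` habitats.
* Shannon-Weaver breadth `H = -sum_j p_j ln p_j` in nats.
* Occupancy: fraction of habitat units with presence (count > 0; no
  detection-limit smoothing).

These satisfy the Hill-number ordering `exp(H) >= B >= 1`, which the suite
checks both as a property on random inputs and against every published
index pair shipped in `gutnet/data/published_niche_indices.tsv`. The
habitat unit defaults to individual samples rather than design cells: the
published index values (Levin's up to 28.6, `H` up to 3.44 > ln 9) are only
attainable when each of the ~50 samples is a unit.

Occurrence rule: a taxon is **core** when present in at least 85% of the
samples of *every* level of the scoped variable(s) (diet, region or both,
default both). The source protocol's phrase "any specific habitat" is
ambiguous between every-level and at-least-one-level; the strict reading is
the default because the published core taxa all show overall occurrence at
or above 0.93, and the lenient reading would absorb the diet-unique taxa
(present in >= 85% of one diet's samples) into the core class. The lenient
reading remains available (`core_any_level=True`). A non-core taxon is
**unique** to a level when present in >= 85% of that level's samples and in
no more than 25% of each other level's; when both variables match, diet
takes priority.

Rank rule: each index is ranked descending with average ranks for ties; the
overall rank is the unweighted mean of the three. Taxa in the best
`ceil(0.1 N)` overall ranks are **generalists**, the worst `ceil(0.1 N)`
**specialists** (ceiling so communities of >= 10 taxa always have a
non-empty decile). Taxa tied across both boundaries (only possible under
massive ties) are left not-significant rather than broken arbitrarily.
Core ∩ generalist is labelled **core generalist**; precedence is
core-generalist > core > unique > generalist/specialist > not significant.

## Compositional network inference

Counts are compositional: only relative information survives sequencing, so
sample correlations of relative abundances are biased by the sum
constraint. The estimator works on the centred log-ratio transform
`clr(x) = log(x + c) - mean(log(x + c))` per sample (pseudocount `c = 0.5`
by default — half a read, the customary continuity correction; the protocol
we follow does not state one, so it is configurable) and solves

    minimize over symmetric PSD Sigma:
      1/2 || S - G Sigma G ||_F^2 + lambda * sum_{i<j} |Sigma_ij|

where `S` is the empirical clr covariance and `G = I - 11'/p` the centring
projector. `G` annihilates row/column offsets, so the latent covariance is
identified only up to `a1' + 1a'`; the L1 penalty selects the sparse
representative. The fitted covariance is rescaled to unit diagonal and
clipped to [-1, 1].

Solver: Davis-Yin three-operator splitting — gradient step on the smooth
quadratic (Lipschitz constant `||G||^4 = 1`, unit step), soft-thresholding
prox for the off-diagonal L1 term, eigenvalue-clipping projection onto the
PSD cone. Because each unordered pair occupies two entries of the symmetric
matrix, the prox thresholds entries at `lambda/2`. Convergence: relative
Frobenius gap between the two operator copies below 1e-6, at most 5000
iterations; the sparse copy is returned so penalised entries are exact
zeros. On 3-taxon problems the solution matches a general-purpose
SLSQP solve with an explicit PSD constraint to better than 1e-4.

`lambda` is chosen by 5-fold cross-validation on held-out Frobenius loss
`||S_test - G Sigma G||^2` over a 20-point log grid from 1e-3 to 1. A grid
point whose fit does not converge within budget (possible at near-zero
penalty, where the problem is indeterminate) simply loses the CV.

Edge significance: each permutation shuffles every taxon row of the clr
matrix independently across samples — destroying all pairwise association
while preserving marginals — and refits at the observed-data lambda (keeps
the null exchangeable and the cost bounded). Two-sided p-values use the
add-one convention `p = (1 + #{|r_null| >= |r_obs|}) / (n_perm + 1)`, so
with 200 permutations the only value below the 0.005 threshold is
1/201 ≈ 0.004975: retained edges must beat every permutation. Edge sign
follows the correlation sign (co-occurrence / co-exclusion). Networks are
inferred per niche subset (overall, each diet pooling regions, each region
pooling diets), re-applying the taxon pre-filter within the subset.

Calibration caveat: at the CV-chosen penalty the lasso sets most null
correlations to exactly zero; a zero observed statistic can never beat a
permutation, so p-values for those pairs are 1 and the test is conservative
(anti-conservative behaviour is not possible). The type-I calibration study
therefore measures rejection at a small fixed penalty (0.01), where
estimates stay off zero and the permutation p-value is exactly uniform on
its attainable grid; there the minimal-p rejection rate matches
`1/(n_perm+1)` within binomial error.

## Network topology and degree-model classification

All topology is computed on the unweighted skeleton (the hop-based
conventions of standard network tools): density `2E/(N(N-1))`, mean local
clustering (degree < 2 contributes 0), diameter as the largest finite
eccentricity, average path length over connected pairs only, sub-clusters
as connected components with >= 2 nodes. The network-level Jaccard edge
index compares edge sets on unordered node-pair identity, ignoring sign;
sign-flipped shared edges are reported separately. Two empty edge sets give
JEI 1 with a warning (nothing differs).

Randomness classification fits the degree sequence (nodes of degree >= 1)
with two one-parameter models — Poisson (rate = mean degree) and the
discrete power law `p(k) = k^-alpha / zeta(alpha)` with `k_min = 1`, alpha
by bounded maximum likelihood — and picks the lower AIC (the models are
non-nested, so a likelihood-ratio test would not apply). Ties and all-equal
degree sequences classify as random, flagged degenerate. Accuracy is
benchmarked on Erdos-Renyi vs preferential-attachment graphs (N = 200);
measured accuracy is ~95%, with errors concentrated in sparse ER draws
whose degree spread mimics a heavy tail.

## Hubs and drivers

Per-node centralities: degree; closeness in the component-scaled convention
`(r / sum of distances) * (r / (N-1))` with `r` the number of reachable
nodes; betweenness as raw unordered-pair counts with fractional credit for
tied shortest paths (a normalised variant is emitted alongside); and
Kleinberg's hub score, the principal eigenvector of the adjacency matrix
max-normalised to 1 (for an undirected graph hub and authority coincide).
The power iteration runs on `A + I`: the shift leaves eigenvectors
unchanged but makes the dominant eigenvalue strictly largest in modulus,
without which bipartite graphs (stars!) oscillate. A node is a **hub** when
it ranks in the top `ceil(0.2 N)` on at least 3 of the 4 measures, ties at
the cutoff included; both knobs are configurable because the source
protocol lists the measures but no combination rule. On a regular graph
every node ties — all are flagged, with a warning, rather than none.

Driver detection compares one niche (case) against each other niche
(control) on per-node neighbour sets A (control) and B (case):

* `JEI = |A ∩ B| / |A ∪ B|` (1 when both empty: no rewiring);
* `NESH = |B\A| / |A ∪ B| + |B\A| / |B|` — 0 when the case set is empty or
  contained in the control set, 2 at complete turnover. The original
  neighbour-shift score is cited by name and threshold only in the protocol
  we follow; this formula is this package's documented definition, so the
  default threshold 1.8 is meaningful only relative to it (it demands
  near-complete turnover: a node keeping `k` old partners needs more than
  `9k` exclusive new ones);
* `delta-B`: betweenness divided by the network's average path length, case
  minus control; a network with no connected pair contributes 0, flagged.

A node is a **driver** of niche X iff, against *each* other niche,
JEI < 0.3, NESH > 1.8 and delta-B > 0. The protocol's "non-zero delta-B"
is implemented as strictly positive by default (drivers are described as
gaining centrality); the literal non-zero reading is a switch. Nodes absent
from a network contribute empty neighbour sets and zero betweenness.

## Community statistics

Rarefaction subsamples each sample without replacement (multivariate
hypergeometric) to a common depth, default 10,000 reads; shallower samples
are dropped, not rescaled. Alpha diversity is Shannon in nats (base
configurable); beta diversity is Bray-Curtis. PERMANOVA is one-factor:
pseudo-F from the between/within partition of squared dissimilarities, p by
label permutation with the add-one convention; the two-factor design is
exposed as the crossed diet x region labelling, since the original
analysis's design matrix is unstated. The pseudo-F matches scikit-bio's
implementation exactly (cross-checked in the suite); it is implemented here
so the permutation stream is seed-controlled. Kruskal-Wallis is
tie-corrected; post hoc Dunn z-tests use the pooled tie-corrected rank
variance and Benjamini-Hochberg adjustment (the protocol says FDR without
naming a procedure), flagged at 0.01.

## Synthetic communities and what the benchmark shows

The generator emulates the study conditions: 3 diets x 3 gut regions,
default 6 replicates per cell (54 samples), sequencing depth 15,000 reads
(the study scale), 150 taxa (a desk-scale stand-in for the study's 434).
Archetypes: 8 core (log-mean 4.0, no dropout), 15 generalists (2.5, dropout
0.25 — occurrence ~0.75, matching the published generalist occurrence range
0.54-0.81 and staying under the 85% core threshold), 12 specialists (3.0 in
at most 2 random habitat cells, dropout 0.1 within them), 4 diet-unique
taxa per diet (3.5; dropout 0.03 in the home diet, 0.95 elsewhere, i.e.
occurrence ~0.97 vs ~0.05), 103 background taxa (log-mean N(0,1), dropout
0.6). Counts follow a logistic-normal-multinomial: latent Gaussian with a
user-supplied taxa correlation (the quantity the inference stage estimates,
making recovery well-posed), scaled by latent sd 1.0, added to the
archetype log-mean, exponentiated, dropout-masked, normalised, multinomial
at depth. One global seed drives named substreams so each stage is
independently reproducible.

The generator does **not** emulate: taxonomic structure, phylogenetic
signal, tank/block effects, variable library sizes, overdispersion beyond
the logistic-normal, or the long-tailed abundance distribution of real
OTU tables. Passing recovery benchmarks therefore shows the estimators are
correct and calibrated under their own modelling assumptions — not that
real data satisfy those assumptions.

Benchmark sizes (chosen as the smallest that give stable Monte-Carlo
estimates): niche recovery at 20 samples per cell; permutation calibration
on 7 null datasets of 25 taxa x 100 samples (2100 edges) at 50 permutations
with a 200-permutation spot-check; edge-recovery AUC on 30 taxa, 5 planted
edges (|r| in 0.7-0.9), 100 samples; degree classifier on 100 + 100 graphs;
driver recovery on 50 planted-rewiring triples; statistic calibration on
500 null simulations at 99 permutations each.

## Known limitations

* The permutation test refits the estimator per permutation; at hundreds of
  taxa this is minutes, not seconds. Practical runs filter or subset taxa
  first (as the emulated study did: its networks have ~30 nodes).
* NESH and its 1.8 threshold are this package's definition; scores from
  other driver-detection tools are not numerically comparable.
* The lasso makes edge p-values conservative at the CV penalty (see above);
  a retained edge is trustworthy, but power at small n is limited by the
  1/(n_perm+1) floor.
* Core/unique classification treats levels of one variable symmetrically;
  the 85%/25% rule is evaluated within all samples of a level, not within
  single region slices.
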
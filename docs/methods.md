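# Methods

`planktonet` re-implements, as a tested pipeline, the community-organization
and network-stability analysis commonly applied to cross-kingdom plankton
amplicon surveys: abundant/rare sub-community partitioning, diversity and
niche breadth, Sloan neutral-model and phylogenetic null-model assembly
inference, correlation-based co-occurrence networks, and removal-based
stability simulation.  This note records the models, the parameters that
matter, and the design choices made where the methodology literature is
genuinely open.

## Preprocessing and abundance classes

Features are removed when they occur in fewer than 2 samples or carry fewer
than 5 reads in total (both thresholds strict "less than" exclusions).
Rarefaction subsamples each sample to a fixed depth without replacement
(multivariate hypergeometric); samples below the depth are dropped with a
warning.

Abundance classes follow the standard rare-biosphere cutoffs: abundant =
relative abundance > 1% in at least 10% of samples OR summed relative
abundance > 20%; rare = summed relative abundance < 0.5%; the remainder is
moderate.  "Summed relative abundance" is ambiguous in the literature; the
default here is the literal sum over samples of per-sample relative
abundances (`sum_convention="total"`).  Under this convention a feature can
never satisfy both the abundant-occupancy rule and the rare rule (>1% in
≥10% of n samples forces a sum of at least 0.001·n ≥ 0.5% for n ≥ 5), which
the classifier asserts.  The mean-relative-abundance convention is available
(`sum_convention="mean"`) but can produce the abundant∩rare conflict for
bloom taxa, in which case the classifier raises rather than guessing.

## Sloan neutral community model

For a taxon with mean relative abundance p in a metacommunity sampled at
depth N with immigration rate m, the Sloan model predicts its local relative
abundance to follow Beta(Nmp, Nm(1−p)).  The occurrence frequency across
samples is then predicted as P(abundance > d) = 1 − I_d(Nmp, Nm(1−p)) with I
the regularized incomplete beta function and d a detection limit.  The fit
minimizes squared error between observed and predicted occurrence frequency
over m (bounded scalar optimization on the logit scale); R² = 1 − SSE/SST.
95% prediction bounds are Wilson intervals on the predicted frequencies.

Detection limit: the common convention is d = 1/N, but detection in count
data is binomial — the probability of seeing at least one read of a taxon at
relative abundance x is 1 − (1 − x)^N, which equals 1/2 at x = ln(2)/N, not
at 1/N.  Using d = 1/N therefore overstates Nm by roughly 25% on communities
simulated from the model itself; the default here is d = ln(2)/N, which is
approximately unbiased (simulate-and-recover with m = 0.1, N = 1000, 200
taxa, 50 samples, 20 seeds: mean error below 3%).  `detection_limit=` makes
either convention available.

## Phylogenetic null models

MNTD is the (optionally abundance-weighted) mean distance of each taxon to
its nearest co-occurring relative; βMNTD is the between-sample analogue,
with each taxon matched to its nearest relative in the other sample (a taxon
present in both contributes zero).  SES MNTD and βNTI standardize these
against a taxa-label shuffle of the cophenetic matrix (picante's
"taxa.labels" convention), with n_null = 999 by default and the same shuffle
applied to the whole tree per replicate so that all sample pairs share each
null draw.  Null spreads below 1e-12 are flagged NaN and excluded from
process fractions with a logged count.  βMNTD is abundance-weighted by
default, matching the framework from which the ±2 βNTI thresholds come.

The βMNTD implementation is vectorized (per sample, the distance of every
taxon to its nearest member of that sample is precomputed, reducing the
double loop to a matrix product); its equivalence with the literal
double-loop definition is asserted to 1e-9 on random small instances.

Raup–Crick on Bray–Curtis follows the standard stochastic-colonization
recipe: each null community preserves the sample's richness and total count;
taxa colonize with probability proportional to occupancy (implemented as
Gumbel top-k weighted sampling without replacement, which reproduces
successive weighted draws), receive one individual each, and the remaining
individuals are distributed multinomially in proportion to pool-wide
relative abundance.  RC = 2·(#{null BC < obs} + ½#{null BC = obs})/n_null − 1
∈ [−1, 1].  The occupancy and pool weights default to the analyzed table but
can be supplied externally (used by the calibration tests, and useful when a
regional reference pool exists).

Process classification: βNTI < −2 homogeneous selection; βNTI > 2 variable
selection; otherwise RC > 0.95 dispersal limitation, RC < −0.95 homogenizing
dispersal, |RC| ≤ 0.95 drift.  Fractions are reported over all classified
pairs and sum to one.

## Diversity, Mantel tests and niche breadth

Shannon entropy is in nats; Pielou evenness J = H/ln S is flagged undefined
for single-taxon samples; Faith PD includes the path to the root (scikit-bio
convention).  Bray–Curtis operates on counts by default, proportions
optionally.  Geographic distance is Euclidean in (longitude, latitude)
degrees by default, haversine km optionally; single-variable environmental
distances are Euclidean on z-scored values, dropping missing samples
pairwise with a logged count.

The Mantel test correlates strict lower triangles (Spearman by default),
permutes rows and columns of the second matrix jointly, and reports the
one-sided p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm).  Permutations are
vectorized (rank matrices are permuted by index gather), which keeps the
500-pair type-I simulation in seconds; the statistic is cross-checked
against scikit-bio's implementation in the tests.

Levins niche breadth B_j = 1/Σ_i P_ij² uses abundance-based usage
proportions P_ij (feature j's abundance in sample i over its total), the
convention of spaa's `niche.width`; 1 ≤ B ≤ n_samples.

## Co-occurrence networks

Correlations are computed on log10 percent-scale relative abundances with
zeros replaced by a 0.01 pseudo-abundance.  Edges require |r| ≥ 0.6
(Spearman default) and Benjamini–Hochberg q ≤ 0.05 over all tested pairs;
features must be present in at least half the samples.  The
random-matrix-theory threshold scan of the MENA pipeline is deliberately not
reproduced: an explicit, recorded threshold is transparent and configurable,
and the construction parameters are stored in the graph attributes.
Constant features are excluded pairwise; self-loops never occur; edge signs
are kept.

Modules come from deterministic greedy modularity maximization (CNM);
node roles follow the Guimerà–Amaral plane with within-module degree z-score
Zi ≥ 2.5 for module hubs and participation coefficient Pi ≥ 0.62 for
connectors.  The degree distribution is fitted by least squares of log
frequency on log degree (≥5 distinct degrees required; otherwise flagged
not assessable).  Average path length is the mean shortest path over
reachable pairs; clustering of degree-<2 nodes counts as zero.

## Stability

Robustness is the fraction of taxa surviving a removal scheme plus secondary
extinction of nodes left with no surviving partner (the cascade can be
disabled).  Random removal deletes ⌊f·n⌋ nodes uniformly (default f = 0.5,
100 replicates); targeted removal deletes ⌈H/2⌉ of the H module hubs —
with no hubs the network is untouched and robustness is 1.0 with a warning.
Vulnerability of node i is (E − E_−i)/E with E the global efficiency (mean
inverse shortest-path distance over ordered pairs, unreachable pairs
contributing zero); it can be negative for peripheral nodes whose removal
raises mean efficiency.  Fragmentation removes the currently
highest-betweenness node per step (ties broken by degree, then id;
betweenness recomputed after every removal) and records
F = 1 − Σ s_k(s_k−1)/(N_r(N_r−1)) over component sizes together with the
largest-component share, so either fragmentation convention can be read
from the series.

## Synthetic data generator

The generator provides ground-truth data at the scale of a 38-station
cross-kingdom coastal survey and is the basis of every end-to-end test.

* **Phylogeny** — Kingman coalescent (merge rate k(k−1)/2, exponential
  waits); tree height has closed-form mean 2(1 − 1/n) and variance
  Σ_k (2/(k(k−1)))², which the tests check.  Coalescent trees carry the
  deep clade structure that phylogenetic niche conservatism needs.
* **Source pool** — Pitman–Yor stick breaking (θ = 20, discount = 0.6),
  giving a power-law abundance tail: a few taxa above 1% and a long rare
  tail that still clears the occurrence/frequency filter at realistic
  depths.  Pool abundances are assigned to tips by a seeded random
  permutation so abundance carries no phylogenetic signal by construction.
* **Neutral mode** — per sample, relative abundances are Dirichlet with
  concentration N·m·p (marginally Beta(Nmp, Nm(1−p)), the Sloan local
  community) and counts are a multinomial of size N.  The occurrence
  frequencies of generated data follow the fitted beta prediction with
  R² > 0.9 at 100 samples — generator (sampling) and fitter (CDF) are
  independent implementations, so this is a genuine cross-check.
* **Selection mode** — each taxon has a Gaussian niche on the latitude
  gradient (optima from Brownian motion on the tree, mapped to [0, 1] by
  rank so they spread evenly at every seed) plus membership in one of 10
  discrete habitat groups (quantile bins of a second Brownian trait).
  Groups bloom and fade independently across stations via lognormal
  factors (`patchiness`), and per-taxon lognormal noise
  (`overdispersion`) prevents perfect coupling through the shared
  gradient.  `selection_strength=0` reproduces the neutral generator bit
  for bit.  `conserved_niches=False` keeps the same niche structure but
  decouples it from the phylogeny, so co-occurrence persists while βNTI
  reads the community as stochastic.
* **Mixed mode** — interpolates on the log-kernel scale with a recorded
  weight; weights 0 and 1 reproduce the neutral and selection generators
  exactly.
* **Cross-kingdom fixture** — 38 samples, 1,945- and 1,818-taxon tables at
  44,800 reads/sample sharing one metadata table.  The "mostly neutral"
  kingdom uses weak (weight 0.35), phylogenetically unconserved patchy
  blooms: it exhibits a modular co-occurrence network while its assembly
  reads as stochastic (near-null βNTI, Sloan R² ≈ 0.9).  The selection
  kingdom uses full-weight conserved niches (strength 4, σ = 0.4): high
  βNTI, mostly selection-classified pairs, lower Sloan R².  Both kingdoms
  use m = 0.05 — of the order implied by published Nm estimates at these
  depths — and produce non-empty abundant classes and rare majorities.

What the generator does **not** emulate: sequencing error and chimeras,
copy-number variation, compositional bias of extraction/PCR, temporal
dynamics, and spatially explicit dispersal.  Passing tests therefore show
the *algorithms* are correct and well calibrated on data whose generating
process is known; they do not certify the ecological conclusions one would
draw from any particular real survey.

## Problem sizes and numerical choices

Tests run the fixture at its full 38 × ~1,900 scale for single analyses and
reduce replication where many repetitions are needed: βNTI in the 20-seed
cross-kingdom contrast uses the 12 gradient-extreme samples at n_null = 99
(the discriminative margins are one to two orders of magnitude); null-model
calibrations use 60-tip trees with n_null = 199 and 200 replicates; the
Mantel type-I simulation uses 500 pairs of 15-sample matrices at 999
permutations.  The acceptance script runs the full fixture once per kingdom
at n_null = 199.  Degenerate inputs (zero-spread nulls, constant features,
edgeless networks, missing module hubs) degrade to flagged NaN values or
warnings rather than silent omission; all randomized procedures take
explicit seeds and results are bit-reproducible given the seed.

## Known limitations

* The Sloan fit treats taxa as independent observations; no uncertainty is
  propagated to Nm beyond the Wilson envelope on frequencies.
* The tip-shuffle null conditions on observed richness and abundance but
  not on habitat structure; βNTI magnitudes on strongly structured
  communities can be far outside ±2 and should be read as ordinal.
* Greedy modularity is deterministic but resolution-limited; very small
  modules may be merged.
* The explicit correlation threshold replaces the RMT scan of MENA; module
  counts and modularity are comparable only between networks built with
  the same thresholds.
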
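# Methods

This note documents the models implemented in `sipa`, the choices made
where the design was genuinely open, and what the synthetic validation
does and does not establish.

## Network model

The network is a typed undirected multipartite graph over compounds,
proteins and diseases with four edge types (CT, CD, DT, TT). Edge
identity is the unordered node pair plus the edge type; provenance
(`known`, `sim_inferred`, `ctcs_predicted`) and support are attributes,
not part of identity, because expansion must deduplicate predicted edges
against known ones regardless of origin. On merge the strongest
provenance wins (known beats any prediction) and supports are maximised.
All edges, including protein–protein, are modelled as undirected.
Entities appearing only in the node table are kept as isolated nodes so
that the isolated-node count is a meaningful topology statistic. Node-id
conventions (`C*`/`T*`/`D*`) are not enforced; the kind always comes from
the node table.

## Simple inference model

Five one-hop rules (README table) run over known edges only, in a single
pass: conclusions are never recycled as premises, so the output is the
one-round closure, not a transitive closure. The audit trail of each
inferred pair is its route list (`a-intermediate-b` chains); support =
number of distinct intermediates, which equals the number of routes
because routes with a repeated intermediate are collapsed.

The compound/disease-centered family (R4, R5) is filtered at support ≥ 2
by default — "more than one independent route" — while the
target-centered family runs unfiltered. The ≥ 2 filter applies to the
whole entity-centered family, R5 included. Two run modes:

* **production** (default): both families, support filters on, pairs
  already known are dropped; the output is the expansion edge set.
* **evaluation**: only the noisier entity-centered family runs (that is
  the family whose reliability the benchmark interrogates), support
  filters are relaxed to 1 and known pairs are retained and flagged, so
  the complete inference table can be compared against a held-back test
  set cell for cell.

## Descriptor preprocessing

Four removal criteria in a fixed order — missing values, near-constant
columns, low relative standard deviation, pairwise correlation — with
strict inequalities (> 0.80 modal share, < 0.05 RSD, > 0.9 |r|), reading
"more than"/"less than" literally.

* Near-constancy is the modal-value share after rounding values to 6
  significant digits; without a stated equality tolerance, rounding makes
  float comparison reproducible.
* RSD uses the sample standard deviation (n−1) over |mean|. A column with
  mean exactly zero and positive spread is kept (its RSD is unbounded,
  and dropping signed, informative descriptors would be destructive);
  mean zero with zero spread drops.
* The correlation filter is greedy: find the worst offending pair, drop
  the member with the larger mean |r| against all surviving columns
  (tie: the later column), recompute. This is deterministic where "drop
  one of the pair" alone is not, and on exact duplicates it keeps the
  earlier column.

The filter order matters (a column can violate several criteria; the
report attributes it to the first) and is regression-tested. Inside
cross-validation the cleaner is fitted on the training entities only.

## Canonical correlation analysis

Classical CCA on column-standardised blocks: the canonical correlations
are the singular values of `Sxx^{-1/2} Sxy Syy^{-1/2}`; weights are
rescaled so variates have unit sample variance; loadings are the Pearson
correlations between original descriptors and variates. Standardisation
statistics are stored in the fitted model and reused for held-out
projections. An optional ridge on the within-set covariances handles
near-collinearity; at ridge 0, `n ≤ max(p, q)` and zero-variance columns
are hard errors (the latter should have been cleaned away).

Per-variate significance is Bartlett's sequential chi-square
approximation: Λ_k = Π_{i≥k}(1 − r_i²),
χ²_k = −(n − 1 − (p+q+1)/2)·ln Λ_k with (p−k+1)(q−k+1) degrees of
freedom. This is the textbook sequential test that SPSS-style CCA output
reports; Rao's F is not exposed. When the sample is too small for a
positive multiplier, p-values are set to 1 with a warning.

Feature selection: variates with r_k > 0.8 and p_k < 0.01 contribute;
descriptors with |loading| ≥ 0.3 on any contributing variate are
selected. Loading-based selection is the standard way to map canonical
variates back to interpretable original variables; the cutoffs are
configurable.

## Correlation-space prediction

Distances are computed in the z-scored selected-descriptor subspace (not
in canonical-variate scores): the selection defines which descriptors
characterise the spaces, and raw selected descriptors keep the spaces
interpretable. Three per-anchor thresholds over the m member pairwise
distances are implemented:

* `ci_mean_t95` (default): d̄ + t_{(1+γ)/2, m−1}·s_d/√m — the literal
  "upper limit of the 95 % confidence interval of all distances" read as
  the CI of the mean distance;
* `mean_plus_1p96sd`: d̄ + z_{(1+γ)/2}·s_d — a normal upper tail of the
  distance distribution;
* `percentile95`: the empirical γ-percentile.

A single distance is its own threshold (degenerate flag set);
`min_members` defaults to 3 because a confidence interval needs at least
two distances. Decision rules: `all` (every candidate–member distance
within the threshold), `mean`, `any`; predicted sets nest
(`all` ⊆ `mean` ⊆ `any`).

Defaults differ between production and evaluation, deliberately.
Production prediction (`CorrelationSpacePredictor`, `sipa predict`) uses
`all`: when mining unknown interactions, demanding that a candidate sit
within the threshold of *every* known partner is the conservative choice.
Cross-validated recall (`cross_validate`, `sipa cv`) defaults to `mean`:
the default threshold is a confidence bound on the *mean* pairwise
distance, so the scale-consistent question for a held-out true partner is
whether its mean member distance is compatible with that bound; comparing
a maximum against a mean-scale bound systematically rejects typical true
members as member count grows and measures the conservatism of the rule
rather than the quality of the space. Either rule can be selected for
either task.

Prediction never re-emits training edges. Precision is undefined by
design — there is no negative set; recall of held-out known interactions
is the evaluation metric. Splitting is per-target (stratified): each
target's edges are shuffled and split 4:1 (or dealt round-robin into k
folds); a single-edge target stays in training. Folds whose test set is
empty are skipped; folds where no significant canonical variate survives
score recall 0 (the pipeline can predict nothing there) rather than
aborting the run. Held-out edges whose target space was skipped for
insufficient members count as misses.

## Topology statistics

Cytoscape-NetworkAnalyzer conventions on the simple undirected view:
density 2E/(N(N−1)); mean degree; heterogeneity = population sd(degree)
/ mean(degree); centralization = N/(N−2)·(max_deg/(N−1) − density);
shortest-path statistics within connected components (characteristic path
length averages over connected ordered pairs; diameter is the largest
finite eccentricity; the radius is the minimum eccentricity over
components evaluated independently, so a disconnected network can have
radius 1 alongside a large diameter). Centralization is undefined below
three nodes and reported as 0 with a flag. These conventions are
cross-checked against python-igraph on random graphs in the test suite.
Note that under the component-wise convention, adding a bridging edge
between components can *increase* the characteristic path length (it adds
long connected pairs); within a connected graph it never does.

Seed modules are induced subgraphs of all nodes within a shortest-path
radius (default 2) of a chosen node, with member counts reported by kind.
External clustering results (e.g. protein-complex module miners) can be
reported through the induced-subgraph interface; no clustering algorithm
is bundled.

## Synthetic data generator

The generator emulates the statistical structure the correlation-space
predictor assumes, so that held-out recall is a genuine recovery metric:

* every compound and protein has a latent position z ∈ R³ (standard
  normal);
* observed descriptors are an orthonormal linear image of z at signal
  scale s plus isotropic noise of sd `noise_sd`. With orthonormal maps,
  the shared-latent canonical correlation is s²/(s²+σ²); s is chosen so
  this equals `canonical_rho` (default 0.9) at the reference noise level
  0.3 (the default `noise_sd`). Raising `noise_sd` above the reference
  therefore attenuates the realized correlation — noise is a real dial,
  not a rescaling that standardisation undoes;
* nuisance columns (one with a missing value, a constant, a low-RSD
  column, a dominant-mode column, an exact-up-to-jitter duplicate and two
  pure-noise columns) are appended so every cleaning stage and the
  loading-based selection have real work to do;
* interactions: compound i partners protein j when their latent distance
  is under a radius. With an explicit radius the rule is global, and the
  radius grows geometrically (up to 100 attempts) until every protein has
  at least `min_partners` (= `min_members`+1 = 4) compound partners; with
  the default auto mode the radius is per-anchor — partners inside the
  tightest global radius, topped up to each protein's `min_partners`
  nearest compounds. The top-up keeps every partner set a
  nearest-neighbour set; inflating one global radius to serve the
  worst-placed protein floods central proteins with distant partners and
  dilutes the planted canonical correlation below the selection cutoff,
  which would defeat the generator's purpose.

Study conditions (defaults): 60 compounds, 20 proteins, 8 informative
descriptors per side, latent dimension 3, ρ = 0.9, noise 0.3, seed 7 —
about 80 CT edges, sized so the full cross-validated pipeline runs in a
couple of seconds.

What passing the synthetic validation shows: the pipeline recovers
planted geometry (tenfold CV recall ≥ 0.85 at the default conditions,
degrading monotonically as noise attenuates the planted correlation) and
each component matches its independent oracle. What it does not show:
performance on real MOE/ProFeat descriptor matrices, whose distributions
(heavy tails, block correlations, mixed scales) the generator does not
attempt to mimic, nor the published recall figures, which depend on
proprietary descriptor tables that were never released.

## Known limitations

* SIM is purely logical; supports are counts, not probabilities.
* The published descriptor lists for the real study cannot be reproduced
  without the proprietary descriptor software; the selection machinery is
  validated on synthetic data only.
* The choice among the three threshold readings is not settled by any
  published source; all three are implemented and the default is the most
  literal one.
* Identifier resolution against external databases (PubChem, UniProt,
  OMIM) is out of scope; inputs are assumed to use consistent ids.
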
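# Methods

## Model

The unit of analysis is an *adjacent KO pair*: two KEGG Orthology groups
connected on the merged pathway network through an intermediate compound.
The network is rebuilt from KGML documents: ECrel relations (two enzymes in
successive reactions) become edges labelled with the relation's compound;
maplink relations are joined across maps — a KO linking from map A towards
map B and a KO linking from map B towards map A through the same compound
become one edge.  Overview/global maps (KEGG 011xx/012xx prefixes by
default) are excluded, ortholog boxes listing several KOs expand to all
cross combinations (never self-pairs), and parallel edges collapse with
their compound sets merged.

For a pair (A, B) the interaction score is `S = D · R`:

- `D = (1 − r_phylo)/2`, with `r_phylo` the Pearson (phi) correlation of the
  binary genus-presence vectors.  The mapping keeps `D ∈ [0, 1]` and
  `S ∈ [−1, 1]`, which is what makes the fixed threshold `τ = 0.6`
  meaningful; `1 − r` and `−r` variants are selectable.  A literal
  reciprocal `1/r` is unbounded and sign-inverting and is not offered.
- `R` is the Pearson correlation of the two KOs' relative abundances across
  samples (Spearman selectable).  The sample set is a parameter, so
  per-cohort scores use the same code path.

A pair is *undefined* when either profile is constant (zero variance); such
pairs are flagged, carry NaN components, and are excluded from thresholded
selections rather than imputed — there is no evidence either way and
exclusion is conservative.  Selection at the threshold is inclusive
(`S ≥ τ`).

Pair classes: a pair is *metabolic–non-metabolic* (boundary) when it matches
a (uptake KO, compound, producer KO) triple — the uptake KO sits on one of
the transporter/signalling maps 02010 (ABC transporters), 02020
(two-component system) or 02060 (PTS), the producer on a metabolic map, and
the linking compound is shared.  The map list is configurable.  Pairs whose
KOs appear only on metabolic-category maps are *metabolic–metabolic*;
everything else is unclassified.

Module lookup: a pair's compounds are checked against pathway-module
definitions (terminal "edge" compounds = initial substrates + final
products; interior compounds = "non-edge").  A compound that is a terminus
in one module and interior in another counts as *edge*: any terminus can
link modules, which is the property being tested.

## Statistical tests

- Boundary validation: one-sided two-sample Kolmogorov–Smirnov test with the
  alternative "boundary scores stochastically greater" (scipy `ks_2samp`
  with the boundary group first and `alternative="less"`, i.e. its CDF lies
  below; the direction is pinned by a unit test against a 10,000-draw
  permutation oracle).
- Module linkage: pairs are binned into half-open score windows (default
  width 0.1 over [−1, 1], last window closed) and the score distributions of
  edge-compound vs non-edge-compound pairs are compared by a one-sided
  Mann–Whitney test (edge greater).  An alternative comparing per-window
  edge fractions below/above a threshold is available behind a flag, since
  the grouping is a genuine modelling choice.
- Null simulation: one-way ANOVA over the three normalized-count groups plus
  pairwise one-sided Mann–Whitney tests (structured > genome null,
  structured > gene null, genome null > gene null).
- Cohort rule: with μ, σ the mean and sample (n−1) SD of
  `delta = score_healthy − score_disease` over all shared pairs,
  healthy-specific pairs satisfy `delta > μ + 2σ` and `score_healthy > τ`
  (symmetrically for disease).  Requiring the unfavoured cohort to be below
  τ is optional and off by default.

## Null models

A genome catalog (genome → genus → KO set) restricted to the community's
genera is resampled by rejection: the genome count is uniform on
[1, catalog size], genomes are drawn without replacement (a genus may
contribute several genomes), and a draw is accepted iff its union KO count
falls in the envelope [ko_min, ko_max].  The envelope defaults to the
min/max of the structured cohort's per-donor detected-KO counts — the
bounds are data values, not method constants.  A matched *gene set* is then
subsampled from each accepted union with size uniform on
[ko_min, min(ko_max, union size)]; the size law is not otherwise
constrained, and uniform is the least-informative choice.  The interacting
pair list is computed once from the structured cohort and reused for all
draws; each group's count of fully contained pairs is normalized by its
unique-KO count.  The rejection cap is 10,000 attempts per accepted draw.

## Donor clustering

Interacting KO pairs are projected to genus pairs: for pair (A, B), genus
pair (g, h), g ≠ h, whenever g carries A and h carries B or vice versa
(a `strict_complement` flag additionally requires each genus to lack the
partner KO).  Per-donor presence of a genus pair requires one supporting KO
pair detected on both sides in that donor.  Pairs present in ≥ 90% of
donors (configurable) are split off as the community-wide core; donors are
clustered on the remainder by agglomerative clustering with Jaccard
distance and average linkage — appropriate for sparse binary profiles and
both configurable — and the tree is cut to a requested cluster count or
height.  The cluster count is an analysis parameter, not a method constant.
Per-cluster genus networks keep edges whose aggregate (summed supporter)
score passes a display threshold; per-pair scores are ≤ 1, so the threshold
operates on the aggregate, and its useful magnitude scales with how many KO
pairs support a genus pair (large catalogs support thresholds around 15,
the small synthetic communities around 5).

## Synthetic data generator

`synthdata` emulates the statistical structure the score assumes, with a
known truth list.  The small reference setting is 20 genera, 300 KOs, 60
donors, 10 planted metabolic pairs, 3 planted boundary pairs, noise SD 0.3,
coupling strengths 0.9.

- **Pathway**: metabolic KOs form a chain split over maps 00010/00020
  (joined by reciprocal maplinks), every edge carries a compound, planted
  pairs occupy every tenth chain edge, and each boundary pair joins a
  producer to a transporter KO on map 02010 through a dedicated compound.
  Chain compounds are grouped into 5-compound modules, which places planted
  edges at module termini — planted interspecific handoffs occur at module
  boundaries by construction.  A small density (2%) of extra random edges
  provides background pairs beyond the chain.
- **Phylogenetic channel**: each planted pair gets complementary balanced
  genus blocks; each side's presence bit flips with probability
  `(1 − complementarity)/2`, so strength 1 gives exact complements
  (`r_phylo = −1`) and strength 0 gives independence (expected D = 0.5).
  Background presence is Bernoulli(0.25) per (KO, genus).
- **Co-occurrence channel**: a planted pair shares a per-donor detection
  indicator (probability 0.9) and a lognormal latent factor mixed at weight
  `cooccurrence_strength` with independent factors, times
  `exp(noise_sd · ε)` noise.  At full coupling and zero noise the two
  abundance vectors are bit-identical, so `R = 1` and `S = 1` exactly
  (the Pearson implementation clips to [−1, 1], making the noiseless limit
  exact in floating point).  Background KOs are detected independently with
  probability 0.6 scaled by a per-donor depth factor uniform on
  [0.75, 1.25] — sequencing-depth heterogeneity, which also gives the donor
  unique-KO envelope realistic width.
- **Donor structure**: 3 community types, each a genus subset drawn at
  inclusion probability 0.6; a donor's genus set is its type's set with 5%
  flips.  Per-donor KO × genus tables are the global table masked to the
  donor's genera.
- **Genome catalog**: 1–3 genomes per genus; each genome carries each of
  its genus's KOs with probability 0.7.

What the generator does *not* emulate: compositional closure of relative
abundances (no simplex renormalization), phylogenetic correlation between
genera, read-level noise, gene prediction or annotation error, and any
coupling between the abundance channel and the genus channel beyond the
planted pairs.  Passing tests therefore demonstrate that the method
recovers the targeted signal structure when it is present, not that real
gut data contains it.

## Numerical choices and degenerate inputs

- Correlations are computed from centred sums and clipped into [−1, 1];
  zero-variance vectors yield NaN, which propagates to `defined = False`.
- Ties in `select_interacting` break lexicographically on the pair key;
  scipy's linkage resolves equal merge distances by index order, making
  clustering deterministic for a fixed input ordering (and stable under
  donor permutation up to relabelling).
- Jaccard distance between two all-zero donors is taken as 0 (identical).
- Window assignment is half-open with the last window closed, so every
  defined score lands in exactly one window.
- All randomness flows through `numpy.random.Generator`; fixed seeds give
  byte-identical outputs.

## Problem sizes

Tests and the acceptance script run on the small reference setting (and a
30-donor variant for clustering): 20 replicates for recovery and boundary
separation, 100 null draws per group, 10 clustering replicates, 1,000-pair
cohort tables.  These sizes give stable Monte-Carlo margins for every
directional claim while keeping a full run in seconds; the `medium` preset
(40 genera, 1,000 KOs, 150 donors) is provided for larger experiments.

## Known limitations

- The maplink join requires reciprocal links with matching compounds; KGML
  files that link asymmetrically will not produce cross-map edges.
- Boundary classification depends on map-category assignments supplied at
  build time; KOs appearing on both metabolic and non-metabolic maps are
  classified through transporter relations only.
- Undefined (constant-profile) pairs are dropped from all thresholded
  analyses; in very sparse communities this can remove real pairs.
- The 2-SD cohort rule assumes the shared-pair delta distribution is
  unimodal with thin tails; heavy-tailed deltas inflate σ and hide true
  cohort-specific pairs.
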
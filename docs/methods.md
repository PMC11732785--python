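# Methods

This note records the conventions, parameter choices, and numerical
decisions behind `webprint`, and what the synthetic tests do and do not
establish about real food-web collections.

## Graphlets, orbits, and numbering

Counting is over **induced** subgraphs: a 4-cycle contains four induced
3-paths and one induced 4-cycle, but no induced 4-path — the graphlet
convention, as opposed to motif (partial-subgraph) counting.  Orbit ids
follow the standard 15-orbit catalogue for 2–4-node graphlets; the 11
non-redundant orbits used here are {0, 1, 2, 4, 5, 6, 7, 8, 9, 10, 11}
(columns in that order everywhere, CSV headers `o0,o1,o2,o4,...,o11`).
Orbit 3 (triangle) and orbits 12–14 (diamond, 4-clique) are excluded as
linearly redundant.  Figures that number the used orbits consecutively
0–10 map onto this set in the same order; we keep the catalogue ids for
interoperability with existing orbit-count tooling.

The fast counter evaluates closed-form identities: non-induced path, star,
cycle and tailed-triangle pattern counts have direct matrix expressions in
the adjacency matrix and the common-neighbor matrix, and induced counts
follow by subtracting the contributions of denser graphlets (tailed
triangle, diamond, 4-clique), which are counted directly from
neighborhood submatrices.  Two identities are asserted on every call
(orbit-0 column = degree sequence; its sum = 2 × edges), and the exhaustive
subset-enumeration counter is retained as an independent oracle — the test
suite checks exact agreement on hundreds of random graphs, so any slip in
the algebra is caught, not trusted.

## GCM-11 and GCD-11 conventions

Spearman correlation is undefined on constant columns, and sparse webs
routinely produce all-zero orbit columns.  Following the practice of
reference graphlet-correlation implementations, one pseudo-row of all ones
is appended to the *n* × 11 count matrix before correlating: an all-zero
column then correlates at −1 with any strictly larger column rather than
being undefined.  Columns still constant after the pseudo-row (i.e.
constant at 1) get correlation 0 with everything; the diagonal is fixed
at 1.  Ties take average ranks.  Correlations are computed by ranking each
column (`scipy.stats.rankdata`) and taking the Pearson correlation of the
ranks, which is the textbook definition and well-behaved for every input
shape.

The distance is the Euclidean norm over the 55 strictly-upper-triangular
GCM entries.  Some renderings of the defining formula show only the double
sum of squares; since the quantity is introduced as a Euclidean distance,
the square root **is** applied here (and a `squared=True` flag exposes the
sum-of-squares variant).  Hence every distance lies in [0, √220 ≈ 14.8324],
and the matrix over a collection satisfies the metric axioms exactly (it is
a Euclidean distance between 55-vectors); identity of indiscernibles holds
at the GCM level — distinct webs with identical GCMs are at distance 0 by
design.

## Inclusion filters

Order of operations, fixed for reproducibility: (1) consumer/resource
roles are counted on the **raw directed** web (a consumer has an incoming
edge from a distinct node, a resource an outgoing one; self-loops ignored;
a node may be both) — roles are only defined while edges still have
direction; (2) symmetrization to a simple undirected graph (reciprocal
pairs collapse, cannibalism loops drop — the graphlet dictionary contains
simple graphs only); (3) giant-component extraction, ties broken by the
component whose lexicographically smallest label is smallest (real webs
essentially never tie; the rule exists so reruns are byte-identical);
(4) thresholds: ≥ 10 final nodes, ≥ 5 consumers, ≥ 5 resources.  Whether
roles should be counted before or after component extraction is genuinely
open; `role_stage="final"` switches to the alternative.  Bipartite study
designs are excluded via a metadata flag supplied by the caller —
two-colorability of the processed web only sets a warning field, because
bipartite-like topology can arise from sampling without a bipartite
design.

## Cohort statistics

Within-group dispersion is the mean (or median — same code path, selected
by a flag, as an outlier-robustness variant) of the C(n,2) pairwise
distances; groups need ≥ 2 webs and smaller groups are reported as
missing, never as zero.  Per-publication dispersions aggregate via a
web-count-weighted mean: Σ(value_p · n_p) / Σ n_p.  Decades are
floor(year/10)·10.  For the decade trend of multi-web publications the
"weighted SD" is ambiguous (weighted SD of per-publication means vs
weighted mean of per-publication SDs); both are emitted (`sd`,
`mean_pub_sd`).  No significance tests are computed anywhere — groups of
pairwise distances with unequal dispersion and location are poorly served
by permutation-ANOVA machinery, so outputs are effect sizes (differences
and ratios of means) only.

MDS is classical/metric: eigendecomposition of the doubly-centred
squared-distance matrix, axes ordered by eigenvalue, each axis sign-fixed
so its largest-magnitude coordinate is positive; the relative stress
√(Σ(d̂−d)²/Σd²) is reported.  Classical MDS is deterministic, which we
prefer over stress-majorization variants for a visualization-only step.

The size diagnostics ask whether dispersion is a sampling-effort artifact:
Spearman correlations of per-group dispersion against group mean and SD of
node count, and of pairwise distance against |n_i − n_j| and (n_i+n_j)/2.
Correlations on constant inputs are reported as missing with a note.  This
diagnostic is a documented reconstruction, and is labelled as such in its
output.

## Synthetic cohorts

The niche model is the base generator: niche values n_i ~ U(0,1), range
width r_i = x·n_i with x ~ Beta(1, 1/(2C) − 1), centre
c_i ~ U(r_i/2, min(n_i, 1 − r_i/2)); i consumes every j with n_j in the
range.  E[L/S²] ≈ C (verified by Monte-Carlo in the tests at S=50,
C=0.15, 500 replicates, tolerance ±0.02).  A *publication profile* adds
protocol distortions: taxon aggregation (merge nodes sharing a niche-axis
bin of the given width; merged node keeps the smallest label) and link
detection (independent Bernoulli thinning of directed links).  Per-web
seeds are SHA-256 hashes of (master seed, publication id, web index), so
cohorts are pure functions of (profiles, master seed) and independent of
generation order.

Default scenarios, chosen once as the study conditions:

- **strong**: 6 publications × 5 webs; connectance spread over
  [0.05, 0.25], detection probability over [1.0, 0.5], aggregation
  alternating 0/0.05, and per-publication richness scales between (20, 30)
  and (60, 80) — i.e. publications differ on all four shared channels, the
  scaled-down analogue of a repository in which each source has its own
  biology *and* its own protocol.
- **null**: same shape, every publication identical (S ∈ [30, 60],
  C = 0.15, no aggregation, full detection) — the publication label
  carries no information.

The generator emulates *parameter sharing* within publications, not real
ecological mechanism: niche-model webs are interval digraphs with none of
the phylogenetic structure, spatial habitat signal, or body-size
constraints of field webs, and the protocol channels are idealized
(uniform detection probability, niche-adjacent aggregation).  Passing the
recovery test therefore shows the *pipeline* can separate within- from
between-source dispersion when a publication effect exists and reports
none when it does not; it does not by itself establish the magnitude of
the effect in any real repository.

## Problem sizes and determinism

Test and acceptance workloads are scaled to desk size: oracle agreement on
200 (tests) / 60 (acceptance script) random connected graphs with
n ∈ [5, 25]; metric checks on 30 filtered niche webs (435 pairs);
publication-effect recovery over 20 replicate cohorts per scenario.  All
randomness flows from explicit seeds; pipeline reruns on identical inputs
and config produce byte-identical CSVs (fixed float format `%.10g`,
deterministic orderings everywhere).

## Known limitations

- Orbit counting covers 2–4-node graphlets (GCD-11); 5-node graphlets
  (GCD-73) and directed graphlets are out of scope.
- The fast counter loops over nodes with dense neighborhood submatrices —
  fine for webs up to a few thousand nodes, not engineered for large dense
  graphs.
- Node labels are opaque strings (trimmed, case-sensitive); no fuzzy
  name harmonization across webs is attempted.
- Adjacency input is binarized (any value > 0 becomes a link); weighted
  analyses are not supported.
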
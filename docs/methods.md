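# Methods

This note documents the models, decision rules, numerical conventions
and design choices behind `barcodeval`, and what the synthetic-data
studies do and do not establish.

## Data model

A dataset is a specimen table (sample id, species, genus, family, plot)
plus one aligned matrix per locus. Validation enforces unique sample
ids, one genus per species and one family per genus ("unknown" is a
permitted species placeholder), and equal row lengths per locus.
Characters outside `{A,C,G,T,-}` — IUPAC ambiguity codes included —
collapse to `N` on input: every downstream rule speaks only of
identical or comparable plain-base sites, so finer ambiguity handling
would never be consulted. Specimens missing from every locus are
retained; they represent total sequencing failure and belong in
recovery denominators. Recovery statistics report fractions of all
specimens by default and accept a caller-supplied denominator, because
sequencing-success conventions sometimes divide by PCR-positive samples
only, a count not derivable from sequence data.

All percentages and ratios in reports use half-up rounding (90.546 →
90.5, 9.55 → 9.6) at one decimal (clade-richness S/G also at two).

## Supermatrix

Loci are concatenated in caller order into a single matrix with a
0-based half-open partition map (also emitted as 1-based RAxML-style
lines). Under the default union member policy a specimen missing a
locus is padded with `-` across that locus's columns; padding encodes
*absence of data*, and all distance/identity code treats `-` as missing
(pairwise deletion), never as an indel.

Loci that cannot be aligned across families (typically *trn*H–*psb*A)
enter as per-family alignments laid out block-diagonally: each family
owns a disjoint column range. This is an explicit design choice — the
cross-family columns of such a locus carry no signal by construction,
so a pair of specimens from different families has zero comparable
sites at that locus and is marked *undefined*, never silently 0. Other
loci in the supermatrix supply the cross-family signal; a tree built on
a block locus alone is refused unless the offending members are
removed (the pipeline removes them greedily and logs the ids).

## Distances, Neighbor-Joining, bootstrap

Two distance models are offered: the p-distance (mismatches over
comparable sites) and Kimura's two-parameter distance
d = −½·ln(1−2P−Q) − ¼·ln(1−2Q), with P and Q the transition and
transversion proportions. K2P is the default, as the long-standing
community convention for barcoding NJ trees; the two agree to first
order at the divergences barcodes operate at, so conclusions do not
hinge on the choice. Saturated pairs (log argument ≤ 0) are marked
undefined.

Neighbor-Joining is the classic Saitou–Nei agglomeration on the
Q-criterion. Two conventions make it deterministic and robust: ties on
Q are broken toward the pair of clusters carrying the lexicographically
smallest leaf names, and negative branch lengths are clamped to zero
with the remainder transferred to the sister edge — downstream use is
topology and support only, so branch-length niceties are deliberately
minimal.

Bootstrap support resamples alignment columns with replacement —
within each partition independently when a partition map is supplied,
so family blocks are resampled inside their own column ranges — and
rebuilds the NJ tree per replicate. Support for each internal edge of
the *original* tree is the percentage of replicate trees containing
the same bipartition (the original topology is kept; no consensus tree
is substituted). Replicates in which some pair loses all comparable
sites are redrawn and counted. Trivial bipartitions (single leaf or
its complement) exist in every tree and are treated as 100% supported.

## Supported-monophyly resolution

A taxon with leaf set S (2 ≤ |S|) on an unrooted tree is monophyletic
iff the bipartition S | rest exists; it is *resolved* when that edge's
support meets the cutoff (default 50%). Taxa with one sampled leaf are
excluded from the denominator ("samples ≥ 2"). Monophyly is defined on
the unrooted tree via bipartitions because no outgroup is available or
needed. A taxon spanning the entire tree has no separating edge and
counts as resolved; edges without recorded support (un-bootstrapped
trees) satisfy the cutoff, so plain topology checks work. Genus and
family resolution use the identical criterion with leaves labeled at
the coarser rank — scored exactly like species, which is one of two
defensible readings; the alternative (requiring only the conspecific
subclades) is not implemented. Combinations are evaluated on union
supermatrices (members with ≥ 1 constituent locus); taxa absent from a
tree are excluded from that tree's denominator.

## Similarity-based identification

Identity between aligned sequences is identical sites over scored
columns, where a column is scored when both sequences carry a plain
base. Multi-locus identity pools matched and scored sites across the
loci shared by query and subject — a scored-site-weighted average,
equal to the identity of the concatenation where both are complete,
and still defined when subjects have different locus availability
(concatenation is not). An unaligned mode computes a free-end-gap
global alignment (match +1, mismatch −1, gap −2, terminal gaps free)
via Biopython's pairwise aligner and scores identity between the first
and last both-residue columns, internal gaps counting against it.
Exact pairwise scoring replaces heuristic local search deliberately:
it makes the ≥ 95% rule exactly auditable against brute force, at the
cost of not reproducing heuristic-specific artefacts.

The decision rule, at species level: let B be the species of the
top-identity subject. The assignment is *correct* iff (i) the query is
≥ threshold (default 0.95) identical to some subject of its own
recorded species, (ii) every subject of B is strictly more identical
than every subject of any other species, and B is the recorded
species. Failing (i) is *no assignment*; failing (ii) or B ≠ recorded
is *incorrect*. A tie between the best conspecific and a
heterospecific breaks strict dominance and scores as incorrect.
Queries with no scorable subject are *unscorable*; queries whose
species has no other database member are vacuous and excluded from the
species denominator (an all-singleton database has species denominator
zero). Rates are correct / (correct + incorrect + no-assignment), with
no-assignment and unscorable counts reported separately.

The genus outcome is *derived from the assigned species*: correct iff
some congeneric subject reaches the threshold and the strictly
dominant best species belongs to the recorded genus. A fully
genus-granular dominance rule (all congeners beating all
non-congeners) was considered and rejected: it violates the natural
contract that a correct species assignment implies a correct genus
assignment, and it penalises exactly the situation genus-level
identification exists for — the query matching a wrong but congeneric
species.

Cross-plot evaluation takes one plot as the database and filters each
query plot to specimens whose species (species-level tally) or genus
(genus-level tally) is represented in the database; querying the
database plot against itself reduces exactly to leave-one-out within
that plot.

## Misidentification audit

A leaf is flagged when the smallest clade (bipartition side) containing
it and at least one other leaf holds no recorded conspecific, and the
best-supported *internal* edge separating it from all conspecifics
meets the support gate (default 50%, matching the resolution cutoff).
The gate deliberately does not use the smallest clade's own edge:
conspecific sequences are nearly identical, so the local edges inside
a species cluster resolve arbitrarily and carry low support even when
a deep, maximally supported split isolates the leaf from its species.
Pendant edges are excluded from the gate as vacuous (they exist in
every replicate). Singleton species have no conspecific to conflict
with: for them the gate falls on the enclosing-clade edge, and a
species-level disagreement is not flagged — singletons are only
reported when nested inside a foreign genus or family.

The flagged leaf's *neighborhood* taxonomy is the per-rank majority
among the other leaves of its smallest clade (ties broken
lexicographically), and the conflict level is the shallowest rank of
disagreement; "unknown" is reserved for placeholder taxonomy. When two
mutually foreign leaves form an isolated pair, both are flagged — the
tree cannot tell which label is wrong; that decision is the
herbarium-review step, which is human work outside this package.
Summaries report the flag rate over audited leaves and per-level
shares, with placeholder-taxonomy flags excludable from the share
denominator (both conventions appear in practice and they disagree;
the package computes either on request rather than reconciling them).

## Synthetic data generator

The generator emulates a plot-based collection campaign. Taxonomy:
configurable counts (fixed or ranges) of families, genera per family,
species per genus, and 1–6 specimens per species; specimens are
allocated to plots by weight, defaulting to four plots weighted
1019 : 725 : 220 : 88 — one large permanent plot plus three smaller
survey plots, the sampling structure of a regional inventory.

Per locus, sequences evolve under Jukes–Cantor (single rate, no
indels — generated data is born aligned; the family-block code path is
exercised by generating block loci per family in independent
coordinate systems) along an ultrametric taxonomy-concordant tree.
The tree is built by nested Yule-style joining: within each genus,
species lineages join pairwise at ages drawn uniformly in
(0.20, 0.45) × H; genera within a family in (0.50, 0.75) × H; families
in (0.80, 1.00) × H, where H is the locus's interspecific root height
(default 0.05 substitutions/site). Conspecific specimens attach as a
star at the intraspecific height (default 0.001), optionally with a
per-plot substructure adding extra between-plot divergence (default
0.0005, half the intraspecific height) so multi-plot sampling inflates
intraspecific variation the way pooling collection sites does. The
disjoint bands guarantee every named taxon is a clade of the true tree
and enforce a clean rank hierarchy; the generator refuses
configurations whose intraspecific height invades the interspecific
band (an inverted barcode gap) unless explicitly overridden. The
default intra/inter heights are stated choices, not estimates — no
quantitative divergence figures were available to calibrate them — and
both are exposed in the configuration.

Sequence recovery is an independent Bernoulli draw per specimen per
locus, with default rates 0.806 (*rbc*L), 0.693 (*mat*K), 0.697
(*trn*H–*psb*A, family-blocked), 0.525 (ITS) — a realistic mixed
profile in which the standard plastid barcode recovers best and the
nuclear marker worst. Misidentification injection corrupts a
configurable fraction of specimen labels (default 9.6%) at
family/genus/species levels in a configurable mix (default 74 : 17 : 5,
allocated by largest remainder so exact mixes reproduce exactly):
a family-level error swaps in a species from another family, a
genus-level error another genus of the same family, a species-level
error another congeneric species. The ground truth retains true
labels and the full error list.

What the generator does *not* emulate: correlated recovery failure
across loci (real failure concentrates in bad extractions, so the
independent model overstates any-marker recovery), indels and
alignment error, rate heterogeneity across sites or lineages,
coalescent discordance between gene trees and the species tree, and
sequencing error. Passing the synthetic studies therefore shows the
*machinery* is correct and the *directional* effects are real under
the stated model; it does not certify identification rates on real
floras, where alignment quality and shared polymorphism dominate.

## Evaluation studies

`barcodeval.studies` fixes the reference experiments (sizes chosen so
the whole set runs in about a minute on one CPU; the contrasts probed
do not depend on census size):

* **Parameter recovery** — 12 species, 2–3 specimens each, two
  1000-column loci, intra 0.001 vs inter 0.05, 100 bootstrap
  replicates, 20 seeds: supported-monophyly species resolution and
  leave-one-out species identification are both 100%, no clean
  specimen is flagged, and ≥ 95% of injected family/genus errors are
  recovered. Species-level injected errors are *not* asserted: a
  specimen relabeled to a congeneric species can sit as close to its
  recorded species as to its true one, and no tree criterion can
  separate those reliably.
* **Clade richness** — ~20 species in 8 genera (S/G ≈ 2.5) vs 13
  genera (S/G ≈ 1.5), same divergence parameters, short (300-column)
  loci so identification is fallible: the high-richness regime
  identifies fewer specimens to species.
* **Cross-plot** — two equal plots, extra between-plot divergence
  0.002 on intra 0.001: cross-plot identification does not exceed
  within-plot identification.
* **Combinations** — two loci with identical parameters: the pooled
  two-locus identification rate is at least each single-locus rate.

## Numerical conventions and degenerate inputs

Deterministic throughout: every stochastic step takes a seed (study
seeds are spawned from one master seed via `numpy.random.SeedSequence`),
NJ tie-breaks are lexicographic, flag and report orders are sorted.
Undefined quantities are explicit — NaN-plus-zero-count distance
marks, `None` rates for empty denominators, "NA" cells in reports —
and every pipeline stage emits its artefact even when empty. Zero-size
inputs (empty datasets, all-singleton species tables, zero-replicate
bootstraps, empty combinations) raise validation errors naming the
problem rather than producing vacuous numbers.

## Known limitations

Maximum-likelihood trees are out of scope (NJ and ML are reported to
rank barcodes near-identically, and NJ keeps the pipeline exact and
fast). BLAST itself is not wrapped; the exact scorer is O(n²) in
database size and is the right tool up to a few thousand sequences,
beyond which a k-mer prefilter would be the natural extension. The NJ
implementation is the O(n³) textbook algorithm — fine for plot-scale
libraries (hundreds of specimens), not for tens of thousands. Genus-
and family-level resolution scored as supported monophyly of the whole
rank is conservative where a genus is paraphyletic on the gene tree
despite every species resolving.
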
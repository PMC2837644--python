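# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Redundancy removal

Keyword-assembled protein sets contain many near-identical deposits of the
same protein. Redundancy is removed by greedy incremental clustering:
sequences are processed longest-first (stable for equal lengths), each
joining the first existing cluster whose *representative* it matches at or
above the identity threshold (default 95 %), otherwise founding a new
cluster. The representative is therefore always the longest member, and the
procedure is deterministic for a fixed input order.

Percent identity between two sequences is the number of identical aligned
positions in the optimal global (Needleman–Wunsch) alignment — match +1,
mismatch 0, linear gap −1 — divided by the length of the **shorter**
sequence. This is CD-HIT's identity notion; using the shorter-sequence
denominator means a fragment fully contained in a longer deposit scores
100 % and is absorbed, which is the desired behaviour for redundancy
removal. The alignment kernel is exact dynamic programming
(`Bio.Align.PairwiseAligner`); when several alignments are co-optimal the
first is used, which is deterministic and shared by the brute-force test
oracle.

A shared-k-mer prefilter (k = 5) skips alignments that provably cannot
reach the threshold: a pair at identity ≥ t over shorter length L preserves
at least (L − k + 1) − k·((1 − t)·L + 3) of the shorter sequence's k-mers
(multiset count; the slack term of three absorbs alignment gap runs).
Candidate representatives are found through an inverted k-mer index, so
unrelated random sequences are rejected without any alignment. The
prefilter is a pure speed device — a brute-force implementation computing
the full pairwise identity matrix with the same greedy rule is kept in the
package (`cluster_brute_force`) and the two are asserted equal on hundreds
of random sets in the test suite.

**Inter-species screen.** After clustering, each cluster keeps its
representative plus, for every *other* species present in the cluster, that
species' longest member. Cross-species (near-)identical proteins are
conserved orthologues, not database redundancy, and per-genome counts would
otherwise be systematically understated.

## Domain annotation

Hits are read either from HMMER3 per-domain tabular output (`domtblout`,
hmmsearch orientation: target = protein, query = domain; independent
E-value, per-domain bit score, envelope coordinates) or from a flat
tab-separated table. Coordinates are 1-based inclusive throughout and never
converted.

Filtering keeps hits with E ≤ 0.1; the boundary is inclusive. Overlap
resolution applies only to hits of the **same** domain family: among
same-name hits overlapping by more than 50 % of the shorter envelope, the
lowest-E-value hit wins (ties: lowest start). This prevents double-counting
a tandem repeat that the profile matched in overlapping fragments while
preserving genuine disjoint repeats; hits of different families are never
removed, since nested or overlapping distinct domains are real. The
filter → resolve → build chain is idempotent on its own output.

A protein whose surviving hits include FYVE belongs to the FYVE dataset,
likewise for PX; a protein with both belongs to both, mirroring the two
independent keyword-defined downloads the analysis models. Pfam clans are
not collapsed and nested domains are not specially treated.

## Core statistics

* **Selectivity** counts distinct FYVE-dataset and PX-dataset proteins per
  species; the bias is FYVE, PX or equal by strict comparison.
* **Presence map / Venn partition.** A domain is "present" in a group if at
  least one anchor protein of that group carries it — presence, never copy
  number. The partition is over the four eukaryotic groups only; the single
  recorded viral FYVE protein is reported separately rather than added as a
  fifth Venn set. Exclusive = one group, core = all four, shared =
  everything between, keyed by the exact group subset. The three
  compartments are disjoint and exhaustive by construction, and the
  exclusivity percentage depends only on compartment sizes (invariant under
  domain renaming).
* **Association score.** A_r counts anchor proteins whose associated set
  contains r — a protein with three Ank copies contributes one — and
  score(r) = A_r / N with N = ΣA_r, so scores sum to one. For ranking
  plots, domains with a single representative (A_r = 1) are dropped; ties
  are broken alphabetically.
* **FYVE–RCC1–DZC correlation.** Per streptophyte genome, x = total FYVE
  proteins, y = FYVE proteins whose associated set contains both RCC1 and
  DZC. Pearson's r is used (the relationship modelled is linear
  amplification of one gene family); it is reported only with ≥3 species
  and non-degenerate variance, and the method name is recorded in the
  output metadata.
* **Percentages** are rounded half-up to integers for reporting (62.5 → 63).

## Functional categories

The shipped mapping assigns associated domains to fifteen categories:
thirteen adopted from the COG functional classification plus
protein-protein interaction and catalytic. The mapping is many-to-many and
unweighted, so a multi-category domain (e.g. PH: signal transduction and
cytoskeleton) contributes its full association score to each of its
categories and category totals may exceed one; reports state this. Unmapped
domains roll up to "unassigned". One bare entry (`M`) is carried verbatim
from the source table and flagged as dubious rather than silently dropped.

## Binding-site classification

The FYVE PtdIns(3)P pocket is located by scanning every hexapeptide of the
FYVE-domain envelope against the three consensus patterns — canonical
R-R-H-H-C-R, K-R/K-H-N-C-Y (FYVE–RCC1–DZC architectures) and G/S-R-H-H-C-R
(DUF500-associated) — scoring one point per matching position, choice
positions counting as matches. The best-scoring window wins, leftmost on
ties; the flanking WxxD and RVC motifs are recorded when present. A window
whose best score is below 5 is flagged low-confidence.

Classification: an exact (6/6) pattern match yields its class; a 5/6 match
yields the best class flagged "near"; below that the site is unclassified
rather than forced into a cluster. Equal scores resolve by precedence
canonical > duf500_type > rcc1_dzc_type, canonical being the ancestral
consensus (note duf500_type differs from canonical at a single position, so
a substitution there is genuinely ambiguous). This pattern classification
reproduces the cluster semantics that tree reconstruction over aligned FYVE
domains yields, because the clusters are *defined* by their binding-site
consensus; multiple alignment and parsimony tree building are deliberately
out of scope.

## Synthetic proteomes

The generator's defaults are the study conditions. The default preset
models 58 completely sequenced genomes — 20 metazoa, 17 fungi, 5
streptophytes, 4 chlorophytes, 12 protists — plus one viral FYVE protein,
with per-genome protein counts drawn negative-binomially (mean +
dispersion). Means are chosen so a run yields ≈2,000 proteins including
duplicates. Group conditions: every fungal genome strictly PX-biased, every
streptophyte strictly FYVE-biased (draws violating a strict bias have their
two counts swapped, with equality broken upward), chlorophytes PX-biased
with FYVE largely absent, protists mixed with two ciliate-like heavy PX
expansions (tail multiplier on a low-dispersion draw), metazoa PX-biased in
aggregate.

The associated-domain pools reproduce the published Venn compartment sizes
exactly — FYVE: 5 core / 8 shared / 9 + 4 + 13 + 19 exclusive (58 total);
PX: 3 core / 19 shared / 22 + 16 + 4 + 21 exclusive (85 total) — with
association frequencies drawn from a Zipf weighting over the pool (core
domains first, hence most frequent, matching the observed ranking). A
fix-up pass plants each configured domain in every group it is assigned to,
so the configured presence structure is always realised; a fraction of
exclusive domains (singleton_rate) is planted exactly once to exercise the
single-representative exclusion rule. RCC1, DZC and DUF500 are attached
only through explicit architecture planting, keeping FYVE–RCC1–DZC strictly
streptophyte-specific (with one seeded metazoan FYVE–RCC1 protein, so RCC1
is shared between viridiplantae and metazoa as observed). Planted
architectures are multi-domain by construction, so the plain-protein
multi-domain probability is down-adjusted per group to hold the anchor-wide
fractions at their configured 63 % (FYVE) and 52 % (PX).

Sequences are i.i.d. uniform over the 20 canonical residues outside planted
segments; every FYVE protein physically contains a 65-residue FYVE segment
with WxxD, its class's pocket hexapeptide and RVC planted, and the backbone
is re-drawn until no other window scores ≥5 against any pattern, making the
planted site the unambiguous best match. Duplicates are created by point
mutation to the configured identity (default 97 %), never touching pocket
positions; intra-species duplicates are the redundancy the clustering stage
must remove, inter-species duplicates (kept within one group spec, and
skipped if they would break a strict genome bias) are the conservation the
screen must protect. Hits carry log-uniform E-values in [1e−30, 1e−3], and
one protein in ten receives a decoy hit with E > 0.1 that the filter must
remove. A `TruthLedger` records per-species counts, per-domain group sets,
per-protein architectures and site classes, and all duplicate pairs; the
configured seed fully determines every output byte.

What the generator does **not** emulate: realistic amino-acid composition
or substitution processes, HMM score distributions, domain length
variation within a family, alignment-ambiguous repeats, or taxon sampling
bias. Passing tests therefore demonstrate the correctness of the pipeline's
logic under its stated assumptions, not robustness to noisy real-world
annotation.

## Reference tables

The full per-domain taxonomic-distribution tables behind the published
Venn counts live in supplementary files that were never deposited with
accessions; `fyvepx.reference` ships a *synthetic* reconstruction
constrained to every published marginal (totals, core identities, per-group
exclusive counts, and the individually reported assignments). Statistics
computed from it depend only on compartment sizes, which are exact;
placeholder group assignments beyond the published facts carry no weight.

## Problem sizes and tolerances

Test-suite and acceptance runs use the preset (~2,000 proteins) across five
seeds, 200 random clustering sets of up to 50 sequences, 1,000 random
architecture sets, and 300 planted segments per binding-site class —
desk-scale sizes that complete in seconds while exercising every code
path. Association-score normalisation is asserted to 1e−9; parameter
recovery (exclusive fraction, group bias signs) to ±5 percentage points;
clustering and motif recovery are exact. Floating-point identity values are
compared exactly between greedy and brute-force paths because both use the
identical kernel.

## Known limitations

* Live database retrieval, HMMER/CD-HIT execution, multiple sequence
  alignment and tree reconstruction are out of scope by design; the
  pipeline starts from sequences plus domain hits.
* The greedy clustering reproduces CD-HIT's *scheme*, not its word-count
  heuristics; on real data the two can differ near the threshold.
* Lineage assignment is table-driven; ambiguous lineages (e.g. placing
  choanoflagellates with protists) follow the supplied table as printed.
* Binding-site classification assumes the pocket is recognisable as one of
  the three consensus classes; genuinely divergent FYVE domains are
  reported unclassified, and no lipid-binding affinity is predicted.
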
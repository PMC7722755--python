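# Methods

## Model and assumptions

The enrichment statistic treats the input microbe list and each library set
as fixed-size draws from a common universe of taxa and asks whether their
overlap is larger than the hypergeometric expectation. The one-sided
(enrichment) Fisher exact test is used throughout; its assumptions —
exchangeability of taxa and independence of set membership — are the usual
ones for overrepresentation analysis and are knowingly approximate for
phylogenetically structured libraries, which is one motivation for the rank
correction below.

**Universe.** The universe is a named member set plus a total size N. The
named portion is the library's member union, optionally extended by a
profiled-taxa list describing what the upstream pipeline can detect. When N
exceeds the named count, the remainder stands for detectable taxa that
appear in no set; input names outside the named portion then stay in the
analysis (they occupy that anonymous capacity). Only in a fully named
universe are unknown input names dropped, with a logged warning, because
profiling pipelines routinely emit taxa outside any library. The default
N = 1000 reflects the scale of genus-level 16S reference taxonomies and is
used only when neither an explicit size nor a profiled list is given; an
explicit size smaller than the named portion is an error rather than a
silent truncation.

**Rank-bias correction.** Proportion tests favor large sets, so per-term
significance ranks are calibrated empirically: random inputs of the same
cardinality as the observed input are drawn uniformly without replacement
from the universe (default 10,000 repetitions), all terms are scored and
ranked per draw (ascending p, average ranks on ties), and the per-term
mean and sample standard deviation (ddof = 1) standardize the observed
rank. The z sign convention is (observed − expected)/sd: negative z means
better than expected. A term whose null rank never varies gets z = 0 and a
degeneracy flag instead of a division by zero.

**Combined score.** c = log10(p) · z multiplies log-significance by rank
surprise; it is zero when p = 1 or z = 0 and positive for enriched terms
(small p, negative z), so both orderings — ascending p (default) and
descending c — are exposed and reported rather than asserting one is
better. Underflowed p-values are floored at 1e-300 before the logarithm.

**Multiple testing.** Benjamini–Hochberg step-up across all terms of the
library tested in one run. The same correction is reused for the pairwise
term-overlap network, where an edge requires corrected p < alpha (default
0.01).

## Library construction

*Taxonomy.* Lineage strings are parsed into a rooted forest keyed by
lineage prefix, so shared prefixes share nodes and every node has a single
parent by construction. Ranks must strictly deepen within a record; tokens
below species (strain designators) are discarded; lineages under the
Viruses or Viroids kingdoms are dropped because 16S profiling cannot
observe them. Species names are formed as "<genus> <epithet>". A library at
rank r contains one set per internal node at r with its leaf descendants as
members — sets at one rank are therefore pairwise disjoint. Nodes at r with
nothing below them (truncated lineages) are omitted; species-level
libraries are rejected since every set would be a singleton of itself.

*Name normalization.* One idempotent normalizer is applied everywhere a
taxon name enters the package: strip whitespace, remove a leading
"<letter>__" rank prefix, remove trailing "_noname"/"_unclassified"
placeholders, replace underscores with spaces. Rank-prefix stripping goes
beyond suffix removal so that lineage-derived members match profiler output
spellings. Matching is case-insensitive with the first-seen spelling kept
as canonical.

*Literature.* Association strength between microbe i and gene j is the
Jaccard index |D_i ∩ D_j| / (|D_i| + |D_j| − |D_i ∩ D_j|) of their
mentioning-document sets, with 0/0 defined as 0. Documents carrying only
one entity kind still contribute to marginals, which is what discounts
frequently discussed entities. Binarization keeps the top fraction of the
*full* microbe × gene grid including zero-score pairs (default 0.1%),
making the cutoff a high quantile of all possible pairs; ties at the cut
are all kept (deterministic and order-independent) and zero-score pairs
never are. When a taxonomy is available the fraction can instead be chosen
from a candidate grid by maximizing the Spearman rank correlation, over all
microbe pairs, between gene-profile Jaccard similarity and taxonomic
similarity (depth of the deepest shared ancestor divided by the tree's
maximum leaf depth). The correlation statistic is deliberately pluggable —
"agreement with the taxonomy" has no canonical metric — and candidates
whose binarization is empty or whose similarity vector is constant are
skipped with a warning rather than scored.

*Disease records.* Organisms reported for a disease join its set regardless
of the direction of change (elevated or reduced): membership encodes that
an association was observed, not its sign. Blank organisms are skipped with
a warning; a record stream with nothing usable is an error.

*TF-IDF.* For embedding, microbes act as documents and genes as terms:
tf is the row-normalized co-count, idf = ln(N_microbes / df) with natural
log, so a gene co-mentioned with every microbe weighs zero everywhere.
This plain variant makes "offset ubiquitous entities" literal and keeps
identical co-mention profiles identical after weighting.

## Synthetic data

The generators produce every input format the package reads, with planted
structure, and are pure functions of their spec (seed included).

* `make_mention_corpus` mentions each entity independently per document at
  `background_rate` and inserts both members of each planted pair jointly
  with probability `co_rate`; the planted pair's co-mention probability is
  therefore co_rate + (1 − co_rate)·background². Defaults (500 documents,
  20×20 entities, background 0.02, planted co-rate 0.3) put planted Jaccard
  scores near 0.9 against a background near 0.01–0.05 — strong but not
  trivial separation.
* `make_planted_library` draws uniform random sets (sizes uniform on
  10–50 by default, a plausible range for curated disease or gene sets)
  from a universe of 1000 named taxa and rebuilds the planted term to share
  exactly `planted_term_overlap` members (default 10) with the emitted
  input of 20 — ten shared members out of twenty in a universe of 1000 is
  overwhelming enrichment, which is the point: recovery failures indicate
  implementation defects, not statistical bad luck.
* `make_toy_taxonomy` emits a balanced kingdom→phylum→genus→species tree
  with systematic names; it takes a seed for API symmetry but is fully
  deterministic regardless.

What the generators do **not** emulate: real literature mention
distributions are heavy-tailed (model organisms dominate), real taxonomies
are unbalanced and hold name irregularities, and real DA lists carry
effect-size structure. Passing tests therefore demonstrate correctness of
the statistical machinery under its own assumptions, not performance on
real corpora.

## Numerical choices

* All Fisher tails ride on one vectorized hypergeometric survival-function
  kernel; the test suite checks it against exact integer enumeration over
  every 2×2 table with N ≤ 60 at 1e-12.
* Odds ratios use the Haldane–Anscombe +0.5 correction only when a cell is
  zero.
* Ranks use average ties everywhere (observed and null), keeping the two
  distributions comparable.
* The null model precomputes, per term, the p-value lookup over all
  possible overlaps, so each Monte-Carlo repetition is a membership count
  plus a table lookup; the model is reusable across inputs of the same
  cardinality via the `null_model` argument.
* Randomness comes exclusively from `numpy.random.default_rng(seed)`
  generators; seeds are recorded in results objects and run manifests, and
  seeded runs are byte-identical.
* t-SNE (scikit-learn, PCA initialization, default perplexity 30) requires
  at least 3·perplexity rows and a non-constant matrix; coordinates are
  mean-centered before return. Note that a corpus in which every gene ends
  up co-mentioned with every microbe yields an all-zero TF-IDF matrix —
  a legitimately empty signal that is rejected rather than embedded.

## Problem sizes in the validation suite

The acceptance measurements use a 200-term library with 1000-rep nulls and
100 evaluation inputs for calibration, 100 seeds for planted-term recovery,
10 corpus seeds for literature recovery, and the full N ≤ 60 table sweep
(635,376 tables) for the Fisher oracle; these sizes give stable statistics
(20,000 pooled z-scores, binomial SEs under 2 points on recovery rates)
while keeping a full run in well under a minute of compute. Calibration is
judged on the pooled z distribution across terms and inputs: per-term
moments at 100 inputs would be dominated by sampling noise (SE ≈ 0.1 on a
mean), whereas the pooled mean and sd pin miscalibration of the null
machinery itself.

## Known limitations

* Set membership is binary: no weighting of input taxa by effect size or
  detection confidence, and no fuzzy membership.
* The Fisher independence assumption ignores phylogenetic correlation
  between taxa; the rank correction compensates for set-size bias, not for
  correlation structure.
* The literature builder consumes an already-recognized mention corpus; it
  performs no entity recognition or symbol mapping itself, so garbage
  mentions propagate.
* OTU misclassification upstream silently becomes membership error here;
  the universe mechanism can absorb unknown names but not wrong ones.
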
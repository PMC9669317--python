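# Methods

## Scope and data model

`ecotaxdb` operates on four kinds of objects: reference records (a
sequence, an abundance, a seven-rank taxonomy with per-rank provenance
*inherited* / *de novo* / *empty*, and optionally a best-hit identity),
per-rank identity thresholds, amplicon datasets (ASV sequences plus a
sample × ASV count table), and IUPAC-degenerate primer pairs written
5'→3' on their own strand. Sequences are stored uppercase with U mapped
to T on ingest; coordinates are 0-based half-open internally.

## Alignment identity and top-hit search

Percent identity is defined on an optimal *glocal* alignment: one
sequence is aligned end to end while the other's overhangs are free and
excluded; both directions are computed and the better one kept, making
the measure symmetric. Aligned columns score match +1, mismatch −1, gap
open −2, gap extension −1 (an internal gap of length L costs 2 + (L −
1)). Among equal-score alignments the one with the most matches is
chosen; remaining ties are resolved by a fixed traceback preference
(substitution, then gap in the second sequence, then gap in the first)
and a fixed end cell, so every result is deterministic. Identity is
matches divided by alignment columns, times 100 — a fragment contained
verbatim in a longer reference scores 100, the semantics short-read
mapping tools use. Requiring one sequence to span the alignment is what
keeps the measure meaningful for unrelated pairs: with end gaps both free
*and* unanchored, the score optimum for dissimilar sequences degenerates
to a few chance-matching columns in a corner of the matrix and identity
saturates at 100. The implementation is an affine-gap dynamic program
compiled with numba; score and match count are packed into one integer
per cell (score · 8192 + matches), which caps supported sequence length
at 8191 nt, ample for 16S genes. The top-hit
search is exhaustive by contract: every reference is aligned, ties go to
the lowest database index, and only the plus strand is searched (queries
and references are required co-oriented). No banded or seeded shortcut is
used; correctness over speed at desk scale.

## Database construction

Building proceeds trim → dereplicate → inherit → de novo:

* **Trimming** locates the forward trimming primer (degenerate-exact
  match, leftmost site) and the reverse primer's reverse complement
  (rightmost site) and keeps the window strictly between them; sequences
  missing either site, with inverted sites, or shorter than the minimum
  retained length (default 500 bp) are discarded with a reason code. The
  default trimming pair is the conventional near-full-length bacterial
  pair 27f/1391r; any pair can be supplied (no archaeal default is
  shipped because the package does not invent primer sequences it cannot
  source).
* **Dereplication** is exact: identical strings collapse, abundance is
  the copy count, records are ordered by descending abundance (ties by
  first occurrence) and numbered FLASV1..n.
* **Inheritance** copies the best hit's names from domain down to the
  deepest rank whose threshold the best-hit identity meets (identity
  exactly equal to a threshold transfers that rank; the domain is always
  copied). A hit that is itself unnamed at a transferable rank leaves
  that rank empty for the de novo stage.
* **De novo placeholders** are assigned rank by rank, phylum to species.
  Within each group of records sharing identical taxonomy above the
  current rank, unnamed records are clustered greedily in database order:
  the first unnamed record seeds a cluster named
  `<prefix>_<rankletter>_<seed ordinal>`; each later record joins the
  first seed it matches at the rank's identity threshold, else seeds a
  new cluster. Constraining clusters to one parent group guarantees
  taxonomic consistency (two records sharing a name at rank r share all
  names above r); seed-based naming makes output deterministic and each
  placeholder traceable to a concrete record. This greedy scheme is this
  package's documented stand-in for centroid clustering; with seeds as
  fixed centroids the invariant "every member is within the rank
  threshold of its seed" is exactly checkable, and the test suite checks
  it.

No chimera filtering is performed: the intended inputs are consensus
sequences from synthetic long-read pipelines that are essentially
chimera- and error-free.

## Bootstrap k-mer classifier

The classifier follows the SINTAX design: each reference is reduced to
its set of 8-mers; per bootstrap iteration (100 iterations) 32 of the
query's unique k-mers are drawn with replacement and the reference
sharing most of them wins (ties to the lowest record ordinal; iterations
where no reference shares any sampled k-mer are winnerless). The overall
winner's taxonomy is reported with per-rank confidence equal to the
fraction of iterations whose winner carries the same name at that rank,
truncated at the deepest rank reaching the confidence cutoff (default
0.8, the standard value for short amplicons). With strand mode `both`
(default for real amplicons) the query and its reverse complement are
classified and the result with the larger summed rank confidence kept;
in-silico amplicons extracted from the database itself are classified
plus-strand only. All randomness comes from a generator seeded by the
classifier parameters, so outputs are bit-reproducible. The classifier is
a faithful stand-in for the published SINTAX algorithm, not a
byte-compatible reimplementation of any particular tool.

## Evaluation suite

* **Sequence novelty**: a record is novel at rank r when its best-hit
  identity against the universal database is strictly below r's
  threshold; categories are therefore nested phylum → species.
* **Taxonomy novelty**: per rank, the fraction of distinct taxa (distinct
  lineage prefixes, so homonyms under different parents count separately)
  carrying placeholder names.
* **Coverage**: ASVs are filtered per sample at ≥ 0.01 % relative
  abundance (per-sample, because the analysis reports per-sample means ±
  sd; an ASV may be retained in one sample and dropped in another). The
  high-identity fraction is the share of retained ASVs with top-hit
  identity ≥ 99 %; coverage is the summed relative abundance retained.
  Samples retaining nothing report missing values. The fraction is
  invariant under per-sample count rescaling.
* **Classification rates**: after the same filter, the fraction of ASVs
  whose reported taxonomy reaches genus (resp. species).
* **In-silico resolution**: the inter-primer region of every record is
  extracted (degenerate-exact site search; the emitted set is redundant —
  duplicates retained, one per parent; records without both sites are
  listed as non-amplifiable) and classified against the full database.
  At genus and species a prediction is *correct* if it equals the
  parent's name, *wrong* if non-empty and different (rank-name
  comparison, not full-path), and *not classified* if empty — an empty
  prediction is never counted as wrong. The three fractions partition
  unity by construction.

## Primer-bias scoring

A primer is placed semi-globally (primer fully aligned, template flanks
free, gaps allowed) by a dynamic program minimizing the overall weighted
score; penalties are held in tenths so the optimization is integral.
Mismatches cost 0.40 (more than five bases from the 3' end), 1.00 (last
five bases, non-terminal) or 3.00 (terminal base; this *replaces* the
generic 3' penalty rather than adding to it — the source material lists
the terminal case as a distinct dominant penalty, and this convention is
applied consistently). Gaps cost 1.00, or 3.00 when the
template-consumed position falls within the last five primer bases. A
degenerate primer base matches any template base whose IUPAC set
intersects its own. Placements are searched over the whole template; if
no placement scores below the ceiling (default 10) the template is
`no_site`. Categories: perfect = 0, partial ≤ 1, poor > 1. Database
surveys score the forward primer against the plus strand and the reverse
primer against the reverse complement and let the worse primer govern,
summarizing category fractions per taxon.

Note that the minimal-score placement is a genuine minimum over
alignments: a perturbation "one 3' gap" can be re-readable as a cheaper
non-3' gap plus 3' mismatches when the 3' end is repetitive (e.g. the
CCC run of the V5–V7 forward primer), in which case the cheaper reading
is the score. The synthetic planting routine therefore verifies every
planted perturbation against a placement enumeration and refuses
combinations whose intended score is not actually minimal.

## Synthetic data

`simulate_reference` draws one universal record per species of a small
taxonomy tree (default 4 phyla down to 32 species; names are synthetic
and never collide with the placeholder grammar). Each record spans
exactly the trimming window (default 1,263 bp = 1,300 bp minus the two
trimming primers) and carries a concrete expansion of the V5–V7 amplicon
pair around a 300-bp variable core. Queries derive from a parent record
by a fixed number of substitutions placed outside primer sites;
divergence uses substitutions only, so the identity to the parent is
analytically 100·(L−s)/L, and that value is a *floor*: a gapped optimal
alignment can only add matches. Per-rank identity targets therefore sit
just above each band's lower threshold (98.85 / 94.8 / 86.8 / 82.3 /
78.8 / 75.3 / 70.0 for species → none), leaving the full band width as
headroom against upward drift; with these defaults the planted
deepest-inheritable rank is recovered exactly. Raw reads re-attach
freshly expanded trimming primers and repeat each query 1–3 times so
dereplication is exercised. Default query allocation is 200 queries
spread over all seven novelty classes, emphasizing the species/genus end
where real soil data concentrates.

`simulate_amplicon_dataset` extracts the unique amplicon cores of a
database, draws per-sample counts from a log-normal (default mean 6.0,
sigma 1.5 on the log scale — about 10⁴–10⁵ reads per sample over a few
dozen ASVs, a typical amplicon sequencing depth; 6 samples, rounded with a
floor of one read)
and can force a chosen number of ASVs to single-read counts to exercise
the abundance filter. `plant_primer_mutations` injects one
substitution or deletion of known weighted score into forward-primer
sites, rejection-sampling so no intact site remains and validating each
plant as described above.

What the generators deliberately do not model: sequencing error, chimeras
(the upstream assembly is error-free by design), indel divergence between
relatives (substitution-only keeps identity analytic; indel robustness of
the aligner is tested separately against oracles), compositional biases,
and realistic phylogenetic correlation between lineages (universal
records are mutually unrelated random sequences). Passing the planted
tests therefore demonstrates the correctness of the pipeline's logic and
arithmetic, not database quality on real communities.

## Numerical and design choices

* Threshold boundaries are inclusive (identity equal to a threshold is
  assignable); novelty categories are strict "below". Identities are
  compared as exact floats, not rounded.
* Tie-breaks everywhere are deterministic: database order for top hits
  and cluster seeds, record ordinal for classifier winners, leftmost
  placement end for primer scoring.
* The weighted-score categorizer tolerates 1e-9 at the partial/poor
  boundary; all scores are multiples of 0.1 by construction.
* The coverage-normalization factor for read-tag libraries,
  `C_seq = molarity · (−0.0124·(size − 215) + 10.332)`, warns outside
  its validated 500–950 bp range and raises once the linear size term
  drives the factor non-positive (≳1,048 bp), where the empirical formula
  is meaningless.
* Problem sizes in the test suite are desk-scale by choice: full-length
  (1,300 bp) simulations with ~200 queries against 32 universal records
  for planted-truth recovery, and oracle comparisons at ≤ 60 nt where
  exhaustive or quadratic references are exact.

## Known limitations

* Mixed-strand input is not oriented; inputs must be co-oriented.
* The greedy de novo clustering depends on database (abundance) order, as
  does any seed-based scheme; reruns on identical input are byte-stable,
  but adding one record can re-seed clusters downstream.
* The classifier's confidence calibration matches the SINTAX family's
  behavior qualitatively; no attempt is made to reproduce a specific
  tool's outputs bit-for-bit.
* `no_site` handling uses a single score ceiling; melting temperature and
  other thermodynamic effects are out of scope.
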
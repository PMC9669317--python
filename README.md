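# ecotaxdb

Tools for building and evaluating **ecosystem-specific, ASV-resolved 16S
rRNA reference databases** with a complete seven-rank taxonomy, and for
quantifying how well such a database serves short-read amplicon studies of
its ecosystem (soil, rhizosphere and endosphere communities are the
motivating case).

Universal 16S reference databases leave most environmental amplicons
unnamed below the family level. An ecosystem-specific database built from
near-full-length, error-free 16S genes (full-length amplicon sequence
variants, *FL-ASVs*) fixes this in two steps:

1. **Taxonomy inheritance.** Each FL-ASV is mapped exhaustively against a
   universal database; the closest relative's taxonomy is copied down to
   the deepest rank its percent identity supports, using per-rank identity
   thresholds (phylum 75.0, class 78.5, order 82.0, family 86.5, genus
   94.5, species 98.7; identity ≥ threshold transfers the rank).
2. **De novo placeholder taxa.** Ranks left empty are filled by greedy
   seed clustering at the rank's threshold, constrained within identical
   parent taxonomy, producing systematic placeholder names such as
   `ECO_g_17` (prefix, rank letter, seed ordinal). Every record ends with
   all seven ranks named.

The evaluation suite measures: per-rank **sequence novelty** (records with
no universal relative within a rank's threshold) and **taxonomy novelty**
(fraction of placeholder taxa); **high-identity coverage** of a short-read
ASV dataset (fraction of ≥ 0.01 %-abundance ASVs with a ≥ 99 %-identity
hit, plus the read abundance they account for); **classification rates**
at genus/species with a bootstrap k-mer (SINTAX-style) classifier at
confidence cutoff 0.8; **in-silico amplicon resolution** (extract each
record's inter-primer region, classify it against its own database,
compare with the parent at genus/species); and **primer bias** via the
overall weighted score

```
OWS = 0.40·(non-3' mismatches) + 1.00·(3' mismatches) + 3.00·[terminal mismatch]
    + 1.00·(non-3' gaps)       + 3.00·(3' gaps)
```

where the 3' region is the last five primer bases, a terminal mismatch
replaces the generic 3' penalty, and sites are *perfect* (OWS = 0),
*partial* (0 < OWS ≤ 1) or *poor* (OWS > 1). A database survey scores the
forward primer on the plus strand and the reverse primer on the reverse
complement; the worse primer governs each record's category.

A seeded synthetic-data module plants ground truth for all of this:
universal databases with full taxonomies, queries on a divergence ladder
whose identity to their nearest relative is analytically controlled,
log-normal amplicon count tables, and primer-site perturbations of known
weighted score.

## Worked example

```
ecotaxdb simulate --seed 7 --queries 16 --out sim/
ecotaxdb build --input sim/reads.fasta --universal sim/universal.fasta \
    --prefix SIM --out db/
ecotaxdb evaluate novelty --db db/database.fasta \
    --universal sim/universal.fasta --out novelty/
```

`build` prints

```
INFO built 16 FL-ASVs from 31 input sequences
```

meaning the 31 simulated reads trimmed and dereplicated into 16 unique
FL-ASVs, each written to `db/database.fasta` with a complete seven-rank
SINTAX-format taxonomy (QIIME export alongside). The novelty report
`novelty/sequence_novelty.tsv` then counts, per rank, how many records lack
a universal relative within that rank's threshold:

```
rank	novel_sequences	percent
phylum	1	6.25
class	2	12.5
order	3	18.75
family	5	31.25
genus	7	43.75
species	11	68.75
```

The counts are nested (a record novel at order is also novel at family,
genus and species). With the planted simulation they equal the simulator's
truth table exactly.

The same stages are available as library functions (`build_database`,
`sequence_novelty`, `coverage_eval`, `classification_rate`,
`resolution_eval`, `survey_database`, `score_primer`, ...) — see
`docs/methods.md` for the underlying models and parameter choices.

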
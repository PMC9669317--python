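"""Construction of an ASV-resolved 16S reference database.

The pipeline turns oriented near-full-length 16S sequences into a database
in four stages:

1. trim every sequence to the window between the trimming-primer binding
   sites (sequences missing either site are discarded);
2. dereplicate exactly into full-length ASVs (FL-ASVs), ordered by
   descending abundance and numbered FLASV1..n;
3. inherit taxonomy from the closest relative in a universal reference
   database, down to the rank allowed by the per-rank identity thresholds;
4. fill the remaining ranks with de novo placeholder names
   (``<prefix>_<rankletter>_<seed-ordinal>``) by greedy seed clustering at
   each rank's threshold, constrained within identical parent taxonomy.

The result is a database where every record carries a complete seven-rank
taxonomy, each rank flagged as inherited or de novo.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import (
    BACTERIAL_TRIM_PAIR,
    DE_NOVO,
    EMPTY,
    INHERITED,
    RANKS,
    THRESHOLD_RANKS,
    PrimerPair,
    ReferenceRecord,
    TaxonomyPath,
    ThresholdTable,
    clean_sequence,
    iupac_regex,
    make_placeholder,
    rank_for_identity,
    reverse_complement,
)
from .seqsearch import global_identity, top_hit


@dataclass(frozen=True)
class BuildConfig:
    thresholds: ThresholdTable = field(default_factory=ThresholdTable)
    prefix: str = "ECO"
    trim_pair: PrimerPair = BACTERIAL_TRIM_PAIR
    min_length: int = 500

    def __post_init__(self) -> None:
        if not self.prefix:
            raise ValueError("placeholder prefix must be non-empty")


@dataclass(frozen=True)
class TrimResult:
    sequence: str | None
    reason: str | None = None  # missing_primer | inverted_sites | too_short

    @property
    def ok(self) -> bool:
        return self.sequence is not None


def find_primer_window(seq: str, pair: PrimerPair) -> tuple[int, int] | None:
    """0-based half-open coordinates of the inter-primer window, or None.

    The forward primer is searched on the plus strand (leftmost site), the
    reverse primer as its reverse complement (rightmost site); primer bases
    are excluded from the window.  Matching is degenerate-exact.
    """
    fwd = iupac_regex(pair.forward).search(seq)
    rc_hits = list(iupac_regex(reverse_complement(pair.reverse)).finditer(seq))
    if fwd is None or not rc_hits:
        return None
    start = fwd.end()
    end = rc_hits[-1].start()
    if end < start:
        return None
    return start, end


def trim_to_primer_window(seq: str, pair: PrimerPair,
                          min_length: int = 0) -> TrimResult:
    """Trim a sequence to the window strictly between the primer sites."""
    seq = clean_sequence(seq)
    fwd = iupac_regex(pair.forward).search(seq)
    rc_hits = list(iupac_regex(reverse_complement(pair.reverse)).finditer(seq))
    if fwd is None or not rc_hits:
        return TrimResult(None, "missing_primer")
    start, end = fwd.end(), rc_hits[-1].start()
    if end < start:
        return TrimResult(None, "inverted_sites")
    window = seq[start:end]
    if len(window) < min_length:
        return TrimResult(None, "too_short")
    return TrimResult(window)


def resolve_flasvs(seqs: Iterable[str]) -> list[ReferenceRecord]:
    """Exact dereplication into FL-ASV records.

    Identical strings collapse; abundance is the copy count.  Records are
    ordered by descending abundance (ties by first occurrence) and named
    FLASV1..n in that order.
    """
    counts: Counter[str] = Counter()
    first_seen: dict[str, int] = {}
    for i, s in enumerate(seqs):
        s = clean_sequence(s)
        counts[s] += 1
        first_seen.setdefault(s, i)
    if not counts:
        raise ValueError("no sequences to dereplicate")
    ordered = sorted(counts, key=lambda s: (-counts[s], first_seen[s]))
    return [ReferenceRecord(id=f"FLASV{i + 1}", sequence=s, abundance=counts[s])
            for i, s in enumerate(ordered)]


def inherit_taxonomy(rec: ReferenceRecord,
                     universal: Sequence[ReferenceRecord],
                     thresholds: ThresholdTable | None = None) -> ReferenceRecord:
    """Transfer taxonomy from the closest universal-database relative.

    The hit's names are copied from domain down to the deepest rank whose
    identity threshold the best-hit identity meets; deeper ranks stay empty.
    The domain is always copied.  Mutates and returns ``rec``.
    """
    thresholds = thresholds or ThresholdTable()
    hit = top_hit(rec.sequence, universal, query_id=rec.id)
    rec.best_hit_identity = hit.identity
    hit_tax = next(r for r in universal if r.id == hit.ref_id).taxonomy
    deepest = rank_for_identity(hit.identity, thresholds)
    cut = 0 if deepest == "none" else RANKS.index(deepest)
    names, prov = [], []
    for i, rank in enumerate(RANKS):
        if i <= cut and hit_tax.names[i]:
            names.append(hit_tax.names[i])
            prov.append(INHERITED)
        else:
            names.append("")
            prov.append(EMPTY)
    rec.taxonomy = TaxonomyPath(tuple(names), tuple(prov))
    return rec


def assign_denovo_placeholders(records: Sequence[ReferenceRecord],
                               thresholds: ThresholdTable | None = None,
                               prefix: str = "ECO") -> list[ReferenceRecord]:
    """Fill every empty rank with a de novo placeholder name.

    Rank by rank (phylum to species), records lacking a name are greedily
    clustered within groups sharing identical taxonomy above that rank.  In
    database order, the first unassigned record of a group seeds a cluster
    named after its 1-based database ordinal; later records join the first
    seed whose seed sequence they match at the rank's identity threshold,
    otherwise seed a new cluster.  Mutates and returns ``records`` as a list.
    """
    thresholds = thresholds or ThresholdTable()
    records = list(records)
    ordinal = {id(r): i + 1 for i, r in enumerate(records)}
    for depth, rank in enumerate(THRESHOLD_RANKS, start=1):
        cut = thresholds.threshold(rank)
        # seeds per parent lineage, in creation order
        seeds: dict[tuple[str, ...], list[ReferenceRecord]] = {}
        for rec in records:
            if rec.taxonomy.names[depth]:
                continue
            parent = rec.taxonomy.names[:depth]
            if any(not n for n in parent):
                raise ValueError(f"record {rec.id} has a gap above rank {rank}")
            home = None
            for seed in seeds.get(parent, []):
                if global_identity(rec.sequence, seed.sequence) >= cut:
                    home = seed
                    break
            if home is None:
                name = make_placeholder(prefix, rank, ordinal[id(rec)])
                seeds.setdefault(parent, []).append(rec)
            else:
                name = home.taxonomy.names[depth]
            rec.taxonomy = rec.taxonomy.with_rank(rank, name, DE_NOVO)
    return records


@dataclass
class BuildReport:
    n_input: int
    n_discarded: dict[str, int]
    n_flasvs: int
    denovo_taxa: dict[str, int]

    def to_frame(self):
        import pandas as pd

        rows = [("input_sequences", self.n_input)]
        rows += [(f"discarded_{k}", v) for k, v in sorted(self.n_discarded.items())]
        rows.append(("flasvs", self.n_flasvs))
        rows += [(f"denovo_{r}", self.denovo_taxa.get(r, 0)) for r in THRESHOLD_RANKS]
        return pd.DataFrame(rows, columns=["stage", "count"])


def build_database(seqs: Iterable[str],
                   universal: Sequence[ReferenceRecord],
                   config: BuildConfig | None = None,
                   trim: bool = True) -> tuple[list[ReferenceRecord], BuildReport]:
    """Run the full trim -> dereplicate -> inherit -> de novo pipeline.

    ``trim=False`` accepts pre-trimmed input (the primer window stage is
    skipped).  Deterministic for fixed inputs.
    """
    config = config or BuildConfig()
    seqs = list(seqs)
    discarded: Counter[str] = Counter()
    if trim:
        trimmed = []
        for s in seqs:
            res = trim_to_primer_window(s, config.trim_pair, config.min_length)
            if res.ok:
                trimmed.append(res.sequence)
            else:
                discarded[res.reason] += 1
    else:
        trimmed = [clean_sequence(s) for s in seqs]
    if not trimmed:
        raise ValueError("no sequences left after primer trimming")
    records = resolve_flasvs(trimmed)
    for rec in records:
        inherit_taxonomy(rec, universal, config.thresholds)
    assign_denovo_placeholders(records, config.thresholds, config.prefix)
    denovo = {
        rank: len({r.taxonomy.names[i] for r in records
                   if r.taxonomy.provenance[i] == DE_NOVO})
        for i, rank in enumerate(RANKS) if rank != "domain"
    }
    report = BuildReport(n_input=len(seqs), n_discarded=dict(discarded),
                         n_flasvs=len(records), denovo_taxa=denovo)
    return records, report
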
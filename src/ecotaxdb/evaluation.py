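"""Database-evaluation suite.

Four analyses quantify how well an ecosystem-specific reference database
serves its community:

* **sequence novelty** — per rank, how many database records lack a
  relative in a universal database within that rank's identity threshold;
* **taxonomy novelty** — per rank, how many distinct taxa carry de novo
  placeholder names rather than inherited ones;
* **coverage / classification rates** — for a short-read ASV dataset
  (abundance-filtered at 0.01% relative abundance per sample), the fraction
  of ASVs with a high-identity (>=99%) database hit, and the fraction the
  bootstrap classifier assigns at genus/species;
* **in-silico amplicon resolution** — extract the inter-primer region of
  every record, classify it against the database it came from, and compare
  with the parent's taxonomy at genus and species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .builder import find_primer_window
from .classifier import ClassifierParams, KmerIndex, classify, train_index
from .core import (
    DE_NOVO,
    RANKS,
    THRESHOLD_RANKS,
    AmpliconDataset,
    PrimerPair,
    ReferenceRecord,
    ThresholdTable,
)
from .seqsearch import top_hit


def sequence_novelty(db: Sequence[ReferenceRecord],
                     universal: Sequence[ReferenceRecord] | None = None,
                     thresholds: ThresholdTable | None = None) -> pd.DataFrame:
    """Per-rank novel-sequence counts and percentages.

    A record is novel at rank r when its best-hit identity against the
    universal database is strictly below r's threshold; the categories are
    therefore nested (counts non-decreasing phylum -> species).  Best-hit
    identities are computed here when absent (requires ``universal``).
    """
    thresholds = thresholds or ThresholdTable()
    idents = []
    for rec in db:
        if rec.best_hit_identity is None:
            if universal is None:
                raise ValueError(f"record {rec.id} lacks best_hit_identity and no "
                                 "universal database was given")
            rec.best_hit_identity = top_hit(rec.sequence, universal,
                                            query_id=rec.id).identity
        idents.append(rec.best_hit_identity)
    idents = np.asarray(idents)
    n = len(idents)
    rows = []
    for rank in THRESHOLD_RANKS:
        count = int((idents < thresholds.threshold(rank)).sum())
        rows.append((rank, count, 100.0 * count / n if n else math.nan))
    return pd.DataFrame(rows, columns=["rank", "novel_sequences", "percent"]
                        ).set_index("rank")


def taxonomy_novelty(db: Sequence[ReferenceRecord]) -> pd.DataFrame:
    """Per-rank counts and percentages of de novo placeholder taxa.

    Taxa are counted as distinct lineage prefixes (names from domain down to
    the rank), so identical names under different parents count separately.
    """
    rows = []
    for i, rank in enumerate(RANKS):
        if rank == "domain":
            continue
        taxa: dict[tuple[str, ...], bool] = {}
        for rec in db:
            if not rec.taxonomy.names[i]:
                continue
            lineage = rec.taxonomy.names[: i + 1]
            taxa[lineage] = rec.taxonomy.provenance[i] == DE_NOVO
        denovo = sum(taxa.values())
        total = len(taxa)
        rows.append((rank, denovo, total,
                     100.0 * denovo / total if total else math.nan))
    return pd.DataFrame(rows, columns=["rank", "denovo_taxa", "total_taxa",
                                       "percent"]).set_index("rank")


@dataclass
class CoverageResult:
    per_sample: pd.DataFrame  # columns: kept, high_identity_fraction, coverage
    mean_fraction: float
    sd_fraction: float
    mean_coverage: float
    sd_coverage: float


def coverage_eval(asvs: AmpliconDataset, db: Sequence[ReferenceRecord],
                  min_rel_abundance: float = 0.0001,
                  id_cut: float = 99.0) -> CoverageResult:
    """High-identity coverage of an ASV dataset by the database.

    Per sample, ASVs are filtered at ``min_rel_abundance``; the reported
    fraction is the share of retained ASVs whose top-hit identity reaches
    ``id_cut``, and coverage is the summed relative abundance the retained
    ASVs account for.  Samples retaining no ASV report NaN fractions.
    """
    rel = asvs.relative_abundance()
    retained_any = rel.index[(rel >= min_rel_abundance).any(axis=1)]
    identity = {aid: top_hit(asvs.sequences[aid], db, query_id=aid).identity
                for aid in retained_any}
    rows = []
    for sample in asvs.samples:
        kept = rel.index[rel[sample] >= min_rel_abundance]
        if len(kept) == 0:
            rows.append((sample, 0, math.nan, 0.0))
            continue
        high = sum(1 for aid in kept if identity[aid] >= id_cut)
        rows.append((sample, len(kept), high / len(kept),
                     float(rel.loc[kept, sample].sum())))
    per_sample = pd.DataFrame(
        rows, columns=["sample", "kept", "high_identity_fraction", "coverage"]
    ).set_index("sample")
    frac = per_sample["high_identity_fraction"].dropna()
    cov = per_sample["coverage"]
    return CoverageResult(per_sample=per_sample,
                          mean_fraction=float(frac.mean()) if len(frac) else math.nan,
                          sd_fraction=float(frac.std(ddof=1)) if len(frac) > 1 else 0.0,
                          mean_coverage=float(cov.mean()),
                          sd_coverage=float(cov.std(ddof=1)) if len(cov) > 1 else 0.0)


@dataclass
class ClassificationRates:
    genus_fraction: float
    species_fraction: float
    per_sample: pd.DataFrame
    n_retained: int


def classification_rate(asvs: AmpliconDataset, db: Sequence[ReferenceRecord],
                        params: ClassifierParams | None = None,
                        min_rel_abundance: float = 0.0001,
                        index: KmerIndex | None = None) -> ClassificationRates:
    """Fraction of abundance-filtered ASVs classified at genus and species."""
    params = params or ClassifierParams()
    index = index or train_index(db, params)
    rel = asvs.relative_abundance()
    retained = list(rel.index[(rel >= min_rel_abundance).any(axis=1)])
    results = {aid: classify(asvs.sequences[aid], index, params) for aid in retained}
    rows = []
    for sample in asvs.samples:
        kept = [aid for aid in rel.index[rel[sample] >= min_rel_abundance]]
        if not kept:
            rows.append((sample, 0, math.nan, math.nan))
            continue
        g = sum(results[a].reaches("genus") for a in kept) / len(kept)
        s = sum(results[a].reaches("species") for a in kept) / len(kept)
        rows.append((sample, len(kept), g, s))
    per_sample = pd.DataFrame(
        rows, columns=["sample", "kept", "genus_fraction", "species_fraction"]
    ).set_index("sample")
    n = len(retained)
    g_all = sum(results[a].reaches("genus") for a in retained) / n if n else math.nan
    s_all = sum(results[a].reaches("species") for a in retained) / n if n else math.nan
    return ClassificationRates(genus_fraction=g_all, species_fraction=s_all,
                               per_sample=per_sample, n_retained=n)


def extract_insilico_asvs(db: Sequence[ReferenceRecord], pair: PrimerPair
                          ) -> tuple[list[tuple[str, str]], list[str]]:
    """Extract the inter-primer region of every record.

    Returns (redundant list of (parent id, amplicon sequence), list of
    non-amplifiable record ids).  Duplicate amplicon sequences are retained,
    one entry per parent.
    """
    amplicons: list[tuple[str, str]] = []
    failed: list[str] = []
    for rec in db:
        window = find_primer_window(rec.sequence, pair)
        if window is None or window[1] <= window[0]:
            failed.append(rec.id)
            continue
        amplicons.append((rec.id, rec.sequence[window[0]:window[1]]))
    return amplicons, failed


@dataclass
class ResolutionReport:
    """Correct / wrong / unclassified fractions at genus and species."""

    fractions: pd.DataFrame  # index: rank; columns: correct, wrong, unclassified
    n_asvs: int
    per_asv: pd.DataFrame


def resolution_eval(insilico: Sequence[tuple[str, str]],
                    db: Sequence[ReferenceRecord],
                    params: ClassifierParams | None = None,
                    index: KmerIndex | None = None) -> ResolutionReport:
    """Classify in-silico amplicons and compare with their parents' taxonomy.

    At genus and species, an amplicon is *correct* when the predicted name
    equals its parent's, *wrong* when a different non-empty name is
    predicted, and *unclassified* when the prediction is empty at that rank.
    Per the amplicon-evaluation protocol, classification uses the plus
    strand by default here.
    """
    params = params or ClassifierParams(strand="plus")
    index = index or train_index(db, params)
    parent_tax = {rec.id: rec.taxonomy for rec in db}
    rows = []
    for parent_id, seq in insilico:
        cls = classify(seq, index, params)
        row = {"parent": parent_id}
        for rank in ("genus", "species"):
            i = RANKS.index(rank)
            truth = parent_tax[parent_id].names[i]
            pred = cls.reported.names[i]
            if not pred:
                row[rank] = "unclassified"
            elif pred == truth:
                row[rank] = "correct"
            else:
                row[rank] = "wrong"
        rows.append(row)
    per_asv = pd.DataFrame(rows)
    n = len(per_asv)
    frac_rows = []
    for rank in ("genus", "species"):
        vc = per_asv[rank].value_counts() if n else pd.Series(dtype=int)
        frac_rows.append((rank,
                          vc.get("correct", 0) / n if n else math.nan,
                          vc.get("wrong", 0) / n if n else math.nan,
                          vc.get("unclassified", 0) / n if n else math.nan))
    fractions = pd.DataFrame(
        frac_rows, columns=["rank", "correct", "wrong", "unclassified"]
    ).set_index("rank")
    return ResolutionReport(fractions=fractions, n_asvs=n, per_asv=per_asv)
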
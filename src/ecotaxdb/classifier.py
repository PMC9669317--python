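"""Bootstrap k-mer taxonomic classifier (SINTAX-style).

Each reference is reduced to its set of k-mers.  A query is classified by
repeatedly drawing a small bootstrap sample of its k-mers; the reference
sharing the most sampled k-mers wins the iteration, and the per-rank
confidence is the fraction of iterations whose winner carries the same name
at that rank as the overall winner.  The reported taxonomy is truncated at
the deepest rank whose confidence reaches the cutoff (default 0.8, the
value used for amplicon classification throughout this package).  With
``strand="both"`` the query and its reverse complement are both classified
and the stronger result kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import RANKS, ReferenceRecord, TaxonomyPath, clean_sequence, reverse_complement


@dataclass(frozen=True)
class ClassifierParams:
    k: int = 8
    bootstraps: int = 100
    draws: int = 32          # k-mers sampled per bootstrap iteration
    cutoff: float = 0.8
    strand: str = "both"     # "plus" or "both"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError("k must be at least 4")
        if not (0.0 <= self.cutoff <= 1.0):
            raise ValueError("cutoff must lie in [0, 1]")
        if self.strand not in ("plus", "both"):
            raise ValueError("strand must be 'plus' or 'both'")


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Sorted unique k-mer codes (base-4 packed) of a sequence."""
    if len(seq) < k:
        return np.empty(0, dtype=np.int64)
    vals = np.array([_CODE[c] for c in seq], dtype=np.int64)
    kernel = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = np.lib.stride_tricks.sliding_window_view(vals, k) @ kernel
    return np.unique(codes)


class KmerIndex:
    """Per-record k-mer sets plus an inverted k-mer -> record-ordinal map."""

    def __init__(self, db: Sequence[ReferenceRecord], params: ClassifierParams):
        import warnings

        self.params = params
        self.records: list[ReferenceRecord] = []
        self.kmer_sets: list[np.ndarray] = []
        self._inverted: dict[int, list[int]] = {}
        for rec in db:
            if len(rec.sequence) < params.k:
                warnings.warn(f"record {rec.id} shorter than k={params.k}; excluded")
                continue
            ordinal = len(self.records)
            self.records.append(rec)
            codes = _kmer_codes(rec.sequence, params.k)
            self.kmer_sets.append(codes)
            for c in codes.tolist():
                self._inverted.setdefault(c, []).append(ordinal)
        self.inverted = {c: np.asarray(v, dtype=np.intp)
                         for c, v in self._inverted.items()}
        del self._inverted

    def __len__(self) -> int:
        return len(self.records)


def train_index(db: Sequence[ReferenceRecord],
                params: ClassifierParams | None = None) -> KmerIndex:
    """Build the classifier index over a completed database."""
    return KmerIndex(db, params or ClassifierParams())


@dataclass
class Classification:
    """Per-rank prediction with bootstrap confidences.

    ``names``/``confidences`` cover all seven ranks; ``reported`` is the
    taxonomy truncated at the deepest rank whose confidence meets the
    cutoff.  ``flagged`` marks degenerate queries (shorter than k)."""

    names: tuple[str, ...] = ("",) * 7
    confidences: tuple[float, ...] = (0.0,) * 7
    reported: TaxonomyPath = field(default_factory=TaxonomyPath)
    strand: str = "plus"
    flagged: bool = False

    def reaches(self, rank: str) -> bool:
        return bool(self.reported.names[RANKS.index(rank)])


def _classify_one_strand(query: str, index: KmerIndex, params: ClassifierParams,
                         rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Bootstrap one strand; returns (per-iteration winners, -1 = none)."""
    codes = _kmer_codes(query, params.k)
    nrec = len(index)
    winners = np.full(params.bootstraps, -1, dtype=np.int64)
    if codes.size == 0 or nrec == 0:
        return winners, 0
    for it in range(params.bootstraps):
        sample = rng.integers(0, codes.size, size=params.draws)
        counts = np.zeros(nrec, dtype=np.int64)
        for c in codes[sample].tolist():
            hits = index.inverted.get(c)
            if hits is not None:
                counts[hits] += 1
        if counts.max() > 0:
            winners[it] = int(counts.argmax())  # first max = lowest ordinal
    return winners, int((winners >= 0).sum())


def _summarize(winners: np.ndarray, index: KmerIndex,
               params: ClassifierParams, strand: str) -> Classification:
    n = params.bootstraps
    valid = winners[winners >= 0]
    if valid.size == 0:
        return Classification(strand=strand)
    counts = np.bincount(valid, minlength=len(index))
    overall = int(counts.argmax())
    names = index.records[overall].taxonomy.names
    confs = []
    for i in range(7):
        agree = sum(1 for w in valid.tolist()
                    if index.records[w].taxonomy.names[i] == names[i] and names[i])
        confs.append(agree / n)
    reported_names, reported_prov = [""] * 7, ["empty"] * 7
    for i in range(7):
        if names[i] and confs[i] >= params.cutoff:
            reported_names[i] = names[i]
            reported_prov[i] = index.records[overall].taxonomy.provenance[i]
        else:
            break
    return Classification(
        names=tuple(names), confidences=tuple(confs),
        reported=TaxonomyPath(tuple(reported_names), tuple(reported_prov)),
        strand=strand)


def classify(query: str, index: KmerIndex,
             params: ClassifierParams | None = None) -> Classification:
    """Classify one query sequence against the index.

    Deterministic for fixed (query, index, params): the bootstrap generator
    is seeded from ``params.seed``.  Queries shorter than k return an empty,
    flagged classification.
    """
    params = params or index.params
    query = clean_sequence(query)
    if len(query) < params.k:
        return Classification(flagged=True)
    rng = np.random.default_rng(params.seed)
    winners, _ = _classify_one_strand(query, index, params, rng)
    result = _summarize(winners, index, params, "plus")
    if params.strand == "both":
        winners_rc, _ = _classify_one_strand(reverse_complement(query), index,
                                             params, rng)
        result_rc = _summarize(winners_rc, index, params, "minus")
        if sum(result_rc.confidences) > sum(result.confidences):
            result = result_rc
    return result


def classify_many(queries: Sequence[tuple[str, str]], index: KmerIndex,
                  params: ClassifierParams | None = None) -> dict[str, Classification]:
    return {qid: classify(seq, index, params) for qid, seq in queries}
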
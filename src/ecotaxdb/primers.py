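"""Ecosystem-specific primer-bias scoring.

A primer is aligned semi-globally against a template (primer fully aligned,
template flanks free, gaps allowed) and penalized with the overall weighted
score (OWS):

* mismatch more than five bases from the 3' end: 0.40 each
* mismatch within the last five bases (not terminal): 1.00 each
* mismatch at the terminal 3' base: 3.00 (this penalty replaces, not adds
  to, the generic 3' per-mismatch penalty)
* gap outside the last five bases: 1.00 each; gap within them: 3.00 each

A degenerate primer base matches any template base whose IUPAC set
intersects its own.  Sites are categorized as perfect (OWS 0), partial
(0 < OWS <= 1) or poor (OWS > 1); templates with no placement under the
score ceiling are ``no_site``.  Database surveys score the forward primer
on the plus strand and the reverse primer on the reverse complement and let
the worse primer govern the record's category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import (
    IUPAC,
    RANKS,
    PrimerPair,
    ReferenceRecord,
    iupac_match,
    reverse_complement,
)

# penalties in tenths to keep the DP integral
_P_NON3_MM = 4
_P_3P_MM = 10
_P_LAST_MM = 30
_P_NON3_GAP = 10
_P_3P_GAP = 30

PERFECT, PARTIAL, POOR, NO_SITE = "perfect", "partial", "poor", "no_site"


@dataclass(frozen=True)
class PrimerScore:
    """OWS breakdown for the best placement of one primer on one template."""

    non3_mismatches: int = 0
    three_prime_mismatches: int = 0
    last_base_mismatch: bool = False
    non3_gaps: int = 0
    three_prime_gaps: int = 0
    ows: float = 0.0
    category: str = PERFECT


def _mismatch_cost(i: int, length: int) -> int:
    if i == length - 1:
        return _P_LAST_MM
    if i >= length - 5:
        return _P_3P_MM
    return _P_NON3_MM


def _gap_cost(i: int, length: int) -> int:
    # a gap whose template-consumed position falls within the last five
    # primer bases is a 3' gap
    return _P_3P_GAP if i >= length - 5 else _P_NON3_GAP


def categorize(ows: float) -> str:
    """Map an overall weighted score to its specificity category."""
    if ows < 0:
        raise ValueError("OWS cannot be negative")
    if ows == 0:
        return PERFECT
    if ows <= 1.0 + 1e-9:
        return PARTIAL
    return POOR


def score_primer(primer: str, template: str, ceiling: float = 10.0) -> PrimerScore:
    """Minimal-OWS placement of ``primer`` (IUPAC, 5'->3') on ``template``.

    Returns the penalty breakdown of the best placement, or a ``no_site``
    score when no placement scores below ``ceiling``.
    """
    primer = primer.upper()
    template = template.upper()
    if len(primer) < 6:
        raise ValueError("primer must be at least 6 nt")
    if set(primer) - set(IUPAC):
        raise ValueError("non-IUPAC letters in primer")
    if len(template) <= len(primer):
        raise ValueError("template must be longer than the primer")
    L, T = len(primer), len(template)
    BIG = 10 ** 9

    # D[i][j]: min cost aligning primer[:i] with template ending at j
    # (template start free); moves: diagonal (match/mismatch), deletion of a
    # primer base (no template consumed), insertion of a template base.
    D = [[BIG] * (T + 1) for _ in range(L + 1)]
    D[0] = [0] * (T + 1)
    for i in range(1, L + 1):
        row, prev = D[i], D[i - 1]
        mm = _mismatch_cost(i - 1, L)
        dele = _gap_cost(i - 1, L)
        ins = _gap_cost(i, L) if i < L else None
        for j in range(0, T + 1):
            best = prev[j] + dele
            if j > 0:
                diag = prev[j - 1] + (0 if iupac_match(primer[i - 1], template[j - 1]) else mm)
                if diag < best:
                    best = diag
                if ins is not None and row[j - 1] + ins < best:
                    best = row[j - 1] + ins
            row[j] = best

    end = min(range(T + 1), key=lambda j: D[L][j])  # leftmost minimal end
    total = D[L][end]
    if total >= round(ceiling * 10):
        return PrimerScore(ows=total / 10.0, category=NO_SITE)

    # traceback (preference: diagonal, deletion, insertion)
    i, j = L, end
    non3_mm = tp_mm = non3_gap = tp_gap = 0
    last_mm = False
    while i > 0:
        cur = D[i][j]
        mm = _mismatch_cost(i - 1, L)
        dele = _gap_cost(i - 1, L)
        if j > 0 and D[i - 1][j - 1] + (
                0 if iupac_match(primer[i - 1], template[j - 1]) else mm) == cur:
            if not iupac_match(primer[i - 1], template[j - 1]):
                if i - 1 == L - 1:
                    last_mm = True
                elif i - 1 >= L - 5:
                    tp_mm += 1
                else:
                    non3_mm += 1
            i, j = i - 1, j - 1
        elif D[i - 1][j] + dele == cur:
            if i - 1 >= L - 5:
                tp_gap += 1
            else:
                non3_gap += 1
            i -= 1
        else:
            if i >= L - 5:
                tp_gap += 1
            else:
                non3_gap += 1
            j -= 1
    ows = total / 10.0
    return PrimerScore(non3_mismatches=non3_mm, three_prime_mismatches=tp_mm,
                       last_base_mismatch=last_mm, non3_gaps=non3_gap,
                       three_prime_gaps=tp_gap, ows=ows, category=categorize(ows))


def ungapped_placement_ows(primer: str, template: str, start: int) -> float:
    """Additive weighted score of one fixed ungapped placement.

    Unlike :func:`score_primer`, no minimization over placements happens:
    this evaluates the penalty sum of the primer laid at ``start``.  The sum
    is additive and monotone — every extra mismatch adds its penalty.
    """
    primer = primer.upper()
    template = template.upper()
    L = len(primer)
    if start < 0 or start + L > len(template):
        raise ValueError("placement outside the template")
    total = 0
    for i in range(L):
        if not iupac_match(primer[i], template[start + i]):
            total += _mismatch_cost(i, L)
    return total / 10.0


def score_pair(record_seq: str, pair: PrimerPair,
               ceiling: float = 10.0) -> tuple[PrimerScore, PrimerScore]:
    """Score the forward primer on the plus strand and the reverse primer on
    the reverse complement of a record."""
    fwd = score_primer(pair.forward, record_seq, ceiling)
    rev = score_primer(pair.reverse, reverse_complement(record_seq), ceiling)
    return fwd, rev


def survey_database(db: Sequence[ReferenceRecord], pair: PrimerPair,
                    ceiling: float = 10.0,
                    summary_rank: str = "phylum") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score both primers against every record; the worse primer governs.

    Returns (per-record table, per-taxon category-fraction summary).
    Non-amplifiable records (either primer ``no_site``) are tallied
    separately as ``no_site``.
    """
    rank_i = RANKS.index(summary_rank)
    rows = []
    for rec in db:
        fwd, rev = score_pair(rec.sequence, pair, ceiling)
        if NO_SITE in (fwd.category, rev.category):
            ows, cat = max(fwd.ows, rev.ows), NO_SITE
        else:
            ows = max(fwd.ows, rev.ows)
            cat = categorize(ows)
        rows.append((rec.id, rec.taxonomy.names[rank_i], fwd.ows, rev.ows, ows, cat))
    per_record = pd.DataFrame(
        rows, columns=["id", summary_rank, "fwd_ows", "rev_ows", "ows", "category"])
    summary = (per_record.groupby(summary_rank)["category"]
               .value_counts(normalize=True).unstack(fill_value=0.0))
    for cat in (PERFECT, PARTIAL, POOR, NO_SITE):
        if cat not in summary.columns:
            summary[cat] = 0.0
    summary = summary[[PERFECT, PARTIAL, POOR, NO_SITE]]
    return per_record, summary
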
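"""Pairwise alignment identity and exhaustive top-hit search.

Identity follows the mapping semantics of the usual amplicon workflows:
one of the two sequences is aligned end to end (both directions are tried
and the better kept, so the measure is symmetric) while the other
sequence's overhangs are free and excluded from the denominator — a
fragment contained verbatim in a longer reference scores 100.  Aligned
columns are scored match +1, mismatch -1, gap open -2, gap extend -1 (an
internal gap of length L costs 2 + (L - 1)).  Among equal-score alignments
the one with the most matches is used; remaining ties are resolved by a
fixed traceback preference (substitution, then gap in the second sequence,
then gap in the first) and a fixed choice of end cell, so results are
deterministic.

The top-hit search is exhaustive by contract — every reference is aligned,
no candidate is ever rejected — mirroring a usearch_global run with
``-id 0 -maxaccepts 0 -maxrejects 0 -top_hit_only -strand plus``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .core import ReferenceRecord, clean_sequence

# lexicographic (score, matches) pairs are packed as score * 8192 + matches;
# valid for sequences up to 8191 nt.
_K = 8192
_SHIFT = 13
_NEG = -(1 << 28)
MAX_LEN = _K - 1

_ENCODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


@njit(cache=True)
def _align_kernel(a, b):  # pragma: no cover - exercised via global_identity
    """Glocal affine-gap DP maximizing (score, matches): sequence ``a`` is
    fully aligned (its first and last bases sit in aligned columns) while
    the overhangs of ``b`` beyond the alignment are free and excluded.
    Returns (score, matches, columns) of the traceback path."""
    n, m = a.size, b.size
    M = np.full((n + 1, m + 1), _NEG, np.int32)
    X = np.full((n + 1, m + 1), _NEG, np.int32)  # gap in b (vertical, consumes a)
    Y = np.full((n + 1, m + 1), _NEG, np.int32)  # gap in a (horizontal, consumes b)
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            d = Mp[j - 1]
            if Xp[j - 1] > d:
                d = Xp[j - 1]
            if Yp[j - 1] > d:
                d = Yp[j - 1]
            if i == 1 and d < 0:
                d = 0  # a[0] anchors here; b's unread prefix is a free end gap
            if ai == b[j - 1]:
                Mi[j] = d + _K + 1
            else:
                Mi[j] = d - _K
            v = Mp[j] - 2 * _K
            if Xp[j] - _K > v:
                v = Xp[j] - _K
            if Yp[j] - 2 * _K > v:
                v = Yp[j] - 2 * _K
            Xi[j] = v
            v = Mi[j - 1] - 2 * _K
            if Yi[j - 1] - _K > v:
                v = Yi[j - 1] - _K
            if Xi[j - 1] - 2 * _K > v:
                v = Xi[j - 1] - 2 * _K
            Yi[j] = v

    # the path ends with a[n-1] in an aligned column; the first maximum in
    # scan order (strict improvement) fixes the end deterministically
    best = _NEG
    bj = 1
    for j in range(1, m + 1):
        if M[n, j] > best:
            best, bj = M[n, j], j
    bi = n

    matches = 0
    columns = 0
    i, j = bi, bj
    state = 0
    while True:
        if state == 0:
            eq = a[i - 1] == b[j - 1]
            step = (_K + 1) if eq else -_K
            prev = M[i, j] - step
            if eq:
                matches += 1
            columns += 1
            i -= 1
            j -= 1
            if i == 0 or j == 0:
                break  # a fully traced back; b's prefix is a free end gap
            if M[i, j] == prev:
                state = 0
            elif X[i, j] == prev:
                state = 1
            else:
                state = 2
        elif state == 1:
            cur = X[i, j]
            columns += 1
            i -= 1
            if M[i, j] == cur + 2 * _K:
                state = 0
            elif X[i, j] == cur + _K:
                state = 1
            else:
                state = 2
        else:
            cur = Y[i, j]
            columns += 1
            j -= 1
            if M[i, j] == cur + 2 * _K:
                state = 0
            elif Y[i, j] == cur + _K:
                state = 2
            else:
                state = 1

    score = best >> _SHIFT
    return score, matches, columns


@dataclass(frozen=True)
class AlignmentStats:
    score: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        if self.columns == 0:
            return 0.0
        return 100.0 * self.matches / self.columns


def align_stats(a: str, b: str) -> AlignmentStats:
    """Optimal alignment statistics for two plain-DNA strings.

    The alignment spans one sequence completely (both directions are tried
    and the better one kept), so identity is symmetric and a fragment
    contained in a longer sequence scores 100."""
    a = clean_sequence(a)
    b = clean_sequence(b)
    if len(a) > MAX_LEN or len(b) > MAX_LEN:
        raise ValueError(f"sequences longer than {MAX_LEN} nt are not supported")
    ea, eb = _encode(a), _encode(b)
    cands = [AlignmentStats(*map(int, _align_kernel(ea, eb))),
             AlignmentStats(*map(int, _align_kernel(eb, ea)))]
    return max(cands, key=lambda s: (s.score, s.matches, s.identity))


def global_identity(a: str, b: str) -> float:
    """Percent identity of the optimal global alignment of ``a`` and ``b``.

    Terminal-gap columns are excluded from the denominator, so a short
    sequence contained verbatim in a longer one scores 100.0.
    """
    return align_stats(a, b).identity


@dataclass(frozen=True)
class HitResult:
    """Best database hit for one query."""

    query_id: str
    ref_id: str
    identity: float
    tie_count: int


def top_hit(query: str, refs: Sequence[ReferenceRecord],
            query_id: str = "query") -> HitResult:
    """Exhaustive best-hit search of ``query`` against ``refs``.

    Every reference is aligned (plus strand only); the maximal-identity
    reference wins, ties going to the lowest database index.  ``tie_count``
    reports how many references attained the winning identity.
    """
    if not refs:
        raise ValueError("reference set is empty")
    best_idx = -1
    best_ident = -1.0
    ties = 0
    for idx, rec in enumerate(refs):
        ident = global_identity(query, rec.sequence)
        if ident > best_ident:
            best_idx, best_ident, ties = idx, ident, 1
        elif ident == best_ident:
            ties += 1
    return HitResult(query_id=query_id, ref_id=refs[best_idx].id,
                     identity=best_ident, tie_count=ties)


def map_queries(queries: Sequence[tuple[str, str]],
                refs: Sequence[ReferenceRecord]):
    """Batch top-hit mapping; returns a DataFrame (query, ref, identity, tie_count)."""
    import pandas as pd

    rows = []
    for qid, seq in queries:
        hit = top_hit(seq, refs, query_id=qid)
        rows.append((hit.query_id, hit.ref_id, hit.identity, hit.tie_count))
    return pd.DataFrame(rows, columns=["query", "ref", "identity", "tie_count"])
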
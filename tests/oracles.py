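"""Independent reference implementations used to cross-check the package.

These are deliberately naive: plain-Python dynamic programming with explicit
(score, matches) tuples, full alignment enumeration for tiny inputs, and a
placement-enumeration primer scorer.  They share no code with the package
internals they validate.
"""

from __future__ import annotations

NEG = (-(10 ** 9), 0)

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 1, -1, -2, -1

IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}


def _glocal(a: str, b: str) -> tuple[int, int, int, float]:
    """Tuple-valued glocal DP: ``a`` fully aligned, ``b`` overhangs free.

    Mirrors the package conventions: lexicographic (score, matches), end
    cell at the first maximum of the last row, traceback preference
    substitution > gap-in-b > gap-in-a.  Returns
    (score, matches, columns, identity).
    """
    n, m = len(a), len(b)
    ZERO = (0, 0)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if i == 1 and best < ZERO:
                best = ZERO  # a[0] anchors here; b's prefix is a free end gap
            if a[i - 1] == b[j - 1]:
                M[i][j] = (best[0] + MATCH, best[1] + 1)
            else:
                M[i][j] = (best[0] + MISMATCH, best[1])
            M_up, X_up, Y_up = M[i - 1][j], X[i - 1][j], Y[i - 1][j]
            X[i][j] = max((M_up[0] + GAP_OPEN, M_up[1]),
                          (X_up[0] + GAP_EXT, X_up[1]),
                          (Y_up[0] + GAP_OPEN, Y_up[1]))
            M_l, X_l, Y_l = M[i][j - 1], X[i][j - 1], Y[i][j - 1]
            Y[i][j] = max((M_l[0] + GAP_OPEN, M_l[1]),
                          (Y_l[0] + GAP_EXT, Y_l[1]),
                          (X_l[0] + GAP_OPEN, X_l[1]))

    best = NEG
    bj = 1
    for j in range(1, m + 1):
        if M[n][j] > best:
            best, bj = M[n][j], j

    matches = columns = 0
    i, j, state = n, bj, 0
    while True:
        if state == 0:
            eq = a[i - 1] == b[j - 1]
            cur = M[i][j]
            prev = (cur[0] - (MATCH if eq else MISMATCH),
                    cur[1] - (1 if eq else 0))
            if eq:
                matches += 1
            columns += 1
            i, j = i - 1, j - 1
            if i == 0 or j == 0:
                break
            if M[i][j] == prev:
                state = 0
            elif X[i][j] == prev:
                state = 1
            else:
                state = 2
        elif state == 1:
            cur = X[i][j]
            columns += 1
            i -= 1
            if M[i][j] == (cur[0] - GAP_OPEN, cur[1]):
                state = 0
            elif X[i][j] == (cur[0] - GAP_EXT, cur[1]):
                state = 1
            else:
                state = 2
        else:
            cur = Y[i][j]
            columns += 1
            j -= 1
            if M[i][j] == (cur[0] - GAP_OPEN, cur[1]):
                state = 0
            elif Y[i][j] == (cur[0] - GAP_EXT, cur[1]):
                state = 2
            else:
                state = 1

    identity = 100.0 * matches / columns if columns else 0.0
    return best[0], best[1], columns, identity


def dp_align(a: str, b: str) -> tuple[int, int, float]:
    """Best-of-both-directions glocal alignment (the package's semantics):
    one sequence fully aligned, the other's overhangs free and excluded.
    Returns (score, matches, identity)."""
    cands = [_glocal(a, b), _glocal(b, a)]
    score, matches, _, identity = max(
        cands, key=lambda t: (t[0], t[1], t[3]))
    return score, matches, identity


def enumerate_alignments(a: str, b: str) -> tuple[tuple[int, int], set[float]]:
    """All global alignments of two tiny strings, scored under the glocal
    semantics: one sequence fully aligned, the other's overhang runs at the
    ends free and excluded, internal columns affine-scored.

    Returns the lexicographically maximal (score, matches) and the set of
    identities over all alignment cores attaining it.
    """
    results: list[list[int]] = []

    def rec(i: int, j: int, cols: list[int]) -> None:
        if i == len(a) and j == len(b):
            results.append(cols.copy())
            return
        if i < len(a) and j < len(b):
            cols.append(0 if a[i] == b[j] else 1)
            rec(i + 1, j + 1, cols)
            cols.pop()
        if i < len(a):
            cols.append(2)  # gap in b, consumes a
            rec(i + 1, j, cols)
            cols.pop()
        if j < len(b):
            cols.append(3)  # gap in a, consumes b
            rec(i, j + 1, cols)
            cols.pop()

    rec(0, 0, [])
    scored: list[tuple[int, int, int]] = []  # (score, matches, columns)
    for cols in results:
        # each direction may trim end runs of its free-overhang gap type
        # (3 = b overhang when a is the anchored sequence, 2 vice versa);
        # the core must start and end with an aligned column
        for free in (3, 2):
            lo, hi = 0, len(cols)
            while lo < hi and cols[lo] == free:
                lo += 1
            while hi > lo and cols[hi - 1] == free:
                hi -= 1
            trimmed = cols[lo:hi]
            if not trimmed or trimmed[0] >= 2 or trimmed[-1] >= 2:
                continue
            score = matches = 0
            prev_gap = 0
            for c in trimmed:
                if c >= 2:
                    score += GAP_EXT if prev_gap == c else GAP_OPEN
                    prev_gap = c
                else:
                    prev_gap = 0
                    if c == 0:
                        score += MATCH
                        matches += 1
                    else:
                        score += MISMATCH
            scored.append((score, matches, len(trimmed)))
    best = max((s, mt) for s, mt, _ in scored)
    identities = {100.0 * mt / cols if cols else 0.0
                  for s, mt, cols in scored if (s, mt) == best}
    return best, identities


def _penalty(i: int, length: int, gap: bool) -> float:
    if gap:
        return 3.0 if i >= length - 5 else 1.0
    if i == length - 1:
        return 3.0
    if i >= length - 5:
        return 1.0
    return 0.4


def primer_min_ows(primer: str, template: str) -> float:
    """Minimal overall weighted score over all placements with <= 1 gap."""
    L, T = len(primer), len(template)
    best = float("inf")

    def match(i: int, t: int) -> bool:
        return t < T and bool(IUPAC[primer[i]] & IUPAC.get(template[t], set()))

    for start in range(T):
        # ungapped
        if start + L <= T:
            c = sum(_penalty(i, L, False) for i in range(L)
                    if not match(i, start + i))
            best = min(best, c)
        # primer base g unaligned (template deletion)
        for g in range(L):
            if start + L - 1 > T:
                continue
            c = _penalty(g, L, True)
            t = start
            ok = True
            for i in range(L):
                if i == g:
                    continue
                if t >= T:
                    ok = False
                    break
                if not match(i, t):
                    c += _penalty(i, L, False)
                t += 1
            if ok:
                best = min(best, c)
        # extra template base before primer base g (insertion)
        for g in range(1, L):
            if start + L + 1 > T:
                continue
            c = _penalty(g, L, True)
            t = start
            ok = True
            for i in range(L):
                if i == g:
                    t += 1
                if t >= T:
                    ok = False
                    break
                if not match(i, t):
                    c += _penalty(i, L, False)
                t += 1
            if ok:
                best = min(best, c)
    return round(best, 10)
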
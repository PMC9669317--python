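"""Seeded generators with planted ground truth.

Everything the builder, classifier and evaluation suites consume can be
simulated here: a universal reference database with a full seven-rank
taxonomy, query sequences placed at controlled identities to their nearest
universal relative (a divergence ladder spanning the rank thresholds),
amplicon datasets with log-normal abundances, and primer sites perturbed
with mismatches or gaps of known weighted score.

Design notes: query divergence uses substitutions only, so the identity to
the parent is analytically ``100 * (L - s) / L`` over the trimmed window;
planted mutations never touch primer binding sites, and perturbed primer
sites are rejection-sampled so no spurious intact site remains.  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .builder import find_primer_window
from .core import (
    BACTERIAL_TRIM_PAIR,
    IUPAC,
    RANKS,
    V5V7_PAIR,
    PrimerPair,
    ReferenceRecord,
    TaxonomyPath,
    ThresholdTable,
    iupac_regex,
    rank_for_identity,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))

#: identity targets for each planted deepest-inheritable rank under the
#: default thresholds.  The substitution-only identity is a floor: an optimal
#: alignment can only gain matches through gaps, never lose them, so targets
#: sit near the bottom of each band to leave headroom below the next
#: threshold.
DEFAULT_BAND_TARGETS: dict[str, float] = {
    "species": 98.85,
    "genus": 94.8,
    "family": 86.8,
    "order": 82.3,
    "class": 78.8,
    "phylum": 75.3,
    "none": 70.0,
}


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the planted-truth reference simulation.

    The taxonomy tree sizes give one universal record per species.  Queries
    are allocated per planted deepest-inheritable rank; each query derives
    from one universal record by substitutions calibrated to the target
    identity band of its rank.  Sequences carry the trimming-primer pair at
    their ends and the amplicon pair around an internal variable region, so
    the same simulation feeds the trimming, mapping, classification and
    in-silico amplicon analyses.
    """

    n_phyla: int = 4
    classes_per_phylum: int = 1
    orders_per_class: int = 1
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 2
    length: int = 1300
    novelty_counts: dict[str, int] = field(default_factory=lambda: {
        "species": 60, "genus": 50, "family": 30, "order": 20,
        "class": 15, "phylum": 15, "none": 10,
    })
    trim_pair: PrimerPair = BACTERIAL_TRIM_PAIR
    amplicon_pair: PrimerPair = V5V7_PAIR
    amplicon_offset: int = 150   # bases between trim-fwd site end and amplicon fwd site
    amplicon_core: int = 300     # length of the inter-amplicon-primer region
    duplicate_max: int = 3       # raw-read copies per query (uniform 1..max)
    samples: int = 6
    lognormal_mean: float = 6.0   # per-ASV log-scale mean: ~10^4-10^5 reads/sample
    lognormal_sigma: float = 1.5
    thresholds: ThresholdTable = field(default_factory=ThresholdTable)
    seed: int = 0

    def n_lineages(self) -> int:
        return (self.n_phyla * self.classes_per_phylum * self.orders_per_class
                * self.families_per_order * self.genera_per_family
                * self.species_per_genus)


def _expand_primer(primer: str, rng: np.random.Generator) -> str:
    """Pick one concrete expansion of a degenerate primer."""
    return "".join(
        ch if len(IUPAC[ch]) == 1 else sorted(IUPAC[ch])[rng.integers(len(IUPAC[ch]))]
        for ch in primer)


def _lineage_names(spec: SimSpec) -> list[TaxonomyPath]:
    """Full seven-rank official-looking names for every simulated species."""
    paths = []
    counters = dict.fromkeys(RANKS, 0)
    labels = {"domain": "Bacteria"}

    def walk(rank_i: int, names: list[str]) -> None:
        rank = RANKS[rank_i]
        fanout = {
            "phylum": spec.n_phyla, "class": spec.classes_per_phylum,
            "order": spec.orders_per_class, "family": spec.families_per_order,
            "genus": spec.genera_per_family, "species": spec.species_per_genus,
        }[rank]
        for _ in range(fanout):
            counters[rank] += 1
            name = f"Sim{rank.capitalize().rstrip('_')}{counters[rank]}"
            if rank_i == 6:
                paths.append(TaxonomyPath.from_names(names + [name]))
            else:
                walk(rank_i + 1, names + [name])

    walk(1, [labels["domain"]])
    return paths


def _build_template(spec: SimSpec, rng: np.random.Generator
                    ) -> tuple[str, np.ndarray]:
    """One random trim-window sequence with planted amplicon-primer sites.

    The template spans exactly the region between the trimming-primer sites
    (the primers themselves are added only to raw reads), so the identity of
    a substituted copy to its template is analytically exact.  Returns
    (sequence, mutable positions) with the amplicon primer sites excluded
    from the mutable set.
    """
    fa = _expand_primer(spec.amplicon_pair.forward, rng)
    ra = reverse_complement(_expand_primer(spec.amplicon_pair.reverse, rng))
    window_len = (spec.length - len(spec.trim_pair.forward)
                  - len(spec.trim_pair.reverse))
    tail = window_len - len(fa) - len(ra) - spec.amplicon_offset - spec.amplicon_core
    if tail < 20:
        raise ValueError("length too short for the requested primer layout")
    seg1 = "".join(rng.choice(_BASES, spec.amplicon_offset))
    core = "".join(rng.choice(_BASES, spec.amplicon_core))
    seg2 = "".join(rng.choice(_BASES, tail))
    seq = seg1 + fa + core + ra + seg2
    fa_start = len(seg1)
    ra_start = fa_start + len(fa) + len(core)
    mutable = np.array(
        [p for p in range(len(seq))
         if not (fa_start <= p < fa_start + len(fa))
         and not (ra_start <= p < ra_start + len(ra))], dtype=np.int64)
    return seq, mutable


def _substitute(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    chars = list(seq)
    for p in positions.tolist():
        choices = [b for b in "ACGT" if b != chars[p]]
        chars[p] = choices[rng.integers(3)]
    return "".join(chars)


def substitutions_for_band(window_len: int, low: float, high: float,
                           target: float) -> int:
    """Substitution count whose analytic identity lies in (low, high).

    Identity is ``100 * (L - s) / L``; raises when no integer count fits the
    band (the band is infeasible at this length).
    """
    s = int(round(window_len * (1.0 - target / 100.0)))
    for cand in (s, s + 1, s - 1):
        if cand < 0 or cand > window_len:
            continue
        ident = 100.0 * (window_len - cand) / window_len
        if low < ident < high or (high == 100.0 and low < ident <= 100.0):
            return cand
    raise ValueError(
        f"identity band ({low}, {high}) infeasible at window length {window_len}")


def _band_for_rank(rank: str, thresholds: ThresholdTable) -> tuple[float, float]:
    if rank == "none":
        return 0.0, thresholds.phylum
    order = ["phylum", "class", "order", "family", "genus", "species"]
    i = order.index(rank)
    low = thresholds.values()[i]
    high = thresholds.values()[i + 1] if i + 1 < 6 else 100.0
    return low, high


def simulate_reference(spec: SimSpec | None = None
                       ) -> tuple[list[ReferenceRecord], list[str], pd.DataFrame]:
    """Simulate a universal database and a query set with planted novelty.

    Returns ``(universal, raw_reads, truth)``: the fully annotated universal
    records (spanning the trim window, amplicon-primer sites intact), the
    raw near-full-length query reads (untrimmed, flanked by the trimming
    primers, with duplicate copies), and a truth table with one row per
    unique query giving its trimmed sequence, parent universal record,
    planted identity and planted deepest-inheritable rank.
    """
    spec = spec or SimSpec()
    rng = np.random.default_rng(spec.seed)
    paths = _lineage_names(spec)
    universal = []
    templates = []
    for i, path in enumerate(paths):
        seq, mutable = _build_template(spec, rng)
        universal.append(ReferenceRecord(id=f"UNI{i + 1}", sequence=seq,
                                         taxonomy=path))
        templates.append((seq, mutable))

    window_len = (spec.length - len(spec.trim_pair.forward)
                  - len(spec.trim_pair.reverse))

    truth_rows = []
    raw_reads: list[str] = []
    seen: set[str] = set()
    qnum = 0
    for rank, count in spec.novelty_counts.items():
        low, high = _band_for_rank(rank, spec.thresholds)
        target = DEFAULT_BAND_TARGETS.get(rank)
        if target is None or not (low < target < high or high == 100.0):
            target = (low + min(high, 100.0)) / 2.0
        s = substitutions_for_band(window_len, low, high, target)
        for _ in range(count):
            qnum += 1
            for _attempt in range(100):
                parent_i = int(rng.integers(len(universal)))
                seq, mutable = templates[parent_i]
                pos = rng.choice(mutable, size=s, replace=False)
                trimmed = _substitute(seq, pos, rng)
                if trimmed not in seen:
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not generate a unique query")
            seen.add(trimmed)
            mutated = (_expand_primer(spec.trim_pair.forward, rng) + trimmed
                       + reverse_complement(_expand_primer(spec.trim_pair.reverse, rng)))
            copies = int(rng.integers(1, spec.duplicate_max + 1))
            raw_reads.extend([mutated] * copies)
            planted_identity = 100.0 * (window_len - s) / window_len
            truth_rows.append({
                "query": f"Q{qnum}",
                "trimmed_sequence": trimmed,
                "parent": universal[parent_i].id,
                "substitutions": s,
                "planted_identity": planted_identity,
                "planted_rank": rank_for_identity(planted_identity, spec.thresholds)
                if planted_identity >= spec.thresholds.phylum else "none",
                "copies": copies,
            })
    # shuffle raw reads so dereplication order is not generation order
    order = rng.permutation(len(raw_reads))
    raw_reads = [raw_reads[i] for i in order]
    return universal, raw_reads, pd.DataFrame(truth_rows)


def simulate_amplicon_dataset(db: Sequence[ReferenceRecord], pair: PrimerPair,
                              spec: SimSpec | None = None,
                              planted_rare: int = 0
                              ) -> tuple["AmpliconDataset", pd.DataFrame]:
    """Extract amplicons from a database and draw per-sample counts.

    ASVs are the unique inter-primer regions of the database records;
    counts follow a seeded log-normal (rounded, minimum 1) per ASV/sample.
    The first ``planted_rare`` ASVs are forced to single-read counts so they
    fall below typical relative-abundance filters; the truth table flags
    per-ASV maximal relative abundance.
    """
    from .core import AmpliconDataset

    spec = spec or SimSpec()
    rng = np.random.default_rng(spec.seed + 1)
    cores: dict[str, dict] = {}
    for rec in db:
        window = find_primer_window(rec.sequence, pair)
        if window is None:
            continue
        core = rec.sequence[window[0]:window[1]]
        entry = cores.setdefault(core, {"parents": []})
        entry["parents"].append(rec.id)
    asv_ids = [f"ASV{i + 1}" for i in range(len(cores))]
    seqs = dict(zip(asv_ids, cores.keys()))
    counts = np.maximum(
        np.rint(rng.lognormal(spec.lognormal_mean, spec.lognormal_sigma,
                              size=(len(asv_ids), spec.samples))), 1).astype(int)
    for i in range(min(planted_rare, len(asv_ids))):
        counts[i, :] = 1
    table = pd.DataFrame(counts, index=asv_ids,
                         columns=[f"S{j + 1}" for j in range(spec.samples)])
    dataset = AmpliconDataset(sequences=seqs, counts=table)
    rel = dataset.relative_abundance()
    truth = pd.DataFrame({
        "asv": asv_ids,
        "parent": [cores[seqs[a]]["parents"][0] for a in asv_ids],
        "n_parents": [len(cores[seqs[a]]["parents"]) for a in asv_ids],
        "max_rel_abundance": rel.max(axis=1).to_numpy(),
    })
    return dataset, truth


_PLANT_KINDS = ("non3", "three_prime", "terminal", "gap_non3", "gap_three_prime")

_EXPECTED_OWS = {"non3": 0.4, "three_prime": 1.0, "terminal": 3.0,
                 "gap_non3": 1.0, "gap_three_prime": 3.0}


def _penalty(i: int, L: int, gap: bool) -> int:
    """Weighted-score penalty in tenths for primer position i."""
    if gap:
        return 30 if i >= L - 5 else 10
    if i == L - 1:
        return 30
    if i >= L - 5:
        return 10
    return 4


def _local_min_ows(primer: str, template: str) -> int:
    """Minimal weighted score (tenths) over all placements with at most one
    gap.  Used as a feasibility check when planting perturbations: a plant
    is accepted only when this enumeration reproduces the intended score.
    Multi-gap reinterpretations cost at least two gap penalties (>= 2.0) and
    cannot undercut any planted score once single-gap ones are excluded."""
    from .core import iupac_match

    L, T = len(primer), len(template)
    best = 10 ** 9

    def ungapped_cost(start: int, skip_primer: int | None, skip_template: int | None,
                      gap_pos: int) -> int:
        c = 0 if skip_primer is None and skip_template is None else _penalty(
            gap_pos, L, gap=True)
        ti = start
        for i in range(L):
            if i == skip_primer:
                continue
            if ti == skip_template:
                ti += 1
            if ti >= T:
                return 10 ** 9
            if not iupac_match(primer[i], template[ti]):
                c += _penalty(i, L, gap=False)
            ti += 1
        return c

    for start in range(0, max(T - L + 2, 1)):
        best = min(best, ungapped_cost(start, None, None, 0))
        for g in range(L):  # primer base g deleted from the template
            best = min(best, ungapped_cost(start, g, None, g))
        for g in range(1, L):  # extra template base before primer base g
            best = min(best, ungapped_cost(start, None, start + g, g))
    return best


def plant_primer_mutations(db: Sequence[ReferenceRecord], pair: PrimerPair,
                           kind: str, n_records: int | None = None,
                           seed: int = 0) -> tuple[list[ReferenceRecord], pd.DataFrame]:
    """Perturb forward-primer binding sites with a known weighted score.

    ``kind`` selects the perturbation: a substitution outside the last five
    primer bases (``non3``, expected score 0.40), inside them but not
    terminal (``three_prime``, 1.00), at the terminal base (``terminal``,
    3.00), or a single-base deletion (``gap_non3`` 1.00 /
    ``gap_three_prime`` 3.00).  Returns perturbed record copies and a truth
    table of expected per-record scores.  Mutations are rejection-sampled so
    the record retains no intact primer site.
    """
    if kind not in _PLANT_KINDS:
        raise ValueError(f"kind must be one of {_PLANT_KINDS}")
    rng = np.random.default_rng(seed)
    primer = pair.forward
    L = len(primer)
    if kind == "non3":
        positions = [i for i in range(L - 5) if len(IUPAC[primer[i]]) < 4]
    elif kind == "three_prime":
        positions = [i for i in range(L - 5, L - 1) if len(IUPAC[primer[i]]) < 4]
    elif kind == "terminal":
        positions = [L - 1] if len(IUPAC[primer[L - 1]]) < 4 else []
    elif kind == "gap_non3":
        positions = list(range(1, L - 5))
    else:
        positions = list(range(L - 5, L - 2))
    if not positions:
        raise ValueError(f"primer has no usable position for kind {kind!r}")

    chosen = list(db if n_records is None else db[:n_records])
    expected_tenths = round(_EXPECTED_OWS[kind] * 10)
    out = []
    rows = []
    pattern = iupac_regex(primer)
    for rec in chosen:
        m = pattern.search(rec.sequence)
        if m is None:
            raise ValueError(f"record {rec.id} lacks a forward-primer site")
        site = m.start()
        mutated = None
        for pos in rng.permutation(positions).tolist():
            chars = list(rec.sequence)
            p = site + pos
            if kind.startswith("gap"):
                del chars[p]
            else:
                disallowed = IUPAC[primer[pos]]
                choices = [b for b in "ACGT" if b not in disallowed and b != chars[p]]
                if not choices:
                    continue
                chars[p] = choices[int(rng.integers(len(choices)))]
            cand = "".join(chars)
            if pattern.search(cand) is not None:
                continue
            lo = max(0, site - L - 5)
            hi = min(len(cand), site + 2 * L + 5)
            if _local_min_ows(primer, cand[lo:hi]) == expected_tenths:
                mutated = cand
                break
        if mutated is None:
            raise ValueError(
                f"cannot plant a {kind!r} perturbation of score "
                f"{_EXPECTED_OWS[kind]} for primer {primer!r} (record {rec.id}): "
                "every candidate position admits a cheaper interpretation")
        out.append(ReferenceRecord(id=rec.id, sequence=mutated,
                                   abundance=rec.abundance, taxonomy=rec.taxonomy))
        rows.append({"id": rec.id, "kind": kind,
                     "expected_ows": _EXPECTED_OWS[kind]})
    return out, pd.DataFrame(rows)
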
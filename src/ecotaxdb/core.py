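"""Domain types and shared utilities for 16S reference-database work.

This module holds the vocabulary every other part of the package speaks:
the seven-rank taxonomy (domain..species), the per-rank identity thresholds
used to decide how deep a taxonomy may be transferred from a database hit,
the reference-record and amplicon-dataset containers, IUPAC-degenerate
primer handling, and the text formats (SINTAX / QIIME headers, FASTA,
count tables) used on disk.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)
#: single-letter rank codes used in SINTAX headers and placeholder names
RANK_LETTERS: dict[str, str] = {
    "domain": "d", "phylum": "p", "class": "c", "order": "o",
    "family": "f", "genus": "g", "species": "s",
}
LETTER_RANKS: dict[str, str] = {v: k for k, v in RANK_LETTERS.items()}

INHERITED = "inherited"
DE_NOVO = "de_novo"
EMPTY = "empty"

_PLACEHOLDER_RE = re.compile(r"^(?P<prefix>.+)_(?P<letter>[pcofgs])_(?P<number>\d+)$")

#: IUPAC degenerate nucleotide alphabet -> set of plain bases
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def clean_sequence(seq: str) -> str:
    """Normalize a nucleotide string: uppercase, U->T; reject non-ACGT."""
    s = seq.upper().replace("U", "T")
    if not s:
        raise ValueError("empty sequence")
    if set(s) - {"A", "C", "G", "T"}:
        bad = sorted(set(s) - {"A", "C", "G", "T"})
        raise ValueError(f"non-ACGT characters in sequence: {bad}")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def parse_placeholder(name: str) -> tuple[str, str, int] | None:
    """Split a de novo placeholder name into (prefix, rank, number).

    Returns None if the name does not follow ``<prefix>_<rankletter>_<int>``.
    """
    m = _PLACEHOLDER_RE.match(name)
    if m is None:
        return None
    return m.group("prefix"), LETTER_RANKS[m.group("letter")], int(m.group("number"))


def make_placeholder(prefix: str, rank: str, number: int) -> str:
    if rank == "domain":
        raise ValueError("no placeholder names at domain rank")
    return f"{prefix}_{RANK_LETTERS[rank]}_{number}"


@dataclass(frozen=True)
class TaxonomyPath:
    """Seven-rank taxonomy with per-rank provenance.

    ``names`` holds one entry per rank in RANKS order; an empty string means
    the rank is unassigned.  ``provenance`` mirrors ``names`` with one of
    ``inherited`` (copied from a database hit), ``de_novo`` (placeholder) or
    ``empty``.
    """

    names: tuple[str, ...] = ("",) * 7
    provenance: tuple[str, ...] = (EMPTY,) * 7

    def __post_init__(self) -> None:
        if len(self.names) != 7 or len(self.provenance) != 7:
            raise ValueError("TaxonomyPath needs exactly seven ranks")
        for name, prov in zip(self.names, self.provenance):
            if (name == "") != (prov == EMPTY):
                raise ValueError("provenance flags inconsistent with names")

    @classmethod
    def from_names(cls, names: Sequence[str], prefix: str | None = None) -> "TaxonomyPath":
        """Build a path, inferring provenance from the placeholder grammar."""
        names = tuple(names) + ("",) * (7 - len(names))
        prov = []
        for name in names:
            if not name:
                prov.append(EMPTY)
            elif parse_placeholder(name) is not None and (
                prefix is None or parse_placeholder(name)[0] == prefix
            ):
                prov.append(DE_NOVO)
            else:
                prov.append(INHERITED)
        return cls(names, tuple(prov))

    def name(self, rank: str) -> str:
        return self.names[RANKS.index(rank)]

    def with_rank(self, rank: str, name: str, provenance: str) -> "TaxonomyPath":
        i = RANKS.index(rank)
        names = list(self.names)
        prov = list(self.provenance)
        names[i], prov[i] = name, provenance
        return TaxonomyPath(tuple(names), tuple(prov))

    def deepest_filled(self) -> str | None:
        """Name of the deepest non-empty rank, or None if fully empty."""
        for rank, name in zip(reversed(RANKS), reversed(self.names)):
            if name:
                return rank
        return None

    def is_contiguous(self) -> bool:
        """No empty rank above a filled rank (domain downward)."""
        seen_empty = False
        for name in self.names:
            if not name:
                seen_empty = True
            elif seen_empty:
                return False
        return True

    def is_complete(self) -> bool:
        return all(self.names)

    def filled_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n)


@dataclass(frozen=True)
class ThresholdTable:
    """Per-rank minimum percent identity for taxonomy transfer.

    Defaults are the rank thresholds commonly used for 16S-based taxonomy
    (phylum 75.0 up to species 98.7).  Identity exactly equal to a threshold
    is assignable at that rank; novelty categories are strict "below".
    """

    phylum: float = 75.0
    class_: float = 78.5
    order: float = 82.0
    family: float = 86.5
    genus: float = 94.5
    species: float = 98.7

    def __post_init__(self) -> None:
        vals = self.values()
        if any(not (0.0 < v <= 100.0) for v in vals):
            raise ValueError("thresholds must lie in (0, 100]")
        if any(a >= b for a, b in zip(vals, vals[1:])):
            raise ValueError("thresholds must increase strictly phylum -> species")

    def values(self) -> tuple[float, ...]:
        return (self.phylum, self.class_, self.order, self.family,
                self.genus, self.species)

    def threshold(self, rank: str) -> float:
        if rank == "domain":
            raise ValueError("no identity threshold at domain rank")
        return self.values()[RANKS.index(rank) - 1]


#: ranks that carry an identity threshold, shallow to deep
THRESHOLD_RANKS: tuple[str, ...] = RANKS[1:]


def rank_for_identity(identity: float, thresholds: ThresholdTable | None = None) -> str:
    """Deepest rank transferable at the given percent identity.

    Returns a rank name, or ``"none"`` when identity is below the phylum
    threshold.  The boundary is inclusive: identity equal to a rank's
    threshold allows that rank.
    """
    if not (0.0 <= identity <= 100.0):
        raise ValueError(f"identity {identity} outside [0, 100]")
    thresholds = thresholds or ThresholdTable()
    best = "none"
    for rank, cut in zip(THRESHOLD_RANKS, thresholds.values()):
        if identity >= cut:
            best = rank
        else:
            break
    return best


@dataclass
class ReferenceRecord:
    """One reference sequence with its taxonomy and provenance."""

    id: str
    sequence: str
    abundance: int = 1
    taxonomy: TaxonomyPath = field(default_factory=TaxonomyPath)
    best_hit_identity: float | None = None

    def __post_init__(self) -> None:
        self.sequence = clean_sequence(self.sequence)
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3' on their own strand."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if len(p) < 6:
                raise ValueError("primers must be at least 6 nt")
            if set(p.upper()) - set(IUPAC):
                raise ValueError(f"non-IUPAC letters in primer {p!r}")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


#: primer sequences used as trimming / amplification defaults.  The V5-V7
#: pair (799F/1192R) is the plant-microbiome amplicon pair; 27f/1391r is the
#: conventional near-full-length bacterial trimming pair.
PRIMER_CATALOG: dict[str, str] = {
    "27f": "AGAGTTTGATCMTGGCTCAG",
    "1391r": "GACGGGCGGTGTGTRCA",
    "799F": "AACMGGATTAGATACCCKG",
    "1192R": "ACGTCATCCCCACCTTCC",
}

BACTERIAL_TRIM_PAIR = PrimerPair(PRIMER_CATALOG["27f"], PRIMER_CATALOG["1391r"])
V5V7_PAIR = PrimerPair(PRIMER_CATALOG["799F"], PRIMER_CATALOG["1192R"])


def iupac_regex(primer: str) -> re.Pattern[str]:
    """Compile a degenerate-exact regex for a primer (plus-strand search)."""
    parts = []
    for ch in primer.upper():
        bases = sorted(IUPAC[ch])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile("".join(parts))


def iupac_match(primer_base: str, template_base: str) -> bool:
    """True when the IUPAC sets of the two bases intersect."""
    return bool(IUPAC[primer_base] & IUPAC.get(template_base, frozenset()))


# ---------------------------------------------------------------------------
# amplicon dataset
# ---------------------------------------------------------------------------

@dataclass
class AmpliconDataset:
    """Short-read ASVs plus a per-sample count table.

    ``counts`` is indexed by ASV id with one column per sample.  Relative
    abundances are derived per sample as count / sample total.
    """

    sequences: dict[str, str]
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.counts.index) - set(self.sequences)
        if missing:
            raise ValueError(f"count table rows without sequences: {sorted(missing)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return self.counts.div(totals.where(totals > 0, other=1), axis=1)


# ---------------------------------------------------------------------------
# taxonomy text dialects
# ---------------------------------------------------------------------------

def format_taxonomy(record_id: str, path: TaxonomyPath, dialect: str = "sintax") -> str:
    """Render one record's taxonomy in the SINTAX or QIIME dialect.

    SINTAX: ``id;tax=d:...,p:...,...;`` — QIIME: ``id<TAB>d__...; p__...``.
    Only filled ranks are emitted (they are contiguous from domain).
    """
    if not path.is_contiguous():
        raise ValueError("taxonomy path has a gap; cannot format")
    pairs = [(RANK_LETTERS[r], n) for r, n in zip(RANKS, path.names) if n]
    if dialect == "sintax":
        body = ",".join(f"{c}:{n}" for c, n in pairs)
        return f"{record_id};tax={body};"
    if dialect == "qiime":
        body = "; ".join(f"{c}__{n}" for c, n in pairs)
        return f"{record_id}\t{body}"
    raise ValueError(f"unknown dialect {dialect!r}")


def parse_taxonomy(line: str, dialect: str = "sintax", prefix: str | None = None
                   ) -> tuple[str, TaxonomyPath]:
    """Inverse of :func:`format_taxonomy`; returns (record id, path)."""
    if dialect == "sintax":
        m = re.match(r"^(?P<id>.*?);tax=(?P<body>.*);$", line)
        if m is None:
            raise ValueError(f"not a SINTAX taxonomy line: {line!r}")
        rec_id, body = m.group("id"), m.group("body")
        tokens = body.split(",") if body else []
        sep = ":"
    elif dialect == "qiime":
        rec_id, _, body = line.partition("\t")
        if not _:
            raise ValueError(f"not a QIIME taxonomy line: {line!r}")
        tokens = [t.replace("__", ":", 1) for t in body.split("; ")] if body else []
        sep = ":"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    names = [""] * 7
    for tok in tokens:
        letter, _, name = tok.partition(sep)
        if letter not in LETTER_RANKS or not name:
            raise ValueError(f"malformed rank token {tok!r}")
        names[RANKS.index(LETTER_RANKS[letter])] = name
    path = TaxonomyPath.from_names(names, prefix=prefix)
    if not path.is_contiguous():
        raise ValueError(f"non-contiguous taxonomy in {line!r}")
    return rec_id, path


# ---------------------------------------------------------------------------
# coverage-normalization factor for read-tag libraries
# ---------------------------------------------------------------------------

def cseq_factor(peak_molarity: float, peak_size: float) -> float:
    """Effective sequencing concentration of a read-tag library fraction.

    Empirical coverage-normalization formula:
    ``C_seq = molarity * (-0.0124 * (size - 215) + 10.332)`` with molarity in
    pmol/L and size in bp.  The formula was validated for 500-950 bp
    fractions; outside that range a warning is emitted.
    """
    if peak_molarity < 0:
        raise ValueError("peak molarity must be non-negative")
    if peak_size <= 0:
        raise ValueError("peak size must be positive")
    factor = -0.0124 * (peak_size - 215.0) + 10.332
    if factor <= 0:
        raise ValueError(
            f"size factor {factor:.4f} <= 0 at {peak_size} bp; formula extrapolated "
            "beyond validity")
    if not (500.0 <= peak_size <= 950.0):
        warnings.warn(
            f"peak size {peak_size} bp outside the validated 500-950 bp range",
            stacklevel=2)
    return peak_molarity * factor


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (full header, uppercase sequence) from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description if rec.description else rec.id
        yield header, clean_sequence(str(rec.seq))


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]],
                wrap: int | None = 80) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            if wrap:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i:i + wrap] + "\n")
            else:
                fh.write(seq + "\n")


def read_reference_fasta(path: str | Path, dialect: str = "sintax",
                         prefix: str | None = None) -> list[ReferenceRecord]:
    """Read a taxonomy-annotated reference FASTA (SINTAX headers)."""
    out = []
    for header, seq in read_fasta(path):
        if ";tax=" in header:
            rec_id, tax = parse_taxonomy(header, "sintax", prefix=prefix)
        else:
            rec_id, tax = header.split()[0], TaxonomyPath()
        out.append(ReferenceRecord(id=rec_id, sequence=seq, taxonomy=tax))
    return out


def write_reference_fasta(path: str | Path, records: Sequence[ReferenceRecord],
                          dialect: str = "sintax", wrap: int | None = 80) -> None:
    write_fasta(path, ((format_taxonomy(r.id, r.taxonomy, dialect="sintax"), r.sequence)
                       for r in records), wrap=wrap)


def write_qiime_taxonomy(path: str | Path, records: Sequence[ReferenceRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(format_taxonomy(r.id, r.taxonomy, dialect="qiime") + "\n")


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV count table (rows = ASV ids, columns = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.astype(int)


def write_count_table(path: str | Path, counts: pd.DataFrame,
                      header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        counts.to_csv(fh, sep="\t")


def read_amplicon_dataset(fasta: str | Path, table: str | Path) -> AmpliconDataset:
    seqs = {h.split()[0]: s for h, s in read_fasta(fasta)}
    return AmpliconDataset(sequences=seqs, counts=read_count_table(table))
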
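from __future__ import annotations

import numpy as np
import pytest

from ecotaxdb.builder import BuildConfig, build_database
from ecotaxdb.core import (
    INHERITED,
    V5V7_PAIR,
    ReferenceRecord,
    TaxonomyPath,
    reverse_complement,
)
from ecotaxdb.simulate import SimSpec, simulate_reference

SMALL_COUNTS = {"species": 6, "genus": 5, "family": 3, "order": 2,
                "class": 2, "phylum": 2, "none": 2}


def random_dna(rng: np.random.Generator, n: int, forbid_runs: bool = False) -> str:
    """Random ACGT string; optionally reject homopolymer 8-runs of A or T so a
    poly-A/poly-T query shares no k-mer with it."""
    while True:
        s = "".join(rng.choice(list("ACGT"), n))
        if not forbid_runs or ("AAAAAAAA" not in s and "TTTTTTTT" not in s):
            return s


@pytest.fixture(scope="session")
def small_sim():
    """A compact planted-truth simulation shared across module tests."""
    spec = SimSpec(seed=1, novelty_counts=dict(SMALL_COUNTS), n_phyla=2,
                   families_per_order=1, genera_per_family=2,
                   species_per_genus=2)
    universal, reads, truth = simulate_reference(spec)
    return spec, universal, reads, truth


@pytest.fixture(scope="session")
def small_db(small_sim):
    spec, universal, reads, truth = small_sim
    records, report = build_database(reads, universal, BuildConfig(prefix="SIM"))
    return records, report


def make_toy_db(seed: int = 7, n_genera: int = 4, species_per_genus: int = 2,
                core_len: int = 120, flank: int = 60) -> list[ReferenceRecord]:
    """Hand-built database: one record per species, same family, unique
    amplicon cores, V5-V7 primer sites planted, complete taxonomy."""
    rng = np.random.default_rng(seed)
    fwd = V5V7_PAIR.forward.replace("M", "A").replace("K", "G")
    rev_rc = reverse_complement(V5V7_PAIR.reverse)
    records = []
    k = 0
    for g in range(n_genera):
        for s in range(species_per_genus):
            k += 1
            core = random_dna(rng, core_len, forbid_runs=True)
            seq = (random_dna(rng, flank, forbid_runs=True) + fwd + core
                   + rev_rc + random_dna(rng, flank, forbid_runs=True))
            tax = TaxonomyPath(
                ("Bacteria", "ToyPhylum", "ToyClass", "ToyOrder", "ToyFamily",
                 f"ToyGenus{g + 1}", f"ToySpecies{k}"),
                (INHERITED,) * 7)
            records.append(ReferenceRecord(id=f"TOY{k}", sequence=seq,
                                           taxonomy=tax))
    return records


@pytest.fixture(scope="session")
def toy_db():
    return make_toy_db()
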
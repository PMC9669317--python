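import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecotaxdb.classifier import ClassifierParams, train_index
from ecotaxdb.core import (
    RANKS,
    V5V7_PAIR,
    AmpliconDataset,
    ReferenceRecord,
    TaxonomyPath,
    ThresholdTable,
)
from ecotaxdb.evaluation import (
    classification_rate,
    coverage_eval,
    extract_insilico_asvs,
    resolution_eval,
    sequence_novelty,
    taxonomy_novelty,
)

from conftest import make_toy_db, random_dna

THRESHOLDS = ThresholdTable()
THR_RANKS = ["phylum", "class", "order", "family", "genus", "species"]


def _db_with_identities(idents):
    rng = np.random.default_rng(0)
    out = []
    for i, ident in enumerate(idents):
        rec = ReferenceRecord(id=f"FLASV{i + 1}", sequence=random_dna(rng, 60),
                              best_hit_identity=ident)
        out.append(rec)
    return out


class TestSequenceNovelty:
    def test_mixed_identities(self):
        nov = sequence_novelty(_db_with_identities([99.0, 98.0, 90.0, 80.0]))
        expected = {"species": 3, "genus": 2, "family": 1, "order": 1,
                    "class": 0, "phylum": 0}
        for rank, count in expected.items():
            assert nov.loc[rank, "novel_sequences"] == count
        assert nov.loc["species", "percent"] == pytest.approx(75.0)

    def test_all_known(self):
        nov = sequence_novelty(_db_with_identities([100.0] * 5))
        assert (nov["novel_sequences"] == 0).all()

    def test_all_novel(self):
        nov = sequence_novelty(_db_with_identities([50.0] * 5))
        assert (nov["novel_sequences"] == 5).all()

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=300, deadline=None)
    def test_nestedness(self, idents):
        """Novelty categories are nested: counts never decrease with rank."""
        nov = sequence_novelty(_db_with_identities(idents))
        counts = [nov.loc[r, "novel_sequences"] for r in THR_RANKS]
        assert counts == sorted(counts)


class TestTaxonomyNovelty:
    def _rec(self, names, i=1):
        return ReferenceRecord(id=f"r{i}", sequence="ACGTACGTAC",
                               taxonomy=TaxonomyPath.from_names(names, prefix="ECO"))

    def test_all_placeholder_species_is_100_percent(self):
        db = [self._rec(["Bacteria", "P", "C", "O", "F", "G", f"ECO_s_{i}"], i)
              for i in range(1, 4)]
        tn = taxonomy_novelty(db)
        assert tn.loc["species", "percent"] == 100.0

    def test_fully_inherited_is_zero(self):
        db = [self._rec(["Bacteria", "P", "C", "O", "F", "G", "S"])]
        assert (taxonomy_novelty(db)["denovo_taxa"] == 0).all()

    def test_two_of_ten_genera(self):
        db = []
        for i in range(1, 9):
            db.append(self._rec(["Bacteria", "P", "C", "O", "F", f"G{i}", f"S{i}"], i))
        for i in (9, 10):
            db.append(self._rec(["Bacteria", "P", "C", "O", "F",
                                 f"ECO_g_{i}", f"ECO_s_{i}"], i))
        tn = taxonomy_novelty(db)
        assert tn.loc["genus", "denovo_taxa"] == 2
        assert tn.loc["genus", "percent"] == pytest.approx(20.0)


def _dataset(seqs, counts):
    ids = [f"ASV{i + 1}" for i in range(len(seqs))]
    table = pd.DataFrame(counts, index=ids,
                         columns=[f"S{j + 1}" for j in range(len(counts[0]))])
    return AmpliconDataset(sequences=dict(zip(ids, seqs)), counts=table)


class TestCoverage:
    def _db_and_asvs(self):
        rng = np.random.default_rng(1)
        refs = [ReferenceRecord(id=f"R{i}", sequence=random_dna(rng, 400))
                for i in range(3)]
        exact = refs[0].sequence[50:250]          # identity 100
        near = list(refs[1].sequence[50:250])     # one substitution: 99.5
        near[100] = {"A": "C", "C": "G", "G": "T", "T": "A"}[near[100]]
        far = random_dna(rng, 200)                # unrelated
        return refs, [exact, "".join(near), far]

    def test_fraction_at_99_cut(self):
        refs, seqs = self._db_and_asvs()
        ds = _dataset(seqs, [[100], [100], [100]])
        res = coverage_eval(ds, refs)
        assert res.per_sample.loc["S1", "high_identity_fraction"] == \
            pytest.approx(2 / 3)
        assert res.per_sample.loc["S1", "coverage"] == pytest.approx(1.0)

    def test_verbatim_members_all_high_identity(self):
        rng = np.random.default_rng(2)
        refs = [ReferenceRecord(id=f"R{i}", sequence=random_dna(rng, 300))
                for i in range(4)]
        ds = _dataset([r.sequence for r in refs], [[10], [10], [10], [10]])
        res = coverage_eval(ds, refs)
        assert res.mean_fraction == 1.0

    def test_low_abundance_asv_excluded(self):
        refs, seqs = self._db_and_asvs()
        # ASV3 at 5 / 100005 = 0.005% relative abundance: below the filter
        ds = _dataset(seqs, [[60000], [40000], [5]])
        res = coverage_eval(ds, refs, min_rel_abundance=0.0001)
        assert res.per_sample.loc["S1", "kept"] == 2
        assert res.per_sample.loc["S1", "high_identity_fraction"] == 1.0

    def test_invariant_under_count_rescaling(self):
        refs, seqs = self._db_and_asvs()
        a = coverage_eval(_dataset(seqs, [[200, 30], [100, 20], [50, 10]]), refs)
        b = coverage_eval(_dataset(seqs, [[2000, 300], [1000, 200], [500, 100]]),
                          refs)
        pd.testing.assert_frame_equal(a.per_sample, b.per_sample)

    def test_empty_sample_reports_missing(self):
        refs, seqs = self._db_and_asvs()
        ds = _dataset(seqs, [[100, 0], [100, 0], [100, 0]])
        res = coverage_eval(ds, refs)
        assert np.isnan(res.per_sample.loc["S2", "high_identity_fraction"])


class TestClassificationRate:
    def test_mixed_verbatim_and_unrelated(self):
        db = make_toy_db(seed=21, n_genera=3, species_per_genus=2)
        verbatim = [r.sequence for r in db]          # 6 members
        unrelated = ["A" * 150, "T" * 150, "A" * 151, "T" * 151]
        ds = _dataset(verbatim + unrelated, [[50]] * 10)
        res = classification_rate(ds, db, ClassifierParams(seed=9))
        assert res.genus_fraction == pytest.approx(0.6)
        assert res.species_fraction == pytest.approx(0.6)

    def test_all_verbatim(self):
        db = make_toy_db(seed=22, n_genera=2, species_per_genus=2)
        ds = _dataset([r.sequence for r in db], [[10]] * 4)
        res = classification_rate(ds, db, ClassifierParams(seed=9))
        assert res.genus_fraction == 1.0 and res.species_fraction == 1.0

    def test_all_unrelated(self):
        db = make_toy_db(seed=23, n_genera=2, species_per_genus=2)
        ds = _dataset(["A" * 120, "T" * 120], [[10], [10]])
        res = classification_rate(ds, db, ClassifierParams(seed=9))
        assert res.genus_fraction == 0.0 and res.species_fraction == 0.0


class TestInsilicoExtraction:
    def test_cores_linked_to_parents(self, toy_db):
        amplicons, failed = extract_insilico_asvs(toy_db, V5V7_PAIR)
        assert not failed
        assert [p for p, _ in amplicons] == [r.id for r in toy_db]
        for parent, core in amplicons:
            rec = next(r for r in toy_db if r.id == parent)
            assert core in rec.sequence and len(core) == 120

    def test_record_without_site_listed_non_amplifiable(self, toy_db):
        rng = np.random.default_rng(3)
        bad = ReferenceRecord(id="NOSITE", sequence=random_dna(rng, 300),
                              taxonomy=toy_db[0].taxonomy)
        amplicons, failed = extract_insilico_asvs(list(toy_db) + [bad], V5V7_PAIR)
        assert failed == ["NOSITE"]

    def test_duplicate_cores_kept_redundantly(self, toy_db):
        db = list(toy_db)
        # graft record 1's amplicon region into record 2
        a, _ = extract_insilico_asvs(db[:2], V5V7_PAIR)
        seq2 = db[1].sequence.replace(a[1][1], a[0][1])
        db[1] = ReferenceRecord(id=db[1].id, sequence=seq2,
                                taxonomy=db[1].taxonomy)
        amplicons, _ = extract_insilico_asvs(db[:2], V5V7_PAIR)
        assert amplicons[0][1] == amplicons[1][1]
        assert amplicons[0][0] != amplicons[1][0]


class TestResolution:
    def test_unique_cores_fully_correct(self, toy_db):
        amplicons, _ = extract_insilico_asvs(toy_db, V5V7_PAIR)
        params = ClassifierParams(strand="plus", seed=5)
        report = resolution_eval(amplicons, toy_db, params)
        assert report.fractions.loc["genus", "correct"] == 1.0
        assert report.fractions.loc["species", "correct"] == 1.0

    def test_collided_species_cannot_both_be_correct(self, toy_db):
        db = list(toy_db)
        # TOY1 and TOY2 share a genus; collapse TOY2's core onto TOY1's
        a, _ = extract_insilico_asvs(db[:2], V5V7_PAIR)
        seq2 = db[1].sequence.replace(a[1][1], a[0][1])
        db[1] = ReferenceRecord(id=db[1].id, sequence=seq2,
                                taxonomy=db[1].taxonomy)
        amplicons, _ = extract_insilico_asvs(db, V5V7_PAIR)
        params = ClassifierParams(strand="plus", seed=5)
        report = resolution_eval(amplicons, db, params)
        n = report.n_asvs
        assert report.fractions.loc["species", "correct"] <= (n - 1) / n
        assert report.fractions.loc["genus", "correct"] == 1.0
        per = report.per_asv.set_index("parent")
        assert not (per.loc["TOY1", "species"] == "correct") or \
            not (per.loc["TOY2", "species"] == "correct")

    def test_fractions_partition_unity(self, toy_db):
        amplicons, _ = extract_insilico_asvs(toy_db, V5V7_PAIR)
        report = resolution_eval(amplicons, toy_db,
                                 ClassifierParams(strand="plus", seed=5))
        for rank in ("genus", "species"):
            total = report.fractions.loc[rank].sum()
            assert total == pytest.approx(1.0, abs=1e-9)
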
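"""Trait-database parsing, validation and summary semantics."""

import math

import pytest

from traitscope._schema import Schema
from traitscope.traitdb import (
    QuantRange,
    TaxonRecord,
    TraitDatabase,
    read_trait_table,
    summarize_quantitative,
    trait_prevalence,
    validate,
    write_trait_table,
)

from conftest import write_tsv

HEADER = ["species", "phylum", "catalase", "oxidase", "oxygen_use", "temperature_min", "temperature_max", "temperature_range"]


def _table(tmp_path, rows, header=None):
    return write_tsv(tmp_path / "db.tsv", header or HEADER, rows)


class TestParsing:
    def test_alias_map(self, tmp_path):
        path = _table(
            tmp_path,
            [["Staphylococcus epidermidis", "Firmicutes", "+", "ND", "facultative", "20", "45", ""]],
        )
        db, report = read_trait_table(path)
        rec = db["Staphylococcus epidermidis"]
        assert rec.binary_traits["catalase"] == "positive"
        assert rec.binary_traits["oxidase"] == "unknown"
        assert rec.temperature.range == pytest.approx(25.0)
        assert rec.temperature.range_derived
        assert ("Staphylococcus epidermidis", "temperature") in report.derived_ranges

    def test_variable_cell_sets_strain_flag(self, tmp_path):
        path = _table(tmp_path, [["X a", "F", "v", "-", "", "", "", ""]])
        db, _ = read_trait_table(path)
        assert db["X a"].binary_traits["catalase"] == "unknown"
        assert "catalase" in db["X a"].strain_variation_flags

    def test_duplicate_species_rejected(self, tmp_path):
        path = _table(tmp_path, [["X a", "F", "+", "-", "", "", "", ""]] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            read_trait_table(path)

    def test_unknown_column_rejected_unless_ignored(self, tmp_path):
        header = HEADER + ["mystery"]
        path = _table(tmp_path, [["X a", "F", "+", "-", "", "", "", "", "?"]], header)
        with pytest.raises(ValueError, match="unknown columns"):
            read_trait_table(path)
        db, _ = read_trait_table(path, ignore_extra_columns=True)
        assert len(db) == 1

    def test_vocabulary_violation_names_row_and_column(self, tmp_path):
        path = _table(tmp_path, [["X a", "F", "+", "-", "psychic", "", "", ""]])
        with pytest.raises(ValueError, match="X a.*oxygen_use|oxygen_use.*X a"):
            read_trait_table(path)

    def test_multivalued_categorical_cell(self, tmp_path):
        header = ["species", "phylum", "aggregation"]
        path = _table(tmp_path, [["X a", "F", "singly;clumps"]], header)
        db, _ = read_trait_table(path)
        assert db["X a"].categorical_traits["aggregation"] == {"singly", "clumps"}

    def test_conflicting_explicit_range_kept(self, tmp_path):
        path = _table(tmp_path, [["X a", "F", "", "", "", "20", "45", "30"]])
        db, report = read_trait_table(path)
        assert db["X a"].temperature.range == pytest.approx(30.0)  # stored value wins
        assert report.conflicting_ranges
        issues = validate(db)
        assert any("range" in i.column for i in issues.warnings)

    def test_roundtrip_identical(self, tmp_path, small_db_pair):
        db, _, _ = small_db_pair
        p1, p2 = tmp_path / "one.tsv", tmp_path / "two.tsv"
        write_trait_table(db, p1)
        db2, _ = read_trait_table(p1)
        write_trait_table(db2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert db2.species_names == db.species_names


class TestValidate:
    def test_optimum_outside_envelope_is_warning(self):
        rec = TaxonRecord("X a", ph=QuantRange(minimum=4.0, maximum=8.0, optimum=9.0))
        report = validate(TraitDatabase([rec]))
        assert any("optimum" in i.message for i in report.warnings)
        assert not report.errors

    def test_gc_out_of_bounds_is_error(self):
        report = validate(TraitDatabase([TaxonRecord("X a", gc_content=150.0)]))
        assert any(i.column == "gc_content" for i in report.errors)

    def test_clean_record_passes(self):
        rec = TaxonRecord(
            "X a",
            gc_content=50.0,
            temperature=QuantRange(minimum=20, maximum=45, optimum=37, range=25),
        )
        report = validate(TraitDatabase([rec]))
        assert report.issues == []

    def test_generated_databases_validate_clean(self, small_db_pair):
        for db in small_db_pair[:2]:
            assert validate(db).errors == []


def _binary_db(states):
    recs = [
        TaxonRecord(f"S sp{i}", binary_traits={"catalase": s}) for i, s in enumerate(states)
    ]
    return TraitDatabase(recs)


class TestPrevalence:
    def test_known_only_denominator(self):
        db = _binary_db(["positive"] * 3 + ["negative"] + ["unknown"] * 2)
        res = trait_prevalence(db, None, "catalase")
        assert (res.k, res.n, res.proportion) == (3, 4, 0.75)

    def test_all_unknown_is_flagged_undefined(self):
        db = _binary_db(["unknown"] * 4)
        res = trait_prevalence(db, None, "catalase")
        assert not res.defined and res.proportion is None

    def test_unknown_trait_raises(self):
        with pytest.raises(KeyError):
            trait_prevalence(_binary_db(["positive"]), None, "telepathy")

    def test_taxon_set_restriction_and_bounds(self, small_db_pair):
        db, _, _ = small_db_pair
        subset = db.species_names[:30]
        res = trait_prevalence(db, subset, "spore_formation")
        assert 0 <= res.k <= res.n <= len(subset)

    def test_single_valued_categorical_levels_sum_to_one(self, small_db_pair):
        db, _, _ = small_db_pair
        vocab = db.schema.categorical_vocabularies["oxygen_use"]
        results = [trait_prevalence(db, None, "oxygen_use", lvl) for lvl in vocab]
        total = sum(r.proportion for r in results if r.defined)
        assert total == pytest.approx(1.0)

    def test_substrate_prevalence(self, small_db_pair):
        db, _, _ = small_db_pair
        res = trait_prevalence(db, None, "glucose")
        assert res.defined and 0.8 <= res.proportion <= 1.0


class TestQuantSummary:
    def test_mean_of_known_values(self):
        recs = [
            TaxonRecord("A a", gc_content=30.0),
            TaxonRecord("B b", gc_content=40.0),
            TaxonRecord("C c"),
        ]
        s = summarize_quantitative(TraitDatabase(recs), None, "gc_content")
        assert (s.n, s.mean) == (2, pytest.approx(35.0))
        assert s.sd == pytest.approx(math.sqrt(50.0))

    def test_no_known_values_flagged(self):
        s = summarize_quantitative(TraitDatabase([TaxonRecord("A a")]), None, "ph_optimum")
        assert not s.defined and s.mean is None

    def test_derived_range_mean_equals_max_minus_min(self, small_db_pair):
        db, _, _ = small_db_pair
        both_known = [
            s
            for s in db.species_names
            if db[s].temperature.minimum is not None and db[s].temperature.maximum is not None
        ]
        s_range = summarize_quantitative(db, both_known, "temperature_range")
        s_min = summarize_quantitative(db, both_known, "temperature_min")
        s_max = summarize_quantitative(db, both_known, "temperature_max")
        assert s_range.mean == pytest.approx(s_max.mean - s_min.mean)

    def test_unknown_variable_raises(self, small_db_pair):
        with pytest.raises(KeyError):
            summarize_quantitative(small_db_pair[0], None, "volume")
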
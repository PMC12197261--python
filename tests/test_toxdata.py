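"""Record screening, geometric-mean aggregation and the ACR."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from ferriqc import (
    TestType,
    ToxicityRecord,
    ValidationError,
    compute_acr,
    genus_values,
    geometric_mean,
    screen_records,
    species_values,
)
from ferriqc.criteria import round_sig
from ferriqc.toxdata import read_toxicity_csv, write_toxicity_csv


def rec(species="Testus species", genus="Testus", test_type="acute",
        endpoint="LC50", conc=100.0, source="S1", **kw):
    return ToxicityRecord(
        species_latin=species, genus=genus, test_type=TestType(test_type),
        endpoint=endpoint, concentration=conc, source_id=source, **kw,
    )


class TestGeometricMean:
    @pytest.mark.parametrize(
        "values, expected_3sf",
        [
            ([100, 10], 31.6),        # Lecane genus value
            ([6000, 3000], 4240),     # Chlorella genus value
            ([123], 123),             # identity on a singleton
            ([10, 40], 20),
        ],
    )
    def test_known_values(self, values, expected_3sf):
        assert round_sig(geometric_mean(values)) == pytest.approx(expected_3sf)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            geometric_mean([])

    def test_nonpositive_entry_named_in_error(self):
        with pytest.raises(ValidationError, match="-5"):
            geometric_mean([10.0, -5.0])

    @settings(deadline=None, max_examples=50)
    @given(
        values=st.lists(st.floats(1e-3, 1e9), min_size=1, max_size=12),
        c=st.floats(1e-3, 1e6),
    )
    def test_scale_equivariance_and_bounds(self, values, c):
        gm = geometric_mean(values)
        assert min(values) * (1 - 1e-9) <= gm <= max(values) * (1 + 1e-9)
        assert geometric_mean([c * v for v in values]) == pytest.approx(
            c * gm, rel=1e-9
        )

    @settings(deadline=None, max_examples=30)
    @given(st.permutations(list(range(1, 8))))
    def test_order_independence(self, perm):
        base = geometric_mean(list(range(1, 8)))
        assert geometric_mean(perm) == pytest.approx(base, rel=1e-12)


class TestScreening:
    def test_reference_table_fully_accepted(self, fixture_records):
        report = screen_records(fixture_records)
        assert len(report.accepted) == 47
        assert report.rejected == []

    @pytest.mark.parametrize(
        "bad, rule",
        [
            (dict(conc=0.0), "nonpositive concentration"),
            (dict(endpoint="NOEC"), "endpoint not allowed for acute"),
            (dict(species=""), "missing species name"),
            (dict(exclude=True), "excluded by curator flag"),
        ],
    )
    def test_rejection_rules(self, bad, rule):
        report = screen_records([rec(), rec(**bad)])
        assert len(report.accepted) == 1
        assert len(report.rejected) == 1
        assert report.rejected[0][2] == rule

    def test_partition_preserved(self):
        records = [rec(), rec(conc=-1), rec(endpoint="IC50")]
        report = screen_records(records)
        assert len(report.accepted) + len(report.rejected) == len(records)

    def test_chronic_accepts_effect_and_lethal_endpoints(self):
        recs = [rec(test_type="chronic", endpoint=e)
                for e in ("NOEC", "LOEC", "MATC", "EC50", "LC50")]
        assert len(screen_records(recs).accepted) == 5


class TestAggregation:
    def test_species_counts(self, acute_species, chronic_species):
        assert len(acute_species) == 18
        assert len(chronic_species) == 4

    def test_daphnia_magna_species_value(self, acute_species):
        dm = next(s for s in acute_species if s.species_latin == "Daphnia magna")
        assert dm.n_records == 3
        assert round_sig(dm.value) == pytest.approx(24800)

    def test_single_record_species_is_identity(self, acute_species):
        nais = next(s for s in acute_species if s.species_latin == "Nais elinguis")
        assert nais.value == pytest.approx(123)

    def test_pimephales_chronic_value(self, chronic_species):
        pp = next(s for s in chronic_species
                  if s.species_latin == "Pimephales promelas")
        assert round_sig(pp.value) == pytest.approx(569)

    def test_genus_counts(self, acute_species, chronic_species):
        assert len(genus_values(acute_species)) == 17
        assert len(genus_values(chronic_species)) == 4

    @pytest.mark.parametrize(
        "genus, expected",
        [
            ("Ceriodaphnia", 33200), ("Daphnia", 15600), ("Gambusia", 99200),
            ("Salmo", 36300), ("Tubifex", 94300),
        ],
    )
    def test_published_acute_genus_values(self, acute_species, genus, expected):
        gv = {g.genus: g.value for g in genus_values(acute_species)}
        assert round_sig(gv[genus]) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "genus, expected",
        [("Chlorella", 4240), ("Daphnia", 958), ("Lecane", 31.6),
         ("Pimephales", 569)],
    )
    def test_published_chronic_genus_values(self, chronic_species, genus, expected):
        gv = {g.genus: g.value for g in genus_values(chronic_species)}
        assert round_sig(gv[genus]) == pytest.approx(expected)

    def test_single_species_genus_equals_species_value(self, acute_species):
        gv = {g.genus: g for g in genus_values(acute_species)}
        lone = next(s for s in acute_species if s.genus == "Xenopus")
        assert gv["Xenopus"].value == lone.value
        assert gv["Xenopus"].n_species == 1

    def test_genus_value_bounded_by_members(self, acute_species):
        for g in genus_values(acute_species):
            members = [s.value for s in acute_species if s.genus == g.genus]
            assert min(members) <= g.value * (1 + 1e-12)
            assert g.value <= max(members) * (1 + 1e-12)

    def test_inconsistent_genus_mapping_rejected(self):
        records = [rec(), rec(genus="Othergenus")]
        with pytest.raises(ValidationError, match="two genera"):
            species_values(records, TestType.acute)


class TestAcr:
    def test_reference_same_source_acr(self, acute_records, chronic_records):
        est = compute_acr(acute_records, chronic_records, "same_source")
        ratios = {p.species_latin: p.ratio for p in est.per_species}
        assert ratios["Daphnia pulex"] == pytest.approx(15.9, abs=0.05)
        assert ratios["Pimephales promelas"] == pytest.approx(38.3, abs=0.05)
        assert est.overall == pytest.approx(24.7, rel=0.005)

    def test_all_records_policy_differs(self, acute_records, chronic_records):
        est = compute_acr(acute_records, chronic_records, "all_records")
        # Daphnia pulex acute gm over all five records drags the ACR down
        assert est.overall < 24.0

    def test_identical_sets_give_unity(self):
        acute = [rec(endpoint="LC50", conc=50.0)]
        chronic = [rec(test_type="chronic", endpoint="NOEC", conc=50.0)]
        assert compute_acr(acute, chronic).overall == pytest.approx(1.0)

    def test_overall_is_gm_of_ratios(self):
        acute = [rec(species="A sp", genus="A", conc=100.0),
                 rec(species="B sp", genus="B", conc=400.0)]
        chronic = [
            rec(species="A sp", genus="A", test_type="chronic",
                endpoint="NOEC", conc=10.0),
            rec(species="B sp", genus="B", test_type="chronic",
                endpoint="NOEC", conc=10.0),
        ]
        est = compute_acr(acute, chronic)
        assert sorted(p.ratio for p in est.per_species) == pytest.approx(
            [10.0, 40.0]
        )
        assert est.overall == pytest.approx(20.0)
        assert min(p.ratio for p in est.per_species) <= est.overall
        assert est.overall <= max(p.ratio for p in est.per_species)

    def test_no_paired_species_is_an_error(self):
        with pytest.raises(ValidationError, match="ACR not computable"):
            compute_acr(
                [rec(species="A sp", genus="A")],
                [rec(species="B sp", genus="B", test_type="chronic",
                     endpoint="NOEC")],
            )

    def test_shared_source_required_under_same_source(self):
        acute = [rec(species="A sp", genus="A", source="S1"),
                 rec(species="B sp", genus="B", source="S2")]
        chronic = [
            rec(species="A sp", genus="A", test_type="chronic",
                endpoint="NOEC", conc=10.0, source="S9"),
            rec(species="B sp", genus="B", test_type="chronic",
                endpoint="NOEC", conc=10.0, source="S2"),
        ]
        est = compute_acr(acute, chronic, "same_source")
        assert [p.species_latin for p in est.per_species] == ["B sp"]


class TestCsvIo:
    def test_unit_conversion_on_read(self, tmp_path):
        p = tmp_path / "tox.csv"
        p.write_text(
            "species,genus,test_type,endpoint,value,unit,source_id\n"
            "A sp,A,acute,LC50,1.5,mg/L,S1\n"
        )
        (record,) = read_toxicity_csv(p)
        assert record.concentration == pytest.approx(1500.0)

    def test_thousands_separator_rejected(self, tmp_path):
        p = tmp_path / "tox.csv"
        p.write_text(
            "species,genus,test_type,endpoint,value,unit,source_id\n"
            'A sp,A,acute,LC50,"1,500",ug/L,S1\n'
        )
        with pytest.raises(ValidationError, match="thousands"):
            read_toxicity_csv(p)

    def test_round_trip(self, tmp_path, fixture_records):
        out = tmp_path / "roundtrip.csv"
        write_toxicity_csv(fixture_records, out)
        again = read_toxicity_csv(out)
        assert again == fixture_records
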
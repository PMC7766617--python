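import warnings
from collections import Counter

import pytest

from oleomics import feature_io, synthdata
from oleomics.feature_io import (
    Feature,
    FixtureIntegrityError,
    Ms2Spectrum,
    ValidationError,
    load_table2_fixture,
    parse_range_cell,
    read_feature_table,
    read_mgf,
    write_feature_table,
    write_mgf,
)


class TestFeature:
    def test_negative_mz_rejected(self):
        with pytest.raises(ValidationError):
            Feature("f", -1.0, 10.0, "-", {"s1": 1.0})

    def test_requires_intensities(self):
        with pytest.raises(ValidationError):
            Feature("f", 100.0, 10.0, "-", {})

    def test_bad_polarity(self):
        with pytest.raises(ValidationError):
            Feature("f", 100.0, 10.0, "neg", {"s1": 1.0})


class TestFeatureTableIO:
    def test_toy_round_trip(self, tmp_path):
        path = tmp_path / "toy.csv"
        path.write_text(
            "feature_id,mz,rt,s1,s2,s3\n"
            "a,100.5,10,1,2,3\n"
            "b,200.25,20,4,5,6\n"
            "c,300.125,30,7,8,9\n")
        feats = read_feature_table(path, "-")
        assert len(feats) == 3
        assert feats[1].intensities == {"s1": 4.0, "s2": 5.0, "s3": 6.0}

    def test_negative_mz_in_file(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("feature_id,mz,rt,s1\na,-5,10,1\n")
        with pytest.raises(ValidationError):
            read_feature_table(path, "-")

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("feature_id,rt,s1\na,10,1\n")
        with pytest.raises(ValidationError, match="missing column"):
            read_feature_table(path, "-")

    def test_non_numeric_cell(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("feature_id,mz,rt,s1\na,100,ten,1\n")
        with pytest.raises(ValidationError, match="non-numeric"):
            read_feature_table(path, "-")

    def test_duplicate_id(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("feature_id,mz,rt,s1\na,100,10,1\na,101,10,1\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_feature_table(path, "-")

    def test_synthetic_round_trip(self, tmp_path, synth_default):
        # write-then-read oracle
        path = tmp_path / "synth.csv"
        write_feature_table(synth_default.features_neg, path)
        back = read_feature_table(path, "-")
        assert len(back) == len(synth_default.features_neg)
        by_id = {f.feature_id: f for f in back}
        for f in synth_default.features_neg:
            g = by_id[f.feature_id]
            assert g.mz == f.mz and g.rt == f.rt
            assert g.intensities == dict(f.intensities)


class TestMgf:
    def test_single_block(self, tmp_path):
        path = tmp_path / "one.mgf"
        path.write_text(
            "BEGIN IONS\nPEPMASS=539.1770\nCHARGE=1-\nRTINSECONDS=381\n"
            "377.1242 100\n345.0980 40\nEND IONS\n")
        spectra = read_mgf(path)
        assert len(spectra) == 1
        assert spectra[0].polarity == "-"
        assert spectra[0].peaks[0][1] == pytest.approx(40 / 100)

    def test_unsorted_peaks_sorted_on_load(self, tmp_path):
        path = tmp_path / "u.mgf"
        path.write_text(
            "BEGIN IONS\nPEPMASS=300\nCHARGE=1+\n"
            "250.0 10\n100.0 50\n180.0 30\nEND IONS\n")
        (s,) = read_mgf(path)
        assert list(s.mzs) == sorted(s.mzs)

    def test_missing_pepmass_is_error(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text("BEGIN IONS\nCHARGE=1-\n100 1\nEND IONS\n")
        with pytest.raises(ValidationError):
            read_mgf(path)

    def test_empty_spectrum_warns_not_errors(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("BEGIN IONS\nPEPMASS=300\nCHARGE=1-\nEND IONS\n")
        with pytest.warns(UserWarning):
            spectra = read_mgf(path)
        assert len(spectra) == 1 and not spectra[0].peaks

    def test_round_trip_6dp(self, tmp_path):
        spectra = [
            Ms2Spectrum(539.177, "-", 381.0,
                        ((377.124199, 1.0), (345.098042, 0.4))),
            Ms2Spectrum(185.0808, "+", 292.0, ((167.0703, 1.0),)),
        ]
        path = tmp_path / "rt.mgf"
        write_mgf(spectra, path)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            back = read_mgf(path)
        for orig, new in zip(spectra, back):
            assert new.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-6)
            for (m1, i1), (m2, i2) in zip(orig.peaks, new.peaks):
                assert m2 == pytest.approx(m1, abs=1e-6)
                assert i2 == pytest.approx(i1, abs=1e-6)


class TestTable1Fixture:
    def test_row_count(self, table1):
        assert len(table1) == 202

    def test_level_census(self, table1):
        census = Counter(r.level for r in table1)
        assert census == {"I": 15, "II": 66, "III": 121}

    def test_generic_unknown_count(self, table1):
        assert sum(r.is_generic_unknown for r in table1) == 21

    def test_hydroxytyrosol_row(self, table1):
        row = next(r for r in table1 if r.compound_id == "C050")
        assert row.formula.hill() == "C8H10O3"
        assert row.level == "I"
        assert any(abs(mz - 153.0558) < 1e-6 for mz, _ in row.ion_entries)

    def test_every_label_parses_or_is_flagged(self, table1):
        for row in table1:
            for _, parsed in row.parsed_ions:
                assert parsed.kind in ("adduct", "fragment", "other")

    def test_checksum_tamper_detected(self):
        with pytest.raises(FixtureIntegrityError):
            feature_io._verify_checksum("table1_annotations.tsv", "tampered\n")


class TestTable2Fixture:
    def test_verbascoside_params(self):
        row = next(r for r in load_table2_fixture() if r.analyte == "Verbascoside")
        assert row.slope == 14737
        assert row.ldr == (0.5, 1536)
        assert row.detector == "DAD"
        assert row.r2 == 1.000


class TestTable3Fixture:
    def test_shape(self, table3):
        assert len(table3) == 26 * 14

    def test_hydroxytyrosol_in_H(self, table3):
        r = next(x for x in table3
                 if x.compound == "Hydroxytyrosol" and x.product == "H")
        assert (r.lo, r.hi) == (74.83, 88.2)
        assert r.censoring == "measured"

    def test_verbascoside_in_K_not_detected(self, table3):
        r = next(x for x in table3
                 if x.compound == "Verbascoside" and x.product == "K")
        assert r.censoring == "not_detected" and r.lo == r.hi == 0

    @pytest.mark.parametrize("cell, expected", [
        ("0.19-0.21", (0.19, 0.21, "measured")),
        ("ND", (0.0, 0.0, "not_detected")),
        ("<LOQ", (0.0, 0.0, "below_loq")),
        ("LOQ-0.51", (0.0, 0.51, "mixed")),
        ("ND-0.03", (0.0, 0.03, "mixed")),
        ("ND-<LOQ", (0.0, 0.0, "mixed")),
        ("0-0.01", (0.0, 0.01, "measured")),
    ])
    def test_range_cell_grammar(self, cell, expected):
        assert parse_range_cell(cell) == expected

    def test_unparseable_cell(self):
        with pytest.raises(ValidationError):
            parse_range_cell("about 3")


class TestTable4Fixture:
    def test_14_products(self, table4):
        assert len(table4) == 14

    def test_product_J_dose(self, table4):
        j = next(p for p in table4 if p.product == "J")
        assert j.daily_dose_g == 72.8
        assert j.plant_part == "leaves"

    def test_plant_parts(self, table4):
        parts = Counter(p.plant_part for p in table4)
        assert parts == {"buds": 3, "leaves": 4, "leaves+fruit": 3, "fruit": 4}

    def test_doses_positive(self, table4):
        assert all(p.daily_dose_g > 0 for p in table4)


def test_synthdata_determinism(small_library):
    a = synthdata.simulate_feature_tables(small_library, seed=7)
    b = synthdata.simulate_feature_tables(small_library, seed=7)
    assert [f.mz for f in a.features_neg] == [f.mz for f in b.features_neg]
    assert a.truth == b.truth
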
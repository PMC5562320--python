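import gzip
import logging

import pytest
from hypothesis import given, strategies as st

from chemscreen.stitch_io import (
    ChemicalLink,
    StitchParseError,
    StitchSchemaError,
    cid_flavor,
    normalize_cid,
    read_chemical_links,
    read_compound_list,
    read_gene_map,
    read_protein_links,
    write_chemical_links,
    write_protein_links,
)

CHEM_HEADER = "chemical_a\tchemical_b\tsimilarity\texperimental\tdatabase\ttextmining\tcombined_score\n"
PROT_HEADER = "protein\tchemical\texperimental\tprediction\tdatabase\ttextmining\tcombined_score\n"


def _chem_file(tmp_path, rows, name="chem.tsv"):
    path = tmp_path / name
    path.write_text(CHEM_HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))
    return path


def _prot_file(tmp_path, rows):
    path = tmp_path / "prot.tsv"
    path.write_text(PROT_HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))
    return path


class TestNormalizeCid:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("CID4033", 4033),
            ("CIDm00004033", 4033),
            ("CIDs00004033", 4033),
            ("123", 123),
            ("CID000001", 1),
        ],
    )
    def test_valid_forms(self, raw, expected):
        assert normalize_cid(raw) == expected

    @pytest.mark.parametrize("raw", ["CIDX123", "CID", "", "4033x", "cid4033"])
    def test_malformed_identifiers_rejected(self, raw):
        with pytest.raises(StitchParseError):
            normalize_cid(raw)

    def test_flavor_reported(self):
        assert cid_flavor("CIDm00004033") == "m"
        assert cid_flavor("CIDs123") == "s"
        assert cid_flavor("CID123") == ""

    @given(st.integers(min_value=1, max_value=10**8), st.integers(min_value=0, max_value=5),
           st.sampled_from(["", "m", "s"]))
    def test_prefix_and_zero_stripping_roundtrip(self, cid, zeros, flavor):
        raw = f"CID{flavor}{'0' * zeros}{cid}"
        assert normalize_cid(raw) == cid


class TestReadChemicalLinks:
    def test_positive_combined_filter(self, tmp_path):
        rows = [("CID1", "CID2", 0, 0, 0, 0, 150),
                ("CID1", "CID3", 0, 0, 0, 0, 0),
                ("CID2", "CID3", 0, 0, 0, 0, 400)]
        links = read_chemical_links(_chem_file(tmp_path, rows))
        assert len(links) == 2
        assert {l.combined for l in links} == {150, 400}

    def test_empty_file_with_header(self, tmp_path):
        assert read_chemical_links(_chem_file(tmp_path, [])) == []

    def test_both_orientations_merge_to_one_record(self, tmp_path):
        rows = [("CID1", "CID2", 10, 20, 30, 40, 500),
                ("CID2", "CID1", 10, 20, 30, 40, 500)]
        links = read_chemical_links(_chem_file(tmp_path, rows))
        assert len(links) == 1
        assert links[0].pair == (1, 2)

    def test_conflicting_duplicate_keeps_larger_combined(self, tmp_path, caplog):
        rows = [("CID1", "CID2", 0, 0, 0, 0, 300),
                ("CID2", "CID1", 0, 0, 0, 0, 700)]
        with caplog.at_level(logging.WARNING):
            links = read_chemical_links(_chem_file(tmp_path, rows))
        assert len(links) == 1 and links[0].combined == 700
        assert any("conflicting" in r.message for r in caplog.records)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chemical_a\tchemical_b\tcombined_score\nCID1\tCID2\t5\n")
        with pytest.raises(StitchSchemaError, match="missing column"):
            read_chemical_links(path)

    def test_non_integer_score_reports_line(self, tmp_path):
        rows = [("CID1", "CID2", 0, 0, 0, 0, 100),
                ("CID1", "CID3", 0, 0, 0, "high", 100)]
        with pytest.raises(StitchParseError, match="line 3"):
            read_chemical_links(_chem_file(tmp_path, rows))

    def test_gzip_supported(self, tmp_path):
        raw = CHEM_HEADER + "CID1\tCID2\t0\t0\t0\t0\t250\n"
        path = tmp_path / "chem.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(raw)
        assert len(read_chemical_links(path)) == 1

    def test_min_combined_monotonicity(self, bundle):
        counts = [len(read_chemical_links(bundle.chemical_links, min_combined=t))
                  for t in (0, 200, 400, 600, 800)]
        assert counts == sorted(counts, reverse=True)


class TestReadProteinLinks:
    def test_organism_filter_and_prefix_strip(self, tmp_path):
        rows = [("9606.ENSP000003", "CID7", 0, 0, 0, 0, 100),
                ("10090.ENSMUSP01", "CID7", 0, 0, 0, 0, 100),
                ("9606.ENSP000004", "CID8", 0, 0, 0, 0, 200)]
        links = read_protein_links(_prot_file(tmp_path, rows))
        assert {l.protein for l in links} == {"ENSP000003", "ENSP000004"}

    def test_zero_combined_dropped(self, tmp_path):
        rows = [("9606.ENSP000003", "CID7", 5, 5, 5, 5, 0)]
        assert read_protein_links(_prot_file(tmp_path, rows)) == []


def test_roundtrip_chemical_and_protein_tables(tables, tmp_path):
    """Writing a parsed table back to the dialect and re-reading is lossless."""
    cpath, ppath = tmp_path / "c.tsv", tmp_path / "p.tsv"
    write_chemical_links(tables.chemical_links, cpath)
    write_protein_links(tables.protein_links, ppath)
    assert read_chemical_links(cpath) == sorted(tables.chemical_links)
    assert read_protein_links(ppath) == sorted(tables.protein_links)


def test_every_parsed_compound_id_is_positive(tables):
    assert all(l.chem_a > 0 and l.chem_b > 0 for l in tables.chemical_links)
    assert all(l.chemical > 0 for l in tables.protein_links)
    assert tables.chemical_universe == {
        c for l in tables.chemical_links for c in l.pair
    }


def test_chemical_link_invariants():
    link = ChemicalLink(5, 2, 0, 0, 0, 0, 10)
    assert link.pair == (2, 5)  # canonical unordered order
    with pytest.raises(ValueError):
        ChemicalLink(2, 2, 0, 0, 0, 0, 10)
    with pytest.raises(ValueError):
        ChemicalLink(1, 2, 0, 0, 0, 0, 1001)


def test_compound_list_and_gene_map_readers(tmp_path):
    clist = tmp_path / "drugs.txt"
    clist.write_text("# header\nCID4033\n36314  # trailing comment\n\n")
    assert read_compound_list(clist) == {4033, 36314}

    gmap = tmp_path / "genes.tsv"
    gmap.write_text("# gene\tprotein\nEGFR\tENSP1\nEGFR\tENSP2\nTP53\tENSP3\n")
    parsed = read_gene_map(gmap)
    assert parsed == {"EGFR": frozenset({"ENSP1", "ENSP2"}), "TP53": frozenset({"ENSP3"})}
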
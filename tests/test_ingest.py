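"""Input readers: database records, the seven predictor dialects, tables."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from protoscheme.feature_model import Category, CoordinateError, VocabularyError
from protoscheme.ingest import (
    CutoffConfig,
    DialectError,
    RawFeature,
    RetrievalError,
    TableSchemaError,
    fetch_record,
    parse_db_record,
    parse_prediction_output,
    read_feature_table,
)

NETPHOS_3ROW = """# NetPhos output, dialect v1
prot 12 S AAAAA 0.900 PKC
prot 30 T BBBBB 0.500 PKA
prot 44 Y CCCCC 0.100 SRC
"""


class TestFetchRecord:
    def test_empty_accession_is_a_retrieval_error(self):
        with pytest.raises(RetrievalError):
            fetch_record("", "uniprot", offline_fixture=None)

    def test_missing_fixture_is_a_retrieval_error(self, tmp_path):
        with pytest.raises(RetrievalError):
            fetch_record("NOPE", "uniprot", offline_fixture=tmp_path)

    def test_offline_directory_lookup(self, fixture_dir, manifest):
        acc = manifest["protein"]["uniprot_accession"]
        text = fetch_record(acc, "uniprot", offline_fixture=fixture_dir)
        assert acc in text


class TestParseDbRecord:
    def test_cd45_uniprot_record_has_length_1306(self, cd45_dir):
        text = fetch_record("P08575", "uniprot", offline_fixture=cd45_dir)
        name, length, raws = parse_db_record(text, "uniprot")
        assert length == 1306
        keywords = " | ".join(r.keyword.lower() for r in raws)
        assert "signal" in keywords
        assert "transmembrane" in keywords
        assert "glycosylation" in keywords

    def test_cd45_genpept_record_has_length_1306(self, cd45_dir):
        text = fetch_record("NP_002829.3", "genpept", offline_fixture=cd45_dir)
        name, length, raws = parse_db_record(text, "genpept")
        assert length == 1306
        assert raws

    def test_generated_records_match_manifest_counts(self, fixture_dir, manifest):
        for db in ("uniprot", "genpept"):
            acc = manifest["protein"][f"{db}_accession"]
            text = fetch_record(acc, db, offline_fixture=fixture_dir)
            name, length, raws = parse_db_record(text, db)
            assert length == manifest["protein"]["length"]
            assert len(raws) == manifest["db_feature_counts"][db]

    def test_category_deselection_returns_subset(self, cd45_dir):
        text = fetch_record("P08575", "uniprot", offline_fixture=cd45_dir)
        _, _, all_raws = parse_db_record(text, "uniprot")
        _, _, only_regions = parse_db_record(text, "uniprot",
                                             selected={Category.REGION})
        assert 0 < len(only_regions) < len(all_raws)
        all_keys = {(r.keyword, r.start, r.end) for r in all_raws}
        assert all((r.keyword, r.start, r.end) in all_keys for r in only_regions)
        # regions only: every survivor classifies as a region-type key
        assert all("domain" in r.keyword.lower() or "region" in r.keyword.lower()
                   for r in only_regions)

    def test_minimal_record_with_one_carbohyd_line(self):
        text = (
            "ID   TEST_SYN                Reviewed;         100 AA.\n"
            "DE   RecName: Full=Test protein;\n"
            "FT   CARBOHYD        25\n"
            'FT                   /note="N-linked (GlcNAc...) asparagine"\n'
            "SQ   SEQUENCE   100 AA;\n"
        )
        name, length, raws = parse_db_record(text, "uniprot")
        assert (name, length, len(raws)) == ("Test protein", 100, 1)
        assert raws[0].start == raws[0].end == 25

    def test_disulfide_interval_becomes_two_sites(self):
        text = (
            "ID   TEST_SYN                Reviewed;         100 AA.\n"
            "FT   DISULFID        26..96\n"
        )
        _, _, raws = parse_db_record(text, "uniprot")
        assert [(r.start, r.end) for r in raws] == [(26, 26), (96, 96)]


class TestPredictionParsers:
    def test_netphos_rows_below_cutoff_are_dropped(self):
        raws = parse_prediction_output(NETPHOS_3ROW, "netphos",
                                       protein_length=100)
        assert len(raws) == 2  # 0.9 and 0.5 survive the 0.5 default
        assert all(r.start == r.end for r in raws)
        assert {r.score for r in raws} == {0.9, 0.5}

    def test_netphos_residue_determines_keyword(self):
        raws = parse_prediction_output(NETPHOS_3ROW, "netphos",
                                       cutoffs=CutoffConfig({"netphos": 0.0}),
                                       protein_length=100)
        assert [r.keyword.split()[0] for r in raws] == [
            "Phospho-serine", "Phospho-threonine", "Phospho-tyrosine"]

    def test_iupred_runs_are_segmented(self):
        lines = ["# POS RES IUPRED2"]
        for pos in range(1, 41):
            score = 0.8 if 10 <= pos <= 20 or 30 <= pos <= 31 else 0.1
            lines.append(f"{pos}\tA\t{score}")
        raws = parse_prediction_output("\n".join(lines), "iupred_anchor",
                                       protein_length=40)
        assert [(r.start, r.end) for r in raws] == [(10, 20), (30, 31)]
        assert all(r.keyword == "Intrinsic disorder" for r in raws)

    def test_anchor_column_emits_binding_intervals(self):
        lines = [f"{p}\tA\t0.1\t{0.9 if 5 <= p <= 8 else 0.2}"
                 for p in range(1, 16)]
        raws = parse_prediction_output("\n".join(lines), "iupred_anchor",
                                       protein_length=15)
        anchor = [r for r in raws if "ANCHOR" in r.keyword]
        assert [(r.start, r.end) for r in anchor] == [(5, 8)]

    def test_empty_text_gives_empty_list(self):
        for source in ("smart", "elm", "netphos", "iupred_anchor"):
            assert parse_prediction_output("", source, protein_length=10) == []

    def test_unknown_source_is_a_dialect_error(self):
        with pytest.raises((DialectError, ValueError)):
            parse_prediction_output("x", "uniprot", protein_length=10)

    def test_position_beyond_protein_is_a_coordinate_error(self):
        with pytest.raises(CoordinateError, match="44"):
            parse_prediction_output(NETPHOS_3ROW, "netphos", protein_length=40)

    def test_smart_evalue_ceiling(self):
        text = ("name=PTPc start=10 end=60 evalue=1e-30 type=SMART\n"
                "name=FN3 start=70 end=90 evalue=0.2 type=SMART\n")
        assert len(parse_prediction_output(text, "smart", protein_length=100)) == 2
        kept = parse_prediction_output(
            text, "smart", cutoffs=CutoffConfig({"smart": 1e-3}),
            protein_length=100)
        assert [r.keyword for r in kept] == ["PTPc domain"]

    def test_all_seven_fixture_outputs_match_manifest(self, fixture_dir, manifest):
        length = manifest["protein"]["length"]
        for fname, info in manifest["files"].items():
            if info["source"] == "table":
                continue
            raws = parse_prediction_output(
                (fixture_dir / fname).read_text(), info["source"],
                protein_length=length)
            assert len(raws) == info["expected_at_default"], fname

    @pytest.mark.parametrize("source,colname", [
        ("netphos", "netphos"), ("netnglyc", "netnglyc"), ("netoglyc", "netoglyc"),
    ])
    def test_cutoff_monotonicity_on_fixture(self, fixture_dir, manifest,
                                            source, colname):
        fname = next(f for f, i in manifest["files"].items()
                     if i["source"] == source)
        text = (fixture_dir / fname).read_text()
        length = manifest["protein"]["length"]
        rng = random.Random(13)
        cutoffs = sorted(rng.uniform(0, 1) for _ in range(50))
        counts = [
            len(parse_prediction_output(
                text, source, CutoffConfig({colname: c}), length))
            for c in cutoffs
        ]
        assert counts == sorted(counts, reverse=True)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=80),
           st.floats(0.05, 0.95))
    def test_segmentation_matches_brute_force(self, scores, cutoff):
        """Run segmentation equals a per-residue brute-force scan."""
        text = "\n".join(f"{i + 1}\tA\t{s:.4f}" for i, s in enumerate(scores))
        raws = parse_prediction_output(
            text, "iupred_anchor",
            cutoffs=CutoffConfig({"iupred": cutoff, "anchor": None}),
            protein_length=len(scores))
        got = [(r.start, r.end) for r in raws]
        # oracle: enumerate residues, start a run at each above-cutoff
        # residue not preceded by one
        expected = []
        above = [round(s, 4) >= cutoff for s in scores]
        i = 0
        while i < len(above):
            if above[i]:
                j = i
                while j + 1 < len(above) and above[j + 1]:
                    j += 1
                expected.append((i + 1, j + 1))
                i = j + 1
            else:
                i += 1
        assert got == expected


class TestReadFeatureTable:
    def test_row_count_matches_fixture(self, fixture_dir, manifest):
        meta, recs = read_feature_table(fixture_dir / "features.csv")
        assert len(recs) == manifest["table_rows"]
        assert int(meta["length"]) == manifest["protein"]["length"]

    def test_csv_tsv_xlsx_yield_identical_records(self, fixture_dir):
        _, csv_recs = read_feature_table(fixture_dir / "features.csv")
        _, tsv_recs = read_feature_table(fixture_dir / "features.tsv")
        _, xlsx_recs = read_feature_table(fixture_dir / "features.xlsx")
        assert csv_recs == tsv_recs == xlsx_recs

    def test_missing_start_column_is_a_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("name,type,end\nA,domain,50\n")
        with pytest.raises(TableSchemaError, match="start"):
            read_feature_table(p)

    def test_non_integer_coordinate_names_the_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("name,type,start,end\nA,domain,one,50\n")
        with pytest.raises(ValueError, match="row 2"):
            read_feature_table(p)

    def test_explicit_category_with_unknown_type_hard_fails(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("name,type,start,end,category\nA,zqx_bogus,1,50,region\n")
        with pytest.raises(VocabularyError, match="zqx_bogus"):
            read_feature_table(p)

    def test_rows_without_category_are_classified(self, tmp_path):
        p = tmp_path / "ok.csv"
        p.write_text("name,type,start,end\nSP,Signal peptide,1,22\n")
        _, recs = read_feature_table(p)
        assert recs[0].type_key == "signal_peptide"
        assert recs[0].label == "SP"

    def test_colour_overrides_collected_in_metadata(self, tmp_path):
        p = tmp_path / "ok.csv"
        p.write_text("name,type,start,end,colour\nD1,domain,1,220,#FF0000\n")
        meta, recs = read_feature_table(p)
        assert meta["colours"] == {"D1": "#FF0000"}
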
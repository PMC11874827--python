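"""Vocabulary, keyword classification, shape/colour rules, deduplication."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from protoscheme.classify import (
    assign_colours,
    assign_shape,
    classify_feature,
    deduplicate,
)
from protoscheme.feature_model import Category, FeatureRecord, Source
from protoscheme.ingest import RawFeature


class TestVocabularyCardinalities:
    def test_exactly_three_categories(self, vocab):
        assert {c.value for c in vocab.categories} == {"region", "motif", "markup"}

    def test_seventeen_motif_types(self, vocab):
        assert len(vocab.type_keys(Category.MOTIF)) == 17

    def test_forty_seven_markup_types(self, vocab):
        assert len(vocab.type_keys(Category.MARKUP)) == 47

    def test_each_type_has_one_glyph_with_unique_id(self, vocab):
        for cat in vocab.categories:
            glyphs = [vocab.glyph(cat, k) for k in vocab.type_keys(cat)]
            ids = [g.glyph_id for g in glyphs]
            assert len(set(ids)) == len(ids)

    def test_markup_glyph_colours_are_pairwise_distinct(self, vocab):
        colours = [vocab.glyph(Category.MARKUP, k).colour
                   for k in vocab.type_keys(Category.MARKUP)]
        assert len(set(colours)) == len(colours)


class TestClassifyFeature:
    @pytest.mark.parametrize(
        "keyword,start,end,category,type_key",
        [
            ("Signal peptide", 1, 23, Category.MOTIF, "signal_peptide"),
            ("phospho-serine", 965, 965, Category.MARKUP, "phospho_serine"),
            ("TRANSMEM Helical", 578, 601, Category.MOTIF, "transmembrane"),
            ("N-linked (GlcNAc...) asparagine", 25, 25, Category.MARKUP,
             "n_glycosylation"),
            ("CARBOHYD", 25, 25, Category.MARKUP, "glycosylation"),
            ("Coiled coil", 100, 140, Category.MOTIF, "coiled_coil"),
            ("LIG_SH2_STAT5", 10, 18, Category.MOTIF, "binding_motif"),
            ("DOMAIN Fibronectin type-III", 391, 486, Category.REGION, "domain"),
            ("Disulfide bond", 56, 56, Category.MARKUP, "disulfide_bond"),
        ],
    )
    def test_keyword_mapping(self, vocab, keyword, start, end, category, type_key):
        rec = classify_feature(RawFeature(keyword, start, end), vocab)
        assert (rec.category, rec.type_key) == (category, type_key)

    def test_longest_pattern_wins_over_generic(self, vocab):
        rec = classify_feature(RawFeature("Phosphoserine; by PKC", 9, 9), vocab)
        assert rec.type_key == "phospho_serine"
        rec = classify_feature(RawFeature("phosphorylation site", 9, 9), vocab)
        assert rec.type_key == "phosphorylation"

    def test_unknown_interval_falls_back_to_other_motif(self, vocab, caplog):
        with caplog.at_level("WARNING", logger="protoscheme.classify"):
            rec = classify_feature(RawFeature("zqx-unknown-zqx", 5, 40), vocab)
        assert (rec.category, rec.type_key) == (Category.MOTIF, "other_motif")
        assert any("zqx-unknown-zqx" in r.message for r in caplog.records)

    def test_unknown_site_falls_back_to_other_markup(self, vocab):
        rec = classify_feature(RawFeature("zqx-unknown-zqx", 5, 5), vocab)
        assert (rec.category, rec.type_key) == (Category.MARKUP, "other")

    def test_interval_never_classifies_as_markup(self, vocab):
        # 'cleavage' exists as markup; the interval must go to the motif type
        rec = classify_feature(RawFeature("cleavage motif", 5, 20), vocab)
        assert rec.category is Category.MOTIF
        rec = classify_feature(RawFeature("cleavage", 5, 20), vocab)
        assert rec.category is not Category.MARKUP

    def test_repeat_keyword_sets_repeat_flag(self, vocab):
        rec = classify_feature(RawFeature("REPEAT Fibronectin", 30, 120), vocab)
        assert rec.category is Category.REGION
        assert rec.is_repeat

    def test_idempotent_on_canonical_display_names(self, vocab):
        """Classifying a feature's own display label preserves its type."""
        for cat in (Category.MOTIF, Category.MARKUP):
            for key in vocab.type_keys(cat):
                label = vocab.display_name(cat, key)
                is_site = cat is Category.MARKUP
                rec = classify_feature(
                    RawFeature(label, 10, 10 if is_site else 30), vocab
                )
                assert rec.type_key == key, (label, rec.type_key)


class TestAssignShape:
    @staticmethod
    def oracle(length, is_repeat):
        # independent re-statement of the published partition
        if is_repeat:
            return "jagged"
        if length > 200:
            return "pointed"
        if 35 <= length <= 200:
            return "curved"
        return "straight"

    def test_exhaustive_partition_lengths_1_to_500(self):
        for length, rep in itertools.product(range(1, 501), (False, True)):
            assert assign_shape(length, rep) == self.oracle(length, rep)

    @pytest.mark.parametrize("length,expected",
                             [(250, "pointed"), (100, "curved"), (20, "straight"),
                              (35, "curved"), (200, "curved"), (34, "straight"),
                              (201, "pointed")])
    def test_boundaries(self, length, expected):
        assert assign_shape(length, False) == expected

    def test_repeats_are_jagged_regardless_of_length(self):
        assert assign_shape(300, True) == "jagged"

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            assign_shape(0, False)


def region(label, start=1, end=50, source=Source.CUSTOM, type_key="domain"):
    return FeatureRecord(Category.REGION, type_key, label, start, end,
                         source=source)


class TestAssignColours:
    def test_shared_labels_share_colour(self):
        cmap = assign_colours([region("A"), region("B", 60, 90), region("A", 95, 120)])
        assert len(cmap) == 2
        assert set(cmap) == {"A", "B"}

    def test_single_label(self):
        assert len(assign_colours([region("A")])) == 1

    def test_six_labels_pairwise_distinct_hex(self):
        regions = [region(lbl, 1 + i * 10, 5 + i * 10)
                   for i, lbl in enumerate("ABCDEF")]
        cmap = assign_colours(regions)
        values = list(cmap.values())
        assert len(set(values)) == 6
        assert all(v.startswith("#") and len(v) == 7 for v in values)

    def test_empty_list_gives_empty_mapping(self):
        assert assign_colours([]) == {}

    def test_rejects_non_regions(self):
        bad = FeatureRecord(Category.MOTIF, "other_motif", "m", 1, 5)
        with pytest.raises(ValueError):
            assign_colours([bad])

    def test_image_size_equals_unique_labels(self):
        rng = random.Random(0)
        labels = [rng.choice("ABCDE") for _ in range(20)]
        regions = [region(lbl, 1 + i * 5, 3 + i * 5)
                   for i, lbl in enumerate(labels)]
        assert len(assign_colours(regions)) == len(set(labels))


def markup(pos, type_key="n_glycosylation", source=Source.CUSTOM):
    return FeatureRecord(Category.MARKUP, type_key, type_key, pos, pos,
                         source=source)


class TestDeduplicate:
    def test_identical_markups_collapse(self):
        out = deduplicate([markup(25), markup(25)])
        assert len(out) == 1

    def test_same_site_different_type_both_kept(self):
        out = deduplicate([markup(25, "n_glycosylation"), markup(25, "o_glycosylation")])
        assert len(out) == 2

    def test_database_annotation_outranks_prediction(self):
        pred = markup(25, source=Source.NETNGLYC)
        db = markup(25, source=Source.UNIPROT)
        out = deduplicate([pred, db])
        assert out == [db]

    def test_idempotent(self):
        feats = [markup(25), markup(40), markup(25)]
        once = deduplicate(feats)
        assert deduplicate(once) == once

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.integers(1, 30),
                              st.sampled_from(["n_glycosylation", "phospho_serine"])),
                    max_size=30))
    def test_length_drops_by_exactly_the_duplicate_count(self, spec):
        feats = [markup(pos, key) for pos, key in spec]
        # brute-force oracle: count of distinct identity keys
        distinct = len({(f.category, f.type_key, f.start, f.end) for f in feats})
        out = deduplicate(feats)
        assert len(out) == distinct
        assert len(out) <= len(feats)
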
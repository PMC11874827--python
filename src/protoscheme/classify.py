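"""Keyword classification, shape assignment, colouring and deduplication.

Raw feature keys from databases, prediction servers or user tables are
mapped onto a controlled vocabulary by case-insensitive substring matching.
The vocabulary has exactly three categories (regions, motifs, markups),
17 canonical motif types and 47 canonical markup types; it ships as a
tabular data file (``data/vocabulary.tsv`` + ``data/glyphs.tsv``) and is
user-extensible.

Matching rules
--------------
* All patterns whose text occurs in the keyword (case-insensitively) are
  candidates; the longest pattern wins, ties broken alphabetically. This
  makes ``phospho-serine`` beat the generic ``phospho``.
* Single-site features (start == end) match markup patterns first and fall
  back to motif/region patterns; interval features never match markup
  patterns (a markup must be a single residue).
* Unmatched keywords never hard-fail: intervals fall back to
  ``other_motif`` (motif), sites to ``other`` (markup), with a warning on
  the ``protoscheme.classify`` logger.
"""

from __future__ import annotations

import colorsys
import csv
import logging
from dataclasses import dataclass
from importlib import resources
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

from .feature_model import Category, FeatureRecord, Source, sort_features

if TYPE_CHECKING:  # pragma: no cover
    from .ingest import RawFeature

__all__ = [
    "GlyphSpec",
    "Vocabulary",
    "default_vocabulary",
    "classify_feature",
    "assign_shape",
    "assign_colours",
    "deduplicate",
]

logger = logging.getLogger(__name__)

#: Shape of a region box, decided by its length unless it is a repeat.
SHAPES = ("pointed", "curved", "straight", "jagged")

#: Lollipop head styles available for markups.
HEAD_STYLES = ("circle", "square", "diamond", "arrow", "pentagon", "line")

#: Source precedence when collapsing duplicate records: curated database
#: annotations outrank predictions; user-supplied custom rows come last.
_SOURCE_RANK = {Source.UNIPROT: 0, Source.GENPEPT: 1}


def _source_rank(source: Source) -> int:
    if source in _SOURCE_RANK:
        return _SOURCE_RANK[source]
    return 3 if source is Source.CUSTOM else 2


@dataclass(frozen=True)
class GlyphSpec:
    """How one canonical type is drawn.

    Regions carry ``colour == "auto"`` (colour comes from the per-protein
    palette, shape from the length rule); motifs carry a fill colour;
    markups carry a head style and colour.
    """

    category: Category
    type_key: str
    display_name: str
    glyph_id: int
    colour: str
    head_style: str


class Vocabulary:
    """The controlled keyword -> (category, canonical type, glyph) mapping."""

    def __init__(
        self,
        patterns: Sequence[tuple[str, Category, str]],
        glyphs: Sequence[GlyphSpec],
    ):
        self._patterns = [(p.lower(), Category(c), k) for p, c, k in patterns]
        self._glyphs = {(g.category, g.type_key): g for g in glyphs}
        ids_by_cat: dict[Category, set[int]] = {}
        for g in glyphs:
            ids = ids_by_cat.setdefault(g.category, set())
            if g.glyph_id in ids:
                raise ValueError(
                    f"duplicate glyph id {g.glyph_id} in category {g.category}"
                )
            ids.add(g.glyph_id)
        for pattern, cat, key in self._patterns:
            if (cat, key) not in self._glyphs:
                raise ValueError(
                    f"pattern {pattern!r} maps to unknown type {cat}/{key}"
                )

    # -- introspection -------------------------------------------------
    @property
    def categories(self) -> list[Category]:
        return sorted({g.category for g in self._glyphs.values()},
                      key=lambda c: c.value)

    def type_keys(self, category: Category) -> list[str]:
        category = Category(category)
        keys = [g.type_key for g in self._glyphs.values() if g.category is category]
        return sorted(set(keys))

    def has_type(self, category: Category, type_key: str) -> bool:
        return (Category(category), type_key) in self._glyphs

    def glyph(self, category: Category, type_key: str) -> GlyphSpec:
        try:
            return self._glyphs[(Category(category), type_key)]
        except KeyError:
            raise KeyError(f"no glyph for {category}/{type_key}") from None

    def display_name(self, category: Category, type_key: str) -> str:
        return self.glyph(category, type_key).display_name

    # -- matching ------------------------------------------------------
    def match(self, keyword: str, is_site: bool) -> Optional[tuple[Category, str]]:
        """Longest case-insensitive substring match compatible with the
        feature's extent; ``None`` when nothing matches."""
        kw = keyword.lower()
        best: Optional[tuple[int, tuple, int, Category, str]] = None
        for pattern, cat, key in self._patterns:
            if cat is Category.MARKUP and not is_site:
                continue  # an interval can never be a single-site markup
            if pattern in kw:
                # longest pattern wins; alphabetical on ties; when the same
                # pattern exists in two categories, a site takes the markup
                markup_pref = 1 if (is_site and cat is Category.MARKUP) else 0
                cand = (len(pattern), _rev(pattern), markup_pref, cat, key)
                if best is None or cand[:3] > best[:3]:
                    best = cand
        if best is None:
            return None
        return best[3], best[4]


def _rev(s: str) -> tuple:
    """Alphabetical tie-break as a max-key: earlier alphabetically wins."""
    return tuple(-ord(ch) for ch in s)


def _read_tsv(name: str) -> list[dict[str, str]]:
    ref = resources.files("protoscheme.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        rows = [ln for ln in fh if not ln.startswith("#")]
    return list(csv.DictReader(rows, delimiter="\t"))


_DEFAULT: Optional[Vocabulary] = None


def default_vocabulary() -> Vocabulary:
    """The vocabulary shipped with the package (loaded once, cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        patterns = [
            (r["pattern"], Category(r["category"]), r["type_key"])
            for r in _read_tsv("vocabulary.tsv")
        ]
        glyphs = [
            GlyphSpec(
                category=Category(r["category"]),
                type_key=r["type_key"],
                display_name=r["display_name"],
                glyph_id=int(r["glyph_id"]),
                colour=r["colour"],
                head_style=r["head_style"],
            )
            for r in _read_tsv("glyphs.tsv")
        ]
        _DEFAULT = Vocabulary(patterns, glyphs)
    return _DEFAULT


def classify_feature(
    raw: "RawFeature", vocabulary: Optional[Vocabulary] = None
) -> FeatureRecord:
    """Map one raw feature onto the controlled vocabulary.

    The raw keyword is matched against the vocabulary patterns
    (longest pattern wins); unmatched intervals become ``other_motif``
    (motif) and unmatched sites become ``other`` (markup), with a warning.
    """
    vocab = vocabulary or default_vocabulary()
    if not raw.keyword:
        raise ValueError("raw feature has an empty keyword")
    is_site = raw.start == raw.end
    hit = vocab.match(raw.keyword, is_site=is_site)
    if hit is None:
        if is_site:
            category, type_key = Category.MARKUP, "other"
        else:
            category, type_key = Category.MOTIF, "other_motif"
        logger.warning(
            "no vocabulary match for keyword %r (%d..%d); classified as %s/%s",
            raw.keyword, raw.start, raw.end, category, type_key,
        )
    else:
        category, type_key = hit
    return FeatureRecord(
        category=category,
        type_key=type_key,
        label=raw.keyword.strip(),
        start=raw.start,
        end=raw.end,
        is_repeat=(category is Category.REGION and type_key == "repeat"),
        score=getattr(raw, "score", None),
        source=getattr(raw, "source", Source.CUSTOM),
    )


def assign_shape(length_aa: int, is_repeat: bool) -> str:
    """Region shape from length: ``jagged`` for repeats, ``pointed`` for
    long regions (> 200 aa), ``curved`` for medium ones (35-200 aa,
    boundaries inclusive), ``straight`` for short ones (< 35 aa)."""
    if length_aa < 1:
        raise ValueError(f"region length must be >= 1, got {length_aa}")
    if is_repeat:
        return "jagged"
    if length_aa > 200:
        return "pointed"
    if length_aa < 35:
        return "straight"
    return "curved"


def assign_colours(
    regions: Sequence[FeatureRecord], palette: str = "rainbow"
) -> dict[str, str]:
    """Per-protein region colour map: one hue per unique label.

    Hues are evenly spaced around the colour wheel in first-occurrence
    order, so regions sharing a name share a colour. The mapping is
    recomputed for every protein; colours are not persistent across
    proteins.
    """
    for f in regions:
        if f.category is not Category.REGION:
            raise ValueError(f"assign_colours expects regions, got {f.category}")
    labels: list[str] = []
    for f in regions:
        if f.label not in labels:
            labels.append(f.label)
    n = len(labels)
    if palette not in ("rainbow",):
        raise ValueError(f"unknown palette {palette!r}")
    out = {}
    for i, label in enumerate(labels):
        r, g, b = colorsys.hsv_to_rgb(i / max(n, 1), 0.6, 0.9)
        out[label] = "#%02X%02X%02X" % (round(r * 255), round(g * 255), round(b * 255))
    return out


def deduplicate(features: Iterable[FeatureRecord]) -> list[FeatureRecord]:
    """Collapse exact duplicates on (category, type_key, start, end).

    When the same annotation arrives from several resources the survivor
    is chosen by source precedence (UniProt > GenPept > predictors >
    custom), ties by input order. The result is re-sorted. Idempotent and
    never longer than its input.
    """
    best: dict[tuple, tuple[int, int, FeatureRecord]] = {}
    for idx, f in enumerate(features):
        key = (f.category, f.type_key, f.start, f.end)
        cand = (_source_rank(f.source), idx, f)
        if key not in best or cand[:2] < best[key][:2]:
            best[key] = cand
    survivors = [v[2] for v in sorted(best.values(), key=lambda v: v[1])]
    return sort_features(survivors)
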
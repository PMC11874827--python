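"""Scheme <-> JSON codec in the Pfam domain-graphics dialect.

A scheme document is a JSON object with the protein ``length`` and three
feature lists::

    {"length": 1306,
     "metadata": {"name": "...", "accession": "..."},
     "regions": [{"start":, "end":, "text":, "colour":,
                  "startStyle":, "endStyle":, "metadata": {...}}, ...],
     "motifs":  [{"start":, "end":, "colour":, "display": true,
                  "opacity":, "metadata": {...}}, ...],
     "markups": [{"start":, "lineColour":, "colour":, "headStyle":,
                  "metadata": {...}}, ...]}

Region start/end styles encode the shape rule (long regions pointed ->
``arrow`` ends, medium ``curved``, short ``straight``, repeats
``jagged``). Each entry carries a ``metadata`` sub-object (label, type,
source, score) so that decoding is lossless: ``decode(encode(x))``
reproduces the feature table field-for-field. The normative structural
description ships as ``data/schema.json``; :func:`validate_document` is
the executable check.

Serialization is canonical — keys sorted, two-space indent, integer
coordinates, ``#RRGGBB`` colours — so the same scheme always yields
byte-identical JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .classify import assign_colours, assign_shape, default_vocabulary
from .feature_model import (
    Category,
    CoordinateError,
    FeatureRecord,
    ProteinScheme,
    RenderOptions,
    SchemeError,
    Source,
)

__all__ = [
    "EncodingError",
    "DecodeError",
    "encode_scheme",
    "decode_scheme",
    "dumps",
    "loads",
    "validate_document",
    "export_table",
]


class EncodingError(SchemeError):
    """A scheme cannot be encoded (e.g. a region label has no colour)."""


class DecodeError(SchemeError):
    """A document violates the scheme-JSON dialect."""


#: start/end styles a region may carry.
EDGE_STYLES = ("curved", "straight", "jagged", "arrow")
#: head styles a markup may carry.
HEAD_STYLES = ("circle", "square", "diamond", "arrow", "pentagon", "line")

_SHAPE_TO_EDGE = {
    "pointed": "arrow",
    "curved": "curved",
    "straight": "straight",
    "jagged": "jagged",
}
_EDGE_TO_SHAPE = {v: k for k, v in _SHAPE_TO_EDGE.items()}

_MARKUP_LINE_COLOUR = "#333333"


def _feature_metadata(f: FeatureRecord) -> dict:
    meta = {"label": f.label, "type": f.type_key, "source": f.source.value}
    if f.score is not None:
        meta["score"] = f.score
    return meta


def encode_scheme(
    scheme: ProteinScheme,
    colour_map: Optional[dict[str, str]] = None,
    options: Optional[RenderOptions] = None,
    vocabulary=None,
) -> dict:
    """Encode a validated scheme as a Pfam-dialect document.

    ``colour_map`` maps region labels to colours; when omitted it is
    computed from the scheme with the rainbow palette. Motif and markup
    colours and markup head styles come from the vocabulary glyphs.
    """
    options = options or RenderOptions()
    vocab = vocabulary or default_vocabulary()
    scheme.validate()
    regions = scheme.by_category(Category.REGION)
    if colour_map is None:
        colour_map = assign_colours(regions, palette=options.palette)
    doc: dict = {
        "length": int(scheme.length),
        "metadata": {"name": scheme.name},
        "regions": [],
        "motifs": [],
        "markups": [],
    }
    if scheme.accession:
        doc["metadata"]["accession"] = scheme.accession
    for f in scheme.features:
        if f.category is Category.REGION:
            if f.label not in colour_map:
                raise EncodingError(
                    f"region label {f.label!r} is missing from the colour map"
                )
            shape = assign_shape(f.length, f.is_repeat)
            edge = _SHAPE_TO_EDGE[shape]
            doc["regions"].append(
                {
                    "start": f.start,
                    "end": f.end,
                    "text": f.label,
                    "colour": colour_map[f.label],
                    "startStyle": edge,
                    "endStyle": edge,
                    "metadata": _feature_metadata(f),
                }
            )
        elif f.category is Category.MOTIF:
            glyph = vocab.glyph(Category.MOTIF, f.type_key)
            doc["motifs"].append(
                {
                    "start": f.start,
                    "end": f.end,
                    "colour": glyph.colour,
                    "display": True,
                    "opacity": options.motif_opacity,
                    "metadata": _feature_metadata(f),
                }
            )
        else:
            glyph = vocab.glyph(Category.MARKUP, f.type_key)
            doc["markups"].append(
                {
                    "start": f.start,
                    "lineColour": _MARKUP_LINE_COLOUR,
                    "colour": glyph.colour,
                    "headStyle": glyph.head_style,
                    "metadata": _feature_metadata(f),
                }
            )
    return doc


def _fail(path: str, message: str) -> None:
    raise DecodeError(f"{path}: {message}")


def _check_entry(entry: dict, path: str, required: dict[str, type]) -> None:
    if not isinstance(entry, dict):
        _fail(path, "entry must be an object")
    for key, typ in required.items():
        if key not in entry:
            _fail(f"{path}.{key}", "missing required key")
        if typ is int:
            if not isinstance(entry[key], int) or isinstance(entry[key], bool):
                _fail(f"{path}.{key}", f"expected integer, got {entry[key]!r}")
        elif not isinstance(entry[key], typ):
            _fail(f"{path}.{key}", f"expected {typ.__name__}, got {entry[key]!r}")


def validate_document(doc: dict) -> dict:
    """Structural validation of a scheme document (the executable form of
    ``data/schema.json``). Returns the document; raises
    :class:`DecodeError` with a JSON path, or :class:`CoordinateError`
    for features beyond the root length."""
    if not isinstance(doc, dict):
        _fail("$", "document must be an object")
    if "length" not in doc:
        _fail("$.length", "missing required key")
    length = doc["length"]
    if not isinstance(length, int) or isinstance(length, bool) or length < 1:
        _fail("$.length", f"expected positive integer, got {length!r}")
    for key in ("regions", "motifs", "markups"):
        if key not in doc:
            _fail(f"$.{key}", "missing required key")
        if not isinstance(doc[key], list):
            _fail(f"$.{key}", "expected a list")
    for i, entry in enumerate(doc["regions"]):
        path = f"$.regions[{i}]"
        _check_entry(
            entry, path,
            {"start": int, "end": int, "text": str, "colour": str,
             "startStyle": str, "endStyle": str},
        )
        for side in ("startStyle", "endStyle"):
            if entry[side] not in EDGE_STYLES:
                _fail(f"{path}.{side}", f"unknown style {entry[side]!r}")
        if not (1 <= entry["start"] <= entry["end"] <= length):
            raise CoordinateError(
                f"{path}: region {entry['start']}..{entry['end']} outside "
                f"protein of length {length}"
            )
    for i, entry in enumerate(doc["motifs"]):
        path = f"$.motifs[{i}]"
        _check_entry(entry, path, {"start": int, "end": int, "colour": str})
        if not (1 <= entry["start"] <= entry["end"] <= length):
            raise CoordinateError(
                f"{path}: motif {entry['start']}..{entry['end']} outside "
                f"protein of length {length}"
            )
        opacity = entry.get("opacity", 1.0)
        if not isinstance(opacity, (int, float)) or not (0 <= opacity <= 1):
            _fail(f"{path}.opacity", f"expected number in [0,1], got {opacity!r}")
    for i, entry in enumerate(doc["markups"]):
        path = f"$.markups[{i}]"
        _check_entry(entry, path, {"start": int, "colour": str, "headStyle": str})
        if entry["headStyle"] not in HEAD_STYLES:
            _fail(f"{path}.headStyle", f"unknown head style {entry['headStyle']!r}")
        if not (1 <= entry["start"] <= length):
            raise CoordinateError(
                f"{path}: markup at {entry['start']} outside protein of "
                f"length {length}"
            )
    return doc


def _decode_feature(entry: dict, category: Category) -> FeatureRecord:
    meta = entry.get("metadata", {})
    start = entry["start"]
    end = entry.get("end", start)
    label = meta.get("label") or entry.get("text") or meta.get("type", "feature")
    type_key = meta.get("type")
    if type_key is None:
        # foreign document without our metadata extension: keep it renderable
        type_key = {"region": "region", "motif": "other_motif", "markup": "other"}[
            category.value
        ]
    is_repeat = (
        category is Category.REGION and entry.get("endStyle") == "jagged"
    )
    return FeatureRecord(
        category=category,
        type_key=type_key,
        label=label,
        start=start,
        end=end,
        is_repeat=is_repeat,
        score=meta.get("score"),
        source=Source(meta.get("source", "custom")),
    )


def decode_scheme(doc: dict) -> ProteinScheme:
    """Decode a scheme document back into a feature table
    (:class:`ProteinScheme`); the inverse of :func:`encode_scheme`."""
    validate_document(doc)
    meta = doc.get("metadata", {})
    features = (
        [_decode_feature(e, Category.REGION) for e in doc["regions"]]
        + [_decode_feature(e, Category.MOTIF) for e in doc["motifs"]]
        + [_decode_feature(e, Category.MARKUP) for e in doc["markups"]]
    )
    return ProteinScheme.assemble(
        name=meta.get("name", ""),
        length=doc["length"],
        accession=meta.get("accession"),
        features=features,
    )


def dumps(doc: dict) -> str:
    """Canonical serialization: sorted keys, two-space indent, newline at
    end — the same document always yields byte-identical text."""
    return json.dumps(doc, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def loads(text: str) -> dict:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DecodeError(f"not valid JSON: {exc}") from exc
    return validate_document(doc)


_TABLE_COLUMNS = [
    "name", "category", "type", "start", "end", "is_repeat", "source", "score",
]


def export_table(
    scheme: ProteinScheme,
    path: Union[str, Path],
    format: Optional[str] = None,
) -> Path:
    """Write a scheme's feature table to csv/tsv/xlsx.

    Columns mirror the curated-table schema, so
    ``read_feature_table(export_table(x))`` reproduces ``x``'s features.
    csv/tsv outputs start with ``# protein/length/accession`` metadata
    comment lines.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("csv", "tsv", "xlsx"):
        raise ValueError(f"unsupported table format {fmt!r}")
    scheme.validate()
    rows = []
    for f in scheme.features:
        rows.append(
            [
                f.label,
                f.category.value,
                f.type_key,
                f.start,
                f.end,
                "true" if f.is_repeat else "false",
                f.source.value,
                f.score if f.score is not None else "",
            ]
        )
    if fmt == "xlsx":
        from ._xlsx import write_rows

        write_rows([_TABLE_COLUMNS] + rows, path)
        return path
    sep = "," if fmt == "csv" else "\t"
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# protein: {scheme.name}\n")
        fh.write(f"# length: {scheme.length}\n")
        if scheme.accession:
            fh.write(f"# accession: {scheme.accession}\n")
        df.to_csv(fh, sep=sep, index=False)
    return path
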
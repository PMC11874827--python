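"""Native SVG renderer for scheme documents.

The protein backbone is a horizontal bar; regions are shaped boxes drawn
over it (arrow-pointed, curved, straight or jagged ends per the length
rule), motifs are translucent rectangles, markups are lollipops (a stem
plus a head glyph) above the backbone. Horizontal geometry is strictly
linear in the options: residue ``p`` starts at ``(p - 1) * px_per_aa *
rescale`` SVG units, so changing ``px_per_aa`` stretches the scheme
("zooming") and ``rescale`` scales the whole drawing proportionally.

Lollipop heads that would overlap are staggered vertically in discovery
order (two tiers); further collisions drop the stem and draw the head
directly above the backbone.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Optional

from .feature_model import RenderOptions, SchemeError
from .codec import validate_document

__all__ = ["render_svg", "render_legend", "RenderError", "GEOMETRY"]


class RenderError(SchemeError):
    """A document cannot be rendered."""


#: Visual constants, in unscaled SVG units (multiplied by ``rescale``).
GEOMETRY = {
    "backbone_height": 14,
    "region_height": 18,
    "motif_height": 14,
    "markup_stem": 18,
    "tier_offset": 10,
    "head_size": 8,
    "top_margin": 46,
    "bottom_margin": 16,
    "side_padding": 12,
    "font_family": "sans-serif",
    "font_size": 10,
    "legend_row_height": 16,
    "legend_swatch": 10,
}

_SVG_NS = "http://www.w3.org/2000/svg"


def _fmt(value: float) -> str:
    text = f"{value:.2f}".rstrip("0").rstrip(".")
    return text if text else "0"


def _jagged_edge(x: float, y_top: float, y_bot: float, direction: int) -> str:
    """Zigzag vertical edge; ``direction`` is +1 to bulge right, -1 left."""
    h = (y_bot - y_top) / 4.0
    amp = direction * (y_bot - y_top) / 4.0
    pts = []
    for i in range(1, 4):
        px = x + (amp if i % 2 else 0)
        pts.append(f"L {_fmt(px)} {_fmt(y_top + i * h)}")
    pts.append(f"L {_fmt(x)} {_fmt(y_bot)}")
    return " ".join(pts)


def _region_path(
    x0: float, x1: float, y0: float, y1: float,
    start_style: str, end_style: str, taper: float,
) -> str:
    """Closed path for a region box with styled left/right edges."""
    parts = [f"M {_fmt(x0)} {_fmt(y0)}", f"L {_fmt(x1)} {_fmt(y0)}"]
    # right (end) edge, drawn top -> bottom
    if end_style == "straight":
        parts.append(f"L {_fmt(x1)} {_fmt(y1)}")
    elif end_style == "curved":
        parts.append(f"C {_fmt(x1 + taper)} {_fmt(y0)} "
                     f"{_fmt(x1 + taper)} {_fmt(y1)} {_fmt(x1)} {_fmt(y1)}")
    elif end_style == "arrow":
        mid = (y0 + y1) / 2.0
        parts.append(f"L {_fmt(x1 + taper)} {_fmt(mid)} L {_fmt(x1)} {_fmt(y1)}")
    else:  # jagged
        parts.append(_jagged_edge(x1, y0, y1, +1))
    parts.append(f"L {_fmt(x0)} {_fmt(y1)}")
    # left (start) edge, drawn bottom -> top
    if start_style == "straight":
        pass
    elif start_style == "curved":
        parts.append(f"C {_fmt(x0 - taper)} {_fmt(y1)} "
                     f"{_fmt(x0 - taper)} {_fmt(y0)} {_fmt(x0)} {_fmt(y0)}")
    elif start_style == "arrow":
        mid = (y0 + y1) / 2.0
        parts.append(f"L {_fmt(x0 - taper)} {_fmt(mid)} L {_fmt(x0)} {_fmt(y0)}")
    else:  # jagged
        parts.append(_jagged_edge(x0, y1, y0, -1))
    parts.append("Z")
    return " ".join(parts)


def _head_element(style: str, cx: float, cy: float, size: float, colour: str):
    half = size / 2.0
    if style == "circle":
        el = ET.Element("circle", {
            "cx": _fmt(cx), "cy": _fmt(cy), "r": _fmt(half), "fill": colour})
    elif style == "square":
        el = ET.Element("rect", {
            "x": _fmt(cx - half), "y": _fmt(cy - half),
            "width": _fmt(size), "height": _fmt(size), "fill": colour})
    elif style == "diamond":
        pts = f"{_fmt(cx)},{_fmt(cy - half)} {_fmt(cx + half)},{_fmt(cy)} " \
              f"{_fmt(cx)},{_fmt(cy + half)} {_fmt(cx - half)},{_fmt(cy)}"
        el = ET.Element("polygon", {"points": pts, "fill": colour})
    elif style == "arrow":
        pts = f"{_fmt(cx - half)},{_fmt(cy - half)} {_fmt(cx + half)},{_fmt(cy - half)} " \
              f"{_fmt(cx)},{_fmt(cy + half)}"
        el = ET.Element("polygon", {"points": pts, "fill": colour})
    elif style == "pentagon":
        import math

        pts = []
        for k in range(5):
            ang = -math.pi / 2 + 2 * math.pi * k / 5
            pts.append(f"{_fmt(cx + half * math.cos(ang))},"
                       f"{_fmt(cy + half * math.sin(ang))}")
        el = ET.Element("polygon", {"points": " ".join(pts), "fill": colour})
    elif style == "line":
        el = ET.Element("line", {
            "x1": _fmt(cx - half), "y1": _fmt(cy), "x2": _fmt(cx + half),
            "y2": _fmt(cy), "stroke": colour, "stroke-width": _fmt(size / 3.0)})
    else:  # pragma: no cover - validated upstream
        raise RenderError(f"unknown head style {style!r}")
    return el


def render_legend(doc: dict, options: Optional[RenderOptions] = None) -> ET.Element:
    """Legend fragment: one row per distinct feature type (regions are
    keyed by their display label), with the category in brackets."""
    validate_document(doc)
    options = options or RenderOptions()
    k = options.rescale
    g = ET.Element("g", {"class": "legend"})
    rows: list[tuple[str, str, str]] = []  # (text, colour, head_style)
    seen: set = set()
    for entry in doc["regions"]:
        key = ("region", entry["text"])
        if key not in seen:
            seen.add(key)
            rows.append((f"{entry['text']} (region)", entry["colour"], "swatch"))
    for kind, head in (("motifs", "swatch"), ("markups", None)):
        for entry in doc[kind]:
            type_key = entry.get("metadata", {}).get("type", "other")
            key = (kind, type_key)
            if key in seen:
                continue
            seen.add(key)
            label = entry.get("metadata", {}).get("label", type_key)
            category = "motif" if kind == "motifs" else "markup"
            rows.append(
                (f"{label} ({category})", entry["colour"],
                 head or entry.get("headStyle", "circle"))
            )
    row_h = GEOMETRY["legend_row_height"] * k
    swatch = GEOMETRY["legend_swatch"] * k
    for i, (text, colour, head) in enumerate(rows):
        row = ET.SubElement(g, "g", {"class": "legend-row"})
        cy = i * row_h + row_h / 2.0
        if head == "swatch":
            ET.SubElement(row, "rect", {
                "class": "legend-swatch", "x": "0", "y": _fmt(cy - swatch / 2),
                "width": _fmt(swatch), "height": _fmt(swatch), "fill": colour})
        else:
            el = _head_element(head, swatch / 2.0, cy, swatch, colour)
            el.set("class", "legend-swatch")
            row.append(el)
        label_el = ET.SubElement(row, "text", {
            "x": _fmt(swatch * 1.8), "y": _fmt(cy + swatch / 2.5),
            "font-family": GEOMETRY["font_family"],
            "font-size": _fmt(GEOMETRY["font_size"] * k)})
        label_el.text = text
    return g


def render_svg(
    doc: dict,
    options: Optional[RenderOptions] = None,
    include_legend: bool = False,
) -> str:
    """Render a scheme document to an SVG 1.1 string."""
    validate_document(doc)
    options = options or RenderOptions()
    k = options.rescale
    px = options.px_per_aa * k
    geo = GEOMETRY

    y_backbone = geo["top_margin"] * k
    backbone_h = geo["backbone_height"] * k
    backbone_mid = y_backbone + backbone_h / 2.0
    width = doc["length"] * px

    svg = ET.Element("svg", {
        "xmlns": _SVG_NS,
        "version": "1.1",
        "class": "protein-scheme",
    })
    scheme = ET.SubElement(svg, "g", {"class": "scheme"})
    ET.SubElement(scheme, "rect", {
        "class": "backbone",
        "x": "0", "y": _fmt(y_backbone),
        "width": _fmt(width), "height": _fmt(backbone_h),
        "fill": "#D8D8D8", "stroke": "#8A8A8A", "stroke-width": _fmt(0.8 * k)})

    # regions: shaped boxes slightly taller than the backbone
    region_h = geo["region_height"] * k
    ry0 = backbone_mid - region_h / 2.0
    ry1 = backbone_mid + region_h / 2.0
    for entry in doc["regions"]:
        x0 = (entry["start"] - 1) * px
        x1 = entry["end"] * px
        grp = ET.SubElement(scheme, "g", {"class": "region"})
        ET.SubElement(grp, "path", {
            "d": _region_path(x0, x1, ry0, ry1, entry["startStyle"],
                              entry["endStyle"], taper=6 * k),
            "fill": entry["colour"], "stroke": "#555555",
            "stroke-width": _fmt(0.8 * k)})
        label = entry.get("text", "")
        if label and (x1 - x0) >= geo["font_size"] * k * 0.9 * max(len(label), 1) * 0.55:
            text_el = ET.SubElement(grp, "text", {
                "x": _fmt((x0 + x1) / 2.0), "y": _fmt(backbone_mid + 3.5 * k),
                "text-anchor": "middle",
                "font-family": geo["font_family"],
                "font-size": _fmt(geo["font_size"] * k), "fill": "#222222"})
            text_el.text = label

    # motifs: translucent bars over the backbone
    motif_h = geo["motif_height"] * k
    my0 = backbone_mid - motif_h / 2.0
    for entry in doc["motifs"]:
        x0 = (entry["start"] - 1) * px
        ET.SubElement(scheme, "rect", {
            "class": "motif",
            "x": _fmt(x0), "y": _fmt(my0),
            "width": _fmt((entry["end"] - entry["start"] + 1) * px),
            "height": _fmt(motif_h),
            "fill": entry["colour"],
            "fill-opacity": _fmt(entry.get("opacity", options.motif_opacity))})

    # markups: lollipops with two-tier collision stagger
    head = geo["head_size"] * k
    stem = geo["markup_stem"] * k
    tier_off = geo["tier_offset"] * k
    tiers: list[list[float]] = [[], []]
    for entry in doc["markups"]:
        cx = (entry["start"] - 0.5) * px
        tier = None
        for t in (0, 1):
            if all(abs(cx - prev) >= head * 1.1 for prev in tiers[t]):
                tier = t
                break
        grp = ET.SubElement(scheme, "g", {"class": "markup"})
        if tier is None:
            # no free tier: head only, tucked against the backbone
            cy = y_backbone - head / 2.0
        else:
            tiers[tier].append(cx)
            top = y_backbone - stem - tier * tier_off
            grp.set("data-tier", str(tier))
            ET.SubElement(grp, "line", {
                "x1": _fmt(cx), "y1": _fmt(y_backbone),
                "x2": _fmt(cx), "y2": _fmt(top),
                "stroke": entry.get("lineColour", "#333333"),
                "stroke-width": _fmt(1.2 * k)})
            cy = top - head / 2.0
        grp.append(_head_element(entry["headStyle"], cx, cy, head, entry["colour"]))

    height = (geo["top_margin"] + geo["region_height"] + geo["bottom_margin"]) * k
    if include_legend:
        legend = render_legend(doc, options)
        n_rows = len(legend.findall("g"))
        legend.set("transform", f"translate(0 {_fmt(height)})")
        svg.append(legend)
        height += n_rows * geo["legend_row_height"] * k + geo["bottom_margin"] * k

    pad = geo["side_padding"] * k
    svg.set("viewBox", f"{_fmt(-pad)} 0 {_fmt(width + 2 * pad)} {_fmt(height)}")
    svg.set("width", _fmt(width + 2 * pad))
    svg.set("height", _fmt(height))
    return ET.tostring(svg, encoding="unicode")
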
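"""Deterministic static SVG rendering of a laid-out annotated module.

Two panes: a *set overview* on the left listing annotation sets per
category with logarithmically scaled significance circles, and the
*network visualization* on the right — opaque set ribbons (largest set
drawn first), link halos and curves, dashed contour outlines so occluded
sections can be inferred, and node labels on white background boxes whose
border color encodes differential expression (green under-, red
over-expressed).

Output is pure: identical inputs yield byte-identical documents
(coordinates are rounded to a fixed precision and nothing time- or
machine-dependent is emitted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry

from examine.contours import SetContour
from examine.hypergraph import AnnotatedModule, Interaction
from examine.rsom import Layout

__all__ = [
    "Style",
    "PALETTES",
    "assign_colors",
    "significance_glyph",
    "score_color",
    "edge_path",
    "render_svg",
]

#: Qualitative Color Brewer schemes (colorbrewer2.org, Cynthia Brewer).
PALETTES: dict[str, list[str]] = {
    "set2": [
        "#66c2a5", "#fc8d62", "#8da0cb", "#e78ac3",
        "#a6d854", "#ffd92f", "#e5c494", "#b3b3b3",
    ],
    "set3": [
        "#8dd3c7", "#ffffb3", "#bebada", "#fb8072", "#80b1d3", "#fdb462",
        "#b3de69", "#fccde5", "#d9d9d9", "#bc80bd", "#ccebc5", "#ffed6f",
    ],
    "dark2": [
        "#1b9e77", "#d95f02", "#7570b3", "#e7298a",
        "#66a61e", "#e6ab02", "#a6761d", "#666666",
    ],
}

#: Dark gray replaces black for text and outlines to reduce visual dominance.
INK = "#404040"


@dataclass(frozen=True)
class Style:
    """Visual constants of the figure."""

    palette: tuple[str, ...] = tuple(PALETTES["set2"])
    scale: float = 28.0  # pixels per canvas unit (one grid tile)
    halo_width: float = 4.0  # px, white halo under link curves
    link_width: float = 1.4  # px
    outline_width: float = 1.0  # px, dashed contour outline
    dash_pattern: str = "4,3"
    font_size: float = 9.0  # px
    font_family: str = "Helvetica, Arial, sans-serif"
    label_pad: float = 2.0  # px around label text
    glyph_radius_max: float = 9.0  # px, significance circle cap
    glyph_radius_per_decade: float = 1.1  # px per -log10(p)
    score_span: float = 2.0  # |score| mapped to full green/red saturation
    overview_width: float = 190.0  # px
    overview_row: float = 16.0  # px per set row
    margin: float = 12.0  # px

    def __post_init__(self) -> None:
        if len(self.palette) < 2:
            raise ValueError("palette needs at least 2 colors")


def assign_colors(
    active_sets: list[str], style: Style | None = None
) -> dict[str, str]:
    """Cycle palette colors over the active sets in selection order.

    Adjacent selections never share a color and the first |palette| sets
    are all distinct; beyond that the palette wraps around.
    """
    style = style or Style()
    pal = style.palette
    return {sid: pal[i % len(pal)] for i, sid in enumerate(active_sets)}


def significance_glyph(
    p_value: float, style: Style | None = None
) -> tuple[float, str]:
    """Circle radius and exponent text for an enrichment p-value.

    The radius grows with -log10(p), clipped to the style's maximum, so
    more significant sets get larger circles; the text is the base-10
    exponent of p in scientific notation (p = 5.6e-6 -> "-6").
    """
    style = style or Style()
    if not (p_value > 0.0):
        raise ValueError("p-value must be positive")
    if p_value > 1.0:
        raise ValueError("p-value must be <= 1")
    neglog = -math.log10(p_value)
    radius = min(style.glyph_radius_max, style.glyph_radius_per_decade * neglog)
    exponent = math.floor(math.log10(p_value)) if p_value < 1.0 else 0
    # exponent of the scientific-notation mantissa representation
    mantissa = p_value / 10.0**exponent
    if mantissa >= 10.0:  # rounding edge, e.g. p = 0.9999999...
        exponent += 1
    return radius, str(exponent)


def score_color(score: float, style: Style | None = None) -> str:
    """Diverging expression color: green negative, red positive, gray zero."""
    style = style or Style()
    s = max(-1.0, min(1.0, score / style.score_span))
    # interpolate ink-gray -> ColorBrewer green / red endpoints
    neutral = (128, 128, 128)
    green = (26, 152, 80)
    red = (215, 48, 39)
    target = green if s < 0 else red
    f = abs(s)
    rgb = tuple(round(n + f * (t - n)) for n, t in zip(neutral, target))
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def _fmt(x: float) -> str:
    """Fixed 3-decimal coordinate formatting; avoids '-0.000'."""
    s = f"{x:.3f}"
    return "0.000" if s == "-0.000" else s


def edge_path(
    layout: Layout,
    interaction: Interaction,
    style: Style | None = None,
    offset: tuple[float, float] = (0.0, 0.0),
) -> str:
    """SVG quadratic path between the endpoints' cell centers.

    The control point sits at the midpoint, offset perpendicularly by 10%
    of the segment length; the side is fixed by the sorted endpoint order,
    so swapping endpoints yields identical geometry.  ``offset`` and the
    style scale map canvas units to pixels.
    """
    style = style or Style()
    a, b = sorted((interaction.a, interaction.b))
    for end in (a, b):
        if end not in layout.positions:
            raise KeyError(f"interaction endpoint {end!r} is not placed")
    s = style.scale
    ax, ay = layout.center(a)
    bx, by = layout.center(b)
    ax, ay = offset[0] + ax * s, offset[1] + ay * s
    bx, by = offset[0] + bx * s, offset[1] + by * s
    dx, dy = bx - ax, by - ay
    # perpendicular offset, to the left of a->b for the sorted order
    cx = (ax + bx) / 2.0 - 0.1 * dy
    cy = (ay + by) / 2.0 + 0.1 * dx
    return (
        f"M {_fmt(ax)} {_fmt(ay)} Q {_fmt(cx)} {_fmt(cy)} {_fmt(bx)} {_fmt(by)}"
    )


def _poly_path(geom: BaseGeometry, scale: float, off: tuple[float, float]) -> str:
    """SVG path data for a (Multi)Polygon, exterior + holes, evenodd."""
    if geom.is_empty:
        return ""
    polys: list[Polygon]
    if isinstance(geom, MultiPolygon):
        polys = list(geom.geoms)
    elif isinstance(geom, Polygon):
        polys = [geom]
    else:  # GeometryCollection from degenerate ops: keep polygonal parts
        polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    parts = []
    for p in polys:
        for ring in [p.exterior, *p.interiors]:
            pts = [
                f"{_fmt(off[0] + x * scale)} {_fmt(off[1] + y * scale)}"
                for x, y in ring.coords
            ]
            parts.append("M " + " L ".join(pts) + " Z")
    return " ".join(parts)


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _overview_rows(module: AnnotatedModule) -> list[tuple[str, object]]:
    """Overview entries: category headers and sets, ascending p per category."""
    rows: list[tuple[str, object]] = []
    for cat in module.categories():
        in_cat = [s for s in module.sets if s.category == cat]
        if not in_cat:
            continue
        rows.append(("category", cat))
        for s in sorted(in_cat, key=lambda s: (s.p_value, s.id)):
            rows.append(("set", s))
    return rows


def render_svg(
    module: AnnotatedModule,
    layout: Layout,
    contours: list[SetContour],
    style: Style | None = None,
) -> str:
    """Render the module as a self-contained SVG 1.1 document.

    Document z-order: set ribbons (ascending contour rank, i.e. largest
    first), link halos, link curves, dashed contour outlines, node labels.
    The set overview pane on the left lists every set grouped by category
    and sorted by ascending p-value, with significance glyphs; active
    sets carry their ribbon color.  Output is byte-identical for
    identical inputs.
    """
    style = style or Style()
    s = style.scale
    colors = assign_colors(module.active, style)
    rows = _overview_rows(module)

    net_w = layout.side * layout.tile * s
    net_h = net_w
    net_off = (style.overview_width + 2 * style.margin, style.margin)
    width = net_off[0] + net_w + style.margin
    height = max(
        net_h + 2 * style.margin,
        style.margin * 2 + style.overview_row * (len(rows) + 1),
    )

    out: list[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">'
    )
    out.append(f'<rect width="{_fmt(width)}" height="{_fmt(height)}" fill="#ffffff"/>')

    # --- network pane: ribbons, back to front -------------------------
    out.append('<g class="ribbons">')
    for c in sorted(contours, key=lambda c: c.z):
        d = _poly_path(c.ribbon, s, net_off)
        color = c.color or colors.get(c.set_id, INK)
        out.append(
            f'<path class="ribbon" data-set="{_esc(c.set_id)}" d="{d}" '
            f'fill="{color}" fill-rule="evenodd" stroke="none"/>'
        )
    out.append("</g>")

    # --- links: halos first, then curves ------------------------------
    paths = [edge_path(layout, e, style, net_off) for e in module.interactions]
    out.append('<g class="halos">')
    for d in paths:
        out.append(
            f'<path d="{d}" fill="none" stroke="#ffffff" '
            f'stroke-width="{_fmt(style.link_width + style.halo_width)}" '
            f'stroke-linecap="round"/>'
        )
    out.append("</g>")
    out.append('<g class="links">')
    for d in paths:
        out.append(
            f'<path d="{d}" fill="none" stroke="{INK}" '
            f'stroke-width="{_fmt(style.link_width)}" stroke-linecap="round"/>'
        )
    out.append("</g>")

    # --- dashed contour outlines so occluded sections can be inferred -
    out.append('<g class="outlines">')
    for c in sorted(contours, key=lambda c: c.z):
        d = _poly_path(c.body, s, net_off)
        color = c.color or colors.get(c.set_id, INK)
        out.append(
            f'<path class="outline" data-set="{_esc(c.set_id)}" d="{d}" '
            f'fill="none" stroke="{color}" '
            f'stroke-width="{_fmt(style.outline_width)}" '
            f'stroke-dasharray="{style.dash_pattern}"/>'
        )
    out.append("</g>")

    # --- node labels on white boxes with score-colored borders --------
    out.append('<g class="labels">')
    char_w = 0.62 * style.font_size  # deterministic text metrics
    for node in module.nodes:
        x, y = layout.center(node.id)
        px, py = net_off[0] + x * s, net_off[1] + y * s
        w = char_w * len(node.label) + 2 * style.label_pad
        h = style.font_size + 2 * style.label_pad
        out.append(
            f'<g class="node" data-node="{_esc(node.id)}">'
            f'<rect x="{_fmt(px - w / 2)}" y="{_fmt(py - h / 2)}" '
            f'width="{_fmt(w)}" height="{_fmt(h)}" rx="2" '
            f'fill="#ffffff" stroke="{score_color(node.score, style)}" '
            f'stroke-width="1.5"/>'
            f'<text x="{_fmt(px)}" y="{_fmt(py + 0.35 * style.font_size)}" '
            f'text-anchor="middle" font-family="{style.font_family}" '
            f'font-size="{_fmt(style.font_size)}" fill="{INK}">'
            f"{_esc(node.label)}</text></g>"
        )
    out.append("</g>")

    # --- set overview pane --------------------------------------------
    out.append('<g class="overview">')
    yy = style.margin + style.overview_row
    for kind, payload in rows:
        if kind == "category":
            out.append(
                f'<text x="{_fmt(style.margin)}" y="{_fmt(yy)}" '
                f'font-family="{style.font_family}" '
                f'font-size="{_fmt(style.font_size + 1)}" font-weight="bold" '
                f'fill="{INK}">{_esc(str(payload))}</text>'
            )
        else:
            st = payload
            radius, expo = significance_glyph(st.p_value, style)
            cx = style.margin + style.glyph_radius_max
            fill = colors.get(st.id, "#ffffff")
            active = st.id in colors
            out.append(
                f'<g class="overview-set" data-set="{_esc(st.id)}">'
                f'<circle cx="{_fmt(cx)}" cy="{_fmt(yy - 3)}" '
                f'r="{_fmt(radius)}" fill="{fill}" stroke="{INK}" '
                f'stroke-width="0.8"/>'
                f'<text x="{_fmt(cx)}" y="{_fmt(yy - 0.5)}" text-anchor="middle" '
                f'font-family="{style.font_family}" '
                f'font-size="{_fmt(style.font_size - 2)}" fill="{INK}">'
                f"{_esc(expo)}</text>"
                f'<text x="{_fmt(cx + style.glyph_radius_max + 5)}" y="{_fmt(yy)}" '
                f'font-family="{style.font_family}" '
                f'font-size="{_fmt(style.font_size)}" '
                f'fill="{"#000000" if active else INK}">'
                f"{_esc(st.label)}</text></g>"
            )
        yy += style.overview_row
    out.append("</g>")
    out.append("</svg>")
    return "\n".join(out) + "\n"
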
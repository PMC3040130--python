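"""SVG renderers for clustering results.

Two views, both emitted as self-contained SVG documents (strings):

* **multiple-cluster view** — one horizontal line per chromosome, drawn
  only from its leftmost to its rightmost cluster, all lines left-aligned
  and sharing one base-pair-to-pixel factor so relative lengths are
  comparable.  Each cluster is one glyph at its first gene's start
  coordinate, with diameter growing with member count, optionally
  labelled with the cluster ID and the first gene's position in kbp.
* **single-cluster view** — one horizontal track per expression stage;
  every member gene appears on every track at its genomic coordinate,
  glyph diameter mapped from that stage's expression value.  Zero (and
  negative) expression collapses to a point-sized glyph; a missing value
  renders hollow at point size; fill color is keyed by the gene's
  dataset label so merged datasets stay distinguishable.

Labels are separate text nodes, deliberately without collision
avoidance — the output is meant to be touched up in any SVG editor.
Glyphs carry ``class`` and ``data-*`` attributes so documents are easy
to post-process (and to test).
"""

from __future__ import annotations

import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .datamodel import Cluster, ClusterSet

_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)

SVG_NS = "http://www.w3.org/2000/svg"


@dataclass
class ViewStyle:
    """Rendering knobs shared by both views.

    ``scaling`` maps magnitude (cluster size or expression value) to
    glyph diameter: ``sqrt`` (default) makes glyph *area* proportional to
    magnitude, ``linear`` makes the diameter proportional.  ``colors``
    maps dataset labels to fill colors; labels without an entry get a
    palette color in order of first appearance.
    """

    min_diameter: float = 3.0
    max_diameter: float = 28.0
    scaling: str = "sqrt"
    glyph: str = "circle"
    colors: dict[str, str] = field(default_factory=dict)
    label_ids: bool = True
    label_kbp: bool = True
    width: float = 900.0
    track_gap: float = 60.0
    margin: float = 70.0

    def __post_init__(self) -> None:
        if self.min_diameter > self.max_diameter:
            raise ValueError("min_diameter must be <= max_diameter")
        if self.scaling not in ("linear", "sqrt"):
            raise ValueError("scaling must be 'linear' or 'sqrt'")
        if self.glyph not in ("circle", "diamond"):
            raise ValueError("glyph must be 'circle' or 'diamond'")

    def color_for(self, dset: str, order: list[str]) -> str:
        if dset in self.colors:
            return self.colors[dset]
        if dset not in order:
            order.append(dset)
        return _PALETTE[order.index(dset) % len(_PALETTE)]


def _scale01(x: float, scaling: str) -> float:
    x = min(max(x, 0.0), 1.0)
    return math.sqrt(x) if scaling == "sqrt" else x


def _diameter(value: float, vmax: float, style: ViewStyle) -> float:
    """Map a magnitude in [0, vmax] to a glyph diameter."""
    if vmax <= 0 or value <= 0:
        return style.min_diameter
    frac = _scale01(value / vmax, style.scaling)
    return style.min_diameter + (style.max_diameter - style.min_diameter) * frac


def _glyph_element(x: float, y: float, diameter: float, fill: str, style: ViewStyle,
                   cls: str, **data: str) -> ET.Element:
    attrs = {"class": cls, "fill": fill}
    attrs.update({f"data-{k.replace('_', '-')}": v for k, v in data.items()})
    attrs["data-diameter"] = f"{diameter:.3f}"
    if style.glyph == "circle":
        el = ET.Element("circle", {
            "cx": f"{x:.2f}", "cy": f"{y:.2f}", "r": f"{diameter / 2:.3f}", **attrs,
        })
    else:
        h = diameter / 2
        pts = f"{x:.2f},{y - h:.2f} {x + h:.2f},{y:.2f} {x:.2f},{y + h:.2f} {x - h:.2f},{y:.2f}"
        el = ET.Element("polygon", {"points": pts, **attrs})
    return el


def _text(x: float, y: float, content: str, cls: str, size: float = 11.0) -> ET.Element:
    el = ET.Element("text", {
        "x": f"{x:.2f}", "y": f"{y:.2f}", "class": cls,
        "font-size": f"{size:g}", "font-family": "sans-serif",
    })
    el.text = content
    return el


def _document(width: float, height: float) -> ET.Element:
    return ET.Element("svg", {
        "xmlns": SVG_NS,
        "width": f"{width:g}",
        "height": f"{height:g}",
        "viewBox": f"0 0 {width:g} {height:g}",
    })


def _tostring(root: ET.Element) -> str:
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(root, encoding="unicode")


def render_multi_cluster_view(cs: ClusterSet, style: ViewStyle | None = None) -> str:
    """Render every cluster of a run on per-chromosome lines (SVG string).

    Raises ``ValueError`` on an empty cluster set — there is nothing to
    draw.
    """
    if not cs.clusters:
        raise ValueError("nothing to draw: empty cluster set")
    style = style or ViewStyle()

    by_chrom: dict[str, list[Cluster]] = {}
    for c in cs.clusters:
        by_chrom.setdefault(c.chrom, []).append(c)

    # One shared bp->px factor across chromosomes, anchored at each
    # chromosome's leftmost cluster (lines are left-aligned).
    spans = {
        chrom: clusters[-1].first_start - clusters[0].first_start
        for chrom, clusters in by_chrom.items()
    }
    max_span = max(spans.values())
    draw_w = style.width - 2 * style.margin
    px_per_bp = draw_w / max_span if max_span > 0 else 0.0

    max_size = max(c.size for c in cs.clusters)
    height = 2 * style.margin + style.track_gap * (len(by_chrom) - 1)
    root = _document(style.width, height + style.margin)

    for row, (chrom, clusters) in enumerate(by_chrom.items()):
        y = style.margin + row * style.track_gap
        origin = clusters[0].first_start
        span_px = max(spans[chrom] * px_per_bp, style.min_diameter)
        line = ET.Element("line", {
            "x1": f"{style.margin:.2f}", "y1": f"{y:.2f}",
            "x2": f"{style.margin + span_px:.2f}", "y2": f"{y:.2f}",
            "class": "chromosome-line", "stroke": "#333", "stroke-width": "1.5",
            "data-chrom": chrom,
        })
        root.append(line)
        root.append(_text(8.0, y + 4.0, chrom, "chromosome-label"))
        for c in clusters:
            x = style.margin + (c.first_start - origin) * px_per_bp
            # Diameter grows with member count, largest cluster at max.
            d = _diameter(c.size, max_size, style)
            root.append(_glyph_element(
                x, y, d, "#4c72b0", style, "cluster-glyph",
                cluster_id=str(c.cid), size=str(c.size), chrom=chrom,
            ))
            if style.label_ids:
                root.append(_text(x, y - d / 2 - 4, str(c.cid), "cluster-id-label"))
            if style.label_kbp:
                kbp = c.first_start / 1000.0
                root.append(_text(x, y + d / 2 + 14, f"{kbp:g} kbp", "cluster-kbp-label", 9.0))
    return _tostring(root)


def render_single_cluster_view(c: Cluster, style: ViewStyle | None = None) -> str:
    """Render one cluster's members across expression stages (SVG string).

    One track per expression stage; each member gene appears on every
    track, glyph diameter following that stage's expression value.
    """
    style = style or ViewStyle()
    n_expr = len(c.members[0].expr) if c.members else 0
    n_tracks = max(n_expr, 1)

    left = c.members[0].start
    right = c.members[-1].start
    span = max(right - left, 1)
    draw_w = style.width - 2 * style.margin
    px_per_bp = draw_w / span

    finite = [v for g in c.members for v in g.expr if not math.isnan(v)]
    if any(v < 0 for v in finite):
        warnings.warn(
            "negative expression values render at point size (like zero)",
            stacklevel=2,
        )
    vmax = max([v for v in finite if v > 0], default=0.0)

    height = 2 * style.margin + style.track_gap * (n_tracks - 1)
    root = _document(style.width, height + style.margin)
    dset_order: list[str] = []

    for stage in range(n_tracks):
        y = style.margin + stage * style.track_gap
        root.append(ET.Element("line", {
            "x1": f"{style.margin:.2f}", "y1": f"{y:.2f}",
            "x2": f"{style.margin + draw_w:.2f}", "y2": f"{y:.2f}",
            "class": "stage-line", "stroke": "#999", "stroke-width": "1",
            "data-stage": str(stage + 1),
        }))
        root.append(_text(8.0, y + 4.0, f"stage {stage + 1}", "stage-label"))
        for g in c.members:
            x = style.margin + (g.start - left) * px_per_bp
            value = g.expr[stage] if stage < len(g.expr) else 0.0
            fill = style.color_for(g.dset, dset_order)
            if math.isnan(value):
                # Hollow point-sized glyph: distinguishable from true zero.
                el = _glyph_element(x, y, style.min_diameter, "none", style,
                                    "expr-glyph missing", gene=g.name,
                                    stage=str(stage + 1), dset=g.dset)
                el.set("stroke", fill)
                el.set("stroke-width", "1")
            else:
                d = _diameter(value, vmax, style)
                el = _glyph_element(x, y, d, fill, style, "expr-glyph",
                                    gene=g.name, stage=str(stage + 1), dset=g.dset)
            root.append(el)
    # Gene name labels once, below the last track.
    y_labels = style.margin + (n_tracks - 1) * style.track_gap + style.track_gap / 2 + 10
    for g in c.members:
        x = style.margin + (g.start - left) * px_per_bp
        root.append(_text(x, y_labels, g.name, "gene-label", 9.0))
    return _tostring(root)
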
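"""Circular composition plots.

The plot places every reference species on a circle in phylogenetic order,
with the arc between circularly adjacent species proportional to their
K2P distance, so tight clades cluster visually. Five concentric rings mark
average-similarity boundaries at 80, 85, 90, 95 and 100%; each read
cluster is drawn as a dot at its reference's angle and a radius given by
its similarity, sized by one of four relative-abundance categories. The
merged two-sample plot recolors dots by the cluster partition: gray for
common clusters, green for sample-A-only, orange for sample-B-only, and
prints the three similarity indices in the lower right.

Output is SVG 1.1, written by a small deterministic template writer so
identical inputs give byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from amplicirc.profiles import ClusterKey, ComparisonResult, SampleProfile
from amplicirc.refdb import ReferencePanel

RING_SIMILARITIES = (80, 85, 90, 95, 100)
MIN_ARC_DEG = 0.1

#: dot radius in px per relative-abundance category
DOT_RADIUS_PX = {1: 2.0, 2: 4.0, 3: 6.5, 4: 9.5}

COLOR_COMMON = "#808080"
COLOR_ONLY_A = "#2ca02c"
COLOR_ONLY_B = "#ff8c00"

_CANVAS = 820.0
_CENTER = _CANVAS / 2.0


@dataclass
class LayoutModel:
    """Angular and radial geometry of the circular plot."""

    angle: dict[str, float]           # ref id -> degrees in [0, 360)
    ring_radii: dict[int, float]      # similarity percent -> radius
    r_inner: float
    r_outer: float

    def __post_init__(self):
        if set(self.ring_radii) != set(RING_SIMILARITIES):
            raise ValueError("ring radii must cover 80/85/90/95/100%")


def compute_layout(panel: ReferencePanel, r_inner: float = 110.0,
                   r_outer: float = 310.0) -> LayoutModel:
    """Angles from adjacent-leaf K2P distances; rings linearly spaced.

    Arc between circularly adjacent species (including the closing arc
    from the last back to the first) is proportional to their pairwise
    distance, normalized so the arcs sum to 360 degrees. Zero distances
    are assigned a fixed minimum arc of 0.1 degrees and the remaining
    angular budget is split proportionally among the nonzero distances.
    """
    order = panel.leaf_order
    if len(order) < 2:
        raise ValueError("layout needs at least 2 references")
    n = len(order)
    gaps = [panel.distances.get(order[i], order[(i + 1) % n])
            for i in range(n)]
    nonzero_total = sum(g for g in gaps if g > 0.0)
    if nonzero_total == 0.0:
        raise ValueError("all adjacent pairwise distances are zero; "
                         "no angular layout exists")
    n_zero = sum(1 for g in gaps if g == 0.0)
    budget = 360.0 - MIN_ARC_DEG * n_zero
    arcs = [MIN_ARC_DEG if g == 0.0 else g * budget / nonzero_total
            for g in gaps]
    angle = {}
    acc = 0.0
    for rid, arc in zip(order, arcs):
        angle[rid] = acc
        acc += arc
    ring_radii = {s: r_inner + (s - 80) / 20.0 * (r_outer - r_inner)
                  for s in RING_SIMILARITIES}
    return LayoutModel(angle=angle, ring_radii=ring_radii,
                       r_inner=r_inner, r_outer=r_outer)


def radial_position(avg_similarity: float,
                    layout: LayoutModel) -> tuple[float, bool]:
    """Map similarity in [80, 100] linearly onto [r_inner, r_outer].

    Values below 80 clamp to the inner ring and set the below-range flag;
    values above 100 are invalid.
    """
    if avg_similarity > 100.0:
        raise ValueError(f"similarity {avg_similarity} exceeds 100%")
    if avg_similarity < 80.0:
        return layout.r_inner, True
    frac = (avg_similarity - 80.0) / 20.0
    return layout.r_inner + frac * (layout.r_outer - layout.r_inner), False


def dot_size_category(rel_abundance: float) -> int:
    """Four abundance bins: <1% -> 1, <5% -> 2, <10% -> 3, >=10% -> 4."""
    if rel_abundance <= 0.0:
        raise ValueError("relative abundance must be positive")
    if rel_abundance < 0.01:
        return 1
    if rel_abundance < 0.05:
        return 2
    if rel_abundance < 0.10:
        return 3
    return 4


def _xy(angle_deg: float, radius: float) -> tuple[float, float]:
    # 0 degrees at 12 o'clock, increasing clockwise
    rad = math.radians(angle_deg - 90.0)
    return (_CENTER + radius * math.cos(rad),
            _CENTER + radius * math.sin(rad))


def _f(x: float) -> str:
    return f"{x:.3f}"


def _esc(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;"))


def _svg_open(parts: list[str]) -> None:
    parts.append(
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(_CANVAS)}" height="{_f(_CANVAS)}" '
        f'viewBox="0 0 {_f(_CANVAS)} {_f(_CANVAS)}">\n'
        f'<rect width="{_f(_CANVAS)}" height="{_f(_CANVAS)}" '
        'fill="white"/>\n')


def _rings(parts: list[str], layout: LayoutModel) -> None:
    for sim in RING_SIMILARITIES:
        r = layout.ring_radii[sim]
        parts.append(
            f'<circle class="ring" cx="{_f(_CENTER)}" cy="{_f(_CENTER)}" '
            f'r="{_f(r)}" fill="none" stroke="#bbbbbb" '
            'stroke-width="0.8"/>\n')
        parts.append(
            f'<text class="ring-label" x="{_f(_CENTER + 4)}" '
            f'y="{_f(_CENTER - r - 3)}" font-size="10" '
            f'fill="#666666">{sim}%</text>\n')


def _species_labels(parts: list[str], panel: ReferencePanel,
                    layout: LayoutModel) -> None:
    r_label = layout.r_outer + 10.0
    for rid in panel.leaf_order:
        rec = panel.record(rid)
        color = panel.phylum_palette[rec.phylum]
        ang = layout.angle[rid]
        x, y = _xy(ang, r_label)
        rot = ang - 90.0
        anchor = "start"
        if 180.0 <= ang < 360.0:
            rot += 180.0
            anchor = "end"
        parts.append(
            f'<text class="species" x="{_f(x)}" y="{_f(y)}" '
            f'font-size="9" font-style="italic" fill="{color}" '
            f'text-anchor="{anchor}" '
            f'transform="rotate({_f(rot)} {_f(x)} {_f(y)})">'
            f'{_esc(rec.species)}</text>\n')


def _dot(parts: list[str], layout: LayoutModel, ref_id: str,
         similarity: float, category: int, color: str) -> bool:
    radius, below = radial_position(similarity, layout)
    x, y = _xy(layout.angle[ref_id], radius)
    parts.append(
        f'<circle class="dot" cx="{_f(x)}" cy="{_f(y)}" '
        f'r="{_f(DOT_RADIUS_PX[category])}" fill="{color}" '
        'fill-opacity="0.75"/>\n')
    return below


def _size_legend(parts: list[str], x: float, y: float) -> None:
    labels = {1: "&lt;1%", 2: "&lt;5%", 3: "&lt;10%", 4: "&#8805;10%"}
    parts.append(f'<text x="{_f(x)}" y="{_f(y)}" font-size="11" '
                 'fill="#333333">relative abundance</text>\n')
    for i, cat in enumerate((1, 2, 3, 4)):
        cy = y + 16 + 20 * i
        parts.append(
            f'<circle cx="{_f(x + 8)}" cy="{_f(cy)}" '
            f'r="{_f(DOT_RADIUS_PX[cat])}" fill="#555555"/>\n')
        parts.append(
            f'<text x="{_f(x + 24)}" y="{_f(cy + 4)}" font-size="10" '
            f'fill="#333333">{labels[cat]}</text>\n')


def _check_refs(profile: SampleProfile, panel: ReferencePanel) -> None:
    for key in profile.clusters:
        if key[0] not in panel:
            raise ValueError(f"cluster references unknown id: {key[0]}")


def render_single(profile: SampleProfile, panel: ReferencePanel,
                  layout: LayoutModel, out_path: str | Path) -> Path:
    """Single-sample circular plot: one dot per cluster, phylum-colored."""
    _check_refs(profile, panel)
    parts: list[str] = []
    _svg_open(parts)
    parts.append(f'<title>{_esc(profile.sample_name)}</title>\n')
    _rings(parts, layout)
    _species_labels(parts, panel, layout)
    any_below = False
    for key in sorted(profile.clusters):
        c = profile.clusters[key]
        color = panel.phylum_palette[panel.record(c.ref_id).phylum]
        below = _dot(parts, layout, c.ref_id, c.sim_floor + 0.5,
                     dot_size_category(c.rel_abundance), color)
        any_below = any_below or below
    _size_legend(parts, _CANVAS - 130, 30)
    if any_below:
        parts.append(
            f'<text class="below-range" x="{_f(_CANVAS - 130)}" '
            f'y="{_f(130)}" font-size="10" fill="#aa0000">'
            '* clusters &lt;80% shown on the 80% ring</text>\n')
    parts.append("</svg>\n")
    return _write(parts, out_path)


def render_merged(a: SampleProfile, b: SampleProfile,
                  comparison: ComparisonResult, panel: ReferencePanel,
                  layout: LayoutModel, out_path: str | Path) -> Path:
    """Merged two-sample plot over the union of cluster keys.

    Common clusters gray, clusters unique to sample A green, unique to
    sample B orange; dot size from the larger of the two samples'
    abundances; the three indices printed in the lower right.
    """
    _check_refs(a, panel)
    _check_refs(b, panel)
    parts: list[str] = []
    _svg_open(parts)
    parts.append(f'<title>{_esc(a.sample_name)} vs '
                 f'{_esc(b.sample_name)}</title>\n')
    _rings(parts, layout)
    _species_labels(parts, panel, layout)
    colors: dict[ClusterKey, str] = {}
    for key in comparison.shared_keys:
        colors[key] = COLOR_COMMON
    for key in comparison.unique_to_a:
        colors[key] = COLOR_ONLY_A
    for key in comparison.unique_to_b:
        colors[key] = COLOR_ONLY_B
    any_below = False
    for key in sorted(colors):
        ref_id, sim_floor = key
        abundance = max(a.abundance(key), b.abundance(key))
        below = _dot(parts, layout, ref_id, sim_floor + 0.5,
                     dot_size_category(abundance), colors[key])
        any_below = any_below or below
    _size_legend(parts, _CANVAS - 130, 30)
    legend = ((COLOR_COMMON, "common"),
              (COLOR_ONLY_A, f"{a.sample_name} only"),
              (COLOR_ONLY_B, f"{b.sample_name} only"))
    for i, (color, label) in enumerate(legend):
        cy = 130 + 18 * i
        parts.append(f'<circle cx="{_f(_CANVAS - 122)}" cy="{_f(cy)}" '
                     f'r="5" fill="{color}"/>\n')
        parts.append(f'<text x="{_f(_CANVAS - 110)}" y="{_f(cy + 4)}" '
                     f'font-size="10" fill="#333333">{_esc(label)}'
                     '</text>\n')
    indices = (("Jaccard", comparison.jaccard),
               ("Lennon", comparison.lennon),
               ("Yue-Clayton theta", comparison.theta))
    for i, (name, value) in enumerate(indices):
        text = f"{name}: {value:.4f}" if value is not None else name
        parts.append(
            f'<text class="index" x="{_f(_CANVAS - 180)}" '
            f'y="{_f(_CANVAS - 60 + 16 * i)}" font-size="11" '
            f'fill="#333333">{_esc(text)}</text>\n')
    if any_below:
        parts.append(
            f'<text class="below-range" x="{_f(_CANVAS - 130)}" '
            f'y="{_f(196)}" font-size="10" fill="#aa0000">'
            '* clusters &lt;80% shown on the 80% ring</text>\n')
    parts.append("</svg>\n")
    return _write(parts, out_path)


def _write(parts: list[str], out_path: str | Path) -> Path:
    out_path = Path(out_path)
    out_path.write_text("".join(parts))
    return out_path
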
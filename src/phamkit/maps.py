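"""Phamerator-style pairwise genome comparison maps as SVG.

Each genome is drawn as a ruler with 1-kbp labels and 100-bp tick marks.
Genes are boxes above the ruler when transcribed rightwards (+ strand)
and below when leftwards (-), filled by a deterministic pham -> color
mapping (orphams are white), labelled with the gene name inside the box
and the pham id with its member count in parentheses above it; putative
function strings are rendered when present. Between consecutive rulers,
nucleotide similarity segments (HSPs at or below the E-value threshold)
are shaded quadrilaterals, spectrum-colored by identity fraction from
violet (most similar) through red (least similar passing the filter).

SVG is emitted as plain XML so tests can assert fill colors and geometry
textually; elements carry class and data-* attributes for that purpose.
"""

from __future__ import annotations

import hashlib
import xml.etree.ElementTree as ET
from typing import Mapping, Optional, Sequence

from .metrics import Hsp
from .records import GenomeRecord, Pham

ORPHAM_FILL = "#FFFFFF"

# Fixed palette for pham fills (orphams are always white).
PALETTE = [
    "#E6194B", "#3CB44B", "#FFE119", "#4363D8", "#F58231", "#911EB4",
    "#46F0F0", "#F032E6", "#BCF60C", "#FABEBE", "#008080", "#E6BEFF",
    "#9A6324", "#FFFAC8", "#800000", "#AAFFC3", "#808000", "#FFD8B1",
    "#000075", "#808080", "#A9A9A9", "#FF69B4", "#1E90FF", "#2E8B57",
    "#DAA520", "#8B008B", "#FF6347", "#40E0D0",
]

PX_PER_BP = 0.05
MARGIN_X = 60.0
BAND_HEIGHT = 150.0
BOX_HEIGHT = 16.0
RULER_GAP = 8.0


def pham_color(pham_id: str, n_members: int) -> str:
    """Deterministic pham fill color; orphams are white."""
    if n_members <= 1:
        return ORPHAM_FILL
    digest = hashlib.md5(pham_id.encode("utf-8")).hexdigest()
    return PALETTE[int(digest, 16) % len(PALETTE)]


def identity_hue(identity: float, min_identity: float) -> float:
    """Linear hue: identity 1.0 -> 270 (violet), min passing -> 0 (red)."""
    if min_identity >= 1.0:
        return 270.0
    frac = (identity - min_identity) / (1.0 - min_identity)
    return 270.0 * max(0.0, min(1.0, frac))


def _clip(lo: float, hi: float, window: tuple[float, float]) -> Optional[tuple[float, float]]:
    a, b = max(lo, window[0]), min(hi, window[1])
    return (a, b) if a < b else None


def render_comparison_map(
    genomes: Sequence[GenomeRecord],
    phams: Sequence[Pham],
    hsps: Mapping[tuple[str, str], Sequence[Hsp]],
    evalue_max: float = 1e-4,
    window: Optional[tuple[int, int]] = None,
    px_per_bp: float = PX_PER_BP,
) -> str:
    """Render an ordered stack of genomes with inter-genome shading.

    ``hsps`` maps (upper_genome_id, lower_genome_id) for each consecutive
    pair to that pair's HSP list (upper genome as query). A window
    (bp_lo, bp_hi) restricts the view for zoomed figures.
    """
    if not genomes:
        raise ValueError("need at least one genome")
    sizes = {p.pham_id: len(p) for p in phams}
    ids = [g.genome_id for g in genomes]
    for g in genomes:
        for gene in g.genes:
            if gene.pham_id is None or gene.pham_id not in sizes:
                raise ValueError(
                    f"gene {gene.gene_id} in {g.genome_id} has no pham assignment"
                )
    for (a, b) in hsps:
        if a not in ids or b not in ids:
            raise ValueError(f"hsp pair ({a}, {b}) names a genome not in the figure")

    max_len = max(len(g) for g in genomes)
    win = (0.0, float(max_len)) if window is None else (float(window[0]), float(window[1]))
    if win[0] >= win[1]:
        raise ValueError(f"empty window {window}")

    width = MARGIN_X * 2 + (win[1] - win[0]) * px_per_bp
    height = BAND_HEIGHT * len(genomes) + 40.0

    def x_of(bp: float) -> float:
        return MARGIN_X + (bp - win[0]) * px_per_bp

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "width": f"{width:.1f}",
            "height": f"{height:.1f}",
            "viewBox": f"0 0 {width:.1f} {height:.1f}",
        },
    )
    ET.SubElement(svg, "rect", {"x": "0", "y": "0", "width": f"{width:.1f}",
                                "height": f"{height:.1f}", "fill": "white"})

    ruler_y = {gid: BAND_HEIGHT * (i + 0.5) + 20.0 for i, gid in enumerate(ids)}

    # Collect passing HSPs first: the spectrum floor is the lowest identity
    # fraction that passes the E-value filter anywhere in the figure.
    passing: dict[tuple[str, str], list[Hsp]] = {}
    for pair, hlist in hsps.items():
        keep = [h for h in hlist if h.evalue <= evalue_max]
        if keep:
            passing[pair] = keep
    min_identity = min(
        (h.identity_fraction for hlist in passing.values() for h in hlist),
        default=1.0,
    )

    # Shading between consecutive rulers (drawn first, under the genes).
    for upper, lower in zip(ids, ids[1:]):
        pair_hsps = passing.get((upper, lower))
        flipped = False
        if pair_hsps is None:
            pair_hsps = passing.get((lower, upper))
            flipped = pair_hsps is not None
        if not pair_hsps:
            continue
        y_top = ruler_y[upper] + RULER_GAP + BOX_HEIGHT + 4
        y_bot = ruler_y[lower] - RULER_GAP - BOX_HEIGHT - 18
        for h in pair_hsps:
            q_iv, s_iv = (h.q_start, h.q_end), (h.s_start, h.s_end)
            if flipped:
                q_iv, s_iv = s_iv, q_iv
            qc = _clip(*q_iv, win)
            sc = _clip(*s_iv, win)
            if qc is None or sc is None:
                continue
            hue = identity_hue(h.identity_fraction, min_identity)
            pts = (
                f"{x_of(qc[0]):.1f},{y_top:.1f} {x_of(qc[1]):.1f},{y_top:.1f} "
                f"{x_of(sc[1]):.1f},{y_bot:.1f} {x_of(sc[0]):.1f},{y_bot:.1f}"
            )
            ET.SubElement(
                svg,
                "polygon",
                {
                    "class": "hsp",
                    "points": pts,
                    "fill": f"hsl({hue:.0f}, 85%, 60%)",
                    "fill-opacity": "0.7",
                    "stroke": "none",
                    "data-identity": f"{h.identity_fraction:.4f}",
                    "data-evalue": f"{h.evalue:.3g}",
                    "data-strand": h.strand,
                },
            )

    for g in genomes:
        y = ruler_y[g.genome_id]
        g_win = _clip(0, len(g), win)
        if g_win is None:
            continue
        ET.SubElement(
            svg,
            "line",
            {
                "class": "ruler",
                "x1": f"{x_of(g_win[0]):.1f}",
                "x2": f"{x_of(g_win[1]):.1f}",
                "y1": f"{y:.1f}",
                "y2": f"{y:.1f}",
                "stroke": "black",
                "stroke-width": "1",
                "data-genome": g.genome_id,
            },
        )
        ET.SubElement(svg, "text", {
            "x": f"{MARGIN_X - 50:.1f}", "y": f"{y - BAND_HEIGHT / 2 + 14:.1f}",
            "class": "genome-label", "font-size": "11",
        }).text = g.genome_id
        bp = int(g_win[0]) - int(g_win[0]) % 100
        while bp <= g_win[1]:
            if g_win[0] <= bp <= min(len(g), g_win[1]):
                major = bp % 1000 == 0
                tick_h = 6.0 if major else 3.0
                ET.SubElement(svg, "line", {
                    "class": "tick-major" if major else "tick-minor",
                    "x1": f"{x_of(bp):.1f}", "x2": f"{x_of(bp):.1f}",
                    "y1": f"{y:.1f}", "y2": f"{y + tick_h:.1f}",
                    "stroke": "black", "stroke-width": "0.5",
                })
                if major:
                    t = ET.SubElement(svg, "text", {
                        "x": f"{x_of(bp):.1f}", "y": f"{y + 16:.1f}",
                        "class": "kbp-label", "font-size": "8",
                        "text-anchor": "middle",
                    })
                    t.text = str(bp // 1000)
            bp += 100

        for gene in g.genes:
            iv = _clip(gene.start, gene.end, win)
            if iv is None:
                continue
            x0, x1 = x_of(iv[0]), x_of(iv[1])
            above = gene.strand == "+"
            box_y = y - RULER_GAP - BOX_HEIGHT if above else y + RULER_GAP
            fill = pham_color(gene.pham_id, sizes[gene.pham_id])
            ET.SubElement(
                svg,
                "rect",
                {
                    "class": "gene",
                    "x": f"{x0:.1f}",
                    "y": f"{box_y:.1f}",
                    "width": f"{x1 - x0:.1f}",
                    "height": f"{BOX_HEIGHT:.1f}",
                    "fill": fill,
                    "stroke": "black",
                    "stroke-width": "0.75",
                    "data-gene": gene.gene_id,
                    "data-pham": gene.pham_id,
                    "data-strand": gene.strand,
                },
            )
            label = ET.SubElement(svg, "text", {
                "x": f"{(x0 + x1) / 2:.1f}",
                "y": f"{box_y + BOX_HEIGHT - 4:.1f}",
                "class": "gene-label", "font-size": "8", "text-anchor": "middle",
            })
            label.text = gene.name or gene.gene_id
            pham_text = ET.SubElement(svg, "text", {
                "x": f"{(x0 + x1) / 2:.1f}",
                "y": f"{box_y - 3:.1f}" if above else f"{box_y + BOX_HEIGHT + 9:.1f}",
                "class": "pham-label", "font-size": "7", "text-anchor": "middle",
            })
            pham_text.text = f"{gene.pham_id} ({sizes[gene.pham_id]})"
            if gene.function:
                fn = ET.SubElement(svg, "text", {
                    "x": f"{(x0 + x1) / 2:.1f}",
                    "y": f"{box_y - 13:.1f}" if above else f"{box_y + BOX_HEIGHT + 19:.1f}",
                    "class": "function-label", "font-size": "7",
                    "text-anchor": "middle", "font-style": "italic",
                })
                fn.text = gene.function

    return ET.tostring(svg, encoding="unicode")


def write_comparison_map(path: str, *args, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0" encoding="UTF-8"?>\n')
        fh.write(render_comparison_map(*args, **kwargs))
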
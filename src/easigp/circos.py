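"""Layered circos plot of inferred genetic architecture.

Rings, innermost to outermost: annotation tracks (QTL, SAM, leaf), the six
model rings, then the ensemble ring. Ring cells are marker regions padded
by 0.2 cM and shaded by the 10-quantile level of the marker-effect
magnitude (blue ramp for individual models, orange for the ensemble).
Links are the top fraction of pairwise interaction magnitudes, red within
a chromosome and blue between chromosomes, width proportional to strength.

Rendered with matplotlib on a polar axis; every ring cell and link is also
exported as TSV so plots are diffable without image comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from matplotlib.patches import PathPatch
from scipy.stats import rankdata

from .attribution import InteractionMatrix
from .data_io import AnnotationTrack, GeneticMap

MODEL_RING_ORDER = ("GAT", "SVR", "RF", "RKHS", "BayesB", "rrBLUP")
ANNOTATION_RING_ORDER = ("QTL", "SAM", "leaf")
PAD_CM = 0.2
TOP_LINK_FRACTION = 0.0001

# 10-step monotone luminance ramps, level 1 (lightest) .. 10 (darkest)
BLUE_RAMP = [f"#{int(230 - 21 * k):02x}{int(238 - 18 * k):02x}ff" for k in range(10)]
ORANGE_RAMP = [f"#ff{int(230 - 19 * k):02x}{int(200 - 22 * k):02x}" for k in range(10)]
ANNOTATION_COLORS = {"QTL": "#7a7a7a", "SAM": "#3f9b6e", "leaf": "#97c01d"}


@dataclass
class RingTrack:
    name: str
    cells: list                    # (chrom, start_cM, end_cM, level_or_label)
    palette: str = "blue"          # blue | orange | annotation


@dataclass
class LinkSet:
    links: list = field(default_factory=list)
    # each link: (chrom_a, pos_a, chrom_b, pos_b, strength, klass)

    def __post_init__(self):
        for (_, _, _, _, strength, klass) in self.links:
            if strength <= 0:
                raise ValueError("link strength must be positive")
            if klass not in ("within", "between"):
                raise ValueError(f"bad link class {klass!r}")

    def __len__(self):
        return len(self.links)


@dataclass
class CircosLayout:
    gmap: GeneticMap
    rings: list                    # RingTracks, innermost first

    @property
    def segments(self) -> list:
        """(chromosome, length cM) in chromosome order."""
        return [(c, self.gmap.chromosome_lengths[c]) for c in self.gmap.chromosomes]


def decile_bins(scores) -> np.ndarray:
    """10-quantile level (1..10, 10 = strongest) of each |score|.

    Levels come from average ranks, so ties share a level and with distinct
    scores each level holds floor(P/10)..ceil(P/10) markers.
    """
    a = np.abs(np.asarray(scores, dtype=float))
    if a.size == 0:
        raise ValueError("no scores")
    ranks = rankdata(a, method="average")
    return np.ceil(ranks * 10.0 / a.size).astype(int)


def extend_regions(gmap: GeneticMap, markers, pad_cM: float = PAD_CM):
    """[pos - pad, pos + pad] per marker, clipped to its chromosome."""
    out = []
    for m in markers:
        if m not in gmap:
            raise KeyError(f"marker {m!r} not in genetic map")
        c, pos = gmap.positions[m]
        L = gmap.chromosome_lengths[c]
        out.append((c, max(0.0, pos - pad_cM), min(L, pos + pad_cM)))
    return out


def select_top_interactions(im: InteractionMatrix, gmap: GeneticMap,
                            fraction: float = TOP_LINK_FRACTION) -> LinkSet:
    """Keep the k = max(1, ceil(fraction * n_pairs)) largest-magnitude pairs
    as links; zero-strength links are suppressed."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction outside (0, 1]")
    n = len(im.marker_names)
    if n < 2:
        raise ValueError("need at least two markers for interactions")
    iu = np.triu_indices(n, 1)
    mags = np.abs(im.M[iu])
    n_pairs = len(mags)
    k = max(1, int(np.ceil(fraction * n_pairs)))
    order = np.argsort(mags)[::-1][:k]
    links = []
    for o in order:
        s = float(mags[o])
        if s <= 0:
            continue
        ma, mb = im.marker_names[iu[0][o]], im.marker_names[iu[1][o]]
        if ma not in gmap or mb not in gmap:
            raise KeyError(f"marker {ma if ma not in gmap else mb!r} not in genetic map")
        ca, pa = gmap.positions[ma]
        cb, pb = gmap.positions[mb]
        links.append((ca, pa, cb, pb, s, "within" if ca == cb else "between"))
    return LinkSet(links)


def build_layout(gmap: GeneticMap, effect_profiles: dict,
                 annotations: list | None = None,
                 pad_cM: float = PAD_CM) -> CircosLayout:
    """Assemble rings: annotations innermost, then model rings (fixed
    order), then the ensemble ring outermost.

    ``effect_profiles`` maps ring name -> MarkerEffectProfile; markers
    absent from the map are skipped (they cannot be placed).
    """
    rings = []
    by_name = {t.name: t for t in (annotations or [])}
    for name in ANNOTATION_RING_ORDER:
        if name in by_name:
            t = by_name[name]
            t.validate(gmap)
            rings.append(RingTrack(name, [(c, s, e, lab) for (c, s, e, lab, _) in t.regions],
                                   palette="annotation"))
    for t in (annotations or []):
        if t.name not in ANNOTATION_RING_ORDER:
            t.validate(gmap)
            rings.append(RingTrack(t.name, [(c, s, e, lab) for (c, s, e, lab, _) in t.regions],
                                   palette="annotation"))

    for name in list(MODEL_RING_ORDER) + ["Ensemble"]:
        if name not in effect_profiles:
            continue
        prof = effect_profiles[name]
        placeable = [(m, s) for m, s in zip(prof.marker_names, prof.scores) if m in gmap]
        if not placeable:
            raise ValueError(f"no marker of ring {name!r} is on the genetic map")
        markers, scores = zip(*placeable)
        levels = decile_bins(scores)
        regions = extend_regions(gmap, markers, pad_cM)
        cells = [(c, s, e, int(lv)) for (c, s, e), lv in zip(regions, levels)]
        rings.append(RingTrack(name, cells,
                               palette="orange" if name == "Ensemble" else "blue"))
    for ring in rings:
        for (c, *_rest) in ring.cells:
            if c not in gmap.chromosome_lengths:
                raise ValueError(f"ring {ring.name!r} references unknown chromosome {c}")
    return CircosLayout(gmap, rings)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _angles(layout: CircosLayout, gap_deg: float = 2.0):
    segs = layout.segments
    total = sum(length for _, length in segs)
    avail = 360.0 - gap_deg * len(segs)
    spans, cursor = {}, 0.0
    for c, length in segs:
        width = avail * length / total if total > 0 else avail / len(segs)
        spans[c] = (cursor, cursor + width, length)
        cursor += width + gap_deg
    return spans


def _theta(spans, chrom, pos):
    a0, a1, length = spans[chrom]
    frac = 0.0 if length == 0 else pos / length
    return np.deg2rad(a0 + frac * (a1 - a0))


def layout_to_frame(layout: CircosLayout) -> pd.DataFrame:
    rows = [(r.name, c, s, e, str(v)) for r in layout.rings for (c, s, e, v) in r.cells]
    return pd.DataFrame(rows, columns=["ring", "chrom", "start_cM", "end_cM", "level_or_label"])


def links_to_frame(links: LinkSet) -> pd.DataFrame:
    return pd.DataFrame(links.links,
                        columns=["chrom_a", "pos_a", "chrom_b", "pos_b", "strength", "class"])


def render(layout: CircosLayout, links: LinkSet | None, out_svg,
           out_png=None, tracks_tsv=None, links_tsv=None, figsize: float = 9.0):
    """Draw the circos plot (SVG, optionally PNG) and export the plain-data
    track/link tables."""
    spans = _angles(layout)
    n_rings = len(layout.rings)
    r0, r1 = 0.35, 0.97
    thick = (r1 - r0) / max(n_rings, 1)

    fig = plt.figure(figsize=(figsize, figsize))
    ax = fig.add_subplot(111, projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_ylim(0, 1.12)
    ax.axis("off")

    for c, (a0, a1, length) in spans.items():
        th = np.deg2rad(np.linspace(a0, a1, 60))
        ax.plot(th, np.full_like(th, 1.0), color="black", lw=1.2)
        ax.text(np.deg2rad((a0 + a1) / 2), 1.07, str(c), ha="center", va="center", fontsize=9)

    for k, ring in enumerate(layout.rings):
        inner = r0 + k * thick
        for (c, s, e, v) in ring.cells:
            th0, th1 = _theta(spans, c, s), _theta(spans, c, e)
            if ring.palette == "annotation":
                color = ANNOTATION_COLORS.get(ring.name, "#888888")
            else:
                ramp = ORANGE_RAMP if ring.palette == "orange" else BLUE_RAMP
                color = ramp[int(v) - 1]
            th = np.linspace(th0, max(th1, th0 + 1e-4), 8)
            ax.fill_between(th, inner, inner + thick * 0.85, color=color, linewidth=0)
        ax.text(np.deg2rad(359.0), inner + thick * 0.4, ring.name,
                fontsize=6, ha="left", va="center")

    if links is not None and len(links):
        strengths = np.array([l[4] for l in links.links])
        smax = strengths.max()
        for (ca, pa, cb, pb, s, klass) in links.links:
            th_a, th_b = _theta(spans, ca, pa), _theta(spans, cb, pb)
            color = "#d62728" if klass == "within" else "#1f77b4"
            verts = [(th_a, r0), ((th_a + th_b) / 2, 0.0), (th_b, r0)]
            path = MplPath(verts, [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3])
            ax.add_patch(PathPatch(path, fill=False, edgecolor=color,
                                   lw=0.5 + 2.5 * s / smax, alpha=0.8))

    fig.savefig(out_svg, format="svg", bbox_inches="tight")
    if out_png is not None:
        fig.savefig(out_png, format="png", dpi=150, bbox_inches="tight")
    plt.close(fig)

    if tracks_tsv is not None:
        layout_to_frame(layout).to_csv(tracks_tsv, sep="\t", index=False)
    if links_tsv is not None:
        links_to_frame(links if links is not None else LinkSet()).to_csv(
            links_tsv, sep="\t", index=False)
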
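"""Static rendering and colour schemes for simulated nuclei.

Colouring mirrors how painted territories are presented in cytogenetics:

* ``arms`` mode highlights one homologous pair, top arms in one colour and
  bottom arms in another (centromeres follow the top arm);
* ``pairs`` mode highlights up to two heterologous pairs, one colour per
  pair, without distinguishing arms.

All other chromatin is drawn white, or omitted entirely in ``transparent``
background mode.  The nucleolus is always drawn as a yellow sphere.  At
most two pairs may be highlighted and at most four distinct highlight
colours exist.

Rendering is a pure function producing a static raster image
(matplotlib 3-D); :func:`export_scene` writes the same scene as a flat
tab-separated file (coordinates + RGBA) loadable by generic 3-D tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless by design; only static output is produced
import matplotlib.pyplot as plt
import numpy as np

from .model import NucleusModel

__all__ = ["ColourScheme", "render_scene", "export_scene", "NUCLEOLUS_COLOUR"]

RGBA = tuple[float, float, float, float]

NUCLEOLUS_COLOUR: RGBA = (1.0, 0.85, 0.0, 0.9)  # yellow
_WHITE: RGBA = (1.0, 1.0, 1.0, 0.25)
_HIDDEN: RGBA = (1.0, 1.0, 1.0, 0.0)

# caption-matching defaults: top/green, bottom/red; pair1/green, pair2/red
_GREEN: RGBA = (0.1, 0.8, 0.1, 1.0)
_RED: RGBA = (0.9, 0.1, 0.1, 1.0)
_BLUE: RGBA = (0.15, 0.3, 0.9, 1.0)
_MAGENTA: RGBA = (0.85, 0.1, 0.8, 1.0)


@dataclass(frozen=True)
class ColourScheme:
    """Pure mapping from (chromosome, arm) to an RGBA colour.

    ``mode="arms"`` takes exactly one highlighted pair and colours its
    top/bottom arms with ``colours[0]``/``colours[1]``; ``mode="pairs"``
    takes one or two pairs, each coloured uniformly.  ``background`` is
    ``"white"`` (dim white chromatin) or ``"transparent"`` (hidden).
    """

    mode: str  # "arms" | "pairs"
    highlight: tuple[int, ...]
    colours: tuple[RGBA, ...] = field(default=(_GREEN, _RED, _BLUE, _MAGENTA))
    background: str = "white"

    def __post_init__(self) -> None:
        if self.mode not in ("arms", "pairs"):
            raise ValueError("mode must be 'arms' or 'pairs'")
        if self.background not in ("white", "transparent"):
            raise ValueError("background must be 'white' or 'transparent'")
        object.__setattr__(self, "highlight", tuple(self.highlight))
        object.__setattr__(self, "colours", tuple(self.colours))
        n = len(self.highlight)
        if self.mode == "arms" and n != 1:
            raise ValueError("'arms' mode highlights exactly one homologous pair")
        if self.mode == "pairs" and not (1 <= n <= 2):
            raise ValueError("'pairs' mode highlights one or two pairs")
        if len(self.colours) > 4:
            raise ValueError("at most four highlight colours")

    def validate_against(self, model: NucleusModel) -> None:
        for pair in self.highlight:
            if not (1 <= pair <= model.config.chr_pair):
                raise ValueError(f"scheme references absent chromosome pair {pair}")

    def colour_of(self, chromosome: int, arm: str) -> RGBA:
        pair = (chromosome + 1) // 2
        if pair in self.highlight:
            if self.mode == "arms":
                # centromere rides with the top arm
                return self.colours[0] if arm in ("top", "cen") else self.colours[1]
            return self.colours[self.highlight.index(pair)]
        return _WHITE if self.background == "white" else _HIDDEN


def _scene_records(model: NucleusModel, scheme: ColourScheme):
    scheme.validate_against(model)
    for b in model.beads:
        yield b.position, b.radius, scheme.colour_of(b.chromosome, b.arm)


def render_scene(
    model: NucleusModel,
    scheme: ColourScheme,
    path: str | Path,
    elev: float = 20.0,
    azim: float = -60.0,
    dpi: int = 150,
) -> Path:
    """Render the nucleus as a static raster image (camera set by elev/azim).

    Beads are drawn as shaded discs scaled to their radius, the nucleolus
    as a yellow sphere and the nuclear envelope as a faint wireframe.  The
    model is not modified.
    """
    path = Path(path)
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    R = model.nucleus.radius

    # nuclear envelope: sparse wireframe
    u = np.linspace(0, 2 * np.pi, 24)
    v = np.linspace(0, np.pi, 12)
    xs = R * np.outer(np.cos(u), np.sin(v))
    ys = R * np.outer(np.sin(u), np.sin(v))
    zs = R * np.outer(np.ones_like(u), np.cos(v))
    ax.plot_wireframe(xs, ys, zs, color="0.85", linewidth=0.3)

    # nucleolus as a solid sphere
    no = model.nucleolus
    ax.plot_surface(
        no.centre[0] + no.radius / R * xs,
        no.centre[1] + no.radius / R * ys,
        no.centre[2] + no.radius / R * zs,
        color=NUCLEOLUS_COLOUR[:3],
        alpha=NUCLEOLUS_COLOUR[3],
        linewidth=0,
    )

    pts, sizes, cols = [], [], []
    # marker area in points^2, scaled so a bead's disc roughly matches its radius
    pt_per_nm = 0.72 * fig.dpi * 6 / (2.2 * R)
    for pos, radius, rgba in _scene_records(model, scheme):
        if rgba[3] == 0.0:
            continue
        pts.append(pos)
        sizes.append((radius * pt_per_nm) ** 2)
        cols.append(rgba)
    if pts:
        pts = np.array(pts)
        order = np.argsort(pts[:, 2])  # painter's order for a fixed view
        ax.scatter(
            pts[order, 0], pts[order, 1], pts[order, 2],
            s=np.array(sizes)[order], c=np.array(cols)[order],
            edgecolors="0.4", linewidths=0.2, depthshade=True,
        )
    ax.view_init(elev=elev, azim=azim)
    ax.set_box_aspect((1, 1, 1))
    lim = 1.05 * R
    ax.set_xlim(-lim, lim); ax.set_ylim(-lim, lim); ax.set_zlim(-lim, lim)
    ax.set_axis_off()
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path


def export_scene(model: NucleusModel, scheme: ColourScheme, path: str | Path) -> Path:
    """Write the coloured scene as a flat TSV: label, x, y, z, radius, r, g, b, a.

    One record per bead plus one for the nucleolus; coordinates in nm,
    colour channels in [0, 1].
    """
    path = Path(path)
    rows = ["label\tx\ty\tz\tradius\tr\tg\tb\ta"]
    no = model.nucleolus
    rows.append(
        "nucleolus\t"
        + "\t".join(repr(float(v)) for v in (*no.centre, no.radius, *NUCLEOLUS_COLOUR))
    )
    scheme.validate_against(model)
    for b in model.beads:
        rgba = scheme.colour_of(b.chromosome, b.arm)
        rows.append(
            f"C{b.chromosome}{b.arm[0]}\t"
            + "\t".join(repr(float(v)) for v in (*b.position, b.radius, *rgba))
        )
    path.write_text("\n".join(rows) + "\n")
    return path
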
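"""Drawing logos onto matplotlib axes.

:func:`render_logo` turns a validated position-by-character matrix into
filled vector paths on a standard Axes, so logos compose with ordinary
matplotlib figures (subplots, annotations, saved SVG/PDF/PNG).  It
returns a :class:`~logoplot.layout.LogoLayout` describing exactly what
was drawn, which is the object tests and per-glyph styling operate on.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from matplotlib.axes import Axes
from matplotlib.patches import PathPatch, Rectangle

from .alignment import infer_alphabet
from .colors import default_scheme_for, get_color_scheme
from .errors import (
    GlyphLookupError,
    HighlightRangeError,
    RenderError,
    SemanticTypeError,
)
from .glyphs import GlyphSpec, glyph_path
from .layout import HighlightSpec, LogoLayout, LogoStyle, layout_position
from .matrix import PositionCharacterMatrix, validate_matrix

_Z_HIGHLIGHT = 0.5
_Z_BASELINE = 1.0
_Z_GLYPH = 2.0


def apply_fade(table: PositionCharacterMatrix) -> pd.DataFrame:
    """Per-cell opacity for a probability logo: alpha(i, c) = p[i, c].

    The identity mapping (clipped to [0, 1]): certain characters are
    opaque, impossible ones invisible.  Only probability matrices may be
    faded.
    """
    if table.matrix_type != "probability":
        raise SemanticTypeError(
            "fade_probabilities requires a probability matrix, got "
            f"{table.matrix_type!r}"
        )
    return table.df.clip(lower=0.0, upper=1.0)


def _resolve_colors(table: PositionCharacterMatrix, style: LogoStyle):
    scheme = style.color_scheme
    if scheme is None:
        scheme = default_scheme_for(infer_alphabet(table.characters))
    return get_color_scheme(scheme, table.characters)


def compute_layout(
    table: PositionCharacterMatrix, style: LogoStyle | None = None
) -> LogoLayout:
    """Lay out a whole matrix without drawing anything.

    Pure geometry: the same layout :func:`render_logo` would draw, minus
    the matplotlib artists.  Deterministic: equal inputs give equal
    layouts.
    """
    style = style or LogoStyle()
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise RenderError("cannot lay out an empty matrix")
    validate_matrix(table)

    arr = table.values
    if style.flip_below is None:
        resolved_flip = bool((arr < 0).any())
    else:
        resolved_flip = style.flip_below

    colors = _resolve_colors(table, style)
    alphas_df = apply_fade(table) if style.fade_probabilities else None

    layout = LogoLayout(baseline_width=style.baseline_width)
    layout.position_labels = tuple(table.positions)

    floors, ceilings = [], []
    for pos, row in zip(table.positions, arr):
        values = dict(zip(table.characters, row))
        alphas = (
            dict(zip(table.characters, alphas_df.loc[pos]))
            if alphas_df is not None
            else None
        )
        pos_style = style if style.flip_below is not None else _with_flip(style, resolved_flip)
        for g in layout_position(values, pos, pos_style, colors=colors, alphas=alphas):
            layout.glyphs[(pos, g.character)] = g
            floors.append(g.floor)
            ceilings.append(g.ceiling)

    first, last = table.positions[0], table.positions[-1]
    layout.xlim = (first - 0.5, last + 0.5)
    ymin = min(0.0, min(floors)) if floors else 0.0
    ymax = max(ceilings) if ceilings else 1.0
    if ymax <= ymin:
        ymax = ymin + 1.0
    margin = 0.05 * (ymax - ymin)
    layout.ylim = (ymin - (margin if ymin < 0 else 0.0), ymax + margin)

    for start, end, color, alpha in style.highlights:
        _add_highlight(layout, start, end, color, alpha)
    return layout


def _with_flip(style: LogoStyle, flip: bool) -> LogoStyle:
    import dataclasses

    return dataclasses.replace(style, flip_below=flip)


def render_logo(
    table: PositionCharacterMatrix,
    style: LogoStyle | None = None,
    ax: Axes | None = None,
) -> LogoLayout:
    """Draw a logo onto ``ax`` (a new figure's axes if None).

    Highlight rectangles go behind the glyphs, a baseline is drawn at
    y = 0, the x-axis spans ``[first_pos - 0.5, last_pos + 0.5]`` and the
    y-axis covers the full stack range with a 5% margin.  Only the given
    axes is touched, so logos drop into sub-panels of larger figures
    without disturbing their siblings.
    """
    style = style or LogoStyle()
    layout = compute_layout(table, style)

    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(max(2.0, 0.5 * len(table)), 2.5))
    layout.ax = ax

    for h in layout.highlights:
        _draw_highlight(ax, h, layout)
    if style.baseline_width > 0:
        ax.axhline(0, color="black", linewidth=style.baseline_width, zorder=_Z_BASELINE)
    for key, spec in layout.glyphs.items():
        layout.patches[key] = _draw_glyph(ax, spec)

    ax.set_xlim(*layout.xlim)
    ax.set_ylim(*layout.ylim)
    return layout


def _draw_glyph(ax: Axes, spec: GlyphSpec) -> PathPatch:
    patch = PathPatch(
        glyph_path(spec),
        facecolor=spec.color,
        edgecolor=spec.edge_color if spec.edge_width > 0 else "none",
        linewidth=spec.edge_width,
        zorder=_Z_GLYPH,
    )
    ax.add_patch(patch)
    return patch


def _add_highlight(layout, start_pos, end_pos, color, alpha) -> HighlightSpec:
    labels = getattr(layout, "position_labels", ())
    if start_pos > end_pos:
        raise HighlightRangeError(
            f"highlight start {start_pos} exceeds end {end_pos}"
        )
    for p in (start_pos, end_pos):
        if labels and p not in labels:
            raise HighlightRangeError(
                f"highlight position {p} is not among the matrix positions "
                f"[{labels[0]} .. {labels[-1]}]"
            )
    from matplotlib.colors import to_rgba

    h = HighlightSpec(start_pos, end_pos, to_rgba(color), float(alpha))
    layout.highlights.append(h)
    return h


def _draw_highlight(ax: Axes, h: HighlightSpec, layout: LogoLayout) -> Rectangle:
    y0, y1 = layout.ylim
    rect = Rectangle(
        (h.xmin, y0),
        h.xmax - h.xmin,
        y1 - y0,
        facecolor=h.color,
        alpha=h.alpha,
        edgecolor="none",
        zorder=_Z_HIGHLIGHT,
    )
    ax.add_patch(rect)
    return rect


def highlight_interval(
    layout: LogoLayout,
    start_pos: int,
    end_pos: int,
    color="gold",
    alpha: float = 0.3,
) -> HighlightSpec:
    """Add a highlight rectangle spanning the closed position interval.

    The rectangle covers ``[start_pos - 0.5, end_pos + 0.5]`` over the
    full y-range and sits behind the glyphs.  Drawn immediately if the
    layout is attached to an axes.
    """
    h = _add_highlight(layout, start_pos, end_pos, color, alpha)
    if layout.ax is not None:
        _draw_highlight(layout.ax, h, layout)
    return h


def style_single_glyph(
    layout: LogoLayout, position: int, character: str, **overrides
) -> LogoLayout:
    """Restyle one glyph in place; its geometry is untouched.

    Style fields: ``color``, ``flip``, ``font_name``, ``edge_width``,
    ``edge_color``.  Colors may be any matplotlib color spec.  If the
    layout has been drawn, the corresponding patch is updated too.
    """
    key = (position, character)
    if key not in layout.glyphs:
        raise GlyphLookupError(
            f"no glyph for character {character!r} at position {position}"
        )
    if not overrides:
        return layout
    if "color" in overrides:
        from matplotlib.colors import to_rgba

        overrides["color"] = to_rgba(overrides["color"])
    if "edge_color" in overrides:
        from matplotlib.colors import to_rgba

        overrides["edge_color"] = to_rgba(overrides["edge_color"])
    old = layout.glyphs[key]
    new = old.with_style(**overrides)
    layout.glyphs[key] = new

    patch = layout.patches.get(key)
    if patch is not None:
        if new.flip != old.flip or new.font_name != old.font_name:
            patch.set_path(glyph_path(new))
        patch.set_facecolor(new.color)
        patch.set_linewidth(new.edge_width)
        patch.set_edgecolor(new.edge_color if new.edge_width > 0 else "none")
    return layout
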